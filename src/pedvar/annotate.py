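"""Transcript models and coding-consequence annotation with HGVS c./p. naming.

A :class:`TranscriptModel` is a minimal gene model: exons and CDS intervals
in genomic coordinates plus the spliced coding sequence in transcript
orientation.  :func:`annotate_consequence` maps a genomic SNV or short indel
into CDS space, translates the affected codon with the standard genetic
code, and emits HGVS-style coding (``c.127G>A``, ``c.295+4C>A``) and protein
(``p.Gly43Arg``) names.  Minus-strand transcripts are handled by working
throughout in transcript orientation, so a minus-strand variant and its
plus-strand mirror produce identical HGVS strings.

Intronic positions within ``splice_window`` bases of an exon junction are
classified ``splice_region`` (default window 8 nt, wide enough to treat a
donor+4 variant as splice-relevant); deeper intronic positions are
``intronic``.  Indel protein-level names are simplified (``fs``/``del``
forms without downstream ter prediction).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

CdnaPos = Union[int, Tuple[Union[int, str], int]]  # plain CDS pos, or (anchor, offset)


class AnnotationError(ValueError):
    """Variant/transcript combination that cannot be annotated."""


@dataclass
class TranscriptModel:
    gene: str
    chrom: str
    strand: str  # '+' or '-'
    exons: List[Tuple[int, int]]  # 1-based closed genomic intervals, ascending
    cds_intervals: List[Tuple[int, int]]  # subset of exon space, ascending
    coding_sequence: str  # spliced CDS in transcript orientation

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        for name, ivs in (("exons", self.exons), ("cds_intervals", self.cds_intervals)):
            prev_end = 0
            for s, e in ivs:
                if s > e or s <= prev_end:
                    raise ValueError(f"{name} must be sorted, non-overlapping 1-based intervals")
                prev_end = e
        span = sum(e - s + 1 for s, e in self.cds_intervals)
        if span != len(self.coding_sequence):
            raise AnnotationError(
                f"{self.gene}: coding_sequence length {len(self.coding_sequence)} "
                f"does not match CDS span {span}"
            )
        if span % 3 != 0:
            raise AnnotationError(f"{self.gene}: CDS length {span} not divisible by 3")
        cds = self.coding_sequence.upper()
        if not cds.startswith("ATG"):
            warnings.warn(f"{self.gene}: CDS does not start with ATG", stacklevel=2)
        if str(Seq(cds[-3:]).translate()) != "*":
            warnings.warn(f"{self.gene}: CDS does not end with a stop codon", stacklevel=2)

    # -- coordinate maps ----------------------------------------------------
    def _genomic_order(self, positions: List[int]) -> List[int]:
        return positions if self.strand == "+" else positions[::-1]

    def exonic_positions(self) -> List[int]:
        """All exonic genomic positions in transcript (5'->3') order."""
        pos = [p for s, e in self.exons for p in range(s, e + 1)]
        return self._genomic_order(pos)

    def cds_positions(self) -> List[int]:
        pos = [p for s, e in self.cds_intervals for p in range(s, e + 1)]
        return self._genomic_order(pos)

    def cds_to_genomic(self, cpos: int) -> int:
        cds = self.cds_positions()
        if not 1 <= cpos <= len(cds):
            raise AnnotationError(f"c.{cpos} outside CDS of length {len(cds)}")
        return cds[cpos - 1]

    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def protein_length(self) -> int:
        return len(self.coding_sequence) // 3 - 1  # excluding the stop


@dataclass
class ConsequenceAnnotation:
    cdna_pos: CdnaPos
    codon_index: Optional[int]
    codon_position: Optional[int]
    ref_aa: Optional[str]
    alt_aa: Optional[str]
    consequence: str
    hgvs_c: str
    hgvs_p: Optional[str]


_COMPL = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPL)[::-1]


def _tx_allele(allele: str, strand: str) -> str:
    return allele.upper() if strand == "+" else revcomp(allele.upper())


def _c_label(r: int, cds_first_r: int, cds_last_r: int) -> Union[int, str]:
    """Transcript (r.) position -> CDS-relative label: int, '-N' (5'UTR) or '*N'."""
    if r < cds_first_r:
        return f"-{cds_first_r - r}"
    if r > cds_last_r:
        return f"*{r - cds_last_r}"
    return r - cds_first_r + 1


def annotate_consequence(
    variant, transcript: TranscriptModel, *, splice_window: int = 8, flank: int = 1000
) -> ConsequenceAnnotation:
    """Annotate one variant (``chrom``, ``pos``, ``ref``, ``alt``) on a transcript."""
    if getattr(variant, "chrom", None) not in (None, transcript.chrom):
        raise AnnotationError(
            f"variant on {variant.chrom} does not match transcript on {transcript.chrom}"
        )
    pos, ref, alt = variant.pos, variant.ref.upper(), variant.alt.upper()
    if ref == alt:
        raise AnnotationError("ref and alt alleles are identical")
    lo, hi = transcript.span()
    if not (lo - flank) <= pos <= (hi + flank):
        raise AnnotationError(
            f"position {pos} outside transcript {transcript.gene} span {lo}-{hi} (+/-{flank})"
        )

    exonic = transcript.exonic_positions()
    r_of = {p: i + 1 for i, p in enumerate(exonic)}
    cds_genomic = transcript.cds_positions()
    cds_first_r = r_of[cds_genomic[0]]
    cds_last_r = r_of[cds_genomic[-1]]

    if pos in r_of:
        label = _c_label(r_of[pos], cds_first_r, cds_last_r)
        if isinstance(label, int):
            if len(ref) == 1 and len(alt) == 1:
                return _annotate_coding_snv(transcript, label, ref, alt)
            return _annotate_indel(transcript, label, ref, alt)
        # UTR position
        tref, talt = _tx_allele(ref, transcript.strand), _tx_allele(alt, transcript.strand)
        return ConsequenceAnnotation(
            cdna_pos=(label, 0),
            codon_index=None,
            codon_position=None,
            ref_aa=None,
            alt_aa=None,
            consequence="utr",
            hgvs_c=f"c.{label}{tref}>{talt}",
            hgvs_p=None,
        )
    return _annotate_intronic(transcript, pos, ref, alt, splice_window, cds_first_r, cds_last_r, r_of)


def _annotate_coding_snv(t: TranscriptModel, c: int, ref: str, alt: str) -> ConsequenceAnnotation:
    cds = t.coding_sequence.upper()
    tref, talt = _tx_allele(ref, t.strand), _tx_allele(alt, t.strand)
    if cds[c - 1] != tref:
        raise AnnotationError(
            f"{t.gene}: reference allele {tref!r} does not match CDS base {cds[c - 1]!r} at c.{c}"
        )
    codon_index = (c - 1) // 3 + 1
    codon_position = (c - 1) % 3 + 1
    codon = cds[3 * (codon_index - 1) : 3 * codon_index]
    alt_codon = codon[: codon_position - 1] + talt + codon[codon_position:]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    ref3, alt3 = seq3(ref_aa), seq3(alt_aa)
    if ref_aa == alt_aa:
        consequence = "synonymous"
        hgvs_p = f"p.({ref3}{codon_index}=)"
    elif alt_aa == "*":
        consequence = "stop_gain"
        hgvs_p = f"p.{ref3}{codon_index}Ter"
    elif ref_aa == "*":
        consequence = "stop_loss"
        hgvs_p = f"p.Ter{codon_index}{alt3}"
    else:
        consequence = "missense"
        hgvs_p = f"p.{ref3}{codon_index}{alt3}"
    return ConsequenceAnnotation(
        cdna_pos=c,
        codon_index=codon_index,
        codon_position=codon_position,
        ref_aa=ref3,
        alt_aa=alt3,
        consequence=consequence,
        hgvs_c=f"c.{c}{tref}>{talt}",
        hgvs_p=hgvs_p,
    )


def _annotate_indel(t: TranscriptModel, c: int, ref: str, alt: str) -> ConsequenceAnnotation:
    delta = len(alt) - len(ref)
    if delta == 0:
        raise AnnotationError("multi-nucleotide substitutions are not supported")
    codon_index = (c - 1) // 3 + 1
    ref3 = seq3(str(Seq(t.coding_sequence[3 * (codon_index - 1) : 3 * codon_index]).translate()))
    if delta % 3 != 0:
        consequence = "frameshift"
        hgvs_p = f"p.({ref3}{codon_index}fs)"
    else:
        consequence = "inframe_indel"
        hgvs_p = f"p.({ref3}{codon_index}del)" if delta < 0 else f"p.({ref3}{codon_index}ins)"
    n = abs(delta)
    if delta < 0:
        hgvs_c = f"c.{c + 1}_{c + n}del" if n > 1 else f"c.{c + 1}del"
    else:
        ins = _tx_allele(alt[1:], t.strand)
        hgvs_c = f"c.{c}_{c + 1}ins{ins}"
    return ConsequenceAnnotation(
        cdna_pos=c,
        codon_index=codon_index,
        codon_position=None,
        ref_aa=ref3,
        alt_aa=None,
        consequence=consequence,
        hgvs_c=hgvs_c,
        hgvs_p=hgvs_p,
    )


def _annotate_intronic(t, pos, ref, alt, splice_window, cds_first_r, cds_last_r, r_of):
    intron = None
    for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:]):
        if e1 < pos < s2:
            intron = (e1, s2)
            break
    if intron is None:
        raise AnnotationError(f"position {pos} flanks transcript {t.gene} but is not intronic")
    left_end, right_start = intron
    if t.strand == "+":
        d5, anchor5 = pos - left_end, left_end  # downstream of a donor site
        d3, anchor3 = right_start - pos, right_start
    else:
        d5, anchor5 = right_start - pos, right_start
        d3, anchor3 = pos - left_end, left_end
    if d5 <= d3:
        offset, anchor_g, sign = d5, anchor5, "+"
    else:
        offset, anchor_g, sign = d3, anchor3, "-"
    anchor_label = _c_label(r_of[anchor_g], cds_first_r, cds_last_r)
    tref, talt = _tx_allele(ref, t.strand), _tx_allele(alt, t.strand)
    consequence = "splice_region" if offset <= splice_window else "intronic"
    signed = offset if sign == "+" else -offset
    return ConsequenceAnnotation(
        cdna_pos=(anchor_label, signed),
        codon_index=None,
        codon_position=None,
        ref_aa=None,
        alt_aa=None,
        consequence=consequence,
        hgvs_c=f"c.{anchor_label}{sign}{offset}{tref}>{talt}",
        hgvs_p=None,
    )


# ---------------------------------------------------------------------------
# HGVS c. parsing/formatting (SNVs and intron offsets)

_HGVS_C_RE = re.compile(
    r"^c\.(?P<anchor>\*?\-?\d+)(?:(?P<sign>[+-])(?P<offset>\d+))?(?P<ref>[ACGT])>(?P<alt>[ACGT])$"
)


def parse_hgvs_c(s: str) -> Tuple[CdnaPos, str, str]:
    """Parse ``c.127G>A`` / ``c.295+4C>A`` / ``c.-99C>A`` style names."""
    m = _HGVS_C_RE.match(s.replace(" ", ""))
    if not m:
        raise ValueError(f"cannot parse HGVS c. string {s!r}")
    anchor_s = m.group("anchor")
    anchor: Union[int, str]
    if anchor_s.startswith("*") or anchor_s.startswith("-"):
        anchor = anchor_s
    else:
        anchor = int(anchor_s)
    pos: CdnaPos
    if m.group("sign"):
        off = int(m.group("offset"))
        pos = (anchor, off if m.group("sign") == "+" else -off)
    else:
        pos = anchor
    return pos, m.group("ref"), m.group("alt")


def format_hgvs_c(pos: CdnaPos, ref: str, alt: str) -> str:
    if isinstance(pos, tuple):
        anchor, offset = pos
        if offset == 0:
            return f"c.{anchor}{ref}>{alt}"
        sign = "+" if offset > 0 else "-"
        return f"c.{anchor}{sign}{abs(offset)}{ref}>{alt}"
    return f"c.{pos}{ref}>{alt}"


# ---------------------------------------------------------------------------
# Transcript construction and TSV I/O


def synthetic_transcript(
    gene: str,
    coding_sequence: str,
    exon_lengths: Sequence[int],
    *,
    chrom: str = "1",
    strand: str = "+",
    start: int = 1_000,
    intron_length: int = 300,
) -> TranscriptModel:
    """Lay a coding sequence onto a toy genomic locus.

    ``exon_lengths`` are CDS-exon lengths in transcript order and must sum to
    the CDS length.  Introns get a fixed length.  For minus-strand models the
    genomic exon order is the reverse of the transcript order.
    """
    if sum(exon_lengths) != len(coding_sequence):
        raise ValueError("exon lengths must sum to the CDS length")
    genomic_lengths = list(exon_lengths) if strand == "+" else list(exon_lengths)[::-1]
    exons: List[Tuple[int, int]] = []
    pos = start
    for ln in genomic_lengths:
        exons.append((pos, pos + ln - 1))
        pos += ln + intron_length
    return TranscriptModel(
        gene=gene,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_intervals=list(exons),
        coding_sequence=coding_sequence,
    )


def read_transcripts_tsv(path) -> Dict[str, TranscriptModel]:
    """Read transcript models from the packaged TSV dialect.

    Columns: gene, chrom, strand, exons, cds, coding_sequence; interval lists
    are ``start-end`` pairs joined by ``;``.
    """

    def _ivs(s: str) -> List[Tuple[int, int]]:
        out = []
        for part in s.split(";"):
            a, b = part.split("-")
            out.append((int(a), int(b)))
        return out

    models: Dict[str, TranscriptModel] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene\t"):
                continue
            gene, chrom, strand, exons, cds, seq = line.split("\t")
            models[gene] = TranscriptModel(gene, chrom, strand, _ivs(exons), _ivs(cds), seq)
    return models


def write_transcripts_tsv(models: Dict[str, TranscriptModel], path) -> None:
    def _fmt(ivs):
        return ";".join(f"{s}-{e}" for s, e in ivs)

    with open(path, "w") as fh:
        fh.write("gene\tchrom\tstrand\texons\tcds\tcoding_sequence\n")
        for t in models.values():
            fh.write(
                f"{t.gene}\t{t.chrom}\t{t.strand}\t{_fmt(t.exons)}\t"
                f"{_fmt(t.cds_intervals)}\t{t.coding_sequence}\n"
            )
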