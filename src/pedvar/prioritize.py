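"""Candidate-variant prioritization for a dominant family phenotype.

The cascade mirrors a standard family-exome workflow: keep exonic (and,
optionally, splice-region) variants, keep variants heterozygous in every
sequenced affected member and absent (homozygous reference) in every
sequenced unaffected member, then keep rare functional consequences
(non-synonymous, stop gain/loss, indel, splice region with population
frequency below a threshold or absent entirely).  Each stage's input/output
counts are recorded in a :class:`FilterTrace`.

Consensus ranking counts, per variant, how many external effect predictors
rendered a damaging verdict (the recognised vocabulary being "pathogenic",
"damaging", "probably damaging", "possibly damaging", "disease causing",
"deleterious"); the predictors themselves are not re-implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from Bio import AlignIO

from .annotate import AnnotationError, ConsequenceAnnotation, TranscriptModel, annotate_consequence
from .pedigree import GenotypeVector, Pedigree

REGIONS = ("exonic", "intronic", "splice_region", "utr5", "utr3", "intergenic")
FUNCTIONAL_CONSEQUENCES = frozenset(
    {"missense", "stop_gain", "stop_loss", "stop_retained", "frameshift", "inframe_indel",
     "splice_region"}
)
DAMAGING_VOCABULARY = frozenset(
    {"pathogenic", "damaging", "probably damaging", "possibly damaging", "disease causing", "deleterious"}
)


@dataclass
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    region: str = "exonic"
    af_pop: Optional[float] = None  # None encodes a novel variant
    genotypes: Optional[GenotypeVector] = None
    consequence: Optional[str] = None
    annotation: Optional[ConsequenceAnnotation] = None
    variant_id: str = ""
    damaging_count: Optional[int] = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.pos < 1:
            raise ValueError("pos is 1-based")
        if self.af_pop is not None and not 0.0 <= self.af_pop <= 1.0:
            raise ValueError("af_pop must be a probability when present")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if not self.variant_id:
            self.variant_id = f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def is_novel(self) -> bool:
        return self.af_pop is None


@dataclass
class FilterTrace:
    stages: List[Tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {name!r} output {n_out} exceeds input {n_in}")
        if self.stages and self.stages[-1][2] != n_in:
            raise ValueError(f"stage {name!r} input {n_in} does not chain from previous output")
        self.stages.append((name, n_in, n_out))

    def counts(self) -> List[int]:
        if not self.stages:
            return []
        return [self.stages[0][1]] + [s[2] for s in self.stages]


@dataclass
class PredictionProfile:
    variant_id: str
    verdicts: Dict[str, str]

    @property
    def damaging_count(self) -> int:
        n = 0
        for tool, verdict in self.verdicts.items():
            v = verdict.strip().lower()
            if v in DAMAGING_VOCABULARY:
                n += 1
            elif v not in _BENIGN_VOCABULARY:
                warnings.warn(f"{self.variant_id}: unknown verdict {verdict!r} from {tool}; counted as non-damaging")
        return n


_BENIGN_VOCABULARY = frozenset(
    {"benign", "tolerated", "neutral", "polymorphism", "unknown", "not scored", "-", "low",
     "medium", "none"}
)


# ---------------------------------------------------------------------------
# VCF reading


def read_vcf(path) -> List[VariantRecord]:
    """Read a multi-sample VCF into variant records.

    INFO keys used: GENE, REGION, AF_POP (absent = novel), CSQ (consequence
    class).  Genotypes become per-sample alternate-allele counts; uncalled
    genotypes become missing.
    """
    from cyvcf2 import VCF  # deferred: cyvcf2 import is relatively heavy

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: List[VariantRecord] = []
    for v in vcf:
        alt = v.ALT[0] if v.ALT else "."
        calls: Dict[str, Optional[int]] = {}
        for sample, gt in zip(samples, v.genotypes):
            alleles = [a for a in gt[:-1]]
            if any(a < 0 for a in alleles):
                calls[sample] = None
            else:
                calls[sample] = int(sum(1 for a in alleles if a > 0))
        af = v.INFO.get("AF_POP")
        records.append(
            VariantRecord(
                chrom=str(v.CHROM),
                pos=int(v.POS),
                ref=str(v.REF),
                alt=str(alt),
                gene=v.INFO.get("GENE"),
                region=v.INFO.get("REGION") or "exonic",
                af_pop=float(af) if af is not None else None,
                consequence=v.INFO.get("CSQ"),
                genotypes=GenotypeVector(str(v.ID) if v.ID else f"{v.CHROM}:{v.POS}", calls),
                variant_id=str(v.ID) if v.ID and v.ID != "." else "",
            )
        )
    vcf.close()
    return records


# ---------------------------------------------------------------------------
# Filters


def region_filter(
    records: Iterable[VariantRecord], keep: Sequence[str] = ("exonic", "splice_region")
) -> List[VariantRecord]:
    keep_set = set(keep)
    return [r for r in records if r.region in keep_set]


def inheritance_filter(
    records: Iterable[VariantRecord], ped: Pedigree, sequenced_ids: Iterable[str]
) -> List[VariantRecord]:
    """Dominant sharing: heterozygous in every sequenced affected member and
    homozygous reference in every sequenced unaffected member.

    A missing call in any sequenced member drops the record ("absent" is read
    conservatively as an observed 0, not as no data).
    """
    seq = list(sequenced_ids)
    for iid in seq:
        if iid not in ped:
            raise ValueError(f"sequenced individual {iid!r} not in pedigree")
        if ped[iid].affection == "unknown":
            raise ValueError(f"sequenced individual {iid!r} has unknown affection status")
    affected = [i for i in seq if ped[i].affection == "affected"]
    unaffected = [i for i in seq if ped[i].affection == "unaffected"]
    if not affected:
        raise ValueError("inheritance filter undefined without sequenced affected members")

    out = []
    for r in records:
        if r.genotypes is None:
            continue
        calls = [r.genotypes.call(i) for i in seq]
        if any(c is None for c in calls):
            continue
        if all(r.genotypes.call(i) == 1 for i in affected) and all(
            r.genotypes.call(i) == 0 for i in unaffected
        ):
            out.append(r)
    return out


def functional_rarity_filter(
    records: Iterable[VariantRecord], freq_threshold: float = 0.01
) -> List[VariantRecord]:
    """Keep rare (or novel) variants with a protein- or splice-affecting consequence."""
    out = []
    for r in records:
        if r.consequence is None:
            continue
        if r.consequence not in FUNCTIONAL_CONSEQUENCES:
            continue
        if r.af_pop is not None and r.af_pop >= freq_threshold:
            continue
        out.append(r)
    return out


@dataclass
class CascadeConfig:
    freq_threshold: float = 0.01
    keep_regions: Tuple[str, ...] = ("exonic", "splice_region")
    splice_window: int = 8


def run_cascade(
    vcf_path,
    ped: Pedigree,
    sequenced_ids: Iterable[str],
    transcripts: Optional[Dict[str, TranscriptModel]] = None,
    config: CascadeConfig = CascadeConfig(),
    profiles: Optional[Dict[str, PredictionProfile]] = None,
) -> Tuple[List[VariantRecord], FilterTrace]:
    """Run region -> inheritance -> functional/rarity filtering over a VCF.

    Records lacking a consequence class are annotated against ``transcripts``
    (matched by gene name) when provided.  Candidates are sorted by damaging
    verdict count (desc), novel before known, then gene name.
    """
    records = read_vcf(vcf_path)
    trace = FilterTrace()

    stage1 = region_filter(records, config.keep_regions)
    trace.add("region", len(records), len(stage1))

    stage2 = inheritance_filter(stage1, ped, sequenced_ids) if stage1 else []
    trace.add("inheritance", len(stage1), len(stage2))

    for r in stage2:
        if r.consequence is None and transcripts and r.gene in transcripts:
            try:
                r.annotation = annotate_consequence(
                    r, transcripts[r.gene], splice_window=config.splice_window
                )
                r.consequence = r.annotation.consequence
            except AnnotationError:
                pass
    stage3 = functional_rarity_filter(stage2, config.freq_threshold)
    trace.add("functional_rarity", len(stage2), len(stage3))

    if profiles:
        for r in stage3:
            prof = profiles.get(r.variant_id)
            if prof is not None:
                r.damaging_count = prof.damaging_count

    stage3.sort(
        key=lambda r: (
            -(r.damaging_count if r.damaging_count is not None else -1),
            0 if r.is_novel else 1,
            r.gene or "",
            r.variant_id,
        )
    )
    return stage3, trace


def consensus_rank(profiles: Iterable[PredictionProfile], min_count: int) -> List[str]:
    """Variant ids whose damaging verdict count reaches ``min_count``, most-damaging first."""
    scored = [(p.damaging_count, p.variant_id) for p in profiles]
    return [vid for cnt, vid in sorted(scored, key=lambda t: (-t[0], t[1])) if cnt >= min_count]


# ---------------------------------------------------------------------------
# Conservation


def conservation_score(msa, column: int) -> Tuple[float, str]:
    """Identity fraction and consensus residue of a 1-based alignment column.

    ``msa`` is a Bio.Align.MultipleSeqAlignment or a FASTA path.  Gaps count
    as mismatches to the consensus (but a gap never becomes the consensus
    unless the column is all-gap).
    """
    if not hasattr(msa, "get_alignment_length"):
        msa = AlignIO.read(str(msa), "fasta")
    ncol = msa.get_alignment_length()
    if not 1 <= column <= ncol:
        raise ValueError(f"column {column} out of range 1..{ncol}")
    residues = [str(rec.seq[column - 1]).upper() for rec in msa]
    counts: Dict[str, int] = {}
    for r in residues:
        counts[r] = counts.get(r, 0) + 1
    non_gap = {r: c for r, c in counts.items() if r != "-"}
    pool = non_gap or counts
    consensus = max(sorted(pool), key=lambda r: pool[r])
    return pool[consensus] / len(residues), consensus
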