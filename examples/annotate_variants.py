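"""HGVS-style consequence annotation against synthetic gene models.

The demo transcripts place known coding variants at their published CDS
coordinates: c.127G>A on a minus-strand 8-exon kinase model (codon 43,
Gly->Arg), c.202G>A (codon 68, Ala->Thr), c.4501C>T (codon 1501, Arg->Trp),
plus a splice-region variant 4 nt past the exon-3 donor site.
"""

from pedvar import VariantRecord, annotate_consequence
from pedvar.annotate import revcomp
from pedvar.datasets import demo_transcripts

tx = demo_transcripts()

cases = [("PBK", 127, "G", "A"), ("ANKRD36", 202, "G", "A"), ("SORL1", 4501, "C", "T")]
for gene, cpos, ref, alt in cases:
    t = tx[gene]
    # on a minus-strand model the genomic alleles are the reverse complement
    g_ref, g_alt = (revcomp(ref), revcomp(alt)) if t.strand == "-" else (ref, alt)
    v = VariantRecord(chrom=t.chrom, pos=t.cds_to_genomic(cpos), ref=g_ref, alt=g_alt)
    ann = annotate_consequence(v, t)
    print(f"{gene} ({t.strand} strand): {ann.hgvs_c} -> {ann.hgvs_p} "
          f"[codon {ann.codon_index}, position {ann.codon_position}, {ann.consequence}]")

t = tx["PBK"]
donor = t.cds_to_genomic(295)
pos = donor - 4 if t.strand == "-" else donor + 4
v = VariantRecord(chrom=t.chrom, pos=pos, ref=revcomp("C"), alt=revcomp("A"))
ann = annotate_consequence(v, t)
print(f"PBK intronic: {ann.hgvs_c} [{ann.consequence}]")
print("\nCodon index is ceil(cdna_pos / 3); intronic positions within 8 nt of")
print("an exon junction are reported splice_region with donor+N / acceptor-N offsets.")
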