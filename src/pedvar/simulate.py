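"""Synthetic study inputs with known ground truth.

Generators for (i) multi-generation autosomal-dominant family cohorts with a
planted rare causal heterozygote gene-dropped from a named founder, (ii)
exome-scale multi-sample variant tables around it, (iii) protein multiple
sequence alignments with chosen conserved columns, and (iv) duplicate-spot
antibody-array datasets with planted signaling hits.  Everything is
deterministic given its spec's seed.

The family generator emulates the shape of the study family: a founder
couple, married-in spouses in each later generation, sibships of 2-5, ages
stratified by generation so the youngest generation straddles the 25-year
onset threshold, and affection assigned by penetrance given carrier status
and liability class.  Background variants are drawn independently of
phenotype from a Beta(0.8, 0.8) frequency distribution truncated to
[0.001, 0.5], so both common and borderline-rare variants exercise the
0.01 rarity threshold; novel variants are encoded by an absent AF_POP key.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .linkage import DiseaseModel
from .pedigree import GenotypeVector, Individual, Pedigree, PedigreeError, planted_drop

_GEN_LABELS = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]
_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"


@dataclass(frozen=True)
class PlantedVariant:
    """Descriptor of the planted causal variant."""

    gene: str = "PBK"
    chrom: str = "8"
    pos: int = 1_270_127
    ref: str = "G"
    alt: str = "A"
    cds_pos: int = 127
    founder_id: Optional[str] = None  # default: the first founder
    af_pop: Optional[float] = None  # None = novel


@dataclass(frozen=True)
class CohortSpec:
    n_generations: int = 3
    sibship_size_range: Tuple[int, int] = (2, 5)
    disease_model: DiseaseModel = field(default_factory=DiseaseModel)
    n_variants: int = 20_000
    fraction_exonic: float = 0.4
    common_freq_distribution: Tuple = ("beta", 0.8, 0.8, 0.001, 0.5)
    planted_variant: PlantedVariant = field(default_factory=PlantedVariant)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not 0.0 <= self.fraction_exonic <= 1.0:
            raise ValueError("fraction_exonic must be a probability")
        lo, hi = self.sibship_size_range
        if not 1 <= lo <= hi:
            raise ValueError("sibship_size_range must be an increasing pair of positive ints")


@dataclass(frozen=True)
class ArraySimSpec:
    n_spots: int = 878  # 613 phosphosite-specific + 265 pan-specific antibodies
    n_true_hits: int = 20
    log_fold_change_range: Tuple[float, float] = (1.2, 3.0)  # |log2 FC| of true hits
    duplicate_cv: float = 0.05
    baseline_intensity_distribution: Tuple = ("lognormal", float(np.log(5000.0)), 0.8)
    seed: int = 0

    def __post_init__(self):
        if self.n_true_hits > self.n_spots:
            raise ValueError("n_true_hits cannot exceed n_spots")
        if self.duplicate_cv < 0:
            raise ValueError("duplicate_cv must be >= 0")


@dataclass
class FamilyCohort:
    pedigree: Pedigree
    planted_genotypes: GenotypeVector
    affection: Dict[str, str]
    spec: CohortSpec


# ---------------------------------------------------------------------------
# Family cohort


def _build_pedigree(spec: CohortSpec, rng: np.random.Generator) -> Pedigree:
    lo, hi = spec.sibship_size_range
    members: List[Individual] = []
    top_age = 24.0 + 27.0 * (spec.n_generations - 1)
    founder_f = Individual("I:1", sex="male", age_years=top_age)
    founder_m = Individual("I:2", sex="female", age_years=top_age - 2)
    members += [founder_f, founder_m]
    couples = [("I:1", "I:2")]
    for g in range(2, spec.n_generations + 1):
        label = _GEN_LABELS[g - 1]
        base_age = 24.0 + 27.0 * (spec.n_generations - g)
        next_couples = []
        k = 0
        for father, mother in couples:
            n_kids = int(rng.integers(lo, hi + 1))
            for _ in range(n_kids):
                k += 1
                child_id = f"{label}:{k}"
                sex = "male" if rng.random() < 0.5 else "female"
                age = float(np.round(base_age + rng.uniform(-6.0, 6.0), 1))
                members.append(
                    Individual(child_id, father_id=father, mother_id=mother, sex=sex, age_years=age)
                )
                if g < spec.n_generations:
                    k += 1
                    spouse_id = f"{label}:{k}"
                    spouse_sex = "female" if sex == "male" else "male"
                    members.append(
                        Individual(
                            spouse_id,
                            sex=spouse_sex,
                            age_years=float(np.round(base_age + rng.uniform(-6.0, 6.0), 1)),
                        )
                    )
                    if sex == "male":
                        next_couples.append((child_id, spouse_id))
                    else:
                        next_couples.append((spouse_id, child_id))
        couples = next_couples
    return Pedigree("SIM", members)


def simulate_family_cohort(spec: CohortSpec) -> FamilyCohort:
    """Generate a pedigree, gene-drop the planted variant, assign affection.

    Affection is a Bernoulli draw with the penetrance implied by each
    member's carrier status and liability class (pre-onset members have
    penetrance 0 under the default policy, or the configured reduced value).
    """
    rng = np.random.default_rng(spec.seed)
    ped = _build_pedigree(spec, rng)
    founder_id = spec.planted_variant.founder_id or "I:1"
    if founder_id not in ped:
        raise PedigreeError(f"planted founder {founder_id!r} absent from pedigree")
    genotypes = planted_drop(ped, founder_id, seed=int(rng.integers(2**31 - 1)))

    model = spec.disease_model
    affection: Dict[str, str] = {}
    for m in ped.members:
        count = genotypes.call(m.iid) or 0
        pen = model.penetrance[count]
        if m.age_years is not None and m.age_years < model.onset_age_threshold:
            pen = 0.0 if model.pre_onset_policy == "unknown_phenotype" else pen * model.pre_onset_policy[1]
        m.affection = "affected" if rng.random() < pen else "unaffected"
        affection[m.iid] = m.affection
    return FamilyCohort(pedigree=ped, planted_genotypes=genotypes, affection=affection, spec=spec)


def choose_sequenced_ids(
    cohort: FamilyCohort, n_affected: int = 5, n_unaffected: int = 3
) -> List[str]:
    """Pick exome-sequencing members the way the study did: affected members
    and post-onset unaffected members (pre-onset members are uninformative)."""
    model = cohort.spec.disease_model
    ped = cohort.pedigree

    def post_onset(iid: str) -> bool:
        age = ped[iid].age_years
        return age is None or age >= model.onset_age_threshold

    affected = [i for i in ped.affected_ids() if post_onset(i)][:n_affected]
    unaffected = [i for i in ped.unaffected_ids() if post_onset(i)][:n_unaffected]
    return affected + unaffected


# ---------------------------------------------------------------------------
# Variant table (VCF)


def _truncated_beta(rng, a: float, b: float, lo: float, hi: float, size: int) -> np.ndarray:
    out = np.empty(size)
    need = np.ones(size, dtype=bool)
    while need.any():
        draw = rng.beta(a, b, size=int(need.sum()))
        ok = (draw >= lo) & (draw <= hi)
        idx = np.flatnonzero(need)[ok]
        out[idx] = draw[ok]
        need[idx] = False
    return out


_EXONIC_CSQ = (
    ("missense", 0.55),
    ("synonymous", 0.35),
    ("stop_gain", 0.04),
    ("frameshift", 0.03),
    ("inframe_indel", 0.03),
)
_NONEXONIC_REGIONS = (("intronic", 0.70), ("utr5", 0.10), ("utr3", 0.10), ("splice_region", 0.05), ("intergenic", 0.05))


def _weighted_choice(rng, pairs) -> str:
    names = [p[0] for p in pairs]
    probs = np.array([p[1] for p in pairs])
    return names[int(rng.choice(len(names), p=probs / probs.sum()))]


def write_variant_table(cohort: FamilyCohort, path, sample_ids: Optional[Sequence[str]] = None) -> str:
    """Write a multi-sample VCF 4.2 around the cohort's planted variant.

    The planted record carries the gene-dropped genotypes (heterozygous in
    carriers) and, being novel, no AF_POP key.  The remaining
    ``n_variants - 1`` background records get genotypes drawn per sample
    from Hardy-Weinberg at their own population frequency, independent of
    phenotype.  Returns the planted record's variant id.
    """
    spec = cohort.spec
    rng = np.random.default_rng(spec.seed + 1)  # independent stream from the cohort draw
    samples = list(sample_ids) if sample_ids is not None else cohort.pedigree.ids()
    pv = spec.planted_variant
    planted_id = f"PLANTED_{pv.gene}"

    n_bg = spec.n_variants - 1
    chroms = rng.integers(1, 23, size=n_bg)
    positions = rng.integers(10_000, 100_000_000, size=n_bg)
    exonic = rng.random(n_bg) < spec.fraction_exonic
    novel = rng.random(n_bg) < 0.02
    dist = spec.common_freq_distribution
    if dist[0] != "beta":
        raise ValueError(f"unknown frequency distribution {dist[0]!r}")
    freqs = _truncated_beta(rng, dist[1], dist[2], dist[3], dist[4], n_bg)
    freqs[novel] = 0.001

    rows = []
    for i in range(n_bg):
        if exonic[i]:
            region = "exonic"
            csq = _weighted_choice(rng, _EXONIC_CSQ)
        else:
            region = _weighted_choice(rng, _NONEXONIC_REGIONS)
            csq = region if region in ("splice_region", "intronic") else ("utr" if region.startswith("utr") else "intergenic")
        ref_i = int(rng.integers(4))
        ref = _BASES[ref_i]
        alt = _BASES[int((ref_i + 1 + rng.integers(3)) % 4)]
        if csq == "frameshift":
            ref, alt = ref + _BASES[int(rng.integers(4))], ref
        elif csq == "inframe_indel":
            ref, alt = ref + "".join(_BASES[int(rng.integers(4))] for _ in range(3)), ref
        gts = rng.binomial(2, freqs[i], size=len(samples))
        rows.append(
            (
                int(chroms[i]),
                int(positions[i]),
                f"BG{i + 1:06d}",
                ref,
                alt,
                f"G{int(chroms[i]):02d}{int(positions[i]) % 997:03d}",
                region,
                csq,
                None if novel[i] else float(freqs[i]),
                gts,
            )
        )
    planted_gts = np.array([cohort.planted_genotypes.call(s) or 0 for s in samples])
    rows.append(
        (
            int(pv.chrom) if pv.chrom.isdigit() else 99,
            pv.pos,
            planted_id,
            pv.ref,
            pv.alt,
            pv.gene,
            "exonic",
            "missense",
            pv.af_pop,
            planted_gts,
        )
    )
    rows.sort(key=lambda r: (r[0], r[1], r[2]))

    missing_mask = None
    if spec.missing_rate > 0:
        missing_mask = rng.random((len(rows), len(samples))) < spec.missing_rate

    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted({r[0] for r in rows}):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene name">\n')
        fh.write('##INFO=<ID=REGION,Number=1,Type=String,Description="Genomic region class">\n')
        fh.write('##INFO=<ID=AF_POP,Number=1,Type=Float,Description="Population allele frequency">\n')
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j, (chrom, pos, vid, ref, alt, gene, region, csq, af, gts) in enumerate(rows):
            info = f"GENE={gene};REGION={region};CSQ={csq}"
            if af is not None:
                info += f";AF_POP={af:.6g}"
            cells = []
            for s_idx, g in enumerate(gts):
                if missing_mask is not None and missing_mask[j, s_idx]:
                    cells.append("./.")
                else:
                    cells.append(gt_str[int(g)])
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t" + "\t".join(cells) + "\n")
    return planted_id


# ---------------------------------------------------------------------------
# Multiple sequence alignment


def generate_msa(
    n_species: int, n_columns: int, conserved_columns: Iterable[int], seed: int
) -> MultipleSeqAlignment:
    """Protein MSA in which the given 1-based columns are perfectly conserved
    and every other column is drawn uniformly over the 20 residues per species."""
    conserved = set(conserved_columns)
    bad = [c for c in conserved if not 1 <= c <= n_columns]
    if bad:
        raise ValueError(f"conserved columns out of range: {bad}")
    rng = np.random.default_rng(seed)
    consensus = {c: _AMINO_ACIDS[int(rng.integers(20))] for c in sorted(conserved)}
    records = []
    for s in range(n_species):
        chars = [
            consensus[c + 1] if (c + 1) in consensus else _AMINO_ACIDS[int(rng.integers(20))]
            for c in range(n_columns)
        ]
        records.append(SeqRecord(Seq("".join(chars)), id=f"species_{s + 1:02d}", description=""))
    return MultipleSeqAlignment(records)


# ---------------------------------------------------------------------------
# Antibody-array dataset


def generate_array_dataset(spec: ArraySimSpec) -> Tuple[pd.DataFrame, List[Tuple[str, str]]]:
    """Raw duplicate spot intensities for two samples plus the true-hit list.

    True hits get a treatment/control ratio of 2**(+/-u) with u uniform in
    ``log_fold_change_range``; duplicates are jittered multiplicatively with
    the given coefficient of variation.  Returns a tidy table (columns
    target, phospho_site, sample, replicate, intensity) and the ground-truth
    (target, phospho_site) list.
    """
    rng = np.random.default_rng(spec.seed)
    kind, mu, sigma = spec.baseline_intensity_distribution
    if kind != "lognormal":
        raise ValueError(f"unknown baseline distribution {kind!r}")
    baselines = np.exp(rng.normal(mu, sigma, size=spec.n_spots))
    hit_idx = set(rng.choice(spec.n_spots, size=spec.n_true_hits, replace=False).tolist())
    lo, hi = spec.log_fold_change_range

    rows = []
    truth: List[Tuple[str, str]] = []
    for i in range(spec.n_spots):
        target = f"AB{i + 1:04d}"
        site = "Pan-specific" if i % 3 == 0 else f"S{100 + i}"
        ratio = 1.0
        if i in hit_idx:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            ratio = 2.0 ** (sign * rng.uniform(lo, hi))
            truth.append((target, site))
        control = baselines[i]
        treatment = baselines[i] * ratio
        for sample, level in (("control", control), ("treatment", treatment)):
            for rep in (1, 2):
                jitter = np.exp(rng.normal(0.0, spec.duplicate_cv)) if spec.duplicate_cv > 0 else 1.0
                rows.append(
                    {
                        "target": target,
                        "phospho_site": site,
                        "sample": sample,
                        "replicate": rep,
                        "intensity": float(level * jitter),
                    }
                )
    return pd.DataFrame(rows), truth
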