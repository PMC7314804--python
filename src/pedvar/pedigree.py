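"""Pedigree representation, PED I/O, validation, obligate-carrier deduction,
and gene-dropping genotype simulation.

The PED dialect is the standard whitespace-delimited 6-column file
(family, individual, father, mother, sex, phenotype) with two optional
extensions used throughout this package:

* column 7 - age in years (``.`` when unknown), needed because the disease
  model treats members younger than the onset threshold as a separate
  liability class;
* column 8 - monozygotic-twin group label (``.`` when not an MZ twin).
  Unlabelled twins are treated as dizygotic, i.e. independent meioses.

Sex is coded 1=male, 2=female, 0=unknown; phenotype 1=unaffected,
2=affected, 0 or -9=unknown.  Missing parents are coded 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

MISSING = None  # missing genotype call

_SEX_IN = {"1": "male", "2": "female", "0": "unknown"}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}
_AFF_IN = {"1": "unaffected", "2": "affected", "0": "unknown", "-9": "unknown"}
_AFF_OUT = {"unaffected": "1", "affected": "2", "unknown": "0"}


class PedigreeError(ValueError):
    """Malformed PED input or an operation on an invalid pedigree."""


@dataclass
class Individual:
    iid: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = "unknown"
    affection: str = "unknown"
    age_years: Optional[float] = None
    mz_twin_group: Optional[str] = None

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Violation:
    individual_id: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.individual_id}: {self.message}"


@dataclass
class GenotypeVector:
    """Alternate-allele counts (0/1/2, or None for missing) per individual."""

    variant_id: str
    calls: Dict[str, Optional[int]]

    def __post_init__(self):
        for iid, call in self.calls.items():
            if call is not None and call not in (0, 1, 2):
                raise ValueError(f"genotype call for {iid!r} must be 0, 1, 2 or None")

    def call(self, iid: str) -> Optional[int]:
        return self.calls.get(iid, MISSING)


class Pedigree:
    """An ordered collection of individuals forming one family."""

    def __init__(self, family_id: str, members: List[Individual]):
        self.family_id = family_id
        self.members: List[Individual] = list(members)
        self._by_id: Dict[str, Individual] = {}
        for m in self.members:
            # duplicates are reported by validate_pedigree; keep first
            self._by_id.setdefault(m.iid, m)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, iid: str) -> bool:
        return iid in self._by_id

    def __getitem__(self, iid: str) -> Individual:
        return self._by_id[iid]

    def ids(self) -> List[str]:
        return [m.iid for m in self.members]

    def founders(self) -> List[Individual]:
        return [m for m in self.members if m.is_founder]

    def nonfounders(self) -> List[Individual]:
        return [m for m in self.members if not m.is_founder]

    def affected_ids(self) -> List[str]:
        return [m.iid for m in self.members if m.affection == "affected"]

    def unaffected_ids(self) -> List[str]:
        return [m.iid for m in self.members if m.affection == "unaffected"]

    def children_of(self, iid: str) -> List[Individual]:
        return [m for m in self.members if iid in (m.father_id, m.mother_id)]

    def depth(self, iid: str) -> int:
        """Longest founder-to-individual path length (founders have depth 0)."""
        seen: Set[str] = set()

        def rec(i: str) -> int:
            if i in seen:  # cycle guard; cycles are reported by validation
                return 0
            seen.add(i)
            ind = self._by_id[i]
            parents = [p for p in (ind.father_id, ind.mother_id) if p in self._by_id]
            d = 1 + max((rec(p) for p in parents), default=-1)
            seen.discard(i)
            return d

        return rec(iid)

    def topological_ids(self) -> List[str]:
        """Member ids with every parent before its children."""
        return sorted(self.ids(), key=lambda i: (self.depth(i), i))


# ---------------------------------------------------------------------------
# I/O


def read_ped(path) -> Pedigree:
    """Read a single family from an extended PED file (see module docstring)."""
    members: List[Individual] = []
    family_id: Optional[str] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(f"{path}:{lineno}: expected >= 6 columns, got {len(fields)}")
            fam, iid, fid, mid, sex, phen = fields[:6]
            if family_id is None:
                family_id = fam
            elif fam != family_id:
                raise PedigreeError(f"{path}:{lineno}: multiple family ids ({family_id!r}, {fam!r})")
            if sex not in _SEX_IN:
                raise PedigreeError(f"{path}:{lineno}: bad sex code {sex!r}")
            if phen not in _AFF_IN:
                raise PedigreeError(f"{path}:{lineno}: bad phenotype code {phen!r}")
            age: Optional[float] = None
            if len(fields) >= 7 and fields[6] not in (".", "-9"):
                try:
                    age = float(fields[6])
                except ValueError as exc:
                    raise PedigreeError(f"{path}:{lineno}: bad age {fields[6]!r}") from exc
                if age < 0:
                    raise PedigreeError(f"{path}:{lineno}: negative age {age}")
            twin = None
            if len(fields) >= 8 and fields[7] not in (".", "0"):
                twin = fields[7]
            members.append(
                Individual(
                    iid=iid,
                    father_id=None if fid == "0" else fid,
                    mother_id=None if mid == "0" else mid,
                    sex=_SEX_IN[sex],
                    affection=_AFF_IN[phen],
                    age_years=age,
                    mz_twin_group=twin,
                )
            )
    if not members:
        raise PedigreeError(f"{path}: no individuals found")
    ped = Pedigree(family_id or "FAM", members)
    violations = validate_pedigree(ped)
    if violations:
        msgs = "; ".join(str(v) for v in violations)
        raise PedigreeError(f"{path}: invalid pedigree: {msgs}")
    return ped


def write_ped(ped: Pedigree, path) -> None:
    """Write the same extended dialect that :func:`read_ped` accepts."""
    with open(path, "w") as fh:
        for m in ped.members:
            age = "." if m.age_years is None else f"{m.age_years:g}"
            twin = m.mz_twin_group or "."
            fh.write(
                "\t".join(
                    [
                        ped.family_id,
                        m.iid,
                        m.father_id or "0",
                        m.mother_id or "0",
                        _SEX_OUT[m.sex],
                        _AFF_OUT[m.affection],
                        age,
                        twin,
                    ]
                )
                + "\n"
            )


def read_genotypes(path) -> Dict[str, GenotypeVector]:
    """Read a genotype TSV (individual_id, variant_id, call) into vectors.

    Calls are alternate-allele counts; ``.`` or ``-1`` denote missing.
    """
    calls: Dict[str, Dict[str, Optional[int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("individual"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise PedigreeError(f"{path}:{lineno}: expected 3 columns")
            iid, vid, raw = parts
            call: Optional[int]
            if raw in (".", "-1"):
                call = None
            else:
                call = int(raw)
            calls.setdefault(vid, {})[iid] = call
    return {vid: GenotypeVector(vid, c) for vid, c in calls.items()}


# ---------------------------------------------------------------------------
# Validation


def validate_pedigree(ped: Pedigree) -> List[Violation]:
    """Check structural invariants; violations are returned, never raised."""
    out: List[Violation] = []
    seen: Set[str] = set()
    for m in ped.members:
        if m.iid in seen:
            out.append(Violation(m.iid, "unique-id", "duplicate individual id"))
        seen.add(m.iid)

    for m in ped.members:
        if (m.father_id is None) != (m.mother_id is None):
            out.append(Violation(m.iid, "parent-pair", "exactly one parent recorded; need both or neither"))
        for ref, label in ((m.father_id, "father"), (m.mother_id, "mother")):
            if ref is not None and ref not in ped:
                out.append(Violation(m.iid, "dangling-parent", f"{label} {ref!r} not in pedigree"))
        if m.father_id is not None and m.father_id in ped and ped[m.father_id].sex == "female":
            out.append(Violation(m.iid, "sex-consistency", f"father {m.father_id!r} is female"))
        if m.mother_id is not None and m.mother_id in ped and ped[m.mother_id].sex == "male":
            out.append(Violation(m.iid, "sex-consistency", f"mother {m.mother_id!r} is male"))
        if not m.is_founder and m.sex == "unknown":
            out.append(Violation(m.iid, "sex-known", "unknown sex permitted for founders only"))
        if m.age_years is not None and m.age_years < 0:
            out.append(Violation(m.iid, "age", "negative age"))

    # cycles (an individual being its own ancestor)
    state: Dict[str, int] = {}

    def has_cycle(iid: str) -> bool:
        st = state.get(iid, 0)
        if st == 1:
            return True
        if st == 2:
            return False
        state[iid] = 1
        ind = ped[iid]
        for p in (ind.father_id, ind.mother_id):
            if p is not None and p in ped and has_cycle(p):
                state[iid] = 2
                return True
        state[iid] = 2
        return False

    for m in ped.members:
        if state.get(m.iid, 0) == 0 and has_cycle(m.iid):
            out.append(Violation(m.iid, "acyclic", "individual is its own ancestor"))

    # MZ twin groups share both parents and sex
    groups: Dict[str, List[Individual]] = {}
    for m in ped.members:
        if m.mz_twin_group:
            groups.setdefault(m.mz_twin_group, []).append(m)
    for label, twins in groups.items():
        parents = {(t.father_id, t.mother_id) for t in twins}
        sexes = {t.sex for t in twins}
        if len(parents) > 1:
            out.append(Violation(twins[0].iid, "mz-parents", f"MZ group {label!r} members differ in parents"))
        if len(sexes) > 1:
            out.append(Violation(twins[0].iid, "mz-sex", f"MZ group {label!r} members differ in sex"))
    return out


# ---------------------------------------------------------------------------
# Obligate-carrier deduction


def infer_obligate_carriers(ped: Pedigree, g: GenotypeVector) -> Set[str]:
    """Deduce ungenotyped carriers forced by their offsprings' genotypes.

    An ungenotyped individual is returned iff at least two distinct offspring
    each carry the alternate allele while the offspring's *other* parent is
    genotyped homozygous reference.  Requiring two such offspring excludes a
    de novo event in a single child; requiring the spouse to be typed 0
    pins the transmitting parent.  Genotyped individuals are never returned.
    """
    for iid in g.calls:
        if iid not in ped:
            raise PedigreeError(f"genotype for unknown individual {iid!r}")
    if not g.calls:
        raise PedigreeError("genotype vector covers no member")

    inferred: Set[str] = set()
    for m in ped.members:
        if g.call(m.iid) is not None:
            continue  # genotyped (even as 0): nothing to infer
        supporting = 0
        for child in ped.children_of(m.iid):
            call = g.call(child.iid)
            if call is None or call < 1:
                continue
            other = child.mother_id if child.father_id == m.iid else child.father_id
            if other is not None and g.call(other) == 0:
                supporting += 1
        if supporting >= 2:
            inferred.add(m.iid)
    return inferred


# ---------------------------------------------------------------------------
# Gene dropping


def gene_drop(ped: Pedigree, founder_alt_freq: float, seed: int) -> GenotypeVector:
    """Simulate a biallelic genotype down the pedigree.

    Founder alleles are i.i.d. Bernoulli(founder_alt_freq) (Hardy-Weinberg);
    each non-founder receives one uniformly chosen allele from each parent.
    Members of an MZ twin group share a single pair of meioses.  Deterministic
    given the seed.
    """
    if not 0.0 <= founder_alt_freq <= 1.0:
        raise ValueError("founder_alt_freq must be a probability")
    rng = np.random.default_rng(seed)
    alleles: Dict[str, Tuple[int, int]] = {}
    twin_draw: Dict[str, Tuple[int, int]] = {}
    for iid in ped.topological_ids():
        m = ped[iid]
        if m.mz_twin_group and m.mz_twin_group in twin_draw:
            alleles[iid] = twin_draw[m.mz_twin_group]
            continue
        if m.is_founder:
            pair = (
                int(rng.random() < founder_alt_freq),
                int(rng.random() < founder_alt_freq),
            )
        else:
            pat = alleles[m.father_id][int(rng.integers(2))]
            mat = alleles[m.mother_id][int(rng.integers(2))]
            pair = (pat, mat)
        alleles[iid] = pair
        if m.mz_twin_group:
            twin_draw[m.mz_twin_group] = pair
    calls = {iid: a + b for iid, (a, b) in alleles.items()}
    return GenotypeVector("gene_drop", calls)


def planted_drop(ped: Pedigree, founder_id: str, seed: int) -> GenotypeVector:
    """Drop a single variant allele introduced heterozygously by one founder.

    All other founders are homozygous reference; used to plant a rare causal
    variant with a known origin.
    """
    if founder_id not in ped:
        raise PedigreeError(f"founder {founder_id!r} not in pedigree")
    if not ped[founder_id].is_founder:
        raise PedigreeError(f"{founder_id!r} is not a founder")
    rng = np.random.default_rng(seed)
    alleles: Dict[str, Tuple[int, int]] = {}
    twin_draw: Dict[str, Tuple[int, int]] = {}
    for iid in ped.topological_ids():
        m = ped[iid]
        if m.mz_twin_group and m.mz_twin_group in twin_draw:
            alleles[iid] = twin_draw[m.mz_twin_group]
            continue
        if m.is_founder:
            pair = (1, 0) if iid == founder_id else (0, 0)
        else:
            pat = alleles[m.father_id][int(rng.integers(2))]
            mat = alleles[m.mother_id][int(rng.integers(2))]
            pair = (pat, mat)
        alleles[iid] = pair
        if m.mz_twin_group:
            twin_draw[m.mz_twin_group] = pair
    return GenotypeVector("planted", {iid: a + b for iid, (a, b) in alleles.items()})
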