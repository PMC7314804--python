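"""Parametric two-point linkage: pedigree likelihood, LOD score, ELOD,
and cosegregation checking under an age-dependent dominant disease model.

Model
-----
Two linked biallelic loci: a disease locus (alleles ``d``/``D`` with disease
allele frequency ``p``) and a marker locus (alleles ``a``/``A`` with alternate
allele frequency ``q``), recombination fraction ``theta``.  Founder phased
genotypes are drawn from Hardy-Weinberg haplotype priors under linkage
equilibrium; each meiosis transmits a parental haplotype intact with
probability ``(1-theta)/2`` per haplotype and a recombinant with ``theta/2``.
Phenotypes enter through a penetrance vector ``(f0, f1, f2)`` = P(affected |
0/1/2 disease alleles), with an age-based liability class: members younger
than the onset threshold carry either no phenotype information (default) or
a proportionally reduced penetrance.

The likelihood sums the product of founder priors, transmission
probabilities and penetrance/marker-observation weights over all unobserved
phased genotypes.  Two engines share one factor construction: ``peel``
(variable elimination, leaves first - the Elston-Stewart recursion on
loop-free pedigrees) and ``enumerate`` (depth-first summation over states,
used as the exact oracle on small pedigrees).  MZ twin groups share a single
genotype variable, i.e. one pair of meioses.

LOD(theta) = log10 L(theta) - log10 L(1/2); ELOD is the expected LOD at
theta=0 of a fully linked, fully informative marker given the observed
phenotypes, the family-informativeness score used to select a pedigree for
sequencing.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np

from .factors import Factor, eliminate_all, eliminate_and_sample, greedy_elimination_order
from .pedigree import GenotypeVector, Pedigree, PedigreeError

DEFAULT_THETA_GRID = (0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)

# phased two-locus state: haplotype h = 2*d + m; genotype g = 4*h_pat + h_mat
_HAPS = [(0, 0), (0, 1), (1, 0), (1, 1)]  # (disease allele, marker alt allele)


def _dis_count(g: int) -> int:
    return _HAPS[g // 4][0] + _HAPS[g % 4][0]


def _mark_count(g: int) -> int:
    return _HAPS[g // 4][1] + _HAPS[g % 4][1]


def _gamete_table(theta: float) -> np.ndarray:
    """G[parent_state, gamete_haplotype]."""
    G = np.zeros((16, 4))
    for hp, hm in itertools.product(range(4), range(4)):
        g = 4 * hp + hm
        d1, m1 = _HAPS[hp]
        d2, m2 = _HAPS[hm]
        G[g, 2 * d1 + m1] += (1 - theta) / 2
        G[g, 2 * d2 + m2] += (1 - theta) / 2
        G[g, 2 * d1 + m2] += theta / 2
        G[g, 2 * d2 + m1] += theta / 2
    return G


def _transmission_tensor(theta: float) -> np.ndarray:
    """T[child, father, mother] for phased two-locus genotypes."""
    G = _gamete_table(theta)
    T = np.zeros((16, 16, 16))
    for gp in range(4):
        for gm in range(4):
            c = 4 * gp + gm
            T[c] = np.outer(G[:, gp], G[:, gm])
    return T


@dataclass(frozen=True)
class DiseaseModel:
    """Dominant single-locus disease model with an age-threshold liability class.

    Defaults encode a rare (frequency 1e-4) fully penetrant autosomal
    dominant trait with onset after 25 years; pre-onset members contribute no
    phenotype information unless a reduced penetrance value is configured.
    """

    disease_allele_freq: float = 1e-4
    penetrance: Tuple[float, float, float] = (0.0, 1.0, 1.0)
    onset_age_threshold: float = 25.0
    pre_onset_policy: Union[str, Tuple[str, float]] = "unknown_phenotype"

    def __post_init__(self):
        if not 0.0 < self.disease_allele_freq < 1.0:
            raise ValueError("disease_allele_freq must be in (0, 1)")
        f0, f1, f2 = self.penetrance
        for f in (f0, f1, f2):
            if not 0.0 <= f <= 1.0:
                raise ValueError("penetrance values must be in [0, 1]")
        if not f0 <= f1 <= f2:
            warnings.warn("penetrance not monotone (f0 <= f1 <= f2): not a dominant configuration")
        policy = self.pre_onset_policy
        if policy != "unknown_phenotype" and not (
            isinstance(policy, tuple) and policy[0] == "reduced_penetrance"
        ):
            raise ValueError("pre_onset_policy must be 'unknown_phenotype' or ('reduced_penetrance', value)")

    def penetrance_by_count(self, individual) -> Optional[np.ndarray]:
        """P(observed phenotype | 0/1/2 disease alleles), or None if uninformative."""
        if individual.affection == "unknown":
            return None
        pen = np.asarray(self.penetrance, dtype=float)
        pre_onset = (
            individual.age_years is not None and individual.age_years < self.onset_age_threshold
        )
        if pre_onset:
            if self.pre_onset_policy == "unknown_phenotype":
                return None
            pen = pen * float(self.pre_onset_policy[1])
        return pen if individual.affection == "affected" else 1.0 - pen


@dataclass
class LinkageResult:
    theta_grid: List[float]
    lod: List[float]
    max_lod: float
    theta_at_max: float
    variant_id: str = ""

    def as_dict(self) -> dict:
        return {
            "variant_id": self.variant_id,
            "theta_grid": list(self.theta_grid),
            "lod": [float(x) for x in self.lod],
            "max_lod": float(self.max_lod),
            "theta_at_max": float(self.theta_at_max),
        }


@dataclass
class ElodResult:
    elod: float
    standard_error: float
    n_replicates: int
    exact: bool = False


@dataclass
class CosegregationReport:
    cosegregates: bool
    discordant_ids: List[str]
    exempted_ids: List[Tuple[str, str]]  # (id, reason)
    n_informative: int = 0


# ---------------------------------------------------------------------------
# Likelihood machinery


class _TwoLocusProblem:
    """Shared factor construction for both likelihood engines."""

    def __init__(
        self,
        ped: Pedigree,
        marker: GenotypeVector,
        model: DiseaseModel,
        marker_alt_freq: float,
        ignore_phenotype_ids: FrozenSet[str],
    ):
        for iid in marker.calls:
            if iid not in ped:
                raise PedigreeError(f"marker genotype for unknown individual {iid!r}")
        self.ped = ped
        self.model = model
        # one genotype variable per MZ twin group, otherwise per individual
        self.var_of: Dict[str, str] = {}
        for m in ped.members:
            self.var_of[m.iid] = f"mz:{m.mz_twin_group}" if m.mz_twin_group else m.iid
        p = model.disease_allele_freq
        q = marker_alt_freq
        hap = np.array([(1 - p) * (1 - q), (1 - p) * q, p * (1 - q), p * q])
        self.founder_prior = np.array([hap[g // 4] * hap[g % 4] for g in range(16)])
        # observation weight per variable (product over members sharing it)
        self.weights: Dict[str, np.ndarray] = {}
        for m in ped.members:
            w = np.ones(16)
            pen = None if m.iid in ignore_phenotype_ids else model.penetrance_by_count(m)
            if pen is not None:
                w *= np.array([pen[_dis_count(g)] for g in range(16)])
            call = marker.call(m.iid)
            if call is not None:
                w *= np.array([1.0 if _mark_count(g) == call else 0.0 for g in range(16)])
            v = self.var_of[m.iid]
            self.weights[v] = self.weights.get(v, np.ones(16)) * w
        # representative member per variable (twins share parents, validated)
        self.rep: Dict[str, str] = {}
        for m in ped.members:
            self.rep.setdefault(self.var_of[m.iid], m.iid)
        self.variables = list(self.rep)

    def factors(self, theta: float) -> List[Factor]:
        T = _transmission_tensor(theta)
        facs = [Factor((v,), self.weights[v]) for v in self.variables]
        for v in self.variables:
            m = self.ped[self.rep[v]]
            if m.is_founder:
                facs.append(Factor((v,), self.founder_prior))
            else:
                fv, mv = self.var_of[m.father_id], self.var_of[m.mother_id]
                facs.append(Factor((v, fv, mv), T))
        return facs

    def peel_order(self) -> List[str]:
        # factor structure is theta-independent; any theta gives the same graph
        return greedy_elimination_order(self.factors(0.5))

    def loglik_peel(self, theta: float) -> float:
        return eliminate_all(self.factors(theta), self.peel_order())

    def loglik_enumerate(self, theta: float) -> float:
        T = _transmission_tensor(theta)
        topo = sorted(self.variables, key=lambda v: (self.ped.depth(self.rep[v]), v))
        allowed = {v: np.flatnonzero(self.weights[v]) for v in topo}
        assign: Dict[str, int] = {}
        # running rescale keeps deep-pedigree products inside double range
        scale = max(self.founder_prior.max(), 1e-300)
        log10_scale = float(np.log10(scale))
        total = 0.0

        def rec(k: int, prod: float) -> None:
            nonlocal total
            if k == len(topo):
                total += prod
                return
            v = topo[k]
            m = self.ped[self.rep[v]]
            w = self.weights[v]
            if m.is_founder:
                trans = self.founder_prior / scale
            else:
                trans = T[:, assign[self.var_of[m.father_id]], assign[self.var_of[m.mother_id]]]
            for g in allowed[v]:
                wg = w[g] * trans[g]
                if wg > 0.0:
                    assign[v] = g
                    rec(k + 1, prod * wg)
            assign.pop(v, None)

        rec(0, 1.0)
        if total <= 0.0:
            return -np.inf
        n_founder_vars = sum(1 for v in topo if self.ped[self.rep[v]].is_founder)
        return float(np.log10(total)) + n_founder_vars * log10_scale


def pedigree_likelihood(
    ped: Pedigree,
    marker: GenotypeVector,
    model: DiseaseModel,
    theta: float,
    *,
    marker_alt_freq: float = 1e-4,
    ignore_phenotype_ids: Iterable[str] = (),
    method: str = "peel",
) -> float:
    """log10 likelihood of phenotypes and marker genotypes at recombination ``theta``.

    ``method`` is ``"peel"`` (variable elimination; the default) or
    ``"enumerate"`` (exact depth-first summation; exponential, intended for
    small pedigrees and as an oracle).
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError("theta must be in [0, 0.5]")
    prob = _TwoLocusProblem(ped, marker, model, marker_alt_freq, frozenset(ignore_phenotype_ids))
    if method == "peel":
        return prob.loglik_peel(theta)
    if method == "enumerate":
        return prob.loglik_enumerate(theta)
    raise ValueError(f"unknown method {method!r}")


def lod_score(
    ped: Pedigree,
    marker: GenotypeVector,
    model: DiseaseModel,
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
    *,
    marker_alt_freq: float = 1e-4,
    married_in_ids: Iterable[str] = (),
    method: str = "peel",
) -> LinkageResult:
    """Two-point LOD curve over a theta grid.

    ``married_in_ids`` are affected spouses who married into the family and
    whose disease is treated as an independent phenocopy: their phenotype is
    masked (their marker genotypes still contribute).
    """
    grid = sorted(set(float(t) for t in theta_grid))
    if not grid or grid[-1] != 0.5:
        raise ValueError("theta grid must contain 0.5")
    if grid[0] < 0.0:
        raise ValueError("theta grid must lie within [0, 0.5]")
    prob = _TwoLocusProblem(ped, marker, model, marker_alt_freq, frozenset(married_in_ids))
    compute = prob.loglik_peel if method == "peel" else prob.loglik_enumerate
    ll = {t: compute(t) for t in grid}
    ll_half = ll[0.5]
    if ll_half == -np.inf:
        raise ValueError("zero likelihood at theta=0.5: data inconsistent with the model")
    lod = [ll[t] - ll_half if ll[t] != -np.inf else -np.inf for t in grid]
    lod[grid.index(0.5)] = 0.0
    finite = [(l, -t) for t, l in zip(grid, lod)]
    max_lod, neg_theta = max(finite)
    return LinkageResult(
        theta_grid=grid,
        lod=lod,
        max_lod=float(max_lod),
        theta_at_max=float(-neg_theta),
        variant_id=marker.variant_id,
    )


# ---------------------------------------------------------------------------
# ELOD


_MENDEL = np.zeros((3, 3, 3))  # P(child count | father count, mother count)
for _f in range(3):
    for _m in range(3):
        pf = np.array([1.0, 0.0]) if _f == 0 else np.array([0.5, 0.5]) if _f == 1 else np.array([0.0, 1.0])
        pm = np.array([1.0, 0.0]) if _m == 0 else np.array([0.5, 0.5]) if _m == 1 else np.array([0.0, 1.0])
        for a in range(2):
            for b in range(2):
                _MENDEL[a + b, _f, _m] += pf[a] * pm[b]


class _DiseaseLocusPosterior:
    """Single-locus disease-genotype posterior given observed phenotypes."""

    def __init__(self, ped: Pedigree, model: DiseaseModel, ignore_phenotype_ids: FrozenSet[str]):
        self.ped = ped
        self.model = model
        p = model.disease_allele_freq
        self.prior = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
        self.var_of = {
            m.iid: (f"mz:{m.mz_twin_group}" if m.mz_twin_group else m.iid) for m in ped.members
        }
        self.weights: Dict[str, np.ndarray] = {}
        for m in ped.members:
            pen = None if m.iid in ignore_phenotype_ids else model.penetrance_by_count(m)
            w = np.ones(3) if pen is None else np.asarray(pen, dtype=float)
            v = self.var_of[m.iid]
            self.weights[v] = self.weights.get(v, np.ones(3)) * w
        self.rep: Dict[str, str] = {}
        for m in ped.members:
            self.rep.setdefault(self.var_of[m.iid], m.iid)
        self.variables = list(self.rep)

    def factors(self) -> List[Factor]:
        facs = [Factor((v,), self.weights[v]) for v in self.variables]
        for v in self.variables:
            m = self.ped[self.rep[v]]
            if m.is_founder:
                facs.append(Factor((v,), self.prior))
            else:
                facs.append(Factor((v, self.var_of[m.father_id], self.var_of[m.mother_id]), _MENDEL))
        return facs

    def peel_order(self) -> List[str]:
        return greedy_elimination_order(self.factors())

    def sample(self, rng: np.random.Generator, n: int) -> List[Dict[str, int]]:
        assigns = eliminate_and_sample(self.factors(), self.peel_order(), rng, n)
        return [{m.iid: a[self.var_of[m.iid]] for m in self.ped.members} for a in assigns]

    def enumerate_configs(self) -> List[Tuple[Dict[str, int], float]]:
        """All genotype configurations with nonzero posterior weight."""
        topo = sorted(self.variables, key=lambda v: (self.ped.depth(self.rep[v]), v))
        out: List[Tuple[Dict[str, int], float]] = []
        assign: Dict[str, int] = {}

        def rec(k: int, prod: float) -> None:
            if k == len(topo):
                out.append(({m.iid: assign[self.var_of[m.iid]] for m in self.ped.members}, prod))
                return
            v = topo[k]
            m = self.ped[self.rep[v]]
            trans = (
                self.prior
                if m.is_founder
                else _MENDEL[:, assign[self.var_of[m.father_id]], assign[self.var_of[m.mother_id]]]
            )
            for g in range(3):
                w = self.weights[v][g] * trans[g]
                if w > 0.0:
                    assign[v] = g
                    rec(k + 1, prod * w)
            assign.pop(v, None)

        rec(0, 1.0)
        return out


def elod(
    ped: Pedigree,
    model: DiseaseModel,
    n_replicates: int = 1000,
    seed: int = 0,
    *,
    typed_ids: Optional[Iterable[str]] = None,
    married_in_ids: Iterable[str] = (),
    marker_alt_freq: Optional[float] = None,
    exact: bool = False,
) -> ElodResult:
    """Expected LOD at theta=0 for a fully linked, fully informative marker.

    Disease-locus genotypes are drawn from their exact posterior given the
    observed phenotypes (peeling + backward sampling); each realization's
    marker equals the disease genotype (complete cosegregation), observed for
    ``typed_ids`` (default: every member).  ``exact=True`` enumerates all
    consistent genotype configurations instead of sampling; feasible when
    penetrance zeros prune the space (e.g. fully penetrant models) or the
    pedigree is small.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ignore = frozenset(married_in_ids)
    typed = set(typed_ids) if typed_ids is not None else set(ped.ids())
    q = marker_alt_freq if marker_alt_freq is not None else model.disease_allele_freq
    post = _DiseaseLocusPosterior(ped, model, ignore)

    def lod0(config: Dict[str, int]) -> float:
        marker = GenotypeVector("elod_marker", {i: c for i, c in config.items() if i in typed})
        res = lod_score(
            ped, marker, model, theta_grid=(0.0, 0.5), marker_alt_freq=q, married_in_ids=ignore
        )
        return res.lod[0]

    if exact:
        configs = post.enumerate_configs()
        total_w = sum(w for _, w in configs)
        cache: Dict[Tuple, float] = {}
        mean = 0.0
        second = 0.0
        for config, w in configs:
            key = tuple(sorted((i, c) for i, c in config.items() if i in typed))
            if key not in cache:
                cache[key] = lod0(config)
            val = cache[key]
            mean += (w / total_w) * val
            second += (w / total_w) * val * val
        return ElodResult(elod=float(mean), standard_error=0.0, n_replicates=len(configs), exact=True)

    rng = np.random.default_rng(seed)
    samples = post.sample(rng, n_replicates)
    cache = {}
    vals = np.empty(n_replicates)
    for k, config in enumerate(samples):
        key = tuple(sorted((i, c) for i, c in config.items() if i in typed))
        if key not in cache:
            cache[key] = lod0(config)
        vals[k] = cache[key]
    se = float(vals.std(ddof=1) / np.sqrt(n_replicates)) if n_replicates > 1 else float("nan")
    return ElodResult(elod=float(vals.mean()), standard_error=se, n_replicates=n_replicates)


# ---------------------------------------------------------------------------
# Cosegregation


def cosegregation_check(
    ped: Pedigree,
    marker: GenotypeVector,
    model: DiseaseModel,
    married_in_ids: Iterable[str] = (),
) -> CosegregationReport:
    """Check whether carrier status tracks affection through the pedigree.

    Discordant: affected non-carriers (unless married in - phenocopies by
    assumption) and unaffected carriers past the onset age.  Unaffected
    carriers younger than the onset threshold are exempted as pre-onset.
    """
    married = set(married_in_ids)
    discordant: List[str] = []
    exempted: List[Tuple[str, str]] = []
    informative = 0
    for m in ped.members:
        call = marker.call(m.iid)
        if call is None or m.affection == "unknown":
            continue
        informative += 1
        carrier = call >= 1
        if m.affection == "affected" and not carrier:
            if m.iid in married:
                exempted.append((m.iid, "married-in phenocopy"))
            else:
                discordant.append(m.iid)
        elif m.affection == "unaffected" and carrier:
            pre_onset = m.age_years is not None and m.age_years < model.onset_age_threshold
            if pre_onset:
                exempted.append((m.iid, "pre-onset age"))
            else:
                discordant.append(m.iid)
        elif m.affection == "affected" and carrier and m.iid in married:
            # carrier married-in affected would be concordant; leave as informative
            pass
    return CosegregationReport(
        cosegregates=not discordant,
        discordant_ids=discordant,
        exempted_ids=exempted,
        n_informative=informative,
    )
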