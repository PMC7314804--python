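"""Shared fixtures: published-table loaders, a phase-known three-generation
family builder, and a random pedigree+data generator for likelihood-engine
agreement checks."""

from __future__ import annotations

import numpy as np
import pytest

from pedvar.datasets import (
    UBRS033_MARRIED_IN_AFFECTED,
    demo_transcripts,
    load_table2_candidates,
    load_table4_spots,
    load_ubrs033,
)
from pedvar.linkage import DiseaseModel
from pedvar.pedigree import GenotypeVector, Individual, Pedigree


@pytest.fixture(scope="session")
def ubrs033():
    return load_ubrs033()


@pytest.fixture(scope="session")
def married_in():
    return UBRS033_MARRIED_IN_AFFECTED


@pytest.fixture(scope="session")
def table4():
    return load_table4_spots()


@pytest.fixture(scope="session")
def table2():
    return load_table2_candidates()


@pytest.fixture(scope="session")
def transcripts():
    return demo_transcripts()


@pytest.fixture()
def dominant_model():
    return DiseaseModel()


def make_three_gen(n_children: int, carrier_pattern=None):
    """Phase-known dominant family: typed affected grandfather, typed
    unaffected grandmother, doubly-informative father, n typed children.

    Each child meiosis is phase-known and non-recombinant, so the LOD at
    theta=0 is exactly n*log10(2) under full penetrance.
    """
    members = [
        Individual("gf", sex="male", affection="affected", age_years=70),
        Individual("gm", sex="female", affection="unaffected", age_years=68),
        Individual("f", "gf", "gm", sex="male", affection="affected", age_years=45),
        Individual("m", sex="female", affection="unaffected", age_years=44),
    ]
    calls = {"gf": 1, "gm": 0, "f": 1, "m": 0}
    for k in range(n_children):
        carrier = (k % 2 == 0) if carrier_pattern is None else carrier_pattern[k]
        members.append(
            Individual(
                f"c{k}",
                "f",
                "m",
                sex="male",
                affection="affected" if carrier else "unaffected",
                age_years=26,
            )
        )
        calls[f"c{k}"] = 1 if carrier else 0
    return Pedigree("3GEN", members), GenotypeVector("marker", calls)


def random_pedigree(rng: np.random.Generator, max_members: int = 12) -> Pedigree:
    """Random multi-generation pedigree grown child-by-child with occasional
    married-in spouses."""
    members = [Individual("F0", sex="male"), Individual("M0", sex="female")]
    couples = [("F0", "M0")]
    k = 0
    target = int(rng.integers(4, max_members + 1))
    while len(members) < target:
        father, mother = couples[int(rng.integers(len(couples)))]
        k += 1
        sex = "male" if rng.random() < 0.5 else "female"
        child = Individual(f"C{k}", father, mother, sex=sex)
        members.append(child)
        if rng.random() < 0.35 and len(members) < target:
            spouse = Individual(f"S{k}", sex="female" if sex == "male" else "male")
            members.append(spouse)
            couples.append((child.iid, spouse.iid) if sex == "male" else (spouse.iid, child.iid))
    return Pedigree("RAND", members)


def random_linkage_data(seed: int, max_members: int = 12, full_penetrance: bool = True):
    """Pedigree + marker genotypes + phenotypes with bounded enumeration cost.

    Phenotypes come from an independent disease-locus drop (so the data are
    always consistent at theta=0.5); marker calls are a separate drop with a
    common allele.  Some calls/phenotypes are masked.  Under the returned
    model the per-member state space stays small enough for the brute-force
    engine.
    """
    from pedvar.pedigree import gene_drop

    rng = np.random.default_rng(seed)
    ped = random_pedigree(rng, max_members=max_members)
    disease = gene_drop(ped, 0.25, seed=seed * 7 + 1)
    marker = gene_drop(ped, 0.4, seed=seed * 7 + 2)
    if full_penetrance:
        model = DiseaseModel(disease_allele_freq=0.05, penetrance=(0.0, 1.0, 1.0))
    else:
        model = DiseaseModel(disease_allele_freq=0.1, penetrance=(0.05, 0.9, 0.95))
    calls = {}
    for m in ped.members:
        m.affection = "affected" if (disease.call(m.iid) or 0) >= 1 else "unaffected"
        if rng.random() < 0.15:
            m.affection = "unknown"
        if rng.random() >= 0.15:  # 85% typed
            calls[m.iid] = marker.call(m.iid)
    if not full_penetrance:
        # bound brute-force cost: without penetrance zeros every untyped
        # unknown-phenotype member contributes 16 states
        cost = 1
        for m in ped.members:
            cost *= 2 if m.iid in calls else 16
        if cost > 500_000:
            return random_linkage_data(seed + 10_000, max_members, full_penetrance)
    return ped, GenotypeVector("mk", calls), model
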