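"""Two-point likelihood engines, LOD properties, ELOD, cosegregation."""

import itertools

import numpy as np
import pytest

from pedvar.linkage import (
    DiseaseModel,
    cosegregation_check,
    elod,
    lod_score,
    pedigree_likelihood,
)
from pedvar.pedigree import GenotypeVector, Individual, Pedigree

from conftest import make_three_gen, random_linkage_data

LOG10_2 = np.log10(2.0)


class TestDiseaseModel:
    def test_frequency_bounds(self):
        with pytest.raises(ValueError):
            DiseaseModel(disease_allele_freq=0.0)

    def test_non_monotone_penetrance_warns(self):
        with pytest.warns(UserWarning, match="not monotone"):
            DiseaseModel(penetrance=(0.9, 0.1, 0.1))

    def test_pre_onset_unknown_policy(self):
        m = DiseaseModel()
        young = Individual("x", sex="male", affection="unaffected", age_years=20)
        assert m.penetrance_by_count(young) is None

    def test_pre_onset_reduced_policy(self):
        m = DiseaseModel(penetrance=(0.0, 1.0, 1.0), pre_onset_policy=("reduced_penetrance", 0.2))
        young = Individual("x", sex="male", affection="affected", age_years=20)
        assert np.allclose(m.penetrance_by_count(young), [0.0, 0.2, 0.2])


class TestPedigreeLikelihood:
    def test_single_founder_hardy_weinberg(self):
        """One genotyped founder, phenotype unknown: likelihood = HW prior."""
        ped = Pedigree("F", [Individual("a", sex="male")])
        q = 0.3
        for call, expected in ((0, (1 - q) ** 2), (1, 2 * q * (1 - q)), (2, q * q)):
            ll = pedigree_likelihood(
                ped, GenotypeVector("m", {"a": call}), DiseaseModel(), 0.1, marker_alt_freq=q
            )
            assert np.isclose(10**ll, expected)

    def test_trio_theta_half_hand_enumeration(self):
        """Fully typed trio at theta=0.5: loci independent, marker side is
        HW priors times one Mendelian transmission per parent."""
        ped = Pedigree(
            "F",
            [
                Individual("f", sex="male"),
                Individual("m", sex="female"),
                Individual("c", "f", "m", sex="male"),
            ],
        )
        q = 0.25
        marker = GenotypeVector("m", {"f": 1, "m": 0, "c": 1})
        ll = pedigree_likelihood(ped, marker, DiseaseModel(), 0.5, marker_alt_freq=q)
        # father het (2q(1-q)), mother hom ref ((1-q)^2); child het requires the
        # alt from the father: P = 1/2
        expected = 2 * q * (1 - q) * (1 - q) ** 2 * 0.5
        assert np.isclose(10**ll, expected)

    def test_theta_out_of_range(self):
        ped = Pedigree("F", [Individual("a", sex="male")])
        with pytest.raises(ValueError):
            pedigree_likelihood(ped, GenotypeVector("m", {"a": 0}), DiseaseModel(), 0.7)

    def test_unknown_individual_in_marker(self):
        ped = Pedigree("F", [Individual("a", sex="male")])
        with pytest.raises(Exception, match="unknown individual"):
            pedigree_likelihood(ped, GenotypeVector("m", {"zz": 0}), DiseaseModel(), 0.1)

    @pytest.mark.parametrize("seed", range(30))
    def test_peel_equals_enumeration(self, seed):
        """Variable elimination agrees with brute-force summation."""
        full_pen = seed % 2 == 0
        ped, marker, model = random_linkage_data(seed, max_members=12 if full_pen else 7,
                                                 full_penetrance=full_pen)
        for theta in (0.0, 0.1, 0.5):
            a = pedigree_likelihood(ped, marker, model, theta, marker_alt_freq=0.4, method="peel")
            b = pedigree_likelihood(ped, marker, model, theta, marker_alt_freq=0.4, method="enumerate")
            if a == -np.inf or b == -np.inf:
                assert a == b
            else:
                assert abs(a - b) < 1e-9

    def test_marker_normalization(self):
        """Summing the likelihood over all typed-marker vectors gives 1
        (trio, phenotypes unknown)."""
        ped = Pedigree(
            "F",
            [
                Individual("f", sex="male"),
                Individual("m", sex="female"),
                Individual("c", "f", "m", sex="male"),
            ],
        )
        total = 0.0
        for calls in itertools.product((0, 1, 2), repeat=3):
            marker = GenotypeVector("m", dict(zip(["f", "m", "c"], calls)))
            ll = pedigree_likelihood(ped, marker, DiseaseModel(), 0.2, marker_alt_freq=0.3)
            if ll != -np.inf:
                total += 10**ll
        assert np.isclose(total, 1.0)


class TestLodScore:
    def test_lod_zero_at_half(self):
        for seed in range(5):
            ped, marker, model = random_linkage_data(seed)
            res = lod_score(ped, marker, model, theta_grid=(0.0, 0.1, 0.3, 0.5))
            assert res.lod[res.theta_grid.index(0.5)] == 0.0

    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_phase_known_closed_form(self, n):
        """n fully penetrant phase-known informative meioses: LOD(0) = n*log10 2."""
        ped, marker = make_three_gen(n)
        res = lod_score(ped, marker, DiseaseModel(), theta_grid=(0.0, 0.5))
        assert np.isclose(res.lod[0], n * LOG10_2, atol=1e-9)
        assert res.theta_at_max == 0.0

    def test_monotone_in_meioses(self):
        """LOD at theta=0 strictly increases as non-recombinant meioses are added."""
        lods = []
        for n in range(2, 7):
            ped, marker = make_three_gen(n)
            lods.append(lod_score(ped, marker, DiseaseModel(), theta_grid=(0.0, 0.5)).lod[0])
        assert all(b > a for a, b in zip(lods, lods[1:]))

    def test_mz_flag_removes_one_meiosis(self):
        """Flagging two concordant sibs as MZ twins shares one meiosis."""
        ped, marker = make_three_gen(4, carrier_pattern=[True, True, False, False])
        base = lod_score(ped, marker, DiseaseModel(), theta_grid=(0.0, 0.5)).lod[0]
        ped["c0"].mz_twin_group = "T"
        ped["c1"].mz_twin_group = "T"
        twin = lod_score(ped, marker, DiseaseModel(), theta_grid=(0.0, 0.5)).lod[0]
        assert np.isclose(base - twin, LOG10_2, atol=1e-9)

    def test_grid_must_contain_half(self):
        ped, marker = make_three_gen(2)
        with pytest.raises(ValueError, match="0.5"):
            lod_score(ped, marker, DiseaseModel(), theta_grid=(0.0, 0.1))

    def test_ubrs033_anchors(self, ubrs033, married_in, dominant_model):
        """The cosegregating variant peaks at theta=0 and dominates the two
        discordant variants; values match the brute-force engine."""
        ped, genotypes = ubrs033
        res = {}
        for vid in genotypes:
            res[vid] = lod_score(ped, genotypes[vid], dominant_model, married_in_ids=married_in)
        pbk = res["PBK_c127GA"]
        assert pbk.theta_at_max == 0.0
        assert pbk.max_lod > 0
        assert pbk.max_lod > res["ANKRD36_c202GA"].max_lod
        assert pbk.max_lod > res["SORL1_c4501CT"].max_lod
        # discordant variants carry obligate recombinants: impossible at theta=0
        assert res["ANKRD36_c202GA"].lod[0] == -np.inf
        assert res["SORL1_c4501CT"].lod[0] == -np.inf


class TestElod:
    def test_phase_known_family_deterministic(self):
        """Fully informative phase-known family: ELOD = n*log10 2 (the LOD is
        the same for every posterior genotype realization)."""
        ped, _ = make_three_gen(5)
        res = elod(ped, DiseaseModel(), exact=True)
        assert res.elod == pytest.approx(5 * LOG10_2, abs=1e-2)
        mc = elod(ped, DiseaseModel(), n_replicates=50, seed=3)
        assert mc.elod == pytest.approx(res.elod, abs=1e-6)
        assert mc.standard_error == pytest.approx(0.0, abs=1e-12)

    def test_no_phenotyped_nonfounders_gives_zero(self):
        """Without phenotyped non-founders there is no segregation information."""
        members = [
            Individual("f", sex="male", affection="affected", age_years=60),
            Individual("m", sex="female"),
            Individual("c1", "f", "m", sex="male"),
            Individual("c2", "f", "m", sex="female"),
        ]
        res = elod(Pedigree("F", members), DiseaseModel(), exact=True)
        assert res.elod == pytest.approx(0.0, abs=1e-12)

    def test_elod_nonnegative_and_monotone_in_family(self):
        """ELOD >= 0, and a sub-pedigree is never more informative."""
        sub, _ = make_three_gen(2)
        full, _ = make_three_gen(5)
        e_sub = elod(sub, DiseaseModel(), exact=True).elod
        e_full = elod(full, DiseaseModel(), exact=True).elod
        assert 0.0 <= e_sub <= e_full

    def test_mc_agrees_with_exact_partial_penetrance(self):
        """Monte Carlo vs exact enumeration within 3 standard errors."""
        members = [
            Individual("f", sex="male", affection="affected", age_years=60),
            Individual("m", sex="female", affection="unaffected", age_years=58),
            Individual("c1", "f", "m", sex="male", affection="affected", age_years=30),
            Individual("c2", "f", "m", sex="female", affection="unaffected", age_years=28),
            Individual("c3", "f", "m", sex="female", affection="affected", age_years=33),
            Individual("c4", "f", "m", sex="male", affection="unknown", age_years=20),
        ]
        ped = Pedigree("F", members)
        model = DiseaseModel(disease_allele_freq=0.01, penetrance=(0.02, 0.9, 0.95))
        ex = elod(ped, model, exact=True)
        mc = elod(ped, model, n_replicates=3000, seed=11)
        assert abs(mc.elod - ex.elod) < 3 * mc.standard_error

    def test_replicates_validated(self):
        ped, _ = make_three_gen(2)
        with pytest.raises(ValueError):
            elod(ped, DiseaseModel(), n_replicates=0)


class TestCosegregation:
    def test_ubrs033_report(self, ubrs033, married_in, dominant_model):
        ped, genotypes = ubrs033
        rep = cosegregation_check(ped, genotypes["PBK_c127GA"], dominant_model, married_in)
        assert rep.cosegregates
        assert rep.discordant_ids == []
        reasons = dict(rep.exempted_ids)
        assert reasons["III:6"] == "pre-onset age"
        assert reasons["II:11"] == "married-in phenocopy"
        assert reasons["II:12"] == "married-in phenocopy"

    def test_affected_noncarrier_breaks_cosegregation(self, ubrs033, married_in, dominant_model):
        ped, genotypes = ubrs033
        rep = cosegregation_check(ped, genotypes["ANKRD36_c202GA"], dominant_model, married_in)
        assert not rep.cosegregates
        assert "II:5" in rep.discordant_ids  # affected non-carrier in the descent line
        assert "III:5" in rep.discordant_ids  # post-onset unaffected carrier

    def test_all_unknown_vacuously_true(self):
        ped = Pedigree(
            "F",
            [Individual("a", sex="male"), Individual("b", sex="female")],
        )
        marker = GenotypeVector("m", {"a": 1, "b": 0})
        rep = cosegregation_check(ped, marker, DiseaseModel())
        assert rep.cosegregates
        assert rep.n_informative == 0
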