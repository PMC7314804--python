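"""Synthetic-data generators: determinism, calibration, ground truth."""

import numpy as np
import pytest

from pedvar.linkage import DiseaseModel
from pedvar.prioritize import read_vcf
from pedvar.simulate import (
    ArraySimSpec,
    CohortSpec,
    PlantedVariant,
    generate_array_dataset,
    generate_msa,
    simulate_family_cohort,
    write_variant_table,
)


class TestFamilyCohort:
    def test_seed_determinism(self):
        a = simulate_family_cohort(CohortSpec(n_variants=1, seed=3))
        b = simulate_family_cohort(CohortSpec(n_variants=1, seed=3))
        assert a.pedigree.ids() == b.pedigree.ids()
        assert a.planted_genotypes.calls == b.planted_genotypes.calls
        assert a.affection == b.affection

    def test_unknown_founder_rejected(self):
        spec = CohortSpec(planted_variant=PlantedVariant(founder_id="nobody"), n_variants=1)
        with pytest.raises(Exception, match="nobody"):
            simulate_family_cohort(spec)

    def test_full_penetrance_post_onset_concordance(self):
        """Under penetrance (0,1,1), carrier status and affection agree for
        every post-onset member."""
        for seed in range(10):
            cohort = simulate_family_cohort(CohortSpec(n_variants=1, seed=seed))
            for m in cohort.pedigree.members:
                if m.age_years is not None and m.age_years < 25:
                    assert m.affection == "unaffected"  # pre-onset liability class
                else:
                    carrier = (cohort.planted_genotypes.call(m.iid) or 0) >= 1
                    assert (m.affection == "affected") == carrier

    def test_zero_penetrance_nobody_affected(self):
        model = DiseaseModel(penetrance=(0.0, 0.0, 0.0))
        cohort = simulate_family_cohort(CohortSpec(disease_model=model, n_variants=1, seed=1))
        assert cohort.pedigree.affected_ids() == []

    def test_phenocopy_rate_matches_f0(self):
        """Bernoulli oracle: non-carrier post-onset members are affected at
        rate f0 (3-SE binomial check pooled over cohorts)."""
        f0 = 0.2
        model = DiseaseModel(penetrance=(f0, 1.0, 1.0))
        affected = total = 0
        for seed in range(150):
            cohort = simulate_family_cohort(CohortSpec(disease_model=model, n_variants=1, seed=seed))
            for m in cohort.pedigree.members:
                carrier = (cohort.planted_genotypes.call(m.iid) or 0) >= 1
                post_onset = m.age_years is None or m.age_years >= 25
                if not carrier and post_onset:
                    total += 1
                    affected += m.affection == "affected"
        se = np.sqrt(f0 * (1 - f0) / total)
        assert abs(affected / total - f0) < 3 * se


class TestVariantTable:
    def test_single_planted_record_round_trips(self, tmp_path):
        cohort = simulate_family_cohort(CohortSpec(n_variants=1, seed=4))
        vcf = tmp_path / "v.vcf"
        planted_id = write_variant_table(cohort, vcf)
        records = read_vcf(vcf)
        assert len(records) == 1
        rec = records[0]
        assert rec.variant_id == planted_id
        assert rec.af_pop is None  # novel: AF_POP key absent
        assert rec.consequence == "missense" and rec.region == "exonic"
        for iid in cohort.pedigree.ids():
            assert rec.genotypes.call(iid) == cohort.planted_genotypes.call(iid)

    def test_record_count_preserved(self, tmp_path):
        spec = CohortSpec(n_variants=500, seed=5)
        cohort = simulate_family_cohort(spec)
        vcf = tmp_path / "v.vcf"
        write_variant_table(cohort, vcf)
        assert len(read_vcf(vcf)) == 500

    def test_exonic_fraction_binomial(self, tmp_path):
        n = 2000
        spec = CohortSpec(n_variants=n, fraction_exonic=0.4, seed=6)
        cohort = simulate_family_cohort(spec)
        vcf = tmp_path / "v.vcf"
        write_variant_table(cohort, vcf)
        n_exonic = sum(r.region == "exonic" for r in read_vcf(vcf) if not r.variant_id.startswith("PLANTED"))
        se = np.sqrt(0.4 * 0.6 * (n - 1))
        assert abs(n_exonic - 0.4 * (n - 1)) < 3 * se

    def test_background_exchangeable_with_phenotype(self, tmp_path):
        """Background alt counts do not differ between affected and unaffected
        members beyond sampling noise (3-SE z-test pooled over variants)."""
        spec = CohortSpec(n_variants=1500, seed=7)
        cohort = simulate_family_cohort(spec)
        vcf = tmp_path / "v.vcf"
        write_variant_table(cohort, vcf)
        aff = cohort.pedigree.affected_ids()
        unaff = cohort.pedigree.unaffected_ids()
        diffs = []
        for r in read_vcf(vcf):
            if r.variant_id.startswith("PLANTED"):
                continue
            a = np.mean([r.genotypes.call(i) for i in aff])
            u = np.mean([r.genotypes.call(i) for i in unaff])
            diffs.append(a - u)
        diffs = np.asarray(diffs)
        z = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(len(diffs)))
        assert abs(z) < 3

    def test_byte_identical_output(self, tmp_path):
        spec = CohortSpec(n_variants=200, seed=8)
        pa, pb = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_variant_table(simulate_family_cohort(spec), pa)
        write_variant_table(simulate_family_cohort(spec), pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_missingness_rate(self, tmp_path):
        spec = CohortSpec(n_variants=400, seed=9, missing_rate=0.1)
        cohort = simulate_family_cohort(spec)
        vcf = tmp_path / "v.vcf"
        write_variant_table(cohort, vcf)
        calls = [c for r in read_vcf(vcf) for c in r.genotypes.calls.values()]
        frac = sum(c is None for c in calls) / len(calls)
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / len(calls))


class TestMsa:
    def test_conserved_columns_forced(self):
        msa = generate_msa(11, 80, {43, 50}, seed=1)
        for col in (43, 50):
            assert len({str(r.seq[col - 1]) for r in msa}) == 1

    def test_out_of_range_conserved_column(self):
        with pytest.raises(ValueError):
            generate_msa(5, 10, {11}, seed=1)

    def test_determinism(self):
        a = generate_msa(6, 40, {5}, seed=2)
        b = generate_msa(6, 40, {5}, seed=2)
        assert [str(r.seq) for r in a] == [str(r.seq) for r in b]

    def test_unconserved_identity_matches_multinomial_oracle(self):
        """Mean identity of random columns equals the expected maximum
        category count of a uniform multinomial (direct simulation oracle)."""
        n_species, n_cols = 11, 400
        msa = generate_msa(n_species, n_cols, set(), seed=3)
        fracs = []
        for col in range(n_cols):
            residues = [str(r.seq[col]) for r in msa]
            fracs.append(max(residues.count(x) for x in set(residues)) / n_species)
        observed = np.mean(fracs)
        rng = np.random.default_rng(99)
        sim = np.random.default_rng(99).multinomial(n_species, [1 / 20] * 20, size=20000).max(axis=1) / n_species
        se = np.sqrt(np.var(fracs) / n_cols + sim.var() / sim.size)
        assert abs(observed - sim.mean()) < 3 * se


class TestArrayDataset:
    def test_zero_cv_duplicates_identical(self):
        tidy, _ = generate_array_dataset(ArraySimSpec(n_spots=50, n_true_hits=5, duplicate_cv=0.0, seed=1))
        piv = tidy.pivot_table(index=["target", "sample"], columns="replicate", values="intensity")
        assert np.allclose(piv[1], piv[2])

    def test_no_hits_means_flat_ratios(self):
        tidy, truth = generate_array_dataset(ArraySimSpec(n_spots=60, n_true_hits=0, duplicate_cv=0.02, seed=2))
        assert truth == []
        piv = tidy.groupby(["target", "sample"])["intensity"].mean().unstack()
        ratios = piv["treatment"] / piv["control"]
        assert np.all(np.abs(np.log2(ratios)) < 0.5)

    def test_truth_size_and_determinism(self):
        spec = ArraySimSpec(seed=4)
        a, ta = generate_array_dataset(spec)
        b, tb = generate_array_dataset(spec)
        assert ta == tb and len(ta) == spec.n_true_hits
        assert a.equals(b)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            ArraySimSpec(n_spots=5, n_true_hits=6)
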