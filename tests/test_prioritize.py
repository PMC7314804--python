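"""Filter cascade, consensus ranking, conservation scoring."""

import numpy as np
import pytest

from pedvar.pedigree import GenotypeVector, Individual, Pedigree
from pedvar.prioritize import (
    DAMAGING_VOCABULARY,
    PredictionProfile,
    VariantRecord,
    consensus_rank,
    conservation_score,
    functional_rarity_filter,
    inheritance_filter,
    region_filter,
    run_cascade,
)
from pedvar.simulate import (
    CohortSpec,
    PlantedVariant,
    choose_sequenced_ids,
    generate_msa,
    simulate_family_cohort,
    write_variant_table,
)


def family_with_sequenced():
    members = [Individual("f", sex="male", affection="affected", age_years=60),
               Individual("m", sex="female", affection="unaffected", age_years=58)]
    for k, aff in enumerate(["affected"] * 4 + ["unaffected"] * 2):
        members.append(Individual(f"c{k}", "f", "m", sex="male", affection=aff, age_years=30))
    ped = Pedigree("F", members)
    affected = ["f", "c0", "c1", "c2", "c3"]
    unaffected = ["m", "c4", "c5"]
    return ped, affected, unaffected


def record(calls, af=None, consequence="missense", region="exonic", vid="v1"):
    return VariantRecord(
        chrom="1", pos=100, ref="G", alt="A", gene="GENE", region=region,
        af_pop=af, consequence=consequence, variant_id=vid,
        genotypes=GenotypeVector(vid, calls),
    )


class TestInheritanceFilter:
    def test_shared_het_kept(self):
        ped, aff, unaff = family_with_sequenced()
        calls = {i: 1 for i in aff} | {i: 0 for i in unaff}
        assert inheritance_filter([record(calls)], ped, aff + unaff) != []

    def test_missing_one_affected_dropped(self):
        ped, aff, unaff = family_with_sequenced()
        calls = {i: 1 for i in aff} | {i: 0 for i in unaff}
        calls[aff[-1]] = 0
        assert inheritance_filter([record(calls)], ped, aff + unaff) == []

    def test_homozygous_alt_affected_dropped(self):
        # "heterozygous variations that were shared": call must be exactly 1
        ped, aff, unaff = family_with_sequenced()
        calls = {i: 1 for i in aff} | {i: 0 for i in unaff}
        calls[aff[0]] = 2
        assert inheritance_filter([record(calls)], ped, aff + unaff) == []

    def test_missing_call_drops_record(self):
        ped, aff, unaff = family_with_sequenced()
        calls = {i: 1 for i in aff} | {i: 0 for i in unaff}
        calls[unaff[0]] = None
        assert inheritance_filter([record(calls)], ped, aff + unaff) == []

    def test_carrier_unaffected_dropped(self):
        ped, aff, unaff = family_with_sequenced()
        calls = {i: 1 for i in aff} | {i: 0 for i in unaff}
        calls[unaff[0]] = 1
        assert inheritance_filter([record(calls)], ped, aff + unaff) == []

    def test_no_affected_errors(self):
        ped, aff, unaff = family_with_sequenced()
        with pytest.raises(ValueError, match="affected"):
            inheritance_filter([], ped, unaff)


class TestFunctionalRarityFilter:
    def test_synonymous_rare_dropped(self):
        assert functional_rarity_filter([record({}, af=0.001, consequence="synonymous")]) == []

    def test_common_missense_dropped(self):
        # mirrors the exclusion of a high-frequency non-synonymous variant
        assert functional_rarity_filter([record({}, af=0.2)]) == []

    def test_novel_missense_kept(self):
        assert len(functional_rarity_filter([record({}, af=None)])) == 1

    def test_threshold_is_strict(self):
        assert functional_rarity_filter([record({}, af=0.01)]) == []
        assert len(functional_rarity_filter([record({}, af=0.0099)])) == 1

    def test_table2_rows_all_retained(self, table2):
        records, _ = table2
        assert len(functional_rarity_filter(records, 0.01)) == 17


class TestCascade:
    def _run(self, tmp_path, spec):
        cohort = simulate_family_cohort(spec)
        vcf = tmp_path / "v.vcf"
        planted_id = write_variant_table(cohort, vcf)
        seq = choose_sequenced_ids(cohort)
        candidates, trace = run_cascade(vcf, cohort.pedigree, seq)
        return planted_id, candidates, trace

    def test_planted_variant_survives(self, tmp_path):
        planted_id, candidates, trace = self._run(tmp_path, CohortSpec(n_variants=1000, seed=5))
        assert planted_id in [c.variant_id for c in candidates]
        counts = trace.counts()
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_common_planted_variant_filtered(self, tmp_path):
        spec = CohortSpec(
            n_variants=500, seed=6, planted_variant=PlantedVariant(af_pop=0.05)
        )
        planted_id, candidates, _ = self._run(tmp_path, spec)
        assert planted_id not in [c.variant_id for c in candidates]

    def test_empty_vcf(self, tmp_path):
        vcf = tmp_path / "empty.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tf\tm\tc0\n"
        )
        ped, aff, unaff = family_with_sequenced()
        candidates, trace = run_cascade(vcf, ped, aff + unaff)
        assert candidates == []
        assert trace.counts() == [0, 0, 0, 0]

    def test_region_functional_filters_commute(self, tmp_path):
        from pedvar.prioritize import read_vcf

        cohort = simulate_family_cohort(CohortSpec(n_variants=800, seed=9))
        vcf = tmp_path / "v.vcf"
        write_variant_table(cohort, vcf)
        records = read_vcf(vcf)
        a = functional_rarity_filter(region_filter(records))
        b = region_filter(functional_rarity_filter(records))
        assert {r.variant_id for r in a} == {r.variant_id for r in b}

    def test_planted_recall_over_seeds(self, tmp_path):
        hits = 0
        for seed in range(20):
            planted_id, candidates, _ = self._run(tmp_path, CohortSpec(n_variants=400, seed=seed))
            hits += planted_id in [c.variant_id for c in candidates]
        assert hits == 20


class TestConsensusRank:
    def test_table2_min5(self, table2):
        _, profiles = table2
        assert consensus_rank(profiles.values(), 5) == ["ANKRD36:p.Ala68Thr", "PBK:p.Gly43Arg"]

    def test_all_benign_excluded(self):
        p = PredictionProfile("x", {"t1": "Benign", "t2": "Tolerated"})
        assert consensus_rank([p], 1) == []

    def test_unknown_verdict_warns_and_counts_zero(self):
        p = PredictionProfile("x", {"t1": "Mysterious"})
        with pytest.warns(UserWarning, match="unknown verdict"):
            assert p.damaging_count == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_counting_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        vocab = sorted(DAMAGING_VOCABULARY) + ["Benign", "Tolerated", "Neutral"]
        profiles = []
        expected = {}
        for v in range(8):
            verdicts = {f"tool{t}": vocab[int(rng.integers(len(vocab)))] for t in range(6)}
            profiles.append(PredictionProfile(f"v{v}", verdicts))
            expected[f"v{v}"] = sum(1 for s in verdicts.values() if s.lower() in DAMAGING_VOCABULARY)
        for min_count in range(7):
            want = sorted((vid for vid, c in expected.items() if c >= min_count),
                          key=lambda vid: (-expected[vid], vid))
            assert consensus_rank(profiles, min_count) == want


class TestConservation:
    def test_conserved_column_is_identity_one(self):
        msa = generate_msa(11, 60, {43}, seed=1)
        frac, _ = conservation_score(msa, 43)
        assert frac == 1.0

    def test_single_sequence_always_one(self):
        msa = generate_msa(1, 30, set(), seed=2)
        assert all(conservation_score(msa, c + 1)[0] == 1.0 for c in range(30))

    def test_matches_direct_frequency_count(self):
        msa = generate_msa(11, 50, {10, 20}, seed=3)
        for col in range(1, 51):
            residues = [str(rec.seq[col - 1]) for rec in msa]
            counts = {r: residues.count(r) for r in set(residues)}
            frac, consensus = conservation_score(msa, col)
            assert frac == max(counts.values()) / 11
            assert counts[consensus] == max(counts.values())

    def test_column_out_of_range(self):
        msa = generate_msa(3, 10, set(), seed=4)
        with pytest.raises(ValueError):
            conservation_score(msa, 11)

    def test_gaps_count_against_consensus(self):
        from Bio.Align import MultipleSeqAlignment
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        msa = MultipleSeqAlignment(
            [SeqRecord(Seq("A-"), id="a"), SeqRecord(Seq("A-"), id="b"), SeqRecord(Seq("AG"), id="c")]
        )
        assert conservation_score(msa, 1) == (1.0, "A")
        frac, consensus = conservation_score(msa, 2)
        assert (frac, consensus) == (1 / 3, "G")
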