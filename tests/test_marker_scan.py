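"""Partition building, dominance, pattern scan and its invariants."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sexlink import (
    GenotypeClass,
    ScanConfig,
    SexRecord,
    build_partition,
    coverage_filter,
    dominant_class,
    enumerate_patterns,
    scan_all,
    scan_locus,
)

from conftest import (
    ABSENT,
    HET,
    HOM,
    INDEL,
    make_locus,
    make_matrix,
    oracle_dominant,
    oracle_scan,
    random_matrix,
    random_partition,
)

THETA = Fraction(4, 5)


class TestBuildPartition:
    def test_first_sex_group_sizes(self, paper_cohort):
        part = build_partition(paper_cohort, "FIRST_SEX")
        sizes = {label: len(ids) for label, ids in part.groups}
        assert sizes == {"FF_FM": 12, "MM_MF": 14}

    def test_stability_and_full(self, paper_cohort):
        stab = build_partition(paper_cohort, "STABILITY")
        assert [(l, len(i)) for l, i in stab.groups] == [("MM", 6), ("FF", 6), ("MF_FM", 14)]
        full = build_partition(paper_cohort, "FULL")
        assert [(l, len(i)) for l, i in full.groups] == [("MM", 6), ("FF", 6), ("MF", 8), ("FM", 6)]

    def test_unknown_second_season_excluded(self, caplog):
        records = [SexRecord("a", "F", "F"), SexRecord("b", "M", "M"), SexRecord("c", "F", None)]
        with caplog.at_level("WARNING"):
            part = build_partition(records, "FIRST_SEX")
        grouped = {s for _, ids in part.groups for s in ids}
        assert grouped == {"a", "b"}
        assert "unknown sex_t2" in caplog.text

    def test_empty_group_is_error(self):
        records = [SexRecord("a", "M", "M"), SexRecord("b", "M", "F")]
        with pytest.raises(ValueError, match="no samples"):
            build_partition(records, "STABILITY")

    def test_unknown_name_rejected(self, paper_cohort):
        with pytest.raises(ValueError, match="unknown partition"):
            build_partition(paper_cohort, "BOGUS")


class TestDominantClass:
    def test_five_of_six_reaches_80_percent(self):
        res = dominant_class([HET] * 5 + [HOM], THETA)
        assert res.dominant is GenotypeClass.HET
        assert res.fraction == Fraction(5, 6)  # exact rational: 5/6 >= 4/5

    def test_four_of_six_does_not(self):
        assert dominant_class([HET] * 4 + [HOM] * 2, THETA).dominant is None

    def test_exact_boundary_four_of_five(self):
        assert dominant_class([HOM] * 4 + [HET], THETA).dominant is GenotypeClass.HOM

    def test_all_absent_dominates(self):
        res = dominant_class([ABSENT] * 6, THETA)
        assert res.dominant is GenotypeClass.ABSENT
        assert res.fraction == 1

    def test_missingness_does_not_veto_called_dominance(self):
        # 4 HET among 4 genotyped samples; 2 ungenotyped samples do not count
        # against the concordance of the called class
        res = dominant_class([HET] * 4 + [ABSENT] * 2, THETA)
        assert res.dominant is GenotypeClass.HET
        assert res.fraction == 1

    def test_absent_takes_precedence_when_group_mostly_ungenotyped(self):
        res = dominant_class([ABSENT] * 8 + [HET] * 2, THETA)
        assert res.dominant is GenotypeClass.ABSENT

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dominant_class([], THETA)

    @pytest.mark.parametrize("theta", [0.5, 0.2, 1.2])
    def test_theta_outside_half_one_rejected(self, theta):
        with pytest.raises(ValueError, match="theta"):
            dominant_class([HET], theta)

    @given(st.lists(st.integers(0, 3), min_size=1, max_size=30),
           st.fractions(min_value=Fraction(51, 100), max_value=1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_direct_counting_oracle(self, codes, theta):
        res = dominant_class(codes, theta)
        expected = oracle_dominant(codes, theta)
        got = None if res.dominant is None else {"HOM": 0, "HET": 1, "INDEL": 2, "ABSENT": 3}[res.dominant.value]
        assert got == expected
        if res.dominant is not None:
            assert res.fraction >= theta


def _scan_one(classes_by_sample, partition, theta="0.8", is_indel=False, **kw):
    matrix = make_matrix([classes_by_sample], is_indel=is_indel)
    config = ScanConfig(partition=partition, theta=theta, **kw)
    idx = {s: i for i, s in enumerate(matrix.samples)}
    return scan_locus(matrix.loci[0], partition, config, idx)


class TestScanLocus:
    def test_het_vs_hom_family(self, paper_cohort):
        part = build_partition(paper_cohort, "FIRST_SEX")
        # sheet order: 8 MF, 6 FM, 6 MM, 6 FF -> MM_MF = MF+MM, FF_FM = FM+FF
        classes = [HET] * 8 + [HOM] * 6 + [HET] * 6 + [HOM] * 6
        call = _scan_one(classes, part)
        assert call.passes and call.family == "HET_VS_HOM"
        assert call.subcode == "het-in-1-of-2"

    def test_presence_absence_family(self, paper_cohort):
        part = build_partition(paper_cohort, "FIRST_SEX")
        classes = [HOM] * 8 + [ABSENT] * 6 + [HOM] * 6 + [ABSENT] * 6
        call = _scan_one(classes, part)
        assert call.passes and call.family == "PRESENCE_ABSENCE"
        assert call.subcode == "absent-in-1-of-2"

    def test_uniform_het_fails(self, paper_cohort):
        part = build_partition(paper_cohort, "FIRST_SEX")
        assert not _scan_one([HET] * 26, part).passes

    def test_uniform_absent_fails(self, paper_cohort):
        # ABSENT is a class: all groups dominant-ABSENT is "all equal"
        part = build_partition(paper_cohort, "STABILITY")
        assert not _scan_one([ABSENT] * 26, part).passes

    def test_hom_vs_het_family_three_groups(self, paper_cohort):
        part = build_partition(paper_cohort, "STABILITY")
        # MM group HOM, FF and MF_FM HET -> hom in the minority of groups
        classes = [HET] * 8 + [HET] * 6 + [HOM] * 6 + [HET] * 6
        call = _scan_one(classes, part)
        assert call.passes and call.family == "HOM_VS_HET"
        assert call.subcode == "hom-in-1-of-3"

    def test_indel_pattern_is_other_family(self, paper_cohort):
        part = build_partition(paper_cohort, "FIRST_SEX")
        classes = [INDEL] * 8 + [HOM] * 6 + [INDEL] * 6 + [HOM] * 6
        call = _scan_one(classes, part, is_indel=True)
        assert call.passes and call.family == "OTHER"

    def test_refined_alphabet_separates_hom_ref_from_hom_alt(self, paper_cohort):
        from sexlink import GenotypeMatrix, LocusRecord

        part = build_partition(paper_cohort, "FIRST_SEX")
        # all collapsed-HOM, but MM_MF side is HOM_ALT while FF_FM is HOM_REF
        refined = np.array([2] * 8 + [0] * 6 + [2] * 6 + [0] * 6, dtype=np.int8)
        locus = make_locus([HOM] * 26)
        locus.per_sample_refined = refined
        matrix = GenotypeMatrix(samples=[r.sample_id for r in paper_cohort], loci=[locus])
        idx = {s: i for i, s in enumerate(matrix.samples)}
        collapsed = scan_locus(locus, part, ScanConfig(partition=part, alphabet="collapsed4"), idx)
        refined_call = scan_locus(locus, part, ScanConfig(partition=part, alphabet="refined"), idx)
        assert not collapsed.passes
        assert refined_call.passes


class TestEnumeratePatterns:
    def test_two_groups_four_classes_gives_twelve(self):
        assert len(enumerate_patterns(2, 4)) == 12

    def test_count_matches_brute_force_formula(self):
        for k in (1, 2, 3, 4):
            for a in (2, 3, 4):
                assert len(enumerate_patterns(k, a)) == a**k - a

    def test_single_group_has_no_patterns(self):
        assert enumerate_patterns(1, 4) == []

    def test_patterns_unique_and_not_constant(self):
        pats = enumerate_patterns(3, 4)
        assert len(set(pats)) == len(pats)
        assert all(len(set(p)) > 1 for p in pats)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            enumerate_patterns(0, 4)


class TestScanAll:
    def test_planted_locus_found_among_neutral(self, paper_cohort):
        rng = np.random.default_rng(5)
        part = build_partition(paper_cohort, "FIRST_SEX")
        neutral = rng.choice([HOM, HET], size=(100, 26), p=[0.5, 0.5]).tolist()
        planted = [HET] * 8 + [HOM] * 6 + [HET] * 6 + [HOM] * 6
        matrix = make_matrix(neutral + [planted])
        calls, families = scan_all(matrix, ScanConfig(partition=part))
        planted_key = matrix.loci[-1].key
        assert planted_key in [c.locus.key for c in calls]
        assert sum(families.values()) == len(calls)

    def test_empty_matrix(self, paper_cohort):
        part = build_partition(paper_cohort, "FIRST_SEX")
        matrix = make_matrix([], samples=[r.sample_id for r in paper_cohort])
        calls, families = scan_all(matrix, ScanConfig(partition=part))
        assert calls == [] and not families

    def test_output_sorted_by_coordinate(self, paper_cohort):
        part = build_partition(paper_cohort, "FIRST_SEX")
        # sheet order 8 MF, 6 FM, 6 MM, 6 FF: MM_MF side HET, FF_FM side HOM
        planted = [HET] * 8 + [HOM] * 6 + [HET] * 6 + [HOM] * 6
        m = make_matrix([planted, planted, planted])
        m.loci[0].chrom, m.loci[0].pos = "ctg2", 100
        m.loci[1].chrom, m.loci[1].pos = "ctg1", 500
        m.loci[2].chrom, m.loci[2].pos = "ctg1", 200
        calls, _ = scan_all(m, ScanConfig(partition=part))
        keys = [c.locus.key for c in calls]
        assert len(keys) == 3
        assert keys == [("ctg1", 200), ("ctg1", 500), ("ctg2", 100)]

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            n_samples = int(rng.integers(4, 11))
            n_loci = int(rng.integers(1, 21))
            matrix = random_matrix(rng, n_loci, n_samples)
            part = random_partition(rng, matrix.samples, int(rng.integers(2, 5)))
            calls, _ = scan_all(matrix, ScanConfig(partition=part))
            assert [c.locus.key for c in calls] == oracle_scan(matrix, part, THETA)

    def test_monotone_in_theta(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            matrix = random_matrix(rng, 40, 10)
            part = random_partition(rng, matrix.samples, 3)
            loose, _ = scan_all(matrix, ScanConfig(partition=part, theta="0.8"))
            strict, _ = scan_all(matrix, ScanConfig(partition=part, theta="0.9"))
            assert set(c.locus.key for c in strict) <= set(c.locus.key for c in loose)

    def test_invariant_under_column_permutation(self):
        rng = np.random.default_rng(17)
        matrix = random_matrix(rng, 30, 8)
        part = random_partition(rng, matrix.samples, 3)
        calls, _ = scan_all(matrix, ScanConfig(partition=part))
        perm = rng.permutation(matrix.n_samples)
        shuffled = make_matrix(
            [locus.per_sample_class[perm].tolist() for locus in matrix.loci],
            samples=[matrix.samples[i] for i in perm],
        )
        calls2, _ = scan_all(shuffled, ScanConfig(partition=part))
        assert [c.locus.key for c in calls] == [c.locus.key for c in calls2]

    def test_passing_patterns_in_enumeration(self):
        rng = np.random.default_rng(19)
        code = {"HOM": 0, "HET": 1, "INDEL": 2, "ABSENT": 3}
        patterns = set(enumerate_patterns(3, 4))
        matrix = random_matrix(rng, 60, 9)
        part = random_partition(rng, matrix.samples, 3)
        calls, _ = scan_all(matrix, ScanConfig(partition=part))
        for call in calls:
            tup = tuple(code[g.dominant.value] for g in call.per_group)
            assert tup in patterns


class TestCoverageFilter:
    def _call(self, classes, depths, part, paper_cohort=None):
        m = make_matrix([classes], depths=depths)
        calls, _ = scan_all(m, ScanConfig(partition=part))
        return m, calls

    def test_sixteen_x_retained_fifteen_removed(self, paper_cohort):
        part = build_partition(paper_cohort, "FIRST_SEX")
        classes = [HET] * 8 + [HOM] * 6 + [HET] * 6 + [HOM] * 6
        _, calls16 = self._call(classes, [16] * 26, part)
        assert len(coverage_filter(calls16, 15.0)) == 1
        _, calls15 = self._call(classes, [15] * 26, part)
        kept = coverage_filter(calls15, 15.0)
        assert kept == [] and calls15[0].passes_coverage is False

    def test_mean_over_genotyped_samples_only(self, paper_cohort):
        part = build_partition(paper_cohort, "FIRST_SEX")
        # sheet order 8 MF, 6 FM, 6 MM, 6 FF: MM_MF side HET, FM ungenotyped,
        # FF homozygous -> passes HET vs HOM
        classes = [HET] * 8 + [ABSENT] * 6 + [HET] * 6 + [HOM] * 6
        depths = [20] * 8 + [0] * 6 + [20] * 6 + [12] * 6
        m = make_matrix([classes], depths=depths)
        calls, _ = scan_all(m, ScanConfig(partition=part))
        assert len(calls) == 1
        coverage_filter(calls, 15.0)
        # hand mean over the 20 genotyped samples: (14*20 + 6*12) / 20 = 17.6
        assert calls[0].mean_depth == pytest.approx(17.6)

    def test_hand_computed_mixed_fixture(self, paper_cohort):
        part = build_partition(paper_cohort, "FIRST_SEX")
        classes = [HET] * 8 + [HOM] * 6 + [HET] * 6 + [HOM] * 6
        means = []
        rng = np.random.default_rng(23)
        loci = []
        for _ in range(5):
            depths = rng.integers(5, 30, size=26)
            means.append(depths.mean())
            loci.append(depths.tolist())
        m = make_matrix([classes] * 5)
        for locus, depths in zip(m.loci, loci):
            locus.per_sample_depth = np.array(depths, dtype=np.int32)
        calls, _ = scan_all(m, ScanConfig(partition=part))
        kept = coverage_filter(calls, 15.0)
        expected_kept = [m.loci[i].key for i, mu in enumerate(means) if mu > 15.0]
        assert [c.locus.key for c in kept] == expected_kept
        for call, mu in zip(calls, means):
            assert call.mean_depth == pytest.approx(mu)
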