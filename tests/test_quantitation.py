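"""Label-free comparison layer: normalization, IF/F selection, DAve, presence test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import exhaustive_presence_p
from psmnet import (
    GroupDesign,
    PSMMatrix,
    anova_f_selection,
    cluster_qc,
    combine_daps,
    dave_index,
    generate_cohort,
    group_mean_profiles,
    identification_frequency,
    normalize_total_signal,
    overlap_partition,
    pairwise_dave_filter,
    pairwise_dave_table,
    presence_ranksum_test,
    presence_sets,
    select_daps,
    select_daps_by_if,
    SimulationConfig,
    spearman_group_correlation,
)


class TestNormalization:
    def test_worked_example_mean_target(self):
        values = pd.DataFrame({"s1": [10, 90], "s2": [100, 200]}, index=["p1", "p2"])
        out = normalize_total_signal(PSMMatrix(values))
        # totals 100 and 300, target mean 200, so subject 1 scales by 2
        assert out.values.loc["p1", "s1"] == pytest.approx(20.0)
        assert out.values.sum(axis=0).tolist() == pytest.approx([200.0, 200.0])
        assert out.normalized

    def test_equal_totals_unchanged(self):
        values = pd.DataFrame({"s1": [10, 90], "s2": [40, 60]}, index=["p1", "p2"])
        out = normalize_total_signal(PSMMatrix(values))
        pd.testing.assert_frame_equal(out.values, values.astype(float))

    def test_zeros_stay_exactly_zero(self, noisy_cohort):
        matrix, _, _ = noisy_cohort
        out = normalize_total_signal(matrix)
        assert ((matrix.values.to_numpy() == 0) == (out.values.to_numpy() == 0)).all()

    def test_all_zero_subject_named_in_error(self):
        values = pd.DataFrame({"s1": [1, 2], "bad": [0, 0]}, index=["p1", "p2"])
        with pytest.raises(ValueError, match="bad"):
            normalize_total_signal(PSMMatrix(values))

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_column_totals_equal_after_normalization(self, seed):
        rng = np.random.default_rng(seed)
        values = pd.DataFrame(rng.integers(0, 50, size=(20, 6)) + rng.binomial(1, 0.5, (20, 6)))
        values.iloc[0] += 1  # no all-zero column
        out = normalize_total_signal(PSMMatrix(values))
        totals = out.values.sum(axis=0).to_numpy()
        np.testing.assert_allclose(totals, totals[0], rtol=1e-9)


class TestGroupProfiles:
    def test_means_match_per_protein_loop(self, noisy_cohort):
        matrix, design, _ = noisy_cohort
        profiles = group_mean_profiles(matrix, design)
        for group in design.groups:
            subjects = design.subjects_in(group)
            for pid in matrix.protein_ids[:25]:
                expected = sum(matrix.values.loc[pid, s] for s in subjects) / len(subjects)
                assert profiles.loc[pid, group] == pytest.approx(expected)

    def test_identical_columns_give_the_column(self, toy_matrix):
        matrix, design = toy_matrix
        profiles = group_mean_profiles(matrix, design)
        assert profiles.loc["pA", "A"] == pytest.approx(11.0)
        assert profiles.loc["pB", "B"] == pytest.approx(8.0)


class TestSpearman:
    def test_self_and_reversed_profiles(self):
        profiles = pd.DataFrame({"A": [1, 2, 3, 4, 5], "B": [5, 4, 3, 2, 1]})
        out = spearman_group_correlation(profiles)
        assert out.loc["A", "A"] == 1.0
        assert out.loc["A", "B"] == pytest.approx(-1.0)

    def test_textbook_rank_example(self):
        profiles = pd.DataFrame({"A": [1, 2, 3, 4, 5], "B": [1, 3, 2, 5, 4]})
        # 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2) = 4
        assert spearman_group_correlation(profiles).loc["A", "B"] == pytest.approx(0.8)

    def test_symmetric_unit_diagonal(self, noisy_cohort):
        matrix, design, _ = noisy_cohort
        out = spearman_group_correlation(group_mean_profiles(matrix, design))
        np.testing.assert_allclose(out.to_numpy(), out.to_numpy().T)
        np.testing.assert_allclose(np.diag(out.to_numpy()), 1.0)

    def test_constant_profile_reported_missing(self):
        profiles = pd.DataFrame({"A": [1, 2, 3], "B": [4, 4, 4]})
        assert math.isnan(spearman_group_correlation(profiles).loc["A", "B"])


class TestOverlapPartition:
    def test_toy_sets_match_enumeration(self):
        sets_ = {"X": {"a", "b", "c"}, "Y": {"b", "c", "d"}, "Z": {"c", "e"}}
        regions = overlap_partition(sets_)
        universe = set().union(*sets_.values())
        for element in universe:
            member = frozenset(g for g in sets_ if element in sets_[g])
            assert regions[member] >= 1
        assert regions[frozenset({"X", "Y", "Z"})] == 1  # c
        assert regions[frozenset({"X", "Y"})] == 1  # b
        assert regions[frozenset({"Z"})] == 1  # e
        assert sum(regions.values()) == len(universe)

    def test_identical_sets_fill_only_triple_region(self):
        s = {"p1", "p2", "p3"}
        regions = overlap_partition({"A": set(s), "B": set(s), "C": set(s)})
        assert regions[frozenset({"A", "B", "C"})] == 3
        assert sum(regions.values()) == 3

    def test_disjoint_sets_fill_only_unique_regions(self):
        regions = overlap_partition({"A": {"a"}, "B": {"b"}, "C": {"c", "d"}})
        assert regions[frozenset({"A"})] == 1
        assert regions[frozenset({"C"})] == 2
        assert regions[frozenset({"A", "B"})] == 0


class TestIdentificationFrequency:
    @pytest.mark.parametrize(
        "detected,size,expected", [(4, 7, 57), (6, 7, 86), (5, 5, 100), (1, 4, 25), (0, 6, 0)]
    )
    def test_printed_percent_convention(self, detected, size, expected):
        values = pd.DataFrame(
            [[1] * detected + [0] * (size - detected) + [1, 1]],
            columns=[f"g{i}" for i in range(size)] + ["o1", "o2"],
            index=["p"],
        )
        design = GroupDesign(
            {**{f"g{i}": "G" for i in range(size)}, "o1": "O", "o2": "O"}
        )
        assert identification_frequency(PSMMatrix(values), design).loc["p", "G"] == expected

    @pytest.mark.parametrize(
        "ifs,expected",
        [((60, 40, 0), True), ((100, 100, 100), False), ((50, 40, 0), False), ((0, 0, 0), False)],
    )
    def test_if_rule_boundaries(self, ifs, expected):
        table = pd.DataFrame([ifs], columns=["A", "B", "C"], index=["p"])
        assert (("p" in select_daps_by_if(table)) is expected)


class TestAnovaSelection:
    def test_identical_values_not_selected(self):
        values = pd.DataFrame({f"s{i}": [5.0] for i in range(6)}, index=["p"])
        design = GroupDesign({f"s{i}": ("A" if i < 3 else "B") for i in range(6)})
        out = anova_f_selection(PSMMatrix(values, normalized=True), design)
        assert out.loc["p", "F_ratio"] == 0.0
        assert not out.loc["p", "selected"]

    def test_textbook_sum_of_squares_oracle(self):
        # A=(10,10,11), B=(2,2,3), C=(2,3,2): SSB=128, SSW=2, df=(2,6) -> F=192
        values = pd.DataFrame(
            [[10, 10, 11, 2, 2, 3, 2, 3, 2]],
            columns=[f"s{i}" for i in range(9)], index=["p"],
        )
        design = GroupDesign({f"s{i}": "ABC"[i // 3] for i in range(9)})
        out = anova_f_selection(PSMMatrix(values, normalized=True), design)
        assert out.loc["p", "F_ratio"] == pytest.approx(192.0)
        from scipy.stats import f as fdist
        assert out.loc["p", "p_value"] == pytest.approx(fdist.sf(192.0, 2, 6))
        assert out.loc["p", "selected"]

    def test_joint_condition_required(self):
        from psmnet._stats import apply_f_rule
        assert not apply_f_rule(np.array([3.4]), np.array([0.04]))[0]
        assert not apply_f_rule(np.array([10.0]), np.array([0.2]))[0]
        assert apply_f_rule(np.array([3.5]), np.array([0.05]))[0]


class TestDAve:
    @pytest.mark.parametrize(
        "a,b,expected", [(5, 0, 2.0), (0, 5, -2.0), (4, 4, 0.0), (3, 1, 1.0)]
    )
    def test_worked_examples(self, a, b, expected):
        assert dave_index(a, b) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        assert math.isnan(dave_index(0.0, 0.0))

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(min_value=0, max_value=1e6),
        st.floats(min_value=0, max_value=1e6),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_antisymmetry_bounds_scale_invariance(self, a, b, c):
        if a == 0 and b == 0:
            return
        d = dave_index(a, b)
        assert abs(d) <= 2.0
        assert dave_index(b, a) == pytest.approx(-d)
        assert dave_index(c * a, c * b) == pytest.approx(d, rel=1e-9)

    @pytest.mark.parametrize("value,kept", [(0.5, True), (0.4, True), (0.39, False), (-2.0, True)])
    def test_magnitude_filter(self, value, kept):
        assert pairwise_dave_filter(value) is kept


class TestCombineDaps:
    def test_disjoint_sets_union(self):
        dave = pd.DataFrame({"A_vs_B": [1.0] * 7}, index=[f"p{i}" for i in range(7)])
        table = combine_daps({"p0", "p1", "p2"}, {"p3", "p4", "p5", "p6"}, dave)
        assert len(table) == 7
        assert set(table["source"]) == {"IF", "LDA"}

    def test_identical_sets_source_both(self):
        dave = pd.DataFrame({"A_vs_B": [2.0, -2.0]}, index=["p0", "p1"])
        table = combine_daps({"p0", "p1"}, {"p0", "p1"}, dave)
        assert len(table) == 2
        assert (table["source"] == "both").all()

    def test_planted_exclusives_selected_via_if(self, clean_cohort):
        matrix, design, truth = clean_cohort
        table = select_daps(matrix, design)
        for pid in truth.all_exclusive():
            assert pid in table.index
            assert table.loc[pid, "source"] in ("IF", "both")
            # exclusive proteins sit at the DAve boundary against some group
            daves = [table.loc[pid, c] for c in table.columns if c.startswith("DAve_")]
            assert 2.0 in [abs(v) for v in daves]


class TestPresenceTest:
    def _matrix(self, pattern_a, pattern_b):
        names_a = [f"a{i}" for i in range(len(pattern_a))]
        names_b = [f"b{i}" for i in range(len(pattern_b))]
        values = pd.DataFrame([list(pattern_a) + list(pattern_b)],
                              columns=names_a + names_b, index=["p"])
        design = GroupDesign({**{s: "A" for s in names_a}, **{s: "B" for s in names_b}})
        return PSMMatrix(values), design

    def test_fully_separated_presence(self):
        matrix, design = self._matrix([3] * 5, [0] * 11)
        out = presence_ranksum_test(matrix, design, "A", "B")
        assert out.loc["p", "p_value"] == pytest.approx(2 / math.comb(16, 5))
        assert out.loc["p", "count_A"] == 5 and out.loc["p", "percent_B"] == 0

    def test_identical_presence_patterns(self):
        matrix, design = self._matrix([1, 0, 1], [1, 0, 1])
        assert presence_ranksum_test(matrix, design, "A", "B").loc["p", "p_value"] == 1.0

    def test_four_vs_seven_separation(self):
        matrix, design = self._matrix([2] * 4, [0] * 7)
        out = presence_ranksum_test(matrix, design, "A", "B")
        assert out.loc["p", "p_value"] == pytest.approx(2 / math.comb(11, 4))

    def test_matches_exhaustive_permutation_oracle(self, rng):
        for n_a, n_b in [(2, 3), (3, 3), (4, 5), (5, 6), (2, 10)]:
            for _ in range(4):
                pattern = rng.integers(0, 2, size=n_a + n_b)
                matrix, design = self._matrix(pattern[:n_a], pattern[n_a:])
                out = presence_ranksum_test(matrix, design, "A", "B")
                expected = exhaustive_presence_p(list(pattern), n_a)
                assert out.loc["p", "p_value"] == pytest.approx(expected)

    def test_small_group_rejected(self):
        matrix, design = self._matrix([1, 1], [1, 0, 1])
        values = matrix.values.rename(columns={"a1": "x"})
        design2 = GroupDesign({"a0": "A", "x": "B", "b0": "B", "b1": "B", "b2": "B"})
        with pytest.raises(ValueError):
            presence_ranksum_test(PSMMatrix(values), design2, "A", "B")


class TestClusterQC:
    def test_duplicate_subjects_merge_first_at_zero(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.integers(1, 50, size=(10, 4)).astype(float),
                              columns=["s1", "s2", "s3", "s4"])
        values["s2"] = values["s1"]
        design = GroupDesign({"s1": "A", "s2": "A", "s3": "B", "s4": "B"})
        qc = cluster_qc(PSMMatrix(values), design)
        assert qc.linkage[0, 2] == pytest.approx(0.0)
        assert {int(qc.linkage[0, 0]), int(qc.linkage[0, 1])} == {0, 1}

    def test_variance_shares_sum_to_one(self, noisy_cohort):
        matrix, design, _ = noisy_cohort
        qc = cluster_qc(matrix, design)
        assert qc.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_separated_groups_split_at_top(self):
        config = SimulationConfig(
            group_sizes=(5, 5), group_labels=("A", "B"), n_proteins=60,
            detection_prob=1.0, n_exclusive_per_group=20,
            n_foldchange_daps=10, fold_change=6.0, dispersion=50.0, seed=13,
        )
        matrix, design, _ = generate_cohort(config)
        table = select_daps(matrix, design)
        restricted = PSMMatrix(matrix.values.loc[sorted(table.index)].astype(float))
        qc = cluster_qc(restricted, design)
        clusters = qc.cut(2)
        by_group = {g: {clusters[s] for s in design.subjects_in(g)} for g in design.groups}
        assert all(len(v) == 1 for v in by_group.values())
        assert by_group["A"] != by_group["B"]

    def test_too_few_proteins_rejected(self):
        values = pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [3.0]}, index=["p"])
        with pytest.raises(ValueError):
            cluster_qc(PSMMatrix(values), GroupDesign({"s1": "A", "s2": "A", "s3": "B"}))
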