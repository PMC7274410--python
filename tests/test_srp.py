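"""SRP selection, direction/cluster rules, ANOVA and centroid clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crosstol.srp import (
    CONDITIONS,
    STRESSES,
    UndefinedStatisticError,
    anova_oneway,
    assign_cluster,
    direction_of,
    fold_change,
    hierarchical_cluster,
    ratio_matrix,
    select_srp,
)
from crosstol.simulate import generate_spot_table

from oracles import anova_from_scratch, centroid_merges_brute_force


class TestAnova:
    def test_equal_means_give_zero_f(self):
        groups = [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]
        f, p = anova_oneway(*groups)
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_groups_equal_t_squared(self):
        from oracles import pooled_t_from_scratch

        rng = np.random.default_rng(5)
        a, b = rng.normal(size=6), rng.normal(loc=1.0, size=5)
        f, p_f = anova_oneway(a, b)
        t, p_t = pooled_t_from_scratch(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            groups = [
                rng.normal(loc=rng.uniform(-1, 1), size=rng.integers(2, 8))
                for _ in range(rng.integers(2, 6))
            ]
            f, p = anova_oneway(*groups)
            f_ref, p_ref = anova_from_scratch(groups)
            assert f == pytest.approx(f_ref, rel=1e-10)
            assert p == pytest.approx(p_ref, rel=1e-10)

    def test_all_identical_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            anova_oneway([2.0, 2.0], [2.0, 2.0])


class TestFoldChange:
    @pytest.mark.parametrize(
        "treat,ctrl,expected", [(3, 2, 1.5), (2, 2, 1.0), (1, 2, 0.5)]
    )
    def test_ratio(self, treat, ctrl, expected):
        assert fold_change(treat, ctrl) == expected

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)

    def test_threshold_is_inclusive(self):
        assert direction_of(1.5) == "up"
        assert direction_of(1.0 / 1.5) == "down"
        assert direction_of(1.49) == "unchanged"


class TestAssignCluster:
    @pytest.mark.parametrize(
        "dirs,expected",
        [
            (("up", "unchanged", "unchanged"), "I"),
            (("down", "down", "down"), "II"),
            (("unchanged", "unchanged", "unchanged"), "III"),
            (("up", "down", "unchanged"), "IV"),
        ],
    )
    def test_documented_examples(self, dirs, expected):
        assert assign_cluster(dict(zip(STRESSES, dirs))) == expected

    def test_exhaustive_truth_table(self):
        """All 27 direction triples map to exactly one class, consistent
        with the counting definition (any-up/no-down -> I, any-down/no-up
        -> II, none -> III, both -> IV)."""
        for triple in itertools.product(
            ["up", "down", "unchanged"], repeat=3
        ):
            cluster = assign_cluster(dict(zip(STRESSES, triple)))
            n_up = triple.count("up")
            n_down = triple.count("down")
            if n_up and n_down:
                assert cluster == "IV"
            elif n_up:
                assert cluster == "I"
            elif n_down:
                assert cluster == "II"
            else:
                assert cluster == "III"

    def test_missing_stress_rejected(self):
        with pytest.raises(ValueError):
            assign_cluster({"WS": "up"})


class TestSelectSrp:
    def test_recovers_planted_spots(self):
        table, truth = generate_spot_table(seed=42)
        records = select_srp(table)
        selected = {r.spot_id for r in records}
        planted = set(truth.planted_srp)
        assert len(selected & planted) >= 9
        assert len(selected - planted) <= 2

    def test_clusters_match_planted_directions(self):
        table, truth = generate_spot_table(seed=42)
        for rec in select_srp(table):
            if rec.spot_id in truth.planted_srp:
                expected = assign_cluster(truth.planted_srp[rec.spot_id])
                assert rec.cluster == expected, rec.spot_id

    def test_identical_spot_excluded(self):
        rows = [
            {
                "spot_id": "S1", "accession": "X", "category": "other",
                "cultivar": "cv", "condition": cond, "replicate": r,
                "density": 100.0,
            }
            for cond in CONDITIONS
            for r in (1, 2, 3)
        ]
        assert select_srp(pd.DataFrame(rows)) == []

    def test_boundary_fold_change_is_included(self):
        # WS exactly 1.5-fold up with clear significance -> selected, up
        rng = np.random.default_rng(2)
        rows = []
        for cond in CONDITIONS:
            mean = 150.0 if cond == "WS" else 100.0
            for r in range(1, 4):
                rows.append(
                    {
                        "spot_id": "S1", "accession": "X",
                        "category": "other", "cultivar": "cv",
                        "condition": cond, "replicate": r,
                        # symmetric offsets keep each group mean exact
                        "density": mean + [0.0, -1.0, 1.0][r - 1],
                    }
                )
        records = select_srp(pd.DataFrame(rows))
        assert len(records) == 1
        assert records[0].directions["WS"] == "up"
        assert records[0].fold_changes["WS"] == pytest.approx(1.5)

    def test_selection_monotone_in_thresholds(self):
        table, _ = generate_spot_table(seed=8, replicate_cv=0.25)
        n_loose = len(select_srp(table, fc_threshold=1.2, alpha=0.10))
        n_mid = len(select_srp(table, fc_threshold=1.5, alpha=0.10))
        n_strict = len(select_srp(table, fc_threshold=1.5, alpha=0.01))
        assert n_loose >= n_mid >= n_strict

    def test_fdr_correction_is_more_conservative(self):
        table, _ = generate_spot_table(seed=8, replicate_cv=0.25)
        raw = {r.spot_id for r in select_srp(table)}
        adjusted = {r.spot_id for r in select_srp(table, fdr_correct=True)}
        assert adjusted <= raw

    def test_cluster_invariant_to_density_rescaling(self):
        table, truth = generate_spot_table(seed=42)
        records = {r.spot_id: r.cluster for r in select_srp(table)}
        scaled = table.copy()
        scaled["density"] *= 7.3
        rescaled = {r.spot_id: r.cluster for r in select_srp(scaled)}
        assert records == rescaled


class TestHierarchicalCluster:
    def test_two_rows_merge_at_their_distance(self):
        m = np.array([[0.0, 0.0], [3.0, 4.0]])
        tree, order = hierarchical_cluster(m)
        assert tree.shape == (1, 4)
        assert tree[0, 2] == pytest.approx(5.0)
        assert sorted(order.tolist()) == [0, 1]

    def test_duplicate_rows_merge_first_at_zero(self):
        m = np.array([[1.0, 1.0], [5.0, 5.0], [1.0, 1.0]])
        tree, _ = hierarchical_cluster(m)
        assert tree[0, 2] == pytest.approx(0.0)
        assert {int(tree[0, 0]), int(tree[0, 1])} == {0, 2}

    def test_merge_heights_match_brute_force(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            m = rng.normal(size=(rng.integers(3, 8), 4))
            tree, _ = hierarchical_cluster(m)
            expected = centroid_merges_brute_force(m)
            np.testing.assert_allclose(
                np.sort(tree[:, 2]), np.sort(expected), rtol=1e-10
            )

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(np.array([[1.0, np.nan], [0.0, 0.0]]))


class TestRatioMatrix:
    def test_unresponsive_rows_stay_near_one(self):
        table, truth = generate_spot_table(seed=42)
        ratios = ratio_matrix(table)
        null_spots = [
            s for s in ratios.index if s not in truth.planted_srp
        ]
        sub = ratios.loc[null_spots, list(STRESSES)]
        assert ((sub >= 1 / 1.5) & (sub <= 1.5)).all().all()


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    means=st.lists(
        st.floats(min_value=10.0, max_value=1000.0), min_size=2, max_size=5
    ),
    scale=st.floats(min_value=0.1, max_value=10.0),
)
def test_anova_f_invariant_to_rescaling(means, scale):
    """The F statistic is scale-free: multiplying all densities by a
    constant leaves it unchanged."""
    rng = np.random.default_rng(1)
    groups = [rng.normal(m, 1.0 + m / 100, size=4) for m in means]
    try:
        f1, _ = anova_oneway(*groups)
    except UndefinedStatisticError:
        return
    f2, _ = anova_oneway(*[g * scale for g in groups])
    assert f1 == pytest.approx(f2, rel=1e-8)
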