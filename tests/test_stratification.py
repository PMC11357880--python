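import math

import numpy as np
import pytest

from vnnsurv.interpretation import ImpactTable, ShapMatrix
from vnnsurv.stratification import (
    StratificationError,
    assign_levels,
    assign_subtypes,
    gpi_score,
    intersection_counts,
    make_gpi_result,
    optimize_thresholds,
    pairwise_interactions,
    sub_subtype_by_shap_rank,
)

from conftest import make_cohort


def impact_table(mapping):
    names = list(mapping)
    vals = np.array([mapping[f] for f in names])
    return ImpactTable(names, vals, np.ones(len(names), int),
                       np.zeros(len(names), bool))


class TestGPI:
    def test_no_alterations_score_zero(self):
        co = make_cohort(np.zeros((3, 2), np.int8), [1, 2, 3], [1, 1, 1],
                         names=["A", "B"])
        scores = gpi_score(co, impact_table({"A": 0.5, "B": -0.2}), ["A", "B"])
        np.testing.assert_array_equal(scores, [0, 0, 0])

    def test_single_key_feature(self):
        co = make_cohort(np.array([[1]], np.int8), [1], [1], names=["A"])
        assert gpi_score(co, impact_table({"A": 0.05}), ["A"])[0] == pytest.approx(0.05)

    def test_matches_dot_product_oracle(self):
        rng = np.random.default_rng(21)
        X = rng.integers(0, 2, (20, 8)).astype(np.int8)
        names = [f"G{j}" for j in range(8)]
        co = make_cohort(X, np.ones(20), np.ones(20), names=names)
        weights = dict(zip(names, rng.normal(size=8)))
        scores = gpi_score(co, impact_table(weights), names)
        expected = X @ np.array([weights[f] for f in names])
        np.testing.assert_allclose(scores, expected, atol=1e-12)

    def test_linearity_on_disjoint_profiles(self):
        names = ["A", "B", "C", "D"]
        w = impact_table(dict(zip(names, [0.1, -0.2, 0.3, 0.05])))
        f1 = np.array([[1, 0, 0, 0]], np.int8)
        f2 = np.array([[0, 0, 1, 1]], np.int8)
        co = lambda X: make_cohort(X, [1.0], [1], names=names)
        s1 = gpi_score(co(f1), w, names)[0]
        s2 = gpi_score(co(f2), w, names)[0]
        s12 = gpi_score(co(f1 | f2), w, names)[0]
        assert s12 == pytest.approx(s1 + s2, abs=1e-14)

    def test_missing_key_feature_rejected(self):
        co = make_cohort(np.zeros((1, 1), np.int8), [1], [1], names=["A"])
        with pytest.raises(StratificationError, match="ZZ"):
            gpi_score(co, impact_table({"A": 0.1}), ["ZZ"])


class TestAssignLevels:
    def test_published_thresholds_map_zero_to_II(self):
        assert assign_levels([0.0], -0.015, 0.025) == ["II"]

    def test_boundary_goes_to_lower_level(self):
        assert assign_levels([-0.015, 0.025, 0.0251], -0.015, 0.025) == [
            "I", "II", "III"
        ]

    def test_partitions_any_score_set(self):
        rng = np.random.default_rng(22)
        scores = rng.normal(size=100)
        levels = assign_levels(scores, -0.5, 0.5)
        assert len(levels) == 100
        counts = {lv: levels.count(lv) for lv in ("I", "II", "III")}
        assert sum(counts.values()) == 100

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(StratificationError):
            assign_levels([0.0], 0.5, -0.5)


class TestOptimizeThresholds:
    def planted(self):
        rng = np.random.default_rng(23)
        scores = np.concatenate([np.full(60, -1.0), np.zeros(60), np.ones(60)])
        time = np.concatenate([
            rng.exponential(10, 60), rng.exponential(2, 60), rng.exponential(0.5, 60)
        ])
        return scores, time, np.ones(180, int)

    def test_recovers_planted_cutpoints(self):
        scores, time, event = self.planted()
        (t1, t2), diag = optimize_thresholds(
            scores, time, event, [-1.5, -0.5, 0.5, 1.5], min_group=10
        )
        assert -1.0 < t1 < 0.0 and 0.0 < t2 < 1.0
        assert not diag.empty

    def test_grid_containing_cutpoints_selects_them(self):
        scores, time, event = self.planted()
        (t1, t2), _ = optimize_thresholds(
            scores, time, event, [-2.0, -0.5, 0.5, 2.0], min_group=10
        )
        assert (t1, t2) == (-0.5, 0.5)

    def test_constant_scores_inadmissible(self):
        with pytest.raises(StratificationError, match="no admissible"):
            optimize_thresholds(
                np.zeros(30), np.arange(1.0, 31.0), np.ones(30, int),
                [-1.0, 0.5, 1.0], min_group=5,
            )


def fisher_two_sided_oracle(a, b, c, d):
    """Hypergeometric enumeration: sum of point probabilities <= P(observed)."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def pmf(k):
        return (
            math.comb(col1, k) * math.comb(n - col1, row1 - k) / math.comb(n, row1)
        )

    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


class TestInteractions:
    def test_identical_columns_co_occur(self):
        X = np.zeros((20, 2), np.int8)
        X[:10] = 1
        co = make_cohort(X, np.ones(20), np.ones(20), names=["A", "B"])
        table = pairwise_interactions(co, ["A", "B"]).table
        row = table.iloc[0]
        assert row["label"] == "co-occurrence"
        assert np.isinf(row["odds_ratio"])
        assert row["p"] == pytest.approx(fisher_two_sided_oracle(10, 0, 0, 10))

    def test_p_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(24)
        for _ in range(40):
            n = int(rng.integers(8, 41))
            X = rng.integers(0, 2, (n, 2)).astype(np.int8)
            if X[:, 0].min() == X[:, 0].max() or X[:, 1].min() == X[:, 1].max():
                continue
            co = make_cohort(X, np.ones(n), np.ones(n), names=["A", "B"])
            row = pairwise_interactions(co, ["A", "B"]).table.iloc[0]
            oracle = fisher_two_sided_oracle(row["a"], row["b"], row["c"], row["d"])
            assert row["p"] == pytest.approx(oracle, rel=1e-9)

    def test_type_one_error_controlled_under_independence(self):
        rng = np.random.default_rng(25)
        labelled = total = 0
        for _ in range(50):
            X = (rng.random((200, 6)) < 0.3).astype(np.int8)
            co = make_cohort(X, np.ones(200), np.ones(200),
                             names=[f"G{j}" for j in range(6)])
            t = pairwise_interactions(co, co.feature_names).table
            labelled += (t["label"] != "none").sum()
            total += len(t)
        assert labelled / total <= 0.05 + 0.05

    def test_constant_feature_excluded(self):
        X = np.zeros((10, 3), np.int8)
        X[:5, 0] = 1
        X[::2, 1] = 1
        co = make_cohort(X, np.ones(10), np.ones(10), names=["A", "B", "C"])
        with pytest.warns(UserWarning, match="'C'"):
            table = pairwise_interactions(co, ["A", "B", "C"]).table
        assert set(zip(table["feature_a"], table["feature_b"])) == {("A", "B")}


class TestIntersections:
    def test_three_patterns(self):
        X = np.array([[1, 1], [1, 0], [0, 0]], np.int8)
        co = make_cohort(X, [1, 2, 3], [1, 1, 1], names=["A", "B"])
        counts = intersection_counts(co, ["A", "B"])
        assert counts == {(1, 1): 1, (1, 0): 1, (0, 0): 1}

    def test_counts_partition_cohort(self):
        rng = np.random.default_rng(26)
        X = rng.integers(0, 2, (57, 4)).astype(np.int8)
        co = make_cohort(X, np.ones(57), np.ones(57),
                         names=[f"G{j}" for j in range(4)])
        counts = intersection_counts(co, co.feature_names)
        assert sum(counts.values()) == 57
        # oracle: exhaustive tally
        for pattern, cnt in counts.items():
            assert cnt == int((X == np.array(pattern)).all(axis=1).sum())


class TestSubtypes:
    def cohort(self):
        #            H1a H1b L1a other
        X = np.array([
            [1, 0, 0, 0],   # H1
            [0, 0, 1, 0],   # L1
            [1, 0, 1, 0],   # both
            [0, 0, 0, 1],   # unclassified
        ], np.int8)
        return make_cohort(X, [1, 2, 3, 4], [1, 1, 1, 1],
                           names=["MYD88", "CDKN2A", "SGK1", "TP53"])

    def test_marker_assignment(self):
        res = assign_subtypes(self.cohort(), ["MYD88", "CDKN2A"], ["SGK1"])
        assert res.subtype == ["H1", "L1", "both", "unclassified"]

    def test_overlapping_markers_rejected(self):
        with pytest.raises(StratificationError, match="overlap"):
            assign_subtypes(self.cohort(), ["MYD88"], ["MYD88", "SGK1"])

    def test_non_marker_columns_irrelevant(self):
        co = self.cohort()
        res1 = assign_subtypes(co, ["MYD88"], ["SGK1"])
        flipped = co.features.copy()
        flipped[:, 3] = 1 - flipped[:, 3]  # permute a non-marker column
        co2 = make_cohort(flipped, co.time, co.event, names=co.feature_names)
        res2 = assign_subtypes(co2, ["MYD88"], ["SGK1"])
        assert res1.subtype == res2.subtype


class TestSubSubtype:
    def shap_for(self, vals, names, n):
        vals = np.asarray(vals, float)
        return ShapMatrix(vals, names, np.zeros(n), vals.sum(axis=1), "inputs")

    def test_top_ranked_anchor_is_dominant_group(self):
        names = [f"G{j}" for j in range(6)]
        X = np.ones((1, 6), np.int8)
        co = make_cohort(X, [1.0], [1], names=names)
        s = [[0.9, 0.1, 0.2, 0.1, 0.05, 0.01]]
        out = sub_subtype_by_shap_rank(self.shap_for(s, names, 1), co, "G0", top_k=5)
        assert out["pt1"] == "G0-II"

    def test_zero_anchor_with_stronger_features_is_I(self):
        names = [f"G{j}" for j in range(6)]
        co = make_cohort(np.ones((1, 6), np.int8), [1.0], [1], names=names)
        s = [[0.0, 0.5, 0.4, 0.3, 0.2, 0.1]]
        out = sub_subtype_by_shap_rank(self.shap_for(s, names, 1), co, "G0", top_k=5)
        assert out["pt1"] == "G0-I"

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(27)
        names = [f"G{j}" for j in range(10)]
        X = rng.integers(0, 2, (30, 10)).astype(np.int8)
        X[:, 0] = rng.integers(0, 2, 30)
        co = make_cohort(X, np.ones(30), np.ones(30), names=names)
        s = rng.normal(size=(30, 10))
        out = sub_subtype_by_shap_rank(self.shap_for(s, names, 30), co, "G0", top_k=5)
        for i, pid in enumerate(co.patient_id):
            if X[i, 0] != 1:
                assert pid not in out
                continue
            rank = 1 + int((np.abs(s[i]) > abs(s[i, 0])).sum())
            assert out[pid] == ("G0-II" if rank <= 5 else "G0-I")

    def test_anchor_only_assigned_to_carriers(self):
        names = ["G0", "G1"]
        X = np.array([[0, 1]], np.int8)
        co = make_cohort(X, [1.0], [1], names=names)
        out = sub_subtype_by_shap_rank(
            self.shap_for([[0.5, 0.2]], names, 1), co, "G0"
        )
        assert out == {}


class TestGPIResult:
    def test_roundtrip(self, tmp_path):
        from vnnsurv.io_formats import read_results, write_results

        co = make_cohort(np.array([[1, 0], [1, 1]], np.int8), [1, 2], [1, 1],
                         names=["A", "B"])
        gpi = make_gpi_result(co, impact_table({"A": 0.03, "B": -0.05}),
                              ["A", "B"], -0.015, 0.025)
        p = tmp_path / "gpi.tsv"
        write_results(gpi, p)
        back = read_results(p)
        np.testing.assert_allclose(back.score, gpi.score, atol=1e-10)
        assert back.level == gpi.level
        assert back.t1 == gpi.t1
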