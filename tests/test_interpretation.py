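import numpy as np
import pytest

from vnnsurv.architecture import build_vnn_spec
from vnnsurv.interpretation import (
    InterpretationError,
    build_sankey,
    feature_impact,
    rank_and_eliminate,
    shap_values,
    ShapMatrix,
)
from vnnsurv.io_formats import GeneSetCollection, HierarchyEdges
from vnnsurv.model import Hyperparams, forward, init_model

from conftest import make_cohort


def linear_net(n_genes, seed=0):
    """Identity-activation network that collapses to f(x) = sum w_j x_j."""
    gs = GeneSetCollection(
        {f"P{j}": frozenset({f"G{j}"}) for j in range(1, n_genes + 1)}
    )
    spec = build_vnn_spec(gs, HierarchyEdges(()), [f"G{j}" for j in range(1, n_genes + 1)])
    m = init_model(spec, 0, head_width=1, dropout=0.0, activation="identity", seed=seed)
    return m


def effective_weights(m, n_genes):
    probe = make_cohort(np.eye(n_genes, dtype=np.int8), np.ones(n_genes),
                        np.ones(n_genes), names=list(m.spec.feature_order))
    zero = make_cohort(np.zeros((1, n_genes), np.int8), [1.0], [1],
                       names=list(m.spec.feature_order))
    return forward(m, probe).risk - forward(m, zero).risk[0]


class TestShapValues:
    def test_linear_model_closed_form(self):
        m = linear_net(4)
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, (6, 4)).astype(np.int8)
        co = make_cohort(X, np.arange(1, 7.0), np.ones(6),
                         names=list(m.spec.feature_order))
        sh = shap_values(m, co, "zeros", scope="inputs", method="exact", seed=0)
        w = effective_weights(m, 4)
        np.testing.assert_allclose(sh.values, X * w, atol=1e-12)

    def test_additivity_everywhere(self, small_bench):
        co = small_bench["cohort"].select_patients(np.arange(10))
        bg = small_bench["cohort"].select_patients(np.arange(10, 15))
        for scope in ("inputs", "pathways"):
            sh = shap_values(small_bench["model"], co, bg, scope=scope,
                             method="exact", seed=0,
                             players=list(co.feature_names) if scope == "inputs" else None)
            assert sh.additivity_gap() < 1e-3

    def test_sampling_close_to_exact(self, small_bench):
        co = small_bench["cohort"].select_patients(np.arange(6))
        bg = small_bench["cohort"].select_patients(np.arange(6, 11))
        players = list(co.feature_names)
        ex = shap_values(small_bench["model"], co, bg, scope="inputs",
                         method="exact", seed=0, players=players)
        sa = shap_values(small_bench["model"], co, bg, scope="inputs",
                         method="sampling", n_samples=2**14, seed=0,
                         players=players)
        assert float(np.abs(ex.values - sa.values).max()) < 0.02

    def test_disconnected_feature_zero_attribution(self):
        # G9 is an orphan but reaches the root; build a net where a feature
        # column is structurally dead by zeroing its only path
        m = linear_net(3)
        m.vnn[0][0][0, 0] = 0.0  # kill G1 -> P1
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, (5, 3)).astype(np.int8)
        co = make_cohort(X, np.ones(5), np.ones(5), names=list(m.spec.feature_order))
        sh = shap_values(m, co, "zeros", scope="inputs", method="exact", seed=0)
        np.testing.assert_allclose(sh.values[:, 0], 0.0, atol=1e-14)

    def test_exact_beyond_player_limit_rejected(self, small_bench):
        co = small_bench["cohort"].select_patients(np.arange(2))
        many = [f"F{i}" for i in range(16)]
        with pytest.raises(InterpretationError):
            shap_values(small_bench["model"], co,
                        small_bench["cohort"].select_patients([0]),
                        scope="inputs", method="exact", players=many)

    def test_empty_background_rejected(self, small_bench):
        co = small_bench["cohort"].select_patients(np.arange(2))
        with pytest.raises(InterpretationError, match="empty"):
            shap_values(small_bench["model"], co, np.zeros((0, 11)),
                        scope="inputs", method="exact")

    def test_sampling_seed_deterministic(self, small_bench):
        co = small_bench["cohort"].select_patients(np.arange(3))
        bg = small_bench["cohort"].select_patients(np.arange(3, 8))
        kw = dict(scope="inputs", method="sampling", n_samples=512, seed=42,
                  players=list(co.feature_names))
        a = shap_values(small_bench["model"], co, bg, **kw)
        b = shap_values(small_bench["model"], co, bg, **kw)
        np.testing.assert_array_equal(a.values, b.values)


class TestFeatureImpact:
    def make_shap(self, values, names, n):
        return ShapMatrix(np.asarray(values, float), names,
                          np.zeros(n), np.asarray(values, float).sum(axis=1),
                          scope="inputs")

    def test_direct_formula(self):
        co = make_cohort(np.array([[1], [0], [1]], np.int8), [1, 2, 3], [1, 1, 1],
                         names=["A"])
        sh = self.make_shap([[0.2], [-0.1], [0.4]], ["A"], 3)
        table = feature_impact(sh, co)
        assert table.impact[0] == pytest.approx(0.3)
        assert table.n_altered[0] == 2
        assert not table.flagged[0]

    def test_never_altered_flagged_zero(self):
        co = make_cohort(np.zeros((3, 1), np.int8), [1, 2, 3], [1, 1, 1], names=["A"])
        table = feature_impact(self.make_shap([[0.5], [0.1], [0.2]], ["A"], 3), co)
        assert table.impact[0] == 0.0 and table.flagged[0]

    def test_matches_masked_mean_bruteforce(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 2, (50, 10)).astype(np.int8)
        X[:, 0] = 1  # ensure at least one fully altered column
        s = rng.normal(size=(50, 10))
        names = [f"G{j}" for j in range(10)]
        co = make_cohort(X, rng.exponential(1, 50) + 0.1, np.ones(50), names=names)
        table = feature_impact(self.make_shap(s, names, 50), co)
        for j, f in enumerate(names):
            carriers = X[:, j] == 1
            expected = s[carriers, j].mean() if carriers.any() else 0.0
            assert table.impact[table.feature.index(f)] == pytest.approx(
                expected, abs=1e-12
            )

    def test_patient_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 2, (20, 5)).astype(np.int8)
        s = rng.normal(size=(20, 5))
        names = [f"G{j}" for j in range(5)]
        co = make_cohort(X, np.ones(20), np.ones(20), names=names)
        t1 = feature_impact(self.make_shap(s, names, 20), co)
        perm = rng.permutation(20)
        co2 = co.select_patients(perm)
        t2 = feature_impact(self.make_shap(s[perm], names, 20), co2)
        np.testing.assert_allclose(t1.impact, t2.impact, atol=1e-14)

    def test_misalignment_rejected(self):
        co = make_cohort(np.zeros((3, 1), np.int8), [1, 2, 3], [1, 1, 1], names=["A"])
        with pytest.raises(InterpretationError, match="align"):
            feature_impact(self.make_shap([[0.1]], ["A"], 1), co)


class TestSankey:
    def make_shap(self, names, widths, n=4):
        # constant-column SHAP matrix whose mean |value| equals `widths`
        vals = np.tile(np.asarray(widths, float), (n, 1))
        return ShapMatrix(vals, list(names), np.zeros(n), vals.sum(axis=1), "x")

    def universe(self):
        gs = GeneSetCollection(
            {"P1": frozenset({"G1", "G2"}), "P2": frozenset({"G3"})}
        )
        return build_vnn_spec(gs, HierarchyEdges((("P1", "P2"),)),
                              ["G1", "G2", "G3"])

    def test_single_source_edge_equals_target_width(self):
        gs = GeneSetCollection({"P1": frozenset({"G1"})})
        spec = build_vnn_spec(gs, HierarchyEdges(()), ["G1"])
        g = build_sankey(
            spec,
            self.make_shap(["P1"], [0.7]),
            self.make_shap(["G1"], [0.4]),
        )
        assert g.edges == [("G1", "P1", pytest.approx(0.7))]

    def test_two_source_split(self):
        spec = self.universe()
        g = build_sankey(
            spec,
            self.make_shap(["P1", "P2"], [0.8, 0.5]),
            self.make_shap(["G1", "G2", "G3"], [0.3, 0.1, 0.2]),
        )
        widths = {(s, t): w for s, t, w in g.edges}
        assert widths[("G1", "P1")] == pytest.approx(0.8 * 0.3 / 0.4)
        assert widths[("G2", "P1")] == pytest.approx(0.8 * 0.1 / 0.4)

    def test_conservation_without_pruning(self):
        spec = self.universe()
        g = build_sankey(
            spec,
            self.make_shap(["P1", "P2"], [0.8, 0.5]),
            self.make_shap(["G1", "G2", "G3"], [0.3, 0.1, 0.2]),
            prune_fraction=0.0,
        )
        node_w = {n: w for n, _, w in g.nodes}
        incoming = {}
        for s, t, w in g.edges:
            incoming[t] = incoming.get(t, 0.0) + w
        for t, total in incoming.items():
            assert total == pytest.approx(node_w[t], abs=1e-9)

    def test_pruning_removes_thin_edges(self):
        spec = self.universe()
        full = build_sankey(
            spec,
            self.make_shap(["P1", "P2"], [0.8, 0.5]),
            self.make_shap(["G1", "G2", "G3"], [0.3, 0.1, 0.2]),
        )
        pruned = build_sankey(
            spec,
            self.make_shap(["P1", "P2"], [0.8, 0.5]),
            self.make_shap(["G1", "G2", "G3"], [0.3, 0.1, 0.2]),
            prune_fraction=0.5,
        )
        assert len(pruned.edges) < len(full.edges)

    def test_zero_input_target_flagged(self):
        spec = self.universe()
        g = build_sankey(
            spec,
            self.make_shap(["P1", "P2"], [0.8, 0.5]),
            self.make_shap(["G1", "G2", "G3"], [0.0, 0.0, 0.2]),
        )
        assert "P1" in g.flagged_targets
        assert all(w == 0.0 for s, t, w in g.edges if t == "P1")


class TestElimination:
    def test_single_round_when_step_large(self, small_bench):
        truth = small_bench["truth"]
        cohort = small_bench["cohort"]
        res = rank_and_eliminate(
            cohort,
            lambda genes: build_vnn_spec(truth.gene_sets, truth.hierarchy, genes),
            grid=[Hyperparams(learning_rate=1e-2, batch_size=None, epochs=15)],
            k_folds=2, step=len(cohort.feature_names) - 1, seed=0, head_width=8,
        )
        assert len(res.stages) == 2  # one elimination + the final panel
        assert len(res.stages[1].features) == 1

    def test_rankings_cover_panel(self, small_bench):
        truth = small_bench["truth"]
        cohort = small_bench["cohort"]
        res = rank_and_eliminate(
            cohort,
            lambda genes: build_vnn_spec(truth.gene_sets, truth.hierarchy, genes),
            grid=[Hyperparams(learning_rate=1e-2, batch_size=None, epochs=15)],
            k_folds=2, step=3, seed=1, head_width=8,
        )
        assert sorted(res.stages[0].ranking) == sorted(cohort.feature_names)
        # curve is recorded at every stage
        assert [n for n, _ in res.curve] == [8, 5, 2]
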