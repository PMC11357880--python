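"""Shared fixtures: tiny hand-built pathway universes, synthetic cohorts,
and a small trained model reused across interpretation tests."""

import numpy as np
import pytest

from vnnsurv.architecture import build_vnn_spec
from vnnsurv.io_formats import CohortTable, GeneSetCollection, HierarchyEdges
from vnnsurv.model import Hyperparams, init_model, train
from vnnsurv.synthetic import benchmark_conditions


@pytest.fixture
def chain_universe():
    """G1,G2 -> P1 -> P2 -> P3; G3 -> P2 (deep member); G9 orphan."""
    gene_sets = GeneSetCollection(
        {
            "P1": frozenset({"G1", "G2"}),
            "P2": frozenset({"G3"}),
            "P3": frozenset({"G4"}),
        }
    )
    hierarchy = HierarchyEdges((("P1", "P2"), ("P2", "P3")))
    return gene_sets, hierarchy


def make_cohort(X, time, event, clinical=None, clinical_names=None, names=None):
    X = np.asarray(X, dtype=np.int8)
    n, p = X.shape
    names = names or [f"G{j + 1}" for j in range(p)]
    if clinical is None:
        clinical = np.zeros((n, 0), dtype=np.int8)
        clinical_names = []
    return CohortTable(
        [f"pt{i + 1}" for i in range(n)],
        X,
        names,
        np.asarray(clinical, dtype=np.int8),
        clinical_names or [],
        np.asarray(time, dtype=float),
        np.asarray(event, dtype=np.int8),
    )


@pytest.fixture
def toy_cohort():
    rng = np.random.default_rng(11)
    X = rng.integers(0, 2, size=(30, 4)).astype(np.int8)
    time = rng.exponential(100, 30) + 1
    event = rng.integers(0, 2, size=30).astype(np.int8)
    event[0] = 1
    return make_cohort(X, time, event)


@pytest.fixture(scope="session")
def small_bench():
    """A small planted-signal cohort with its pathway universe and a model
    trained long enough to carry real signal (8 genetic features)."""
    cohort, truth = benchmark_conditions(
        seed=4, n=120, n_signal=3, n_noise=5, n_pathways=6, max_depth=3
    )
    spec = build_vnn_spec(truth.gene_sets, truth.hierarchy, cohort.feature_names)
    m0 = init_model(spec, cohort.n_clinical, head_width=8, dropout=0.1, seed=5)
    fitted, history = train(
        m0, cohort,
        Hyperparams(learning_rate=1e-2, batch_size=None, epochs=60, seed=0),
    )
    return {
        "cohort": cohort,
        "truth": truth,
        "spec": spec,
        "model": fitted,
        "history": history,
    }
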