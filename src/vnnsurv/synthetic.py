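"""Synthetic pathway hierarchies and Cox-structured binary-alteration
cohorts with known ground truth.

The generator emulates the shape of a targeted-sequencing DLBCL cohort:
independent Bernoulli gene-alteration indicators with chosen marginal
frequencies (optionally correlated through a Gaussian copula, to plant
co-occurrence or mutual exclusivity), three binary clinical covariates,
exponential event times whose hazard follows a proportional-hazards
mechanism on the true effects, and independent exponential censoring
calibrated to a target censoring fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .io_formats import CohortTable, GeneSetCollection, HierarchyEdges

__all__ = [
    "GroundTruth",
    "SyntheticError",
    "simulate_hierarchy",
    "simulate_cohort",
    "benchmark_conditions",
]


class SyntheticError(ValueError):
    pass


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must recover."""

    true_beta: np.ndarray                  # per genetic feature, log-hazard units
    feature_names: list[str]
    clinical_beta: np.ndarray              # per clinical covariate
    baseline_hazard: float
    censor_rate_target: float
    seed: int
    gene_sets: GeneSetCollection | None = None
    hierarchy: HierarchyEdges | None = None
    censor_hazard: float = float("nan")    # filled in by the generator

    def linear_predictor(self, cohort: CohortTable) -> np.ndarray:
        lp = cohort.features @ self.true_beta
        if cohort.n_clinical:
            lp = lp + cohort.clinical @ self.clinical_beta[: cohort.n_clinical]
        return lp


def simulate_hierarchy(
    n_pathways: int,
    n_genes: int,
    max_depth: int,
    seed: int = 0,
    nonleaf_gene_fraction: float = 0.25,
    extra_edge_prob: float = 0.3,
) -> tuple[GeneSetCollection, HierarchyEdges]:
    """Random pathway DAG whose longest child-chain is exactly ``max_depth``.

    Pathways are spread over ``max_depth`` depth levels; every pathway above
    level 1 receives at least one child exactly one level below (so a full
    chain exists) and optional extra child edges from any strictly lower
    level, including level-skipping edges that exercise skip-through
    channels.  Every pathway gets at least one member gene; a fraction of
    genes is attached to non-leaf pathways.
    """
    if n_pathways < 1 or max_depth < 1 or n_genes < 1:
        raise SyntheticError("n_pathways, n_genes and max_depth must be >= 1")
    if max_depth > n_pathways:
        raise SyntheticError("max_depth cannot exceed n_pathways")
    rng = np.random.default_rng(seed)

    names = [f"PW{i + 1:03d}" for i in range(n_pathways)]
    # one pathway per level first (guarantees the chain), remainder random
    level = {}
    for i, p in enumerate(names):
        level[p] = (i % max_depth) + 1 if i < max_depth else int(rng.integers(1, max_depth + 1))
    by_level = {d: [p for p in names if level[p] == d] for d in range(1, max_depth + 1)}

    edges: set[tuple[str, str]] = set()
    for d in range(2, max_depth + 1):
        for parent in by_level[d]:
            child = str(rng.choice(by_level[d - 1]))
            edges.add((child, parent))
            # extra edges, possibly skipping levels (non-strict hierarchy)
            for lower in range(1, d):
                for cand in by_level[lower]:
                    if cand != child and rng.random() < extra_edge_prob / max(1, len(by_level[lower])):
                        edges.add((cand, parent))

    genes = [f"G{i + 1:03d}" for i in range(n_genes)]
    leaves = by_level[1]
    non_leaves = [p for p in names if p not in leaves]
    sets: dict[str, set[str]] = {p: set() for p in names}
    for i, g in enumerate(genes):
        if non_leaves and rng.random() < nonleaf_gene_fraction:
            sets[str(rng.choice(non_leaves))].add(g)
        else:
            sets[str(rng.choice(leaves))].add(g)
    # every pathway needs at least one member
    for p in names:
        if not sets[p]:
            sets[p].add(str(rng.choice(genes)))
    collection = GeneSetCollection({p: frozenset(s) for p, s in sets.items()})
    return collection, HierarchyEdges(tuple(sorted(edges)))


def _correlated_bernoulli(rng, n, freqs, correlation) -> np.ndarray:
    """Gaussian-copula draw: latent MVN with the given equicorrelation or
    full correlation matrix, thresholded at the frequency quantiles."""
    p = len(freqs)
    if np.isscalar(correlation):
        corr = np.full((p, p), float(correlation))
        np.fill_diagonal(corr, 1.0)
    else:
        corr = np.asarray(correlation, dtype=float)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(p))
    z = rng.standard_normal((n, p)) @ chol.T
    cuts = stats.norm.ppf(1.0 - np.asarray(freqs))
    return (z > cuts).astype(np.int8)


def simulate_cohort(
    n: int,
    freqs,
    truth: GroundTruth,
    clinical_freqs=(0.5, 0.8, 0.8),
    correlation: float | np.ndarray | None = None,
    weibull_shape: float = 1.0,
) -> tuple[CohortTable, GroundTruth]:
    """Draw a cohort of ``n`` patients under ``truth``.

    Event times follow a proportional-hazards mechanism with hazard
    ``baseline_hazard * exp(x . beta)`` (exponential by default, Weibull
    with the given shape as an option); censoring times are independent
    exponentials whose rate is calibrated so the expected censored fraction
    matches ``truth.censor_rate_target``.  Recorded time is the minimum of
    the two, event = 1 when death is observed.
    """
    freqs = np.asarray(freqs, dtype=float)
    if n < 1:
        raise SyntheticError("n must be >= 1")
    if ((freqs <= 0) | (freqs >= 1)).any():
        raise SyntheticError("feature frequencies must lie strictly in (0, 1)")
    if freqs.shape[0] != truth.true_beta.shape[0]:
        raise SyntheticError("freqs and true_beta length mismatch")
    rng = np.random.default_rng(truth.seed)

    if correlation is None:
        features = (rng.random((n, freqs.size)) < freqs).astype(np.int8)
    else:
        features = _correlated_bernoulli(rng, n, freqs, correlation)
    n_clin = truth.clinical_beta.shape[0]
    clin_freqs = np.asarray(clinical_freqs, dtype=float)[:n_clin]
    clinical = (rng.random((n, n_clin)) < clin_freqs).astype(np.int8)

    lp = features @ truth.true_beta + clinical @ truth.clinical_beta
    hazard = truth.baseline_hazard * np.exp(lp)
    u = rng.random(n)
    event_time = (-np.log(u) / hazard) ** (1.0 / weibull_shape)

    target = truth.censor_rate_target
    if target <= 0:
        censor_time = np.full(n, np.inf)
        truth.censor_hazard = 0.0
    else:
        # P(censored) = E[ lc / (lc + h) ] for exponential races; solve for lc
        def censored_fraction(lc):
            if weibull_shape == 1.0:
                return float(np.mean(lc / (lc + hazard))) - target
            # general shape: Monte-Carlo-free approximation via the drawn times
            return float(np.mean(1 - np.exp(-lc * event_time))) - target

        lo, hi = 1e-12, truth.baseline_hazard
        while censored_fraction(hi) < 0:
            hi *= 4.0
            if hi > 1e12:
                raise SyntheticError("cannot calibrate censoring hazard")
        lc = optimize.brentq(censored_fraction, lo, hi)
        truth.censor_hazard = float(lc)
        censor_time = rng.exponential(1.0 / lc, size=n)

    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(np.int8)
    time = np.maximum(time, 1e-9)  # guard the strictly-positive invariant

    names = (
        list(truth.feature_names)
        if truth.feature_names
        else [f"G{i + 1:03d}" for i in range(freqs.size)]
    )
    clin_names = ["age_gt_60", "rchop", "de_novo"][:n_clin]
    cohort = CohortTable(
        [f"P{i + 1:05d}" for i in range(n)],
        features,
        names,
        clinical,
        clin_names,
        time,
        event,
    )
    return cohort, truth


def benchmark_conditions(
    seed: int = 0,
    n: int = 600,
    n_signal: int = 5,
    n_noise: int = 15,
    effect: float = float(np.log(2)),
    signal_freq: float = 0.5,
    noise_freq: float = 0.3,
    censor_rate: float = 0.3,
    n_pathways: int = 12,
    max_depth: int = 4,
) -> tuple[CohortTable, GroundTruth]:
    """The planted-signal study conditions used throughout the test bench.

    Five signal alterations at |beta| = log 2 (alternating sign) carried at
    frequency 0.5, fifteen pure-noise alterations at frequency 0.3, three
    clinical covariates with effects (log 2, -log 2, -0.35) mirroring the
    prognostic roles of age > 60, R-CHOP treatment and de-novo disease, and
    ~30% independent censoring.  The genes are routed through a random
    pathway DAG so that the signal flows through pathway-connected inputs.
    """
    p = n_signal + n_noise
    gene_sets, hierarchy = simulate_hierarchy(
        n_pathways=n_pathways, n_genes=p, max_depth=max_depth, seed=seed
    )
    beta = np.zeros(p)
    beta[:n_signal] = effect * np.where(np.arange(n_signal) % 2 == 0, 1.0, -1.0)
    truth = GroundTruth(
        true_beta=beta,
        feature_names=[f"G{i + 1:03d}" for i in range(p)],
        clinical_beta=np.array([effect, -effect, -0.35]),
        baseline_hazard=1.0 / 2000.0,  # days^-1; median survival a few years
        censor_rate_target=censor_rate,
        seed=seed,
        gene_sets=gene_sets,
        hierarchy=hierarchy,
    )
    freqs = np.full(p, noise_freq)
    freqs[:n_signal] = signal_freq
    cohort, truth = simulate_cohort(n, freqs, truth)
    return cohort, truth
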