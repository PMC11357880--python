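"""Model interpretation: Shapley attribution of the risk output, the
altered-cases-only feature impact statistic, impact-ranked backward feature
elimination, and Sankey-graph construction from attributions.

Attribution uses interventional Shapley values with a background sample:
the value of a coalition S is the expected risk when the coalition's nodes
take the patient's values and the remaining nodes are drawn from the
background.  Input-level attribution intervenes on the input columns;
pathway-level attribution intervenes on each pathway's hidden neuron block
(one coalition player per pathway).  ``exact`` enumerates every coalition
(<= 15 players); ``sampling`` averages marginal contributions over seeded
permutations, collapsing to exact enumeration when a single background row
leaves few effective players (a binary input equal to its background value
is a null player with attribution exactly zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import ArchitectureError, VNNSpec
from .io_formats import CohortTable, register_result
from .model import (
    ACTIVATIONS,
    Hyperparams,
    ModelParams,
    _forward_arrays,
    init_model,
    train,
)

logger = logging.getLogger(__name__)

__all__ = [
    "InterpretationError",
    "ShapMatrix",
    "ImpactTable",
    "SankeyGraph",
    "EliminationResult",
    "shap_values",
    "feature_impact",
    "rank_and_eliminate",
    "build_sankey",
]

_EXACT_LIMIT = 15        # declared-player cap for exact enumeration
_REDUCED_EXACT_LIMIT = 13  # effective-player cap for the sampling shortcut


class InterpretationError(ValueError):
    pass


@dataclass
class ShapMatrix:
    """Per-patient, per-node Shapley attributions ``s_ij``.

    ``base_value[i]`` is the expected risk over the background with every
    player interveined; local accuracy guarantees
    ``base_value[i] + sum_j values[i, j] == risk_i``.
    """

    values: np.ndarray            # (n_patients, n_nodes)
    node_names: list[str]
    base_value: np.ndarray        # (n_patients,)
    risk: np.ndarray              # (n_patients,) model output being explained
    scope: str

    def additivity_gap(self) -> float:
        """max_i |base + sum_j s_ij - risk_i|; ~0 up to sampling error."""
        return float(np.abs(self.base_value + self.values.sum(axis=1) - self.risk).max())

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.node_names.index(name)]


@register_result
@dataclass
class ImpactTable:
    """Impact_j = mean SHAP value of feature j over the N_j patients that
    carry the alteration (f_ij = 1); 0 and flagged when N_j = 0."""

    KIND = "impact"

    feature: list[str]
    impact: np.ndarray
    n_altered: np.ndarray
    flagged: np.ndarray   # True where never altered (impact undefined -> 0)

    def __post_init__(self):
        self.impact = np.asarray(self.impact, dtype=float)
        self.n_altered = np.asarray(self.n_altered, dtype=int)
        self.flagged = np.asarray(self.flagged, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature,
                "impact": self.impact,
                "n_altered": self.n_altered,
                "flagged": self.flagged.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ImpactTable":
        return cls(
            df["feature"].astype(str).tolist(),
            df["impact"].to_numpy(float),
            df["n_altered"].to_numpy(int),
            df["flagged"].to_numpy(int).astype(bool),
        )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.feature, self.impact))


@register_result
@dataclass
class SankeyGraph:
    """Multilayer Sankey data: nodes (name, layer, width) and weighted
    edges.  Widths derive from mean |SHAP|; the width of every edge into a
    target is the target's width split proportionally to its sources'
    widths, so incoming widths sum to the target width before pruning."""

    KIND = "sankey"

    nodes: list[tuple[str, int, float]]
    edges: list[tuple[str, str, float]]
    flagged_targets: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"record": "node", "a": n, "b": str(layer), "width": w}
            for n, layer, w in self.nodes
        ]
        rows += [
            {"record": "edge", "a": s, "b": t, "width": w} for s, t, w in self.edges
        ]
        rows += [
            {"record": "flag", "a": t, "b": "", "width": 0.0}
            for t in self.flagged_targets
        ]
        return pd.DataFrame(rows, columns=["record", "a", "b", "width"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SankeyGraph":
        nodes, edges, flags = [], [], []
        for _, row in df.iterrows():
            if row["record"] == "node":
                nodes.append((str(row["a"]), int(row["b"]), float(row["width"])))
            elif row["record"] == "edge":
                edges.append((str(row["a"]), str(row["b"]), float(row["width"])))
            else:
                flags.append(str(row["a"]))
        return cls(nodes, edges, flags)


# ---------------------------------------------------------------------------
# value functions
# ---------------------------------------------------------------------------

def _background_matrix(background, n_feat: int, n_clin: int) -> np.ndarray:
    """Normalize the background to a (n_bg, n_feat + n_clin) array.

    Accepts a CohortTable, a raw array, or the string ``"zeros"`` for the
    all-reference (no alteration) profile.
    """
    if isinstance(background, str):
        if background != "zeros":
            raise InterpretationError(f"unknown background {background!r}")
        return np.zeros((1, n_feat + n_clin))
    if isinstance(background, CohortTable):
        mat = np.hstack([background.features, background.clinical]).astype(float)
    else:
        mat = np.asarray(background, dtype=float)
        if mat.ndim == 1:
            mat = mat[None, :]
    if mat.shape[0] == 0:
        raise InterpretationError("background set is empty")
    if mat.shape[1] != n_feat + n_clin:
        raise InterpretationError(
            f"background has {mat.shape[1]} columns, model expects {n_feat + n_clin}"
        )
    return mat


def _risk_of_rows(params: ModelParams, rows: np.ndarray) -> np.ndarray:
    p = params.spec.n_features
    risk, _ = _forward_arrays(params, rows[:, :p], rows[:, p:], training=False)
    return risk


def _input_value_fn(params, x_row, bg, player_cols):
    """vf(B) for input-scope attribution: B is (C, m) boolean coalition
    membership; returns the background-averaged risk per coalition."""
    m = len(player_cols)
    x_on_players = x_row[player_cols]

    def vf(B: np.ndarray) -> np.ndarray:
        C = B.shape[0]
        total = np.zeros(C)
        for b_row in bg:
            R = np.tile(x_row, (C, 1))
            R[:, player_cols] = np.where(B, x_on_players, b_row[player_cols])
            total += _risk_of_rows(params, R)
        return total / bg.shape[0]

    return vf


def _bg_layer_activations(params: ModelParams, bg: np.ndarray) -> list[np.ndarray]:
    p = params.spec.n_features
    _, cache = _forward_arrays(
        params, bg[:, :p], bg[:, p:], training=False, keep_cache=True
    )
    return cache["h"]


def _pathway_value_fn(params, x_feat, x_clin, bg, pathways):
    """vf(B) for pathway-scope attribution: pathways outside the coalition
    have their hidden neuron block replaced by the background's own
    activations at that block; skip-through copies downstream inherit the
    replacement automatically because the intervention happens at the
    block's origin layer."""
    spec = params.spec
    act, _ = ACTIVATIONS[params.activation]
    blocks = [spec.pathway_blocks[p] for p in pathways]
    bg_h = _bg_layer_activations(params, bg)

    def vf(B: np.ndarray) -> np.ndarray:
        C = B.shape[0]
        total = np.zeros(C)
        for bi in range(bg.shape[0]):
            h = np.tile(x_feat.astype(float), (C, 1))
            for k, (W, b) in enumerate(params.vnn):
                Weff = W * spec.masks[k] + spec.frozen[k]
                z = h @ Weff + b
                h = np.where(spec.passthrough[k], z, act(z))
                for j, (layer_k, s, e) in enumerate(blocks):
                    if layer_k == k + 1:
                        out_rows = ~B[:, j]
                        if out_rows.any():
                            h[out_rows, s:e] = bg_h[k + 1][bi, s:e]
            if params.root is not None:
                Wr, br = params.root
                h = act(h @ Wr + br)
            x_head = np.concatenate([h, np.tile(x_clin.astype(float), (C, 1))], axis=1)
            (W1, b1), (W2, b2) = params.head
            total += (act(x_head @ W1 + b1) @ W2 + b2).ravel()
        return total / bg.shape[0]

    return vf


# ---------------------------------------------------------------------------
# Shapley combination rules
# ---------------------------------------------------------------------------

def _exact_shapley(vf, m: int) -> tuple[np.ndarray, float]:
    """Exact Shapley values by full coalition enumeration (2^m values)."""
    masks = np.arange(2**m, dtype=np.uint32)
    B = ((masks[:, None] >> np.arange(m)) & 1).astype(bool)
    v = vf(B)
    sizes = B.sum(axis=1)
    from math import factorial

    w = np.array(
        [factorial(s) * factorial(m - s - 1) / factorial(m) for s in range(m)]
    )
    phi = np.empty(m)
    for j in range(m):
        without = np.flatnonzero(~B[:, j])
        with_j = without | np.uint32(1 << j)
        phi[j] = np.sum(w[sizes[without]] * (v[with_j] - v[without]))
    return phi, float(v[0])


def _sampled_shapley(vf, m: int, n_samples: int, rng) -> tuple[np.ndarray, float]:
    """Permutation-sampling Shapley: marginal contributions along random
    player orderings; ~n_samples value-function evaluations."""
    n_perm = max(1, n_samples // (m + 1))
    prefix = np.arange(m + 1)[:, None] > np.arange(m)[None, :]  # (m+1, m)
    phi = np.zeros(m)
    base = 0.0
    B = np.zeros((n_perm * (m + 1), m), dtype=bool)
    perms = np.empty((n_perm, m), dtype=int)
    for i in range(n_perm):
        perm = rng.permutation(m)
        perms[i] = perm
        block = np.zeros((m + 1, m), dtype=bool)
        block[:, perm] = prefix
        B[i * (m + 1) : (i + 1) * (m + 1)] = block
    v = vf(B).reshape(n_perm, m + 1)
    base = float(v[:, 0].mean())
    diffs = np.diff(v, axis=1)  # (n_perm, m): contribution of perms[i, j]
    for i in range(n_perm):
        phi[perms[i]] += diffs[i]
    return phi / n_perm, base


# ---------------------------------------------------------------------------
# public attribution API
# ---------------------------------------------------------------------------

def shap_values(
    model: ModelParams,
    cohort: CohortTable,
    background,
    scope: str = "inputs",
    method: str = "exact",
    n_samples: int = 2048,
    seed: int = 0,
    players: list[str] | None = None,
) -> ShapMatrix:
    """Shapley attribution of the risk output for every patient.

    ``scope="inputs"`` treats input columns as players (all genetic and
    clinical columns by default; restrict with ``players``);
    ``scope="pathways"`` treats each pathway's hidden block as one player;
    ``scope="both"`` concatenates the two analyses (additivity holds within
    each block).  Non-player inputs keep the patient's own values.
    """
    if scope not in ("inputs", "pathways", "both"):
        raise InterpretationError(f"unknown scope {scope!r}")
    if scope == "both":
        a = shap_values(model, cohort, background, "inputs", method, n_samples, seed, players)
        b = shap_values(model, cohort, background, "pathways", method, n_samples, seed)
        return ShapMatrix(
            np.hstack([a.values, b.values]),
            a.node_names + b.node_names,
            a.base_value,
            a.risk,
            scope="both",
        )
    if method not in ("exact", "sampling"):
        raise InterpretationError(f"unknown method {method!r}")

    spec = model.spec
    n_feat, n_clin = spec.n_features, model.n_clinical
    bg = _background_matrix(background, n_feat, n_clin)
    X = np.hstack([cohort.features, cohort.clinical]).astype(float)
    risk = _risk_of_rows(model, X)
    rng = np.random.default_rng(seed)

    if scope == "inputs":
        all_names = list(spec.feature_order) + list(cohort.clinical_names)
        node_names = list(players) if players is not None else all_names
        missing = [p for p in node_names if p not in all_names]
        if missing:
            raise InterpretationError(f"unknown players: {missing}")
        player_cols = np.array([all_names.index(p) for p in node_names])
    else:
        node_names = sorted(spec.pathway_blocks)
        if not node_names:
            raise InterpretationError("architecture has no pathway blocks to attribute")
    m = len(node_names)
    if method == "exact" and m > _EXACT_LIMIT:
        raise InterpretationError(
            f"exact enumeration limited to {_EXACT_LIMIT} players, got {m}"
        )

    values = np.zeros((cohort.n, m))
    bases = np.zeros(cohort.n)
    single_bg = bg.shape[0] == 1
    for i in range(cohort.n):
        if scope == "inputs":
            x_row = X[i]
            active = np.arange(m)
            if single_bg:
                # binary inputs equal to the background are null players
                active = np.flatnonzero(x_row[player_cols] != bg[0, player_cols])
            vf_cols = player_cols[active]
            vf = _input_value_fn(model, x_row, bg, vf_cols)
        else:
            active = np.arange(m)
            vf = _pathway_value_fn(
                model, X[i : i + 1, :n_feat], X[i : i + 1, n_feat:], bg,
                node_names,
            )

        ma = len(active)
        if ma == 0:
            # every player is null: the prediction equals the base value
            bases[i] = risk[i]
            continue
        use_exact = method == "exact" or (
            scope == "inputs" and single_bg and ma <= _REDUCED_EXACT_LIMIT
        )
        if use_exact:
            phi, base = _exact_shapley(vf, ma)
        else:
            phi, base = _sampled_shapley(vf, ma, n_samples, rng)
        if scope == "inputs":
            values[i, active] = phi
        else:
            values[i] = phi
        bases[i] = base

    return ShapMatrix(values, node_names, bases, risk, scope=scope)


def feature_impact(shap: ShapMatrix, cohort: CohortTable) -> ImpactTable:
    """Altered-cases-only mean attribution per genetic feature.

    Averaging only over carriers keeps low-frequency alterations visible:
    a rare variant with a strong per-carrier effect scores as highly as a
    common one.
    """
    if shap.values.shape[0] != cohort.n:
        raise InterpretationError(
            f"attribution rows ({shap.values.shape[0]}) do not align with "
            f"cohort patients ({cohort.n})"
        )
    names, impacts, counts, flags = [], [], [], []
    for j, fname in enumerate(cohort.feature_names):
        if fname not in shap.node_names:
            continue
        col = shap.column(fname)
        carriers = cohort.features[:, j] == 1
        nj = int(carriers.sum())
        names.append(fname)
        counts.append(nj)
        if nj == 0:
            impacts.append(0.0)
            flags.append(True)
        else:
            impacts.append(float(col[carriers].mean()))
            flags.append(False)
    if not names:
        raise InterpretationError("no genetic features present in the attribution")
    return ImpactTable(names, np.array(impacts), np.array(counts), np.array(flags))


# ---------------------------------------------------------------------------
# impact-ranked backward elimination
# ---------------------------------------------------------------------------

@dataclass
class EliminationStage:
    features: list[str]
    mean_cv_cindex: float
    ranking: list[str]          # by |impact| descending
    impacts: dict[str, float]
    dropped: list[str]


@dataclass
class EliminationResult:
    stages: list[EliminationStage]
    elimination_order: list[str]   # first dropped first

    @property
    def curve(self) -> list[tuple[int, float]]:
        return [(len(s.features), s.mean_cv_cindex) for s in self.stages]


def rank_and_eliminate(
    cohort: CohortTable,
    spec_builder,
    grid: list[Hyperparams] | None = None,
    k_folds: int = 10,
    step: int = 1,
    seed: int = 0,
    head_width: int = 16,
    activation: str = "tanh",
    background="zeros",
    n_samples: int = 2048,
) -> EliminationResult:
    """Iteratively drop the ``step`` features with smallest |impact|.

    Each round cross-validates on the current panel, trains a model on the
    full cohort with the chosen hyperparameters, attributes with Shapley
    values against ``background``, ranks features by |impact| and removes
    the weakest ``step``; the architecture is rebuilt on the reduced panel
    via ``spec_builder(genes)``.  Stops cleanly when fewer than ``step + 1``
    features remain or the panel can no longer reach any pathway.
    """
    from .evaluation import c_index  # noqa: F401  (documented dependency)
    from .model import cross_validate, forward

    if step < 1:
        raise InterpretationError("step must be >= 1")
    genes = list(cohort.feature_names)
    stages: list[EliminationStage] = []
    order: list[str] = []
    round_no = 0
    while genes:
        sub = cohort.with_features(genes)
        try:
            spec = spec_builder(genes)
        except ArchitectureError as err:
            logger.info("stopping elimination: %s", err)
            break
        stage_seed = (seed * 7919 + round_no) % (2**31)
        report = cross_validate(
            sub, spec, grid, k=k_folds, seed=stage_seed,
            head_width=head_width, activation=activation,
        )
        hp = report.chosen
        model = init_model(
            spec, sub.n_clinical, head_width, hp.dropout_rate, activation,
            seed=stage_seed,
        )
        fitted, _ = train(model, sub, Hyperparams(
            learning_rate=hp.learning_rate, weight_decay=hp.weight_decay,
            batch_size=hp.batch_size, epochs=hp.epochs,
            dropout_rate=hp.dropout_rate, seed=stage_seed,
        ))
        shap = shap_values(
            fitted, sub, background, scope="inputs", method="sampling",
            n_samples=n_samples, seed=stage_seed, players=genes,
        )
        impact = feature_impact(shap, sub)
        by_strength = sorted(
            impact.feature, key=lambda f: abs(impact.as_dict()[f]), reverse=True
        )
        n_drop = min(step, len(genes))
        dropped = list(reversed(by_strength[-n_drop:])) if len(genes) > step else []
        stages.append(
            EliminationStage(list(genes), report.mean_score, by_strength,
                             impact.as_dict(), dropped)
        )
        if len(genes) <= step:
            break
        order.extend(dropped)
        genes = [g for g in genes if g not in dropped]
        round_no += 1
    return EliminationResult(stages, order)


# ---------------------------------------------------------------------------
# Sankey construction
# ---------------------------------------------------------------------------

def build_sankey(
    spec: VNNSpec,
    shap_pathways: ShapMatrix,
    shap_inputs: ShapMatrix,
    prune_fraction: float = 0.0,
) -> SankeyGraph:
    """Sankey graph of the visible architecture weighted by attribution.

    Node width = mean |SHAP| across patients.  Every structural connection
    (gene -> member pathway, child -> parent) becomes an edge whose width is
    the target's width multiplied by the source's share of the summed source
    widths, so pre-pruning the incoming widths of a target add up to its
    width.  Afterwards, edges whose width falls below the ``prune_fraction``
    quantile are removed to de-clutter the diagram.
    """
    if not (0.0 <= prune_fraction < 1.0):
        raise InterpretationError("prune_fraction must lie in [0, 1)")

    def mean_abs(shap: ShapMatrix) -> dict[str, float]:
        return {
            name: float(np.abs(shap.values[:, j]).mean())
            for j, name in enumerate(shap.node_names)
        }

    w_in = mean_abs(shap_inputs)
    w_pw = mean_abs(shap_pathways)

    nodes: list[tuple[str, int, float]] = []
    for g in spec.feature_order:
        if g in w_in:
            nodes.append((g, 0, w_in[g]))
    for p in sorted(spec.pathway_blocks):
        if p in w_pw:
            nodes.append((p, spec.layer_of[p], w_pw[p]))

    width_of = {name: w for name, _, w in nodes}
    # structural sources of each pathway: member genes in the panel + children
    children: dict[str, list[str]] = {p: [] for p in spec.pathway_blocks}
    parents_by_child: dict[str, list[str]] = {}
    # reconstruct membership/child relations from the masks' unit names
    members: dict[str, list[str]] = {p: [] for p in spec.pathway_blocks}
    gene_set = set(spec.feature_order)
    for k, mask in enumerate(spec.masks):
        src_names = spec.unit_names[k]
        tgt_names = spec.unit_names[k + 1]
        rows, cols = np.nonzero(mask)
        for r, c in zip(rows, cols):
            tgt = tgt_names[c]
            if "[" not in tgt:
                continue
            p = tgt[len("p:"): tgt.index("[")]
            src = src_names[r]
            if src in gene_set:
                if src not in members[p]:
                    members[p].append(src)
            elif src.startswith("p:"):
                child = src[len("p:"): src.index("[")]
                if child not in children[p]:
                    children[p].append(child)

    edges: list[tuple[str, str, float]] = []
    flagged: list[str] = []
    for p in sorted(spec.pathway_blocks):
        if p not in width_of:
            continue
        sources = [s for s in members[p] + children[p] if s in width_of]
        total = sum(width_of[s] for s in sources)
        if not sources:
            continue
        if total == 0.0:
            flagged.append(p)
            edges.extend((s, p, 0.0) for s in sources)
            continue
        for s in sources:
            edges.append((s, p, width_of[p] * width_of[s] / total))

    if prune_fraction > 0 and edges:
        widths = np.array([w for _, _, w in edges])
        cut = float(np.quantile(widths, prune_fraction))
        edges = [(s, t, w) for s, t, w in edges if w >= cut]
    return SankeyGraph(nodes, edges, flagged)
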