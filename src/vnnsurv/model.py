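"""The survival network and its training machinery.

The network is a masked multilayer perceptron whose connectivity is dictated
by a :class:`~vnnsurv.architecture.VNNSpec`: gene inputs feed pathway
neurons, pathway neurons feed parent pathways, frozen identity channels
carry skip-through values, and the root embedding is concatenated with the
clinical covariates before a two-layer dense head produces a scalar risk.

Training minimizes the negative Cox log partial likelihood (Breslow tie
handling, risk sets computed within each mini-batch) with AdamW and
dropout.  Masked-out weight positions are structurally absent: they are
zero at initialization, receive zero gradient, and remain exactly zero
after every update.

Two baselines accompany the visible network: a dense network of matching
depth/width and a linear proportional-hazards fit (via lifelines).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .architecture import VNNSpec
from .io_formats import CohortTable, register_result

logger = logging.getLogger(__name__)

__all__ = [
    "ModelError",
    "Hyperparams",
    "ModelParams",
    "RiskTable",
    "CVReport",
    "default_grid",
    "init_model",
    "forward",
    "cox_loss",
    "cox_loss_grad",
    "train",
    "cross_validate",
    "dense_spec_like",
    "baseline_dense",
    "baseline_linear_ph",
    "save_model",
    "load_model",
]


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def _tanh(z):
    return np.tanh(z)


def _dtanh(z, h):
    return 1.0 - h * h


def _relu(z):
    return np.maximum(z, 0.0)


def _drelu(z, h):
    return (z > 0).astype(float)


def _identity(z):
    return z


def _didentity(z, h):
    return np.ones_like(z)


ACTIVATIONS = {
    "tanh": (_tanh, _dtanh),
    "relu": (_relu, _drelu),
    "identity": (_identity, _didentity),
}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Hyperparams:
    """Training hyperparameters.  ``batch_size=None`` means full-batch."""

    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int | None = 64
    epochs: int = 100
    dropout_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.weight_decay < 0 or self.epochs < 0:
            raise ModelError("learning_rate must be > 0, weight_decay/epochs >= 0")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ModelError("dropout_rate must lie in [0, 1)")
        if self.batch_size is not None and self.batch_size < 1:
            raise ModelError("batch_size must be >= 1 or None (full batch)")


def default_grid() -> list[Hyperparams]:
    """Default hyperparameter search grid for cross-validation.

    Learning rate {1e-2, 1e-3} x weight decay {1e-2, 1e-4} x batch size
    {64, full}; 100 epochs, dropout 0.2.
    """
    grid = []
    for lr in (1e-2, 1e-3):
        for wd in (1e-2, 1e-4):
            for bs in (64, None):
                grid.append(Hyperparams(learning_rate=lr, weight_decay=wd, batch_size=bs))
    return grid


@register_result
@dataclass
class RiskTable:
    """Per-patient predicted survival risk (higher = worse prognosis)."""

    KIND = "risks"

    patient_id: list[str]
    risk: np.ndarray

    def __post_init__(self) -> None:
        self.risk = np.asarray(self.risk, dtype=float)
        if not np.isfinite(self.risk).all():
            raise ModelError("risk scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"patient_id": self.patient_id, "risk": self.risk})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RiskTable":
        return cls(df["patient_id"].astype(str).tolist(), df["risk"].to_numpy(float))


@dataclass
class ModelParams:
    """All learnable state of a survival network.

    ``vnn`` holds one ``(W, b)`` pair per masked layer; ``root`` the
    optional dense root projection; ``head`` the two dense head layers.
    Weight matrices are stored with masked positions already zero.
    """

    spec: VNNSpec
    n_clinical: int
    head_width: int
    dropout_rate: float
    activation: str
    seed: int
    vnn: list[tuple[np.ndarray, np.ndarray]]
    root: tuple[np.ndarray, np.ndarray] | None
    head: list[tuple[np.ndarray, np.ndarray]]

    def copy(self) -> "ModelParams":
        return ModelParams(
            spec=self.spec,
            n_clinical=self.n_clinical,
            head_width=self.head_width,
            dropout_rate=self.dropout_rate,
            activation=self.activation,
            seed=self.seed,
            vnn=[(W.copy(), b.copy()) for W, b in self.vnn],
            root=None if self.root is None else (self.root[0].copy(), self.root[1].copy()),
            head=[(W.copy(), b.copy()) for W, b in self.head],
        )

    def masked_weight_max(self) -> float:
        """Largest |weight| sitting on a masked-out (structurally absent)
        position; exactly 0.0 for a valid model."""
        worst = 0.0
        for (W, _), mask in zip(self.vnn, self.spec.masks):
            off = np.abs(W * (1.0 - mask))
            if off.size:
                worst = max(worst, float(off.max()))
        return worst


@dataclass
class CVReport:
    """Cross-validation outcome: per-fold held-out C-index for the chosen
    hyperparameters, the chosen point itself, and the full grid summary."""

    fold_scores: list[float]
    chosen: Hyperparams
    histories: list[list[float]]
    grid_summary: list[tuple[Hyperparams, float]]

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.fold_scores))


# ---------------------------------------------------------------------------
# initialization and forward pass
# ---------------------------------------------------------------------------

def init_model(
    spec: VNNSpec,
    n_clinical: int,
    head_width: int = 64,
    dropout: float = 0.2,
    activation: str = "tanh",
    seed: int = 0,
) -> ModelParams:
    """Create a model with Glorot-uniform weights (masked positions zero)
    and zero biases; deterministic for a given seed."""
    if head_width < 1:
        raise ModelError("head_width must be >= 1")
    if not (0.0 <= dropout < 1.0):
        raise ModelError("dropout must lie in [0, 1)")
    if activation not in ACTIVATIONS:
        raise ModelError(f"unknown activation {activation!r}")
    rng = np.random.default_rng(seed)

    def glorot(shape):
        limit = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-limit, limit, size=shape)

    vnn = []
    for mask in spec.masks:
        W = glorot(mask.shape) * mask
        b = np.zeros(mask.shape[1])
        vnn.append((W, b))
    root = None
    if spec.root_mode == "dense":
        final = spec.masks[-1].shape[1] if spec.masks else spec.n_features
        root = (glorot((final, spec.root_width)), np.zeros(spec.root_width))
    head_in = spec.root_width + n_clinical
    head = [
        (glorot((head_in, head_width)), np.zeros(head_width)),
        (glorot((head_width, 1)), np.zeros(1)),
    ]
    return ModelParams(
        spec=spec,
        n_clinical=n_clinical,
        head_width=head_width,
        dropout_rate=dropout,
        activation=activation,
        seed=seed,
        vnn=vnn,
        root=root,
        head=head,
    )


def _forward_arrays(
    params: ModelParams,
    X_feat: np.ndarray,
    X_clin: np.ndarray,
    training: bool = False,
    rng: np.random.Generator | None = None,
    keep_cache: bool = False,
):
    """Run the network on raw arrays; returns (risk, cache)."""
    act, _ = ACTIVATIONS[params.activation]
    rate = params.dropout_rate if training else 0.0
    if rate > 0 and rng is None:
        raise ModelError("training-mode forward needs an rng for dropout")
    spec = params.spec
    cache = {"h": [X_feat], "z": [None], "drop": [None]} if keep_cache else None

    h = X_feat.astype(float)
    for k, (W, b) in enumerate(params.vnn):
        Weff = W * spec.masks[k] + spec.frozen[k]
        z = h @ Weff + b
        pt = spec.passthrough[k]
        h = np.where(pt, z, act(z))
        dm = None
        if rate > 0:
            dm = np.ones_like(h)
            cols = ~pt
            dm[:, cols] = (rng.random(size=(h.shape[0], int(cols.sum()))) >= rate) / (1 - rate)
            h = h * dm
        if keep_cache:
            cache["z"].append(z)
            cache["h"].append(h)
            cache["drop"].append(dm)

    if params.root is not None:
        Wr, br = params.root
        zr = h @ Wr + br
        hr = act(zr)
        dmr = None
        if rate > 0:
            dmr = (rng.random(size=hr.shape) >= rate) / (1 - rate)
            hr = hr * dmr
        if keep_cache:
            cache["root"] = (zr, hr, dmr)
        root_vec = hr
    else:
        root_vec = h
        if keep_cache:
            cache["root"] = None

    x_head = np.concatenate([root_vec, X_clin.astype(float)], axis=1)
    (W1, b1), (W2, b2) = params.head
    z1 = x_head @ W1 + b1
    h1 = act(z1)
    dm1 = None
    if rate > 0:
        dm1 = (rng.random(size=h1.shape) >= rate) / (1 - rate)
        h1 = h1 * dm1
    risk = (h1 @ W2 + b2).ravel()
    if keep_cache:
        cache.update({"x_head": x_head, "z1": z1, "h1": h1, "drop1": dm1})
    return risk, cache


def _check_features(params: ModelParams, cohort: CohortTable) -> None:
    want = list(params.spec.feature_order)
    have = list(cohort.feature_names)
    if want != have:
        missing = sorted(set(want) - set(have))
        extra = sorted(set(have) - set(want))
        raise ModelError(
            f"cohort features do not match the architecture's panel; "
            f"missing from cohort: {missing}; unexpected in cohort: {extra}"
        )
    if cohort.n_clinical != params.n_clinical:
        raise ModelError(
            f"model expects {params.n_clinical} clinical covariates, "
            f"cohort has {cohort.n_clinical}"
        )


def forward(
    params: ModelParams,
    cohort: CohortTable,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> RiskTable:
    """Predict one scalar risk per patient.  With ``training=False`` the
    output is deterministic (dropout disabled)."""
    _check_features(params, cohort)
    risk, _ = _forward_arrays(
        params, cohort.features, cohort.clinical, training=training, rng=rng
    )
    return RiskTable(list(cohort.patient_id), risk)


# ---------------------------------------------------------------------------
# Cox partial likelihood
# ---------------------------------------------------------------------------

def _as_risk_array(risks) -> np.ndarray:
    if isinstance(risks, RiskTable):
        return risks.risk
    return np.asarray(risks, dtype=float)


def cox_loss(risks, time, event) -> float:
    """Negative Cox log partial likelihood (Breslow ties, log-sum-exp
    stabilized): ``-sum_{i in D} [ r_i - log sum_{j: t_j >= t_i} exp(r_j) ]``.
    """
    loss, _ = cox_loss_grad(risks, time, event)
    return loss


def cox_loss_grad(risks, time, event) -> tuple[float, np.ndarray]:
    """Loss plus its analytic gradient with respect to the risk scores."""
    r = _as_risk_array(risks)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event)
    n = r.shape[0]
    if not (t > 0).all():
        raise ModelError("survival times must be positive")
    if d.sum() == 0:
        raise ModelError("Cox partial likelihood undefined with zero events")

    order = np.argsort(-t, kind="stable")  # descending time
    r_s, t_s, d_s = r[order], t[order], d[order]
    m = float(r_s.max())
    # log of the risk-set sum for each position, including all tied times
    cum = np.cumsum(np.exp(r_s - m))
    # positions sharing a time must all see the full tie group's sum
    last_of_group = np.empty(n, dtype=int)
    first_of_group = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_s[j + 1] == t_s[i]:
            j += 1
        last_of_group[i : j + 1] = j
        first_of_group[i : j + 1] = i
        i = j + 1
    logS = m + np.log(cum[last_of_group])

    ev = d_s == 1
    loss = -float(np.sum(r_s[ev] - logS[ev]))

    # gradient: dL/dr_k = -(d_k - exp(r_k) * sum_{event times tau <= t_k} 1/S_tau).
    # In descending-time order, "tau <= t_k" means positions at or after the
    # first index of k's tie group, hence a reverse cumulative sum.
    inv_S = np.zeros(n)
    inv_S[ev] = np.exp(-(logS[ev] - m))
    rev_cum = np.cumsum(inv_S[::-1])[::-1]
    grad_s = -(d_s.astype(float) - np.exp(r_s - m) * rev_cum[first_of_group])
    grad = np.empty(n)
    grad[order] = grad_s
    return loss, grad


# ---------------------------------------------------------------------------
# backward pass and AdamW
# ---------------------------------------------------------------------------

def _backward(params: ModelParams, cache, drisk: np.ndarray):
    """Backpropagate dL/drisk to gradients for every learnable array."""
    _, dact = ACTIVATIONS[params.activation]
    spec = params.spec
    (W1, b1), (W2, b2) = params.head

    h1, z1, dm1, x_head = cache["h1"], cache["z1"], cache["drop1"], cache["x_head"]
    dcol = drisk[:, None]
    gW2 = h1.T @ dcol
    gb2 = dcol.sum(axis=0)
    dh1 = dcol @ W2.T
    h1_pre = h1 if dm1 is None else np.where(dm1 > 0, h1 / np.where(dm1 == 0, 1, dm1), 0.0)
    if dm1 is not None:
        dh1 = dh1 * dm1
    dz1 = dh1 * dact(z1, h1_pre)
    gW1 = x_head.T @ dz1
    gb1 = dz1.sum(axis=0)
    dx_head = dz1 @ W1.T
    droot = dx_head[:, : x_head.shape[1] - params.n_clinical]

    groot = None
    if params.root is not None:
        Wr, _ = params.root
        zr, hr, dmr = cache["root"]
        hr_pre = hr if dmr is None else np.where(dmr > 0, hr / np.where(dmr == 0, 1, dmr), 0.0)
        if dmr is not None:
            droot = droot * dmr
        dzr = droot * dact(zr, hr_pre)
        groot = (cache["h"][-1].T @ dzr, dzr.sum(axis=0))
        droot = dzr @ Wr.T

    gvnn = []
    dh = droot
    for k in range(len(params.vnn) - 1, -1, -1):
        W, _ = params.vnn[k]
        mask, fro, pt = spec.masks[k], spec.frozen[k], spec.passthrough[k]
        z = cache["z"][k + 1]
        h_out = cache["h"][k + 1]
        dm = cache["drop"][k + 1]
        h_pre = h_out if dm is None else np.where(dm > 0, h_out / np.where(dm == 0, 1, dm), 0.0)
        if dm is not None:
            dh = dh * dm
        dz = np.where(pt, dh, dh * dact(z, h_pre))
        h_prev = cache["h"][k]
        gW = (h_prev.T @ dz) * mask  # frozen and absent positions get no gradient
        gb = dz.sum(axis=0)
        gb[pt] = 0.0
        gvnn.append((gW, gb))
        Weff = W * mask + fro
        dh = dz @ Weff.T
    gvnn.reverse()
    return {"vnn": gvnn, "root": groot, "head": [(gW1, gb1), (gW2, gb2)]}


class _AdamW:
    """Decoupled-weight-decay Adam on a flat list of arrays."""

    def __init__(self, arrays, lr, weight_decay, beta1=0.9, beta2=0.999, eps=1e-8):
        self.arrays = arrays
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, grads, decay_flags):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for a, g, m, v, decay in zip(self.arrays, grads, self.m, self.v, decay_flags):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if decay:
                update = update + self.wd * a
            a -= self.lr * update


def _flatten(params: ModelParams):
    """(arrays, grads-aligner, decay flags): weights decay, biases do not."""
    arrays, decay = [], []
    for W, b in params.vnn:
        arrays += [W, b]
        decay += [True, False]
    if params.root is not None:
        arrays += list(params.root)
        decay += [True, False]
    for W, b in params.head:
        arrays += [W, b]
        decay += [True, False]
    return arrays, decay


def _flatten_grads(params: ModelParams, grads):
    out = []
    for gW, gb in grads["vnn"]:
        out += [gW, gb]
    if params.root is not None:
        out += list(grads["root"])
    for gW, gb in grads["head"]:
        out += [gW, gb]
    return out


def train(
    params: ModelParams,
    cohort: CohortTable,
    hp: Hyperparams,
) -> tuple[ModelParams, dict]:
    """Train a copy of ``params`` on ``cohort`` and return it with a history.

    Mini-batches are drawn with seed-controlled shuffling; the partial
    likelihood and its risk sets are computed within each batch.  A batch
    that happens to contain no events is skipped with a log notice.  The
    history records the full-cohort loss (dropout off) after each epoch.
    """
    _check_features(params, cohort)
    if int(cohort.event.sum()) < 2:
        raise ModelError("training requires at least 2 observed events")
    params = params.copy()
    if hp.dropout_rate is not None:
        params = replace(params, dropout_rate=hp.dropout_rate)
    arrays, decay = _flatten(params)
    opt = _AdamW(arrays, hp.learning_rate, hp.weight_decay)
    rng = np.random.default_rng(hp.seed)
    n = cohort.n
    bs = hp.batch_size or n
    X, C = cohort.features, cohort.clinical
    history: dict = {"loss": [], "skipped_batches": 0}

    def full_loss():
        risk, _ = _forward_arrays(params, X, C, training=False)
        return cox_loss(risk, cohort.time, cohort.event)

    for _epoch in range(hp.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, bs):
            idx = perm[start : start + bs]
            if cohort.event[idx].sum() == 0:
                history["skipped_batches"] += 1
                logger.info("skipping mini-batch with zero events")
                continue
            risk, cache = _forward_arrays(
                params, X[idx], C[idx], training=params.dropout_rate > 0, rng=rng,
                keep_cache=True,
            )
            _, drisk = cox_loss_grad(risk, cohort.time[idx], cohort.event[idx])
            grads = _backward(params, cache, drisk)
            opt.step(_flatten_grads(params, grads), decay)
            # masked positions receive zero gradient and zero decay, but
            # re-assert structural absence exactly
            for (W, _b), mask in zip(params.vnn, params.spec.masks):
                W *= mask
        history["loss"].append(full_loss())
    return params, history


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _stratified_folds(event: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Event-stratified fold assignment; every fold holds >= 1 event."""
    n = event.shape[0]
    if k < 2 or n < k:
        raise ModelError("need k >= 2 and n >= k for cross-validation")
    if int(event.sum()) < k:
        raise ModelError(
            f"cannot build {k} folds each containing an event: only "
            f"{int(event.sum())} events observed"
        )
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=int)
    for cls in (1, 0):
        idx = np.flatnonzero(event == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % k
    return [np.flatnonzero(fold == f) for f in range(k)]


def cross_validate(
    cohort: CohortTable,
    spec: VNNSpec,
    grid: list[Hyperparams] | None = None,
    k: int = 10,
    seed: int = 0,
    head_width: int = 64,
    activation: str = "tanh",
) -> CVReport:
    """K-fold cross-validation with hyperparameter search.

    Folds are split once (stratified by event status) and shared by every
    grid point; the point with the highest mean held-out C-index wins.
    """
    from .evaluation import c_index

    grid = grid or default_grid()
    folds = _stratified_folds(cohort.event, k, seed)
    all_idx = np.arange(cohort.n)

    summary: list[tuple[Hyperparams, float]] = []
    best = None
    for gi, hp in enumerate(grid):
        scores, hists = [], []
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(all_idx, test_idx)
            tr = cohort.select_patients(train_idx)
            te = cohort.select_patients(test_idx)
            fold_seed = (seed * 9973 + gi * 131 + f) % (2**31)
            m0 = init_model(
                spec, cohort.n_clinical, head_width, hp.dropout_rate,
                activation, seed=fold_seed,
            )
            fitted, hist = train(m0, tr, replace(hp, seed=fold_seed))
            risks = forward(fitted, te)
            scores.append(c_index(risks, te.time, te.event).value)
            hists.append(hist["loss"])
        mean = float(np.mean(scores))
        summary.append((hp, mean))
        if best is None or mean > best[0]:
            best = (mean, hp, scores, hists)
    _, chosen, fold_scores, histories = best
    return CVReport(fold_scores, chosen, histories, summary)


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def dense_spec_like(spec: VNNSpec) -> VNNSpec:
    """A fully connected architecture with the same layer count and the
    same number of units per layer as ``spec`` (no masking, no skip
    channels); its parameter count is therefore >= the masked model's."""
    masks = [np.ones(m.shape) for m in spec.masks]
    return VNNSpec(
        n_layers=spec.n_layers,
        layer_of={},
        node_width=spec.node_width,
        feature_order=spec.feature_order,
        unit_names=spec.unit_names,
        masks=masks,
        frozen=[np.zeros(m.shape) for m in spec.masks],
        passthrough=[np.zeros(m.shape[1], dtype=bool) for m in spec.masks],
        pathway_blocks={},
        root_mode="concat",
        root_width=spec.masks[-1].shape[1] if spec.masks else len(spec.feature_order),
        orphan_genes=(),
        roots=(),
    )


def baseline_dense(
    cohort: CohortTable,
    spec: VNNSpec,
    grid: list[Hyperparams] | None = None,
    k: int = 10,
    seed: int = 0,
    head_width: int = 64,
    activation: str = "tanh",
) -> CVReport:
    """Cross-validate the dense (unmasked) counterpart of ``spec``."""
    return cross_validate(
        cohort, dense_spec_like(spec), grid, k=k, seed=seed,
        head_width=head_width, activation=activation,
    )


def baseline_linear_ph(cohort: CohortTable):
    """Linear Cox proportional-hazards baseline fitted by partial-likelihood
    maximization (lifelines).  Returns ``(RiskTable, coefficients)`` where
    the risk is the linear predictor.  Constant columns are dropped with a
    warning; an all-censored cohort is rejected."""
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if int(cohort.event.sum()) == 0:
        raise ModelError("cannot fit a proportional-hazards model with zero events")
    df = cohort.to_frame().drop(columns=["patient_id"])
    covariates = [c for c in df.columns if c not in ("time", "event")]
    kept = []
    for c in covariates:
        if df[c].nunique() < 2:
            warnings.warn(f"dropping constant covariate {c!r} from the linear PH fit")
        else:
            kept.append(c)
    if not kept:
        raise ModelError("no non-constant covariates to fit")
    fitter = CoxPHFitter(penalizer=0.0)
    try:
        fitter.fit(df[kept + ["time", "event"]], duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise ModelError(f"linear proportional-hazards fit did not converge: {err}")
    coefs = fitter.params_
    risk = df[kept].to_numpy(float) @ coefs.to_numpy(float)
    return RiskTable(list(cohort.patient_id), risk), coefs


# ---------------------------------------------------------------------------
# serialization (text container: spec + weights + config, versioned)
# ---------------------------------------------------------------------------

def save_model(params: ModelParams, path) -> None:
    payload = {
        "format": "vnnsurv-model-v1",
        "spec": json.loads(params.spec.to_json()),
        "n_clinical": params.n_clinical,
        "head_width": params.head_width,
        "dropout_rate": params.dropout_rate,
        "activation": params.activation,
        "seed": params.seed,
        "vnn": [[W.tolist(), b.tolist()] for W, b in params.vnn],
        "root": None if params.root is None
        else [params.root[0].tolist(), params.root[1].tolist()],
        "head": [[W.tolist(), b.tolist()] for W, b in params.head],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path) -> ModelParams:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != "vnnsurv-model-v1":
        raise ModelError(f"{path} is not a vnnsurv model file")
    spec = VNNSpec.from_json(json.dumps(payload["spec"]))
    return ModelParams(
        spec=spec,
        n_clinical=payload["n_clinical"],
        head_width=payload["head_width"],
        dropout_rate=payload["dropout_rate"],
        activation=payload["activation"],
        seed=payload["seed"],
        vnn=[(np.asarray(W), np.asarray(b)) for W, b in payload["vnn"]],
        root=None if payload["root"] is None
        else (np.asarray(payload["root"][0]), np.asarray(payload["root"][1])),
        head=[(np.asarray(W), np.asarray(b)) for W, b in payload["head"]],
    )
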