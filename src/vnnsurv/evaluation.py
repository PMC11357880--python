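"""Survival-model evaluation: concordance index, Kaplan-Meier curves,
log-rank and Wilcoxon rank-sum tests, and the significance-star convention.

The concordance index follows the printed double-sum definition: *i* runs
over patients with an observed event, *j* over the risk set at t_i
(everyone with t_j >= t_i, excluding i itself), and a pair counts as
concordant when the predicted risk of the earlier-dying patient is strictly
higher.  ``ties="half"`` awards 0.5 to risk ties for comparability with
other tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CIndexResult",
    "SurvivalCurve",
    "EvaluationError",
    "c_index",
    "km_curve",
    "logrank_test",
    "wilcoxon_ranksum",
    "significance_stars",
]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class CIndexResult:
    value: float
    n_effective: int  # number of comparable (event, at-risk) pairs

    def __post_init__(self):
        if not (0.0 <= self.value <= 1.0) or self.n_effective < 1:
            raise EvaluationError("invalid concordance result")


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit (Kaplan-Meier) estimate."""

    times: np.ndarray        # distinct event times, ascending
    survival: np.ndarray     # S(t) just after each event time
    at_risk: np.ndarray      # risk-set size just before each event time
    n_events: np.ndarray     # deaths at each event time

    def __post_init__(self):
        s = self.survival
        if s.size and (np.any(np.diff(s) > 1e-12) or s.min() < -1e-12 or s.max() > 1 + 1e-12):
            raise EvaluationError("survival probabilities must be non-increasing in [0, 1]")

    def at(self, t: float) -> float:
        """S(t); 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def c_index(risks, time, event, ties: str = "strict") -> CIndexResult:
    """Concordance between predicted risks and observed survival.

    ``strict`` scores a pair 1 only when the event patient's risk is
    strictly greater (tied risks score 0); ``half`` gives ties 0.5 credit.
    """
    from .model import RiskTable  # late import to avoid a cycle

    if isinstance(risks, RiskTable):
        risks = risks.risk
    r = np.asarray(risks, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event).astype(int)
    if ties not in ("strict", "half"):
        raise EvaluationError(f"unknown tie mode {ties!r}")
    if d.sum() == 0:
        raise EvaluationError("concordance undefined with zero events")

    comparable = (d[:, None] == 1) & (t[None, :] >= t[:, None])
    np.fill_diagonal(comparable, False)
    n_eff = int(comparable.sum())
    if n_eff == 0:
        raise EvaluationError("no comparable patient pairs")
    greater = r[:, None] > r[None, :]
    score = float((greater & comparable).sum())
    if ties == "half":
        tied = r[:, None] == r[None, :]
        score += 0.5 * float((tied & comparable).sum())
    return CIndexResult(score / n_eff, n_eff)


def km_curve(time, event) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator; censored observations shrink
    the risk set without producing a step."""
    from lifelines import KaplanMeierFitter

    t = np.asarray(time, dtype=float)
    d = np.asarray(event).astype(int)
    if t.size == 0:
        raise EvaluationError("empty sample")
    kmf = KaplanMeierFitter()
    kmf.fit(t, d)
    event_times = np.unique(t[d == 1])
    if event_times.size == 0:
        return SurvivalCurve(
            np.empty(0), np.empty(0), np.empty(0, dtype=int), np.empty(0, dtype=int)
        )
    surv = np.array([float(kmf.predict(tt)) for tt in event_times])
    at_risk = np.array([(t >= tt).sum() for tt in event_times])
    n_ev = np.array([((t == tt) & (d == 1)).sum() for tt in event_times])
    return SurvivalCurve(event_times, surv, at_risk, n_ev)


def logrank_test(groups) -> tuple[float, float]:
    """Unweighted (Mantel-Haenszel) log-rank test across ``groups``, a list
    of ``(time, event)`` pairs.  Returns ``(chi_square, p_value)`` with
    ``len(groups) - 1`` degrees of freedom; exact tie handling through
    hypergeometric moments at each distinct event time."""
    from lifelines.statistics import multivariate_logrank_test

    if len(groups) < 2:
        raise EvaluationError("log-rank test needs at least two groups")
    times, events, labels = [], [], []
    for g, (t, d) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        d = np.asarray(d).astype(int)
        if t.size == 0:
            raise EvaluationError(f"group {g} is empty")
        times.append(t)
        events.append(d)
        labels.append(np.full(t.size, g))
    times = np.concatenate(times)
    events = np.concatenate(events)
    labels = np.concatenate(labels)
    if events.sum() == 0:
        raise EvaluationError("log-rank test undefined with zero events")
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


def wilcoxon_ranksum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Mid-ranks for ties; exact enumeration for small samples without ties,
    otherwise the normal approximation with continuity correction.
    Returns ``(U, p_value)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EvaluationError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    small = max(a.size, b.size) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    """ns, * < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001."""
    if not (0.0 <= p <= 1.0):
        raise EvaluationError(f"p-value {p} outside [0, 1]")
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p < cut:
            return stars
    return "ns"
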