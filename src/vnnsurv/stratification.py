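"""Genetic prognostic index (GPI), three-level risk stratification,
pairwise alteration-interaction statistics, intersection (UpSet) counts,
and genetic subtype / sub-subtype assignment.

The GPI is a per-patient weighted sum of key alteration indicators with
their impact values as weights; two thresholds split the score range into
risk levels I (score <= t1), II (t1 < score <= t2) and III (score > t2).
Interaction analysis labels feature pairs as co-occurring or mutually
exclusive by two-sided Fisher exact tests with Benjamini-Hochberg false
discovery control.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .evaluation import logrank_test
from .interpretation import ImpactTable, ShapMatrix
from .io_formats import CohortTable, register_result

__all__ = [
    "StratificationError",
    "GPIResult",
    "InteractionTable",
    "SubtypeAssignment",
    "gpi_score",
    "assign_levels",
    "make_gpi_result",
    "optimize_thresholds",
    "pairwise_interactions",
    "intersection_counts",
    "assign_subtypes",
    "sub_subtype_by_shap_rank",
]

LEVELS = ("I", "II", "III")


class StratificationError(ValueError):
    pass


@register_result
@dataclass
class GPIResult:
    """Per-patient GPI score and risk level under thresholds (t1, t2)."""

    KIND = "gpi"

    patient_id: list[str]
    score: np.ndarray
    level: list[str]
    t1: float
    t2: float
    f_key: list[str]

    def __post_init__(self):
        self.score = np.asarray(self.score, dtype=float)
        if self.t1 >= self.t2:
            raise StratificationError("thresholds must satisfy t1 < t2")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"patient_id": self.patient_id, "score": self.score, "level": self.level}
        )
        df["t1"] = self.t1
        df["t2"] = self.t2
        df["f_key"] = ",".join(self.f_key)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GPIResult":
        return cls(
            df["patient_id"].astype(str).tolist(),
            df["score"].to_numpy(float),
            df["level"].astype(str).tolist(),
            float(df["t1"].iloc[0]),
            float(df["t2"].iloc[0]),
            str(df["f_key"].iloc[0]).split(","),
        )


@register_result
@dataclass
class InteractionTable:
    """Pairwise co-occurrence / mutual-exclusivity calls."""

    KIND = "interactions"

    table: pd.DataFrame  # feature_a, feature_b, a, b, c, d, odds_ratio,
    #                      odds_ratio_haldane, p, q, label

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "InteractionTable":
        return cls(df.copy())


@register_result
@dataclass
class SubtypeAssignment:
    """Marker-based subtype and anchor-rank sub-subtype per patient."""

    KIND = "subtypes"

    patient_id: list[str]
    subtype: list[str]       # H1 | L1 | both | unclassified
    sub_subtype: list[str]   # MYD88-I | MYD88-II | NA (anchor-negative)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "subtype": self.subtype,
                "sub_subtype": self.sub_subtype,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SubtypeAssignment":
        return cls(
            df["patient_id"].astype(str).tolist(),
            df["subtype"].astype(str).tolist(),
            df["sub_subtype"].astype(str).tolist(),
        )


# ---------------------------------------------------------------------------
# GPI
# ---------------------------------------------------------------------------

def gpi_score(cohort: CohortTable, impact: ImpactTable, f_key) -> np.ndarray:
    """score_i = sum over key features j of f_ij * Impact_j."""
    f_key = list(f_key)
    impacts = impact.as_dict()
    missing = [f for f in f_key if f not in impacts or f not in cohort.feature_names]
    if missing:
        raise StratificationError(
            f"key features absent from cohort or impact table: {missing}"
        )
    cols = [cohort.feature_names.index(f) for f in f_key]
    weights = np.array([impacts[f] for f in f_key])
    return cohort.features[:, cols].astype(float) @ weights


def assign_levels(scores, t1: float, t2: float) -> list[str]:
    """I if score <= t1, II if t1 < score <= t2, III if score > t2;
    boundary scores fall to the lower level."""
    if t1 >= t2:
        raise StratificationError("thresholds must satisfy t1 < t2")
    scores = np.asarray(scores, dtype=float)
    return ["I" if s <= t1 else ("II" if s <= t2 else "III") for s in scores]


def make_gpi_result(
    cohort: CohortTable, impact: ImpactTable, f_key, t1: float, t2: float
) -> GPIResult:
    scores = gpi_score(cohort, impact, f_key)
    return GPIResult(
        list(cohort.patient_id), scores, assign_levels(scores, t1, t2),
        float(t1), float(t2), list(f_key),
    )


def optimize_thresholds(
    scores,
    time,
    event,
    grid,
    min_group: int = 10,
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Search ordered grid pairs (t1 < t2) for the split whose three risk
    levels differ most significantly in survival.

    Objective: minimize the worst (largest) of the three pairwise log-rank
    p-values, subject to every level holding at least ``min_group``
    patients.  Ties break toward more balanced group sizes, then the
    lexicographically smaller pair.  Returns the chosen pair plus a
    diagnostics frame of every admissible pair evaluated.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    grid = sorted(set(float(g) for g in grid))
    if len(grid) < 2:
        raise StratificationError("threshold grid needs at least 2 distinct values")
    if min_group < 1:
        raise StratificationError("min_group must be >= 1")

    rows = []
    best = None
    for t1, t2 in itertools.combinations(grid, 2):
        levels = np.array(assign_levels(scores, t1, t2))
        sizes = [(levels == lv).sum() for lv in LEVELS]
        if min(sizes) < min_group:
            continue
        ps = []
        ok = True
        for a, b in itertools.combinations(LEVELS, 2):
            ia, ib = levels == a, levels == b
            if event[ia].sum() + event[ib].sum() == 0:
                ok = False
                break
            _, p = logrank_test([(time[ia], event[ia]), (time[ib], event[ib])])
            ps.append(p)
        if not ok:
            continue
        worst = max(ps)
        imbalance = max(sizes) - min(sizes)
        rows.append(
            {"t1": t1, "t2": t2, "worst_p": worst, "imbalance": imbalance,
             "n_I": sizes[0], "n_II": sizes[1], "n_III": sizes[2]}
        )
        key = (worst, imbalance, t1, t2)
        if best is None or key < best[0]:
            best = (key, (t1, t2))
    if best is None:
        raise StratificationError(
            "no admissible threshold pair: every split leaves a level below "
            f"min_group={min_group} or without events"
        )
    return best[1], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pairwise interactions & intersections
# ---------------------------------------------------------------------------

def pairwise_interactions(
    cohort: CohortTable, features, alpha: float = 0.05
) -> InteractionTable:
    """Fisher exact tests for co-occurrence/mutual exclusivity.

    For each unordered feature pair the 2x2 table counts patients altered
    in both (a), first only (b), second only (c), neither (d).  Two-sided
    Fisher p-values are corrected by Benjamini-Hochberg across all tested
    pairs; a pair is labelled ``co-occurrence`` when q < alpha and the odds
    ratio exceeds 1, ``exclusivity`` when q < alpha and it is below 1.
    Degenerate tables keep the inf/0 odds-ratio convention; a
    Haldane-corrected column (+0.5 on each cell) is supplied for plotting.
    """
    features = list(features)
    testable = []
    for f in features:
        if f not in cohort.feature_names:
            raise StratificationError(f"feature {f!r} absent from cohort")
        col = cohort.features[:, cohort.feature_names.index(f)]
        if col.min() == col.max():
            warnings.warn(f"excluding constant feature {f!r} from interaction tests")
        else:
            testable.append(f)
    if len(testable) < 2:
        raise StratificationError("need at least 2 non-constant features to test")

    rows = []
    for fa, fb in itertools.combinations(testable, 2):
        xa = cohort.features[:, cohort.feature_names.index(fa)].astype(bool)
        xb = cohort.features[:, cohort.feature_names.index(fb)].astype(bool)
        a = int((xa & xb).sum())
        b = int((xa & ~xb).sum())
        c = int((~xa & xb).sum())
        d = int((~xa & ~xb).sum())
        orr, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        rows.append(
            {"feature_a": fa, "feature_b": fb, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": float(orr), "odds_ratio_haldane": float(haldane),
             "p": float(p)}
        )
    df = pd.DataFrame(rows)
    _, q, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
    df["q"] = q
    labels = []
    for orr, qv in zip(df["odds_ratio"], df["q"]):
        if qv < alpha and orr > 1:
            labels.append("co-occurrence")
        elif qv < alpha and orr < 1:
            labels.append("exclusivity")
        else:
            labels.append("none")
    df["label"] = labels
    return InteractionTable(df)


def intersection_counts(cohort: CohortTable, features) -> dict[tuple[int, ...], int]:
    """Exclusive-intersection (UpSet) counts: patients are grouped by their
    exact presence pattern over ``features``; zero-count patterns omitted.
    The counts partition the cohort."""
    features = list(features)
    if not features:
        raise StratificationError("feature list must be non-empty")
    cols = [cohort.feature_names.index(f) for f in features]
    patterns = cohort.features[:, cols]
    out: dict[tuple[int, ...], int] = {}
    for row in patterns:
        key = tuple(int(v) for v in row)
        out[key] = out.get(key, 0) + 1
    return out


# ---------------------------------------------------------------------------
# subtypes
# ---------------------------------------------------------------------------

def assign_subtypes(
    cohort: CohortTable, h1_markers, l1_markers
) -> SubtypeAssignment:
    """Marker-based genetic subtypes: any high-risk marker altered -> H1,
    any low-risk marker altered -> L1, both -> "both" (reported, not
    silently resolved), neither -> unclassified."""
    h1 = list(h1_markers)
    l1 = list(l1_markers)
    overlap = set(h1) & set(l1)
    if overlap:
        raise StratificationError(f"marker sets overlap: {sorted(overlap)}")
    for f in h1 + l1:
        if f not in cohort.feature_names:
            raise StratificationError(f"marker {f!r} absent from cohort")
    h_cols = [cohort.feature_names.index(f) for f in h1]
    l_cols = [cohort.feature_names.index(f) for f in l1]
    has_h = cohort.features[:, h_cols].any(axis=1)
    has_l = cohort.features[:, l_cols].any(axis=1)
    subtype = []
    for hh, ll in zip(has_h, has_l):
        if hh and ll:
            subtype.append("both")
        elif hh:
            subtype.append("H1")
        elif ll:
            subtype.append("L1")
        else:
            subtype.append("unclassified")
    return SubtypeAssignment(
        list(cohort.patient_id), subtype, ["NA"] * cohort.n
    )


def sub_subtype_by_shap_rank(
    shap: ShapMatrix,
    cohort: CohortTable,
    anchor_feature: str,
    top_k: int = 5,
) -> dict[str, str]:
    """Split anchor-positive patients by whether the anchor alteration's
    |SHAP| ranks in the top ``top_k`` genetic features for that patient.

    Competition ranking (ties share the better rank).  Rank <= top_k maps
    to sub-subtype II (anchor-dominant, reported as the worse-prognosis
    group), the rest to sub-subtype I.  Only carriers of the anchor
    alteration are assigned.
    """
    genetic = [f for f in cohort.feature_names if f in shap.node_names]
    if anchor_feature not in genetic:
        raise StratificationError(
            f"anchor feature {anchor_feature!r} absent from the attribution scope"
        )
    anchor_col = cohort.feature_names.index(anchor_feature)
    abs_vals = np.abs(
        np.column_stack([shap.column(f) for f in genetic])
    )
    anchor_j = genetic.index(anchor_feature)
    out: dict[str, str] = {}
    prefix = anchor_feature.split()[0].split("_")[0]
    for i, pid in enumerate(cohort.patient_id):
        if cohort.features[i, anchor_col] != 1:
            continue
        rank = 1 + int((abs_vals[i] > abs_vals[i, anchor_j]).sum())
        out[pid] = f"{prefix}-II" if rank <= top_k else f"{prefix}-I"
    return out
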