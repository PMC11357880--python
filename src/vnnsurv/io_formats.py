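"""Readers and writers for the file formats vnnsurv consumes and emits.

Input side: the patient cohort table (TSV), gene-set collections (GMT) and
pathway hierarchies (two-column child/parent TSV).  Output side: every
tabular result produced by the package plus the Sankey graph file.  All
formats are plain text, UTF-8, tab-separated with a header, and round-trip
losslessly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "GeneSetCollection",
    "HierarchyEdges",
    "FormatError",
    "DEFAULT_CLINICAL_NAMES",
    "read_cohort",
    "write_cohort",
    "read_gene_sets",
    "read_hierarchy",
    "write_results",
    "read_results",
]

#: Canonical binary clinical covariates: age at diagnosis > 60 years,
#: R-CHOP treatment received, de novo (vs transformed) disease.
DEFAULT_CLINICAL_NAMES = ("age_gt_60", "rchop", "de_novo")

RESERVED_COLUMNS = ("patient_id", "time", "event")

# float format that survives a text round trip bit-exactly for doubles
_FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """A file violated the expected dialect or an encoding invariant."""


@dataclass
class CohortTable:
    """A patient cohort: binary alteration features, binary clinical
    covariates, survival time in days and the event (death) indicator.

    ``features[i, j]`` is 1 when patient *i* carries genetic alteration
    *j* and 0 otherwise; clinical covariates are encoded the same way.
    """

    patient_id: list[str]
    features: np.ndarray            # (n, p) values in {0, 1}
    feature_names: list[str]
    clinical: np.ndarray            # (n, c) values in {0, 1}
    clinical_names: list[str]
    time: np.ndarray                # (n,) positive reals, days
    event: np.ndarray               # (n,) in {0, 1}; 1 = death observed

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.int8)
        self.clinical = np.asarray(self.clinical, dtype=np.int8)
        if self.clinical.size == 0:
            self.clinical = self.clinical.reshape(len(self.patient_id), 0)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=np.int8)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n = len(self.patient_id)
        if self.features.shape != (n, len(self.feature_names)):
            raise FormatError(
                f"feature matrix shape {self.features.shape} does not match "
                f"{n} patients x {len(self.feature_names)} feature names"
            )
        if self.clinical.shape != (n, len(self.clinical_names)):
            raise FormatError("clinical matrix/name mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise FormatError("feature names are not unique")
        for name, mat in (("feature", self.features), ("clinical", self.clinical)):
            bad = (mat != 0) & (mat != 1)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise FormatError(f"non-binary {name} value at row {i}, column {j}")
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise FormatError("time/event length mismatch")
        if (self.time <= 0).any():
            i = int(np.argmax(self.time <= 0))
            raise FormatError(f"non-positive survival time for patient {self.patient_id[i]!r}")
        if not np.isin(self.event, (0, 1)).all():
            raise FormatError("event indicator must be 0 or 1")

    # -- conveniences ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.patient_id)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_clinical(self) -> int:
        return len(self.clinical_names)

    def select_patients(self, index) -> "CohortTable":
        index = np.asarray(index)
        return CohortTable(
            [self.patient_id[i] for i in index],
            self.features[index],
            list(self.feature_names),
            self.clinical[index],
            list(self.clinical_names),
            self.time[index],
            self.event[index],
        )

    def with_features(self, names) -> "CohortTable":
        """Restrict (and reorder) the genetic feature panel to ``names``."""
        missing = [f for f in names if f not in self.feature_names]
        if missing:
            raise FormatError(f"features absent from cohort: {missing}")
        cols = [self.feature_names.index(f) for f in names]
        return replace(self, features=self.features[:, cols], feature_names=list(names))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"patient_id": self.patient_id})
        for j, name in enumerate(self.feature_names):
            df[name] = self.features[:, j]
        for j, name in enumerate(self.clinical_names):
            df[name] = self.clinical[:, j]
        df["time"] = self.time
        df["event"] = self.event
        return df


@dataclass(frozen=True)
class GeneSetCollection:
    """Mapping of pathway identifier to its member gene symbols."""

    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for pid, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {pid!r} has no members")

    def __getitem__(self, pid: str) -> frozenset[str]:
        return self.sets[pid]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def pathways_of(self, gene: str) -> set[str]:
        return {pid for pid, members in self.sets.items() if gene in members}


@dataclass(frozen=True)
class HierarchyEdges:
    """Directed (child, parent) relations between pathways."""

    edges: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for child, parent in self.edges:
            if child == parent:
                raise FormatError(f"self-edge on pathway {child!r}")

    def __iter__(self):
        return iter(self.edges)

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# cohort TSV
# ---------------------------------------------------------------------------

def read_cohort(
    path,
    missing_default: dict[str, int] | None = None,
    clinical_names=DEFAULT_CLINICAL_NAMES,
) -> CohortTable:
    """Read a cohort table from a tab-separated file.

    Expected columns: optional ``patient_id``, any number of binary
    feature columns, then ``time`` and ``event``.  Columns whose name is
    listed in ``clinical_names`` are treated as clinical covariates; all
    other binary columns are genetic features.

    ``missing_default`` maps feature names that the file may lack to the
    constant value (0 or 1) assigned uniformly to every patient, the
    convention used when a cohort's sequencing panel did not cover a
    feature.  Features already present in the file are left untouched;
    defaulted columns are appended after the file's own features.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("time", "event"):
        if col not in df.columns:
            raise FormatError(f"required column {col!r} missing from {path}")
    if "patient_id" in df.columns:
        patient_id = df["patient_id"].astype(str).tolist()
    else:
        patient_id = [f"P{i + 1:04d}" for i in range(len(df))]

    time = pd.to_numeric(df["time"], errors="coerce").to_numpy(float)
    if np.isnan(time).any():
        row = int(np.argmax(np.isnan(time)))
        raise FormatError(f"non-numeric time at row {row + 2} of {path}")
    event = _binary_column(df["event"], "event", path)

    binary_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    values = {c: _binary_column(df[c], c, path) for c in binary_cols}
    clin_present = [c for c in binary_cols if c in clinical_names]
    feat_present = [c for c in binary_cols if c not in clinical_names]

    feature_names = list(feat_present)
    columns = [values[c] for c in feat_present]
    for name, default in (missing_default or {}).items():
        if default not in (0, 1):
            raise FormatError(f"missing-feature default for {name!r} must be 0 or 1")
        if name in feature_names or name in clin_present:
            continue  # present in the file; the file wins
        feature_names.append(name)
        columns.append(np.full(len(df), default, dtype=np.int8))
    features = (
        np.column_stack(columns) if columns else np.zeros((len(df), 0), dtype=np.int8)
    )
    clinical = (
        np.column_stack([values[c] for c in clin_present])
        if clin_present
        else np.zeros((len(df), 0), dtype=np.int8)
    )
    return CohortTable(
        patient_id, features, feature_names, clinical, list(clin_present), time, event
    )


def _binary_column(series: pd.Series, name: str, path) -> np.ndarray:
    out = np.empty(len(series), dtype=np.int8)
    for i, raw in enumerate(series):
        s = str(raw).strip()
        if s not in ("0", "1"):
            raise FormatError(
                f"non-binary value {raw!r} in column {name!r}, row {i + 2} of {path}"
            )
        out[i] = int(s)
    return out


def write_cohort(cohort: CohortTable, path) -> None:
    df = cohort.to_frame()
    df["time"] = [(_FLOAT_FMT % t) for t in cohort.time]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets and hierarchy edge lists
# ---------------------------------------------------------------------------

def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: ``id <TAB> description <TAB> gene1 <TAB> gene2 ...``.

    The description field is discarded and duplicate member genes within a
    line are collapsed.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno} has fewer than 3 fields")
            pid = fields[0]
            if pid in sets:
                raise FormatError(f"duplicate pathway id {pid!r} at GMT line {lineno}")
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise FormatError(f"GMT line {lineno}: pathway {pid!r} has no members")
            sets[pid] = members
    return GeneSetCollection(sets)


def write_gene_sets(gene_sets: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sorted(gene_sets.sets):
            members = "\t".join(sorted(gene_sets.sets[pid]))
            fh.write(f"{pid}\tna\t{members}\n")


def read_hierarchy(path) -> HierarchyEdges:
    """Read a two-column (child, parent) TSV; an optional header line with
    the tokens ``child``/``parent`` is skipped; duplicate edges collapse."""
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise FormatError(f"malformed hierarchy line {lineno}: {line!r}")
            child, parent = fields
            if lineno == 1 and child.lower() in ("child", "child_pathway_id"):
                continue
            if child == parent:
                raise FormatError(f"self-edge {child!r} at hierarchy line {lineno}")
            if (child, parent) not in seen:
                seen.add((child, parent))
                edges.append((child, parent))
    return HierarchyEdges(tuple(edges))


def write_hierarchy(hierarchy: HierarchyEdges, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("child\tparent\n")
        for child, parent in hierarchy:
            fh.write(f"{child}\t{parent}\n")


# ---------------------------------------------------------------------------
# result tables (generic, registry-based)
# ---------------------------------------------------------------------------
# Every result class exposes KIND, to_frame() and from_frame(); SankeyGraph
# additionally uses a node/edge record layout handled by the same TSV shape.

_RESULT_REGISTRY: dict[str, type] = {}


def register_result(cls):
    """Class decorator registering a result type for read/write dispatch."""
    _RESULT_REGISTRY[cls.KIND] = cls
    return cls


def write_results(table, path) -> None:
    """Serialize a result table (or Sankey graph) to a tagged TSV file.

    The first line is a ``#vnnsurv <kind>`` marker so that
    :func:`read_results` can reconstruct the original object.  Floats are
    written with 17 significant digits and round-trip exactly.
    """
    kind = getattr(table, "KIND", None)
    if kind is None or kind not in _RESULT_REGISTRY:
        raise FormatError(f"object of type {type(table).__name__} is not a writable result")
    df = table.to_frame()
    buf = io.StringIO()
    buf.write(f"#vnnsurv\t{kind}\n")
    df.to_csv(buf, sep="\t", index=False, float_format=_FLOAT_FMT)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def read_results(path):
    """Read back a file written by :func:`write_results`."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 2 or header[0] != "#vnnsurv":
            raise FormatError(f"{path} is not a vnnsurv result file")
        kind = header[1]
        if kind not in _RESULT_REGISTRY:
            raise FormatError(f"unknown result kind {kind!r} in {path}")
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    return _RESULT_REGISTRY[kind].from_frame(df)
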