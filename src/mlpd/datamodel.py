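"""Containers and I/O for multi-source feature tables with block-wise missingness.

A *source* is a named block of feature columns (e.g. a panel of MRI ROI
volumes, or PET ROI intensities).  Missingness is block-wise: for any subject
a source is either fully observed or fully absent.  Subjects that share the
same set of observed sources (an *availability pattern*) form a *task*; each
task is a complete two-class data matrix over the union of its pattern's
feature columns.  Task decomposition is the entry point of the multi-task
discriminant machinery: one classifier is trained per pattern, jointly.

Conventions
-----------
* labels are coded +1 (positive class, e.g. progressive MCI) and -1
  (negative class, e.g. stable MCI);
* missing values are NaN in memory, empty cells or the literal ``NA`` on disk;
* task ids are 1-based and deterministic: patterns are ordered by descending
  number of sources, ties broken lexicographically by the sorted source names.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import BlockConsistencyError, MLPDError, NoTrainableTaskError

__all__ = [
    "MultiSourceDataset",
    "TaskDataset",
    "SharedFeatureSet",
    "read_feature_table",
    "write_feature_table",
    "read_schema",
    "write_schema",
    "decompose_tasks",
    "shared_feature_set",
    "reorder_shared_first",
    "restrict_sources",
    "complete_cases",
]


@dataclass
class MultiSourceDataset:
    """Labeled subjects x features table with named source blocks.

    Parameters
    ----------
    subject_ids
        Opaque per-subject identifiers (unique).
    labels
        Integer vector in {+1, -1}.
    sources
        Ordered list of ``(source_name, feature_names)``; the concatenation
        of all feature name lists indexes the columns of ``values``.
    values
        ``(n_subjects, n_features)`` float array, NaN where a block is absent.
    availability
        ``(n_subjects, n_sources)`` boolean mask.
    """

    subject_ids: list
    labels: np.ndarray
    sources: list
    values: np.ndarray
    availability: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.availability = np.asarray(self.availability, dtype=bool)
        self.validate()

    # ---- derived views -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def source_names(self) -> list:
        return [name for name, _ in self.sources]

    @property
    def feature_names(self) -> list:
        return [f for _, cols in self.sources for f in cols]

    def source_columns(self, name: str) -> np.ndarray:
        """Global column indices belonging to one source."""
        start = 0
        for sname, cols in self.sources:
            if sname == name:
                return np.arange(start, start + len(cols))
            start += len(cols)
        raise KeyError(name)

    def pattern_of(self, row: int) -> frozenset:
        """Availability pattern (set of observed source names) of a subject."""
        return frozenset(
            name for j, name in enumerate(self.source_names) if self.availability[row, j]
        )

    def validate(self) -> None:
        n, p = self.values.shape
        names = self.feature_names
        if len(names) != p:
            raise MLPDError("schema feature count does not match value columns")
        if len(set(names)) != len(names):
            raise MLPDError("feature names must be unique across sources")
        if len(self.subject_ids) != n or self.labels.shape != (n,):
            raise MLPDError("subject ids / labels / values dimensions disagree")
        if self.availability.shape != (n, len(self.sources)):
            raise MLPDError("availability mask has wrong shape")
        if not np.all(np.isin(self.labels, (-1, 1))):
            raise MLPDError("labels must be coded +1 / -1")
        if not self.availability.any(axis=1).all():
            bad = [self.subject_ids[i] for i in np.flatnonzero(~self.availability.any(axis=1))]
            raise MLPDError(f"subjects with no available source: {bad[:5]}")
        # mask consistency: a block is fully present or fully NaN
        for j, name in enumerate(self.source_names):
            cols = self.source_columns(name)
            block_nan = np.isnan(self.values[:, cols])
            present = ~block_nan.any(axis=1)
            absent = block_nan.all(axis=1)
            if not np.all(present | absent):
                bad = np.flatnonzero(~(present | absent))
                raise BlockConsistencyError(
                    f"source {name!r}: partially missing block for subjects "
                    f"{[self.subject_ids[i] for i in bad[:5]]}"
                )
            if not np.array_equal(present, self.availability[:, j]):
                raise MLPDError(f"availability mask inconsistent with NaN pattern of {name!r}")

    # ---- subsetting ----------------------------------------------------
    def subset(self, rows) -> "MultiSourceDataset":
        """Dataset restricted to the given row indices (order preserved)."""
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return MultiSourceDataset(
            subject_ids=[self.subject_ids[i] for i in rows],
            labels=self.labels[rows],
            sources=[(n, list(c)) for n, c in self.sources],
            values=self.values[rows].copy(),
            availability=self.availability[rows].copy(),
        )

    def subset_by_id(self, ids) -> "MultiSourceDataset":
        index = {s: i for i, s in enumerate(self.subject_ids)}
        return self.subset([index[s] for s in ids])

    def to_frame(self, id_column: str = "subject_id", label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, label_column, self.labels)
        df.insert(0, id_column, self.subject_ids)
        return df


@dataclass
class TaskDataset:
    """One availability pattern's subjects, split by class, fully observed.

    ``global_index`` maps local feature positions to global feature ids of
    the parent dataset, so discriminant vectors fitted per task can be
    interpreted against the original columns.
    """

    task_id: int
    pattern: frozenset
    X1: np.ndarray  # class +1 subjects, (n1, p)
    X2: np.ndarray  # class -1 subjects, (n2, p)
    global_index: np.ndarray
    ids1: list = field(default_factory=list)
    ids2: list = field(default_factory=list)

    def __post_init__(self):
        self.X1 = np.atleast_2d(np.asarray(self.X1, dtype=float))
        self.X2 = np.atleast_2d(np.asarray(self.X2, dtype=float))
        self.global_index = np.asarray(self.global_index, dtype=int)
        if self.X1.shape[0] < 1 or self.X2.shape[0] < 1:
            raise MLPDError("each class of a task needs at least one subject")
        if self.X1.shape[1] != self.X2.shape[1] or self.X1.shape[1] != len(self.global_index):
            raise MLPDError("task matrices / feature index dimensions disagree")
        if np.isnan(self.X1).any() or np.isnan(self.X2).any():
            raise MLPDError("task matrices must be complete")
        if len(set(self.global_index.tolist())) != len(self.global_index):
            raise MLPDError("global feature index must be injective")

    @property
    def n1(self) -> int:
        return self.X1.shape[0]

    @property
    def n2(self) -> int:
        return self.X2.shape[0]

    @property
    def p(self) -> int:
        return self.X1.shape[1]

    def restrict_features(self, kept_local) -> "TaskDataset":
        """Task with columns restricted to the given local positions."""
        kept = np.asarray(kept_local, dtype=int)
        return replace(
            self,
            X1=self.X1[:, kept],
            X2=self.X2[:, kept],
            global_index=self.global_index[kept],
        )


@dataclass
class SharedFeatureSet:
    """Features common to a pair of tasks, as aligned local position pairs."""

    task_pair: tuple
    pairs: list  # [(local position in task i, local position in task j), ...]

    @property
    def m(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_NA_STRINGS = ["", "NA"]


def read_feature_table(
    path,
    schema: dict,
    label_column: str,
    *,
    id_column: str | None = None,
    positive_label=None,
    coerce_partial_blocks: bool = False,
    sep: str | None = None,
) -> MultiSourceDataset:
    """Read a subjects x features CSV/TSV into a :class:`MultiSourceDataset`.

    ``schema`` maps source names to ordered lists of feature column names.
    Labels already coded +1/-1 are taken as-is; any other two-level coding
    requires an explicit ``positive_label``.  A subject with some but not all
    entries of a block missing is rejected unless ``coerce_partial_blocks``
    is set, in which case the whole block is treated as absent.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, na_values=_NA_STRINGS, keep_default_na=False)

    missing_cols = [c for cols in schema.values() for c in cols if c not in df.columns]
    if missing_cols:
        raise MLPDError(f"schema columns absent from table: {missing_cols[:5]}")
    if label_column not in df.columns:
        raise MLPDError(f"label column {label_column!r} absent from table")

    subject_ids = (
        df[id_column].astype(str).tolist() if id_column else [str(i) for i in range(len(df))]
    )
    labels = _coerce_labels(df[label_column], positive_label)

    sources = [(name, list(cols)) for name, cols in schema.items()]
    all_cols = [c for _, cols in sources for c in cols]
    values = df[all_cols].to_numpy(dtype=float)

    n = len(df)
    availability = np.zeros((n, len(sources)), dtype=bool)
    start = 0
    for j, (name, cols) in enumerate(sources):
        block = values[:, start : start + len(cols)]
        nan = np.isnan(block)
        present = ~nan.any(axis=1)
        absent = nan.all(axis=1)
        mixed = ~(present | absent)
        if mixed.any():
            if not coerce_partial_blocks:
                bad = [subject_ids[i] for i in np.flatnonzero(mixed)[:5]]
                raise BlockConsistencyError(
                    f"source {name!r}: block partially missing for subjects {bad}; "
                    "set coerce_partial_blocks=True to treat such blocks as absent"
                )
            block[mixed] = np.nan
            present = present & ~mixed
        availability[:, j] = present
        start += len(cols)

    return MultiSourceDataset(subject_ids, labels, sources, values, availability)


def _coerce_labels(col: pd.Series, positive_label) -> np.ndarray:
    levels = pd.unique(col.dropna())
    if len(levels) > 2:
        raise MLPDError(f"label column has {len(levels)} levels; exactly 2 expected")
    if col.isna().any():
        raise MLPDError("missing labels are not allowed")
    if positive_label is None:
        try:
            vals = col.astype(float).to_numpy()
        except (TypeError, ValueError):
            raise MLPDError(
                "non-numeric label coding requires an explicit positive_label"
            ) from None
        if not np.all(np.isin(vals, (-1.0, 1.0))):
            raise MLPDError(
                f"unknown label codes {sorted(set(vals.tolist()))}; expected +1/-1 "
                "or an explicit positive_label"
            )
        return vals.astype(int)
    pos = col == positive_label
    if not pos.any():
        raise MLPDError(f"positive label {positive_label!r} not found in label column")
    return np.where(pos, 1, -1)


def write_feature_table(
    ds: MultiSourceDataset,
    path,
    *,
    id_column: str = "subject_id",
    label_column: str = "label",
) -> None:
    """Write the dataset back to CSV/TSV (absent blocks become empty cells)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    ds.to_frame(id_column, label_column).to_csv(path, sep=sep, index=False, na_rep="")


def write_schema(ds: MultiSourceDataset, path, *, id_column="subject_id", label_column="label"):
    """Write the companion YAML schema (source -> columns, label coding)."""
    doc = {
        "id_column": id_column,
        "label_column": label_column,
        "positive_label": 1,
        "sources": {name: list(cols) for name, cols in ds.sources},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_schema(path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    if "sources" not in doc:
        raise MLPDError("schema file must define a 'sources' mapping")
    return doc


# ---------------------------------------------------------------------------
# Task decomposition and shared-feature bookkeeping
# ---------------------------------------------------------------------------


def decompose_tasks(ds: MultiSourceDataset, min_per_class: int = 2) -> list:
    """Split the dataset into one complete :class:`TaskDataset` per pattern.

    Only patterns with at least ``min_per_class`` subjects in each class are
    retained (the pooled covariance needs centered vectors in both classes).
    Task ids are assigned deterministically: descending number of sources,
    ties lexicographic on sorted source names.
    """
    if min_per_class < 1:
        raise ValueError("min_per_class must be >= 1")
    groups: dict = {}
    for i in range(ds.n_subjects):
        groups.setdefault(ds.pattern_of(i), []).append(i)

    ordered = sorted(groups, key=lambda pat: (-len(pat), tuple(sorted(pat))))
    tasks = []
    tid = 0
    for pat in ordered:
        rows = np.array(groups[pat])
        pos = rows[ds.labels[rows] == 1]
        neg = rows[ds.labels[rows] == -1]
        if len(pos) < min_per_class or len(neg) < min_per_class:
            continue
        cols = np.concatenate(
            [ds.source_columns(name) for name in ds.source_names if name in pat]
        )
        tid += 1
        tasks.append(
            TaskDataset(
                task_id=tid,
                pattern=pat,
                X1=ds.values[np.ix_(pos, cols)],
                X2=ds.values[np.ix_(neg, cols)],
                global_index=cols,
                ids1=[ds.subject_ids[i] for i in pos],
                ids2=[ds.subject_ids[i] for i in neg],
            )
        )
    if not tasks:
        raise NoTrainableTaskError(
            f"no availability pattern has >= {min_per_class} subjects per class"
        )
    return tasks


def shared_feature_set(t_i: TaskDataset, t_j: TaskDataset) -> SharedFeatureSet:
    """Enumerate features present in both tasks, in global feature order."""
    loc_i = {g: l for l, g in enumerate(t_i.global_index.tolist())}
    loc_j = {g: l for l, g in enumerate(t_j.global_index.tolist())}
    common = sorted(set(loc_i) & set(loc_j))
    pairs = [(loc_i[g], loc_j[g]) for g in common]
    return SharedFeatureSet(task_pair=(t_i.task_id, t_j.task_id), pairs=pairs)


def reorder_shared_first(t_i: TaskDataset, t_j: TaskDataset, s: SharedFeatureSet):
    """Permute both tasks' columns so shared features come first, aligned.

    Returns new tasks plus the updated shared set, whose pairs become
    ``(0,0)..(m-1,m-1)``.  Any fit is invariant to this permutation (it is a
    relabeling of coordinates); it exists to make the joint LP's structure
    match the conventional "common features first" layout.
    """
    perm_i = [a for a, _ in s.pairs] + [
        l for l in range(t_i.p) if l not in {a for a, _ in s.pairs}
    ]
    perm_j = [b for _, b in s.pairs] + [
        l for l in range(t_j.p) if l not in {b for _, b in s.pairs}
    ]
    new_i = t_i.restrict_features(perm_i)
    new_j = t_j.restrict_features(perm_j)
    new_s = SharedFeatureSet(task_pair=s.task_pair, pairs=[(k, k) for k in range(s.m)])
    return new_i, new_j, new_s


# ---------------------------------------------------------------------------
# Comparison-arm helpers
# ---------------------------------------------------------------------------


def restrict_sources(ds: MultiSourceDataset, names) -> MultiSourceDataset:
    """Drop all sources not named; subjects lacking every kept source are dropped."""
    names = list(names)
    keep_cols = np.concatenate([ds.source_columns(n) for n in names])
    src_idx = [ds.source_names.index(n) for n in names]
    avail = ds.availability[:, src_idx]
    rows = np.flatnonzero(avail.any(axis=1))
    return MultiSourceDataset(
        subject_ids=[ds.subject_ids[i] for i in rows],
        labels=ds.labels[rows],
        sources=[(n, list(c)) for n, c in ds.sources if n in names],
        values=ds.values[np.ix_(rows, keep_cols)],
        availability=avail[rows],
    )


def complete_cases(ds: MultiSourceDataset) -> MultiSourceDataset:
    """Keep only subjects with every source observed."""
    rows = np.flatnonzero(ds.availability.all(axis=1))
    if len(rows) == 0:
        raise MLPDError("no subject has all sources observed")
    return ds.subset(rows)
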