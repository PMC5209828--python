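"""Temporal gene-expression dataset container, text I/O and preprocessing.

The central object is :class:`TemporalDataset`: an ``N x G x T`` expression
tensor (subjects x genes x time steps) with one class label per subject.
Datasets are exchanged as plain delimited text, either long format
(``subject_id,gene_id,time_index,value``) or one wide matrix per time step
listed in a manifest.  Preprocessing follows the usual pipeline for temporal
expression studies: per-trajectory linear interpolation of missing values,
then per-gene min-max normalization to [0, 1].
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TemporalDataset",
    "FlattenedDataset",
    "GeneTrajectoryMatrix",
    "FormatError",
    "ConsistencyError",
    "ImputationError",
    "read_temporal_dataset",
    "write_temporal_dataset",
    "read_labels",
    "impute_linear",
    "minmax_normalize",
    "flatten",
]


class FormatError(ValueError):
    """Malformed input file (duplicate triples, bad header, non-numeric value)."""


class ConsistencyError(ValueError):
    """Expression and label files disagree (e.g. unlabeled subject)."""


class ImputationError(ValueError):
    """A (subject, gene) trajectory has no observed value at all."""


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


@dataclass(frozen=True)
class GeneTrajectoryMatrix:
    """One gene's ``N x T`` matrix of per-subject trajectories."""

    values: np.ndarray
    gene_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("trajectory matrix must be 2-D (subjects x time)")
        object.__setattr__(self, "values", v)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class TemporalDataset:
    """Expression tensor indexed (subject, gene, time) plus per-subject labels.

    ``labels`` are dense integers ``1..K`` in first-appearance order of the
    original label strings, which are preserved in ``label_names``.
    Missing cells are NaN until :func:`impute_linear` runs.
    """

    expression: np.ndarray
    labels: np.ndarray
    gene_ids: tuple[str, ...]
    subject_ids: tuple[str, ...]
    time_index: np.ndarray
    label_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        expr = np.asarray(self.expression, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        time_index = np.asarray(self.time_index, dtype=float)
        object.__setattr__(self, "expression", expr)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "time_index", time_index)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "label_names", tuple(self.label_names))
        n, g, t = expr.shape
        if n < 2 or g < 1 or t < 1:
            raise ValueError(f"need N>=2, G>=1, T>=1; got shape {expr.shape}")
        if len(self.subject_ids) != n or len(self.gene_ids) != g:
            raise ValueError("id lists do not match tensor shape")
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject_ids")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene_ids")
        if labels.shape != (n,):
            raise ValueError("labels must have one entry per subject")
        k = labels.max(initial=0)
        if k < 2 or set(np.unique(labels)) != set(range(1, k + 1)):
            raise ValueError("labels must cover 1..K with K>=2, every class non-empty")
        if time_index.shape != (t,) or np.any(np.diff(time_index) <= 0):
            raise ValueError("time_index must be strictly increasing, length T")

    @property
    def n_subjects(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def n_times(self) -> int:
        return self.expression.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max())

    def has_missing(self) -> bool:
        return bool(np.isnan(self.expression).any())

    def gene(self, j: int) -> GeneTrajectoryMatrix:
        """The j-th gene's ``N x T`` trajectory matrix."""
        return GeneTrajectoryMatrix(self.expression[:, j, :], self.gene_ids[j])

    def subset_subjects(self, idx: Sequence[int]) -> "TemporalDataset":
        idx = np.asarray(idx, dtype=int)
        labels = self.labels[idx]
        # re-densify labels so every class 1..K is present in the subset
        uniq = sorted(set(labels.tolist()))
        remap = {old: new for new, old in enumerate(uniq, start=1)}
        names = tuple(self.label_names[o - 1] for o in uniq) if self.label_names else ()
        return replace(
            self,
            expression=self.expression[idx],
            labels=np.array([remap[v] for v in labels]),
            subject_ids=tuple(self.subject_ids[i] for i in idx),
            label_names=names,
        )

    def subset_times(self, idx: Sequence[int]) -> "TemporalDataset":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            expression=self.expression[:, :, idx],
            time_index=self.time_index[idx],
        )


@dataclass(frozen=True)
class FlattenedDataset:
    """``N x (G*T)`` matrix in gene-major column order, for the classical baseline."""

    matrix: np.ndarray
    column_ids: tuple[tuple[str, float], ...]
    labels: np.ndarray


def read_labels(path_labels: str | Path) -> dict[str, str]:
    path_labels = Path(path_labels)
    delim = _sniff_delimiter(path_labels)
    out: dict[str, str] = {}
    with open(path_labels, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["subject_id", "label"]:
            raise FormatError(f"{path_labels}: expected header 'subject_id,label'")
        for row in reader:
            if not row:
                continue
            sid, lab = row[0].strip(), row[1].strip()
            if sid in out and out[sid] != lab:
                raise ConsistencyError(f"subject {sid!r} has conflicting labels")
            out[sid] = lab
    return out


def _densify_labels(
    subject_ids: Sequence[str], label_map: dict[str, str]
) -> tuple[np.ndarray, tuple[str, ...]]:
    missing = [s for s in subject_ids if s not in label_map]
    if missing:
        raise ConsistencyError(f"subjects without label: {missing}")
    names: list[str] = []
    dense = []
    for s in subject_ids:
        lab = label_map[s]
        if lab not in names:
            names.append(lab)
        dense.append(names.index(lab) + 1)
    return np.array(dense, dtype=int), tuple(names)


def _read_long(path: Path) -> pd.DataFrame:
    delim = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim, dtype={"subject_id": str, "gene_id": str})
    required = ["subject_id", "gene_id", "time_index", "value"]
    if list(df.columns[:4]) != required:
        raise FormatError(f"{path}: expected header {','.join(required)}")
    for col in ("time_index", "value"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric {col}: {exc}") from exc
    if df.duplicated(["subject_id", "gene_id", "time_index"]).any():
        dup = df[df.duplicated(["subject_id", "gene_id", "time_index"])].iloc[0]
        raise FormatError(
            f"{path}: duplicate triple "
            f"({dup.subject_id}, {dup.gene_id}, {dup.time_index})"
        )
    return df


def read_temporal_dataset(
    path_expression: str | Path,
    path_labels: str | Path,
    format: str = "long",
) -> TemporalDataset:
    """Read a temporal dataset from delimited text.

    ``format='long'`` expects columns ``subject_id,gene_id,time_index,value``;
    absent (subject, gene, time) triples become NaN cells.  ``format=
    'wide_per_time'`` expects a manifest with header ``time_index,path``
    naming one subjects-by-genes matrix file per time step.
    """
    path_expression = Path(path_expression)
    if format == "long":
        df = _read_long(path_expression)
        subjects = tuple(dict.fromkeys(df["subject_id"]))
        genes = tuple(dict.fromkeys(df["gene_id"]))
        times = np.array(sorted(df["time_index"].unique()), dtype=float)
        s_pos = {s: i for i, s in enumerate(subjects)}
        g_pos = {g: i for i, g in enumerate(genes)}
        t_pos = {t: i for i, t in enumerate(times)}
        expr = np.full((len(subjects), len(genes), len(times)), np.nan)
        si = df["subject_id"].map(s_pos).to_numpy()
        gi = df["gene_id"].map(g_pos).to_numpy()
        ti = df["time_index"].map(t_pos).to_numpy()
        expr[si, gi, ti] = df["value"].to_numpy(dtype=float)
    elif format == "wide_per_time":
        delim = _sniff_delimiter(path_expression)
        manifest = pd.read_csv(path_expression, sep=delim)
        if list(manifest.columns[:2]) != ["time_index", "path"]:
            raise FormatError(f"{path_expression}: expected header 'time_index,path'")
        manifest = manifest.sort_values("time_index")
        times = manifest["time_index"].to_numpy(dtype=float)
        slabs = []
        subjects = genes = None
        for p in manifest["path"]:
            fp = Path(p)
            if not fp.is_absolute():
                fp = path_expression.parent / fp
            wide = pd.read_csv(fp, sep=_sniff_delimiter(fp), index_col=0)
            if subjects is None:
                subjects = tuple(str(s) for s in wide.index)
                genes = tuple(str(g) for g in wide.columns)
            elif tuple(str(s) for s in wide.index) != subjects or tuple(
                str(g) for g in wide.columns
            ) != genes:
                raise ConsistencyError(f"{fp}: subject/gene layout differs across time files")
            slabs.append(wide.to_numpy(dtype=float))
        expr = np.stack(slabs, axis=-1)[:, :, :]
        expr = expr.reshape(len(subjects), len(genes), len(times))
    else:
        raise ValueError(f"unknown format {format!r}")

    labels, names = _densify_labels(subjects, read_labels(path_labels))
    return TemporalDataset(expr, labels, genes, subjects, times, names)


def write_temporal_dataset(
    ds: TemporalDataset, path_expression: str | Path, path_labels: str | Path | None = None
) -> None:
    """Write long-format expression (sorted by subject, gene, time) and labels."""
    rows = []
    for p, sid in enumerate(ds.subject_ids):
        for j, gid in enumerate(ds.gene_ids):
            for t, ti in enumerate(ds.time_index):
                v = ds.expression[p, j, t]
                if not np.isnan(v):
                    rows.append((sid, gid, ti, v))
    df = pd.DataFrame(rows, columns=["subject_id", "gene_id", "time_index", "value"])
    df["time_index"] = [int(t) if float(t).is_integer() else t for t in df["time_index"]]
    df.to_csv(path_expression, index=False)
    if path_labels is not None:
        names = ds.label_names or tuple(str(k) for k in range(1, ds.n_classes + 1))
        lab = pd.DataFrame(
            {"subject_id": ds.subject_ids, "label": [names[c - 1] for c in ds.labels]}
        )
        lab.to_csv(path_labels, index=False)


def impute_linear(ds: TemporalDataset) -> TemporalDataset:
    """Fill missing cells per (subject, gene) trajectory.

    Interior gaps are linearly interpolated against the numeric time index
    (so uneven sampling is honored); leading/trailing gaps take the nearest
    observed value.  Observed values are untouched; idempotent.
    """
    expr = ds.expression.copy()
    t = ds.time_index
    nan_mask = np.isnan(expr)
    if not nan_mask.any():
        return replace(ds, expression=expr)
    if nan_mask.all(axis=2).any():
        p, j = np.argwhere(nan_mask.all(axis=2))[0]
        raise ImputationError(
            f"subject {ds.subject_ids[p]!r}, gene {ds.gene_ids[j]!r}: "
            "no observed time point"
        )
    for p, j in zip(*np.nonzero(nan_mask.any(axis=2))):
        y = expr[p, j]
        obs = ~np.isnan(y)
        # np.interp clamps to edge values outside the observed range,
        # which is exactly the nearest-observed extrapolation rule
        expr[p, j] = np.interp(t, t[obs], y[obs])
    return replace(ds, expression=expr)


def minmax_normalize(
    ds: TemporalDataset, bounds: np.ndarray | None = None
) -> TemporalDataset:
    """Scale each gene to [0, 1] over all its N*T values.

    A constant gene maps to all zeros.  ``bounds`` (a ``G x 2`` array of
    per-gene min/max, e.g. computed on training subjects only) overrides the
    dataset's own range; values outside are clipped to [0, 1].
    """
    if ds.has_missing():
        raise ValueError("impute missing values before normalization")
    expr = ds.expression
    if bounds is None:
        lo = expr.min(axis=(0, 2))
        hi = expr.max(axis=(0, 2))
    else:
        lo, hi = np.asarray(bounds, dtype=float).T
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    out = (expr - lo[None, :, None]) / safe[None, :, None]
    out = np.where((span > 0)[None, :, None], out, 0.0)
    return replace(ds, expression=np.clip(out, 0.0, 1.0))


def gene_bounds(ds: TemporalDataset) -> np.ndarray:
    """Per-gene (min, max) over all subjects and time steps, as a ``G x 2`` array."""
    return np.stack(
        [ds.expression.min(axis=(0, 2)), ds.expression.max(axis=(0, 2))], axis=1
    )


def flatten(ds: TemporalDataset) -> FlattenedDataset:
    """Concatenate each subject's per-gene trajectories into one wide row.

    Column order is gene-major: all T time steps of gene 1, then gene 2, ...
    This is the flattening the classical mRMR baseline consumes; it discards
    the grouping of columns into trajectories but loses no values.
    """
    if ds.has_missing():
        raise ValueError("impute missing values before flattening")
    n, g, t = ds.expression.shape
    matrix = ds.expression.reshape(n, g * t).copy()
    cols = tuple(
        (gid, float(ti)) for gid in ds.gene_ids for ti in ds.time_index
    )
    return FlattenedDataset(matrix, cols, ds.labels.copy())


def unflatten(flat: FlattenedDataset, ds: TemporalDataset) -> np.ndarray:
    """Regroup a flattened matrix back into the (N, G, T) tensor layout."""
    n = flat.matrix.shape[0]
    return flat.matrix.reshape(n, ds.n_genes, ds.n_times)
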