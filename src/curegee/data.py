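"""Data containers and delimited-file I/O for clustered right-censored survival data.

A :class:`ClusteredDataset` holds one record per subject: a cluster label,
the observed follow-up time ``T``, the event indicator ``delta`` (1 = failure
observed, 0 = censored), a matrix ``Z`` of incidence covariates (no intercept
column; the intercept is added at fit time) and a matrix ``X`` of latency
covariates (the AFT latency model carries no intercept at all -- the location
of the error distribution absorbs it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClusteredDataset",
    "FitControl",
    "read_clustered_survival",
    "write_clustered_survival",
]


class SchemaError(ValueError):
    """A required column is absent from the input table."""


class ValidationError(ValueError):
    """A record violates a dataset invariant (non-positive time, bad event code, NaN)."""


@dataclass
class ClusteredDataset:
    """Clustered right-censored survival data, one row per subject.

    Subjects keep their input order.  Cluster indices are assigned by first
    appearance of each cluster label, so all downstream bookkeeping is
    deterministic under relabeling.
    """

    cluster_id: np.ndarray  # shape (N,), arbitrary labels
    time: np.ndarray        # shape (N,), strictly positive
    event: np.ndarray       # shape (N,), values in {0, 1}
    Z: np.ndarray           # shape (N, pZ) incidence covariates (no intercept)
    X: np.ndarray           # shape (N, pX) latency covariates (no intercept)
    z_names: Sequence[str] = field(default_factory=list)
    x_names: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cluster_id = np.asarray(self.cluster_id)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.Z.shape[0] != self.n_subjects and self.Z.size:
            self.Z = self.Z.reshape(self.n_subjects, -1)
        if self.X.shape[0] != self.n_subjects and self.X.size:
            self.X = self.X.reshape(self.n_subjects, -1)
        if not self.z_names:
            self.z_names = [f"z{j}" for j in range(self.Z.shape[1])]
        if not self.x_names:
            self.x_names = [f"x{j}" for j in range(self.X.shape[1])]
        self._validate()
        # cluster index by first appearance
        labels, idx = np.unique(self.cluster_id, return_index=True)
        order = np.argsort(idx, kind="stable")
        self.cluster_labels = labels[order]
        label_to_pos = {lab: k for k, lab in enumerate(self.cluster_labels)}
        self.cluster_index = np.array([label_to_pos[lab] for lab in self.cluster_id])
        self.cluster_sizes = np.bincount(self.cluster_index, minlength=len(self.cluster_labels))

    # -- basic shape accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.time)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_labels)

    @property
    def p_z(self) -> int:
        return self.Z.shape[1]

    @property
    def p_x(self) -> int:
        return self.X.shape[1]

    def _validate(self) -> None:
        n = self.n_subjects
        for name, arr in (("cluster", self.cluster_id), ("event", self.event)):
            if len(arr) != n:
                raise ValidationError(f"column '{name}' has length {len(arr)}, expected {n}")
        for name, arr in (("Z", self.Z), ("X", self.X)):
            if arr.shape[0] != n:
                raise ValidationError(f"covariate block '{name}' has {arr.shape[0]} rows, expected {n}")
        bad = np.where(~np.isfinite(self.time) | (self.time <= 0))[0]
        if bad.size:
            raise ValidationError(f"non-positive or missing time at row {bad[0]} (value {self.time[bad[0]]!r})")
        ev = np.asarray(self.event, dtype=float)
        bad = np.where(~np.isin(ev, (0.0, 1.0)))[0]
        if bad.size:
            raise ValidationError(f"event indicator not in {{0,1}} at row {bad[0]} (value {self.event[bad[0]]!r})")
        self.event = ev.astype(int)
        for name, arr in (("Z", self.Z), ("X", self.X)):
            bad = np.where(~np.isfinite(arr))
            if bad[0].size:
                raise ValidationError(f"missing/non-finite {name} covariate at row {bad[0][0]}")

    def clusters(self) -> list[np.ndarray]:
        """Subject row indices of each cluster, in first-appearance order."""
        order = np.argsort(self.cluster_index, kind="stable")
        splits = np.cumsum(self.cluster_sizes)[:-1]
        return np.split(order, splits)

    def size_groups(self) -> dict[int, np.ndarray]:
        """Group clusters by size for batched linear algebra.

        Returns a mapping ``size -> (n_clusters_of_that_size, size)`` array of
        subject row indices, preserving within-cluster input order.
        """
        groups: dict[int, list[np.ndarray]] = {}
        for rows in self.clusters():
            groups.setdefault(len(rows), []).append(rows)
        return {sz: np.vstack(v) for sz, v in groups.items()}

    def subset_clusters(self, cluster_positions: Sequence[int]) -> "ClusteredDataset":
        """New dataset made of the given clusters (positions into
        ``cluster_labels``), relabeled ``0..len-1`` so duplicates are distinct."""
        rows_by_cluster = self.clusters()
        parts, labels = [], []
        for new_lab, pos in enumerate(cluster_positions):
            rows = rows_by_cluster[pos]
            parts.append(rows)
            labels.append(np.full(len(rows), new_lab))
        rows = np.concatenate(parts)
        return ClusteredDataset(
            cluster_id=np.concatenate(labels),
            time=self.time[rows],
            event=self.event[rows],
            Z=self.Z[rows],
            X=self.X[rows],
            z_names=list(self.z_names),
            x_names=list(self.x_names),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cluster": self.cluster_id, "time": self.time, "status": self.event})
        for j, name in enumerate(self.z_names):
            df[name] = self.Z[:, j]
        for j, name in enumerate(self.x_names):
            if name not in df.columns:
                df[name] = self.X[:, j]
        return df


@dataclass
class FitControl:
    """Convergence control for the EM/GEE fit.

    ``em_tol`` is the threshold on the sum of squared differences of the
    concatenated (gamma, beta) vector between consecutive EM iterations
    (default 1e-4).  The inner correlation/GEE loop iterates to ``inner_tol``.
    """

    em_tol: float = 1e-4
    max_em_iter: int = 100
    max_inner_iter: int = 20
    inner_tol: float = 1e-6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.em_tol <= 0 or self.inner_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_em_iter < 1 or self.max_inner_iter < 1:
            raise ValueError("iteration caps must be positive integers")


_DEFAULT_MAP = {"cluster": "cluster", "time": "time", "event": "status"}


def read_clustered_survival(
    path,
    column_map: Mapping[str, object] | None = None,
    sep: str = ",",
) -> ClusteredDataset:
    """Read a delimited table of clustered survival records.

    ``column_map`` may override the column names: keys ``cluster``, ``time``,
    ``event`` (scalars) and ``Z``, ``X`` (lists of covariate column names).
    By default every non-core column is used as both an incidence and a
    latency covariate.
    """
    cmap = dict(_DEFAULT_MAP)
    zcols = xcols = None
    if column_map:
        for key in ("cluster", "time", "event"):
            if key in column_map:
                cmap[key] = column_map[key]
        zcols = column_map.get("Z")
        xcols = column_map.get("X")
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for key in ("cluster", "time", "event"):
        if cmap[key] not in df.columns:
            raise SchemaError(f"required column '{cmap[key]}' (role: {key}) not found in {path}")
    core = {cmap["cluster"], cmap["time"], cmap["event"]}
    if zcols is None:
        zcols = [c for c in df.columns if c not in core]
    if xcols is None:
        xcols = [c for c in df.columns if c not in core]
    for c in list(zcols) + list(xcols):
        if c not in df.columns:
            raise SchemaError(f"covariate column '{c}' not found in {path}")
    return ClusteredDataset(
        cluster_id=df[cmap["cluster"]].to_numpy(),
        time=df[cmap["time"]].to_numpy(dtype=float),
        event=df[cmap["event"]].to_numpy(),
        Z=df[list(zcols)].to_numpy(dtype=float),
        X=df[list(xcols)].to_numpy(dtype=float),
        z_names=list(zcols),
        x_names=list(xcols),
    )


def write_clustered_survival(dataset: ClusteredDataset, path, sep: str = ",") -> None:
    """Write a dataset as delimited text, losslessly round-trippable by
    :func:`read_clustered_survival` (floats at 17 significant digits)."""
    df = dataset.to_frame()
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
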