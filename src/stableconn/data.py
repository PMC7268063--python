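"""Data model and I/O for connectome feature matrices and trait tables.

A subject's resting-state functional connectome is a symmetric node x node
matrix of edge weights (Fisher-z transformed correlations when sourced from
Pearson connectivity).  Internally every dataset is a dense
``(n_subjects, n_edges)`` matrix whose columns enumerate the strict upper
triangle of that matrix in row-major order: (0,1), (0,2), ..., (0,n-1),
(1,2), ...  All feature indices reported anywhere in the package refer to
this single ordering.

Edge tables follow the HCP "netmats" text dialect: one whitespace- or
comma-delimited row per subject, holding either the edge vector directly or
a flattened full n x n matrix.  Trait tables are CSV with a header row, the
first column being the subject ID; empty cells or "NA" mark missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectomeDataset",
    "ConnectomeFormatError",
    "vectorize_upper_triangle",
    "upper_triangle_index",
    "load_edge_table",
    "load_trait_table",
    "attach_traits",
    "fisher_z",
]


class ConnectomeFormatError(ValueError):
    """Malformed connectome or trait input."""


@dataclass
class ConnectomeDataset:
    """Subjects x edges feature matrix with aligned trait vectors.

    Parameters
    ----------
    subject_ids : list of str
        Opaque subject identifiers, one per feature-matrix row.
    features : ndarray of shape (n_subjects, n_edges)
        Edge weights; must be finite.
    n_nodes : int, optional
        Parcellation size.  Absent when rows arrived pre-vectorized with no
        declared parcellation.
    edge_index : ndarray of shape (n_edges, 2), optional
        (node_i, node_j) with i < j, row-major upper-triangle order.
    traits : dict of str -> ndarray
        Per-trait score vectors aligned with ``subject_ids``; NaN encodes a
        missing entry (missingness is allowed only here, never in
        ``features``).
    """

    subject_ids: list[str]
    features: np.ndarray
    n_nodes: int | None = None
    edge_index: np.ndarray | None = None
    traits: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ConnectomeFormatError("features must be 2-D (subjects x edges)")
        if len(self.subject_ids) != self.features.shape[0]:
            raise ConnectomeFormatError(
                f"{len(self.subject_ids)} subject ids for "
                f"{self.features.shape[0]} feature rows"
            )
        if not np.all(np.isfinite(self.features)):
            raise ConnectomeFormatError("features contain NaN/Inf")
        if self.n_nodes is not None:
            expect = self.n_nodes * (self.n_nodes - 1) // 2
            if self.features.shape[1] != expect:
                raise ConnectomeFormatError(
                    f"n_nodes={self.n_nodes} implies {expect} edges, "
                    f"got {self.features.shape[1]}"
                )
            if self.edge_index is None:
                self.edge_index = upper_triangle_index(self.n_nodes)
        for name, vec in self.traits.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.features.shape[0],):
                raise ConnectomeFormatError(
                    f"trait {name!r} has length {vec.shape}, "
                    f"expected ({self.features.shape[0]},)"
                )
            self.traits[name] = vec

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.features.shape[1]

    def trait_mask(self, name: str) -> np.ndarray:
        """Boolean mask of subjects with an observed (non-missing) value."""
        return np.isfinite(self.traits[name])

    def subset(self, idx: np.ndarray) -> "ConnectomeDataset":
        """New dataset restricted to the given subject indices (order kept)."""
        idx = np.asarray(idx)
        return replace(
            self,
            subject_ids=[self.subject_ids[i] for i in idx],
            features=self.features[idx],
            traits={k: v[idx] for k, v in self.traits.items()},
        )


def upper_triangle_index(n_nodes: int) -> np.ndarray:
    """(node_i, node_j) pairs of the strict upper triangle, row-major."""
    iu = np.triu_indices(n_nodes, k=1)
    return np.column_stack(iu)


def vectorize_upper_triangle(matrix: np.ndarray, *, tol: float = 1e-8) -> np.ndarray:
    """Strict-upper-triangle entries of a symmetric matrix, row-major.

    The diagonal is ignored (self-connections carry no information).
    Raises :class:`ConnectomeFormatError` naming the first offending node
    pair if the matrix is not square or not symmetric within ``tol``.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConnectomeFormatError(f"matrix is not square: shape {m.shape}")
    asym = np.abs(m - m.T)
    if np.any(asym > tol):
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ConnectomeFormatError(
            f"matrix not symmetric at ({i},{j}): {m[i, j]!r} vs {m[j, i]!r}"
        )
    return m[np.triu_indices(m.shape[0], k=1)]


def _read_numeric_rows(path: str | Path) -> np.ndarray:
    """Read a netmats-dialect table: one numeric row per subject."""
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            try:
                row = np.array([float(p) for p in parts])
            except ValueError as exc:
                raise ConnectomeFormatError(
                    f"{path}, line {lineno}: non-numeric entry ({exc})"
                ) from None
            if not np.all(np.isfinite(row)):
                raise ConnectomeFormatError(
                    f"{path}, line {lineno}: NaN/Inf entry"
                )
            if rows and row.size != rows[0].size:
                raise ConnectomeFormatError(
                    f"{path}, line {lineno}: ragged row "
                    f"({row.size} values, expected {rows[0].size})"
                )
            rows.append(row)
    if not rows:
        raise ConnectomeFormatError(f"{path}: no data rows")
    return np.vstack(rows)


def load_edge_table(
    path: str | Path,
    *,
    n_nodes: int | None = None,
    subject_ids: list[str] | None = None,
) -> ConnectomeDataset:
    """Load a netmats-dialect edge table into a :class:`ConnectomeDataset`.

    Row length is interpreted against ``n_nodes`` when declared: ``n**2``
    columns are taken as flattened full matrices (reshaped, symmetry-checked
    and reduced to the upper triangle), ``n*(n-1)/2`` columns as
    pre-vectorized edges.  Without ``n_nodes`` the rows are stored as-is and
    no edge index is attached.  Zero-variance columns are retained so that
    feature indices stay stable, but their count is logged.
    """
    data = _read_numeric_rows(path)
    n_sub, width = data.shape
    if n_nodes is not None:
        n_edges = n_nodes * (n_nodes - 1) // 2
        if width == n_nodes * n_nodes:
            feats = np.vstack(
                [vectorize_upper_triangle(row.reshape(n_nodes, n_nodes)) for row in data]
            )
        elif width == n_edges:
            feats = data
        else:
            raise ConnectomeFormatError(
                f"{path}: row length {width} matches neither "
                f"{n_nodes}^2={n_nodes**2} nor {n_nodes}({n_nodes}-1)/2={n_edges}"
            )
    else:
        feats = data
    if subject_ids is None:
        subject_ids = [f"sub-{i:04d}" for i in range(n_sub)]
    n_const = int(np.sum(feats.std(axis=0) == 0.0))
    if n_const:
        logger.info("%s: %d zero-variance edge column(s) retained", path, n_const)
    return ConnectomeDataset(subject_ids=list(subject_ids), features=feats, n_nodes=n_nodes)


def load_trait_table(path: str | Path) -> pd.DataFrame:
    """Trait CSV -> DataFrame indexed by subject ID; ""/"NA" become NaN."""
    df = pd.read_csv(path, na_values=["NA"], dtype={0: str})
    df = df.set_index(df.columns[0])
    return df.astype(float)


def attach_traits(
    dataset: ConnectomeDataset,
    trait_table: pd.DataFrame,
    trait_name: str,
) -> ConnectomeDataset:
    """Attach one trait, dropping subjects whose value is missing.

    Subjects absent from ``trait_table`` are treated as missing (dropped,
    with a warning).  Surviving subjects keep their input order.  The number
    dropped is logged; an error is raised if no subjects remain.
    """
    if trait_name not in trait_table.columns:
        raise KeyError(f"trait {trait_name!r} not in table columns {list(trait_table.columns)}")
    col = trait_table[trait_name]
    values = np.full(dataset.n_subjects, np.nan)
    n_absent = 0
    for i, sid in enumerate(dataset.subject_ids):
        if sid in col.index:
            values[i] = col.loc[sid]
        else:
            n_absent += 1
    if n_absent:
        logger.warning(
            "%d subject(s) absent from trait table; treated as missing", n_absent
        )
    keep = np.flatnonzero(np.isfinite(values))
    n_dropped = dataset.n_subjects - keep.size
    if keep.size == 0:
        raise ConnectomeFormatError(
            f"no subjects remain after excluding missing {trait_name!r}"
        )
    if n_dropped:
        logger.info(
            "trait %r: dropped %d/%d subject(s) with missing values",
            trait_name, n_dropped, dataset.n_subjects,
        )
    out = dataset.subset(keep)
    out.traits[trait_name] = values[keep]
    return out


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transform ``z = atanh(r)``, elementwise.

    Approximately Gaussianizes a Pearson correlation.  HCP netmats arrive
    already transformed; this is provided for users supplying raw
    correlation matrices.  Requires ``|r| < 1``.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out
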