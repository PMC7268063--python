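"""Spearman correlation screening of edges against a trait.

The baseline feature-selection method: every edge is rank-correlated with
the phenotype over the training subjects, and edges significant at a
two-sided level alpha (default .05) are split by correlation sign into
positive, negative and combined feature sets.  No multiplicity correction
is applied at this stage — the screen is a deliberately permissive filter
whose stability across resamples is assessed downstream.

P-values use the t approximation t = rho*sqrt((n-2)/(1-rho^2)) on n-2
degrees of freedom; at screening sample sizes (hundreds of subjects) this
is indistinguishable from the permutation distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EdgeScreenResult",
    "FeatureSets",
    "rank_columns",
    "spearman_rho",
    "spearman_pvalue",
    "spearman_rho_matrix",
    "screen",
    "critical_rho",
]


@dataclass
class EdgeScreenResult:
    """Per-edge Spearman statistics against one trait.

    rho is exactly 0 and pval exactly 1 for degenerate (zero-variance)
    edges, so constant columns can never enter a feature set.
    """

    rho: np.ndarray
    pval: np.ndarray
    alpha: float
    n: int

    def sign(self) -> np.ndarray:
        return np.sign(self.rho).astype(int)


@dataclass
class FeatureSets:
    """Index sets of significantly correlated edges, split by sign."""

    positive: np.ndarray
    negative: np.ndarray

    def __post_init__(self) -> None:
        self.positive = np.asarray(self.positive, dtype=np.intp)
        self.negative = np.asarray(self.negative, dtype=np.intp)

    @property
    def combined(self) -> np.ndarray:
        return np.union1d(self.positive, self.negative)

    def counts(self) -> dict[str, int]:
        return {
            "positive": self.positive.size,
            "negative": self.negative.size,
            "combined": self.combined.size,
        }


def rank_columns(x: np.ndarray) -> np.ndarray:
    """Midrank transform of each column (ranks 1..n, ties get averages).

    Tie-free columns take a pure argsort path; columns with ties get exact
    midranks via group-boundary scans.  Agrees with
    ``scipy.stats.rankdata(x, axis=0, method='average')``.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    order = np.argsort(x, axis=0, kind="stable")
    s = np.take_along_axis(x, order, axis=0)
    pos = np.arange(n, dtype=float)[:, None]
    ranks_sorted = np.broadcast_to(pos + 1.0, x.shape)
    if n > 1:
        tied = s[1:] == s[:-1]
        if tied.any():
            # group start: last index where a new value begins, at or below i
            new = np.vstack([np.ones((1, x.shape[1]), bool), ~tied])
            start = np.maximum.accumulate(np.where(new, pos, -np.inf), axis=0)
            # group end: first index where the value changes, at or above i
            last = np.vstack([~tied, np.ones((1, x.shape[1]), bool)])
            end = np.flip(
                np.minimum.accumulate(np.flip(np.where(last, pos, np.inf), 0), axis=0), 0
            )
            ranks_sorted = (start + end) / 2.0 + 1.0
    ranks = np.empty(x.shape)
    np.put_along_axis(ranks, order, ranks_sorted, axis=0)
    return ranks[:, 0] if squeeze else ranks


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation: Pearson correlation of midrank vectors.

    Zero-variance input (all values tied after ranking) is degenerate and
    returns 0.0 rather than NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need n >= 3 observations")
    return float(spearman_rho_matrix(x[:, None], y)[0])


def spearman_rho_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rho of every column of ``X`` against ``y`` (vectorized)."""
    rx = rank_columns(X)
    ry = rank_columns(y)
    rx = rx - rx.mean(axis=0, keepdims=True)
    ry = ry - ry.mean()
    sx = np.sqrt(np.einsum("ij,ij->j", rx, rx))
    sy = float(np.sqrt(ry @ ry))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ry @ rx) / denom
    rho[denom == 0.0] = 0.0
    return np.clip(rho, -1.0, 1.0)


def spearman_pvalue(rho: np.ndarray | float, n: int) -> np.ndarray | float:
    """Two-sided p-value for Spearman rho via the t approximation.

    |rho| = 1 maps to p = 0; rho = 0 maps to p = 1.  Requires n >= 4 so the
    t reference has positive degrees of freedom.
    """
    if n < 4:
        raise ValueError("insufficient sample: need n >= 4 for a p-value")
    r = np.asarray(rho, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("|rho| must be <= 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    return float(p) if np.isscalar(rho) else p


def critical_rho(n: int, alpha: float) -> float:
    """|rho| above which the two-sided t-approximate p falls below alpha."""
    if alpha <= 0.0:
        return np.inf
    if alpha >= 1.0:
        return 0.0
    tcrit = stats.t.isf(alpha / 2.0, df=n - 2)
    return float(tcrit / np.sqrt(n - 2 + tcrit * tcrit))


def screen(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
) -> tuple[EdgeScreenResult, FeatureSets]:
    """Screen every edge (column of ``X``) against trait ``y``.

    Returns the per-edge statistics and the positive/negative/combined
    index sets at strict significance ``p < alpha``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects to screen")
    rho = spearman_rho_matrix(X, y)
    pval = np.asarray(spearman_pvalue(rho, n))
    pval[rho == 0.0] = np.maximum(pval[rho == 0.0], 1.0)  # degenerate columns
    sig = pval < alpha
    fs = FeatureSets(
        positive=np.flatnonzero(sig & (rho > 0)),
        negative=np.flatnonzero(sig & (rho < 0)),
    )
    return EdgeScreenResult(rho=rho, pval=pval, alpha=alpha, n=n), fs
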