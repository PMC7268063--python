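"""Bootstrap-stabilized Spearman feature selection.

Instead of trusting a single full-sample screen, the screen is repeated on
NB resampled subject sets and an edge survives only if it is significant
(with a consistent sign) in at least a fraction FP of the resamples.  Two
resampling schemes are supported:

* ``without_replacement`` — each resample draws ``floor(BP * n)`` distinct
  subjects (BP, the "bootstrap percentage", is the subsample fraction);
* ``with_replacement`` — the classical bootstrap: n draws with replacement,
  duplicated subjects entering the rank screen as genuine repeated
  observations (midranks absorb the induced ties).

Sign bookkeeping is per-sign: an edge coming up significantly positive in
some resamples and negative in others accrues to two separate counters, and
neither mixed stream can reach a high stability threshold.  This preserves
the positive/negative split that CPM requires downstream.

Per-resample RNG streams are spawned from a root ``SeedSequence``, so
resample b is identical whether NB is 50 or 1000 — frequency counts for a
whole NB grid can be read off one counting pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .screen import FeatureSets, critical_rho, rank_columns, spearman_rho_matrix

__all__ = [
    "BootstrapConfig",
    "StabilityFrequencies",
    "draw_subsample",
    "draw_bootstrap",
    "stability_frequencies",
    "stability_frequency_path",
    "threshold_stability",
    "select_features",
]

#: Resampling-parameter grids used for the full grid search.
NB_GRID = (10, 20, 50, 100, 500, 1000)
BP_GRID = (0.25, 0.50, 0.60, 0.70, 0.80)
FP_GRID = (0.50, 0.60, 0.70, 0.80, 0.90, 1.00)


@dataclass(frozen=True)
class BootstrapConfig:
    """Parameters of one bootstrap selection run.

    scheme : 'without_replacement' or 'with_replacement'
    nb : number of resamples
    fp : stability threshold — minimum fraction of resamples in which an
         edge must be significant (inclusive: freq >= fp selects, so
         fp = 1.0 is attainable)
    bp : subsample fraction; used only without replacement
    alpha : per-resample screening level
    seed : root RNG seed (ignored when an explicit SeedSequence is passed
           to the selection functions)
    """

    scheme: str
    nb: int
    fp: float
    bp: float | None = None
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("without_replacement", "with_replacement"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.nb < 1:
            raise ValueError("nb must be >= 1")
        if not 0.0 < self.fp <= 1.0:
            raise ValueError("fp must be in (0, 1]")
        if self.scheme == "without_replacement":
            if self.bp is None or not 0.0 < self.bp <= 1.0:
                raise ValueError("without_replacement requires bp in (0, 1]")

    def label(self) -> str:
        if self.scheme == "with_replacement":
            return f"wr(nb={self.nb},fp={self.fp:g})"
        return f"wor(nb={self.nb},bp={self.bp:g},fp={self.fp:g})"


@dataclass
class StabilityFrequencies:
    """Per-edge selection frequencies across resamples.

    Each entry is a multiple of 1/nb, and pos_freq + neg_freq <= 1
    elementwise (an edge is significant with exactly one sign per
    resample).
    """

    pos_freq: np.ndarray
    neg_freq: np.ndarray
    nb: int
    config: BootstrapConfig | None = field(default=None, repr=False)


def draw_subsample(n: int, bp: float, rng: np.random.Generator) -> np.ndarray:
    """floor(bp*n) distinct subject indices, uniformly without replacement."""
    m = int(np.floor(bp * n))
    if m < 4:
        raise ValueError(
            f"subsample of floor({bp}*{n})={m} subjects is too small to screen"
        )
    return rng.choice(n, size=m, replace=False)


def draw_bootstrap(n: int, rng: np.random.Generator) -> np.ndarray:
    """n subject indices drawn iid uniform with replacement."""
    return rng.integers(0, n, size=n)


def _resample_streams(seed: int | np.random.SeedSequence, nb: int) -> list[np.random.Generator]:
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in root.spawn(nb)]


class _SubsampleScreener:
    """Fast repeated Spearman screens on subsamples of a fixed matrix.

    Re-sorting every column for every resample dominates the cost of the
    without-replacement scheme.  Instead each column's full-sample sort
    order is computed once; the ranks of any subsample then follow from a
    cumulative count of kept rows along that order.  Columns containing
    tied values (where subsample midranks cannot be read off the order
    alone) fall back to the general midrank path; the trait vector is
    midranked per resample directly (it is a single column).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.X = X
        self.y = y
        self.n = X.shape[0]
        self.order = np.argsort(X, axis=0, kind="stable")
        s = np.take_along_axis(X, self.order, axis=0)
        self.tied_cols = np.flatnonzero((s[1:] == s[:-1]).any(axis=0))

    def rho(self, idx: np.ndarray) -> np.ndarray:
        m = idx.size
        kept = np.zeros(self.n, dtype=bool)
        kept[idx] = True
        K = kept[self.order]
        P = np.cumsum(K, axis=0, dtype=np.float64)
        P *= K  # subsample ranks 1..m in sorted position, 0 elsewhere

        ry = rank_columns(self.y[idx])
        ryc = ry - ry.mean()
        ssy = float(ryc @ ryc)
        yr = np.zeros(self.n)
        yr[idx] = ryc
        G = yr[self.order]
        num = np.einsum("ij,ij->j", P, G)  # sum over kept of rank_x * centered rank_y
        ssx = m * (m * m - 1.0) / 12.0  # tie-free rank variance * m
        denom = np.sqrt(ssx * ssy)
        if denom == 0.0:
            return np.zeros(self.X.shape[1])
        rho = num / denom
        if self.tied_cols.size:
            rho[self.tied_cols] = spearman_rho_matrix(
                self.X[np.ix_(idx, self.tied_cols)], self.y[idx]
            )
        return np.clip(rho, -1.0, 1.0)


def stability_frequency_path(
    X: np.ndarray,
    y: np.ndarray,
    scheme: str,
    nb_grid: tuple[int, ...],
    bp: float | None = None,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
) -> dict[int, StabilityFrequencies]:
    """Selection frequencies at every NB in ``nb_grid`` from one counting pass.

    Because resample b's RNG stream depends only on (seed, b), the counts
    at NB=50 are exactly the first 50 resamples of the NB=100 run; the
    returned frequencies are snapshots of one cumulative count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    nb_grid = tuple(sorted(set(int(b) for b in nb_grid)))
    nb_max = nb_grid[-1]
    rngs = _resample_streams(seed, nb_max)

    pos_counts = np.zeros(X.shape[1], dtype=np.int64)
    neg_counts = np.zeros(X.shape[1], dtype=np.int64)
    out: dict[int, StabilityFrequencies] = {}
    snapshots = set(nb_grid)
    screener = _SubsampleScreener(X, y) if scheme == "without_replacement" else None
    for b in range(nb_max):
        if scheme == "without_replacement":
            idx = draw_subsample(n, bp, rngs[b])
            rho = screener.rho(idx)
        elif scheme == "with_replacement":
            idx = draw_bootstrap(n, rngs[b])
            rho = spearman_rho_matrix(X[idx], y[idx])
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        # p < alpha under the t approximation <=> |rho| > critical value
        rcrit = critical_rho(idx.size, alpha)
        pos_counts += rho > rcrit
        neg_counts += rho < -rcrit
        if (b + 1) in snapshots:
            out[b + 1] = StabilityFrequencies(
                pos_freq=pos_counts / (b + 1.0),
                neg_freq=neg_counts / (b + 1.0),
                nb=b + 1,
            )
    return out


def stability_frequencies(
    X: np.ndarray,
    y: np.ndarray,
    config: BootstrapConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> StabilityFrequencies:
    """Run the resampled screen and return per-edge selection frequencies."""
    freqs = stability_frequency_path(
        X, y,
        scheme=config.scheme,
        nb_grid=(config.nb,),
        bp=config.bp,
        alpha=config.alpha,
        seed=config.seed if seed is None else seed,
    )[config.nb]
    freqs.config = config
    return freqs


def threshold_stability(freqs: StabilityFrequencies, fp: float) -> FeatureSets:
    """Edges whose selection frequency reaches the stability threshold.

    The comparison is inclusive (freq >= fp): the threshold grid includes
    100%, which would be unsatisfiable under a strict inequality.
    """
    if not 0.0 < fp <= 1.0:
        raise ValueError("fp must be in (0, 1]")
    # inclusive >= on a count scale, robust to float division noise
    tol = 1e-12
    return FeatureSets(
        positive=np.flatnonzero(freqs.pos_freq >= fp - tol),
        negative=np.flatnonzero(freqs.neg_freq >= fp - tol),
    )


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    config: BootstrapConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> FeatureSets:
    """Bootstrap-stabilized feature selection: frequencies then threshold."""
    return threshold_stability(stability_frequencies(X, y, config, seed=seed), config.fp)
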