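"""Downstream regression models: CPM-P/CPM-N, linear SVR, LASSO, Ridge.

Connectome-based predictive modelling (CPM) compresses the selected edges
into a single per-subject network-strength score — the SUM of edge weights
over the positive (CPM-P) or negative (CPM-N) feature set — and fits a
univariate ordinary-least-squares regression of the phenotype on that
score.  SVR, LASSO and Ridge are fit on the combined feature set.

Objectives (on the scale written above):

* linear SVR:  min 0.5*||beta||^2 + C * sum(xi + xi_hat), epsilon-insensitive
  tube of width ``epsilon`` (default 0.1 on standardized targets);
* LASSO:       min ||y - X beta||^2 + lambda * sum|beta_j|;
* Ridge:       min ||y - X beta||^2 + lambda * sum beta_j^2.

All three are delegated to scikit-learn solvers with the penalty above
mapped to each solver's native parameterization (Ridge: alpha = lambda;
Lasso: alpha = lambda/(2n); LinearSVR's C needs no rescaling).  Features
are standardized to training-fold mean/variance before the penalized
fits (the objectives are scale-sensitive); CPM uses raw edge
weights.  The intercept is never penalized, and predictions are
de-standardized transparently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoLars, Ridge
from sklearn.svm import LinearSVR

__all__ = [
    "C_GRID",
    "LAMBDA_GRID",
    "MODEL_KINDS",
    "DegenerateModelError",
    "FittedModel",
    "cpm_summary",
    "cpm_fit",
    "fit_penalized",
    "fit_model",
    "predict",
]

#: SVR penalty grid 2^-5 .. 2^10 and LASSO/Ridge penalty grid 2^-10 .. 2^5.
C_GRID = tuple(2.0 ** k for k in range(-5, 11))
LAMBDA_GRID = tuple(2.0 ** k for k in range(-10, 6))

MODEL_KINDS = ("cpm_p", "cpm_n", "svr", "lasso", "ridge")

#: Iteration budget for the iterative solvers.  LinearSVR's dual coordinate
#: descent slows sharply at the top of the C grid; the cap trades exactness
#: there for bounded runtime and is overridable per call.
DEFAULT_MAX_ITER = 500


class DegenerateModelError(ValueError):
    """Model cannot be fit (empty feature set or constant summary)."""


@dataclass
class FittedModel:
    """A fitted predictor, serializable and self-contained for prediction.

    ``beta`` lives on the standardized-feature scale for svr/lasso/ridge
    (``x_mean``/``x_scale`` recorded), and is the single slope on the raw
    network-strength sum for CPM kinds.  Prediction is affine:
    intercept + features_std @ beta (after any stored standardization).
    """

    kind: str
    beta: np.ndarray
    intercept: float
    feature_idx: np.ndarray
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    y_mean: float = 0.0
    y_scale: float = 1.0
    hyperparams: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "beta": np.asarray(self.beta).tolist(),
            "intercept": float(self.intercept),
            "feature_idx": np.asarray(self.feature_idx).tolist(),
            "x_mean": None if self.x_mean is None else self.x_mean.tolist(),
            "x_scale": None if self.x_scale is None else self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
            "hyperparams": self.hyperparams,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        return cls(
            kind=d["kind"],
            beta=np.asarray(d["beta"], dtype=float),
            intercept=float(d["intercept"]),
            feature_idx=np.asarray(d["feature_idx"], dtype=np.intp),
            x_mean=None if d["x_mean"] is None else np.asarray(d["x_mean"], dtype=float),
            x_scale=None if d["x_scale"] is None else np.asarray(d["x_scale"], dtype=float),
            y_mean=float(d.get("y_mean", 0.0)),
            y_scale=float(d.get("y_scale", 1.0)),
            hyperparams=dict(d.get("hyperparams", {})),
        )


def cpm_summary(X: np.ndarray, feature_idx: np.ndarray) -> np.ndarray:
    """Per-subject network strength: sum of edge weights over the set."""
    feature_idx = np.asarray(feature_idx, dtype=np.intp)
    if feature_idx.size == 0:
        raise DegenerateModelError("empty feature set: no edges to summarize")
    return np.asarray(X, dtype=float)[:, feature_idx].sum(axis=1)


def cpm_fit(summary: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS slope and intercept of the phenotype on the summary score."""
    summary = np.asarray(summary, dtype=float)
    y = np.asarray(y, dtype=float)
    if summary.size < 3:
        raise ValueError("need n >= 3 to fit")
    sc = summary - summary.mean()
    var = sc @ sc
    if var == 0.0:
        raise DegenerateModelError("constant summary score: slope undefined")
    slope = (sc @ (y - y.mean())) / var
    intercept = y.mean() - slope * summary.mean()
    return float(slope), float(intercept)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0.0, 1.0, scale)  # constant columns pass through
    return (X - mean) / scale, mean, scale


def fit_model(
    X: np.ndarray,
    y: np.ndarray,
    kind: str,
    feature_sets,
    *,
    C: float | None = None,
    lam: float | None = None,
    epsilon: float = 0.1,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FittedModel:
    """Fit any model kind, routing it to its feature set.

    CPM-P uses the positive set, CPM-N the negative set, and the penalized
    models the combined set.  ``X`` holds all edges; the relevant columns
    are extracted here.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    if kind == "cpm_p":
        idx = feature_sets.positive
    elif kind == "cpm_n":
        idx = feature_sets.negative
    else:
        idx = feature_sets.combined
    idx = np.asarray(idx, dtype=np.intp)
    if idx.size == 0:
        raise DegenerateModelError(f"{kind}: empty feature set")
    if kind in ("cpm_p", "cpm_n"):
        s = cpm_summary(X, idx)
        slope, intercept = cpm_fit(s, y)
        return FittedModel(
            kind=kind, beta=np.array([slope]), intercept=intercept, feature_idx=idx
        )
    return fit_penalized(
        np.asarray(X, dtype=float)[:, idx], y, kind, idx,
        C=C, lam=lam, epsilon=epsilon, max_iter=max_iter,
    )


def fit_penalized(
    Xsel: np.ndarray,
    y: np.ndarray,
    kind: str,
    feature_idx: np.ndarray | None = None,
    *,
    C: float | None = None,
    lam: float | None = None,
    epsilon: float = 0.1,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FittedModel:
    """Fit SVR/LASSO/Ridge on an already-selected feature matrix.

    ``Xsel`` has the combined-set columns only; ``feature_idx`` records the
    original edge indices (defaults to 0..p-1).
    """
    Xsel = np.asarray(Xsel, dtype=float)
    y = np.asarray(y, dtype=float)
    if feature_idx is None:
        feature_idx = np.arange(Xsel.shape[1], dtype=np.intp)
    Xs, x_mean, x_scale = _standardize(Xsel)
    n = Xsel.shape[0]
    y_mean, y_scale = 0.0, 1.0

    if kind == "ridge":
        lam = LAMBDA_GRID[0] if lam is None else lam
        est = Ridge(alpha=lam, fit_intercept=True)
        est.fit(Xs, y)
        beta, intercept = est.coef_, float(est.intercept_)
        hp = {"lambda": lam}
    elif kind == "lasso":
        lam = LAMBDA_GRID[0] if lam is None else lam
        # sklearn's lasso minimizes (1/2n)||y-Xb||^2 + a||b||_1 => a = lam/(2n);
        # the LARS solver returns an exact path solution, whose active set
        # never exceeds the sample size
        est = LassoLars(alpha=lam / (2.0 * n), fit_intercept=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(Xs, y)
        beta, intercept = est.coef_, float(est.intercept_)
        hp = {"lambda": lam}
    elif kind == "svr":
        C = 1.0 if C is None else C
        y_mean = float(y.mean())
        y_scale = float(y.std()) or 1.0
        ys = (y - y_mean) / y_scale
        est = LinearSVR(
            C=C, epsilon=epsilon, loss="epsilon_insensitive",
            fit_intercept=True, random_state=0, max_iter=max_iter, tol=1e-3,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(Xs, ys)
        beta, intercept = est.coef_.copy(), float(np.ravel(est.intercept_)[0])
        hp = {"C": C, "epsilon": epsilon}
    else:
        raise ValueError(f"unknown penalized kind {kind!r}")

    return FittedModel(
        kind=kind, beta=np.asarray(beta, dtype=float), intercept=intercept,
        feature_idx=np.asarray(feature_idx, dtype=np.intp),
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
        hyperparams=hp,
    )


def predict(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Predict the phenotype for new subjects from the full edge matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (subjects x edges)")
    if model.kind in ("cpm_p", "cpm_n"):
        if model.feature_idx.max(initial=-1) >= X.shape[1]:
            raise ValueError("feature indices exceed matrix width")
        s = cpm_summary(X, model.feature_idx)
        return model.intercept + model.beta[0] * s
    if model.feature_idx.size and model.feature_idx.max() >= X.shape[1]:
        raise ValueError("feature indices exceed matrix width")
    Xsel = X[:, model.feature_idx]
    if model.x_mean is not None:
        Xsel = (Xsel - model.x_mean) / model.x_scale
    raw = model.intercept + Xsel @ model.beta
    return model.y_mean + model.y_scale * raw
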