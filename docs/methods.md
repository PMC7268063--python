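# Methods

This note documents the statistical procedures implemented in `stableconn`,
the defaults and why they were chosen, the numerical decisions that affect
results at the margin, and what the synthetic benchmark does and does not
establish about real connectome data.

## Data model

A cohort is a `(n_subjects × n_edges)` matrix of edge weights plus aligned
trait vectors. Edges enumerate the strict upper triangle of the symmetric
connectivity matrix in row-major order — (0,1), (0,2), …, (1,2), … — and
every feature index reported anywhere in the package refers to this one
ordering. Zero-variance edge columns are kept (their Spearman rho is
defined as 0 with p = 1, so they can never be selected) rather than
removed, so indices remain stable across runs and exports. Missing trait
values are allowed only in trait vectors (NaN-coded); subjects missing the
analysed trait are dropped per trait, so different traits can have
different effective n. Edge weights are expected in Fisher-z units;
`fisher_z` (atanh) is provided for users starting from raw Pearson
matrices.

## Edge screening

Each edge is correlated with the trait by Spearman's rank correlation:
midranks (average ranks for ties) of both vectors, then Pearson on the
ranks. Two-sided p-values use the t approximation
t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of freedom; at screening sample sizes
(n in the hundreds) this is indistinguishable from the permutation
distribution (the test suite checks agreement with a 10⁶-shuffle
permutation oracle to within 0.005 at n = 30). Significance is strict
(p < α, default α = 0.05) and two-sided, since both correlation signs are
harvested; no multiplicity correction is applied at this stage — the
screen is deliberately permissive and the stability filter supplies the
error control in practice. Significant edges split by sign into
positive, negative and combined sets; CPM-P consumes the positive set,
CPM-N the negative set, and SVR/LASSO/Ridge the combined set.

## Stability selection

The screen is repeated on NB resampled subject sets:

* **without replacement** — ⌊BP·n⌋ distinct subjects per resample
  (floor, never rounding, so the size is deterministic and ≤ n);
* **with replacement** — n iid draws; duplicated subjects enter the rank
  screen as genuine repeated observations (midranks absorb the ties), the
  standard bootstrap semantics.

An edge's positive (negative) frequency is the fraction of resamples in
which it was significantly positive (negative). The two signs are counted
separately: an edge that flips sign across resamples accrues to both
counters and neither mixed stream can clear a high threshold, which
preserves CPM's positive/negative split. Thresholding is inclusive
(frequency ≥ FP selects); the grid contains FP = 100%, which only an
inclusive comparison can satisfy.

Per-resample RNG streams are spawned from a root `SeedSequence`, keyed by
resample index, so resample b is identical whether NB is 50 or 1000.
Consequences: NB can be grown without changing earlier resamples, a whole
NB grid is served by one counting pass, and identical (data, config, seed)
always reproduce bit-identical frequencies.

*Fast path.* Re-sorting every column per resample dominates the cost of
the without-replacement scheme, so each column's full-sample sort order is
computed once and subsample ranks are read off a cumulative count of kept
rows along that order (exactly equal to the general midrank path; columns
containing ties fall back to it). This makes a 100-resample selection on a
300 × 1770 cohort take about half a second.

## Predictors

* **CPM**: the summary statistic is the SUM of edge weights over the set
  (the network-strength convention; sum and mean differ by a constant
  factor absorbed by the regression slope), followed by ordinary least
  squares of the trait on the summary. Raw edge weights, no
  standardization.
* **Ridge / LASSO / linear SVR** are delegated to scikit-learn solvers
  under the objectives stated above, with features standardized to
  training-fold mean and unit variance (the penalties are scale-sensitive)
  and the intercept unpenalized. The package's λ is mapped to each
  solver's native parameterization so the λ = 0 and λ → ∞ limits hold
  exactly: Ridge uses α = λ directly; LASSO uses α = λ/(2n) (scikit-learn
  normalizes the residual term by 1/(2n)) and is solved by LARS, whose
  exact path solutions keep the active set no larger than the sample size
  and make the coefficients at every grid λ available from one path by
  linear interpolation. SVR's C is already on the objective scale.
* **SVR ε** is fixed at 0.1 on standardized targets (the target is
  z-scored inside the SVR fit and predictions are de-standardized); only C
  is tuned. ε is exposed for callers who want a different tube width.

Numerical choice: the dual coordinate-descent solver behind `LinearSVR`
slows sharply at the top of the C grid (C up to 2¹⁰ on standardized data
approaches hard interpolation). Fits are capped at `max_iter = 500`,
tol = 1e-3, fixed `random_state`. Measured consequence: the capped inner
CV can pick a smaller C than a fully converged one, but attains the same
held-out correlation to within ~0.01; the cap is overridable per call.

Fold failure: if a model's feature set is empty on a fold (common under
FP = 100%), the fold is recorded as failed and excluded from the averages
— visible in `PredictionResult.failed_folds` — rather than imputed. A
configuration whose folds all fail raises in `run_cv`; `grid_search`
records such configurations as failed and excludes them from `best` so a
grid containing degenerate corners still returns a winner.

## Cross-validation design

Outer folds are **sorted round-robin**: subjects sorted by trait value
(stable sort; ties keep input order) are dealt cyclically into k = 10
folds, so fold trait distributions match by construction and repeated
random splitting is unnecessary. The partition is computed once per trait,
before any selection, so the baseline and all grid configurations are
compared on identical folds (a paired comparison). Inner tuning builds
5 inner folds from the training subjects by the same scheme.

The inner criterion maximizes mean inner-fold Pearson R (consistent with
the outer "largest R" selection); ties prefer the simpler model — smaller
C for SVR, larger λ for LASSO/Ridge. Ridge's inner path is evaluated by
SVD (β(λ) = V·diag(s/(s²+λ))·Uᵀy with one SVD per inner fold), which is
algebraically the solver's solution at every λ.

Evaluation: R = Pearson correlation(predicted, observed), MSE = mean
squared residual, averaged as plain means over non-failed folds. A
constant prediction (or constant observed fold) has undefined correlation
and scores R = 0, flagged in `flagged_folds`, so fold averages stay
defined.

Grid-search ties in best mean R resolve to the smallest NB, then largest
FP, then smallest BP — the cheapest, most stringent configuration —
making the reported optimum deterministic.

External validation fits once on the entire discovery cohort (features
selected on all of it; hyperparameters tuned by inner 5-fold CV on all of
it — the protocol does not say how tuning happens at this stage, and
whole-set inner CV is the assumption documented here) and predicts the
held-out cohort; the default configuration list is the 2×2×2 grid
NB ∈ {50, 100} × BP ∈ {0.7, 0.8} × FP ∈ {0.8, 0.9}, reported per
configuration and as the across-configuration mean.

## Synthetic cohorts

The generator emulates the statistical shape of Fisher-z edge data, not
its network topology: edges are iid Normal(0, 0.3) per subject (an
optional knob adds equicorrelated blocks of 10 edges, ρ = 0.3, default
off). The trait is

y = Σₑ βₑ·(xₑ/0.3) + ε,  ε ~ Normal(0, noise_sd²),

with coefficients on standardized edge scores so `effect_beta` reads
directly as a per-edge contribution. Half the planted coefficients are
positive and half negative by default (`positive_fraction`), so CPM-P and
CPM-N are both exercisable.

**Default calibration** (chosen from closed-form power arithmetic):
n = 300 subjects, 60 nodes (1770 edges), 20 signal edges,
effect_beta = 0.5, noise_sd = 1. Per-edge trait correlation is then
0.5/√(20·0.25+1) ≈ 0.20 against a detection threshold of ≈ 0.114 at
n = 300 (per-edge screen power ≈ 0.94), leaving room both for
near-complete recovery on clean data and for measurable degradation under
contamination. Note that with equal planted effects the per-edge
correlation saturates at 1/√n_signal as β grows, so power is governed by
the sparsity/noise balance rather than the raw effect size.

**Contamination** models two failure modes the resampling screen is meant
to resist: a fraction (5%) of outlier subjects whose edge rows are redrawn
from a heavy-tailed law (t with 2 degrees of freedom, scaled ×3 relative
to the edge SD) *after* the trait was computed from their clean edges — so
their edge–trait link is severed entirely — and a heteroscedastic flag
multiplying the noise SD by (1 + |standardized signal score|). Both
degrade the full-sample screen's precision sharply (the test suite checks
this in 10-seed majorities) while stability selection retains near-pure
signal sets.

**What the synthetic benchmark does not show.** Edges are independent (no
network covariance, no shared-node structure), traits are exactly linear
in edges, and outliers are exchangeable across subjects; none of this
holds in real cohorts. Passing tests establish that the machinery is
correct and that the selection/prediction contrast moves in the expected
direction under the modelled failure modes — not that the same effect
sizes transfer to any particular dataset. One scale artifact deserves
emphasis: at desk scale (1770 edges, 270 training subjects) the baseline
screen selects ~100 features, well below the training sample size, so
ridge/lasso/SVR absorb the false positives through their own shrinkage and
the prediction advantage of stability selection is small and
seed-dependent for them; the advantage is robust for CPM, which has no
internal regularization, and for the selected-feature-count contrast
(roughly an order of magnitude fewer edges). In the regime the method
targets — tens of thousands of edges, selected sets comparable to or
exceeding the training sample — the mechanism favours the stabilized sets
for all models.

**Noise-free check conditions.** The noiseless recovery test uses a
3-edge, all-positive, zero-noise cohort: with noise_sd = 0 the per-edge
correlation is pinned at 1/√n_signal, and the positive set must equal the
planted set exactly for CPM's summary regression to interpolate, so the
check runs CPM-P under a strict stability screen (NB = 100, BP = 0.7,
FP = 100%, α = 0.01) and ridge under the baseline screen (for which extra
false-positive features are harmless at n > p).

## Problem sizes used in the shipped checks

Test-suite and acceptance-script simulations run at the default cohort
size (300 × 1770) with 3–10 seeded replicates per statistical claim, a
reduced resampling grid ({NB 50, 100} × {BP 0.5, 0.7} × {FP 0.7, 0.8})
for the contaminated contrast, and the full 180/36 grids for enumeration
checks. These sizes keep a complete run in minutes on a single core while
leaving every per-claim sampling error far below the asserted margins.

## Known limitations

* The per-fold screen and frequency counting are exact but O(NB · n · E);
  NB = 1000 on a 44k-edge cohort is feasible but minutes-per-fold.
* LinearSVR's iteration cap means reported SVR coefficients at C ≥ 2⁸ are
  approximate minimizers; rankings by inner CV are unaffected in measured
  cases but the cap is a pragmatic compromise.
* The with-replacement scheme has no fast rank path (duplicates change
  midranks per resample) and is several times slower per resample.
* `grid_search` memoizes model fits per feature set within one call; no
  persistent caching across calls.
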