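# Methods

## Model

Each gene is modeled marginally against pseudotime. With counts
`Y_ij` (cell *i*, gene *j*) and normalized pseudotime `T_i ∈ [0, 1]`
(min–max rescaled so the extreme cells sit at 0 and 1):

- **NB-GAM.** `Y_ij ~ NB(mu_ij, phi_j)` with `Var = mu + mu²/phi` (large
  `phi` is the Poisson limit) and `log(mu_ij) = beta_j0 + f_j(T_i)`. The
  smooth `f_j` is a cubic B-spline with K = 6 knots at quantiles of `T`
  (duplicated quantiles collapse, with K reduced), an
  integrated-squared-second-derivative penalty (null space: linear trends),
  and a sum-to-zero centering constraint over the observed cells so `f_j` is
  identifiable next to the intercept. Counts are modeled raw: the model has
  no library-size offset.
- **ZINB-GAM.** Adds `Z_ij ~ Bernoulli(p_ij)` with
  `logit(p_ij) = alpha_j0 + alpha_j1 log(mu_ij)`; the count is observed only
  when `Z = 1`, otherwise zero. Fitted by EM (below). In `auto` mode the
  ZINB flavor replaces the NB flavor for a gene only when it lowers AIC by
  at least 10 and its EM converged; genes without any zero count keep the NB
  fit (the zero-inflation parameters are not identifiable).

## Fitting

Penalized IRLS (Fisher scoring) over the design `[1 | X_centered]`, batched
over genes: all genes sharing one pseudotime vector share one design, so a
whole count block is fitted at once with stacked per-gene weights; a single
gene is the width-1 case of the same code path. Per gene:

- the smoothing parameter is selected on a fixed 6-point log-spaced grid
  (`1e-3 … 1e7`, penalty scaled to unit spectral norm) by a
  Laplace-approximate REML score
  `-l(beta) + (lam/2) beta'P beta + ½ log|H + lam P| - ½ rank(P) log lam`
  (GCV on the NB deviance is available as `GAMControls(criterion="gcv")`);
- `phi` is estimated by alternating profile maximum likelihood
  (golden-section search on `log phi` over `[1e-3, 1e6]`), interleaved with
  the IRLS/selection steps;
- IRLS convergence is declared per gene when the linear predictor stops
  moving (relative `max |Δeta| < 1e-7`), with at most 50 iterations;
  unconverged genes are flagged, not dropped;
- effective degrees of freedom come from the trace of the smoother matrix
  and the coefficient covariance is the Bayesian `(H + lam P)^{-1}`; AIC
  uses `edf + 1` parameters (`+2` more for the ZINB alphas).

**ZINB EM.** The E-step gives posterior keep-probabilities for the observed
zeros; the M-step runs three weighted IRLS steps for `beta` (smoothing
parameter inherited from the preliminary NB fit and held fixed), re-profiles
`phi` every third iteration on the weighted likelihood, and takes Newton
steps for `(alpha_0, alpha_1)` (clipped at ±30 / ±15; hitting a bound flags
separation). Convergence: relative change of the penalized observed-data
log-likelihood below 1e-6, at most 100 iterations. A generalized-EM
safeguard freezes any gene whose penalized log-likelihood would decrease, so
the tracked likelihood path is non-decreasing by construction.

## Test statistic and p-values

The DE statistic is `s_j = f̂' V̂_f^{r-} f̂`, the quadratic form of the fitted
smooth under the rank-truncated pseudoinverse of its covariance, evaluated
in the spline-coefficient space via the QR factorization of the centered
design (algebraically identical to the n×n form). The rank *r* counts
eigenvalues above `sqrt(machine eps)` times the largest, capped at
`round(edf_smooth) + 1`.

**Permutation null.** Cells are subsampled (fraction 0.8, floor rounding,
without replacement — bootstrapping duplicates cells, which trajectory tools
cannot digest; with cell groups, stratified with uniformly sampled leftover
cells to reach `floor(0.8 n)`). The user's pseudotime method is re-run on
every subsample and its output independently permuted. For each usable
subsample the gene's selected model flavor is refit with the identical
configuration against the permuted pseudotime, giving null values `s_j^b`.
Subsamples where the method fails (exception, constant output) or where the
gene is all-zero are dropped and `B'` decremented; a gene needs a minimum
number of null values (default 50, never more than B) or its p-values are
reported missing. The per-gene model flavor is decided once on the observed
full-data fit and reused for all of that gene's null fits, keeping observed
and null statistics on one fitting path.

**P-values.** Empirical: `(#{s^b ≥ s} + 1)/(B' + 1)` (floor `1/(B'+1)`).
Parametric: a gamma and a two-component gamma mixture are fitted to the
positive null values by maximum likelihood (mixture: EM with five restarts —
quantile, moment, and random splits plus one start at the degenerate
single-gamma solution, which guarantees the mixture log-likelihood is never
below the gamma one; tolerance 1e-8, gamma weight clipped to [0.01, 0.99]);
a 3-df likelihood-ratio test at level 0.01 selects the mixture, and
`p_param = 1 - F̂(s_j)` (floored at 1e-300). Exact-zero null statistics are
excluded from the parametric fit but kept in the empirical p-value; a gene
with more than 10% zeros falls back to empirical-only. An Anderson–Darling
goodness-of-fit p-value (fixed-parameter Monte Carlo) can be recorded as a
diagnostic (`compute_gof=True`); it never gates the output. BH adjustment is
computed from the parametric p-values (both p-values are always reported).
The 3-df chi-squared reference for the LRT ignores the boundary
irregularity of mixture testing deliberately; the selection behavior under
the null is verified empirically in the test suite.

**Fixed-pseudotime mode.** Without subsampling, the smooth test uses the
fractional-edf pseudoinverse construction for extended GAMs and a
chi-squared reference with fractional degrees of freedom. (The permutation
pipeline keeps the integer-rank statistic above: its null is estimated by
permutation, where only identical treatment of observed and null fits
matters, and the pinned integer rank is simpler to reproduce.)

## Synthetic data

`simulate_lineage` emulates dyntoy-style lineage counts: latent times
uniform on [0, 1] (rescaled to span it exactly), NB counts, per-gene size
parameters drawn log-uniformly per dispersion tier — **low** `phi ∈ [10,
100]`, **medium** `[3, 10]`, **high** `[1, 3]`; the tier constants are this
package's convention. Baseline means are log-normal (median 5). Each DE gene
follows a random smooth trend in latent time — monotone power, sigmoidal, or
transient Gaussian bump — scaled so the max/min mean ratio is between 2- and
8-fold; non-DE genes are constant. Bifurcations share a root segment on
`t ≤ 0.4`, after which the second branch departs smoothly and continuously.
`simulate_zero_inflation` thins counts with the same logistic-dropout law
the ZINB-GAM assumes and records the realized indicators, so EM recovery is
testable. The generator does not model library-size variation, ambient
noise, batch effects, or cell-cycle structure: passing tests show the
statistical machinery is calibrated and powered under the stated generative
law, not that any particular real dataset satisfies it.

The built-in pseudotime is a deliberately minimal principal-curve surrogate
(library-size normalization, log1p, PCA, ordering along the first component
with a deterministic sign convention). Real analyses should supply an actual
trajectory method as a callable, or precomputed per-subsample pseudotime
from an external tool.

## Calibration design notes

A pseudotime inferred from the very genes being tested is mildly
self-referential: under a *completely* null dataset the first principal
component is pure noise-mining, every gene correlates with it by selection,
and no permutation scheme can absorb that — the effect shrinks as the gene
panel grows and as genuine trajectory signal anchors the inference. The null
calibration check therefore infers pseudotime (built-in method, re-run per
subsample, genuinely uncertain) from a disjoint null gene panel of the same
cells and tests the other panel, mirroring practice where the tested genes
rarely dominate the embedding. The FDR-control check keeps the standard
self-contained design (20% DE genes anchor the pseudotime).

Two further approximations worth knowing: the observed statistic is computed
on all *n* cells while null statistics come from subsamples of size `0.8n`
(the method's own design — the statistic is approximately pivotal in *n*),
and at B=100 the gamma tail slightly underestimates extreme quantiles; both
leave a small conservative margin inside the BH bound in the acceptance
runs.

## Problem sizes and reproducibility

The test and acceptance runs use scaled-down conditions chosen to exercise
every code path at useful Monte-Carlo resolution: 200 cells × 300–600 genes
with B=100 subsamples for calibration and FDR runs (5 seeds for the FDR
average), a 100-gene panel with B=1000 for the subsample-stability
comparison, and n=500–1000 replicates for estimator-recovery checks. All
randomness flows from explicit seeds; per-subsample RNG streams are
counter-based (`default_rng([seed, tag, b])`), so subsample *b* of a B=1000
run equals subsample *b* of a B=100 run, results are independent of worker
count, and identical configurations reproduce byte-identical outputs.

## Limitations

Single-lineage tests only (a bifurcating dataset can be analyzed one lineage
at a time; lineage matching across subsamples is the user's responsibility
via the callable contract). No covariates, offsets, or branch-comparison
tests. The parametric null assumes the permutation statistics are
gamma-mixture-like; genes where even that fails fall back to the empirical
p-value with resolution `1/(B'+1)`.
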