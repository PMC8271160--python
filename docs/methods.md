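# Methods

## The copy-number ratio

The normalization `r_ij = (L_ij / L_total,i) / (N_j / N_total)` compares a
species' *share* of a gene family with the family's share of all genes in
the data set.  Two properties are load-bearing and tested:

* **Weighted-mean identity.**  For every family,
  `Σ_i (L_total,i / N_total) · r_ij = 1` exactly.  The *unweighted* mean is
  1 only when all genomes have equal `L_total,i`; the package documents and
  tests the weighted form, which holds for arbitrary valid inputs.
* **Scale invariance.**  Multiplying all counts and totals by a common
  positive integer leaves every ratio unchanged.

`N_j` and `N_total` are computed over whatever species set is passed in, so
ratios are *set-dependent*.  The pipeline's convention is to normalize once
on the full species set and subset afterwards, so that later filtering
(shrubs, algae) does not silently re-normalize the ratios.  Families with
`N_j = 0` are dropped with a log note rather than producing NaN columns.

## Species-set filters

Two rules define the analysis sets: shrubs are removed before life-form
comparison (intermediate, tree-like habit of short stature and lifespan),
and algae plus any species absent from the phylogeny are removed before
PGLS.  On the bundled 65-species PLAZA reference roster this yields 61 and
59 species respectively.  Fewer than three retained species is a hard error
(the regression would be underdetermined).

## PGLS with Pagel's λ

Residuals follow `ε ~ N(0, σ² V(λ))` with `V(λ)` the Brownian tip
covariance matrix (entry = shared root-to-MRCA path length; diagonal =
root-to-tip depth) whose off-diagonal is multiplied by λ.  Estimation
choices, all exercised by tests:

* **ML, not REML**, for the λ profile likelihood; standard errors use the
  unbiased `n − p` residual-variance denominator, and coefficient tests are
  two-sided t with `n − p` degrees of freedom.
* **Optimizer:** 21-point grid on [0, 1] followed by bounded scalar
  minimization within one grid step of the best point (`xatol = 1e-7`);
  ties break toward the smaller λ (the grid scan returns the first
  maximizer).  Fits record the grid likelihoods, and a property test checks
  the reported optimum dominates a 101-point grid.
* **Bounds:** λ is capped at 1 rather than at the larger algebraic bound a
  non-ultrametric tree can admit; boundary optima (λ̂ = 0 or 1) are flagged
  via `lambda_at_boundary` because a boundary hit usually means a flat
  profile at the given sample size.
* **Degeneracies:** a PSD-singular `V` gets one jitter of
  `1e-10 · mean(diag)`; if factorization still fails the error names `V`
  (vs a rank-deficient `X`, which is reported separately).  An exact fit
  (zero residual) floors `σ²` at 1e-300 so the log-likelihood stays finite;
  affected coefficients report `t = ±inf`, `p = 0`.

At λ = 0 on an ultrametric tree, `V ∝ I` and the fit reproduces OLS
coefficients, standard errors and p-values to 1e-8 (tested against
statsmodels).  The full estimator is cross-checked against an independent
implementation (R's `nlme::gls` with `ape::corPagel`, ML) on a seeded
25-species data set: coefficients, SEs and λ̂ agree to ≤ 1e-3.

Life forms enter as treatment coding with trees as baseline, so each herb
coefficient is that group's mean ratio offset from trees.

## Multiple testing

Storey q-values are computed from the definition: `π̂0(λ')` on the grid
0, 0.05, …, 0.90, a cubic polynomial smoother (3 df) evaluated at 0.90,
clamped to (0, 1]; step-up `q_(i) = min_{k≥i} π̂0 m p_(k)/k`.  With fewer
than 30 p-values the histogram is too coarse and π̂0 falls back to 1, making
the procedure exactly Benjamini–Hochberg (verified against an independent
BH implementation).  q-values are computed *within* each test family — per
contrast across gene families, across enrichment tables, across growth
fits — matching the granularity of the screens; pooling across contrasts is
not done by default.

## Clustering and enrichment

Species ratio profiles are clustered with Ward's criterion on Euclidean
distances (scipy's `ward`, i.e. Ward.D2).  Rows are sorted by species id
before linkage so the partition is input-order invariant, and cluster ids
are assigned by first appearance along that canonical order.  A `ward_d`
flag applies the Ward recurrence to unsquared distances (the R `ward.D`
variant, obtained here by feeding √d to the D2 routine — identical merge
sequence, different heights) for sensitivity checks.  `k` defaults to 4 and
is a config parameter; no automatic selection is attempted.

Enrichment uses the point-probability two-sided Fisher convention (sum of
all hypergeometric outcomes no more probable than the observed table),
verified against exhaustive enumeration to 1e-12.  Cluster mean-ratio
shifts are one-sample t tests of per-species mean ratios against μ0 = 1
with `df = n − 1`; singleton clusters are reported untested, zero-variance
clusters as `t = ±inf, p = 0` with a flag.

## Growth-rate regression

Response = copy-number ratio, predictor = `ln(mean growth rate)` (natural
log; a base-10 convention would scale slopes by ln 10).  The regression
direction follows the convention of plotting ratio against growth rate;
the reverse direction is a one-line change at the call site.  Family sets
(e.g. paralog groups) are pooled by re-running the ratio formula on summed
counts — the `ALL` row — never by averaging per-family ratios, which would
mis-weight members of unequal size.  At least 5 species with positive rates
are required.

## The synthetic-data generator

What it emulates: a Yule (pure-birth) ultrametric phylogeny of height 1;
life forms as a thresholded Brownian liability (phylogenetically clumped,
group sizes matched exactly by largest-remainder rounding); per-family
latent traits `z ~ MVN(μ_j + effect, σ² V(λ_true))` emitted as counts
`round(exp(z))`; log-normal genome totals independent of family counts;
growth rates `ln g = a − b·r_planted + ε` for tree species only.

Defaults are fixed to the study-like design and are not tuning knobs:
59 species in proportions 23/15/21 (tree/perennial/annual), 121 families,
λ_true = 0.5, one planted family with latent herb offset −0.5 and baseline
3 copies, other families 2–6 mean copies (log-uniform), σ = 0.15, genome
totals ≈ 30k genes with CV 0.2 (the scale of well-annotated plant genomes),
growth slope b = 0.7 with ln-scale noise 0.1 around a 0.5 m/year mean.
Stage-specific substreams are spawned from the master seed, so one seed
fixes every output byte and adding a stage never perturbs earlier draws.

What it does **not** emulate: orthology-inference noise, correlated family
sizes (duplication bursts affecting many families at once), genome totals
that covary with family counts (real repair-gene counts track genome size;
here totals are independent by default, which *adds* per-species noise to
the ratios rather than removing it), birth–death gain/loss dynamics, or
non-ultrametric rate variation.  Passing tests therefore demonstrate that
the estimators recover the generating model's parameters under the model's
own assumptions — not that real PLAZA-derived data satisfy those
assumptions.

**λ-recovery scale.**  Count rounding and the independent genome totals are
non-phylogenetic noise on the ratio scale, so at the 2–6-copy default scale
λ̂ is attenuated by construction.  The λ-recovery experiments therefore use
a large, well-measured family (baseline 50 copies, the scale of the big
kinase-like families, σ = 0.6) and fit on log ratios, where the generative
model is linear-Gaussian; recovered medians for λ_true = 0.8 land near
0.7, inside the documented [0.6, 0.95] band.

## Problem sizes

The test suite and acceptance script use: 500 null simulations at n = 59
for calibration; 200 replicates for coefficient bias; 50 replicates at 100
tips for λ recovery; 50 seeds of the full 59 × 121 design for the
end-to-end screen; 1000 label permutations for Fisher calibration.  These
sizes give Monte-Carlo error comfortably inside the asserted bands while
keeping a full run in the minutes range on a single CPU.

## Known limitations

* λ̂ at the [0, 1] boundary has no standard error and the reported profile
  is flat there; boundary flags should be inspected before interpreting λ.
* With heterogeneous genome sizes the unweighted mean ratio per family is
  not exactly 1; analyses that assume "mean = 1" (e.g. the cluster mean
  tests against μ0 = 1) inherit a small offset that the weighted identity
  quantifies.
* π̂0's cubic smoother targets the canonical q-value default; alternative
  π0 estimators (bootstrap, local FDR) are out of scope.
* The generator's count emission rounds a log-normal variable; for
  near-zero baselines this produces zero-inflated families, which the
  screens handle (dropped if the whole column is zero) but which make
  per-family λ̂ noisy — a property shared with small real families.
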