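# Methods

## The admixture model

Each individual carries a domestic ancestry fraction `q_i`; each biallelic
locus has alternate-allele frequencies `f_dj` in the domestic cluster and
`f_wj` in the wild cluster. Conditional on these, genotypes are
`g_ij ~ Binomial(2, q_i f_dj + (1 − q_i) f_wj)`. The log-likelihood is
maximized jointly over `(q, f_d, f_w)` by EM on the latent
cluster-of-origin of each allele copy, the classical block-relaxation
scheme of model-based ancestry estimators. EM gives closed-form updates and
a provably non-decreasing log-likelihood, which the estimator asserts at
every iteration. K is fixed at two: one wild lake population paired with
one hatchery strain.

Estimation is unsupervised. The hatchery reference panel is used only
afterwards, to anchor labels: the cluster with the higher mean ancestry
among reference individuals is called "domestic". This keeps the estimator
symmetric (swapping the initialization flips `q` to `1 − q` before
anchoring and changes nothing after it) while matching a paired
lake-plus-strain sampling design.

Numerical choices:

* parameters are clipped to `[1e−6, 1 − 1e−6]`; boundary genotypes would
  otherwise send the log-likelihood to −∞;
* five seeded restarts by default, best final log-likelihood kept, since EM
  on a mixture surface can stall in local optima;
* convergence when an iteration gains less than `tol` (default 1e−4) in
  log-likelihood, capped at 2000 iterations with the best iterate returned
  and flagged if the cap is hit.

**Identifiability.** When the two source populations have (nearly)
identical allele frequencies, `q` is meaningless — but this cannot be read
off the estimated frequency separation, because EM happily overfits
sampling noise into an apparent split. The estimator instead re-estimates
`q` on the even-indexed and odd-indexed loci separately: genuine ancestry
signal accumulates across loci and the two half-panel estimates agree,
whereas under identical sources they are independent noise. If their
correlation falls below 0.5 the estimate is flagged `q_defined = False`
with a warning. The diagnostic is deliberately conservative: panels with
very weak divergence (≈0.1 over a few hundred loci) are also flagged, which
is the honest answer at that signal level.

**Boundary noise in lake means.** `q` is truncated at 0, so a truly
un-introgressed individual receives a small positive estimate whose
magnitude scales like the per-individual sampling noise
(σ ≈ 0.06 at 500 moderately divergent loci, a few thousandths at
study-sized panels of ~4,500 strongly divergent SNPs). Lake means near zero
are therefore only reproducible at realistic panel sizes, and the tests
exercise that regime explicitly.

## Filtering and imputation

Filters follow the order: individual missingness → biallelic → MAF → one
SNP per RAD locus, with retention counts reported per step. Boundary
conventions are literal: an individual with exactly 20% missing calls is
removed ("less than 20%" kept); a locus with MAF exactly 0.10 is kept
("< 0.10" removed). MAF is computed over the combined wild + domestic pair,
matching per-pair SNP calling. The kept SNP within a locus is the one with
the lowest within-locus position.

Missing genotypes are imputed by drawing `Binomial(2, p̂)` with `p̂` the
within-population allele frequency at the locus (pooled frequency as
fallback for loci unobserved in a population), under a fixed seed. This is
a deliberately simple, fully reproducible scheme; at ≤ 20% missingness its
perturbation of downstream ancestry estimates is below the estimator's own
Monte-Carlo noise, which the pipeline tests confirm by recovering each
lake's generated mean membership to < 0.05 through the full
filter → impute → EM chain.

## Beta regression

The lake-level response (mean domestic membership) lives in (0, 1), so it
is modeled as `y ~ Beta(μφ, (1 − μ)φ)` with `logit(μ) = x'β` — the
mean/precision parameterization, `Var(y) = μ(1 − μ)/(1 + φ)`. Predictors
are centered and scaled (sample SD, n − 1); interaction columns are
products of standardized main effects, formed after standardization. The
per-variable (mean, SD) pairs are frozen in the fit and reused verbatim for
all later predictions.

The likelihood is maximized over `(β, log φ)` by BFGS with the analytic
score; the starting point is OLS on `logit(y)` with a delta-method moment
estimate of φ. A Nelder-Mead restart from the same point covers the rare
quasi-Newton failure, and convergence is judged by the score norm at the
optimum rather than the optimizer's exit flag. Standard errors come from
the inverse observed information (central finite differences of the
analytic gradient); φ's standard error is delta-method-transformed from the
log scale. Responses sitting exactly on 0 or 1 are pulled inside by
`y' = (y(n − 1) + ½)/n` before fitting; interior data pass through
untouched.

Model metrics:

* `AIC = −2ℓ + 2·df` and `AICc = AIC + 2·df(df + 1)/(n − df − 1)`, with
  `df = slopes + intercept + φ`;
* pseudo-R² is the squared Pearson correlation between `logit(y)` and the
  fitted linear predictor, adjusted by the Wherry correction
  `1 − (1 − R²)(n − 1)/(n − k − 1)` with `k` the slope count — the
  adjustment can be negative for weak models, intentionally;
* VIFs from auxiliary OLS regressions of each standardized term on the
  others (infinite, with a warning, under perfect collinearity), plus the
  pairwise Pearson matrix with p-values.

φ is constant across lakes (no variable-dispersion extension), and no
bias-corrected estimators are used.

## Model selection

The 21 candidate models span environment-only, stocking-only and mixed
term sets over nine predictors, with interactions confined to the
stocking-intensity block. Selection is a three-step cascade:

1. ΔAICc ≤ 2 shortlist (weights `W_i ∝ exp(−Δ_i/2)` over all candidates);
2. leave-one-lake-out jackknife on shortlist members: each fold re-fits on
   the remaining lakes, *re-standardizing predictors within the fold* so no
   information from the held-out lake leaks in, and predicts its mean
   membership; a model survives if the mean absolute observed−predicted
   difference is below 0.05. The absolute (not signed) mean is used — a
   signed mean would reward cancelling errors and could not measure
   predictive quality; the signed variant remains available for
   sensitivity runs;
3. the surviving model with the highest adjusted pseudo-R² wins.

An empty survivor set is a first-class outcome: the pipeline reports the
ranking and exits with a distinct status rather than forcing a winner.
Model-averaged coefficients renormalize Akaike weights over the models that
contain the term.

## Cessation projection

After stocking stops, only time moves: the years-since-stocking variable is
incremented (10-year steps to a 100-year horizon by default), standardized
with the frozen scaler, interaction columns recomputed, and
`μ(t) = inv-logit(x̃(t)'β̂)` recorded. Two start conventions are provided:

* **anchored** (default): the trajectory starts at the lake's *observed*
  mean membership; the model contributes only the logit-scale increments,
  i.e. `μ*(t) = inv-logit(logit(q_obs) + η(t) − η(0))`;
* **model-prediction**: the trajectory starts at the fitted value `μ(0)`.

Years-to-threshold (default threshold 0.10, a practical "returned to wild
state" criterion) is reported on the step grid; a continuous crossing time
via Brent root-finding on `μ(t)` is optional. Under a negative fitted time
coefficient trajectories are strictly decreasing and every lake eventually
crosses any positive threshold.

## Synthetic data

The genotype generator draws an ancestral frequency `p0 ~ U(0.1, 0.9)` per
locus and sets `p_w = p0(1 − d)`, `p_d = p_w + d`, so the divergence
parameter `d` *is* the per-locus allele-frequency difference: `d = 0` gives
identical sources (the unidentifiability control) and `d = 1` fixed
differences. Wild individuals draw true ancestry from a configurable
mixture (default: half pure wild, half `Beta(1, 6)`, giving lake means in
the observed 0–0.3 range); the hatchery panel is pure domestic. Genotypes
are binomial given `q` and the frequencies; missingness is injected
uniformly at random.

The lake-table generator draws the nine predictors from `Beta(2, 2)`
marginals scaled to the observed min–max ranges (placing medians mid-range,
consistent with the published spread), optionally correlated through a
Gaussian copula, and draws the response from the exact beta-regression
process above (defaults: β_time = −0.44, β_fish = 0.30, intercept
logit⁻¹ ≈ 0.08, φ = 20 — a precision that reproduces lake-level response
spreads comparable to the study's per-lake SDs). What the generators do
*not* emulate: linkage disequilibrium between loci, drift or selection
dynamics of repeated stocking events, spatial structure among lakes, and
measurement error in covariates. Passing tests therefore certify the
statistical machinery under the model's own assumptions, not robustness to
their violation.

## Problem sizes and determinism

Default test and acceptance problem sizes are desk-scale by design:
genotype panels of 120–2,500 loci and 20–60 individuals, 29-lake tables,
40–100 replicate simulations. The pipeline derives every stage seed from
one global seed through `SeedSequence` spawning, so identical configuration
implies byte-identical numeric output.

## Known limitations

* Bootstrap standard errors on `q`, K > 2, and least-squares ancestry
  comparisons are out of scope.
* The jackknife screen's 0.05 threshold is a management convention, not an
  estimated quantity; results near the boundary should be read with the
  ranking table, not the binary verdict alone.
* The adjusted pseudo-R² definition (logit-scale correlation + Wherry) is
  one of several in circulation for beta regression; comparisons across
  software should use the reported log-likelihoods and AICc, which are
  parameterization-exact.
* On small panels with weak source divergence the identifiability
  diagnostic flags estimates as undefined even though a biased point
  estimate exists; that is intended behavior.
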