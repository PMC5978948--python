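# stockadmix

Quantifying and predicting domestic introgression in stocked fish
populations from SNP genotypes and stocking-history covariates.

Supplementation ("stocking") of recreational fisheries releases large
numbers of captive-reared, domesticated fish into wild lakes. Repeated
hybridization between the domestic strain and wild populations moves
hatchery alleles into the wild gene pool. `stockadmix` implements the full
analysis chain a management-genetics study of this problem runs, for lakes
sampled with reduced-representation (GBS/RAD) SNP panels:

1. **Genotype filtering** — per lake × hatchery-strain pair: drop
   individuals with ≥ 20% missing genotypes, drop non-biallelic loci, drop
   loci with minor allele frequency < 0.10, keep one SNP per RAD locus, and
   impute remaining gaps with seeded binomial draws from within-population
   allele frequencies.
2. **Ancestry estimation** — a two-population (K = 2) admixture model:
   genotype `g_ij ~ Binomial(2, q_i f_dj + (1 − q_i) f_wj)`, maximized by
   multi-start EM, giving each individual's domestic ancestry fraction
   `q ∈ [0, 1]`. Cluster labels are anchored by the hatchery reference
   panel; the per-lake mean over wild-caught fish is the lake's
   *q-domestic*. Individuals classify as wild (q ≤ 0.1), admixed, or
   domestic (q ≥ 0.9).
3. **Beta regression** — lake means are proportions, so
   `y_i ~ Beta(μ_i φ, (1 − μ_i) φ)` with `logit(μ_i) = x_i'β` over
   centered-and-scaled stocking-intensity and environmental predictors.
   Fitting is by maximum likelihood in `(β, log φ)` with analytic
   gradients; Wald tests, VIF diagnostics, AICc and a logit-scale pseudo-R²
   come with the fit.
4. **Model selection** — 21 candidate models (environment-only,
   stocking-only, mixed) screened in three steps: AICc shortlist
   (ΔAICc ≤ 2), a leave-one-lake-out jackknife of predictive error (mean
   |observed − predicted| < 0.05), then highest adjusted pseudo-R² among
   the survivors. Akaike weights support model-averaged coefficients.
5. **Cessation projection** — after stocking stops only time advances:
   the years-since-stocking covariate is shifted, re-standardized with the
   scaler frozen at fitting time, and `μ(t)` is tracked on a 10-year grid
   to a 100-year horizon, anchored so t = 0 reproduces the observed
   q-domestic. The years until a lake falls below a management threshold
   (default 0.10) summarize its resilience.

A synthetic-data module generates both layers with known truth — admixed
genotypes from two divergent source populations, and lake tables whose
response follows the exact beta-regression data-generating process — so
every stage is testable without the original archive. The bundled study
summary tables (29 lakes, sampling effort, q-domestic, SNP retention) feed
the table-level checks.

## Worked example

Simulate a 29-lake covariate table whose mean domestic membership declines
with time since stocking (β_time = −0.44, β_fish = 0.30, φ = 20), then fit,
select, and project:

```bash
stockadmix simulate lakes --config lakes.yaml --seed 7 --out lakes.csv
stockadmix fit --lakes lakes.csv --terms SinceMeanYear,MeanFishStock --out fit.json
```

```
             (Intercept)  -2.395 ± 0.131  p=0.0000
           SinceMeanYear  -0.580 ± 0.107  p=0.0000
           MeanFishStock  +0.260 ± 0.130  p=0.0448
phi=26.51  AICc=-93.86  adj pseudo-R2=0.55
```

The fitted standardized time coefficient is negative and dominant, the
stocking-quantity effect positive and weaker — the structure the table was
generated from. `stockadmix select --lakes lakes.csv --out report/` then
runs the full 21-model cascade:

```
shortlist (ΔAICc): [14]
survivors (jackknife): [14]
best model: 14 (SinceMeanYear:TotalHa + SinceMeanYear + TotalHa + MeanFishStock)
model-averaged SinceMeanYear coefficient: -0.570
```

and `stockadmix project --fit report/best_fit.json --lakes lakes.csv --out proj/`
converts the winning fit into per-lake recovery times:

```
SL01: reaches 0.10 in 40 y
SL02: reaches 0.10 in 0 y
SL03: reaches 0.10 in 20 y
SL04: reaches 0.10 in 50 y
```

Lakes already below q-domestic 0.10 report 0 years; the most introgressed
lakes take several decades — the qualitative pattern that motivates
treating stocking impacts as reversible.

`stockadmix run-all --config cfg.yaml` chains every stage (synthetic
genotypes per lake → filtering → admixture → selection → projection) and
writes a manifest that makes the run byte-reproducible.

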