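# Methods

`seqblup` implements a multi-stage genomic-prediction workflow for
multi-breed dairy-cattle-style populations: sequence variants near QTL
peaks are selected from a (multi-breed) GWAS and fitted as a second genetic
component alongside a standard SNP-array component in a Bayesian SNP-BLUP
model. This note records the models, the defaults and why, the numerical
choices, and what the synthetic data generator does and does not emulate.

## 1. The prediction models

The response is the deregressed proof (DRP), standardized to mean 0 and
variance 1 within each breed. With `z_im` the allele dose (0–2) of animal
`i` at array marker `m` and `z_in` the dose at QTL-component marker `n`:

* **WB-50K** (within-breed, array only):
  `y_i = mu + sum_m z_im a_m + e_i`, with `a_m ~ N(0, sigma2_a)` and
  `e_i ~ N(0, sigma2_e)`.
* **WB-50K + QTL**: a second component `sum_n z_in q_n` is added, with
  `q_n ~ N(0, sigma2_q)` — a separate variance, so a handful of
  strong-effect variants are not shrunk at the genome-wide rate.
* **MB** (multi-breed): populations are pooled and a fixed breed effect
  `b_j` absorbs mean differences; marker effects are common to all breeds.
* **MT** (multi-trait): the same trait in different breeds is treated as
  correlated traits. Marker `m` carries a vector of per-breed effects
  `a_jm` with across-breed covariance matrix `Sigma_a` (and the QTL
  component its own `Sigma_q`); residuals are independent across breeds.
  The genomic correlation between breeds `j` and `k` for a component is
  `sigma_jk / sqrt(sigma_jj * sigma_kk)`, derived per stored draw.

All variances carry flat (uniform, non-informative) priors. Chains default
to 5,000 iterations with 1,000 burn-in for desk-scale work; the
full-length setting of 50,000/10,000 is used for the chain-agreement check
and is available through `MCMCConfig`.

### Gibbs sampler details

Per iteration, in order: location parameters (intercept; breed effects for
MB; per-breed intercepts for MT) from their flat-prior normal
conditionals; every marker effect of the array component, then of the QTL
component, from its normal (MT: multivariate normal) full conditional with
the residual vector updated incrementally; then the variances.

Numerical choices, each of which matters for reproducibility:

* **Flat-prior variance conditionals.** A component of `m` effects draws
  `sigma2 = SS / chi2_df` with `df = m - 2` (`n - 2` for residuals), the
  degrees of freedom under a uniform prior on the variance; `df` is
  floored at 1 so very small components stay proper, and draws are floored
  at 1e-12 so degenerate (e.g. all-zero) data cannot divide by zero.
* **MT covariance conditionals.** `Sigma` is drawn from an inverse-Wishart
  with scale `B'B` (the effect cross-products) and `m` degrees of freedom
  — the flat-prior data degrees of freedom `m - B - 1` plus the minimal
  `B + 1`. A 1e-8 diagonal jitter guards positive definiteness, with one
  jittered retry before aborting with a diagnostic state dump.
* **Column centering.** Design-matrix columns are centered on the
  training-mean dosage. This decouples the intercept from the marker
  effects (otherwise the single-site sampler mixes very slowly along the
  intercept/allele-frequency ridge) and makes the fixed-variance sampler
  converge to the textbook ridge solution `(Z'Z + lambda I)^-1 Z'y`. GEBV
  are therefore deviations from the training mean; reliability and bias
  slope are invariant to that constant.
* **Sweep order** is fixed (array component then QTL component, by column
  index), and animals are sorted by (breed, animal id) inside
  `build_design`, so results are exactly invariant to the order animals
  are supplied in.
* **Component variances for reporting.** Per iteration the across-animal
  variances var(Za) and var(Zq) of the two genetic components are stored;
  their chain means are the `sigma2_50K` and `sigma2_QTL` used in
  `h2_QTL = sigma2_QTL / (sigma2_50K + sigma2_QTL + sigma2_e)`.
* DRP enter unweighted (their reliability is used only in the evaluation
  denominator); validation animals are excluded from sampling entirely.

## 2. GWAS and marker selection

The single-marker scan is `y = mu + s + beta g + e` with a random sire
effect `s` capturing paternal half-sib covariance; the multi-breed scan
adds a reference-coded fixed breed effect and nests sires within breed.
Design choices where the procedure was open:

* Sire and residual variances are estimated once per population by EM-REML
  on the no-marker null model and held fixed for every marker;
  the per-marker effect is then a GLS estimate under that covariance with
  a two-sided normal-reference Wald p-value. (At these sample sizes a t
  reference is indistinguishable; fixing the choice makes p-values
  reproducible.) EM near the zero-variance boundary converges slowly, so a
  sire variance below 1e-6 of the residual is truncated to the boundary.
* The multi-breed scan pools the residual variance (animal-weighted mean
  of the per-population estimates) — DRP are standardized within breed, so
  scales are comparable — while sire variances stay population-specific.
* Scan filters: MAF >= 0.005 and INFO score >= 0.60. Prediction-marker
  eligibility (both the array panel and QTL candidates): MAF strictly
  above 0.01 and INFO >= 0.9.
* Preselection for the pooled scan takes the union of variants below
  1e-5 in a Holstein-like population or 1e-3 in a smaller population, in
  any population for any trait.

Selection then proceeds: keep candidates with `p < 10^-t`; greedy LD
pruning in ascending-p order at `R^2 <= 0.95`, computed on the pooled
training genotypes of the scan's source populations and restricted to a
1-Mb comparison window for tractability (both configurable); optionally
cap each peak interval at the `n` lowest-p variants per window of `w` Mb,
iterating from the most significant remaining variant with intervals
centered on the peak (`peak +- w/2`); and finally remove every selected
QTL variant from the array component so the two sets are disjoint. Ties
on p break by genomic position. Open points resolved as package choices:
windows are peak-centered (left-anchoring would be an alternative), and
pruning r² uses pooled training genotypes of the source populations.

## 3. The synthetic data generator

The generator emulates the features of multi-breed cattle data that this
design rests on — nothing more:

* **Breed divergence**: per-breed allele frequencies from a
  Balding–Nichols Beta distribution around ancestral frequencies,
  parameterized by per-breed FST. Defaults: two Holstein-like populations
  (FST 0.010/0.015), a moderately related red breed (0.05) and a distant
  Jersey-like breed (0.15).
* **LD**: haplotypes follow a Gaussian-copula first-order process along
  the map; latent correlation between markers `d` Mb apart is
  `ld_decay^d` (default `ld_decay = 0.01`, giving dosage r² of roughly
  0.3 between adjacent markers ~10 kb apart and near-zero beyond ~1 Mb —
  a livestock-like but not cattle-calibrated decay). Each adjacent-marker
  interval carries an LD phase sign; breeds flip the ancestral sign
  independently with probability `min(1, 3 * FST)`, so LD phase agreement
  (and hence pooled across-breed LD) decays faster between more diverged
  breeds, while within-breed LD is unaffected. No real LD structure is
  matched quantitatively; the parameters are free knobs.
* **Families**: paternal haplotypes are recombined copies of a genotyped
  sire's pair (~1 crossover per 100 Mb); maternal haplotypes are fresh
  draws. Combined with a polygenic term transmitted through sires (half
  the sire value plus Mendelian sampling), paternal half-sib TBV
  covariance is ~1/4 of the additive variance, which is what the GWAS
  sire effect models.
* **Trait**: 50 QTL sampled among off-array variants, per-breed effects
  multivariate normal with across-breed correlation 0.8 (the regime in
  which preselected QTL variants are useful across breeds), rescaled so
  the QTL explain one third of a unit genetic variance. DRP = TBV +
  independent noise sized so cor²(TBV, DRP) equals the target reliability
  (0.9), standardized within breed. At the defaults the QTL therefore
  carry ~30% of the phenotypic variance.
* **Array panel**: ~1 in 50 common variants (mean-frequency MAF >= 0.15)
  is flagged `on_array`, standing in for a 50K chip thinned at desk scale.
  INFO scores default to a point mass at 1.0 (a Beta draw is available so
  the INFO filters can be exercised); imputation itself is not simulated.

Deliberately not emulated: genotype imputation, selection and drift over
generations, dam-side pedigree, residual covariances between DRP, the X
chromosome, multiple real traits (the multi-trait machinery models one
trait across breeds). Passing tests therefore show the pipeline's
statistical machinery is correct under its own assumptions, not that real
cattle data would yield the same reliabilities.

## 4. Evaluation

Validation animals are the youngest fraction of each breed; their sires
are removed from training. Reliability is cor²(DRP, GEBV) divided by the
mean DRP reliability of the validation animals; bias is the regression
slope of DRP on GEBV (below 1 = inflated predictions); a genomic
correlation is flagged significant when its absolute posterior mean
exceeds twice its posterior standard deviation (posterior SD standing in
for the standard error).

## 5. Problem sizes and limitations

Default desk scale: 4 breeds, 500–1,000 training animals each, one 100-Mb
chromosome with ~10,000 sequence variants, ~200 array markers, 50 QTL —
the full simulate→GWAS→select→predict→evaluate chain runs in well under a
minute per scenario, and the heavier consistency checks (five 50,000-
iteration chains; ten end-to-end replicates) in a few minutes each.

Known limitations: the LD model is first-order (no long-range haplotype
blocks); sire variance is not re-estimated per marker; the greedy pruner
compares only within a physical window; `h2_QTL` is upward-biased when
the QTL component also tags polygenic variance through LD; and with very
few markers in a component the MT covariance posterior concentrates near
correlation ±1 (an inverse-Wishart small-sample artifact), so MT runs
deserve a component of at least a few dozen markers.
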