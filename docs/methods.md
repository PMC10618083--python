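# Methods

## The model

`trscore` implements a transcriptomic-risk-score (TRS) analysis for a binary
phenotype.  The inputs are (i) per-tissue gene-level TWAS summary statistics
(signed Z-score and p-value per gene), (ii) an observed samples × genes
expression matrix in a case-control target cohort, (iii) a per-sample table
with phenotype, covariates (sex, age, genotyping wave, genetic PCs) and a
precomputed polygenic risk score (PRS), and optionally (iv) gene-level
colocalization probabilities (GLCP) per (gene, tissue).

For a gene set *S* selected from one tissue's TWAS panel, the score of
sample *i* is

    TRS_i = Σ_{g ∈ S}  z_g · x_ig

with `z_g` the signed TWAS Z and `x_ig` the standardized observed
expression (per-gene mean 0, SD 1 with the n−1 denominator).  Gene sets are
taken at a ladder of TWAS p-value thresholds — the per-panel Bonferroni
level (α / genes tested in that panel), 0.001, 0.05, 0.1, 0.2, 0.3, 0.4,
0.5 and 1 — and the TRS at each threshold is tested against the phenotype
with a covariate-adjusted logistic regression.  The "best" threshold per
tissue is the one with the smallest Wald p for the score coefficient.

Because picking the minimum over a ladder of correlated tests overfits, the
reported significance is a permutation empirical p-value: the phenotype is
permuted B times (covariates stay attached to their samples), the **entire
threshold scan** is repeated on each permutation, and the observed minimum
p is ranked against the permuted minima, `p_emp = (r+1)/(B+1)`.  The
smallest attainable value is therefore 1/(B+1).  A cheaper variant that
re-tests only the observed best threshold is available
(`scan_per_permutation=False`) but is anti-conservative by construction;
the test suite demonstrates both behaviours.

Variance explained is reported on the liability scale: the Cox–Snell
pseudo-R², `1 − exp((2/n)(ℓ₀ − ℓ₁))`, is converted with Lee et al.'s
ascertainment-corrected transformation for a case-control sample with
sample case proportion P and population prevalence K (default K = 0.05):

    t = Φ⁻¹(1−K),  z = φ(t),  m = z/K,
    C = [K(1−K)/z²]·[K(1−K)/(P(1−P))],
    θ = m·((P−K)/(1−K))·(m·((P−K)/(1−K)) − t),
    R²_liab = C·R²_CS / (1 + C·θ·R²_CS).

With K = P the curvature term θ vanishes and the transform is linear in
R²_CS.

Across tissues the best-threshold TRSs are strongly correlated, so the
family-wise correction uses the Galwey effective number of tests,
`Meff = (Σ√λ)² / Σλ` over the eigenvalues of the TRS Pearson correlation
matrix (negative eigenvalues clamped to 0), followed by the Sidák per-test
threshold `1 − (1−α)^(1/Meff)`.

Two restricted score variants are provided: locus pruning (single-linkage
clustering of selected genes at TSS distance ≤ 500 kb per chromosome, then
the lowest-TWAS-p gene per locus) and colocalization filtering (keep genes
with GLCP ≥ 0.5, boundary inclusive).  The PRS enters three ways: its own
covariate-adjusted association, Pearson correlation with each TRS
(Bonferroni over pairs), and a likelihood-ratio test of PRS+covariates
versus PRS+TRS+covariates.

## Numerical and design choices

* **Logistic fits** are maximum-likelihood via Newton scoring (IRLS),
  tolerance 1e-8 on the coefficient update, at most 100 iterations.
  Perfect/quasi separation is detected by coefficient divergence
  (‖β‖∞ > 50 in standardized designs) or a singular information matrix and
  raised explicitly; rank-deficient designs are rejected with the collinear
  columns named (pivoted QR).  Wald two-sided p-values and CIs for single
  coefficients; chi-square LRT for nested model comparison.  The
  permutation loop uses the same Newton iteration vectorized over
  permutations (verified against the scalar path to < 1e-10).
* **Expression standardization** uses the full analysis sample (cases and
  controls jointly), n−1 denominator.  Control-only moments would be a
  defensible alternative; full-sample is the common convention for
  observed-expression scores and standardization choices only rescale the
  per-gene weights.
* **TRS scale.** The raw weighted sum is divided by its own sample SD
  before regression, so estimates are per-SD log-odds and comparable across
  tissues and thresholds.  Raw sums are also emitted.
* **Pseudo-R² increment.** The reported value is Lee-transform(full-model
  R²_CS) − Lee-transform(covariate-only R²_CS), both anchored at the
  intercept-only model ("transform-then-subtract").  The alternative —
  Cox–Snell computed directly between full and covariate-only fits, then
  transformed — is available as `method="relative"`; the two agree closely
  when covariate effects are weak.
* **Locus boundary.** "Within 500 kb" is implemented as TSS distance
  ≤ 500,000 joins a locus, so "< 500 kb ⇒ same locus" and "> 500 kb ⇒
  independent" are jointly exhaustive; an exact tie at the boundary is
  merged and logged.  Lead-gene ties are broken by smaller TSS, then
  lexicographic gene id.
* **Threshold ties** in the scan are broken toward fewer genes, and at
  exactly equal (p, gene count) toward the stricter end of the ladder
  (stable sort in ladder order).
* **Galwey rounding.** Meff is rounded half away from zero and clamped to
  [1, m] before Sidák; the unrounded value is also reported.
* **Empty selections** are legal flagged results at selection level (the
  caller decides); a threshold with no scoreable genes is skipped in the
  scan, and a tissue where no threshold is scoreable is skipped with a
  warning.
* **p-value floors.** Simulated two-sided normal p-values are clipped at
  1e-300 to stay in the valid (0, 1] range.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
any particular biology:

* **TWAS panels.** Per gene, tissue Z-scores follow an equicorrelated
  multivariate normal with pairwise correlation `cross_tissue_corr`
  (default 0.98, matching the near-complete correlation of brain-panel TWAS
  results); signal genes get a shared mean shift of magnitude
  `twas_effect` (default 5, the |Z| scale of top TWAS hits) and random
  sign.  `p = 2Φ(−|Z|)` exactly.
* **Cohort.** 222 cases and 269 controls by default (the study's design),
  ascertained from a population pool by retrospective sampling: cases are
  drawn with weight exp(η) where η is a logistic liability over sex, age,
  wave, PCs (`covariate_effects`, log-odds per unit) and the PRS
  (`prs_effect`, default 0.33 per SD), controls uniformly from the rest.
  Case/control counts are fixed by design — exactly the ascertainment
  Lee's transformation corrects for — so no explicit liability threshold
  is modelled for the phenotype itself.
* **Expression** is simulated directly on the standardized scale: controls
  N(0, 1) per gene; cases shifted by `sign(Z)·expr_effect` for signal
  genes.  The default `expr_effect = 0.06` is chosen so that, with the
  default number of signal genes, the score-level case-control difference
  is ≈ 0.35 SD — the per-SD logistic-estimate scale (0.2–0.45) this kind
  of analysis reports — rather than any per-gene literature value.  A
  `discordant_fraction` switch plants genes whose expression shift opposes
  their TWAS sign.
* **PRS** is drawn independently of expression, so TRS and PRS are
  conditionally independent given case status; their marginal correlation
  is the (small) product of their phenotype correlations.
* **Colocalization.** GLCP ~ Beta(8, 2) for signal genes, Beta(2, 8)
  otherwise.
* **Determinism.** Every generator is a pure function of (config, seed);
  each draws from its own stream at `seed + fixed offset`, so adding one
  generator never shifts another's output.

What the generator does **not** emulate: linkage disequilibrium and shared
eQTL between neighbouring genes (simulated Z-scores are independent across
genes, so locus pruning is exercised structurally, not against realistic
local correlation), gene-gene expression correlation, batch structure,
measurement noise specific to microarrays, and any real gene identity.
Passing tests therefore show that the pipeline's statistics behave as
designed under its own assumptions, not that the effect sizes in any real
cohort are recoverable.

## Problem sizes used in tests and the acceptance script

Monte Carlo checks run at deliberately small scale, chosen as the smallest
sizes at which the checked behaviour is stably resolved: null calibration
of the permutation scan at 50+50 samples, 120 genes, B = 199 over 400
replicates (the scripted run uses 150 replicates at B = 99); power at the
planted-signal condition (0.3-SD shift, 5% signal genes, 250+250, 500
genes) over 100–200 replicates; the end-to-end demonstration at 1500 genes
per panel with the absolute number of signal genes preserved at the
study-scale default (24).  B = 10,000 permutations — the floor-1e-4 setting
of the original analysis — remains the library default.

## Known limitations

* The permutation null permutes the phenotype only; covariate-phenotype
  linkage is broken under the null, which is the standard simple
  permutation scheme and slightly miscalibrated when covariates are strong.
* Wald inference for individual coefficients (no profile likelihood or
  Firth correction); near-separating designs raise rather than regularize.
* No continuous-phenotype mode, mixed models, or alternative Meff
  estimators (Nyholt, Li–Ji).
* Gene identifiers are matched as literal strings across TWAS, expression
  and colocalization tables; no symbol/Ensembl translation is attempted.
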