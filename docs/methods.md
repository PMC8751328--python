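# Methods

This note documents the statistical models behind `pathprs`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not establish about real cohort data.

## Case-cohort Cox estimation

The case-cohort design assembles covariates for a random subcohort drawn
at baseline plus all incident cases.  `pathprs.cox` maximizes the
Prentice pseudo-partial-likelihood: subcohort members contribute to every
risk set over their follow-up, while cases sampled from outside the
subcohort enter the risk set only at their own failure time.  This is
implemented with separate risk-sum accumulators for the two groups rather
than epsilon-perturbed entry times, so tied, coarse or adversarial time
grids cannot reorder risk sets through floating-point artifacts.

* **Ties.** Efron's correction is the default (coarse time scales produce
  heavy ties); Breslow is available through `RiskSetPolicy` and is used
  for oracle comparisons.  With continuous event times the two coincide.
* **Variance.** Model-based covariance is the inverse observed
  information.  The reported confidence intervals use a score-residual
  sandwich clustered on participant id, which absorbs the extra
  variability from sampling the subcohort.  The score residuals use
  Breslow-form cumulative-hazard increments even under Efron ties; this
  is exact for untied data (the generator's event times are continuous)
  and a standard approximation otherwise.
* **Estimator variants.** A Barlow-weighted variant (subcohort
  person-time up-weighted by the inverse sampling fraction, supplied
  explicitly) sits behind the same policy switch.  The two variants give
  asymptotically equivalent estimates; Prentice is the default.
* **Optimization.** Newton-Raphson with step-halving, at most 50 steps,
  gradient tolerance 1e-9.  Monotone likelihoods (separation) are flagged
  as non-converged when any standardized coefficient exceeds 10; callers
  treat such per-SNP fits as exclusions, never silent successes.
* **Diagnostics.** `ph_check` correlates scaled Schoenfeld residuals with
  event time per covariate (t-test p); it is flagged undefined below 3
  events.  Simulations under exact proportional hazards show ~5%
  rejection at the 5% level.
* On a pure-subcohort (full-cohort) dataset the fit reduces to an
  ordinary Cox model; tests pin coefficients, model SEs and robust SEs to
  an independent reference implementation at 1e-6.

## Score construction

The split-half cross-weighted construction is described stage by stage in
the `pathprs.prs` module docstring.  Open points resolved here:

* **Split.** Halves are stratified by sex x case status (the source
  procedure says only "random sets of approximately equal size"); the
  stratification guarantees that sex-specific Cox fits are estimable in
  both halves, at the cost of fixing the case fraction per half.
* **Exactly-zero betas** count as direction-inconsistent (a measure-zero
  event with continuous data).
* **LD pruning** evaluates offending pairs in descending r² order and
  removes one member per pair by a seeded uniform draw.  The r² = 0.6
  boundary is inclusive: both members of a pair at exactly 0.6 stay.
* **Standardization constants** are per half, per sex, from that half's
  subcohort members only, and are *not* recomputed after the merge; the
  merged subcohort scores therefore have mean ≈ 0 and SD ≈ 1 rather than
  exactly 1.
* **Missingness rescaling** divides by the proportion of successfully
  genotyped score SNPs; an individual with no genotyped score SNPs has an
  undefined score and is dropped from score analyses (logged).

### Calibration of the construction: a measured gap

A deliberate property of this package is that it *measures* the
anti-overfitting claim usually attached to split-half weighting, rather
than assuming it.  Under a global genetic null (all per-allele hazard
ratios 1), the continuous-PRS Wald test on the merged dataset rejects far
above the nominal 5% (≈60% at the tested design).  Two mechanisms, both
verified by ablation in the test suite's companion experiments:

1. **Selection leakage.** A SNP enters the score only when its estimated
   effect has the same sign in both halves, and the risk-allele
   orientation is that shared sign.  Conditional on inclusion, each
   half's orientation therefore aligns with its *own* in-sample noise —
   cross-weighting supplies the magnitude from the other half, but the
   direction is partly in-sample.
2. **Merged evaluation.** Even with the consistency filter removed, the
   two halves' cross-weighted association statistics are asymptotically
   the same quantity (each is the inner product of the two halves'
   per-SNP z-vectors).  Averaging them by merging doubles the variance of
   the pooled estimate, which the cluster-robust sandwich — seeing only
   independent rows — cannot detect: the null z-statistics have SD ≈ √2.

Ablations confirm the machinery itself is sound: a fixed covariate, a
random-weight score, or a cross-weighted score evaluated *within one
half only* all reject at ~5%.  Same-half weighting (the negative-control
mode `cross_weighting=False`) rejects at ~96%, so the split-half design
removes most — but not all — of the overfitting.  The corresponding
calibration test in `tests/test_acceptance.py` is expected to fail and is
kept as the honest record of this property; hazard ratios produced by
this construction on null data are biased away from 1 in whichever
direction the data suggest, and confidence intervals are anti-conservative.

## Association analyses

* **Endpoints** are cause-specific: overall CRC and subsites, with
  colon = proximal + distal and rectosigmoid counting as an event only
  for overall CRC.  For a narrower endpoint, cases of other subsites are
  censored at their diagnosis time (standard cause-specific hazards; the
  source design does not state its convention).  Non-subcohort cases of
  other subsites then carry no risk time and are dropped.
* **Tertiles** are cut at the sex-specific subcohort 1/3 and 2/3
  quantiles; boundary values fall to the lower tertile.  All individuals,
  cases included, are classified by the subcohort cuts.
* **Reported person-time** is the summed follow-up of subcohort members
  in the stratum — the case-cohort estimate of cohort person-time at
  risk.
* **Interaction tests** use tertile-coded score terms (matching the
  stratified presentation): one pooled model with exposure dummies,
  tertile dummies and all products, and a joint robust Wald test on the
  products.  Empty exposure-by-stratum cells reduce the df and are
  logged.  Calibration: ~5% rejection under homogeneous exposure effects;
  power > 50% for an effect of log HR 0.5 confined to one tertile at
  n = 20,000.
* **Gene-based FDR** pools each gene's SNP x sex p-values (the pooling
  unit is configurable), applies Benjamini-Hochberg step-up at q = 0.20,
  and declares significance only when the raw p is also below 0.05.

## Genotype QC

* **HWE** uses the exact conditional test (probability-ordered two-sided
  sum given the minor-allele count) because small genotype classes occur
  at panel scale; violations are flagged, never excluded, mirroring the
  flag-only policy of the source design.
* **LD r²** comes from EM over the double-heterozygote phase ambiguity,
  single deterministic start at linkage equilibrium.  The EM stop is on
  haplotype-frequency movement (< 1e-13, up to 50,000 cheap iterations)
  rather than log-likelihood change: EM converges linearly and the
  likelihood flattens well before the frequencies settle, which would
  otherwise cost ~1e-3 accuracy in r².  Monomorphic pairs are undefined,
  flagged, and treated as r² = 0 for pruning.  LD is computed on all
  analysis individuals pairwise-complete.

## Pathway ranking

Relative betweenness centrality on the undirected interaction graph via
Brandes accumulation (networkx), normalized by (n−1)(n−2)/2 to [0, 1];
graphs with fewer than 3 nodes return all-zero centralities by convention
(degenerate normalizer).  Disconnected graphs are allowed — unreachable
pairs contribute nothing.  Ties in the ranking break lexicographically
(the source procedure states no rule).  The canonical input is a plain
two-column edge list; a best-effort KGML reader exists but KEGG
group/compound semantics are not resolved, so published top-k gene lists
are treated as fixtures, not reproduction targets.

## Synthetic data

The generator emulates the statistical skeleton of a prospective
case-cohort study of 55-69-year-olds with ~20 years of follow-up:

* **Genotypes.** Per LD block, two latent Gaussian haplotype vectors with
  exchangeable correlation `block_rho` (one-factor construction),
  thresholded at the Φ⁻¹(MAF) quantile and summed — Hardy-Weinberg holds
  marginally, within-block r² rises monotonically with `block_rho`
  (verified empirically; the mapping is not analytic), across-block r²
  decays to 0.  Default panel: 24 SNPs in 10 pathway genes, one block per
  gene, MAF 0.09-0.45.
* **Event times** are exponential with rate
  `baseline_hazard · exp(Σ β_j g_j + exposure terms)` — proportional
  hazards holds exactly, isolating estimator tests from misspecification.
  Defaults: baseline 0.0019/year, administrative censoring at 20.3 years
  (≈4% cumulative incidence), cohort 20,000 with subcohort 3,000 — a
  scaled-down version of the motivating design chosen so that a full
  pipeline run takes seconds.
* **Subsites** are multinomial among cases (proximal colon 0.360, distal
  colon 0.317, rectosigmoid 0.095, rectum 0.228).
* **Exposures and confounders** are drawn from simple parametric families
  with sex-specific parameters at cohort-typical values (BMI, height,
  clothing size, activity and smoking categories, alcohol, meat and
  energy intake); they are independent of genotypes unless configured
  otherwise, since the joint distribution is not characterized by the
  motivating study.
* **Missingness** is completely at random: a per-SNP base rate plus a
  small stratum of samples with elevated missingness that lands below the
  95% call-rate threshold.

What passing tests therefore show: the estimators recover the parameters
of *this* generative model (correct risk sets, weights, standardization,
FDR arithmetic) at realistic scale.  What they do not show: robustness to
population stratification, batch effects, informative missingness,
non-proportional hazards, or exposure-genotype dependence — none of which
the generator produces.

## Problem sizes used in the test suite

Oracle comparisons run at toy scale (≤ 8 nodes, 30 individuals, 6 rows).
Calibration and recovery studies run at 2,000-20,000-person cohorts with
100-300 replicates; Monte-Carlo acceptance bands are set a priori at 2.5
to 3 binomial SDs around the nominal value.
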