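# Methods

## Cohort model

Samples belong to one of four groups — healthy control, benign breast
disease, DCIS, invasive carcinoma — with the diagnostic clubbing
DCIS + invasive = cases, benign + control = controls.  Each marker is a
nonnegative measurement: plasma protein concentration (pg/ml) or an M/U
ratio (methylated over unmethylated MSP band intensity in cell-free
DNA, each band first normalised against a DNA-ladder reference; a U
intensity of 0 makes M/U +inf, which exceeds every cut-off).

The synthetic generator draws each marker from a log-normal law
parameterised by the per-group **median** m_g and a **log-scale SD**
σ_g: X = m_g · exp(σ_g Z).  The median parameterisation is chosen
because published summaries report medians with long right tails; a
log-normal is the simplest nonnegative right-skewed family matching
that shape.  Values under a per-marker **detection floor** are recorded
as 0, emulating analytes that fall below the assay's limit of
detection (the default WIF1 floor leaves roughly a third of samples at
0, matching the reported 30–40% below-detection rate for that
protein).  Each marker uses a substream keyed by (seed, marker name),
so adding a marker never perturbs the others.

Defaults: group medians of the 15 proteins follow the published plasma
medians; the three methylation markers use control/benign medians well
below 1 (0.28–0.42) and DCIS/invasive medians well above (2.2–3.4),
matching the group separation of the densitometric M/U read-out.  The
dispersions are **free choices, not estimates** — published tables give
medians and ranges but no scale parameter.  σ = 0.8 (proteins) and
σ = 0.6 (M/U) were fixed a priori as values a plasma-proteomics
practitioner would call realistic inter-individual spread.  A
consequence worth knowing: per-marker discrimination in the synthetic
cohort follows AUC = Φ(Δlog-median/(σ√2)) and does not reproduce any
specific published per-marker AUC (synthetic IL17B, for instance, is a
stronger marker than its real counterpart).  Passing tests therefore
demonstrate correctness of the pipeline's arithmetic and its operating
characteristics under the assumed structure, not field performance of
any real marker.

Optional covariates (stage, grade, nodal, metastasis, ER/PR/HER2, age,
menstrual status, cfDNA concentration) are sampled with frequencies
matching the case-group composition of the emulated study; M/U markers
of invasive cases are multiplied by `mu_stage_factor`^(stage − II)
(default 1.25), giving the monotone stage-methylation link without
moving the group median away from its configured value at the modal
stage.  Age-matching of cases and controls is not modelled.

## Expression screen

The three-class screen operates on log2 values with classes T/PN/AN
(study sizes 41/18/6).  Per gene, a one-way F-test across classes;
selection requires p strictly below the threshold (default 0.001) *and*
a largest pairwise class-mean difference of at least log2 of the fold
threshold, inclusive ("two-fold or higher"), with a 1e-9 tolerance so
an exactly-two-fold planted shift survives floating-point means.  Fold
changes are differences of class means of log2 values, i.e. ratios of
geometric means — the natural-scale convention is not documented in
the source analysis tooling, so the log-scale choice is this package's
documented decision.  A class with fewer than two samples is excluded
(no within-class variance); an all-constant gene receives p = 1.  No
multiplicity correction is applied, mirroring the original fixed-α
design; an FDR column can be added by the caller from the returned
p-values.  A stricter preset (p < 0.0001, 2.5-fold) reproduces the
more conservative shortlist variant.

Relative quantification: ΔCt = Ct_gene − mean(reference Cts)
(arithmetic mean on the Ct scale = geometric-mean normalisation on the
expression scale; the reference set is typically UBC + GAPDH), ΔΔCt
subtracts the calibrator-class mean ΔCt per gene (calibrator =
apparently-normal tissue), RQ = 2^−ΔΔCt.  Per-gene summaries use the
geometric mean of RQ with zeros excluded and counted.

## Group statistics

Median (range) summaries use the midpoint convention for even n.  The
two-sample comparison offers both a tie-corrected normal-approximation
rank-sum Z (midranks; variance correction Σ(t³−t)/(N(N−1))) and a Welch
t; published tables in this field sometimes label Z-valued columns as
t-tests, and the two-tailed p of a printed Z is always
p = 2(1 − Φ(|Z|)), which `two_tailed_p_from_z` reproduces to printed
precision.  Kruskal–Wallis is tie-corrected with a χ² reference on
k − 1 df; for two groups H = Z² (the suite checks this to < 2%).
Covariate associations use Welch t for two levels and one-way ANOVA for
three or more, reporting per-level mean ± SD; levels with fewer than
two samples are dropped with a warning.  Many plasma values sit at the
detection floor, hence the midrank/tie-correction choices.

## Panel construction

* **MAD cut-off**: threshold = median + k·MAD of the *pooled* cases and
  controls (the quoted procedure pools "across cases and controls");
  per-group pooling is available by passing the subset explicitly.
  The MAD is unscaled — no 1.4826 normal-consistency factor — because
  the cut-off is a robust location + spread offset, not a variance
  estimate.
* **Directions**: markers elevated in disease call positive above the
  threshold, suppressed markers positive below, same threshold
  arithmetic.  Note that median + k·MAD with a positive-below direction
  calls more than half of all samples positive; an OR fusion is
  therefore only sensible over up-regulated markers, and combinations
  mixing directions belong on the logistic path (this is visible in
  `analysis/04_protein_panel.py`).
* **Strictness**: every call uses strict inequality; a value exactly at
  the cut-off is negative (generalising the "greater than 1" scoring
  rule).  The M/U = cut-off case is not covered by the quoted rule;
  strict-greater is this package's documented choice.
* **Fusion**: any_positive (OR) — the unique simple rule consistent
  with a combined panel whose sensitivity exceeds, and specificity
  falls below, every constituent marker.  Probabilistic fusion lives in
  the diagnostics module as the logistic combined ROC.
* **Selection**: backward marker elimination maximising sensitivity;
  among removals that keep sensitivity, the one with the highest
  resulting specificity is taken (name order breaks exact ties, and any
  accepted removal shrinks the panel, covering the fewer-markers
  preference).  Removing a marker can only lower sensitivity and raise
  specificity under OR, so the procedure never returns a panel less
  sensitive than the full candidate set.  The term "leave one out" in
  this context means marker removal, **not** leave-one-out
  cross-validation, which is out of scope.

## Diagnostics

Confidence intervals are exact Clopper–Pearson in beta-quantile form:
lower = B(α/2; x, n−x+1), upper = B(1−α/2; x+1, n−x), fixed as the
default because published 100%-sensitivity rows match the closed form
(α/2)^(1/n) exactly (97.59% at n = 151, 94.64% at n = 67).  Display
rounding mirrors the published convention: whole-percent points,
two-decimal CI bounds.  Undefined metrics (no cases, or no controls)
raise — they are never silently 0.  Coverage of the exact interval is
conservative (≥ 95% by construction; ~97.8% at n = 73, p = 0.89).

ROC: full threshold sweep; AUC equals concordant-pair fraction with
ties ½ (checked against exhaustive pair counting).  The combined ROC
fits a logistic model by maximum likelihood (Newton/IRLS, relative
log-likelihood tolerance 1e-8, ≤ 100 iterations).  Complete separation
— the expected regime for strongly separated methylation panels — is
detected from the fitted probabilities and flagged; the coefficients
are then obtained from a weakly ridged refit purely to stabilise the
ranking, which leaves the AUC valid because AUC depends only on the
ordering.  Non-convergence without separation raises.

`evaluate_split` freezes cut-offs and marker selection on the training
set and applies them unchanged to the test set; the logistic model is
likewise fitted on the training set and test samples are scored with
the trained coefficients.  The suite asserts this hygiene by mutating
test values and confirming thresholds do not move.

## Problem sizes

The reference synthetic cohort uses the study-sized groups
203/37/16/202 with a 70/30 stratified split (~317 vs ~141 samples).
Monte-Carlo suites use 1,000 × 500-gene null matrices for screen
calibration, 200 seeded cohorts for the OR-panel closed-form check,
10,000 binomial draws for interval coverage, and 5 seeded 400-sample
cohorts against the exhaustive backward-search oracle — sizes chosen so
each estimate's Monte-Carlo error is small against the tolerance it is
tested at while the whole suite stays fast.

## Known limitations

* The log-normal + floor family cannot express bimodality or heavy
  contamination; real plasma panels show both.
* Marker draws are independent given the group; real proteins correlate
  (e.g. adipokines), so the independence closed form used to validate
  OR-panel arithmetic is a property of the generator, not of plasma.
* The backward elimination is greedy; it matches the best
  sensitivity-preserving removal path on the tested cohorts, but no
  global optimality over all subsets is claimed in general.
* Clinical covariates are sampled independently of each other given the
  group (no grade-stage correlation), and age-matching is not modelled.
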