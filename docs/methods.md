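# Methods

## Problem setting

The package targets case-control targeted metabolomics where the working
hypothesis is *metabolic heterogeneity*: no metabolite separates the whole
case group from controls, but small case subpopulations (a few percent
each) carry distinct metabolic phenotypes that push one or a few
metabolites — and hence many metabolite ratios — into a tail that controls
essentially never occupy. The analysis therefore looks for quantitative
*thresholds*, not mean shifts: a feature becomes a biomarker if some cutoff
isolates a subpopulation that is almost entirely cases.

## Preanalytical model

Plasma free hemoglobin marks hemolysis. Red-cell lysis releases purines,
so xanthine, urate and hypoxanthine are unreliable in hemolyzed plasma:
samples with hemoglobin > 600 mg/dL are removed entirely, and in the
300–600 mg/dL band only those three analytes are blanked. Samples whose
entire concentration row is missing model failed LC–MS/MS acquisitions and
are removed. Values below/above the validated quantification limits are
replaced by 0.9·LLOQ / 1.1·ULOQ; equality with a limit is *not* clipped
(the rules speak of values below/above the limits), which also makes
clipping idempotent. Every participant-level removal is a ledger entry and
`ExclusionLedger.reconcile` asserts n_in = n_out + n_excluded on every
pipeline run. Missing hemoglobin is treated as non-hemolyzed and logged
rather than excluded — a deliberate choice; the synthetic generator always
provides it.

## Feature space

Features are single metabolites and all unordered metabolite pairs as
ratios; three chronically low-abundance analytes (CMPF,
4-ethylphenylsulfate, dodecanedioate; > 90% of measurements below LLOQ)
are excluded from ratio generation, leaving C(51,2) = 1,275 ratios. Their
single features are kept but flagged, and the default screen drops them,
so 51 + 1,275 features are screened. All features are log2 transformed (a
ratio is a difference of logs) and standardized with the sample (n−1) SD
computed once on the full cohort. Standardization before or after the
screen is immaterial: every screening statistic is a function of ranks
only, a property the test suite asserts explicitly. Ratios are stored with
a lexicographic canonical ordering; the biomarker orientation (which
direction of the ratio is "high") is determined during screening and folded
into the display name, so reports read like `decanoylcarnitine/carnitine`
regardless of storage order.

Missing features (any missing constituent) are omitted pairwise by
consumers; where an algorithm needs complete data — the vectorized screen —
the per-feature median is imputed, and because the imputation is identical
for observed and permuted labels it cannot manufacture case enrichment.

## Threshold screen

For an oriented feature, candidate thresholds are the midpoints between
consecutive distinct sorted values plus a −∞ sentinel (everyone positive).
The selected threshold maximizes PMP = (cases above t)/(all above t)
subject to sensitivity = (cases above t)/(all cases) ≥ 0.045; ties break
to higher sensitivity, then larger threshold (a smaller, purer
subpopulation). "Exceeds" is strict. The implementation is an O(n log n)
cumulative scan over the sorted order; an exhaustive brute-force oracle in
the tests confirms exact equality of the constrained objective on random
instances up to n = 200, including heavy ties.

Acceptance requires three gates:

* **CV sensitivity ≥ 0.045 and CV PMP ≥ 0.90.** 4-fold stratified CV
  repeated 50 times (fast profile: 10). Strata are diagnosis × sex ×
  diagnosis-specific age terciles; strata smaller than the fold count are
  coarsened by dropping their last component (logged), never fatal.
  Thresholds are fit on each 75% training split and applied to the held-out
  25%; the means over all test folds are the gating quantities. Test folds
  with zero threshold-exceeders are dropped from the PMP mean (no 0/0 is
  fabricated) but keep their sensitivity of 0.
* **Permutation FDR.** The permutation statistic is the full-data
  constrained-PMP objective (infeasible → 0); labels are permuted
  uniformly, p = (1 + #{perm ≥ obs})/(n_perm + 1), and Benjamini–Hochberg
  at 0.1 is applied across the entire candidate set. Default n_perm is
  1,000, reducible for fast runs; note that with B permutations the
  smallest attainable p is 1/(B+1), so B must be large enough that
  BH at α over m features can reject at all (BH needs ≥ α⁻¹·m·p_min
  features at the floor; with m ≈ 1,326 and α = 0.1, B = 199 makes
  acceptance a knife-edge while B ≥ 499 does not — the recovery tests use
  499 for this reason).
* **Both orientations** are scanned and the better full-data objective
  fixes the feature's orientation before CV and permutation.

Final thresholds are refit on the entire cohort, and thresholds are
reported both on the standardized scale and back-transformed to the raw
concentration-ratio scale. Binary profiles score a participant positive on
strict exceedance; a missing constituent scores negative (logged).

## Clustering into metabolic phenotypes

Biomarkers are the clustered objects; their pairwise distance is the
Jaccard distance between positive-participant sets, computed over
participants identified by ≥ 1 biomarker. Complete-linkage trees are cut
at every k in 5–50 (truncated for small biomarker sets) and the k with the
maximum average silhouette width wins, ties to the smallest k; identical
objects that cannot be split yield the degenerate single-cluster cut with
a warning. Per-cluster summaries report %ASD (cases identified by ≥ 1
member biomarker over all cases) and PMP (case fraction among everyone
flagged by the cluster).

Fold changes are mean raw concentration in cluster-positive over
cluster-negative participants, computed **within the case group** by
default (`scope="all"` is available): the positive/negative contrast is
about which *cases* a phenotype identifies, and controls would dilute it.
Cluster grouping uses |1−r| Pearson distances on *log2* fold-change
vectors (symmetric in up/down changes), pairwise-complete over metabolites,
cut at a configurable group count (default 7). Primary-cluster assignment
gives each identified participant the cluster holding most of their
positive biomarkers; ties break to the cluster with higher %ASD, then the
lower cluster id; all-negative participants are unassigned.

## Panel stacking

Accepted biomarkers are individually specific but insensitive; the panel
declares a participant positive when any member is positive. Greedy
forward selection adds, at each step, the candidate with the largest
resulting panel sensitivity among those keeping specificity ≥ 0.90 (ties:
higher resulting specificity, then earliest candidate), stopping when no
admissible candidate adds sensitivity. The spec of the underlying study
method is not algorithmic, so greedy-with-guard is this package's
documented interpretation; an exhaustive subset search (≤ 20 candidates)
is included, and the tests quantify the greedy gap on random instances in
the method's operating regime (member tests with ≥ 98% individual
specificity): greedy reaches ≥ 90% of the exhaustive optimum in ≥ 95% of
trials. Panel performance is reported as a full-cohort fit; an out-of-fold
evaluation can be run by rescreening on training folds.

## Association statistics

Partial Spearman correlation (mid-ranks, first-order partial formula, t
approximation with n−3 df, age as default covariate) for continuous
against continuous; Kruskal–Wallis with rank η² = (H−k+1)/(n−k) for
continuous against categorical, with Wilcoxon rank-sum post hocs (effect
r = |Z|/√n, tie-corrected normal approximation); Welch t with Cohen's d
standardized by the root-mean of the two variances (consistent with
Welch's unequal-variance stance) for binary-status contrasts; Fisher exact
with Haldane-corrected odds ratios for 2×2 and Monte-Carlo exact p (tables
sampled under fixed margins, statistic = table probability) with
Bergsma bias-corrected Cramér's V for 2×K. Metadata variables with > 10%
missing among cases or > 98% identical responses are dropped before
testing. BH adjustment is applied within each analysis suite — the family
is the suite, a documented choice — and significance is reported at
adj. p < 0.1. Cases with zero positive biomarkers enter the cluster-count
analyses with count 0 rather than being dropped: burden zero is a real
observation and the contrast gains power.

## Synthetic cohort generator

The generator exists to reproduce the *statistical shape* of the study,
not its biology. Defaults: 499 cases / 209 controls; ages 35.1 ± 7.8 vs
32.6 ± 8.7 months clipped to 18–48; 79% vs 59% male; race, BMI, MSEL and
ADOS-2 marginals from the study's demographic table. Concentrations are
block-correlated multivariate normal on the log2 scale around typical
pediatric plasma values (µM), exponentiated; within-block correlations
(BCAAs 0.6, lactate/pyruvate 0.5, TCA 0.4, purines 0.5, acylcarnitine
chains 0.6, indoles 0.4) and per-metabolite log2 SDs (0.30 amino acids,
0.35 organic acids, 0.45 acylcarnitines, 0.8 microbiome-derived; ≈ CV
20–35% for endogenous analytes) are plausible fabrications — no real
cohort covariance is published — chosen so that a planted 1.0–1.5 log2
case-only shift at 5–12% prevalence produces exactly the phenomenon the
method targets: threshold subpopulations that are 90–100% cases at 4.5–11%
sensitivity. Wider dispersions (CV ≥ 40%) make that phenomenon physically
unattainable (the noncarrier tail caps PMP near 0.9 even for a perfectly
placed threshold), which is why the defaults sit at the tighter, targeted-
assay-realistic end.

Six default phenotypes span the panel's compound classes (lactate+pyruvate
↑, carnitine ↓, BCAAs ↓, glycine ↑, purines ↑, medium-chain
acylcarnitines ↑) with case prevalences 6–12% and control contamination
≤ 1%; two share a latent "bioenergetics" carrier state (agreement 0.7) so
phenotype memberships can co-occur. Assay limits sit at the 10⁻⁵ /
1−10⁻⁵ quantiles of each baseline distribution — a validated assay spans
pathological excursions, so typical samples essentially never censor —
except the three low-abundance metabolites whose LLOQ sits at the 92nd
percentile, exercising the low-clip path heavily. Hemoglobin follows a
mixture (95% U[0,100], 4% U[300,600], 1% U[600,1200]) and samples above
300 mg/dL get a +1.5 log2 purine contamination shift, so the hemolysis
filter has a real measurable effect. Cells go missing completely at random
at rate 0.01.

Behavioral scores shift linearly with the number of phenotypes carried:
DQ −7.0 points and MSEL subscales −4.0 points per phenotype, overall and
social-affect ADOS severity +0.7 (restricted-repetitive behavior is
deliberately unlinked). These slopes are calibrated so that the *measured*
rank correlation between the discovered biomarker-cluster count and DQ
lands near −0.13 to −0.16 at default scale: the discovered count is an
attenuated proxy for the true carried count (attenuation ≈ 0.5–0.6 — false
positives in non-carriers, missed carriers, clusters not mapping 1:1 to
phenotypes), so the slope on the true count must overshoot the target
correlation by roughly the inverse attenuation.

What the generator does **not** emulate: real metabolite covariance
(fabricated blocks), diet/medication causal structure, batch effects,
longitudinal sampling, or non-log-normal tails. Passing recovery tests
therefore demonstrate that the *pipeline* finds what it is designed to
find under its own assumptions — not that the biological findings of any
study are correct.

## Problem sizes and numerical choices

Simulation-based tests run a reduced profile — 10 CV repeats and 199
permutations (499 where BH resolution requires it, see above) over the
full 51+1,275-feature space at full cohort size, 20 seeds per suite —
chosen as the smallest sizes at which the monitored quantities are stable;
the library defaults remain 50 repeats / 1,000 permutations. Tie-breaks
everywhere are deterministic (documented above), all randomness flows
through seeded NumPy generators, and a fixed seed reproduces every output
byte-for-byte. Degenerate inputs (constant features, empty clusters,
all-negative participants, zero-positive biomarkers, undefined
correlations) take defined paths — drop with warning, distance-1
convention, exclusion — rather than NaNs.

## Known limitations

* The permutation statistic saturates under the null for very small
  cohorts (the 4.5% floor then admits 1–2-participant subpopulations), so
  p-values are only well-behaved at a few hundred participants and above.
* Orientation is chosen on the full cohort before cross-validation (as is
  the full-cohort standardization); both are rank-invariant or
  near-immaterial for the gating statistics, but a fully nested CV would
  re-orient per fold.
* The greedy panel is not optimal; the exhaustive mode quantifies the gap
  only up to 20 candidates.
* Fold-change-based cluster grouping inherits the instability of
  pairwise-complete correlations when clusters identify few participants.
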