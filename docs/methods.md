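# Methods

This note records the models, conventions and design choices behind
`matrisig`, what the synthetic-data generators do and do not emulate, and
the package's known limitations.

## Input model and missingness

Protein-level quantification tables carry one non-negative intensity per
protein and sample (total precursor ion / LFQ intensity, arbitrary units),
a distinct-peptide count and a protein-level FDR per protein, and a design
map sample → (model, tumor type, replicate). Both an empty cell and a
literal 0 are treated as "not detected" and stored as NaN: LFQ software
reports zeros for absent proteins, and a measured zero intensity is not
meaningful on this scale. This single convention makes the detection rule
well defined downstream. Gene symbols are matched case-insensitively after
trimming; multi-ID cells (`Col1a1;Col1a1-ps`) keep the first token. Writers
round-trip values to 6 significant digits and preserve the missingness mask
exactly.

## Matrisome annotation

The matrisome reference maps gene symbols to a division (core matrisome /
matrisome-associated) and one of six categories; the division↔category
consistency is enforced at load time. Proteins absent from the reference are
non-matrisome by contract — annotation never fails, and matrisome +
non-matrisome always partition the input. The packaged reference
(`data/matrisome_subset.tsv`, ~100 genes) is a curated convenience subset
covering all six categories; real analyses should supply the full
species-specific matrisome list. Agrin (Agrn) is recorded as a core
matrisome proteoglycan; where narrative sources and list sources disagree
on a gene's category, the reference file is authoritative.

## Detection profiles

Identification filters retain a protein iff peptide_count ≥ 2 AND
protein FDR < 0.01 (strict inequality, configurable). Detection in a sample
means a non-missing filtered intensity — per-sample peptide evidence is not
available in protein-level tables, so no per-sample peptide threshold is
applied. A model profile contains the matrisome-annotated proteins detected
in ≥ k of the model's n replicates (default 3 of 5; the rule is "≥ k of the
available n", so unequal replicate numbers are supported). A tumor-type
profile is the intersection of its two model profiles. Annotation order
(before vs after the replicate rule) does not change the result; we
annotate first. Profiles are monotone: increasing k or the peptide
threshold never grows them.

## Signatures and differential abundance

Signatures are computed by set algebra on uppercase gene symbols (the unit
in which ECM signatures are reported), giving shared = lo ∩ hi and the two
exclusive sets, with per-category summaries. For quantification, each
sample's intensities are rescaled so per-sample totals equal the median raw
sample sum ("total_sum"); a DESeq-style median-ratio option and an identity
option exist. Shared proteins are compared between tumor types with an
unpaired two-sided Student t test (pooled variance; Welch optional) on the
raw normalized scale — matching total-precursor-intensity practice — with a
log2 option. A protein needs ≥ 2 non-missing values per group; no
imputation is performed, and untestable proteins are reported separately.
Calls use p < 0.05 together with a ±20% abundance change (hi/lo ratio
≥ 1.2 or ≤ 0.8, read literally as ±20% of the reference mean; the
log-symmetric alternative ≤ 1/1.2 is available via the thresholds). No
multiple-testing correction enters the calls — the volcano convention —
but a Benjamini–Hochberg q column is emitted for transparency. Combined
signatures are the union of a type's exclusive set with the differential
proteins called toward it, with per-protein source tags.

## ssGSEA

The single-sample enrichment score follows the summed weighted-ECDF-
difference convention (not a running-maximum deviation): within each
sample, genes get tie-averaged ascending ranks r_g; walking down the
descending ranking, the running ECDF of set members weighted by r^α
(α = 0.25 by default) is compared with the unweighted ECDF of non-members
and the differences are summed. Tie groups advance both ECDFs linearly
across their positions, which makes an all-constant sample score exactly
zero and keeps the score invariant under any strictly monotone per-sample
transform. With these conventions the sum collapses to the closed form
used in the implementation; the test suite verifies it against a direct
position-walk oracle to 1e-9. Normalization divides the score vector by its
range (max − min) across the samples of the current matrix; it is
meaningless for a single sample and should then be disabled. Because the
score is a within-sample rank statistic, it is weakly compositional: large
co-regulated gene groups depress the ranks (and hence scores) of unrelated
sets. On transcriptome-scale matrices the effect is negligible; on small
matrices it is visible (see the generator defaults below).

Pathway overrepresentation is a one-sided hypergeometric tail
P[X ≥ k] of the query/annotation overlap within an explicit user-supplied
universe — an offline, database-free replacement for web-service enrichment.

## Survival models

Quartile stratification labels patients high (value ≥ Q3) or low
(value ≤ Q1), excluding the middle half from two-group contrasts; quartiles
use the linear-interpolation quantile rule (R type 7) with inclusive
boundaries, a convention choice the results are robust to except at tiny n.
Kaplan–Meier estimation is the product-limit formula, with subjects
censored at an event time at risk through that time; with no censoring it
equals one minus the empirical CDF exactly. The log-rank test accumulates
per-group observed-minus-expected event counts with hypergeometric
variances at each distinct event time (k-group form, chi-square with k − 1
df). The Cox model maximizes the partial likelihood by Newton–Raphson with
step-halving (the log partial likelihood never decreases across accepted
iterations), Efron tie correction by default (Breslow optional; they agree
exactly on tie-free data), Wald standard errors from the observed
information, convergence and separation (|β| > 15) flags, and a guard
against collinear covariates. The standard downstream model is the
high-vs-low stratum indicator (low quartile = reference, coded 0) plus a
stromal-content covariate such as an expression-derived stromal score;
additional covariates can be passed explicitly. The composed analysis
(score → stratify → KM/log-rank/Cox) joins expression and clinical tables
on sample identifiers and requires ≥ 8 joined patients.

## Synthetic data: what it emulates, and what it does not

`simulate_proteomics` emulates a 4-model × 5-replicate label-free design
(two models per tumor type). Per-protein baseline log10 intensities are
N(6.5, 0.7); replicates add N(0, 0.1) (≈ 26% CV). Planted structure:
114 shared matrisome proteins (5 + 7 of them with 2-fold planted changes,
favoring cold and hot respectively), 16 cold-exclusive and 8 hot-exclusive
proteins (detection probability p_in = 0.9 in their own type, p_out = 0.05
in the other, per the type-exclusive contract), per-model-specific proteins
(20 per cold model, 28 per hot model) sized so each sample carries ~150
matrisome proteins with ~60% core-matrisome share, and 250 non-matrisome
background proteins. Missingness is logistic in log10 intensity
(midpoint 4.0, slope 3.0) — missing-not-at-random, the standard LFQ
behavior — which leaves proteins a decade above the detection limit as
near-certain detections while low-intensity proteins drop out. Named
planted genes are real matrisome genes with their curated categories;
fillers are synthetic symbols. Ground truth is always available as a
manifest so tests never re-derive it. `paper_shaped_config()` is the
deterministic verification limit of the same scenario (p_in = 1, p_out = 0,
no dropout, replicate noise 0.02 log10) in which the planted profile,
signature and combined-signature counts are recovered exactly.

The generator does **not** emulate peptide-level evidence, shared-peptide
protein grouping, match-between-runs, batch effects, or intensity-dependent
variance heterogeneity. Passing tests therefore demonstrate the
correctness of the statistical chain on data satisfying its assumptions,
not robustness to every artifact of real LFQ data.

`simulate_expression_cohort` draws one latent infiltration factor per
sample; hot-signature and CTL genes load on it (default loading 0.6,
unit noise), cold-signature and background genes are independent with the
same marginal variance. The analytic score correlation
λ² / √((λ² + σ²/m₁)(λ² + σ²/m₂)) is exposed for recovery tests. The
default background is 2000 genes: with a small background the rank-score
compositionality described above drives a spurious negative cold–CTL
correlation; at transcriptome scale it shrinks to ≲ 0.05, matching the
regime the analytic value describes.

`simulate_survival_cohort` draws times from an exponential
proportional-hazards model: hazard = rate · exp(β_high · 1[latent ≥ Q3] +
β_stromal · stromal), with independent exponential censoring (defaults
give ~30% censoring). With `with_expression`, signature genes load
strongly on the latent score so the composed scoring analysis can be
tested; its fitted hazard ratio is mildly attenuated (≈ 10% on the log
scale) relative to the planted value because quartile boundaries computed
on the noisy score misclassify a few boundary patients relative to the
latent driver — an inherent property of score-dichotomized designs, not an
estimation bias of the Cox fit itself (the fit on the true indicator is
unbiased, with ~95% CI coverage).

## Problem sizes and numerical choices

The test suite and acceptance script use: 20 seeds of the default
proteomics generator for signature recovery; 30 random fixtures (≤ 50
genes × 10 samples) for the ssGSEA oracle; 1,000 null replicates (n = 60)
for log-rank type-I-error calibration; 200 replicates at n = 400 for Cox
CI coverage; and 10 replicate cohorts (n = 200 / n = 400) for the
correlation and hazard recoveries — sizes at which the binomial noise of
each calibration estimate is well inside the asserted tolerances. Newton
iterations cap at 100 with tolerance 1e-9 on the step; t statistics and
hypergeometric tails come from scipy; BH q-values from statsmodels. All
randomness flows through `numpy.random.default_rng` seeds; identical seeds
give bit-identical outputs.

## Known limitations

- Protein inference, peptide FDR modeling and quantification upstream of
  the protein table are out of scope; the pipeline starts at protein-level
  tables.
- The packaged matrisome reference is a curated subset, not the full
  matrisome of any species.
- Signature gene sets are bridged between species by case-normalized
  symbol equality unless the user supplies an orthology map.
- The ssGSEA score range normalization is dataset-relative; scores are not
  comparable across matrices.
- The Cox implementation covers fixed covariates only — no time-varying
  covariates, stratified baselines, penalization or competing risks.
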