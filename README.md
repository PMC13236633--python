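# matrisig

Matrisome signature analysis for label-free tumor ECM proteomics.

Tumors with low ("cold", CD8^lo) versus high ("hot", CD8^hi) cytotoxic
T-lymphocyte infiltration assemble different extracellular matrices.
`matrisig` implements the analysis chain that turns protein-level label-free
quantification (LFQ / total precursor ion intensity) tables from such an
experiment into ECM protein signatures and their downstream clinical
read-outs:

1. **Matrisome annotation** — classify each protein into the two matrisome
   divisions (core matrisome: ECM glycoproteins, collagens, proteoglycans;
   matrisome-associated: ECM-affiliated proteins, ECM regulators, secreted
   factors) from a user-supplied reference list.
2. **Detection profiles** — apply identification filters (≥ 2 peptides,
   protein FDR < 1%) and the *k-of-n* replicate rule (default: detected in
   ≥ 3 of 5 biological replicates) per tumor model; intersect the two models
   of each tumor type to obtain type-level matrisome profiles.
3. **Signatures** — set algebra between the two type profiles: shared
   matrisome, type-exclusive signatures, per-category summaries.
4. **Differential abundance** — total-sum normalization, unpaired Student
   *t* tests on the shared proteins, volcano calls at *p* < 0.05 and ±20%
   abundance change; combined signatures = exclusive ∪ differential.
5. **ssGSEA scoring** — single-sample gene-set enrichment (summed weighted
   ECDF difference, exponent α = 0.25) of expression cohorts, and Spearman
   correlation of signature scores against a cytotoxic-lymphocyte (CTL)
   gene set; a generic hypergeometric overrepresentation test.
6. **Survival analysis** — quartile stratification (upper vs lower quartile,
   middle half excluded), Kaplan–Meier product-limit curves, the log-rank
   test, and Cox proportional-hazards fits (Newton–Raphson partial
   likelihood, Efron or Breslow ties) with a stromal-content adjustment
   covariate — all implemented from their defining formulas, with
   `lifelines` used only as an independent cross-check in the test suite.

A seeded synthetic-data generator (`matrisig.simulate`) emulates the
4-model × 5-replicate experimental design with planted type-exclusive
proteins, planted fold changes and missing-not-at-random dropout, plus
expression and survival cohorts with known ground truth, so every stage is
testable without any external download.

## The statistics in brief

For sample *s* and gene set *S* (|S| = m of N genes), with tie-averaged
expression ranks r_g, the ssGSEA score is the summed difference between the
weighted in-set ECDF and the unweighted out-of-set ECDF along the ranking,
which collapses to

    ES(s, S) = Σ_{g∈S} r_g^α · r_g / Σ_{g∈S} r_g^α  −  Σ_{g∉S} r_g / (N − m)

The Cox model maximizes the partial likelihood
L(β) = Π_events exp(x_iβ) / Σ_{j∈R(t_i)} exp(x_jβ) (Efron correction on
ties) by Newton–Raphson with step-halving; hazard ratios are exp(β) with
Wald tests. The log-rank statistic sums observed-minus-expected event counts
with hypergeometric variances at each distinct event time.

## Worked example

Generate a planted study-shaped experiment (20 samples; 114 shared
matrisome proteins, 16 cold-exclusive, 8 hot-exclusive, 5 + 7 planted fold
changes) and run the full pipeline:

```sh
matrisig simulate --seed 17 --config sim_cfg.yaml --out sim/
matrisig run-all --config config.yaml
```

where `sim_cfg.yaml` selects the deterministic-detection scenario
(`deterministic_detection: true`, `p_in: 1.0`, `p_out: 0.0`,
`replicate_sd_log10: 0.02`) and `config.yaml` points the pipeline at the
emitted `quant.tsv`, `design.json` and `matrisome_reference.tsv`. Output:

```json
{
  "profile_lo": 130,
  "profile_hi": 122,
  "shared": 114,
  "exclusive_lo": 16,
  "exclusive_hi": 8,
  "combined_lo": 21,
  "combined_hi": 15
}
```

Reading: 130 matrisome proteins pass the 3-of-5 rule in both cold models
and 122 in both hot models; 114 are shared between the tumor types, leaving
a 16-protein cold-exclusive and an 8-protein hot-exclusive signature; adding
the differentially abundant shared proteins (5 up in cold, 7 up in hot)
yields the 21- and 15-protein combined signatures — exactly the planted
ground truth written beside the data in `ground_truth.json`.

Downstream, score a synthetic patient cohort with a signature gene set and
test its effect on survival (planted hazard ratio 2.0 for upper- vs
lower-quartile scorers, stromal-score-adjusted):

```python
import numpy as np
from matrisig import simulate_survival_cohort, signature_score_survival

clin, expr, gene_set, truth = simulate_survival_cohort(
    n=400, beta_high=np.log(2.0), beta_stromal=0.3, seed=12,
    with_expression=True)
res = signature_score_survival(expr, gene_set, clin)
print(res.cox.summary().round(3))
```

```
                coef     HR  se(coef)      z      p  HR lower 95%  HR upper 95%
score_high     0.586  1.797     0.168  3.485  0.000         1.292         2.498
stromal_score  0.237  1.267     0.079  2.987  0.003         1.085         1.480
log-rank chi2=10.61, df=1, p=1.13e-03
```

The fitted hazard ratio for high- vs low-score patients (1.80, 95% CI
1.29–2.50) recovers the planted 2.0, mildly attenuated by quartile-boundary
misclassification between the noisy enrichment score and the latent driver.

## Layout

- `matrisig.io` — domain types and TSV/GMT/clinical readers and writers
  (generic and proteinGroups quantification dialects)
- `matrisig.annotation`, `matrisig.detection`, `matrisig.signatures`,
  `matrisig.diffabund` — the proteomic signature chain
- `matrisig.enrichment`, `matrisig.survival` — ssGSEA and survival models
- `matrisig.simulate` — seeded generators with ground-truth manifests
- `matrisig.pipeline`, `matrisig.cli` — orchestration and the `matrisig`
  command (`simulate`, `annotate`, `profile`, `signatures`, `diffabund`,
  `score`, `survive`, `run-all`)

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
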