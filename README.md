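# synergybench

A tested, reusable pipeline for analysing drug-combination viability screens:

- **`dose_response`** — Hill-curve monotherapy fits, Loewe-additive reference
  surfaces (bisection solve of `a/D_A(E) + b/D_B(E) = 1`), synergy
  distributions, and a single area-normalised log-space synergy score capped
  to ±100 (≥ 20 synergistic, ≤ −20 antagonistic).
- **`challenge_metrics`** (`synergybench.metrics`) — community-benchmark
  scoring: weighted Pearson across combinations with its synergy-subset
  tie-break, signed sequential three-way ANOVA for binary predictions with
  balanced-accuracy tie-break, paired-bootstrap Bayes factors, within-cell-
  line permutation nulls, replicate upper bounds, better-than-random calls
  at a fixed FDR, and per-combination predictability classes.
- **`ensembles`** — label-free spectral meta-learner (covariance-eigenvector
  performance estimates + weighted vote) and random equal-weight aggregation.
- **`biomarkers`** — extended binary event matrices (deletion / >7-copy
  amplification / any mutation), Wilcoxon rank-sum monotherapy-resistance
  associations, threshold-stringency synergy-enrichment curves with 5×80%
  bootstrap bands, tissue-corrected ANOVA synergy biomarkers with BH
  correction, and directionality validation on independent tables.
- **`response_classes`** — PDX best-response coding (CR=4 … PD=1),
  combination-benefit classes versus the better monotherapy (±2 thresholds),
  and per-combination synergy-rate concordance between PDX and cell lines.
- **`synthdata`** — fully seeded generators for every input: cell-line
  panels with binary event matrices, drug libraries, sparse screen designs,
  Loewe-additive 6×6 surfaces with calibrated synergy bumps and optional
  biomarker coupling, teams of controllable skill, challenge-style data
  splits, and PDX cohorts.
- **`interface`** — long-format CSV I/O with validation, YAML run
  configuration, and an end-to-end pipeline driver with a machine-readable
  manifest.

## CLI

```sh
synergybench run-all --seed 1 --out run1            # full pipeline
synergybench simulate --seed 1 --out run1           # generators only
synergybench score-surfaces run1/screen.csv --out synergy.csv
synergybench score-teams run1/predictions.csv run1/synergy.csv
synergybench ensemble run1/predictions.csv
synergybench biomarkers run1/monotherapy_response.csv run1/synergy.csv run1/bem.csv
synergybench pdx run1/pdx_classes.csv --synergy run1/synergy.csv
```

Subcommands compose to the same results as `run-all`. All randomness flows
from a single root seed through stage-named substreams, so identical
configurations give byte-identical outputs. A YAML config (see
`synergybench.interface.RunConfig` for keys and defaults) can be passed with
`--config`; analysis thresholds default to the published values (synergy 20,
cap 100, Bayes-factor cutoff 5, FDR 0.05, enrichment grid step 0.1, 1000
bootstrap iterations, 5×80% enrichment bootstrap).

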