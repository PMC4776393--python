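# embryosel

Morphometric embryo scoring and implantation prediction for single-embryo
transfer: derive computer-assisted (CASS) features from blastomere diameter
measurements, fit and validate logistic-regression and adaptive
regression-spline (MARS) models of clinical pregnancy, evaluate them with
ROC/AUC and agreement statistics, and rank embryos per patient. A synthetic
cohort generator with volume-conserving embryo geometry and known outcome
models stands in for clinical data, so the whole pipeline is testable end
to end.

## What's inside

| Module | Purpose |
| --- | --- |
| `embryosel.morphometry` | Diameter measurements → feature set: total cytoplasmic volume (sphere model), size-diversity ratio (COD), volume-loss fragmentation, counts, Day-2 parity, transformed Day-3 count \|n − 8.4\| |
| `embryosel.cohort` | Clinical covariate encodings, SSS visual grades, model-ready feature tables, univariate logistic screen (p < 0.3), KS test, cohort bookkeeping |
| `embryosel.lr_model` | IRLS logistic regression with two-way products, likelihood-ratio backward elimination (p < 0.1, hierarchy-aware), and the fixed published 12-coefficient scoring equation |
| `embryosel.mars` | From-scratch MARS: reflected hinge-pair forward pass, GCV backward pruning (penalty 3/knot), 10-fold CV, JSON serialization |
| `embryosel.evaluation` | ROC/AUC (Mann–Whitney with DeLong variance), paired/unpaired AUC comparison, grading bands, ICC(A,1), Cohen's kappa, condition-index/VIF collinearity diagnostics, mutual information |
| `embryosel.synthetic` | Seeded cohort simulation: volume-conserving geometry with explicit fragments, derived visual grades with mis-grading noise, logistic outcome models, recovery experiments |
| `embryosel.selection` | Per-patient embryo ranking and standard-vs-model decision comparison |
| `embryosel.pipeline` | The four-model experiment (LR/MARS × SSS/CASS) on separate training and validation cohorts |

## CLI

```bash
embryosel simulate --seed 1 --n-patients 200 --out scratch/cohort
embryosel features --measurements scratch/cohort_measurements.csv --out scratch/features.csv
embryosel fit-lr --features-csv scratch/features.csv --profiles scratch/cohort_profiles.csv \
    --screen-alpha 0.3 --removal-p 0.1 --out scratch/lr.csv
embryosel fit-mars --features-csv scratch/features.csv --profiles scratch/cohort_profiles.csv \
    --penalty 3 --folds 10 --seed 1 --out scratch/mars.json
embryosel evaluate --scores-csv scratch/scores.csv --out scratch/eval.json
embryosel run-experiment --config experiment.yaml --seed 1 --out scratch/report.json
```

All inputs and outputs are plain text (CSV with header, UTF-8, `.` decimal;
JSON reports; YAML configs). Per-day diameter lists are stored as
semicolon-separated µm values within one CSV cell.

## Notes

- Blastomeres are modelled as spheres; volume = (π/6)·d³.
- Objects ≥ 45 µm (Day 2) / ≥ 40 µm (Day 3) count as blastomeres; smaller
  objects are fragments.
- Fragmentation is the fractional reduction of total volume from Day 1,
  clamped at 0 (a warning reports apparent volume gain); the raw value is
  kept in a diagnostics field.
- The published scoring equation's TCV scale factor is configurable
  (default 10⁻⁵ per µm³) in `src/embryosel/data/published_lr.yaml`.
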