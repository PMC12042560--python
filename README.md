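# qmoaks

Quantitative per-subregion knee-cartilage scoring against a normative
thickness model, with the statistics needed to compare it to
semi-quantitative radiologist scoring: cross-sectional concordance
(cross-tabulations, tie-corrected Spearman correlation) and longitudinal
responsiveness (standardised response means with bootstrap confidence
intervals). A synthetic cohort generator provides controls, progressing
knees with focal lesions, and a simulated ordinal reader, so the whole
pipeline runs without any external data.

## What it computes

Given per-landmark cartilage thickness tables on a set of corresponded
bone-surface landmarks and an atlas assigning each landmark to one of
the ten tibiofemoral subregions (cMF, cLF, pMF, pLF, aMT, cMT, pMT,
aLT, cLT, pLT):

- a **normative model**: per-landmark mean thickness over a non-OA
  control cohort, with thinning defined as thickness < 95% of normative
  and denudation as < 5% (fractions configurable; an empirical
  per-landmark control-percentile mode is also available);
- per knee/visit/region the **area percentages** of thinning
  (`thqcm_pct`) and denudation (`dqcm_pct`), their **ordinal bands**
  (0: none, 1: 0–10%, 2: 10–75%, 3: >75%), and the area-weighted
  **mean regional thickness** (`thctab_mm`);
- **concordance statistics** against 0–3 reader scores: 4×4
  cross-tabulations, row-wise concordance proportions, midrank Spearman
  ρ with Fisher-z 95% CIs, and tidy boxplot-data export;
- **responsiveness**: change vectors over 1- and 2-year intervals
  (including within-grade ±0.5 reader change codes), SRM point
  estimates, and percentile-bootstrap CIs.

## CLI

All stages are exposed through a single entry point:

```sh
qmoaks simulate        --config config.json --out-dir out/
qmoaks normative-build --controls out/controls_thickness.csv \
                       --atlas out/atlas.csv --out out/model.json
qmoaks score           --thickness out/cohort_thickness.csv \
                       --atlas out/atlas.csv --model out/model.json \
                       --out out/qmoaks_results.csv
qmoaks concordance     --results out/qmoaks_results.csv \
                       --moaks out/moaks_scores.csv --out-dir out/
qmoaks responsiveness  --results out/qmoaks_results.csv \
                       --moaks out/moaks_scores.csv --out out/srm_table.csv
qmoaks run             --config config.json --out-dir out/   # all of the above
```

`qmoaks run` writes the cross-tabulation, correlation, boxplot-data and
SRM tables plus a manifest (seed, config hash, output list). Outputs are
byte-identical across reruns of the same config and seed. Exit codes:
0 success, 2 validation error, 1 runtime error.

A minimal config:

```json
{
  "seed": 7,
  "n_controls": 100,
  "n_progressors": 50,
  "visits": [0, 12, 24],
  "field":  {"grid_shape": [8, 8], "base_mean": 2.2, "noise_sd": 0.05},
  "lesion": {"region_probs": {"cMF": 0.6, "cMT": 0.4},
             "initial_depth_fraction": 0.4, "depth_growth_per_year": 0.2},
  "reader": {"overcall_bias": 0.1, "within_grade_sensitivity": 0.5},
  "n_boot": 1000
}
```

## File formats

Plain CSV with headers throughout:

| file | columns |
| --- | --- |
| atlas | `landmark_id,region[,area_weight]` |
| thickness (long) | `knee_id,visit_month,landmark_id,thickness_mm` |
| reader scores | `knee_id,visit_month,region,measure,score` |
| scored results | `knee_id,visit_month,region,thqcm_pct,dqcm_pct,thqcm_score,dqcm_score,thctab_mm` |

Reader scores are whole grades 0–3 at baseline; at follow-up the codes
+0.5 / −0.5 record within-grade worsening / improvement.

## Package layout

- `qmoaks.atlas` — subregion codes, atlas/thickness/score types and CSV I/O
- `qmoaks.cohort` — synthetic field, control and progressor generators, reader simulation
- `qmoaks.normative` — normative model construction and threshold rule
- `qmoaks.scoring` — landmark classification, area percentages, banding, regional thickness
- `qmoaks.concordance` — cross-tabulation, Spearman/CI, boxplot export
- `qmoaks.responsiveness` — change vectors, SRM, bootstrap CIs
- `qmoaks.cli` — the `qmoaks` command
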