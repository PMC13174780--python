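# titertime

Time-of-day structure in autoantibody titer data, as a reusable, tested
pipeline. Two study designs are covered:

* **Longitudinal (diurnal) design** — duplicate-assay titers per participant,
  drawn every 4 h over 24 h starting 09:00. Tools: participant z-scoring,
  daily ranges, diurnal CVs vs inter-assay CV, fixed-24-h-period cosinor
  rhythmometry (MESOR / amplitude / acrophase with zero-amplitude F-test and
  delta-method or subject-bootstrap acrophase CIs), expected-mean-squares
  variance components (between-subject / time-of-day / assay), and a
  bootstrap comparison of fixed-time vs random clinical-day sampling
  precision (restricted/random SD ratio).
* **Cross-sectional design** — one draw per participant at a recorded clock
  time. Tools: hour rounding, a deterministic depth-limited CART regression
  tree on ln titers over age and sampling hour, two-group ANOVA of subgroup
  mean ln titers with fold changes `exp(diff)`, detection rates with exact
  Clopper–Pearson intervals, Pearson chi-square detection comparison, and
  Spearman confounding checks.

Synthetic-data generators for both designs (`titertime.simulate`) produce
cosinor-structured panels and cohorts with planted age-band × time-of-day
effects, so every analysis stage is testable without external data.

## CLI

```sh
titertime simulate panel  --config cfg.yaml --out panel.csv  --seed 1
titertime simulate cohort --config cfg.yaml --out cohort.csv --seed 1
titertime diurnal summarize --panel panel.csv --config analytes.yaml --out summary.json
titertime cosinor fit --panel panel.csv --analyte GADA --zscore --out fit.json
titertime varcomp --panel panel.csv --analyte IA --out vc.json
titertime restrict --panel panel.csv --analyte GADA --time 13 --nboot 10000 --seed 17 --out restrict.json
titertime subgroups --cohort cohort.csv --analyte IA2A --out report.json
titertime run --config cfg.yaml --out-dir out/ --seed 3   # simulate + all analyses + manifest
```

Exit codes: 0 ok, 2 configuration error, 3 data error. `run` derives one
substream seed per stage from the top-level `--seed`, and writes a
`manifest.json` with config/input digests; deterministic stages are
byte-identical across reruns.

Config files are YAML. `simulate panel` reads a `panel:` mapping
(`n_subjects`, `schedule`, `n_replicates`, per-analyte `mesor`, `amplitude`,
`acrophase_h`, `between_subject_sd`, `tod_extra_sd`, `assay_cv_pct`);
`simulate cohort` reads a `cohort:` mapping (`n`, age-mixture and
time-of-day distribution parameters, `age_time_rho`, per-analyte
`baseline_ln`, `age_slope`, `noise_sd`, `threshold`, and `planted` effects
`{age_lo, age_hi, tod_cut, delta_ln}`). All fields have defaults; see
`titertime/simulate.py`.

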