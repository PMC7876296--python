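# carproc

Age-and-gender-adjusted statistical indicators of cardiac autonomic
regulation (CAR), and a nine-test non-parametric battery grading the evidence
that BMI-group transitions (normoweight → overweight → obese) alter them.

Starting from a subject-level table with demographics, BMI and 16 short-term
heart-rate- and blood-pressure-variability measures ("ANS proxies"), the
pipeline:

1. **adjusts** every proxy for age and gender (OLS residuals, optional log
   pre-transform for the right-skewed spectral powers);
2. fits a **maximum-likelihood factor analysis with varimax rotation** to the
   16 adjusted proxies, retains factors reproducing ≥ 10% of total variance
   and ≥ 15% of total communality, and interprets them against the reference
   sign pattern of four autonomic domains (oscillatory, amplitude, pressure,
   pulse);
3. re-expresses factor scores, the baroreflex α index and BMI as **midrank
   percentiles** on (0, 100) (`OSC_ind`, `AMP_ind`, `PRESS_ind`, `PUL_ind`,
   `alpha_aPRT`, `BMI_aPRT`) and builds the composite autonomic index
   **ANSI** from RR Mean, RR TP and ΔRR LFnu (higher = better);
4. runs, per indicator, a **battery of 9 non-parametric tests**: Kruskal-
   Wallis, three pairwise bootstrap median tests, three pairwise kernel-
   density equality tests (Bonferroni α = 0.05/3), Jonckheere-Terpstra and
   Hettmansperger-Norton (pseudorank) trend tests against the ordered
   monotone alternative;
5. maps each battery onto a **six-level evidence grade** (strong,
   almost-strong, medium-strong, medium, weak, insignificant) and renders a
   synoptic summary.

A seeded synthetic-cohort generator with planted latent structure (four
orthogonal domains, configurable group shifts, age/gender effects, monotone
range-preserving links) makes every stage testable without clinical data.

## CLI

```bash
carproc simulate --n 756 --seed 1 --out cohort.csv
carproc adjust --in cohort.csv --model-out adj.json --out adjusted.csv
carproc indicators --in cohort.csv --efa-model-out efa.json --out indicators.csv
carproc battery --in indicators.csv --seed 1 --out battery.csv
carproc grade --in battery.csv --out synoptic.csv
carproc run --seed 1 --out report/ --figures   # full pipeline in one step
```

`carproc run` writes per-stage CSVs (cohort, indicators, battery results,
synoptic table, median CIs, notches, correlation matrices), serialized
adjustment/factor models, a provenance block (config hash, seed, versions)
and, with `--figures`, notched box panels, density panels with reference
bands, and a correlation plot.

## Python API

```python
from carproc import (default_config, generate_cohort, fit_adjustment, adjust,
                     run_pipeline, PipelineConfig)

cohort, truth = generate_cohort(default_config(seed=1, n_total=756))
report = run_pipeline(PipelineConfig(source="simulate", seed=1))
print(report.synoptic[["concordant", "grade"]])
```

## Layout

```
src/carproc/
  proxies.py     # canonical proxy metadata: names, units, ranges, domains
  reference.py   # reference cohort demographics (per-group cells)
  synthetic.py   # seeded cohort generator with planted ground truth
  adjustment.py  # BMI groups, OLS age/gender adjustment, percentile ranks
  factors.py     # ML factor analysis, varimax, retention, labels, ANSI
  nptests.py     # KW, bootstrap median, kernel-density, JT, HN, battery
  grading.py     # six-level evidence taxonomy, synoptic table
  pipeline.py    # end-to-end orchestration and report files
  plots.py       # figures
  cli.py         # typer CLI
tests/           # unit, property and oracle tests + tests/test_acceptance.py
scripts/acceptance.py
```
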