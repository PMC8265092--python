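# clustersim

Monte-Carlo machinery for studying what happens when linear regression
ignores clustering. Epidemiological and clinical datasets are often
grouped into clusters (study centres, practices, schools) whose outcomes
remain correlated after the explanatory variable is accounted for, yet
cluster-unadjusted ordinary least squares (OLS) is still widely used on
such data. `clustersim` generates clustered data from a random-intercept
model, fits both the cluster-unadjusted OLS model and the random-intercept
(RI) linear mixed model to every sample, and measures the damage: bias of
the slope, relative precision (SE_RI/SE_OLS), coverage of 95% confidence
intervals, and Type I error.

It is aimed at biostatisticians and methods researchers who want a
reproducible, scriptable version of this simulation design — at full
scale (100,000 replicates per scenario) or desk scale (minutes).

## Model

Samples follow the random-intercept specification on a balanced design of
100 clusters × 100 observations:

    y_ij = β0 + β1 x_ij + u_j + e_ij,     u_j ~ N(0, SD_u²),  e_ij ~ N(0, SD_e²)

with the intraclass correlation ICC = SD_u²/(SD_u² + SD_e²) controlled on
a six-point grid (0.001 … 0.3) by acceptance-rejection on the sample ICC.
The explanatory variable is continuous (x_ij = N(0,1) + cluster shift,
shift SD ~ U[0,20]) or binary (cluster prevalences = target prevalence ∈
{0.05, 0.1, 0.2, 0.4} plus a shift with SD ~ U[0,0.05]), so the degree of
clustering of **x** varies independently of the clustering of the
outcome. The RI fitter is an exact maximum-likelihood routine that
profiles the balanced-design likelihood down to one dimension, making a
fit on 10,000 rows sub-millisecond. See `docs/methods.md` for the full
account.

## Worked example

Simulate one accepted sample at the highest clustering level (ICC target
0.25–0.349, so ≈0.3) with moderately clustered x, then fit both models:

```sh
clustersim simulate --x-type continuous --sd-u 0.6547 --sd-shift 5 \
    --icc-low 0.25 --icc-high 0.349 --seed 7 --out sample.csv
clustersim fit sample.csv
```

which prints (abridged):

```
OLS: beta1=1.0019  se=0.00266  ci=(0.9967, 1.0071)  icc_hat=0.0000
RI:  beta1=1.0083  se=0.00839  ci=(0.9918, 1.0247)  icc_hat=0.3115
```

Both slopes sit near the true value 1 — the estimators are unbiased — but
the OLS standard error is three times *smaller* than the RI one. With x
clustered this strongly (cluster shift SD 5), the OLS precision is
spurious: its confidence intervals are far too narrow, which is exactly
why its coverage collapses (to ≈30% at ICC 0.3) and its Type I error
inflates (to ≈70%) across replicates. The RI interval is honest.

The same machinery is available as a library:

```python
from clustersim import StudyPlan, run_study

plan = StudyPlan(x_type="continuous", beta1_true=0.0, scale_factor=0.01,
                 master_seed=42)           # Type I study, 100 reps/level
records, summary = run_study(plan)
print(summary.value("rejection_rate", "OLS", icc_level=0.3))   # ~70
print(summary.value("rejection_rate", "RI", icc_level=0.3))    # ~5
```

Study plans can also be written as YAML and driven from the CLI
(`clustersim study --config plan.yaml --scale 0.01 --out runs/`), with
per-scenario CSV checkpoints, bit-reproducible seeding, and
`clustersim table1` to rebuild the coverage-by-dispersion-fifths grid
next to the published reference totals.

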