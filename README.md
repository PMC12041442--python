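# flushcurve

Growth-curve analysis of perennial-crop yield that arrives in repeated
flushes, built for daily harvest records from randomized block trials —
the motivating case is cut-rose production, where beds of ~500 plants are
harvested every day for 18 months and the crop produces ~8 successive
flowering flushes, each tracing one sigmoidal segment of cumulative yield.

The package answers two questions a trial analyst has: *where does one
flush end and the next begin*, and *how do treatments shift the yield
ceiling and the growth speed of each flush*.

## The model

Within flush *k*, cumulative yield of bed *i* is transformed to flush
coordinates (t' = t − t_k, y' = y − y_k) and modelled by a Gompertz curve

```
y'_ij = A_i · exp(−exp(B_i − C·t'_ij)) + ε_ij,      ε_ij ~ N(0, σ²/w_ij)
A_i = a_trt(i) + u_blk(i),A + v_i,A
B_i = b_trt(i) + u_blk(i),B + v_i,B
```

with treatment fixed effects on the asymptote *A* (stems) and growth-rate
parameter *B*, a shared shift rate *C* (per day), normal block (*u*) and
bed (*v*) random effects, and observation weights *w* that down-weight
harvest-pause artifacts. The curve's single inflection lies at t = B/C
where y = A/e. Estimation is by SAEM (stochastic approximation EM with a
Metropolis-within-Gibbs E-step); standard errors come from the Fisher
information of the linearized marginal model. A penalized-spline additive
mixed model (smooth in t' + treatment effect + bed/block random
intercepts, fitted jointly by REML) serves as the flexible benchmark, with
Efron's R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² comparing the two families.

Flush boundaries are detected from the pooled cumulative series: smooth
(penalized-spline GAM or LOESS), difference daily, take a centered 7-day
rolling mean, and locate local minima of that rate — each minimum is a day
of minimal yield change separating two flushes. A sensitivity analysis
reports how far the boundaries move (RMSE in days) as the smoothing
parameter varies.

A synthetic-data generator reproduces the trial design (5 treatments × 3
blocks, ~8 flushes, integer daily counts, optional mid-flush harvest
pause) with known ground truth, so every stage is testable end to end.

## Worked example

```python
from flushcurve import (ExperimentDesign, PipelineConfig, SegmentationConfig,
                        run_pipeline, trajectory_table)

config = PipelineConfig(
    design=ExperimentDesign(),          # 5 treatments x 3 blocks, 560 days
    segmentation=SegmentationConfig(method="loess", loess_span=0.06,
                                    candidate_window_halfwidth=15),
    seed=1,
)
report = run_pipeline(config)
print("boundaries:", report.boundaries.boundary_days)
print(report.gompertz_fits[4].summary())
```

prints

```
boundaries: [138, 193, 246, 305, 366, 426, 488]
Gompertz mixed model, flush 4 (estimator: saem, converged: True)
obs: 885  beds: 15  blocks: 3
Efron R2: 1.0000  residual SD: 5.90

param           estimate        SE
A[C]                2967        46
A[Control]          2609        46
A[R]                2921        46
A[R50]              2889        46
A[T]                2957        46
B[C]                2.34    0.0311
B[Control]         2.133     0.031
...
C                  0.101  7.13e-05
```

Seven rate minima split the 560-day record into eight flushes. In flush 4
the compost treatments top out ~300–360 stems above the untreated control,
and the contrast table turns that into Wald intervals:

```python
print(report.contrast_table.query("flush == 4 and parameter == 'A'")
      [["treatment", "difference", "lower", "upper", "significant"]].round(1))
```

```
treatment  difference  lower  upper  significant
        C       357.7  230.2  485.3         True
        R       311.4  183.9  439.0         True
      R50       279.9  152.4  407.5         True
        T       347.3  219.7  474.8         True
```

so every amended treatment's asymptote gain excludes zero at the 95%
level in this flush. `trajectory_table(report)` assembles the A and B
trajectories across all eight flushes with qualitative flags (asymptote
rising as the crop matures, growth rate declining).

The same pipeline runs from the shell on a CSV of daily records
(`bed_id, block_id, treatment, day, stems`):

```
flushcurve simulate --seed 1 --out yield.csv
flushcurve run --data yield.csv --out results/
```

## Layout

- `flushcurve.simulate` — synthetic trial generator and yield-CSV I/O
- `flushcurve.segmentation` — boundary detection and sensitivity analysis
- `flushcurve.nlme` — `GompertzMixedModel` / `GompertzMixedResults` (SAEM,
  two-stage fallback, treatment tables, contrasts)
- `flushcurve.gamm` — `FlushGAMM` / `FlushGAMMResults` benchmark and
  basis-dimension selection
- `flushcurve.pipeline` — `run_pipeline`, reporting, optional plots
- `flushcurve.cli` — `flushcurve` command-line entry point

See `docs/methods.md` for modelling assumptions, numerical choices and
known limitations.
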