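# leafrhythm

Circadian leaf-movement analysis for *Arabidopsis thaliana* seedlings grown
in 25-chamber vertical plates.

Rhythmic cotyledon and leaf movement is a classical output of the plant
circadian clock: under constant light, leaf tips keep nodding up and down
with the plant's endogenous free-running period (~24 h). Measuring that
period from time-lapse photographs is a standard first assay for clock
mutants and for treatments (sucrose, iron, temperature) that speed up or
slow down the clock. `leafrhythm` covers the whole path from images to
statistics in two stages:

1. **Imaging** — four red fiducial dots on each plate define the plate and a
   reference chamber; a radial HSV hue filter locates them, the chamber grid
   is tiled from their centroids, each seedling is segmented by iterative
   luminance contrasting (eight shearing passes, then binarisation), plant
   fragments are fused by a metric blob filter, and the left/right leaf-tip
   vertical positions are traced through the stack into a CSV.
2. **Rhythm** — each tip trace is detrended (OLS line by default), a
   zero-padded FFT seeds a sum-of-cosines model

   y(t) ≈ c₀ + c₁·t + Σₖ Aₖ · cos( 2π (t − φₖ) / Tₖ ),   k ≤ 4,

   which is refined by Gauss–Newton nonlinear least squares with step
   halving; each period Tₖ gets an approximate *support-plane* joint
   confidence interval (displace Tₖ, re-optimise everything else, stop when
   the SSE crosses the F-scaled threshold `SSE_min·(1 + p/(n−p)·F(p, n−p; 1−α))`),
   and the component with the **least relative error** inside the circadian
   window (15–35 h) is reported as the leaf-movement period. Traces where no
   component is reliable are called arrhythmic. Per plant, the left leaf is
   used and the right leaf only as a fallback (never averaged). Group
   contrasts use a two-sample, equal-variance Student's t test.

A synthetic module generates both simulated tip series (cosine + uniform
noise + optional growth trend/phase delay) and rendered plate image stacks
with stored ground-truth geometry and tip trajectories, so the entire
pipeline is testable without a camera.

## Worked example

```python
from leafrhythm import analyze_series
from leafrhythm.synthetic import SimulationSpec, simulate_series

spec = SimulationSpec(period_h=24.0, amplitude=10.0, noise_frac=0.15,
                      trend_slope=0.5, seed=42)
series, truth = simulate_series(spec)
fit = analyze_series(series)
print(fit.selected_period, fit.selected_phase, fit.rel_err[0])
```

Running `python examples/simulate_and_fit.py` (the same computation) prints

```
true period    : 24.00 h  (trend 0.5 px/h)
selected period: 24.000 h   phase 0.03 h
amplitude      : 10.01 px
relative error : 0.0017  (reliability ceiling 0.15)
removed trend  : 0.501 px/h
```

i.e. from a series carrying ±15% uniform noise and a 0.5 px/h growth trend,
the pipeline recovers the 24 h period to a few thousandths of an hour, the
amplitude to 0.1%, and the trend slope to 0.2%; the relative error of 0.0017
says the support-plane confidence interval of the period is ±0.17% — a
highly reliable rhythm. `examples/plate_to_periods.py` runs the full
image-to-period path on a rendered plate and `examples/group_comparison.py`
contrasts a wild-type against a short-period cohort with Student's t.

## Command line

```bash
leafrhythm simulate --period 24 --noise 0.15 --seed 1 --out sim.csv
leafrhythm analyze  --in sim.csv --out periods.csv
leafrhythm detect   --images frames/ --rows 5 --cols 5 --interval-min 10 \
                    --out positions.csv --overlay-out qc/
leafrhythm compare  --in periods.csv --groups groups.csv --out stats.csv
leafrhythm render-plate --spec spec.json --out-dir frames/
```

Every subcommand accepts `--config FILE` (JSON with the fields of
`leafrhythm.Config`); precedence is CLI flag > config file > documented
default. Module errors map to distinct exit codes for batch use.

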