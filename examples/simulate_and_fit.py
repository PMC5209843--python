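"""Simulate one noisy leaf-movement series and estimate its period.

Builds a 24 h cosine rhythm (amplitude 10 px, +/-15% uniform noise, 10-min
sampling over 120 h), runs the full analysis and prints the fitted
components.  The selected period should land within a few hundredths of an
hour of the true 24 h; the relative error is the support-plane confidence
half-width divided by the period (small = reliable rhythm).
"""

from leafrhythm import analyze_series
from leafrhythm.synthetic import SimulationSpec, simulate_series

spec = SimulationSpec(period_h=24.0, amplitude=10.0, noise_frac=0.15,
                      trend_slope=0.5, seed=42)
series, truth = simulate_series(spec)
fit = analyze_series(series)

print(f"true period    : {truth['period_h']:.2f} h  (trend {truth['trend_slope']} px/h)")
print(f"selected period: {fit.selected_period:.3f} h   phase {fit.selected_phase:.2f} h")
print(f"amplitude      : {fit.selected_amplitude:.2f} px")
print(f"relative error : {fit.rel_err[0]:.4f}  (reliability ceiling 0.15)")
print(f"removed trend  : {fit.trend[0]:.3f} px/h")
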