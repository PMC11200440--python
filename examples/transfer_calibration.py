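"""Simulate transfer and spike-in capture trials, then run the calibration
statistics: per-count efficiency summaries and the capture regression.

The generator draws per-cell Bernoulli retention (lossless up to 10 cells,
declining to ~86.7% expected efficiency at 15) and binomial device capture
at p_dev = 0.90, so the statistics layer can be exercised end to end with
a fixed seed.
"""

from sct import (
    SimulationConfig,
    calibration_curve,
    estimate_capture_probability,
    simulate_spiked_capture,
    simulate_transfer,
    summarize_efficiency,
)

cfg = SimulationConfig(seed=7)

transfer = simulate_transfer(cfg)  # 4 replicates x counts {1, 5, 10, 15}
print("transfer efficiency by target count (4 replicates each):")
for s in summarize_efficiency(transfer):
    sd = "   --" if s.sd is None else f"{s.sd:5.1f}"
    print(f"  k = {s.target:2d}: mean {s.mean:6.1f}%  SD {sd}%  "
          f"range [{s.range_low:.1f}, {s.range_high:.1f}]%")

capture = simulate_spiked_capture(cfg)  # 3 replicates x counts {1, 5, 10, 15}
fit = calibration_curve(capture, on="means")
p, se = estimate_capture_probability(capture)
print("\nspike-in capture calibration (per-count replicate means):")
print(f"  slope     = {fit.slope:6.3f}   (device capture x retention)")
print(f"  intercept = {fit.intercept:6.3f} cells")
print(f"  R^2       = {fit.r_squared:6.4f}")
print(f"  pooled capture probability = {p:.3f} +/- {se:.3f}")
print("\nSmall transfers are lossless (100%); at 15 cells efficiency drops")
print("toward ~87%. The near-unit-slope, high-R^2 line is what makes the")
print("spike-in series usable as a device calibration curve.")
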