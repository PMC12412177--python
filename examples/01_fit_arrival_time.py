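"""Extract a precise arrival time from one arrival-time distribution.

Builds a noisy Gaussian ATD (a peptide-like ion at separation time
100 ms), fits a Gaussian by nonlinear least squares, and prints the
fitted arrival time t_n, peak width and fit quality.
"""

import numpy as np

import cimscal as c

rng = np.random.default_rng(0)
t = np.arange(20.0, 30.0, 0.05)
y = 1000.0 * np.exp(-((t - 25.37) ** 2) / (2 * 0.5**2)) + 40.0
y = np.clip(y + rng.normal(0, 20.0, t.size), 0, None)
trace = c.ATDTrace("leuenk", separation_time=100.0, times=t, intensities=y)

window = c.pick_primary_peak(trace)
fit = c.fit_gaussian(trace, window=window)

print(f"fit window: [{window[0]:.2f}, {window[1]:.2f}] ms")
print(f"arrival time t_n = {fit.center:.4f} ms (true 25.3700)")
print(f"peak sigma       = {fit.sigma:.4f} ms")
print(f"baseline         = {fit.baseline:.1f} counts, r^2 = {fit.r_squared:.5f}")
# t_n is the quantity carried forward into pass counting and the
# perturbation-corrected drift-time model; sub-0.01 ms accuracy at this
# noise level is typical.
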