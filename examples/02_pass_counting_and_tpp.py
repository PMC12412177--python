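"""Automated pass counting and the perturbation-corrected drift time.

Generates one synthetic calibrant measured at the bypass setting
(t_s = 0.01 ms), a single-pass setting, and six multipass separation
times; counts passes from the single-pass/bypass references and fits the
linear model of total drift time on pass number.  The slope is the
perturbation-corrected periodic drift time t_pp.
"""

import warnings

import cimscal as c

cal = c.default_calibrants()[2]
traces, truths = c.generate_dataset(calibrants=[cal], seed=42)
truth = truths[0]

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    drifts = c.analyze_analyte(traces)

print(f"analyte {cal.name}: bypass = {drifts.bypass_time:.4f} ms, "
      f"t_p1 = {drifts.t_p1:.4f} ms")
print("  t_s (ms)    n    t_nd (ms)")
for p in drifts.points:
    print(f"  {p.separation_time:8.1f}  {p.n_passes:3d}  {p.total_drift:10.4f}")
m = drifts.model
print(f"t_pp = {m.t_pp:.4f} ms/pass (true {truth.true_t_pp:.4f}), "
      f"intercept = {m.intercept:+.4f} ms, r^2 = {m.r_squared:.6f}")
# The +/-0.2 ms per-run perturbations land in the residuals and the
# intercept; the slope recovers the true per-pass drift time to ~0.1%.
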