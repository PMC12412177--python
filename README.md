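# cimscal

Multipass collision cross section (CCS) calibration for cyclic ion
mobility–mass spectrometry (cIMS-MS).

## The problem

In cyclic ion mobility spectrometry, ions circulate a closed-loop
traveling-wave separator one or more times ("passes") before ejection to
the mass analyzer. Because the electric field is not static, CCS cannot
be computed from first principles; it must be calibrated against
standards of known CCS. Multipass measurements complicate this further:
the field switching that ejects ions to the detector perturbs measured
arrival times, and single-acquisition drift times therefore do not scale
cleanly with pass number.

`cimscal` implements the calibration chain for this setting, aimed at
practitioners processing cIMS-MS arrival-time distribution (ATD)
exports:

1. **Arrival-time extraction** — the precise arrival time *t_n* is the
   center of a Gaussian fitted to the raw ATD by nonlinear least squares;
   multi-peak ATDs (isomer mixtures) are deconvolved by sums of
   Gaussians, and peaks split by wrap-around (part of the population
   completing an extra lap) can be reconstructed by shifting the wrapped
   segment one period.
2. **Automated pass counting** — with the bypass time *t_b* (measured at
   separation time *t_s* = 0.01 ms) and the single-pass arrival time
   *t_p1*, the pass count of any acquisition is
   *n* = round((*t_n* − *t_b*)/(*t_p1* − *t_b*)).
3. **Perturbation-corrected periodic drift time** (Lin & Costello linear
   model) — each acquisition contributes a point (*n*, *t_nd*), where
   *t_nd* = *t_n* − *t_b* is the total drift time; ordinary least squares
   of *t_nd* on *n* gives the slope *t_pp*, the per-pass drift time with
   the field-switch perturbation relegated to the residuals and the fixed
   transit offset to the intercept. At least six points per analyte and
   at least four passes are expected, matching common acquisition
   practice.
4. **Power-law CCS calibration** — calibrant reference CCS values are
   placed on the standard traveling-wave scaled ordinate
   Ω′ = Ω·√μ/z (μ the ion–gas reduced mass, z the charge) and fitted
   against the drift value (*t_p1* for single-pass mode, *t_pp* for
   multipass mode) as Ω′ = A·t^B by log-log regression. Unknowns get
   Ω = A·t^B·z/√μ.

A synthetic-data generator with exact ground truth
(`cimscal.synth`) makes the entire chain testable without instrument
data.

## Worked example

```python
import warnings
import cimscal as c

calibrants = c.default_calibrants()        # six lipid-like standards
traces, _ = c.generate_dataset(seed=3)     # 8 ATDs per calibrant

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    curve, _ = c.calibrate(traces, calibrants)            # multipass mode
    records = c.process(traces, curve,
                        references={x.name: x for x in calibrants})
for r in records:
    print(r.analyte_id, round(r.ccs_measured, 3), r.percent_difference)
```

prints

```
cal01 229.997 0.0
cal02 243.995 0.0
cal03 258.04 0.02
cal04 271.963 0.01
cal05 285.987 0.0
cal06 300.018 0.01
```

i.e. each calibrant's CCS (Å²), recovered through the full chain —
Gaussian fits, pass counting, the *t_nd* vs *n* linear model, and the
power-law curve — agrees with its reference value within 0.02% despite
±0.2 ms per-run arrival-time perturbations and 2% intensity noise. The
`examples/` directory holds one short script per capability (arrival-time
fitting, pass counting, curve building, processing unknowns, wrap-around
reconstruction, isomer deconvolution), and the `cimscal` console command
exposes the same workflows as `synth`, `calibrate`, `process`, `passes`
and `plot` subcommands.

Workbook layout: one XLSX sheet per (analyte, separation time) named
`<analyte>__ts<t_s>` with columns `drift_time_ms`, `intensity` (an
optional `_meta` sheet supplies m/z and charge), or the equivalent
long-format CSV. Calibrant lists are CSV with columns
`name, mz, charge, ccs[, adduct]`. Curves persist as versioned JSON.

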