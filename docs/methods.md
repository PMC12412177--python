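# Methods

## Model

A cyclic traveling-wave ion mobility separator passes ions around a
closed loop; an acquisition at separation time `t_s` ejects them to the
detector after `n` complete passes. The measured arrival time of a
species is modeled as

    t_n = t_b + n * t_pp + p,

where `t_b` is the bypass/transit offset (measured directly at
`t_s = 0.01 ms`, when ions effectively skip the separation region),
`t_pp` is the per-pass ("periodic") drift time — the quantity that
carries the mobility information — and `p` is an acquisition-specific
perturbation introduced by the electric-field switching at ejection.
Because `p` does not scale with `n`, no single acquisition yields
`t_pp`; instead each acquisition contributes a point `(n, t_nd)` with
`t_nd = t_n − t_b`, and `t_pp` is the ordinary-least-squares slope of
`t_nd` on `n` (the Lin & Costello construction). The intercept absorbs
any fixed offset; the perturbations land in the residuals. `r²` is
computed on included points only.

Pass counts are assigned automatically as
`n = round((t_n − t_b)/(t_p1 − t_b))` from the single-pass arrival time
`t_p1`. Ratios farther than 0.25 from the nearest integer raise an
ambiguity warning rather than an error: with realistic perturbation
amplitudes the rounding is exact, and the warning flags schedules that
push `n` high enough for the reference error to accumulate.

Calibration follows the standard traveling-wave convention: for a
calibrant of reference CCS Ω, charge z and ion mass m = (m/z)·z (electron
mass neglected), the scaled value Ω′ = Ω·√μ/z with reduced mass
μ = m·M/(m+M) (buffer gas mass M = 28.0134 Da for N₂ by default) is
regressed against the drift value as Ω′ = A·t^B in log-log space. The
drift value is `t_p1` in single-pass mode and `t_pp` in multipass mode;
the two curves are independent artifacts and are kept separate on disk.
Predictions invert the same relation, Ω = A·t^B·z/√μ. Percent
differences against a reference workflow use the reference as the
denominator and are reported to two decimals.

## Peak fitting

Arrival times come from fitting `a·exp(−(t−c)²/(2σ²)) + b` by
`scipy.optimize.least_squares` with bounds (center inside the fitted
window, σ ∈ (0, span]), tolerances 1e-12 and an evaluation cap of 2000;
hitting the cap returns `converged=False` rather than raising.
Initialization: center at the intensity argmax (earliest sample on
ties), amplitude = max − min, baseline = min, σ = FWHM/2.3548 with the
FWHM interpolated linearly at half height. A constant baseline is fitted
by default because raw ATDs carry a noise floor; it can be fixed to zero.
The fitted window defaults to ±3 FWHM around the most intense peak
(`pick_primary_peak`), which confines multi-peak ATDs to their dominant
feature. Multi-component fits share one baseline across k Gaussians,
initialized at the k highest local maxima separated by at least 3 grid
steps (ties toward earlier time); the user supplies k — automatic model
selection is out of scope.

Wrap-around splitting (part of the population completing an extra lap
and being recorded one period early) is undone by shifting all points
before a split time late by one period and re-sorting; point count and
the intensity multiset are conserved exactly, and an exact collision of
time stamps raises an error. When no split time is given it is placed in
the dominant gap between time stamps if one exists, otherwise at the
intensity minimum between the two most prominent peaks. Split detection
for exclusion purposes (`has_secondary_component`) flags a trace when a
dominant time-stamp gap exists or when more than 10% of the
median-subtracted intensity lies outside the primary-peak window; small
wrapped fractions (≲ 0.3 of the points, carrying a few percent of the
peak mass) can evade the mass criterion when the trace grid is
contiguous — such traces also barely perturb the fit.

## Synthetic data generator

`cimscal.synth` emulates exactly the structure above: per-calibrant true
`t_pp` values are derived by inverting a known power-law curve (defaults
A = 300, B = 0.55) applied to each calibrant's reference CCS; arrival
times are `t_b + n·t_pp + p` with `n = floor(t_s/t_pp)` (the most passes
completing within the separation time) and `p` uniform on [−δ, +δ],
drawn once per acquisition run and shared across analytes, emulating the
run-level nature of the field-switch artifact. Peaks render as Gaussians
(σ = 0.5 ms, sampled every 0.05 ms over ±5σ, amplitude 1000) with
additive Gaussian intensity noise floored at zero. Defaults: bypass
5 ms, δ = 0.2 ms, noise sd 20 counts (2% of amplitude); the six default
calibrants are singly charged with m/z 600–850 and CCS 230–300 Å²,
lipid-like values chosen so per-pass drift times (12.2–20.1 ms) span
less than a factor of two and one shared separation-time schedule —
bypass 0.01 ms, single-pass 22.1 ms, six multipass settings from
4.25× to 8.5× the slowest per-pass time, rounded as an operator would
enter them — gives every calibrant exactly one pass at the single-pass
setting, at least four passes per multipass point, and six model points.
Workbook output is byte-deterministic for a fixed seed (document and
zip-entry timestamps are pinned).

What the generator does **not** emulate: non-Gaussian peak shapes and
tailing, mobility-dependent peak broadening with pass number, ion loss
at high pass counts, m/z-domain information, detector saturation, and
any physical model of the traveling-wave perturbation (the uniform draw
is a stand-in with the right scale, not the physics). Passing tests
therefore demonstrate correctness of the calibration arithmetic and its
statistical behavior under the stated noise model, not robustness to
every instrumental artifact.

## Numerical choices and edge cases

- OLS for the drift-time model uses `scipy.stats.linregress`
  (covariance form); tests and the acceptance script check it against
  independently coded normal equations at 1e-12 relative.
- Fewer than six usable model points raises an error naming the analyte
  and the six-point minimum; a series never reaching four passes warns.
  Both thresholds are configurable (`RunConfig`).
- Wrap-around-flagged points are excluded from the regression with
  reason `"wraparound"`; acquisitions completing no pass with
  `"no_pass"`.
- The bypass trace is accepted leniently for `t_s ∈ [0.005, 0.05]` ms;
  strict mode errors outside the window. Bypass measurement error shifts
  every `t_nd` by a constant and therefore moves only the intercept.
- Flat traces, windows excluding all points, non-positive masses/CCS,
  and charge 0 raise typed errors; the CLI maps input errors to exit
  code 2 and model-fit errors to 3.
- Predictions beyond 1.5× outside the calibrant drift range raise an
  extrapolation warning and flag the result row.
- XLSX float cells round-trip at ~15 significant digits; the workbook
  read/write identity is therefore asserted at 1e-12 relative, while CSV
  and curve-JSON round trips are exact for text-representable values.

## Problem sizes

Default synthetic datasets are 6 calibrants × 8 acquisitions
(~100 samples per trace). Statistical claims are checked over 20 dataset
seeds (CCS recovery within 0.5% of truth; observed worst error about
0.03%) and 200 single-calibrant replicates (mean `t_pp` recovery within
0.1% of truth; observed about 0.001–0.02% depending on seed), sizes at
which the whole verification chain runs in well under a minute on one
core.

## Known limitations

- Pass counting assumes the single-pass reference is truly single-pass;
  the default schedule guarantees this for the synthetic panel, but for
  real schedules the user should confirm via the `passes` report.
- The power law is empirical; curves must not be reused across tune
  states or gases (the curve JSON records gas mass and settings to make
  mismatches visible).
- k (number of ATD components) is user-supplied; no automatic model
  selection.
- Wrap-around detection is heuristic (see above); reconstruction
  requires the user-known or auto-detected period and assumes a single
  wrapped segment.
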