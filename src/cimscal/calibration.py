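"""Power-law CCS calibration with reduced-mass/charge scaling.

Traveling-wave instruments do not yield CCS from first principles, so
reference compounds of known CCS are used to build an empirical curve.
Each calibrant's reference CCS is put on the standard scaled ordinate
``Ω' = Ω·sqrt(μ)/z`` (μ the ion–gas reduced mass, z the charge), paired
with its measured drift value — the single-pass arrival time ``t_p1`` or
the perturbation-corrected periodic drift time ``t_pp`` — and the pairs
are fitted to a power law ``Ω' = A·t^B`` by linear regression in log-log
space.  Unknowns are then assigned ``Ω = A·t^B · z / sqrt(μ)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import CalibrantSpec
from .errors import (
    ExtrapolationWarning,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "N2_MASS",
    "CalibrationCurve",
    "CCSResult",
    "reduced_mass",
    "scale_ccs",
    "unscale_ccs",
    "fit_power_law",
    "build_curve",
    "predict_ccs",
    "percent_difference",
]

#: Mass of molecular nitrogen, Da (the usual cIMS buffer gas).
N2_MASS = 28.0134


def reduced_mass(ion_mass: float, gas_mass: float = N2_MASS) -> float:
    """Reduced mass μ = m_ion·m_gas/(m_ion + m_gas), Da."""
    if not (ion_mass > 0 and gas_mass > 0):
        raise ValidationError(
            f"masses must be positive (ion {ion_mass}, gas {gas_mass})"
        )
    return ion_mass * gas_mass / (ion_mass + gas_mass)


def scale_ccs(ccs: float, charge: int, mu: float) -> float:
    """Scaled CCS ``Ω' = Ω·sqrt(μ)/z`` used on the calibration ordinate."""
    if charge == 0:
        raise ValidationError("charge must be nonzero")
    if not (ccs > 0 and mu > 0):
        raise ValidationError(f"ccs and reduced mass must be positive")
    return ccs * math.sqrt(mu) / charge


def unscale_ccs(scaled: float, charge: int, mu: float) -> float:
    """Inverse of :func:`scale_ccs`: ``Ω = Ω'·z/sqrt(μ)``."""
    if charge == 0:
        raise ValidationError("charge must be nonzero")
    if not (scaled > 0 and mu > 0):
        raise ValidationError("scaled ccs and reduced mass must be positive")
    return scaled * charge / math.sqrt(mu)


def fit_power_law(
    drifts: np.ndarray, scaled_ccs: np.ndarray
) -> tuple[float, float, float]:
    """Fit ``scaled_ccs = A·drift^B`` by OLS in log-log space.

    Returns ``(A, B, r_squared)``; the r² is the coefficient of
    determination of the straight-line fit of ln(Ω') on ln(t).
    """
    drifts = np.asarray(drifts, dtype=float)
    scaled_ccs = np.asarray(scaled_ccs, dtype=float)
    if drifts.size != scaled_ccs.size:
        raise ValidationError("drift and scaled-CCS arrays differ in length")
    if drifts.size < 3:
        raise InsufficientDataError(
            f"power-law calibration needs at least 3 calibrants, got {drifts.size}"
        )
    if np.any(drifts <= 0) or np.any(scaled_ccs <= 0):
        raise ValidationError("drift values and scaled CCS must all be positive")
    res = stats.linregress(np.log(drifts), np.log(scaled_ccs))
    return float(math.exp(res.intercept)), float(res.slope), float(res.rvalue**2)


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted power-law calibration ``Ω' = A·t^B`` for one drift mode.

    ``mode`` records which drift quantity the curve was built from
    ("single-pass" → t_p1, "multipass" → t_pp); curves for the two modes
    are independent artifacts.  ``calibrant_table`` retains the per-
    calibrant inputs for audit and extrapolation checks.
    """

    A: float
    B: float
    mode: str
    gas_mass: float
    fit_r_squared: float
    calibrant_table: tuple[dict, ...]
    created_with: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValidationError(f"power-law coefficient A must be positive")
        if not 0 < self.B < 2:
            raise ValidationError(
                f"power-law exponent B={self.B} outside the physical range (0, 2)"
            )
        if self.mode not in ("single-pass", "multipass"):
            raise ValidationError(f"unknown mode '{self.mode}'")
        if len(self.calibrant_table) < 3:
            raise ValidationError("a calibration curve needs >= 3 calibrants")

    @property
    def drift_range(self) -> tuple[float, float]:
        d = [row["drift_ms"] for row in self.calibrant_table]
        return min(d), max(d)


@dataclass
class CCSResult:
    """A predicted CCS value with its provenance."""

    analyte_id: str
    mode: str
    drift_value: float  # ms (t_p1 or t_pp)
    mz: float
    charge: int
    reduced_mass: float  # Da
    ccs: float  # squared angstroms
    ccs_reference: float | None = None
    percent_difference: float | None = None
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if not self.ccs > 0:
            raise ValidationError(f"'{self.analyte_id}': CCS must be positive")


def build_curve(
    calibrants: list[CalibrantSpec],
    drift_values: dict[str, float],
    mode: str,
    gas_mass: float = N2_MASS,
    created_with: dict | None = None,
) -> CalibrationCurve:
    """Build a power-law curve from calibrants and their measured drifts.

    ``drift_values`` maps calibrant name to the measured drift value in
    the requested mode (t_p1 for "single-pass", t_pp for "multipass").
    A calibrant without a drift value is an error naming it.
    """
    missing = [c.name for c in calibrants if c.name not in drift_values]
    if missing:
        raise InsufficientDataError(
            f"no {mode} drift value for calibrant(s): {', '.join(missing)}"
        )
    table = []
    for c in calibrants:
        mu = reduced_mass(c.mz * c.charge, gas_mass)
        table.append(
            {
                "name": c.name,
                "drift_ms": float(drift_values[c.name]),
                "ccs_ref": c.ccs_ref,
                "mz": c.mz,
                "charge": c.charge,
                "scaled_ccs": scale_ccs(c.ccs_ref, c.charge, mu),
            }
        )
    A, B, r2 = fit_power_law(
        np.array([row["drift_ms"] for row in table]),
        np.array([row["scaled_ccs"] for row in table]),
    )
    return CalibrationCurve(
        A=A,
        B=B,
        mode=mode,
        gas_mass=gas_mass,
        fit_r_squared=r2,
        calibrant_table=tuple(table),
        created_with=dict(created_with or {}),
    )


def predict_ccs(
    curve: CalibrationCurve,
    drift: float,
    mz: float,
    charge: int,
    analyte_id: str = "",
    ccs_reference: float | None = None,
    extrapolation_factor: float = 1.5,
) -> CCSResult:
    """Predict CCS for an unknown from its drift value and m/z, charge.

    ``Ω = A·t^B · z / sqrt(μ)`` with μ from the ion mass ``mz·z`` (electron
    mass neglected) and the curve's gas mass.  Drift values beyond
    ``extrapolation_factor`` times outside the calibrant drift range raise
    an :class:`ExtrapolationWarning` and flag the result.
    """
    if not drift > 0:
        raise ValidationError(f"'{analyte_id}': drift value must be positive")
    mu = reduced_mass(mz * charge, curve.gas_mass)
    ccs = curve.A * drift**curve.B * charge / math.sqrt(mu)
    lo, hi = curve.drift_range
    extrapolated = drift > hi * extrapolation_factor or drift < lo / extrapolation_factor
    if extrapolated:
        warnings.warn(
            f"'{analyte_id}': drift {drift:g} ms lies beyond "
            f"{extrapolation_factor}x the calibrant range [{lo:g}, {hi:g}] ms",
            ExtrapolationWarning,
            stacklevel=2,
        )
    pdiff = (
        percent_difference(ccs_reference, ccs) if ccs_reference is not None else None
    )
    return CCSResult(
        analyte_id=analyte_id,
        mode=curve.mode,
        drift_value=drift,
        mz=mz,
        charge=charge,
        reduced_mass=mu,
        ccs=ccs,
        ccs_reference=ccs_reference,
        percent_difference=pdiff,
        extrapolated=extrapolated,
    )


def percent_difference(reference: float, measured: float) -> float:
    """Absolute percent deviation from the reference, to two decimals.

    ``100·|measured - reference|/reference``, the convention used when
    comparing against a reference workflow's CCS values.
    """
    if not reference > 0:
        raise ValidationError("reference CCS must be positive")
    return round(100.0 * abs(measured - reference) / reference, 2)
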