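"""Core domain containers shared across the package.

The central object is :class:`ATDTrace`: one arrival-time distribution
(intensity versus drift time, in milliseconds) for one ion species at one
applied separation time ``t_s``.  All drift times in the package are in
milliseconds, CCS values in squared angstroms, and masses in daltons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["ATDTrace", "CalibrantSpec", "ResultRecord"]


@dataclass(frozen=True)
class ATDTrace:
    """One arrival-time distribution at one separation time.

    Parameters
    ----------
    analyte_id:
        Label of the ion species (sheet/base name in workbooks).
    separation_time:
        Applied separation time ``t_s`` in ms; must be positive.  The
        bypass acquisition is conventionally recorded at 0.01 ms.
    times:
        Strictly increasing drift times in ms, at least 5 samples.
    intensities:
        Non-negative intensities, same length as ``times``.
    mz:
        Optional mass-to-charge of the species (Th).
    charge:
        Positive integer charge state (default 1).
    """

    analyte_id: str
    separation_time: float
    times: np.ndarray
    intensities: np.ndarray
    mz: float | None = None
    charge: int = 1

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intensities)
        if times.ndim != 1 or intensities.ndim != 1:
            raise ValidationError("times and intensities must be 1-D")
        if times.size != intensities.size:
            raise ValidationError(
                f"trace '{self.analyte_id}': {times.size} times but "
                f"{intensities.size} intensities"
            )
        if times.size < 5:
            raise ValidationError(
                f"trace '{self.analyte_id}': need at least 5 points, got {times.size}"
            )
        if not np.all(np.diff(times) > 0):
            raise ValidationError(
                f"trace '{self.analyte_id}': drift times must be strictly increasing"
            )
        if np.any(intensities < 0):
            raise ValidationError(
                f"trace '{self.analyte_id}': intensities must be non-negative"
            )
        if not self.separation_time > 0:
            raise ValidationError(
                f"trace '{self.analyte_id}': separation_time must be positive, "
                f"got {self.separation_time}"
            )
        if self.charge < 1:
            raise ValidationError(
                f"trace '{self.analyte_id}': charge must be a positive integer"
            )

    @property
    def span(self) -> tuple[float, float]:
        """(first, last) drift time of the trace, ms."""
        return float(self.times[0]), float(self.times[-1])

    def windowed(self, window: tuple[float, float]) -> "ATDTrace":
        """Return the sub-trace with times inside ``window`` (inclusive)."""
        lo, hi = window
        mask = (self.times >= lo) & (self.times <= hi)
        if not mask.any():
            raise ValidationError(
                f"trace '{self.analyte_id}': window [{lo}, {hi}] excludes all points"
            )
        return ATDTrace(
            analyte_id=self.analyte_id,
            separation_time=self.separation_time,
            times=self.times[mask],
            intensities=self.intensities[mask],
            mz=self.mz,
            charge=self.charge,
        )


@dataclass(frozen=True)
class CalibrantSpec:
    """A calibration standard with a literature reference CCS.

    ``ccs_ref`` is the reference collision cross section in squared
    angstroms (e.g. the Waters Major Mix literature values); ``mz`` and
    ``charge`` identify the calibrant ion for reduced-mass scaling.
    """

    name: str
    mz: float
    charge: int
    ccs_ref: float
    adduct: str | None = None

    def __post_init__(self) -> None:
        if not self.ccs_ref > 0:
            raise ValidationError(
                f"calibrant '{self.name}': reference CCS must be positive, "
                f"got {self.ccs_ref}"
            )
        if self.charge < 1:
            raise ValidationError(f"calibrant '{self.name}': charge must be >= 1")
        if not self.mz > 0:
            raise ValidationError(f"calibrant '{self.name}': m/z must be positive")


@dataclass
class ResultRecord:
    """One output row: a measured CCS value and optional reference comparison."""

    analyte_id: str
    mode: str  # "single-pass" | "multipass"
    ccs_measured: float
    ccs_reference: float | None = None
    percent_difference: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("single-pass", "multipass"):
            raise ValidationError(f"unknown mode '{self.mode}'")
        if (self.ccs_reference is None) != (self.percent_difference is None):
            raise ValidationError(
                "percent_difference must be present exactly when ccs_reference is"
            )
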