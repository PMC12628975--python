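"""Electrode calibration: voltage vs log10(concentration).

Calibration points are entered as (concentration in mM, voltage in mV); the
fitted line V = intercept + slope * log10(c / 1 mM) is inverted to convert
measured voltages back to concentrations.  The slope is signed — an
inverting amplifier in the measurement chain simply yields a negative
calibration slope, and every downstream flux formula uses only the slope
(or the inverted line), so any constant gain cancels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, ParseError

#: Slopes below this magnitude (mV/decade) indicate a dead electrode.
MIN_SLOPE_MAGNITUDE = 1.0


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted electrode line: slope (mV/decade, signed), intercept (mV at 1 mM)."""

    points: tuple  # ((conc_mM, voltage_mV), ...)
    slope: float
    intercept: float
    r_squared: float


def fit_calibration(points) -> CalibrationCurve:
    """OLS fit of voltage against log10(concentration / 1 mM).

    Requires at least two distinct, strictly positive concentrations and a
    fitted |slope| of at least 1 mV/decade.
    """
    pts = tuple((float(c), float(v)) for c, v in points)
    conc = np.array([c for c, _ in pts])
    volt = np.array([v for _, v in pts])
    if np.any(conc <= 0):
        raise CalibrationError("calibration concentrations must be > 0")
    if len(np.unique(conc)) < 2:
        raise CalibrationError("need >= 2 distinct calibration concentrations")
    x = np.log10(conc)
    slope, intercept = np.polyfit(x, volt, 1)
    fitted = intercept + slope * x
    ss_res = float(np.sum((volt - fitted) ** 2))
    ss_tot = float(np.sum((volt - np.mean(volt)) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if abs(slope) < MIN_SLOPE_MAGNITUDE:
        raise CalibrationError(
            f"degenerate electrode: |slope| = {abs(slope):.3g} mV/decade < "
            f"{MIN_SLOPE_MAGNITUDE} mV/decade"
        )
    return CalibrationCurve(points=pts, slope=float(slope),
                            intercept=float(intercept), r_squared=r2)


def voltage_to_concentration(cal: CalibrationCurve, V: float):
    """Invert the calibration line: c = 10^((V - intercept) / slope) mM."""
    return 10.0 ** ((V - cal.intercept) / cal.slope)


def read_calibration_table(path) -> CalibrationCurve:
    """Fit a calibration from a two-column TSV (conc_mM, voltage_mV).

    Lines starting with '#' are comments; a header row naming the columns is
    allowed and skipped.
    """
    pts = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) != 2:
                raise ParseError("expected two columns (conc_mM, voltage_mV)",
                                 line=lineno)
            try:
                pts.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if lineno == 1 or not pts:  # tolerated header row
                    continue
                raise ParseError(f"non-numeric calibration row {parts}",
                                 line=lineno) from None
    return fit_calibration(pts)
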