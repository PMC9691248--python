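"""Absorbance spectra and Soret-band quantification of heme/hemoglobin.

Free heme and hemoglobin show an intense Soret absorption band near
410 nm; the absorbance of the upper (aqueous) phase at 410 nm, before and
after extraction with the ionic liquid, quantifies how much heme/hemoglobin
the IL phase removed.  Quantification uses Beer–Lambert proportionality:
an absorbance of ~1 at 410 nm corresponds to 0.15 mg/mL hemoglobin for the
instrument/path length assumed here, so the default calibration slope is
1/0.15 absorbance units per (mg/mL).

Spectra are plain two-column CSV files (``wavelength_nm,absorbance``).
Blank subtraction is assumed to have been applied upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ilextract.errors import ParseError, RangeError, ValidationError

#: Default Beer-Lambert slope: absorbance 1.0 at 410 nm <-> 0.15 mg/mL hemoglobin.
DEFAULT_SLOPE = 1.0 / 0.15

#: Analytical wavelength of the Soret band, nm.
SORET_WAVELENGTH = 410.0

CSV_COLUMNS = ("wavelength_nm", "absorbance")


@dataclass(frozen=True)
class Spectrum:
    """An absorbance spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths : array-like of float
        Wavelengths in nm, strictly increasing.
    absorbances : array-like of float
        Unitless absorbances, same length as ``wavelengths``, all finite.
    label : str
        Free-text description of the sample.
    """

    wavelengths: np.ndarray
    absorbances: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbances, dtype=float)
        if wl.ndim != 1 or ab.ndim != 1:
            raise ValidationError("wavelengths and absorbances must be 1-D")
        if wl.size != ab.size:
            raise ValidationError(
                f"length mismatch: {wl.size} wavelengths vs {ab.size} absorbances"
            )
        if wl.size == 0:
            raise ValidationError("spectrum must contain at least one point")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(ab)):
            raise ValidationError("spectrum values must be finite")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbances", ab)


@dataclass(frozen=True)
class BeerLambertCalibration:
    """Proportionality between absorbance and concentration at one wavelength.

    ``slope`` is the absorbance per (mg/mL) at ``wavelength``; it bundles the
    molar absorptivity and the path length into a single empirical constant.
    """

    slope: float = DEFAULT_SLOPE
    wavelength: float = SORET_WAVELENGTH

    def __post_init__(self) -> None:
        if not (self.slope > 0):
            raise ValidationError(f"calibration slope must be > 0, got {self.slope}")


def read_spectrum(path, label: str = "") -> Spectrum:
    """Read a spectrum from a ``wavelength_nm,absorbance`` CSV file.

    Raises :class:`ParseError` naming the offending line for malformed rows
    and :class:`ValidationError` for non-monotone wavelength grids.
    """
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}; header must be "
                         f"'{','.join(CSV_COLUMNS)}'")
    values = {}
    for col in CSV_COLUMNS:
        try:
            values[col] = frame[col].astype(float).to_numpy()
        except (TypeError, ValueError):
            # locate the first bad cell so the error names a data line
            for i, cell in enumerate(frame[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}: line {i + 2}: cannot parse {col}={cell!r} as a number"
                    ) from None
            raise
    return Spectrum(values["wavelength_nm"], values["absorbance"], label=label)


def write_spectrum(spec: Spectrum, path) -> None:
    """Write a spectrum as CSV, round-trippable through :func:`read_spectrum`."""
    pd.DataFrame(
        {CSV_COLUMNS[0]: spec.wavelengths, CSV_COLUMNS[1]: spec.absorbances}
    ).to_csv(path, index=False, float_format="%.17g")


def absorbance_at(spec: Spectrum, wavelength: float) -> float:
    """Absorbance at ``wavelength``, linearly interpolated between grid points.

    Exact grid points are returned exactly; queries outside the recorded
    range raise :class:`RangeError`.
    """
    lo, hi = spec.wavelengths[0], spec.wavelengths[-1]
    if not (lo <= wavelength <= hi):
        raise RangeError(
            f"wavelength {wavelength} nm outside recorded range [{lo}, {hi}] nm"
        )
    return float(np.interp(wavelength, spec.wavelengths, spec.absorbances))


def concentration_from_absorbance(
    absorbance: float, cal: BeerLambertCalibration | None = None
) -> float:
    """Concentration in mg/mL from absorbance via Beer–Lambert linearity."""
    if cal is None:
        cal = BeerLambertCalibration()
    if absorbance < 0:
        raise ValidationError(f"absorbance must be >= 0, got {absorbance}")
    return absorbance / cal.slope


def extraction_efficiency(a_before: float, a_after: float) -> float:
    """Percent of absorbing species removed, from before/after absorbances.

    Efficiency is ``100*(A_before - A_after)/A_before``.  Under Beer–Lambert
    linearity this equals the efficiency computed on concentrations.  Values
    outside [0, 100] indicate a measurement problem and raise instead of
    being clipped.
    """
    if not (a_before > 0):
        raise ValidationError(f"A_before must be > 0, got {a_before}")
    if a_after < 0:
        raise ValidationError(f"A_after must be >= 0, got {a_after}")
    if a_after > a_before:
        raise ValidationError(
            f"A_after ({a_after}) exceeds A_before ({a_before}): "
            "negative efficiency signals a measurement problem"
        )
    return 100.0 * (1.0 - a_after / a_before)
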