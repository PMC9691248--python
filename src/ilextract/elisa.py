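"""Competitive-ELISA calibration, inverse prediction, and accuracy statistics.

In a solid-phase competitive ELISA the measured absorbance (450 nm)
decreases as analyte concentration increases.  The dose-response is
modeled with the standard four-parameter logistic (4PL)

    A(c) = A_bottom + (A_top - A_bottom) / (1 + (c/IC50)^h),

with A_top the zero-analyte plateau, A_bottom the saturating plateau,
IC50 the midpoint concentration and h > 0 the slope.  The 4PL has an
analytic inverse, so back-calculated sample concentrations are exact
inverse predictions rather than numerical root solves.

Replicate sets of back-calculated concentrations are summarized by the
usual assay quality metrics: arithmetic mean, sample SD (n-1), CV% =
100*SD/mean, and the signed relative error 100*(mean - nominal)/nominal.
:func:`accuracy_comparison` quantifies how the accuracy of an assay
changes after a pretreatment step (here: heme/hemoglobin depletion).

Relative error is kept signed internally; rendered reports also expose
its magnitude because assay tables conventionally print |RE| in some
rows.  Rounding for display is half-up, applied only at render time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ilextract.errors import (
    ConvergenceError,
    ParseError,
    RangeError,
    ValidationError,
)

PLATE_CSV_COLUMNS = ("well", "role", "nominal_ng_per_ml", "absorbance")
PLATE_ROLES = ("standard", "sample", "blank")

#: Standard cotinine calibration levels, ng/mL.
DEFAULT_STANDARD_LEVELS = (0.0, 5.0, 10.0, 25.0, 50.0, 100.0)


def four_pl(c, a_top: float, a_bottom: float, ic50: float, slope: float):
    """Forward 4PL response: absorbance at concentration ``c`` (ng/mL)."""
    c = np.asarray(c, dtype=float)
    out = a_bottom + (a_top - a_bottom) / (1.0 + (c / ic50) ** slope)
    return float(out) if out.ndim == 0 else out


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero to ``decimals`` places (report rendering)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted 4PL standard curve with the standards used to fit it."""

    a_top: float
    a_bottom: float
    ic50: float
    slope: float
    standards: tuple[tuple[float, float], ...] = ()
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.a_top > self.a_bottom >= 0):
            raise ValidationError(
                f"need A_top > A_bottom >= 0, got {self.a_top}, {self.a_bottom}"
            )
        if not (self.ic50 > 0):
            raise ValidationError(f"IC50 must be > 0, got {self.ic50}")
        if not (self.slope > 0):
            raise ValidationError(f"slope must be > 0, got {self.slope}")
        if self.standards:
            nonzero = {c for c, _ in self.standards if c > 0}
            if len(nonzero) < 3:
                raise ValidationError(
                    "standards must span at least 3 distinct non-zero concentrations"
                )

    def forward(self, concentration) -> float:
        """Predicted absorbance at ``concentration`` ng/mL."""
        return four_pl(concentration, self.a_top, self.a_bottom, self.ic50, self.slope)


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate back-calculated concentrations for one assay condition."""

    condition: str
    nominal: float
    concentrations: np.ndarray
    absorbances: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if c.size < 2:
            raise ValidationError("need >= 2 replicates for an SD")
        if np.any(c < 0):
            raise ValidationError("concentrations must be >= 0")
        object.__setattr__(self, "concentrations", c)
        if self.absorbances is not None:
            object.__setattr__(
                self, "absorbances", np.asarray(self.absorbances, dtype=float)
            )


@dataclass(frozen=True)
class AccuracyReport:
    """Accuracy and precision summary of one replicate set."""

    condition: str
    nominal: float
    mean: float
    sd: float
    cv_percent: float
    relative_error_percent: float  # signed
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")

    @property
    def abs_relative_error_percent(self) -> float:
        return abs(self.relative_error_percent)

    def rendered(self) -> dict:
        """Report dict rounded half-up to conventional table precision."""
        return {
            "condition": self.condition,
            "nominal_ng_per_ml": self.nominal,
            "mean_ng_per_ml": round_half_up(self.mean, 3),
            "sd_ng_per_ml": round_half_up(self.sd, 3),
            "cv_percent": round_half_up(self.cv_percent, 3),
            "relative_error_percent": round_half_up(self.relative_error_percent, 2),
            "abs_relative_error_percent": round_half_up(
                self.abs_relative_error_percent, 2
            ),
            "n": self.n,
        }


def fit_calibration(standards) -> CalibrationCurve:
    """Fit a 4PL standard curve to (concentration ng/mL, absorbance) pairs.

    Requires at least 4 standards; the zero-concentration standard anchors
    the upper plateau.  Standards whose absorbance trends upward with
    concentration (non-competitive) are rejected.  Non-convergence of the
    optimiser raises :class:`ConvergenceError`.
    """
    pairs = [(float(c), float(a)) for c, a in standards]
    if len(pairs) < 4:
        raise ValidationError("need >= 4 standards for a 4PL fit")
    conc = np.array([c for c, _ in pairs])
    absb = np.array([a for _, a in pairs])
    if np.any(conc < 0):
        raise ValidationError("standard concentrations must be >= 0")
    order = np.argsort(conc)
    a_sorted = absb[order]
    # overall trend must be decreasing (competitive assay)
    if a_sorted[-1] >= a_sorted[0] or np.ptp(absb) == 0:
        raise ValidationError(
            "standards do not decrease with concentration: not a competitive response"
        )

    top0 = float(a_sorted[0])
    bot0 = max(float(a_sorted[-1]) * 0.5, 1e-6)
    mid_a = 0.5 * (top0 + bot0)
    ic50_0 = float(np.interp(mid_a, a_sorted[::-1], conc[order][::-1]))
    ic50_0 = ic50_0 if ic50_0 > 0 else float(np.median(conc[conc > 0]))
    p0 = [top0, bot0, ic50_0, 1.0]
    try:
        popt, _ = curve_fit(
            four_pl, conc, absb, p0=p0,
            bounds=([1e-9, 0.0, 1e-9, 1e-3], [np.inf, np.inf, np.inf, 20.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise ConvergenceError(f"4PL fit did not converge: {exc}") from exc
    a_top, a_bottom, ic50, slope = (float(v) for v in popt)
    if not a_top > a_bottom:
        raise ConvergenceError("4PL fit collapsed: A_top <= A_bottom")
    return CalibrationCurve(
        a_top=a_top, a_bottom=a_bottom, ic50=ic50, slope=slope,
        standards=tuple(pairs), converged=True,
    )


def invert_calibration(curve: CalibrationCurve, absorbance: float) -> float:
    """Back-calculate concentration (ng/mL) from absorbance.

    The 4PL inverse is analytic:
    c = IC50 * ((A_top - A)/(A - A_bottom))^(1/h).  Absorbances outside
    the open interval (A_bottom, A_top) raise :class:`RangeError` naming
    the violated bound (above-range or below-range sample).
    """
    if absorbance >= curve.a_top:
        raise RangeError(
            f"absorbance {absorbance} >= A_top {curve.a_top}: "
            "below-range sample (concentration indistinguishable from 0)"
        )
    if absorbance <= curve.a_bottom:
        raise RangeError(
            f"absorbance {absorbance} <= A_bottom {curve.a_bottom}: "
            "above-range sample (beyond the calibrated range)"
        )
    ratio = (curve.a_top - absorbance) / (absorbance - curve.a_bottom)
    return float(curve.ic50 * ratio ** (1.0 / curve.slope))


def replicate_stats(reps: ReplicateSet) -> AccuracyReport:
    """Mean, sample SD, CV%, and signed relative error of a replicate set."""
    c = reps.concentrations
    if reps.nominal <= 0:
        raise ValidationError("nominal must be > 0 for a relative error")
    mean = float(np.mean(c))
    sd = float(np.std(c, ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else math.inf
    rel_err = 100.0 * (mean - reps.nominal) / reps.nominal
    return AccuracyReport(
        condition=reps.condition, nominal=reps.nominal, mean=mean, sd=sd,
        cv_percent=cv, relative_error_percent=rel_err, n=int(c.size),
    )


def accuracy_comparison(before: AccuracyReport, after: AccuracyReport) -> dict:
    """Compare assay accuracy before vs after a pretreatment step.

    Returns the two signed relative errors, their signed difference
    (before - after), the change in |relative error| (positive = accuracy
    improved), and whether precision (CV%) also improved.  Both reports
    must refer to the same nominal concentration.
    """
    if before.nominal != after.nominal:
        raise ValidationError(
            f"nominal mismatch: {before.nominal} vs {after.nominal} ng/mL"
        )
    re_b = before.relative_error_percent
    re_a = after.relative_error_percent
    return {
        "nominal_ng_per_ml": before.nominal,
        "relative_error_before_percent": re_b,
        "relative_error_after_percent": re_a,
        "decrease_points": re_b - re_a,
        "abs_error_change_points": abs(re_b) - abs(re_a),
        "accuracy_improved": abs(re_a) < abs(re_b),
        "cv_before_percent": before.cv_percent,
        "cv_after_percent": after.cv_percent,
        "precision_improved": after.cv_percent < before.cv_percent,
    }


@dataclass(frozen=True)
class PlateTable:
    """Parsed plate CSV: standards, samples, and blanks."""

    frame: pd.DataFrame

    @property
    def standards(self) -> list[tuple[float, float]]:
        sub = self.frame[self.frame["role"] == "standard"]
        return list(zip(sub["nominal_ng_per_ml"].astype(float),
                        sub["absorbance"].astype(float)))

    @property
    def samples(self) -> pd.DataFrame:
        return self.frame[self.frame["role"] == "sample"]


def read_plate(path) -> PlateTable:
    """Read a plate table CSV (``well,role,nominal_ng_per_ml,absorbance``)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in PLATE_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    bad = set(frame["role"]) - set(PLATE_ROLES)
    if bad:
        raise ParseError(f"{path}: unknown role(s) {sorted(bad)}")
    return PlateTable(frame)


def analyze_plate(plate: PlateTable, nominal: float, condition: str = "") -> AccuracyReport:
    """Fit the plate's standards, back-calculate its samples, summarize."""
    curve = fit_calibration(plate.standards)
    conc = [invert_calibration(curve, a)
            for a in plate.samples["absorbance"].astype(float)]
    reps = ReplicateSet(
        condition=condition, nominal=nominal,
        concentrations=np.asarray(conc),
        absorbances=plate.samples["absorbance"].to_numpy(float),
    )
    return replicate_stats(reps)
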