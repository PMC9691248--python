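"""Equilibrium partitioning of heme/hemoglobin between serum and IL phases.

At equilibrium the solute distributes between the aqueous and
ionic-liquid phases.  Two models are supported:

- ``linear``: a constant separation ratio S0 = C_IL/C_aq, adequate at low
  solute concentration;
- ``hyperbolic``: an empirical saturation relation in which the separation
  ratio decays with aqueous concentration,

      S(C_aq) = S0 / (1 + C_aq/K),   C_IL = S(C_aq) * C_aq,

  so the IL-phase concentration saturates at S0*K as C_aq grows.  This is
  the simplest hyperbola in the separation factor consistent with a
  decreasing observed ratio and with saturation of the IL phase; it is an
  empirical stand-in, isolated behind :class:`PartitionModel` so that
  alternative saturation laws can be added.

Given a model and a system composition, :func:`predict_depletion` solves
the solute mass balance q = C_aq*V_aq + C_IL*V_IL for the equilibrium
state and the resulting depletion efficiency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ilextract.errors import ParseError, ValidationError
from ilextract.kinetics import ExtractionSystem

ISO_CSV_COLUMNS = ("c_aq_mg_per_ml", "c_il_mg_per_ml")

#: Default relative RSS improvement required for `auto` to prefer hyperbolic.
AUTO_RSS_IMPROVEMENT = 0.20


@dataclass(frozen=True)
class Isotherm:
    """Paired equilibrium concentrations (C_aq, C_IL), both mg/mL."""

    c_aq: np.ndarray
    c_il: np.ndarray
    metadata: str = ""

    def __post_init__(self) -> None:
        ca = np.asarray(self.c_aq, dtype=float)
        ci = np.asarray(self.c_il, dtype=float)
        if ca.size != ci.size:
            raise ValidationError("c_aq and c_il must have equal length")
        if ca.size == 0:
            raise ValidationError("isotherm needs at least one pair")
        if np.any(ca < 0) or np.any(ci < 0):
            raise ValidationError("concentrations must be >= 0")
        object.__setattr__(self, "c_aq", ca)
        object.__setattr__(self, "c_il", ci)


@dataclass(frozen=True)
class PartitionModel:
    """Equilibrium relation between phase concentrations.

    ``kind='linear'`` uses a constant separation ratio ``s0``;
    ``kind='hyperbolic'`` adds a half-saturation constant ``k`` (mg/mL).
    """

    kind: Literal["linear", "hyperbolic"]
    s0: float
    k: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "hyperbolic"):
            raise ValidationError(f"unknown model kind {self.kind!r}")
        if not (self.s0 > 0):
            raise ValidationError(f"S0 must be > 0, got {self.s0}")
        if self.kind == "hyperbolic" and not (self.k is not None and self.k > 0):
            raise ValidationError(f"hyperbolic model needs K > 0, got {self.k}")


def separation_ratio(model: PartitionModel, c_aq) -> np.ndarray | float:
    """Separation ratio C_IL/C_aq at aqueous concentration ``c_aq`` (mg/mL)."""
    c = np.asarray(c_aq, dtype=float)
    if np.any(c < 0):
        raise ValidationError("C_aq must be >= 0")
    if model.kind == "linear":
        out = np.full_like(c, model.s0)
    else:
        out = model.s0 / (1.0 + c / model.k)
    return float(out) if np.isscalar(c_aq) or c.ndim == 0 else out


def c_il_from_c_aq(model: PartitionModel, c_aq) -> np.ndarray | float:
    """Equilibrium IL-phase concentration C_IL(C_aq) = S(C_aq)*C_aq, mg/mL."""
    s = separation_ratio(model, c_aq)
    out = np.asarray(s) * np.asarray(c_aq, dtype=float)
    return float(out) if np.isscalar(c_aq) or out.ndim == 0 else out


def predict_depletion(
    model: PartitionModel, system: ExtractionSystem
) -> tuple[float, float, float]:
    """Equilibrium state and depletion efficiency for one extraction system.

    Solves the mass balance q = C_aq*V_aq + C_IL(C_aq)*V_IL for the unique
    non-negative C_aq and returns ``(C_aq_eq, C_IL_eq, efficiency %)``,
    with efficiency = 100*(1 - C_aq_eq*V_aq/q).
    """
    q, v_aq, v_il = system.q, system.v_aq, system.v_il
    if q == 0:
        return 0.0, 0.0, 0.0
    if model.kind == "linear":
        c_aq = q / (v_aq + model.s0 * v_il)
    else:
        # Balance becomes (V_aq/K) C^2 + (V_aq + S0 V_IL - q/K) C - q = 0;
        # product of roots is -q*K/V_aq < 0, so exactly one root is positive.
        a = v_aq / model.k
        b = v_aq + model.s0 * v_il - q / model.k
        c = -q
        disc = b * b - 4.0 * a * c
        if disc < 0:  # pragma: no cover - impossible under invariants
            raise ValidationError("mass balance has no real root")
        # numerically stable quadratic: avoid cancellation for b > 0
        if b >= 0:
            c_aq = (2.0 * c) / (-b - math.sqrt(disc))
        else:
            c_aq = (-b + math.sqrt(disc)) / (2.0 * a)
    c_il = float(c_il_from_c_aq(model, c_aq))
    efficiency = 100.0 * (1.0 - c_aq * v_aq / q)
    return float(c_aq), c_il, float(efficiency)


def fit_partition(
    iso: Isotherm, kind: Literal["linear", "hyperbolic", "auto"] = "auto"
) -> PartitionModel:
    """Least-squares fit of the partition relation to isotherm data.

    The fit is performed on the (C_aq, C_IL) pairs rather than on the
    ratio, to avoid noise amplification at small C_aq.  ``auto`` selects
    the hyperbolic model when it reduces the residual sum of squares by
    more than 20% relative to the linear fit, mirroring the two-regime
    treatment of dilute vs concentrated solutions.
    """
    if kind not in ("linear", "hyperbolic", "auto"):
        raise ValidationError(f"unknown fit kind {kind!r}")
    ca, ci = iso.c_aq, iso.c_il

    def lin_fit() -> tuple[PartitionModel, float]:
        denom = float(np.sum(ca * ca))
        if denom == 0:
            raise ValidationError("all C_aq are zero: separation ratio undefined")
        s0 = float(np.sum(ca * ci) / denom)
        if s0 <= 0:
            raise ValidationError("fitted S0 is not positive")
        rss = float(np.sum((ci - s0 * ca) ** 2))
        return PartitionModel("linear", s0), rss

    def hyp_fit() -> tuple[PartitionModel, float]:
        if np.unique(ca).size < 2:
            raise ValidationError(
                "hyperbolic fit needs at least 2 distinct C_aq values"
            )

        def f(c, s0, k):
            return s0 * c / (1.0 + c / k)

        lin_s0 = max(float(np.sum(ca * ci) / np.sum(ca * ca)), 1e-12)
        k0 = max(float(np.median(ca[ca > 0])) if np.any(ca > 0) else 1.0, 1e-9)
        popt, _ = curve_fit(
            f, ca, ci, p0=[lin_s0, k0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000,
        )
        rss = float(np.sum((ci - f(ca, *popt)) ** 2))
        return PartitionModel("hyperbolic", float(popt[0]), float(popt[1])), rss

    if kind == "linear":
        return lin_fit()[0]
    if kind == "hyperbolic":
        return hyp_fit()[0]
    lin_model, lin_rss = lin_fit()
    try:
        hyp_model, hyp_rss = hyp_fit()
    except ValidationError:
        return lin_model
    if hyp_rss < (1.0 - AUTO_RSS_IMPROVEMENT) * lin_rss:
        return hyp_model
    return lin_model


def read_isotherm(path, metadata: str = "") -> Isotherm:
    """Read an isotherm from a ``c_aq_mg_per_ml,c_il_mg_per_ml`` CSV file."""
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ISO_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return Isotherm(
        frame[ISO_CSV_COLUMNS[0]].to_numpy(float),
        frame[ISO_CSV_COLUMNS[1]].to_numpy(float),
        metadata=metadata,
    )


def write_isotherm(iso: Isotherm, path) -> None:
    """Write an isotherm as CSV, round-trippable through :func:`read_isotherm`."""
    pd.DataFrame(
        {ISO_CSV_COLUMNS[0]: iso.c_aq, ISO_CSV_COLUMNS[1]: iso.c_il}
    ).to_csv(path, index=False, float_format="%.17g")
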