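"""Reversible first-order kinetics of biphasic liquid-liquid extraction.

The aqueous-phase solute concentration C_aq(t) during shaking of a
serum + ionic-liquid biphasic system is modeled by the reversible
first-order rate law

    dC_aq/dt = -k1*C_aq + k2*(q - C_aq*V_aq)/V_IL

with boundary condition C_aq(0) = q/V_aq: solute leaves the aqueous phase
at a rate proportional to its aqueous concentration (k1) and returns at a
rate proportional to its IL-phase concentration C_IL = (q - C_aq*V_aq)/V_IL
(k2).  The ODE is linear, so the solution is a single exponential
relaxation

    C_aq(t) = C_inf + (C0 - C_inf) * exp(-a*t),
    a = k1 + k2*V_aq/V_IL,    C_inf = (k2*q/V_IL) / a,

monotone from C0 = q/V_aq toward the equilibrium plateau C_inf.  At
equilibrium k1*C_aq = k2*C_IL, i.e. the model reduces to a constant
separation ratio S = C_IL/C_aq = k1/k2, which links this module to
:mod:`ilextract.partition`.

Rate constants carry units of 1/min to match shaking-time axes measured
in minutes; ionic-liquid volume may be given as a mass through the IL
density (1.12 g/mL for OMIM BF4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ilextract.errors import DegenerateModelError, ParseError, ValidationError

#: Density of the OMIM BF4 ionic liquid, g/mL, used to convert IL mass to volume.
DEFAULT_IL_DENSITY = 1.12

TRACE_CSV_COLUMNS = ("time_min", "c_aq_mg_per_ml")


@dataclass(frozen=True)
class ExtractionSystem:
    """Geometry and composition of one biphasic extraction experiment.

    Parameters
    ----------
    v_aq : float
        Aqueous (serum) phase volume, mL.
    q : float
        Total amount of solute in the system, mg.
    v_il : float, optional
        Ionic-liquid phase volume, mL.  If omitted, computed as
        ``il_mass / density``.
    il_mass : float, optional
        Ionic-liquid mass, g.
    density : float
        Ionic-liquid density, g/mL (default 1.12, OMIM BF4).
    """

    v_aq: float
    q: float
    v_il: float | None = None
    il_mass: float | None = None
    density: float = DEFAULT_IL_DENSITY

    def __post_init__(self) -> None:
        if self.v_il is None:
            if self.il_mass is None:
                raise ValidationError("provide either v_il or il_mass")
            if not (self.density > 0):
                raise ValidationError(f"density must be > 0, got {self.density}")
            object.__setattr__(self, "v_il", self.il_mass / self.density)
        if not (self.v_aq > 0):
            raise ValidationError(f"V_aq must be > 0, got {self.v_aq}")
        if not (self.v_il > 0):
            raise ValidationError(f"V_IL must be > 0, got {self.v_il}")
        if self.q < 0:
            raise ValidationError(f"q must be >= 0, got {self.q}")

    @property
    def c0(self) -> float:
        """Initial aqueous concentration q/V_aq, mg/mL."""
        return self.q / self.v_aq


@dataclass(frozen=True)
class KineticModel:
    """Rate constants (1/min) for the reversible extraction of one system."""

    k1: float
    k2: float
    system: ExtractionSystem

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ValidationError(
                f"rate constants must be >= 0, got k1={self.k1}, k2={self.k2}"
            )

    @property
    def relaxation_rate(self) -> float:
        """Exponential relaxation rate a = k1 + k2*V_aq/V_IL, 1/min."""
        return self.k1 + self.k2 * self.system.v_aq / self.system.v_il

    @property
    def c_inf(self) -> float:
        """Equilibrium aqueous concentration, mg/mL."""
        a = self.relaxation_rate
        if a == 0:
            raise DegenerateModelError("k1 = k2 = 0: no relaxation, C_inf undefined")
        return (self.k2 * self.system.q / self.system.v_il) / a

    @property
    def separation_ratio(self) -> float:
        """Equilibrium C_IL/C_aq = k1/k2 (infinite when k2 = 0)."""
        if self.k2 == 0:
            return math.inf
        return self.k1 / self.k2


@dataclass(frozen=True)
class KineticTrace:
    """A measured or simulated aqueous-phase time course."""

    times: np.ndarray
    c_aq: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.c_aq, dtype=float)
        if t.size != c.size:
            raise ValidationError("times and c_aq must have equal length")
        if t.size == 0:
            raise ValidationError("trace must contain at least one point")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValidationError("times must be nondecreasing")
        if np.any(c < 0):
            raise ValidationError("concentrations must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "c_aq", c)


@dataclass(frozen=True)
class KineticFit:
    """Result of least-squares estimation of (k1, k2)."""

    model: KineticModel
    rss: float
    se_k1: float
    se_k2: float
    converged: bool

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise ValidationError("residual sum of squares must be >= 0")


def caq_closed_form(model: KineticModel, t) -> np.ndarray | float:
    """Closed-form aqueous concentration C_aq(t), mg/mL.

    Accepts a scalar or array of times (min, >= 0).  Raises
    :class:`DegenerateModelError` when k1 = k2 = 0.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("time must be >= 0")
    a = model.relaxation_rate
    if a == 0:
        raise DegenerateModelError("k1 = k2 = 0: degenerate model")
    c0 = model.system.c0
    c_inf = model.c_inf
    out = c_inf + (c0 - c_inf) * np.exp(-a * t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def c_il_from_balance(model: KineticModel, t) -> np.ndarray | float:
    """IL-phase concentration from the mass balance C_IL = (q - C_aq*V_aq)/V_IL."""
    c_aq = caq_closed_form(model, t)
    sys = model.system
    return (sys.q - np.asarray(c_aq) * sys.v_aq) / sys.v_il if not np.isscalar(c_aq) \
        else (sys.q - c_aq * sys.v_aq) / sys.v_il


def simulate_trace(
    model: KineticModel, times, noise_sd: float = 0.0, seed: int | None = None
) -> KineticTrace:
    """Simulate a noisy time course from the closed form.

    Noise is additive zero-mean Gaussian with standard deviation
    ``noise_sd`` (mg/mL), truncated at zero.  Reproducible under a fixed
    ``seed``.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValidationError("times must be non-empty")
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    c = np.asarray(caq_closed_form(model, times), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        c = np.maximum(c + rng.normal(0.0, noise_sd, size=c.shape), 0.0)
    return KineticTrace(times, c)


def _k_grid(n: int = 5) -> np.ndarray:
    return np.logspace(-2, 1, n)


def fit_kinetics(
    trace: KineticTrace,
    system: ExtractionSystem,
    init: tuple[float, float] | None = None,
) -> KineticFit:
    """Estimate (k1, k2) by unweighted nonlinear least squares.

    Residuals are differences between the trace and the closed-form
    solution; non-negativity of the rate constants is enforced through
    bounds.  Without an explicit ``init``, a multi-start over a log-spaced
    (k1, k2) grid guards against local minima.  Standard errors come from
    the Gauss-Newton approximation to the covariance at the optimum;
    failure to converge is flagged on the result, never silent.
    """
    if np.unique(trace.times).size < 3:
        raise ValidationError("need at least 3 distinct time points to fit")

    def residuals(k):
        model = KineticModel(k1=k[0], k2=k[1], system=system)
        a = model.relaxation_rate
        if a == 0:
            return trace.c_aq - system.c0
        return caq_closed_form(model, trace.times) - trace.c_aq

    starts = [np.asarray(init, dtype=float)] if init is not None else [
        np.array([g1, g2]) for g1 in _k_grid() for g2 in _k_grid()
    ]
    best = None
    for x0 in starts:
        try:
            res = least_squares(
                residuals, x0, bounds=(0.0, np.inf), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:  # pragma: no cover - scipy internal failure
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise ValidationError("least-squares optimisation failed from every start")

    rss = float(2.0 * best.cost)
    n, p = trace.times.size, 2
    dof = max(n - p, 1)
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * (rss / dof)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.array([np.inf, np.inf])
    model = KineticModel(k1=float(best.x[0]), k2=float(best.x[1]), system=system)
    return KineticFit(
        model=model,
        rss=rss,
        se_k1=float(se[0]),
        se_k2=float(se[1]),
        converged=bool(best.success),
    )


def equilibration_time(model: KineticModel, fraction: float = 0.99) -> float:
    """Time (min) to close ``fraction`` of the gap between C0 and C_inf.

    Closed form: t = -ln(1 - fraction)/a with a the relaxation rate.
    """
    if not (0.0 < fraction < 1.0):
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    a = model.relaxation_rate
    if a == 0:
        raise DegenerateModelError("k1 = k2 = 0: system never equilibrates")
    return -math.log(1.0 - fraction) / a


def read_trace(path) -> KineticTrace:
    """Read a kinetic trace from a ``time_min,c_aq_mg_per_ml`` CSV file."""
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return KineticTrace(
        frame[TRACE_CSV_COLUMNS[0]].to_numpy(float),
        frame[TRACE_CSV_COLUMNS[1]].to_numpy(float),
    )


def write_trace(trace: KineticTrace, path) -> None:
    """Write a kinetic trace as CSV, round-trippable through :func:`read_trace`."""
    pd.DataFrame(
        {TRACE_CSV_COLUMNS[0]: trace.times, TRACE_CSV_COLUMNS[1]: trace.c_aq}
    ).to_csv(path, index=False, float_format="%.17g")
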