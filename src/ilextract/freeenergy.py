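"""Free-energy estimation from work samples and transfer-cycle arithmetic.

The favorability of moving a solute (heme, hemoglobin, cotinine) from
water into the ionic liquid is quantified by a thermodynamic cycle of two
alchemical decoupling legs: the free energy of decoupling the solute from
water and from the ionic liquid.  Their difference,

    dG_transfer(water -> IL) = dG_decouple(water) - dG_decouple(IL),

is negative when the solute prefers the ionic liquid.

Each leg's free energy is estimated from forward (A -> B) and reverse
(B -> A) work samples with the Bennett Acceptance Ratio (BAR), the
minimum-variance unbiased combination of the two directions.  With
reduced works u = beta*w and the log sample-size ratio M = ln(n_F/n_R),
the estimate x = beta*dG solves the self-consistent equation

    sum_F 1/(1 + exp(M + u_F - x)) = sum_R 1/(1 + exp(-M + u_R + x)),

whose left side increases and right side decreases in x, so the root is
unique.  The uncertainty uses the maximum-likelihood asymptotic variance

    var(x) = [ sum_i 1/(2 + 2*cosh(M + w_i - x)) ]^-1 - 1/n_F - 1/n_R,

where the sum runs over all works expressed in the forward frame
(forward works, and reverse works negated).  The variance diverges when
the two work distributions do not overlap; that condition is raised as
:class:`~ilextract.errors.OverlapError` rather than silently returning a
huge number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import log_expit, logsumexp

from ilextract.errors import ConvergenceError, OverlapError, ParseError, ValidationError

#: Boltzmann constant in kJ/(mol K).
KB_KJ_PER_MOL_K = 8.31446261815324e-3

#: Reference temperature, K.
DEFAULT_TEMPERATURE = 298.0

WORK_CSV_COLUMNS = ("direction", "work_kj_per_mol")


@dataclass(frozen=True)
class WorkSamples:
    """Forward (A->B) and reverse (B->A) work samples, kJ/mol."""

    forward: np.ndarray
    reverse: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        fwd = np.asarray(self.forward, dtype=float)
        rev = np.asarray(self.reverse, dtype=float)
        if fwd.size == 0 or rev.size == 0:
            raise ValidationError("both forward and reverse samples must be non-empty")
        if not (self.temperature > 0):
            raise ValidationError(f"temperature must be > 0 K, got {self.temperature}")
        object.__setattr__(self, "forward", fwd)
        object.__setattr__(self, "reverse", rev)

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(kB*T), mol/kJ."""
        return 1.0 / (KB_KJ_PER_MOL_K * self.temperature)


@dataclass(frozen=True)
class FreeEnergyLeg:
    """One free-energy change with its statistical uncertainty, kJ/mol."""

    label: str
    dg: float
    uncertainty: float

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise ValidationError("uncertainty must be >= 0")


@dataclass(frozen=True)
class TransferCycle:
    """Two decoupling legs of one solute: in water and in ionic liquid."""

    leg_water: FreeEnergyLeg
    leg_il: FreeEnergyLeg
    solute: str

    def __post_init__(self) -> None:
        if not self.solute:
            raise ValidationError("cycle must name its solute")


def _bar_root_function(w: WorkSamples):
    """Return g(x) = log LHS - log RHS of the BAR equation; g is increasing."""
    beta = w.beta
    u_f = beta * w.forward
    u_r = beta * w.reverse
    m = math.log(w.forward.size / w.reverse.size)

    def g(x: float) -> float:
        lhs = logsumexp(log_expit(-(m + u_f - x)))
        rhs = logsumexp(log_expit(-(-m + u_r + x)))
        return lhs - rhs

    return g, beta, m


def overlap_measure(w: WorkSamples, dg: float) -> float:
    """Mean Fermi overlap 4*<f(1-f)> in (0, 1]; ~0 means no overlap."""
    beta = w.beta
    m = math.log(w.forward.size / w.reverse.size)
    args = np.concatenate(
        [m + beta * (w.forward - dg), m + beta * (-w.reverse - dg)]
    )
    with np.errstate(over="ignore"):
        return float(np.mean(1.0 / (1.0 + np.cosh(args))) * 2.0)


def bar_estimate(w: WorkSamples) -> tuple[float, float]:
    """Bennett Acceptance Ratio estimate (dG, uncertainty) in kJ/mol.

    Solves the BAR self-consistent equation by bracketed root finding
    (the root is unique by monotonicity) and reports the asymptotic
    maximum-likelihood standard error.  Raises
    :class:`~ilextract.errors.OverlapError` when the forward and reverse
    work distributions do not overlap enough for the variance estimator
    to be finite.
    """
    g, beta, m = _bar_root_function(w)
    # Initial guess: midpoint of the two exponential-averaging estimates.
    guess = 0.5 * (jarzynski_forward(w) + jarzynski_reverse(w))
    x0 = beta * guess
    # expand a bracket around the guess until the sign changes
    half_width = 1.0
    lo, hi = x0 - half_width, x0 + half_width
    for _ in range(200):
        if g(lo) < 0 < g(hi):
            break
        half_width *= 2.0
        lo, hi = x0 - half_width, x0 + half_width
    else:
        raise ConvergenceError("could not bracket the BAR root")
    x_hat = brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16)
    dg = x_hat / beta

    # asymptotic variance over all samples in the forward frame
    args = np.concatenate(
        [m + beta * w.forward - x_hat, m - beta * w.reverse - x_hat]
    )
    with np.errstate(over="ignore"):
        info = float(np.sum(0.5 / (1.0 + np.cosh(args))))
    # mean acceptance overlap per sample; ~0 when distributions are disjoint
    overlap = 4.0 * info / args.size
    if info <= 0 or not np.isfinite(info) or overlap < 1e-12:
        raise OverlapError(
            "forward and reverse work distributions do not overlap "
            f"(mean Fermi overlap {overlap:.2e}); BAR variance estimator diverges"
        )
    var_x = 1.0 / info - (1.0 / w.forward.size + 1.0 / w.reverse.size)
    var_x = max(var_x, 0.0)
    return dg, math.sqrt(var_x) / beta


def jarzynski_forward(w: WorkSamples) -> float:
    """Exponential-averaging (Jarzynski) estimate of dG from forward works."""
    beta = w.beta
    return float(
        -(logsumexp(-beta * w.forward) - math.log(w.forward.size)) / beta
    )


def jarzynski_reverse(w: WorkSamples) -> float:
    """Jarzynski estimate of the same A->B dG from reverse (B->A) works."""
    beta = w.beta
    return float(
        (logsumexp(-beta * w.reverse) - math.log(w.reverse.size)) / beta
    )


def transfer_free_energy(cycle: TransferCycle) -> FreeEnergyLeg:
    """Water -> IL transfer free energy from the two decoupling legs.

    dG_transfer = dG_decouple(water) - dG_decouple(IL); uncertainties add
    in quadrature.  A negative result means the solute prefers the ionic
    liquid.
    """
    dg = cycle.leg_water.dg - cycle.leg_il.dg
    unc = math.hypot(cycle.leg_water.uncertainty, cycle.leg_il.uncertainty)
    return FreeEnergyLeg(
        label=f"transfer water->IL ({cycle.solute})", dg=dg, uncertainty=unc
    )


Preference = Literal["IL-preferring", "water-preferring", "indeterminate"]


def classify_preference(leg: FreeEnergyLeg, threshold_sigma: float = 2.0) -> Preference:
    """Classify solvent preference from a transfer free energy.

    ``IL-preferring`` when dG < -threshold_sigma*u, ``water-preferring``
    when dG > +threshold_sigma*u, else ``indeterminate``.
    """
    bound = threshold_sigma * leg.uncertainty
    if leg.dg < -bound:
        return "IL-preferring"
    if leg.dg > bound:
        return "water-preferring"
    return "indeterminate"


def read_work_samples(path, temperature: float = DEFAULT_TEMPERATURE) -> WorkSamples:
    """Read work samples from a ``direction,work_kj_per_mol`` CSV file."""
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in WORK_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    bad = set(frame["direction"]) - {"forward", "reverse"}
    if bad:
        raise ParseError(f"{path}: unknown direction(s) {sorted(bad)}")
    fwd = frame.loc[frame["direction"] == "forward", "work_kj_per_mol"]
    rev = frame.loc[frame["direction"] == "reverse", "work_kj_per_mol"]
    return WorkSamples(
        forward=fwd.to_numpy(float), reverse=rev.to_numpy(float),
        temperature=temperature,
    )


def write_work_samples(w: WorkSamples, path) -> None:
    """Write work samples as CSV, round-trippable through the reader."""
    pd.DataFrame(
        {
            WORK_CSV_COLUMNS[0]: ["forward"] * w.forward.size
            + ["reverse"] * w.reverse.size,
            WORK_CSV_COLUMNS[1]: np.concatenate([w.forward, w.reverse]),
        }
    ).to_csv(path, index=False, float_format="%.17g")
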