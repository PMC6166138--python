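"""Thermodynamic reversal-potential model of coupled Na+/Cl-/substrate transport.

An electrogenic cotransporter that moves ``n_na`` Na+ ions and ``n_cl`` Cl-
ions per substrate molecule carries a net charge ``z_T = n_na - n_cl`` per
cycle.  Transport is at equilibrium (zero transporter current) at the
potential

    E_T = (2.3 R T / (z_T F)) * log10( [Na]o^n_na [Cl]o^n_cl [S]o /
                                       ([Na]i^n_na [Cl]i^n_cl [S]i) )

so the shift of E_T per tenfold change of external [Na+] is
``2.3 R T n_na / (z_T F)`` — a slope diagnostic of the number of coupled
sodium ions.  This module houses that model and the arithmetic built on it:
predicting E_T, predicting the Na+ slope, inverting a measured slope to an
ion count, and fitting measured (log10[Na+]o, E_rev) series by ordinary
least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "PhysicalConstants",
    "Stoichiometry",
    "IonConditions",
    "SlopeFit",
    "reversal_potential",
    "slope_per_decade",
    "infer_n_na",
    "fit_reversal_series",
]


class ElectroneutralError(ValueError):
    """Raised when z_T = 0: an electroneutral cycle has no reversal potential."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants entering the Nernst-type slope factor.

    ``ln10_factor`` is the natural-log-to-log10 conversion prefactor; the
    conventional rounded value 2.3 is the default, and 2.303 (or
    ``math.log(10)``) may be substituted for stricter conversions.
    """

    gas_constant: float = 8.314  # J mol^-1 K^-1
    faraday: float = 96485.0  # C mol^-1
    ln10_factor: float = 2.3

    def __post_init__(self) -> None:
        if self.gas_constant <= 0 or self.faraday <= 0 or self.ln10_factor <= 0:
            raise ValueError("physical constants must be strictly positive")

    def slope_factor_mv(self, temperature_c: float) -> float:
        """2.3*R*T/F in mV at the given temperature (°C)."""
        t_k = temperature_c + 273.15
        return self.ln10_factor * self.gas_constant * t_k / self.faraday * 1000.0


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class Stoichiometry:
    """Coupled ion counts per transport cycle; the substrate count is fixed at 1."""

    n_na: float
    n_cl: float
    n_substrate: float = field(default=1.0)

    def __post_init__(self) -> None:
        if self.n_na < 0 or self.n_cl < 0:
            raise ValueError("ion counts must be non-negative")
        if self.n_substrate != 1:
            raise ValueError("one substrate molecule per cycle is assumed")

    @property
    def z_t(self) -> float:
        """Net charge moved per cycle (Na+ in, Cl- in, neutral substrate)."""
        return self.n_na - self.n_cl

    def require_electrogenic(self) -> None:
        if self.z_t == 0:
            raise ElectroneutralError(
                f"stoichiometry {self.n_na}:{self.n_cl} is electroneutral "
                "(z_T = 0): reversal potential undefined"
            )


# Internal concentrations in oocytes are not directly measured; these
# defaults are stated assumptions, not measurements.
DEFAULT_NA_I = 10.0  # mM
DEFAULT_CL_I = 40.0  # mM
DEFAULT_GLY_I = 10.0  # mM


@dataclass(frozen=True)
class IonConditions:
    """External/internal concentrations (mM) and bath temperature (°C).

    The model is logarithmic in every concentration, so zeros are rejected.
    Only concentration ratios enter E_T; the mM unit cancels.
    """

    na_o: float
    cl_o: float
    gly_o: float
    na_i: float = DEFAULT_NA_I
    cl_i: float = DEFAULT_CL_I
    gly_i: float = DEFAULT_GLY_I
    temperature_c: float = 18.0

    def __post_init__(self) -> None:
        for name in ("na_o", "cl_o", "gly_o", "na_i", "cl_i", "gly_i"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive (log model)")
        if not 0.0 <= self.temperature_c <= 45.0:
            raise ValueError("temperature_c outside the supported 0-45 °C range")

    def swapped(self) -> "IonConditions":
        """Exchange every external concentration with its internal counterpart."""
        return replace(
            self,
            na_o=self.na_i,
            na_i=self.na_o,
            cl_o=self.cl_i,
            cl_i=self.cl_o,
            gly_o=self.gly_i,
            gly_i=self.gly_o,
        )

    def with_na_o(self, na_o: float) -> "IonConditions":
        return replace(self, na_o=na_o)


@dataclass(frozen=True)
class SlopeFit:
    """OLS summary of an E_rev-versus-log10[Na+]o regression."""

    slope: float  # mV per tenfold change of [Na+]o
    intercept: float  # mV
    slope_se: float  # mV
    n_points: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a slope fit needs at least two points")
        if self.slope_se < 0:
            raise ValueError("slope_se must be non-negative")


def reversal_potential(
    stoich: Stoichiometry,
    cond: IonConditions,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Equilibrium (reversal) potential E_T of the coupled cycle, in mV.

    Raises :class:`ElectroneutralError` for z_T = 0.
    """
    stoich.require_electrogenic()
    log_arg = (
        stoich.n_na * math.log10(cond.na_o / cond.na_i)
        + stoich.n_cl * math.log10(cond.cl_o / cond.cl_i)
        + math.log10(cond.gly_o / cond.gly_i)
    )
    return consts.slope_factor_mv(cond.temperature_c) / stoich.z_t * log_arg


def slope_per_decade(
    stoich: Stoichiometry,
    temperature_c: float = 18.0,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Predicted E_T shift per tenfold change of [Na+]o, in mV/decade.

    Equals ``2.3 R T n_na / (z_T F)``; e.g. 86.5 mV at 18 °C for 3Na:1Cl
    (z_T = 2) and 115.4 mV for 2Na:1Cl (z_T = 1).
    """
    stoich.require_electrogenic()
    return consts.slope_factor_mv(temperature_c) * stoich.n_na / stoich.z_t


def infer_n_na(
    slope_mv_per_decade: float,
    z_t: float,
    temperature_c: float = 18.0,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Number of coupled Na+ ions implied by a measured E_rev slope.

    Pure inversion of :func:`slope_per_decade` at an assumed net charge:
    ``n_na = slope * z_T * F / (2.3 R T)``.
    """
    if not math.isfinite(slope_mv_per_decade):
        raise ValueError("slope must be finite")
    if z_t == 0:
        raise ElectroneutralError("z_T = 0: slope carries no n_Na information")
    return slope_mv_per_decade * z_t / consts.slope_factor_mv(temperature_c)


def fit_reversal_series(
    series: Iterable[Tuple[float, float]] | Sequence[Tuple[float, float]],
) -> SlopeFit:
    """OLS fit of measured reversal potentials against log10 [Na+]o.

    ``series`` holds ([Na+]o in mM, E_rev in mV) pairs; at least two distinct
    sodium concentrations are required.
    """
    pts = list(series)
    na = np.asarray([p[0] for p in pts], dtype=float)
    erev = np.asarray([p[1] for p in pts], dtype=float)
    if np.any(na <= 0):
        raise ValueError("all [Na+]o values must be strictly positive")
    if np.unique(na).size < 2:
        raise ValueError("need at least two distinct [Na+]o values to fit a slope")
    res = stats.linregress(np.log10(na), erev)
    return SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr) if math.isfinite(res.stderr) else 0.0,
        n_points=len(pts),
        r_squared=float(res.rvalue**2),
    )
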