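"""Current-trace and current-voltage analysis for voltage-clamped oocytes.

Covers the electrophysiological measurements around a coupled transporter:
subtracting background currents to isolate the substrate-evoked component,
normalizing I/V curves to a reference potential, locating the reversal
potential by interpolation, quantifying inward rectification, integrating
evoked charge over an application window, converting scintillation counts to
moles of substrate, and forming the charge-to-flux ratio that estimates the
net charge moved per transported molecule.

Sign convention: inward current is negative (nA).  Charges are reported with
sign preserved; ratios use magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

from .thermo import PhysicalConstants, DEFAULT_CONSTANTS

__all__ = [
    "CurrentTrace",
    "IVCurve",
    "ChargeFluxResult",
    "evoked_iv",
    "normalize_iv",
    "estimate_erev",
    "rectification_degree",
    "integrate_charge",
    "moles_from_tracer",
    "charge_to_flux",
    "DPM_PER_CI",
]

DPM_PER_CI = 2.22e12  # disintegrations per minute per curie


class NonReversingError(ValueError):
    """I/V curve does not cross zero within the tested potential range."""


@dataclass(frozen=True)
class CurrentTrace:
    """A uniformly sampled clamp recording.

    ``application_window`` marks the substrate application (start, end) in
    seconds; the 5 s preceding it define the baseline for charge integration.
    """

    time: np.ndarray  # s, uniform grid
    current: np.ndarray  # nA, inward negative
    holding_potential: float  # mV
    application_window: Tuple[float, float]
    condition: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        i = np.asarray(self.current, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "current", i)
        if t.ndim != 1 or t.size < 2 or t.shape != i.shape:
            raise ValueError("time and current must be equal-length 1-D arrays")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-9 * max(abs(dt[0]), 1.0):
            raise ValueError("time grid must be uniform")
        w0, w1 = self.application_window
        if not (t[0] <= w0 < w1 <= t[-1]):
            raise ValueError("application window must lie inside the trace")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class IVCurve:
    """Steady-state current-voltage relation averaged over oocytes."""

    potential: np.ndarray  # mV, ascending
    current: np.ndarray  # nA (mean)
    sem: np.ndarray  # nA
    n_oocytes: int = 1
    condition: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.potential, dtype=float)
        i = np.asarray(self.current, dtype=float)
        s = np.asarray(self.sem, dtype=float)
        object.__setattr__(self, "potential", v)
        object.__setattr__(self, "current", i)
        object.__setattr__(self, "sem", s)
        if v.size < 4:
            raise ValueError("an I/V curve needs at least 4 potentials")
        if v.shape != i.shape or v.shape != s.shape:
            raise ValueError("potential, current and sem must align")
        if np.any(np.diff(v) <= 0):
            raise ValueError("potentials must be strictly ascending")
        if np.any(s < 0):
            raise ValueError("sem must be non-negative")


@dataclass(frozen=True)
class ChargeFluxResult:
    """Charge moved, substrate accumulated, and their ratio."""

    charge_c: float  # C, sign preserved (inward negative)
    moles_charge: float  # mol of elementary charge, magnitude
    moles_substrate: float  # mol
    ratio: float  # elementary charges per substrate molecule

    def __post_init__(self) -> None:
        if self.moles_substrate <= 0:
            raise ValueError("moles_substrate must be positive")


def evoked_iv(with_substrate: IVCurve, without: IVCurve) -> IVCurve:
    """Substrate-evoked I/V: (substrate-supplemented) minus (background).

    SEMs of the two recordings combine in quadrature.
    """
    if not np.array_equal(with_substrate.potential, without.potential):
        raise ValueError("potential grids differ between the two I/V curves")
    return IVCurve(
        potential=with_substrate.potential.copy(),
        current=with_substrate.current - without.current,
        sem=np.hypot(with_substrate.sem, without.sem),
        n_oocytes=min(with_substrate.n_oocytes, without.n_oocytes),
        condition={**without.condition, **with_substrate.condition},
    )


def normalize_iv(iv: IVCurve, reference_potential: float = -150.0) -> IVCurve:
    """Scale currents by the magnitude of the current at a reference potential.

    With inward (negative) currents the normalized value at the reference is
    -1.  Idempotent up to the sign convention: normalizing twice equals
    normalizing once.
    """
    mask = iv.potential == reference_potential
    if not np.any(mask):
        raise ValueError(f"{reference_potential} mV not in the potential grid")
    ref = float(iv.current[mask][0])
    if ref == 0:
        raise ValueError("current at the reference potential is zero")
    scale = abs(ref)
    return replace(iv, current=iv.current / scale, sem=iv.sem / scale)


def estimate_erev(iv: IVCurve) -> float:
    """Reversal potential from the single zero crossing of an I/V curve, mV.

    Linear interpolation between the bracketing pair of grid points.  An exact
    zero at a grid point counts as the crossing.  Raises
    :class:`NonReversingError` when no sign change exists (the wild-type
    phenotype over the tested range) and ``ValueError`` on multiple crossings.
    """
    i = iv.current
    v = iv.potential
    exact = np.flatnonzero(i == 0.0)
    sign_change = np.flatnonzero(i[:-1] * i[1:] < 0)
    n_crossings = exact.size + sign_change.size
    if n_crossings == 0:
        raise NonReversingError("current does not reverse within the tested range")
    if n_crossings > 1:
        raise ValueError(f"{n_crossings} zero crossings: reversal ambiguous")
    if exact.size:
        return float(v[exact[0]])
    k = sign_change[0]
    frac = -i[k] / (i[k + 1] - i[k])
    return float(v[k] + frac * (v[k + 1] - v[k]))


def rectification_degree(iv: IVCurve, k: int = 3) -> float:
    """Ratio of limb slopes: hyperpolarized over depolarized.

    OLS slope through the ``k`` most-negative-potential points divided by the
    slope through the ``k`` most-positive ones.  1.0 for any affine I/V;
    values > 1 indicate inward rectification.  A zero depolarized-limb slope
    returns ``inf``.
    """
    if k < 2:
        raise ValueError("need at least 2 points per limb")
    if iv.potential.size < 2 * k:
        raise ValueError(f"need at least {2 * k} points for k = {k}")
    neg_slope = np.polyfit(iv.potential[:k], iv.current[:k], 1)[0]
    pos_slope = np.polyfit(iv.potential[-k:], iv.current[-k:], 1)[0]
    if pos_slope == 0:
        return float("inf")
    return float(neg_slope / pos_slope)


BASELINE_SECONDS = 5.0


def integrate_charge(
    trace: CurrentTrace,
    window: Optional[Tuple[float, float]] = None,
) -> float:
    """Charge moved during the application window, in coulombs.

    Trapezoidal integral of (current - baseline) over the window.  The
    baseline is the mean current over the 5 s preceding the trace's
    application window (or the shorter pre-application segment), so
    integrals over sub-windows of the application are additive.  nA·s are
    converted to C (1e-9); the sign is preserved, so an inward evoked
    current yields negative charge.
    """
    w0, w1 = window if window is not None else trace.application_window
    t = trace.time
    if not (t[0] <= w0 < w1 <= t[-1]):
        raise ValueError("integration window outside the trace")
    app0 = trace.application_window[0]
    pre = (t >= app0 - BASELINE_SECONDS) & (t < app0)
    baseline = float(np.mean(trace.current[pre])) if np.any(pre) else 0.0
    inside = (t >= w0) & (t <= w1)
    q_nas = float(
        np.trapezoid(trace.current[inside] - baseline, t[inside])
    )
    return q_nas * 1e-9


def moles_from_tracer(
    dpm_sample: float,
    dpm_background: float,
    specific_activity_ci_per_mmol: float,
) -> float:
    """Moles of substrate from scintillation counts.

    Background counts (non-injected oocytes) are subtracted; the net dpm is
    divided by 2.22e12 dpm/Ci and the specific activity (Ci/mmol), then
    converted mmol → mol.
    """
    if specific_activity_ci_per_mmol <= 0:
        raise ValueError("specific activity must be positive")
    if dpm_background > dpm_sample:
        raise ValueError("background dpm exceeds sample dpm")
    net = dpm_sample - dpm_background
    return net / (DPM_PER_CI * specific_activity_ci_per_mmol) * 1e-3


def charge_to_flux(
    charge_c: float,
    moles_substrate: float,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
) -> ChargeFluxResult:
    """Elementary charges moved per substrate molecule transported.

    |charge|/F gives moles of charge; dividing by the moles of substrate
    (from radiotracer counting) estimates the net charge z_T per cycle.
    """
    if moles_substrate <= 0:
        raise ValueError("moles_substrate must be positive")
    moles_charge = abs(charge_c) / consts.faraday
    return ChargeFluxResult(
        charge_c=charge_c,
        moles_charge=moles_charge,
        moles_substrate=moles_substrate,
        ratio=moles_charge / moles_substrate,
    )
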