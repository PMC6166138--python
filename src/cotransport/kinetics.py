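"""Saturation kinetics of radiotracer uptake: Hill and Michaelis-Menten fits.

Uptake assays measure substrate accumulation (nmol per mg protein per 10 min)
as a function of the varied species concentration.  Sodium dependence is
cooperative and fitted with the Hill equation

    v(C) = Vmax * C^n / (EC50^n + C^n)

while chloride and substrate dependence follow Michaelis-Menten kinetics
(the n = 1 special case, EC50 = Km).  Accumulation by mock-transfected cells
is subtracted point-by-point before fitting, and the transport efficiency
Vmax/Km summarizes each fit.

Fitting is unweighted nonlinear least squares on individual replicate rates
(via ``scipy.optimize.curve_fit``) with a deterministic multi-start over the
Hill exponent; no randomness is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "UptakeDataset",
    "HillFit",
    "MMFit",
    "subtract_background",
    "fit_hill",
    "fit_mm",
    "transport_efficiency",
    "hill_rate",
]

HILL_N_STARTS = (0.5, 1.0, 2.0, 3.0)


class FitError(RuntimeError):
    """Nonlinear fit failed to converge from every start.

    Carries the best attempt (possibly ``None``) in ``best_attempt``.
    """

    def __init__(self, message: str, best_attempt: Optional["HillFit"] = None):
        super().__init__(message)
        self.best_attempt = best_attempt


def hill_rate(conc, vmax: float, ec50: float, n: float):
    """Hill saturation curve; n = 1 gives Michaelis-Menten."""
    conc = np.asarray(conc, dtype=float)
    cn = np.power(conc, n)
    return vmax * cn / (np.power(ec50, n) + cn)


@dataclass(frozen=True)
class UptakeDataset:
    """Concentration-rate observations for one construct and varied species.

    ``concentration`` and ``rate`` are parallel per-replicate arrays;
    replicates at the same concentration appear as separate rows and enter
    fits individually.  ``conc_unit`` is carried through so Km is reported
    in the input unit (μM for substrate titrations, mM for ion titrations).
    """

    concentration: np.ndarray
    rate: np.ndarray
    replicate_id: np.ndarray
    construct: str = ""
    varied_species: str = ""
    conc_unit: str = "mM"
    background_subtracted: bool = False
    clipped_negative: int = 0
    ground_truth: Optional[dict] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentration, dtype=float)
        rate = np.asarray(self.rate, dtype=float)
        rep = np.asarray(self.replicate_id)
        object.__setattr__(self, "concentration", conc)
        object.__setattr__(self, "rate", rate)
        object.__setattr__(self, "replicate_id", rep)
        if conc.shape != rate.shape or conc.shape != rep.shape:
            raise ValueError("concentration, rate and replicate_id must align")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")

    def __len__(self) -> int:
        return self.concentration.size

    def distinct_concentrations(self) -> np.ndarray:
        return np.unique(self.concentration)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "construct": self.construct,
                "varied_species": self.varied_species,
                "concentration": self.concentration,
                "conc_unit": self.conc_unit,
                "rate_nmol_per_mg_10min": self.rate,
                "replicate": self.replicate_id,
            }
        )


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters with asymptotic standard errors."""

    vmax: float
    ec50: float
    n_hill: float
    vmax_se: float
    ec50_se: float
    n_hill_se: float
    r_squared: float
    saturation_warning: bool = False

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.ec50 <= 0 or self.n_hill <= 0:
            raise ValueError("vmax, ec50 and n_hill must be strictly positive")

    def predict(self, conc):
        return hill_rate(conc, self.vmax, self.ec50, self.n_hill)


@dataclass(frozen=True)
class MMFit:
    """Fitted Michaelis-Menten parameters; ``efficiency`` is Vmax/Km."""

    vmax: float
    km: float
    vmax_se: float
    km_se: float
    r_squared: float
    conc_unit: str = "mM"
    saturation_warning: bool = False

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError("vmax and km must be strictly positive")

    @property
    def efficiency(self) -> float:
        return self.vmax / self.km

    def predict(self, conc):
        return hill_rate(conc, self.vmax, self.km, 1.0)


def subtract_background(sample: UptakeDataset, mock: UptakeDataset) -> UptakeDataset:
    """Subtract per-concentration mean mock-cell uptake from a sample dataset.

    Grids must match: every sample concentration needs mock observations at
    the same concentration.  Rates that go negative after subtraction are
    clipped to zero and counted in ``clipped_negative``.
    """
    sample_grid = set(np.unique(sample.concentration).tolist())
    mock_grid = set(np.unique(mock.concentration).tolist())
    missing = sorted(sample_grid - mock_grid)
    if missing:
        raise ValueError(
            f"mock dataset lacks concentrations {missing}; grids must match"
        )
    mock_mean = {
        c: float(np.mean(mock.rate[mock.concentration == c])) for c in mock_grid
    }
    corrected = sample.rate - np.array([mock_mean[c] for c in sample.concentration])
    n_clipped = int(np.sum(corrected < 0))
    corrected = np.clip(corrected, 0.0, None)
    return replace(
        sample,
        rate=corrected,
        background_subtracted=True,
        clipped_negative=n_clipped,
    )


def _prepare_fit(data: UptakeDataset):
    conc = data.concentration
    rate = data.rate
    if np.unique(conc).size < 4:
        raise ValueError("need at least 4 distinct concentrations to fit")
    if np.allclose(rate, rate[0]):
        raise ValueError("rates are all equal; saturation curve unidentifiable")
    return conc, rate


def _saturation_not_approached(data: UptakeDataset) -> bool:
    grid = data.distinct_concentrations()
    low = float(np.mean(data.rate[data.concentration == grid[0]]))
    return float(np.max(data.rate)) < 2.0 * low if low > 0 else False


def _ec50_init(conc: np.ndarray, rate: np.ndarray) -> float:
    """Concentration nearest the half-maximal observed rate."""
    half = np.max(rate) / 2.0
    positive = conc[conc > 0]
    if positive.size == 0:
        return 1.0
    idx = int(np.argmin(np.abs(rate[conc > 0] - half)))
    return float(positive[idx])


def _r_squared(rate: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((rate - fitted) ** 2))
    ss_tot = float(np.sum((rate - np.mean(rate)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def fit_hill(data: UptakeDataset) -> HillFit:
    """Fit the Hill equation to an uptake dataset by least squares.

    Multi-start over Hill exponents ``{0.5, 1, 2, 3}``, keeping the
    lowest-SSE converged solution.  A ``saturation_warning`` is set when the
    largest observed rate is less than twice the rate at the lowest
    concentration (the plateau was not approached, so Vmax and EC50 are
    weakly constrained).
    """
    conc, rate = _prepare_fit(data)
    vmax0 = float(np.max(rate))
    ec50_0 = _ec50_init(conc, rate)
    best = None
    for n0 in HILL_N_STARTS:
        try:
            popt, pcov = curve_fit(
                hill_rate,
                conc,
                rate,
                p0=[vmax0, ec50_0, n0],
                bounds=([1e-12, 1e-12, 1e-3], [np.inf, np.inf, 10.0]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((rate - hill_rate(conc, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        raise FitError("Hill fit failed to converge from every start")
    _, popt, pcov = best
    se = np.sqrt(np.diag(pcov))
    return HillFit(
        vmax=float(popt[0]),
        ec50=float(popt[1]),
        n_hill=float(popt[2]),
        vmax_se=float(se[0]),
        ec50_se=float(se[1]),
        n_hill_se=float(se[2]),
        r_squared=_r_squared(rate, hill_rate(conc, *popt)),
        saturation_warning=_saturation_not_approached(data),
    )


def fit_mm(data: UptakeDataset) -> MMFit:
    """Fit the Michaelis-Menten equation (Hill with n fixed at 1)."""
    conc, rate = _prepare_fit(data)
    vmax0 = float(np.max(rate))
    km0 = _ec50_init(conc, rate)
    mm = lambda c, vmax, km: hill_rate(c, vmax, km, 1.0)
    try:
        popt, pcov = curve_fit(
            mm,
            conc,
            rate,
            p0=[vmax0, km0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Michaelis-Menten fit failed: {exc}") from exc
    se = np.sqrt(np.diag(pcov))
    return MMFit(
        vmax=float(popt[0]),
        km=float(popt[1]),
        vmax_se=float(se[0]),
        km_se=float(se[1]),
        r_squared=_r_squared(rate, mm(conc, *popt)),
        conc_unit=data.conc_unit,
        saturation_warning=_saturation_not_approached(data),
    )


def transport_efficiency(fit: MMFit) -> tuple[float, float]:
    """Vmax/Km with first-order (delta-method) standard error.

    The ratio of fitted means; SE treats Vmax and Km as uncorrelated, which
    overstates precision slightly when they covary.
    """
    eff = fit.efficiency
    rel_var = (fit.vmax_se / fit.vmax) ** 2 + (fit.km_se / fit.km) ** 2
    return eff, abs(eff) * math.sqrt(rel_var)
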