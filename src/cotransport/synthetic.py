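"""Synthetic voltage-clamp and uptake experiments with known ground truth.

Every generator draws from an explicit seed and embeds its generating
parameters in the returned object, so downstream analyses can be tested for
parameter recovery without external data.  The emulated protocols:

* I/V families: voltage steps from -150 to +30 mV in 20 mV increments, with
  substrate-evoked currents reversing exactly at the thermodynamic E_T of
  the chosen stoichiometry and ion conditions.
* Reversal-potential series: per-oocyte E_rev at several external [Na+]
  levels with Gaussian measurement noise.
* Charge-to-flux experiments: a 1-min application of radiolabeled substrate
  at fixed holding potential, yielding a current trace plus scintillation
  counts at 0.4 Ci/mmol specific activity.
* Uptake datasets: Hill- or Michaelis-Menten-shaped concentration series
  with multiplicative Gaussian replicate noise and optional mock-cell
  background rows.

The steady-state current model is a linear driving force gated by a
sigmoidal rectification factor,

    I(V) = g * z_T * (V - E_T) * sigma(V),    sigma(V) = 1/(1 + exp((V - V0)/k)),

the simplest form with an exact thermodynamic reversal and tunable inward
rectification; it is a phenomenological choice, not a kinetic transport
model.

Randomness uses one seeded stream per experiment, split hierarchically per
oocyte/replicate (``numpy.random.SeedSequence.spawn``), so enlarging an
experiment never perturbs the replicates already drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .thermo import (
    IonConditions,
    PhysicalConstants,
    DEFAULT_CONSTANTS,
    Stoichiometry,
    reversal_potential,
)
from .traces import CurrentTrace, IVCurve
from .kinetics import UptakeDataset, hill_rate

__all__ = [
    "SimulationSpec",
    "RevPotSeries",
    "TracerCounts",
    "VOLTAGE_GRID",
    "gen_iv_family",
    "gen_erev_series",
    "gen_charge_flux_experiment",
    "gen_uptake_dataset",
]

# Step protocol: -150 to +30 mV in 20 mV increments (ascending order).
VOLTAGE_GRID = np.arange(-150.0, 31.0, 20.0)

SPECIFIC_ACTIVITY_CI_PER_MMOL = 0.4
SAMPLING_HZ = 1000.0
BASELINE_PAD_S = 5.0
TAIL_PAD_S = 2.0


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth parameters and noise levels for one synthetic experiment.

    ``max_conductance`` (nA/mV) scales the linear driving-force current;
    ``rectification_v0``/``rectification_k`` (mV) place and sharpen the
    sigmoidal gate (``rectification_k = None`` disables rectification).
    Noise: ``noise_sd_current`` (nA) on sampled currents, ``noise_sd_erev``
    (mV) on per-oocyte reversal potentials, ``noise_cv_rate`` (fraction) as
    the multiplicative CV of uptake rates.  ``seed`` is mandatory: there is
    no implicit randomness.
    """

    stoichiometry: Stoichiometry
    conditions: IonConditions
    seed: int
    max_conductance: float = 0.5  # nA/mV, gives tens-of-nA currents at -150 mV
    rectification_v0: Optional[float] = -40.0  # mV
    rectification_k: Optional[float] = 30.0  # mV
    noise_sd_current: float = 0.0  # nA
    noise_sd_erev: float = 0.0  # mV
    noise_cv_rate: float = 0.0  # fraction of the mean rate
    n_replicates: int = 3
    constants: PhysicalConstants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        if self.noise_sd_current < 0 or self.noise_sd_erev < 0 or self.noise_cv_rate < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        if self.max_conductance <= 0:
            raise ValueError("max_conductance must be positive")

    def rng_streams(self, n: int) -> List[np.random.Generator]:
        """``n`` independent child generators derived from the spec seed."""
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(n)]


@dataclass(frozen=True)
class RevPotSeries:
    """Per-oocyte ([Na+]o, E_rev) observations from a reversal-potential assay."""

    oocyte_id: np.ndarray
    na_o: np.ndarray  # mM
    e_rev: np.ndarray  # mV
    ground_truth: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        oid = np.asarray(self.oocyte_id)
        na = np.asarray(self.na_o, dtype=float)
        ev = np.asarray(self.e_rev, dtype=float)
        object.__setattr__(self, "oocyte_id", oid)
        object.__setattr__(self, "na_o", na)
        object.__setattr__(self, "e_rev", ev)
        if not (oid.shape == na.shape == ev.shape):
            raise ValueError("oocyte_id, na_o and e_rev must align")

    def points(self) -> List[Tuple[float, float]]:
        """All (na_o, e_rev) pairs, pooled across oocytes."""
        return list(zip(self.na_o.tolist(), self.e_rev.tolist()))

    def per_oocyte(self) -> dict:
        """Mapping oocyte id -> list of (na_o, e_rev) pairs."""
        out: dict = {}
        for oid, na, ev in zip(self.oocyte_id, self.na_o, self.e_rev):
            out.setdefault(oid.item() if hasattr(oid, "item") else oid, []).append(
                (float(na), float(ev))
            )
        return out


@dataclass(frozen=True)
class TracerCounts:
    """Scintillation-counting output of a radiotracer uptake measurement."""

    dpm_sample: float
    dpm_background: float
    specific_activity_ci_per_mmol: float = SPECIFIC_ACTIVITY_CI_PER_MMOL


def _sigma(v: np.ndarray, v0: Optional[float], k: Optional[float]) -> np.ndarray:
    if v0 is None or k is None:
        return np.ones_like(v)
    return 1.0 / (1.0 + np.exp((v - v0) / k))


def gen_iv_family(
    spec: SimulationSpec,
    na_o_list: Sequence[float],
    potentials: Optional[np.ndarray] = None,
) -> List[IVCurve]:
    """One steady-state I/V curve per external [Na+] level.

    The noiseless curve crosses zero exactly at the thermodynamic E_T for
    the spec's stoichiometry and conditions; Gaussian current noise of SD
    ``noise_sd_current`` is added on top.
    """
    spec.stoichiometry.require_electrogenic()
    v = np.asarray(potentials if potentials is not None else VOLTAGE_GRID, dtype=float)
    curves = []
    rngs = spec.rng_streams(len(na_o_list))
    for na_o, rng in zip(na_o_list, rngs):
        cond = spec.conditions.with_na_o(na_o)
        e_t = reversal_potential(spec.stoichiometry, cond, spec.constants)
        ideal = (
            spec.max_conductance
            * spec.stoichiometry.z_t
            * (v - e_t)
            * _sigma(v, spec.rectification_v0, spec.rectification_k)
        )
        noisy = ideal + rng.normal(0.0, spec.noise_sd_current, size=v.shape) \
            if spec.noise_sd_current > 0 else ideal
        curves.append(
            IVCurve(
                potential=v,
                current=noisy,
                sem=np.full_like(v, spec.noise_sd_current),
                n_oocytes=1,
                condition={"na_o_mM": float(na_o), "e_t_true_mV": float(e_t)},
            )
        )
    return curves


def gen_erev_series(
    spec: SimulationSpec,
    na_o_list: Sequence[float],
    n_oocytes: int,
) -> RevPotSeries:
    """Per-oocyte reversal potentials over a grid of external [Na+] levels.

    Each oocyte observes the thermodynamic E_T at every sodium level plus
    independent Gaussian noise of SD ``noise_sd_erev``.
    """
    spec.stoichiometry.require_electrogenic()
    oocyte_ids, na_vals, e_vals = [], [], []
    rngs = spec.rng_streams(n_oocytes)
    for oocyte, rng in enumerate(rngs):
        for na_o in na_o_list:
            cond = spec.conditions.with_na_o(na_o)
            e_t = reversal_potential(spec.stoichiometry, cond, spec.constants)
            noise = rng.normal(0.0, spec.noise_sd_erev) if spec.noise_sd_erev > 0 else 0.0
            oocyte_ids.append(oocyte)
            na_vals.append(float(na_o))
            e_vals.append(e_t + noise)
    return RevPotSeries(
        oocyte_id=np.asarray(oocyte_ids),
        na_o=np.asarray(na_vals),
        e_rev=np.asarray(e_vals),
        ground_truth={
            "n_na": spec.stoichiometry.n_na,
            "n_cl": spec.stoichiometry.n_cl,
            "z_t": spec.stoichiometry.z_t,
            "temperature_c": spec.conditions.temperature_c,
        },
    )


def gen_charge_flux_experiment(
    spec: SimulationSpec,
    transport_rate_mol_per_s: float,
    duration_s: float = 60.0,
    holding_potential: float = -60.0,
    dpm_background: float = 200.0,
) -> Tuple[CurrentTrace, TracerCounts]:
    """A radiolabeled-substrate application at fixed holding potential.

    ``N = rate * duration`` moles of substrate are transported, moving
    ``z_T * F * N`` coulombs, i.e. a steady evoked current of amplitude
    ``z_T * F * N / duration`` (inward, negative) during the application
    window.  The trace is sampled at 1 kHz with a 5 s pre-application
    baseline and 2 s tail; scintillation counts follow from the specific
    activity (dpm = N[mmol] * SA * 2.22e12) on top of the background.
    """
    if transport_rate_mol_per_s <= 0 or duration_s <= 0:
        raise ValueError("transport rate and duration must be positive")
    spec.stoichiometry.require_electrogenic()
    # snap the application window onto the sampling grid, and derive its
    # endpoints from the same index arithmetic as the time grid, so the
    # integrated charge corresponds exactly to the simulated transport
    n_base = int(round(BASELINE_PAD_S * SAMPLING_HZ))
    n_dur = int(round(duration_s * SAMPLING_HZ))
    n_tail = int(round(TAIL_PAD_S * SAMPLING_HZ))
    if n_dur < 1:
        raise ValueError("duration shorter than one sampling interval")
    t = np.arange(n_base + n_dur + n_tail + 1) / SAMPLING_HZ
    window = (float(t[n_base]), float(t[n_base + n_dur]))
    duration_s = window[1] - window[0]
    n_mol = transport_rate_mol_per_s * duration_s
    amplitude_na = (
        spec.stoichiometry.z_t * spec.constants.faraday * n_mol / duration_s * 1e9
    )
    current = np.zeros_like(t)
    inside = (t >= window[0]) & (t <= window[1])
    current[inside] = -amplitude_na  # inward
    if spec.noise_sd_current > 0:
        rng = spec.rng_streams(1)[0]
        current = current + rng.normal(0.0, spec.noise_sd_current, size=t.shape)
    trace = CurrentTrace(
        time=t,
        current=current,
        holding_potential=holding_potential,
        application_window=window,
        condition={
            "z_t_true": spec.stoichiometry.z_t,
            "moles_true": n_mol,
            "amplitude_na_true": amplitude_na,
        },
    )
    dpm_net = n_mol * 1e3 * SPECIFIC_ACTIVITY_CI_PER_MMOL * 2.22e12
    counts = TracerCounts(
        dpm_sample=dpm_net + dpm_background,
        dpm_background=dpm_background,
    )
    return trace, counts


def gen_uptake_dataset(
    model: str,
    params: dict,
    concentrations: Sequence[float],
    spec: SimulationSpec,
    conc_unit: str = "mM",
    varied_species: str = "Na+",
    construct: str = "synthetic",
    mock_mean: float = 0.0,
) -> Tuple[UptakeDataset, Optional[UptakeDataset]]:
    """Hill- or MM-shaped uptake data with multiplicative replicate noise.

    Rates are drawn as ``model(C) * (1 + eps)`` with
    ``eps ~ N(0, noise_cv_rate)``.  When ``mock_mean`` is nonzero a matching
    mock-transfected background dataset (constant mean rate ``mock_mean`` on
    the same grid) is returned alongside and *added* to the sample rates, so
    that background subtraction recovers the transporter-specific signal.
    """
    if model == "hill":
        truth = dict(vmax=params["vmax"], ec50=params["ec50"], n=params["n"])
    elif model == "mm":
        truth = dict(vmax=params["vmax"], ec50=params["km"], n=1.0)
    else:
        raise ValueError(f"unknown saturation model {model!r}")
    conc_grid = np.asarray(concentrations, dtype=float)
    rngs = spec.rng_streams(2 * spec.n_replicates)
    conc_all, rate_all, rep_all = [], [], []
    mock_rate_all = []
    for rep in range(spec.n_replicates):
        rng = rngs[rep]
        mock_rng = rngs[spec.n_replicates + rep]
        ideal = hill_rate(conc_grid, truth["vmax"], truth["ec50"], truth["n"])
        eps = (
            rng.normal(0.0, spec.noise_cv_rate, size=conc_grid.shape)
            if spec.noise_cv_rate > 0
            else np.zeros_like(conc_grid)
        )
        mock = np.full_like(conc_grid, mock_mean)
        if mock_mean != 0.0 and spec.noise_cv_rate > 0:
            mock = mock * (1.0 + mock_rng.normal(0.0, spec.noise_cv_rate, size=conc_grid.shape))
        conc_all.append(conc_grid)
        rate_all.append(ideal * (1.0 + eps) + (mock_mean if mock_mean else 0.0))
        rep_all.append(np.full(conc_grid.shape, rep))
        mock_rate_all.append(mock)
    sample = UptakeDataset(
        concentration=np.concatenate(conc_all),
        rate=np.concatenate(rate_all),
        replicate_id=np.concatenate(rep_all),
        construct=construct,
        varied_species=varied_species,
        conc_unit=conc_unit,
        ground_truth=truth,
    )
    mock_ds = None
    if mock_mean != 0.0:
        mock_ds = UptakeDataset(
            concentration=np.concatenate(conc_all),
            rate=np.concatenate(mock_rate_all),
            replicate_id=np.concatenate(rep_all),
            construct="mock",
            varied_species=varied_species,
            conc_unit=conc_unit,
        )
    return sample, mock_ds
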