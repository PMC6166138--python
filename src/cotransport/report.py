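"""End-to-end stoichiometry report: the full analysis chain on one config.

For each construct the pipeline runs whatever stages its inputs support —
sodium-dependence Hill fit, chloride-dependence Michaelis-Menten fit,
reversal-potential slope and the inferred Na+ count, charge-to-flux ratio,
and I/V rectification — and assembles them into a single report with full
provenance (inputs, seed, config hash).  Inputs may be measured CSV files
or a synthetic-experiment block; both go through the identical analysis
path.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import io as cio
from .kinetics import fit_hill, fit_mm, subtract_background, transport_efficiency
from .synthetic import (
    RevPotSeries,
    SimulationSpec,
    gen_charge_flux_experiment,
    gen_erev_series,
    gen_iv_family,
    gen_uptake_dataset,
)
from .thermo import (
    IonConditions,
    PhysicalConstants,
    Stoichiometry,
    fit_reversal_series,
    infer_n_na,
)
from .traces import (
    charge_to_flux,
    estimate_erev,
    integrate_charge,
    moles_from_tracer,
    rectification_degree,
)

__all__ = ["StoichiometryReport", "run_pipeline", "load_config"]

log = logging.getLogger("cotransport.pipeline")


@dataclass
class StoichiometryReport:
    """Per-construct analysis blocks plus provenance."""

    constructs: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"constructs": self.constructs, "provenance": self.provenance}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = ["Stoichiometry report", "=" * 20]
        for name, block in self.constructs.items():
            lines.append(f"\n[{name}]")
            for stage, vals in block.items():
                lines.append(f"  {stage}:")
                for k, v in vals.items():
                    lines.append(f"    {k}: {v}")
        lines.append("\nprovenance:")
        for k, v in self.provenance.items():
            lines.append(f"  {k}: {v}")
        return "\n".join(lines) + "\n"


def load_config(path_or_dict: Union[str, Path, dict]) -> dict:
    if isinstance(path_or_dict, dict):
        return path_or_dict
    text = Path(path_or_dict).read_text()
    return yaml.safe_load(text)


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _parse_stoichiometry(s: Union[str, dict]) -> Stoichiometry:
    if isinstance(s, dict):
        return Stoichiometry(n_na=s["n_na"], n_cl=s["n_cl"])
    n_na, n_cl = (float(x) for x in str(s).split(":"))
    return Stoichiometry(n_na=n_na, n_cl=n_cl)


def _conditions(block: dict, temperature_c: float) -> IonConditions:
    cond = dict(block.get("conditions", {}))
    cond.setdefault("na_o", 100.0)
    cond.setdefault("cl_o", 106.0)
    cond.setdefault("gly_o", 1.0)
    return IonConditions(temperature_c=temperature_c, **cond)


def _slope_block(series: RevPotSeries, z_t: float, temperature_c: float,
                 consts: PhysicalConstants) -> dict:
    """Per-oocyte OLS slopes averaged, plus pooled fit and inferred n_Na."""
    per = series.per_oocyte()
    slopes = []
    for pts in per.values():
        if len({p[0] for p in pts}) >= 2:
            slopes.append(fit_reversal_series(pts).slope)
    pooled = fit_reversal_series(series.points())
    mean_slope = float(np.mean(slopes)) if slopes else pooled.slope
    se_slope = (
        float(np.std(slopes, ddof=1) / np.sqrt(len(slopes))) if len(slopes) > 1 else pooled.slope_se
    )
    return {
        "slope_mV_per_decade": mean_slope,
        "slope_se_mV": se_slope,
        "pooled_slope_mV_per_decade": pooled.slope,
        "pooled_r_squared": pooled.r_squared,
        "n_oocytes": len(per),
        "inferred_n_na": infer_n_na(mean_slope, z_t, temperature_c, consts),
        "assumed_z_t": z_t,
    }


def _simulate_inputs(name: str, block: dict, stoich: Stoichiometry,
                     cond: IonConditions, consts: PhysicalConstants,
                     seed: int) -> dict:
    sim = block["simulate"]
    spec = SimulationSpec(
        stoichiometry=stoich,
        conditions=cond,
        seed=seed,
        noise_sd_current=float(sim.get("noise_sd_current", 0.0)),
        noise_sd_erev=float(sim.get("noise_sd_erev", 0.0)),
        noise_cv_rate=float(sim.get("noise_cv_rate", 0.0)),
        n_replicates=int(sim.get("n_replicates", 3)),
        constants=consts,
    )
    inputs: dict = {}
    na_list = sim.get("na_o_list", [20, 40, 60, 80, 100])
    inputs["erev_series"] = gen_erev_series(spec, na_list, int(sim.get("n_oocytes", 8)))
    if "hill" in sim:
        h = sim["hill"]
        sample, mock = gen_uptake_dataset(
            "hill",
            {"vmax": h["vmax"], "ec50": h["ec50"], "n": h["n"]},
            h.get("concentrations", [5, 10, 20, 40, 60, 80, 100, 150]),
            spec,
            varied_species="Na+",
            construct=name,
            mock_mean=float(h.get("mock_mean", 0.0)),
        )
        inputs["uptake_na"] = (sample, mock)
    if "mm_cl" in sim:
        m = sim["mm_cl"]
        sample, mock = gen_uptake_dataset(
            "mm",
            {"vmax": m["vmax"], "km": m["km"]},
            m.get("concentrations", [2, 5, 10, 20, 40, 80, 120, 150]),
            spec,
            varied_species="Cl-",
            construct=name,
            mock_mean=float(m.get("mock_mean", 0.0)),
        )
        inputs["uptake_cl"] = (sample, mock)
    inputs["charge_flux"] = gen_charge_flux_experiment(
        spec,
        float(sim.get("transport_rate_mol_per_s", 1e-14)),
        float(sim.get("duration_s", 60.0)),
    )
    inputs["iv"] = gen_iv_family(spec, [cond.na_o])[0]
    return inputs


def _file_inputs(block: dict) -> dict:
    inputs: dict = {}
    if "erev_csv" in block:
        inputs["erev_series"] = cio.read_reversal_series(block["erev_csv"])
    if "uptake_na_csv" in block:
        sample = cio.read_uptake(block["uptake_na_csv"], block.get("construct_label"))
        mock = None
        if "mock_na_csv" in block:
            mock = cio.read_uptake(block["mock_na_csv"], "mock")
        inputs["uptake_na"] = (sample, mock)
    if "uptake_cl_csv" in block:
        sample = cio.read_uptake(block["uptake_cl_csv"], block.get("construct_label"))
        mock = None
        if "mock_cl_csv" in block:
            mock = cio.read_uptake(block["mock_cl_csv"], "mock")
        inputs["uptake_cl"] = (sample, mock)
    if "trace_csv" in block:
        trace = cio.read_trace(block["trace_csv"])
        inputs["charge_flux"] = (trace, None)
    if "iv_csv" in block:
        inputs["iv"] = cio.read_iv(block["iv_csv"])
    return inputs


def run_pipeline(config: Union[str, Path, dict],
                 out_dir: Optional[Union[str, Path]] = None) -> StoichiometryReport:
    """Execute every analysis stage the config's inputs support.

    Writes ``report.json`` and ``report.txt`` into ``out_dir`` when given.
    Raises on missing inputs or schema violations; warnings (clipped rates,
    non-reversing curves) are logged and recorded in the report.
    """
    cfg = load_config(config)
    consts = PhysicalConstants(**cfg.get("constants", {}))
    seed = int(cfg.get("seed", 0))
    report = StoichiometryReport(
        provenance={
            "seed": seed,
            "config_hash": _config_hash(cfg),
            "constants": {
                "gas_constant": consts.gas_constant,
                "faraday": consts.faraday,
                "ln10_factor": consts.ln10_factor,
            },
        }
    )
    constructs = cfg.get("constructs")
    if not constructs:
        raise ValueError("config must define at least one construct")
    for i, (name, block) in enumerate(constructs.items()):
        log.info("stage=construct name=%s", name)
        stoich = _parse_stoichiometry(block["stoichiometry"])
        temperature_c = float(block.get("temperature_c", 18.0))
        cond = _conditions(block, temperature_c)
        if "simulate" in block:
            inputs = _simulate_inputs(name, block, stoich, cond, consts, seed + i)
            provenance_inputs = {"simulated": True, "seed": seed + i}
        else:
            inputs = _file_inputs(block)
            provenance_inputs = {
                k: str(v) for k, v in block.items() if k.endswith("_csv")
            }
        if not inputs:
            raise ValueError(f"construct {name!r}: no inputs (files or simulate block)")
        out_block: dict = {}

        if "erev_series" in inputs:
            out_block["reversal"] = _slope_block(
                inputs["erev_series"], stoich.z_t, temperature_c, consts
            )
            log.info(
                "stage=erev-slope construct=%s slope=%.2f",
                name,
                out_block["reversal"]["slope_mV_per_decade"],
            )

        if "uptake_na" in inputs:
            sample, mock = inputs["uptake_na"]
            if mock is not None:
                sample = subtract_background(sample, mock)
                if sample.clipped_negative:
                    log.warning(
                        "stage=subtract construct=%s clipped=%d",
                        name, sample.clipped_negative,
                    )
            hf = fit_hill(sample)
            out_block["sodium_hill"] = {
                "ec50_mM": hf.ec50,
                "ec50_se_mM": hf.ec50_se,
                "n_hill": hf.n_hill,
                "n_hill_se": hf.n_hill_se,
                "vmax": hf.vmax,
                "r_squared": hf.r_squared,
                "saturation_warning": hf.saturation_warning,
                "clipped_negative": sample.clipped_negative,
            }

        if "uptake_cl" in inputs:
            sample, mock = inputs["uptake_cl"]
            if mock is not None:
                sample = subtract_background(sample, mock)
            mf = fit_mm(sample)
            eff, eff_se = transport_efficiency(mf)
            out_block["chloride_mm"] = {
                "km": mf.km,
                "km_se": mf.km_se,
                "conc_unit": mf.conc_unit,
                "vmax": mf.vmax,
                "vmax_se": mf.vmax_se,
                "efficiency_vmax_over_km": eff,
                "efficiency_se": eff_se,
                "r_squared": mf.r_squared,
            }

        if "charge_flux" in inputs:
            trace, counts = inputs["charge_flux"]
            charge = integrate_charge(trace)
            if counts is not None:
                moles = moles_from_tracer(
                    counts.dpm_sample,
                    counts.dpm_background,
                    counts.specific_activity_ci_per_mmol,
                )
                res = charge_to_flux(charge, moles, consts)
                out_block["charge_flux"] = {
                    "charge_C": res.charge_c,
                    "moles_substrate": res.moles_substrate,
                    "ratio_charges_per_molecule": res.ratio,
                    "holding_potential_mV": trace.holding_potential,
                }
            else:
                out_block["charge_flux"] = {"charge_C": charge}

        if "iv" in inputs:
            iv = inputs["iv"]
            iv_block: dict = {
                "rectification_degree": rectification_degree(iv),
            }
            try:
                iv_block["e_rev_mV"] = estimate_erev(iv)
            except ValueError as exc:
                iv_block["e_rev_mV"] = None
                iv_block["e_rev_note"] = str(exc)
                log.warning("stage=erev construct=%s note=%s", name, exc)
            out_block["iv"] = iv_block

        out_block["provenance"] = provenance_inputs
        report.constructs[name] = out_block

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(report.to_json() + "\n")
        (out_dir / "report.txt").write_text(report.to_text())
    return report
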