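"""CSV/JSON/YAML round-trip I/O for every dataset the analyses consume.

Schemas (all CSV, header required, '.' decimal regardless of locale):

* reversal series:  oocyte_id, na_o_mM, e_rev_mV
* uptake:           construct, varied_species, concentration, conc_unit,
                    rate_nmol_per_mg_10min, replicate
                    (mock-transfected background rows carry construct=mock)
* I/V curve:        potential_mV, current_nA, sem_nA, n
* current trace:    time_s, current_nA  + a JSON/YAML sidecar with the
                    holding potential, application window and condition tags
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .kinetics import UptakeDataset
from .synthetic import RevPotSeries
from .traces import CurrentTrace, IVCurve

__all__ = [
    "read_reversal_series",
    "write_reversal_series",
    "read_uptake",
    "write_uptake",
    "read_iv",
    "write_iv",
    "read_trace",
    "write_trace",
    "SchemaError",
]

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """An input file does not match its expected schema."""


def _read_csv(path: PathLike, required: Tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    for col in required:
        if col in ("oocyte_id", "construct", "varied_species", "conc_unit", "replicate"):
            continue
        if not np.issubdtype(df[col].dtype, np.number):
            raise SchemaError(f"{path}: column {col!r} is not numeric")
    return df


# -- reversal-potential series -------------------------------------------------

REV_COLS = ("oocyte_id", "na_o_mM", "e_rev_mV")


def read_reversal_series(path: PathLike) -> RevPotSeries:
    df = _read_csv(path, REV_COLS)
    return RevPotSeries(
        oocyte_id=df["oocyte_id"].to_numpy(),
        na_o=df["na_o_mM"].to_numpy(dtype=float),
        e_rev=df["e_rev_mV"].to_numpy(dtype=float),
    )


def write_reversal_series(series: RevPotSeries, path: PathLike) -> None:
    pd.DataFrame(
        {
            "oocyte_id": series.oocyte_id,
            "na_o_mM": series.na_o,
            "e_rev_mV": series.e_rev,
        }
    ).to_csv(path, index=False)


# -- uptake --------------------------------------------------------------------

UPTAKE_COLS = (
    "construct",
    "varied_species",
    "concentration",
    "conc_unit",
    "rate_nmol_per_mg_10min",
    "replicate",
)


def read_uptake(path: PathLike, construct: str | None = None) -> UptakeDataset:
    """Read one construct's rows (mock rows are read with construct='mock')."""
    df = _read_csv(path, UPTAKE_COLS)
    if construct is not None:
        df = df[df["construct"] == construct]
        if df.empty:
            raise SchemaError(f"{path}: no rows for construct {construct!r}")
    constructs = df["construct"].unique()
    if len(constructs) > 1:
        raise SchemaError(
            f"{path}: multiple constructs {sorted(constructs)}; pass construct="
        )
    units = df["conc_unit"].unique()
    if len(units) > 1:
        raise SchemaError(f"{path}: mixed concentration units {sorted(units)}")
    return UptakeDataset(
        concentration=df["concentration"].to_numpy(dtype=float),
        rate=df["rate_nmol_per_mg_10min"].to_numpy(dtype=float),
        replicate_id=df["replicate"].to_numpy(),
        construct=str(constructs[0]),
        varied_species=str(df["varied_species"].iloc[0]),
        conc_unit=str(units[0]),
    )


def write_uptake(data: UptakeDataset, path: PathLike, mode: str = "w") -> None:
    data.to_frame().to_csv(path, index=False, mode=mode, header=(mode == "w"))


# -- I/V curves ----------------------------------------------------------------

IV_COLS = ("potential_mV", "current_nA", "sem_nA", "n")


def read_iv(path: PathLike) -> IVCurve:
    df = _read_csv(path, IV_COLS)
    return IVCurve(
        potential=df["potential_mV"].to_numpy(dtype=float),
        current=df["current_nA"].to_numpy(dtype=float),
        sem=df["sem_nA"].to_numpy(dtype=float),
        n_oocytes=int(df["n"].iloc[0]),
    )


def write_iv(iv: IVCurve, path: PathLike) -> None:
    pd.DataFrame(
        {
            "potential_mV": iv.potential,
            "current_nA": iv.current,
            "sem_nA": iv.sem,
            "n": iv.n_oocytes,
        }
    ).to_csv(path, index=False)


# -- current traces ------------------------------------------------------------

TRACE_COLS = ("time_s", "current_nA")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def read_trace(path: PathLike) -> CurrentTrace:
    path = Path(path)
    df = _read_csv(path, TRACE_COLS)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise SchemaError(f"{path}: metadata sidecar {sidecar.name} not found")
    meta = yaml.safe_load(sidecar.read_text())
    try:
        holding = float(meta["holding_potential_mV"])
        window = tuple(float(x) for x in meta["application_window_s"])
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{sidecar}: missing/invalid metadata: {exc}") from exc
    return CurrentTrace(
        time=df["time_s"].to_numpy(dtype=float),
        current=df["current_nA"].to_numpy(dtype=float),
        holding_potential=holding,
        application_window=window,  # type: ignore[arg-type]
        condition=meta.get("condition", {}),
    )


def write_trace(trace: CurrentTrace, path: PathLike) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": trace.time, "current_nA": trace.current}).to_csv(
        path, index=False
    )
    meta = {
        "holding_potential_mV": float(trace.holding_potential),
        "application_window_s": [float(x) for x in trace.application_window],
        "condition": {k: _jsonable(v) for k, v in trace.condition.items()},
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def write_json(obj: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
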