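"""Plain-text persistence for every pipeline artifact.

All formats are CSV (curves, risk tables, patient records, interval
counts, posterior draws) or JSON (draw metadata, diagnostics), so a run
can be archived and re-read without any binary dependencies.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import INTERVAL_COLUMNS, KMCurve, PseudoIPD, RiskTable, validate_interval_data
from .model import PosteriorDraws

__all__ = [
    "write_km", "read_km",
    "write_risk_table", "read_risk_table",
    "write_ipd", "read_ipd",
    "write_intervals", "read_intervals",
    "write_draws", "read_draws",
]


def write_km(curve: KMCurve, path) -> None:
    pd.DataFrame({"time_months": curve.times, "survival": curve.survival}).to_csv(
        path, index=False
    )


def read_km(path, arm_label: str = "") -> KMCurve:
    df = pd.read_csv(path)
    return KMCurve(df["time_months"].to_numpy(), df["survival"].to_numpy(), arm_label)


def write_risk_table(risk: RiskTable, path) -> None:
    pd.DataFrame({"time_months": risk.times, "n_at_risk": risk.n_at_risk}).to_csv(
        path, index=False
    )


def read_risk_table(path) -> RiskTable:
    df = pd.read_csv(path)
    return RiskTable(df["time_months"].to_numpy(), df["n_at_risk"].to_numpy())


def write_ipd(ipd: PseudoIPD, path) -> None:
    ipd.to_frame().to_csv(path, index=False)


def read_ipd(path, arm_label: str = "") -> PseudoIPD:
    df = pd.read_csv(path)
    return PseudoIPD(df["time_months"].to_numpy(), df["event"].to_numpy(), arm_label)


def write_intervals(df: pd.DataFrame, path) -> None:
    validate_interval_data(df)[list(INTERVAL_COLUMNS)].to_csv(path, index=False)


def read_intervals(path) -> pd.DataFrame:
    return validate_interval_data(pd.read_csv(path))


def write_draws(draws: PosteriorDraws, csv_path, meta_path) -> None:
    """Draws as CSV (chain, iteration, one column per parameter) + JSON meta."""
    draws.to_frame().to_csv(csv_path, index=False)
    meta = {
        "family": draws.family,
        "studies": draws.studies,
        "treatments": draws.treatments,
        "reference": draws.reference,
        "baselines": draws.baselines,
        "param_names": draws.param_names,
        "meta": draws.meta,
    }
    Path(meta_path).write_text(json.dumps(meta, indent=2))


def read_draws(csv_path, meta_path) -> PosteriorDraws:
    meta = json.loads(Path(meta_path).read_text())
    df = pd.read_csv(csv_path)
    chains = int(df["chain"].max()) + 1
    iters = int(df["iteration"].max()) + 1
    samples = (
        df.sort_values(["chain", "iteration"])[meta["param_names"]]
        .to_numpy()
        .reshape(chains, iters, len(meta["param_names"]))
    )
    return PosteriorDraws(
        samples=samples,
        param_names=meta["param_names"],
        family=meta["family"],
        studies=meta["studies"],
        treatments=meta["treatments"],
        reference=meta["reference"],
        meta=meta["meta"],
        baselines=meta.get("baselines", {}),
    )
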