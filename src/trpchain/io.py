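"""File formats: occupation/series CSV schemas and JSON sidecars.

Occupation CSV schema: ``sim_id,time_ps,occ_A,occ_B,occ_C,occ_D`` (long
format, one row per simulation and time point).  Site-energy CSV:
``sim_id,time_ps,eps_A,eps_B,eps_C,eps_D``; coupling CSV:
``sim_id,time_ps,T_AB,T_BC,T_CD``.  Floats are written with 12 significant
digits so occupation values round-trip at that precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .analysis import ClassificationResult, SeriesSummary
from .kinetics import (
    RATE_KEYS,
    SITES,
    TAU_KEYS,
    KineticFit,
    OccupationTrace,
    RateConstants,
)
from .synthetic import NEIGHBOUR_PAIRS, SiteSeries, TrajectoryEnsemble

FLOAT_FMT = "%.12g"

OCC_COLUMNS = ["sim_id", "time_ps", "occ_A", "occ_B", "occ_C", "occ_D"]
EPS_COLUMNS = ["sim_id", "time_ps", "eps_A", "eps_B", "eps_C", "eps_D"]
COUPLING_COLUMNS = ["sim_id", "time_ps", "T_AB", "T_BC", "T_CD"]


def _require_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; expected {expected}")


def write_occupations_csv(path, ensemble: TrajectoryEnsemble) -> None:
    """Write an ensemble in the long occupation CSV schema."""
    n_t = ensemble.times.size
    frames = []
    for i, sim_id in enumerate(ensemble.sim_ids):
        df = pd.DataFrame({"sim_id": sim_id, "time_ps": ensemble.times})
        for j, s in enumerate(SITES):
            df[f"occ_{s}"] = ensemble.occupations[i, :, j]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_occupations_csv(path) -> TrajectoryEnsemble:
    """Read an occupation CSV back into a TrajectoryEnsemble (no labels)."""
    df = pd.read_csv(path)
    _require_columns(df, OCC_COLUMNS, path)
    sim_ids = list(dict.fromkeys(df["sim_id"].astype(str)))
    times = None
    occ = []
    for sim_id in sim_ids:
        sub = df[df["sim_id"].astype(str) == sim_id]
        t = sub["time_ps"].to_numpy(dtype=float)
        if times is None:
            times = t
        elif t.shape != times.shape or not np.array_equal(t, times):
            raise ValueError(f"{path}: simulation {sim_id} is not on the shared time grid")
        occ.append(sub[[f"occ_{s}" for s in SITES]].to_numpy(dtype=float))
    occ = np.stack(occ)
    # tolerate 12-significant-digit rounding of normalized rows
    occ = np.clip(occ, 0.0, 1.0)
    occ /= occ.sum(axis=2, keepdims=True)
    return TrajectoryEnsemble(times=times, occupations=occ, sim_ids=tuple(sim_ids))


def write_trace_csv(path, trace: OccupationTrace, sim_id: str = "mean") -> None:
    """Write a single trace using the occupation CSV schema."""
    ens = TrajectoryEnsemble(
        times=trace.times,
        occupations=trace.occ[None, :, :],
        sim_ids=(trace.sim_id or sim_id,),
    )
    write_occupations_csv(path, ens)


def rates_to_json_dict(rates: RateConstants) -> dict:
    """Rates (1/ps) under their canonical keys plus a mirrored tau block (ps)."""
    d: dict = dict(zip(RATE_KEYS, (float(v) for v in rates.as_array())))
    d["tau_ps"] = {k: float(v) for k, v in rates.time_constants().items()}
    return d


def rates_from_json_dict(d: Mapping) -> RateConstants:
    return RateConstants(**{k: float(d[k]) for k in RATE_KEYS})


def write_rates_json(path, rates: RateConstants) -> None:
    Path(path).write_text(json.dumps(rates_to_json_dict(rates), indent=1))


def read_rates_json(path) -> RateConstants:
    return rates_from_json_dict(json.loads(Path(path).read_text()))


def write_fit_json(path, fit: KineticFit, extra: Mapping | None = None) -> None:
    d = rates_to_json_dict(fit.rates)
    d.update(
        {
            "residual_norm": fit.residual_norm,
            "n_points": fit.n_points,
            "converged": fit.converged,
            "per_parameter_spread": [float(v) for v in fit.per_parameter_spread],
            "n_starts": fit.n_starts,
            "n_starts_succeeded": fit.n_starts_succeeded,
            "seed": fit.seed,
        }
    )
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=1))


def write_labels_json(path, labels: Mapping[str, str]) -> None:
    Path(path).write_text(json.dumps(dict(labels), indent=1, sort_keys=True))


def read_labels_json(path) -> dict[str, str]:
    return {str(k): str(v) for k, v in json.loads(Path(path).read_text()).items()}


def write_meta_json(path, meta: Mapping) -> None:
    Path(path).write_text(json.dumps(dict(meta), indent=1, default=str))


def write_ensemble(outdir, ensemble: TrajectoryEnsemble) -> dict[str, Path]:
    """Write occupations.csv (+ labels.json, meta.json) into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"occupations": outdir / "occupations.csv"}
    write_occupations_csv(paths["occupations"], ensemble)
    if ensemble.labels is not None:
        paths["labels"] = outdir / "labels.json"
        write_labels_json(paths["labels"], ensemble.labels)
    meta = dict(ensemble.meta)
    meta["seed"] = ensemble.seed
    meta["n_traj"] = ensemble.n_traj
    paths["meta"] = outdir / "meta.json"
    write_meta_json(paths["meta"], meta)
    return paths


def write_site_series_csv(path, series_by_sim: Mapping[str, SiteSeries]) -> None:
    """Write site-energy or coupling series for several simulations."""
    frames = []
    kind = None
    for sim_id, s in series_by_sim.items():
        if kind is None:
            kind = s.kind
        elif s.kind != kind:
            raise ValueError("all series must share one kind")
        df = pd.DataFrame({"sim_id": sim_id, "time_ps": s.times})
        if kind == "site_energy":
            for site in SITES:
                df[f"eps_{site}"] = s.values.get(site, np.zeros_like(s.times))
        else:
            for pair in NEIGHBOUR_PAIRS:
                df[f"T_{pair}"] = s.get(pair)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_site_series_csv(path) -> dict[str, SiteSeries]:
    df = pd.read_csv(path)
    if all(c in df.columns for c in EPS_COLUMNS):
        kind, names, prefix = "site_energy", list(SITES), "eps_"
    elif all(c in df.columns for c in COUPLING_COLUMNS):
        kind, names, prefix = "coupling", list(NEIGHBOUR_PAIRS), "T_"
    else:
        raise ValueError(
            f"{path}: expected columns {EPS_COLUMNS} or {COUPLING_COLUMNS}, got {list(df.columns)}"
        )
    out = {}
    for sim_id in dict.fromkeys(df["sim_id"].astype(str)):
        sub = df[df["sim_id"].astype(str) == sim_id]
        out[sim_id] = SiteSeries(
            times=sub["time_ps"].to_numpy(dtype=float),
            values={n: sub[f"{prefix}{n}"].to_numpy(dtype=float) for n in names},
            kind=kind,
            sim_id=sim_id,
        )
    return out


def write_classification(outdir, result: ClassificationResult) -> dict[str, Path]:
    """Write labels_out.json plus a one-row summary CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "labels_out": outdir / "labels_out.json",
        "summary": outdir / "summary.csv",
    }
    write_labels_json(paths["labels_out"], result.per_sim)
    pd.DataFrame(
        [
            {
                "n_total": result.n_completed + result.n_stuck,
                "n_completed": result.n_completed,
                "n_stuck": result.n_stuck,
                "threshold": result.threshold,
            }
        ]
    ).to_csv(paths["summary"], index=False)
    return paths


def write_summary_csv(path, summary: SeriesSummary) -> None:
    """Write a SeriesSummary as ``time_ps,<name>_mean,<name>_sd`` columns."""
    df = pd.DataFrame({"time_ps": summary.times})
    for name in sorted(summary.mean):
        df[f"{name}_mean"] = summary.mean[name]
        df[f"{name}_sd"] = summary.sd[name]
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
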