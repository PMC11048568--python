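"""Run configuration: one structured YAML file covering every stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .kinetics import CHCRY4_TIME_CONSTANTS_PS, TAU_KEYS, RateConstants


@dataclass
class RunConfig:
    """Parameters of a full synthetic run.

    Defaults mirror the study conditions: 51 trajectories (23 completed +
    28 stuck) of 1 ns sampled at 1 ps, the ChCry4 reference time constants,
    completion threshold 0.3 and a 5 A water cutoff.
    """

    seed: int = 1
    t_max_ps: float = 1000.0
    dt_sample_ps: float = 1.0
    tau_ps: dict[str, float] = field(
        default_factory=lambda: dict(CHCRY4_TIME_CONSTANTS_PS)
    )
    n_completed: int = 23
    n_stuck: int = 28
    sigma: float = 0.0
    threshold: float = 0.3
    water_cutoff_A: float = 5.0
    n_starts: int = 16

    def __post_init__(self) -> None:
        for name in ("t_max_ps", "dt_sample_ps", "threshold", "water_cutoff_A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.n_completed < 0 or self.n_stuck < 0 or self.n_completed + self.n_stuck < 1:
            raise ValueError("need n_completed + n_stuck >= 1")
        missing = [k for k in TAU_KEYS if k not in self.tau_ps]
        if missing:
            raise ValueError(f"tau_ps missing keys {missing}")
        if any(float(self.tau_ps[k]) <= 0 for k in TAU_KEYS):
            raise ValueError("all time constants must be positive")

    def rates(self) -> RateConstants:
        return RateConstants.from_time_constants(self.tau_ps)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "grid": {"t_max_ps": self.t_max_ps, "dt_sample_ps": self.dt_sample_ps},
            "rates": {k: float(v) for k, v in self.tau_ps.items()},
            "ensemble": {
                "n_completed": self.n_completed,
                "n_stuck": self.n_stuck,
                "sigma": self.sigma,
            },
            "classification": {"threshold": self.threshold},
            "structure": {"water_cutoff_A": self.water_cutoff_A},
            "fit": {"n_starts": self.n_starts},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        grid = d.get("grid", {})
        ens = d.get("ensemble", {})
        kwargs = dict(
            seed=int(d.get("seed", 1)),
            t_max_ps=float(grid.get("t_max_ps", 1000.0)),
            dt_sample_ps=float(grid.get("dt_sample_ps", 1.0)),
            n_completed=int(ens.get("n_completed", 23)),
            n_stuck=int(ens.get("n_stuck", 28)),
            sigma=float(ens.get("sigma", 0.0)),
            threshold=float(d.get("classification", {}).get("threshold", 0.3)),
            water_cutoff_A=float(d.get("structure", {}).get("water_cutoff_A", 5.0)),
            n_starts=int(d.get("fit", {}).get("n_starts", 16)),
        )
        if "rates" in d:
            kwargs["tau_ps"] = {k: float(v) for k, v in d["rates"].items()}
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
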