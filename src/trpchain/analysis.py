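"""Ensemble reduction: completed/stuck classification and series summaries.

A hole-transfer trajectory counts as "completed" when the hole occupation on
Trp_C or Trp_D reaches at least the classification threshold (default 0.3)
at any sampled time point; otherwise the hole is "stuck" on Trp_A/Trp_B.
Ensembles are summarized by pointwise means with population standard
deviations, optionally split by classification outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .kinetics import SITES, OccupationTrace
from .synthetic import SiteSeries, TrajectoryEnsemble

COMPLETED = "completed"
STUCK = "stuck"

#: Sites whose occupation defines transfer completion.
CRITERION_SITES: tuple[str, ...] = ("C", "D")


@dataclass(frozen=True)
class ClassificationResult:
    """Completed/stuck outcome for every trajectory of an ensemble."""

    per_sim: dict[str, str]
    n_completed: int
    n_stuck: int
    threshold: float
    criterion_sites: tuple[str, ...] = CRITERION_SITES
    agreement: float | None = None

    def __post_init__(self) -> None:
        if self.n_completed + self.n_stuck != len(self.per_sim):
            raise ValueError("class counts must sum to the ensemble size")


def classify_completion(
    trace: OccupationTrace,
    threshold: float = 0.3,
    criterion_sites: Sequence[str] = CRITERION_SITES,
) -> str:
    """Classify one trajectory as completed or stuck.

    "completed" iff the occupation of any criterion site reaches at least
    ``threshold`` at some sampled time point (closed boundary: a peak of
    exactly ``threshold`` completes).
    """
    idx = [SITES.index(s) for s in criterion_sites]
    peak = trace.occ[:, idx].max()
    return COMPLETED if peak >= threshold else STUCK


def classify_ensemble(
    ensemble: TrajectoryEnsemble,
    threshold: float = 0.3,
    criterion_sites: Sequence[str] = CRITERION_SITES,
) -> ClassificationResult:
    """Classify every trajectory; report counts and ground-truth agreement.

    When the ensemble carries generator labels, ``agreement`` is the fraction
    of trajectories whose predicted class matches its label.
    """
    if ensemble.n_traj == 0:
        raise ValueError("cannot classify an empty ensemble")
    per_sim = {
        t.sim_id: classify_completion(t, threshold, criterion_sites)
        for t in ensemble.traces()
    }
    n_completed = sum(1 for v in per_sim.values() if v == COMPLETED)
    agreement = None
    if ensemble.labels:
        matches = [
            per_sim[s] == ensemble.labels[s] for s in ensemble.sim_ids if s in ensemble.labels
        ]
        if matches:
            agreement = float(np.mean(matches))
    return ClassificationResult(
        per_sim=per_sim,
        n_completed=n_completed,
        n_stuck=len(per_sim) - n_completed,
        threshold=float(threshold),
        criterion_sites=tuple(criterion_sites),
        agreement=agreement,
    )


@dataclass(frozen=True)
class SeriesSummary:
    """Pointwise mean and population standard deviation of a series bundle."""

    times: np.ndarray
    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name, s in self.sd.items():
            if np.any(np.asarray(s) < 0):
                raise ValueError(f"negative sd in series {name!r}")


def summarize_series(series_collection: Sequence[SiteSeries]) -> SeriesSummary:
    """Pointwise mean and population sd across a collection of SiteSeries."""
    if len(series_collection) < 1:
        raise ValueError("need at least one series")
    first = series_collection[0]
    names = sorted(first.values)
    for s in series_collection[1:]:
        if s.times.shape != first.times.shape or not np.allclose(
            s.times, first.times, rtol=0, atol=0
        ):
            raise ValueError("all series must share one time grid")
        if sorted(s.values) != names:
            raise ValueError("all series must carry the same named channels")
    stacked = {
        name: np.stack([s.values[name] for s in series_collection]) for name in names
    }
    return SeriesSummary(
        times=first.times,
        mean={k: v.mean(axis=0) for k, v in stacked.items()},
        sd={k: v.std(axis=0, ddof=0) for k, v in stacked.items()},
        n=len(series_collection),
    )


def _occupation_summary(ensemble: TrajectoryEnsemble, sim_ids: Sequence[str]) -> SeriesSummary:
    idx = [ensemble.sim_ids.index(s) for s in sim_ids]
    occ = ensemble.occupations[idx]
    return SeriesSummary(
        times=ensemble.times,
        mean={f"occ_{s}": occ[:, :, i].mean(axis=0) for i, s in enumerate(SITES)},
        sd={f"occ_{s}": occ[:, :, i].std(axis=0, ddof=0) for i, s in enumerate(SITES)},
        n=len(idx),
    )


@dataclass(frozen=True)
class SubsetComparison:
    """Summaries over (all, completed, stuck) subsets on a shared grid.

    A summary is ``None`` (flagged absent) when its subset is empty or when
    the requested quantity was not provided for the ensemble.
    """

    quantity: str
    all: "SeriesSummary | None"
    completed: "SeriesSummary | None"
    stuck: "SeriesSummary | None"


def compare_subsets(
    ensemble: TrajectoryEnsemble,
    result: ClassificationResult,
    quantity: str = "occupations",
    series: Mapping[str, SiteSeries] | None = None,
) -> SubsetComparison:
    """Summaries of a quantity over the whole ensemble and per class.

    ``quantity`` is "occupations" (taken from the ensemble itself) or
    "energies"/"couplings" (taken from ``series``, a mapping sim_id ->
    SiteSeries).  Missing series or an empty class yields an absent (None)
    summary rather than an error.
    """
    if quantity not in ("occupations", "energies", "couplings"):
        raise ValueError(f"unknown quantity {quantity!r}")
    missing = set(ensemble.sim_ids) - set(result.per_sim)
    if missing:
        raise ValueError(f"classification does not cover sim_ids {sorted(missing)}")
    groups = {
        "all": list(ensemble.sim_ids),
        COMPLETED: [s for s in ensemble.sim_ids if result.per_sim[s] == COMPLETED],
        STUCK: [s for s in ensemble.sim_ids if result.per_sim[s] == STUCK],
    }
    out: dict[str, SeriesSummary | None] = {}
    for key, ids in groups.items():
        if not ids:
            out[key] = None
            continue
        if quantity == "occupations":
            out[key] = _occupation_summary(ensemble, ids)
        else:
            if series is None or any(s not in series for s in ids):
                out[key] = None
                continue
            out[key] = summarize_series([series[s] for s in ids])
    return SubsetComparison(
        quantity=quantity, all=out["all"], completed=out[COMPLETED], stuck=out[STUCK]
    )
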