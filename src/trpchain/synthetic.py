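"""Synthetic trajectory ensembles with known ground truth.

The study conditions this generator emulates are ensembles of 51 independent
1 ns hole-transfer simulations sampled on a 1 ps grid, starting with the
hole on Trp_A, that split into a "completed" subpopulation (hole reaches
Trp_C or Trp_D) and a "stuck" subpopulation (hole confined to Trp_A/Trp_B).

Hole hopping is realized as a continuous-time Markov jump process (kinetic
Monte Carlo / Gillespie) on the four sites with the six chain rates; the
ensemble mean of the indicator occupations converges to the master-equation
solution, playing the role of the ensemble-averaged quantum populations.
Site energies and electronic couplings are emulated as stationary
Ornstein-Uhlenbeck series; toy structure frames provide PDB fixtures with
exactly known water distances and inter-residue separations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .kinetics import (
    SITES,
    SITE_RESIDUES,
    OccupationTrace,
    RateConstants,
    chcry4_rates,
    _validate_grid,
)

logger = logging.getLogger(__name__)

#: Neighbouring site pairs of the chain; the only pairs with non-zero coupling.
NEIGHBOUR_PAIRS: tuple[str, ...] = ("AB", "BC", "CD")
#: All site pairs, for zero-filled non-neighbour coupling lookups.
ALL_PAIRS: tuple[str, ...] = ("AB", "AC", "AD", "BC", "BD", "CD")


@dataclass
class TrajectoryEnsemble:
    """A set of occupation traces sharing one time grid.

    ``occupations`` has shape ``(n_traj, n_times, 4)``.  ``labels`` maps
    sim_id to the ground-truth subpopulation tag ("completed" / "stuck")
    when the generator attached one.
    """

    times: np.ndarray
    occupations: np.ndarray
    sim_ids: tuple[str, ...]
    labels: dict[str, str] | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = _validate_grid(np.asarray(self.times, dtype=float))
        self.occupations = np.asarray(self.occupations, dtype=float)
        self.sim_ids = tuple(str(s) for s in self.sim_ids)
        n = len(self.sim_ids)
        if len(set(self.sim_ids)) != n:
            raise ValueError("sim_id values must be unique")
        if self.occupations.shape != (n, self.times.size, 4):
            raise ValueError(
                f"occupations shape {self.occupations.shape} does not match "
                f"({n}, {self.times.size}, 4)"
            )
        if self.labels is not None:
            unknown = set(self.labels) - set(self.sim_ids)
            if unknown:
                raise ValueError(f"labels reference unknown sim_ids: {sorted(unknown)}")

    @property
    def n_traj(self) -> int:
        return len(self.sim_ids)

    def trace(self, sim_id: str) -> OccupationTrace:
        i = self.sim_ids.index(sim_id)
        return OccupationTrace(self.times, self.occupations[i], sim_id=sim_id)

    def traces(self) -> Iterator[OccupationTrace]:
        for sim_id in self.sim_ids:
            yield self.trace(sim_id)

    def subset(self, sim_ids: Iterable[str]) -> "TrajectoryEnsemble":
        wanted = list(sim_ids)
        unknown = set(wanted) - set(self.sim_ids)
        if unknown:
            raise ValueError(
                f"unknown sim_ids {sorted(unknown)}; valid ids: {list(self.sim_ids)}"
            )
        idx = [self.sim_ids.index(s) for s in wanted]
        labels = None
        if self.labels is not None:
            labels = {s: self.labels[s] for s in wanted if s in self.labels}
        return TrajectoryEnsemble(
            times=self.times,
            occupations=self.occupations[idx],
            sim_ids=tuple(wanted),
            labels=labels,
            seed=self.seed,
            meta=dict(self.meta),
        )


def _out_rates(k: np.ndarray) -> list[list[tuple[float, int]]]:
    """Per-state outgoing (rate, target) lists for the Gillespie sampler."""
    kfAB, kbAB, kfBC, kbBC, kfCD, kbCD = k
    return [
        [(kfAB, 1)],
        [(kbAB, 0), (kfBC, 2)],
        [(kbBC, 1), (kfCD, 3)],
        [(kbCD, 2)],
    ]


def _gillespie_states(
    out: list[list[tuple[float, int]]],
    rng: np.random.Generator,
    grid: np.ndarray,
) -> np.ndarray:
    """One jump-process realization started in state 0, sampled on ``grid``."""
    t_max = grid[-1]
    t = 0.0
    state = 0
    jump_times: list[float] = []
    jump_states: list[int] = [0]
    while True:
        channels = out[state]
        total = sum(r for r, _ in channels)
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t > t_max:
            break
        u = rng.uniform(0.0, total)
        acc = 0.0
        for r, target in channels:
            acc += r
            if u < acc:
                state = target
                break
        jump_times.append(t)
        jump_states.append(state)
    idx = np.searchsorted(np.asarray(jump_times), grid, side="right")
    return np.asarray(jump_states)[idx]


def _states_to_occ(states: np.ndarray) -> np.ndarray:
    occ = np.zeros((states.size, 4))
    occ[np.arange(states.size), states] = 1.0
    return occ


def _smooth_occ(occ: np.ndarray, window_pts: int) -> np.ndarray:
    """Sliding-window mean of indicator occupations; preserves row sums."""
    if window_pts <= 1:
        return occ
    return uniform_filter1d(occ, size=window_pts, axis=0, mode="nearest")


def _sample_grid(t_max: float, dt_sample: float) -> np.ndarray:
    n = int(round(t_max / dt_sample))
    return np.linspace(0.0, n * dt_sample, n + 1)


def simulate_kmc(
    rates: RateConstants,
    t_max: float,
    dt_sample: float,
    n_traj: int,
    seed: int,
    smooth_window_ps: float | None = None,
) -> TrajectoryEnsemble:
    """Kinetic-Monte-Carlo ensemble of hole-hopping trajectories.

    Each trajectory is an exact continuous-time Markov jump process on
    {A, B, C, D} started at A, sampled on the ``dt_sample`` grid as indicator
    occupations (exactly one site occupied per time point).  With
    ``smooth_window_ps`` set, a centered sliding-window mean converts the
    indicators into fractional per-trace occupations, mimicking single-trace
    quantum populations.

    Random streams are split per trajectory from the master ``seed``, so
    changing ``n_traj`` never reshuffles earlier trajectories.
    """
    if t_max <= 0 or dt_sample <= 0:
        raise ValueError("t_max and dt_sample must be positive")
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    if not isinstance(rates, RateConstants):
        rates = RateConstants.from_array(np.asarray(rates, dtype=float))
    grid = _sample_grid(t_max, dt_sample)
    out = _out_rates(rates.as_array())
    window_pts = 1
    if smooth_window_ps is not None:
        if smooth_window_ps <= 0:
            raise ValueError("smooth_window_ps must be positive")
        window_pts = max(1, int(round(smooth_window_ps / dt_sample)))
    children = np.random.SeedSequence(seed).spawn(n_traj)
    occ = np.empty((n_traj, grid.size, 4))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        states = _gillespie_states(out, rng, grid)
        occ[i] = _smooth_occ(_states_to_occ(states), window_pts)
    sim_ids = tuple(f"sim_{i:03d}" for i in range(n_traj))
    meta = {
        "generator": "simulate_kmc",
        "rates_per_ps": rates.to_dict(),
        "t_max_ps": float(t_max),
        "dt_sample_ps": float(dt_sample),
        "smooth_window_ps": smooth_window_ps,
    }
    return TrajectoryEnsemble(grid, occ, sim_ids, seed=seed, meta=meta)


def ensemble_mean(
    ensemble: TrajectoryEnsemble, subset: Iterable[str] | None = None
) -> OccupationTrace:
    """Pointwise arithmetic mean occupation over the (sub)ensemble."""
    if subset is not None:
        ensemble = ensemble.subset(subset)
    if ensemble.n_traj == 0:
        raise ValueError("cannot average an empty ensemble")
    mean = ensemble.occupations.mean(axis=0)
    return OccupationTrace.from_raw(ensemble.times, mean)


def add_observation_noise(
    trace: OccupationTrace, sigma: float, seed: int
) -> OccupationTrace:
    """Gaussian observation noise per site/time, clipped and renormalized.

    Adds i.i.d. N(0, sigma^2) noise to every occupation, clips to [0, 1] and
    renormalizes each time point to sum exactly 1.  ``sigma = 0`` returns the
    trace unchanged.  Note the clipping makes the noise slightly biased near
    the boundaries (occupations close to 0 or 1).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return OccupationTrace(trace.times, trace.occ, sim_id=trace.sim_id)
    rng = np.random.default_rng(seed)
    noisy = np.clip(trace.occ + rng.normal(0.0, sigma, size=trace.occ.shape), 0.0, 1.0)
    sums = noisy.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):  # pragma: no cover - requires sigma >> 1
        raise ValueError("noise clipped an entire time point to zero; reduce sigma")
    return OccupationTrace(trace.times, noisy / sums, sim_id=trace.sim_id)


def _trace_completes(occ: np.ndarray, threshold: float) -> bool:
    return bool(occ[:, 2:4].max() >= threshold)


def make_heterogeneous_ensemble(
    rates_completed: RateConstants | None = None,
    rates_stuck: RateConstants | None = None,
    n_completed: int = 23,
    n_stuck: int = 28,
    t_max: float = 1000.0,
    dt_sample: float = 1.0,
    sigma: float = 0.0,
    seed: int = 0,
    threshold: float = 0.3,
    smooth_window_ps: float | None = None,
) -> TrajectoryEnsemble:
    """Labeled mixture of completed and stuck hole-transfer trajectories.

    Defaults are the study conditions: 23 completed + 28 stuck = 51
    trajectories of 1 ns at 1 ps sampling.  ``rates_completed`` defaults to
    the ChCry4 reference rates; ``rates_stuck`` to the same set with
    ``kfBC = 0``, confining the hole to {A, B} (the simplest mechanism that
    reproduces the stuck phenotype).  Completed-labeled trajectories are
    redrawn (from per-slot child streams, deterministically) until the hole
    actually visits Trp_C or Trp_D, so the ground-truth labels are correct
    by construction on noiseless output.
    """
    if n_completed < 0 or n_stuck < 0 or n_completed + n_stuck < 1:
        raise ValueError("need n_completed + n_stuck >= 1, both non-negative")
    if rates_completed is None:
        rates_completed = chcry4_rates()
    if rates_stuck is None:
        rates_stuck = rates_completed.replace(kfBC=0.0)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    grid = _sample_grid(t_max, dt_sample)
    window_pts = 1
    if smooth_window_ps is not None:
        window_pts = max(1, int(round(smooth_window_ps / dt_sample)))
    out_completed = _out_rates(rates_completed.as_array())
    out_stuck = _out_rates(rates_stuck.as_array())
    n_total = n_completed + n_stuck
    children = np.random.SeedSequence(seed).spawn(n_total + 1)
    noise_rng = np.random.default_rng(children[-1])

    occ = np.empty((n_total, grid.size, 4))
    labels: dict[str, str] = {}
    sim_ids = tuple(f"sim_{i:03d}" for i in range(n_total))
    n_redrawn = 0
    for i in range(n_total):
        slot = children[i]
        if i < n_completed:
            states = _gillespie_states(out_completed, np.random.default_rng(slot), grid)
            one_hot = _states_to_occ(states)
            while not _trace_completes(one_hot, threshold):
                slot = slot.spawn(1)[0]
                states = _gillespie_states(out_completed, np.random.default_rng(slot), grid)
                one_hot = _states_to_occ(states)
                n_redrawn += 1
            labels[sim_ids[i]] = "completed"
        else:
            states = _gillespie_states(out_stuck, np.random.default_rng(slot), grid)
            one_hot = _states_to_occ(states)
            labels[sim_ids[i]] = "stuck"
        trace_occ = _smooth_occ(one_hot, window_pts)
        if sigma > 0:
            noisy = np.clip(
                trace_occ + noise_rng.normal(0.0, sigma, size=trace_occ.shape), 0.0, 1.0
            )
            trace_occ = noisy / noisy.sum(axis=1, keepdims=True)
        occ[i] = trace_occ
    if n_redrawn:
        logger.info("redrew %d completed-slot trajectories that failed to reach C/D", n_redrawn)
    meta = {
        "generator": "make_heterogeneous_ensemble",
        "rates_completed_per_ps": rates_completed.to_dict(),
        "rates_stuck_per_ps": rates_stuck.to_dict(),
        "n_completed": n_completed,
        "n_stuck": n_stuck,
        "t_max_ps": float(t_max),
        "dt_sample_ps": float(dt_sample),
        "sigma": float(sigma),
        "threshold": float(threshold),
        "smooth_window_ps": smooth_window_ps,
        "n_redrawn": n_redrawn,
    }
    return TrajectoryEnsemble(grid, occ, sim_ids, labels=labels, seed=seed, meta=meta)


# ---------------------------------------------------------------------------
# Site-energy / coupling series
# ---------------------------------------------------------------------------


@dataclass
class SiteSeries:
    """Per-site (site energies, eV) or per-pair (couplings, eV) time series.

    ``kind`` is "site_energy" (keys A..D) or "coupling" (keys AB, BC, CD).
    Non-neighbour couplings are identically zero: :meth:`get` returns a zero
    series for the pairs AC, AD, BD without storing them.
    """

    times: np.ndarray
    values: dict[str, np.ndarray]
    kind: str
    sim_id: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.kind not in ("site_energy", "coupling"):
            raise ValueError(f"kind must be 'site_energy' or 'coupling', got {self.kind!r}")
        valid = set(SITES) if self.kind == "site_energy" else set(NEIGHBOUR_PAIRS)
        for name, series in self.values.items():
            if name not in valid:
                raise ValueError(f"invalid series name {name!r} for kind {self.kind!r}")
            arr = np.asarray(series, dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"series {name!r} does not match the time grid")
            self.values[name] = arr

    def get(self, name: str) -> np.ndarray:
        name = _normalize_pair(name) if self.kind == "coupling" else name
        if name in self.values:
            return self.values[name]
        if self.kind == "coupling" and name in ALL_PAIRS:
            return np.zeros_like(self.times)
        raise KeyError(name)


def _normalize_pair(pair: str | Sequence[str]) -> str:
    if not isinstance(pair, str):
        pair = "".join(pair)
    pair = "".join(sorted(pair.upper()))
    if len(pair) != 2 or any(c not in SITES for c in pair):
        raise ValueError(f"invalid site pair {pair!r}")
    return pair


def simulate_site_series(
    means: Mapping[str, float],
    sd: float,
    correlation_time: float,
    times: Sequence[float],
    seed: int,
) -> SiteSeries:
    """Stationary Ornstein-Uhlenbeck series around the given means (eV).

    ``means`` is keyed either by site (A..D -> site energies) or by
    neighbouring pair (AB/BC/CD -> electronic couplings); requesting a
    non-neighbour pair such as AC is rejected, since couplings are only
    non-zero between adjacent sites of the chain.  The exact OU update
    x' = mu + (x - mu) a + sd sqrt(1 - a^2) xi with a = exp(-dt/tau) is used,
    started from the stationary distribution.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if correlation_time <= 0:
        raise ValueError("correlation_time must be positive")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1 or not np.all(np.diff(times) > 0):
        raise ValueError("times must be a strictly increasing 1-d grid")
    keys = list(means)
    if all(k in SITES for k in keys):
        kind = "site_energy"
        names = keys
    else:
        kind = "coupling"
        names = [_normalize_pair(k) for k in keys]
        bad = [n for n in names if n not in NEIGHBOUR_PAIRS]
        if bad:
            raise ValueError(
                f"non-neighbour coupling pair(s) {bad}: couplings are non-zero "
                f"only for {list(NEIGHBOUR_PAIRS)}"
            )
    mu = np.array([float(v) for v in means.values()])
    rng = np.random.default_rng(seed)
    n, m = times.size, mu.size
    x = np.empty((n, m))
    x[0] = mu + sd * rng.standard_normal(m)
    if n > 1:
        a = np.exp(-np.diff(times) / correlation_time)
        innov = rng.standard_normal((n - 1, m))
        for i in range(1, n):
            ai = a[i - 1]
            x[i] = mu + (x[i - 1] - mu) * ai + sd * np.sqrt(1.0 - ai * ai) * innov[i - 1]
    values = {name: x[:, j].copy() for j, name in enumerate(names)}
    return SiteSeries(times=times, values=values, kind=kind)


# ---------------------------------------------------------------------------
# Toy structure frames
# ---------------------------------------------------------------------------

# Planar tryptophan side-chain template (heavy atoms, indole + CB) in the
# (y, z) plane; all atoms of one residue share the same x coordinate, so two
# residues offset purely along x have a minimum inter-atomic distance exactly
# equal to the offset.  Coordinates are exact at PDB precision (3 decimals).
_TRP_TEMPLATE: tuple[tuple[str, float, float], ...] = (
    ("CB", 0.000, 0.000),
    ("CG", 1.520, 0.000),
    ("CD1", 2.380, -1.080),
    ("NE1", 3.700, -0.750),
    ("CE2", 3.850, 0.620),
    ("CD2", 2.580, 1.100),
    ("CE3", 2.720, 2.460),
    ("CZ3", 3.980, 3.000),
    ("CH2", 5.100, 2.220),
    ("CZ2", 5.200, 0.950),
)

#: Order of the four Trp residues along the synthetic chain axis.
_CHAIN_ORDER: tuple[int, ...] = tuple(SITE_RESIDUES[s] for s in SITES)


def _round3(x: float) -> float:
    return float(np.round(x, 3))


def _build_frame_atoms(
    separations: Sequence[float],
    water_placements: Sequence[tuple[int, float, int]],
) -> tuple[list[dict], dict]:
    """Atom records of one unshifted frame plus brute-force ground truth."""
    if len(separations) != 3:
        raise ValueError("separations must give the three gaps (A-B, B-C, C-D)")
    seps = [float(s) for s in separations]
    if any(s <= 0 for s in seps):
        raise ValueError("separations must be positive")
    x_res = {}
    x = 0.0
    for gap, resid in zip([0.0] + seps, _CHAIN_ORDER):
        x = _round3(x + gap)
        x_res[resid] = x

    atoms: list[dict] = []
    for resid in _CHAIN_ORDER:
        for name, y, z in _TRP_TEMPLATE:
            atoms.append(
                dict(
                    atom_name=name,
                    res_name="TRP",
                    res_id=resid,
                    chain="A",
                    element=name[0],
                    xyz=np.array([x_res[resid], y, z]),
                    hetero=False,
                )
            )

    water_id = 1000
    requested = []
    requested_per_water: list[tuple[int, float]] = []
    fan_index: dict[int, int] = {}
    step = 0.5  # rad; fan angle between successive waters of one residue
    for resid, dist, count in water_placements:
        if resid not in x_res:
            raise ValueError(f"unknown residue {resid}; tetrad residues are {_CHAIN_ORDER}")
        dist = float(dist)
        if dist <= 0:
            raise ValueError("water placement distances must be positive")
        if count < 1:
            raise ValueError("water placement count must be >= 1")
        # Waters sit on the circle of radius `dist` around CB, in the residue
        # plane, on the side (-y) opposite the indole ring; the fan continues
        # across placements of the same residue so waters never overlap.  The
        # water at fan position 0 is at the exact 3-decimal point
        # (0, -dist, 0) relative to CB.
        for _ in range(count):
            j = fan_index.get(resid, 0)
            fan_index[resid] = j + 1
            beta = step * ((j + 1) // 2) * (1 if j % 2 else -1)
            y = _round3(-dist * np.cos(beta))
            z = _round3(dist * np.sin(beta))
            atoms.append(
                dict(
                    atom_name="O",
                    res_name="HOH",
                    res_id=water_id,
                    chain="W",
                    element="O",
                    xyz=np.array([x_res[resid], y, z]),
                    hetero=True,
                )
            )
            requested_per_water.append((resid, dist))
            water_id += 1
        requested.append({"residue": resid, "distance_A": dist, "count": count})

    coords = np.stack([a["xyz"] for a in atoms])
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < 1.0:
        raise ValueError(f"clashing placements: minimum atom separation {d.min():.3f} A < 1 A")

    # Verify each water realizes its requested minimum distance (the fan
    # geometry guarantees this only while the angular spread stays moderate).
    n_protein = 40
    for w, (resid, dist) in enumerate(requested_per_water):
        res_coords = np.stack(
            [a["xyz"] for a in atoms[:n_protein] if a["res_id"] == resid]
        )
        realized = float(
            np.min(np.linalg.norm(res_coords - atoms[n_protein + w]["xyz"], axis=1))
        )
        if abs(realized - dist) > 5e-3:
            raise ValueError(
                f"cannot place water at {dist} A from residue {resid}: fan "
                f"position realizes {realized:.3f} A; reduce the water count"
            )

    # Brute-force ground truth from the as-written (3-decimal) coordinates.
    is_water = np.array([a["res_name"] == "HOH" for a in atoms])
    truth_counts = {}
    truth_min_dists = {}
    for resid in _CHAIN_ORDER:
        res_mask = np.array(
            [a["res_id"] == resid and not w for a, w in zip(atoms, is_water)]
        )
        dist_rw = d[np.ix_(is_water, res_mask)]
        per_water = dist_rw.min(axis=1) if dist_rw.size else np.array([])
        truth_counts[str(resid)] = int(np.sum(per_water <= 5.0 + 1e-9))
        truth_min_dists[str(resid)] = sorted(float(v) for v in per_water)
    truth_edges = {}
    for i, pair in enumerate(("AB", "BC", "CD")):
        ra, rb = _CHAIN_ORDER[i], _CHAIN_ORDER[i + 1]
        ma = np.array([a["res_id"] == ra and not a["hetero"] for a in atoms])
        mb = np.array([a["res_id"] == rb and not a["hetero"] for a in atoms])
        truth_edges[pair] = float(d[np.ix_(ma, mb)].min())
    truth = {
        "separations_A": dict(zip(("AB", "BC", "CD"), seps)),
        "edge_to_edge_A": truth_edges,
        "water_counts_5A": truth_counts,
        "water_min_distances_A": truth_min_dists,
        "requested_placements": requested,
    }
    return atoms, truth


def make_toy_frames(
    n_frames: int = 1,
    water_placements: Sequence[tuple[int, float, int]] = (),
    seed: int = 0,
    separations: Sequence[float] = (5.2, 5.0, 5.4),
    separation_jitter_A: float = 0.0,
    out_path=None,
):
    """Minimal multi-MODEL PDB fixture with exactly known geometry.

    Four TRP side chains are placed in parallel planes so that the minimum
    heavy-atom distance between neighbours equals ``separations`` exactly;
    ``water_placements`` is a list of ``(residue_number, distance_A, count)``
    tuples placing waters at the given minimum distance from that residue
    (the first water of each placement is exact to PDB coordinate precision;
    additional waters are fanned out and exact to ~2e-3 A after rounding).
    With ``separation_jitter_A`` set, each frame draws its own Gaussian-
    perturbed separations (for distance-distribution fixtures); every frame
    is also rigidly translated, snapped to the 0.001 A PDB grid so all
    distances survive PDB coordinate rounding bit-for-bit.

    Returns ``(pdb_text, ground_truth)``; the ground truth carries the
    per-frame brute-force water counts, minimum water distances and
    edge-to-edge distances under ``"frames"``.  With ``out_path`` set, also
    writes the PDB file and a ``<out_path>.json`` ground-truth sidecar.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if separation_jitter_A < 0:
        raise ValueError("separation_jitter_A must be >= 0")
    rng = np.random.default_rng(seed)

    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    frames = []
    frame_truths = []
    base = np.asarray(separations, dtype=float)
    for _ in range(n_frames):
        seps = base
        if separation_jitter_A > 0:
            seps = np.maximum(base + rng.normal(0.0, separation_jitter_A, size=3), 1.5)
        seps = [_round3(s) for s in seps]
        atoms, truth = _build_frame_atoms(seps, water_placements)
        shift = np.round(rng.uniform(-5.0, 5.0, size=3), 3)
        arr = struc.AtomArray(len(atoms))
        arr.coord = (np.stack([a["xyz"] for a in atoms]) + shift).astype(np.float32)
        arr.atom_name = np.array([a["atom_name"] for a in atoms])
        arr.res_name = np.array([a["res_name"] for a in atoms])
        arr.res_id = np.array([a["res_id"] for a in atoms])
        arr.chain_id = np.array([a["chain"] for a in atoms])
        arr.element = np.array([a["element"] for a in atoms])
        arr.hetero = np.array([a["hetero"] for a in atoms])
        frames.append(arr)
        frame_truths.append(truth)

    pdb = PDBFile()
    pdb.set_structure(struc.stack(frames))
    text = "\n".join(pdb.lines) + "\n"
    truth = {
        "n_frames": n_frames,
        "seed": seed,
        "requested_separations_A": [float(s) for s in base],
        "separation_jitter_A": float(separation_jitter_A),
        "frames": frame_truths,
    }
    if out_path is not None:
        out_path = str(out_path)
        with open(out_path, "w") as fh:
            fh.write(text)
        with open(out_path + ".json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return text, truth
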