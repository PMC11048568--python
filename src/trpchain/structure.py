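"""Structural descriptors: solvent shells and donor-acceptor edge distances.

Two descriptors characterize the environment of the tryptophan tetrad in
coordinate frames: the number of water molecules within a cutoff (default
5 A) of each tryptophan, and the edge-to-edge distance between residues --
the minimum separation of their side-chain heavy atoms, the distance that
enters exponential distance dependences of electron-transfer rates.
Distance samples pooled over frames are histogrammed and fit with a single
Gaussian whose mean is reported as the location of the distribution maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial.distance import cdist

#: Residue names recognized as water (extensible via function arguments).
WATER_RESNAMES: frozenset[str] = frozenset({"HOH", "WAT", "SOL", "TIP3"})

#: Backbone atom names excluded from side-chain (edge) distance computation.
BACKBONE_ATOMS: frozenset[str] = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass
class StructureFrame:
    """One coordinate frame: parallel per-atom arrays plus (N, 3) coordinates."""

    atom_name: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    chain_id: np.ndarray
    element: np.ndarray
    coord: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        n = self.coord.shape[0]
        if self.coord.shape != (n, 3) or not np.all(np.isfinite(self.coord)):
            raise ValueError("coord must be a finite (N, 3) array")
        for name in ("atom_name", "res_name", "res_id", "chain_id", "element"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, arr)

    @property
    def n_atoms(self) -> int:
        return int(self.coord.shape[0])

    def water_mask(self, water_resnames: frozenset[str] = WATER_RESNAMES) -> np.ndarray:
        return np.isin(self.res_name, sorted(water_resnames))

    def heavy_mask(self) -> np.ndarray:
        return np.char.upper(self.element.astype(str)) != "H"

    def residue_mask(self, residue_number: int, water_resnames=WATER_RESNAMES) -> np.ndarray:
        """Atoms of the (non-water) residue with this number."""
        return (self.res_id == residue_number) & ~self.water_mask(water_resnames)


def read_frames(path, water_resnames: frozenset[str] = WATER_RESNAMES) -> list[StructureFrame]:
    """Read a (possibly multi-MODEL) PDB file into a list of frames.

    Waters are recognized by residue name (HOH/WAT/SOL/TIP3 by default).
    Parsing is delegated to biotite; malformed records raise a ValueError
    carrying biotite's diagnostic.  Coordinates are restored to the file's
    literal 0.001 A precision in float64 (biotite parses into float32, whose
    representation error would otherwise leak into closed-boundary cutoff
    comparisons).
    """
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:
        raise ValueError(f"failed to parse PDB file {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise ValueError(f"PDB file {path} contains no atoms")
    frames = []
    n_models = stack.stack_depth()
    for i in range(n_models):
        model = stack[i]
        frames.append(
            StructureFrame(
                atom_name=np.asarray(model.atom_name),
                res_name=np.asarray(model.res_name),
                res_id=np.asarray(model.res_id),
                chain_id=np.asarray(model.chain_id),
                element=np.asarray(model.element),
                coord=np.round(np.asarray(model.coord, dtype=float), 3),
                frame_index=i,
            )
        )
    return frames


def count_waters_near(
    frame: StructureFrame,
    residue_number: int,
    cutoff: float = 5.0,
    water_resnames: frozenset[str] = WATER_RESNAMES,
) -> int:
    """Number of water molecules within ``cutoff`` A of a residue.

    A water counts if ANY of its atoms lies within the closed cutoff
    (distance <= cutoff) of ANY heavy (non-hydrogen) atom of the residue;
    each water molecule is counted once.  The boundary comparison carries a
    1e-9 A guard so that distances exactly at the cutoff are not dropped by
    floating-point representation error.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    res_mask = frame.residue_mask(residue_number, water_resnames) & frame.heavy_mask()
    if not res_mask.any():
        raise ValueError(f"residue {residue_number} not found (or has no heavy atoms)")
    wat_mask = frame.water_mask(water_resnames)
    if not wat_mask.any():
        return 0
    d = cdist(frame.coord[wat_mask], frame.coord[res_mask])
    within = d.min(axis=1) <= cutoff + 1e-9
    # group water atoms into molecules by (chain, res_id)
    keys = list(zip(frame.chain_id[wat_mask], frame.res_id[wat_mask]))
    hit: set = set()
    for k, w in zip(keys, within):
        if w:
            hit.add(k)
    return len(hit)


def edge_to_edge(
    frame: StructureFrame,
    resA: int,
    resB: int,
    sidechain_only: bool = True,
) -> float:
    """Minimum heavy-atom distance between two residues (A).

    By default only side-chain heavy atoms enter (backbone N, CA, C, O, OXT
    excluded), the standard convention for electron-transfer edge distances;
    ``sidechain_only=False`` switches to the all-heavy-atom minimum.
    """
    if resA == resB:
        raise ValueError("edge_to_edge requires two distinct residues")
    masks = []
    for res in (resA, resB):
        m = frame.residue_mask(res) & frame.heavy_mask()
        if sidechain_only:
            m &= ~np.isin(frame.atom_name, sorted(BACKBONE_ATOMS))
        if not m.any():
            raise ValueError(f"residue {res} has no (side-chain) heavy atoms")
        masks.append(m)
    return float(cdist(frame.coord[masks[0]], frame.coord[masks[1]]).min())


@dataclass
class DistanceDistribution:
    """Histogram density of distance samples with a single-Gaussian fit.

    The fitted mean is the reported location of the distribution maximum.
    ``fit_ok`` is False for degenerate samples (zero variance) or when the
    least-squares fit fails.
    """

    samples: np.ndarray
    bin_edges: np.ndarray
    density: np.ndarray
    amplitude: float | None
    mean: float | None
    sd: float | None
    fit_ok: bool

    def __post_init__(self) -> None:
        mass = float(np.sum(self.density * np.diff(self.bin_edges)))
        if abs(mass - 1.0) > 1e-6:
            raise ValueError(f"density must integrate to 1, got {mass}")
        if self.fit_ok and (self.sd is None or self.sd <= 0):
            raise ValueError("fit_ok requires sd > 0")


def _gaussian(x: np.ndarray, a: float, mu: float, sd: float) -> np.ndarray:
    return a * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def fit_distance_distribution(
    samples: Sequence[float],
    n_bins: int | None = None,
) -> DistanceDistribution:
    """Histogram distance samples and fit a Gaussian to the bin profile.

    ``n_bins`` defaults to the Freedman-Diaconis rule (at least 5 bins).
    The Gaussian amplitude, mean and sd are fit to the bin centers by
    unweighted least squares, initialized at the sample moments.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1 or samples.size < 30:
        raise ValueError(f"need at least 30 samples, got {samples.size}")
    if not np.all(np.isfinite(samples)):
        raise ValueError("samples must be finite")
    if n_bins is not None and n_bins < 5:
        raise ValueError("n_bins must be >= 5")

    if samples.std() == 0.0:
        edges = np.array([samples[0] - 0.5, samples[0] + 0.5])
        density = np.array([1.0])
        return DistanceDistribution(samples, edges, density, None, None, None, False)

    if n_bins is None:
        edges = np.histogram_bin_edges(samples, bins="fd")
        if edges.size - 1 < 5:
            edges = np.histogram_bin_edges(samples, bins=5)
    else:
        edges = np.histogram_bin_edges(samples, bins=n_bins)
    density, edges = np.histogram(samples, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(density.max()), float(samples.mean()), float(samples.std()))
    try:
        popt, _ = curve_fit(_gaussian, centers, density, p0=p0, maxfev=10000)
        a, mu, sd = float(popt[0]), float(popt[1]), abs(float(popt[2]))
        ok = np.isfinite([a, mu, sd]).all() and sd > 0
    except RuntimeError:
        a = mu = sd = None
        ok = False
    if not ok:
        a = mu = sd = None
    return DistanceDistribution(samples, edges, density, a, mu, sd, bool(ok))
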