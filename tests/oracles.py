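"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the RK4 integrator is a
fixed-step textbook scheme (no matrix exponentials, no eigendecomposition),
and the distance oracles are plain O(N^2) loops over atom pairs.
"""

from __future__ import annotations

import numpy as np


def generator_matrix(k: np.ndarray) -> np.ndarray:
    """Rate matrix built independently, straight from the four rate equations."""
    kfAB, kbAB, kfBC, kbBC, kfCD, kbCD = k
    M = np.zeros((4, 4))
    # dA/dt = -kfAB A + kbAB B
    M[0, 0] = -kfAB
    M[0, 1] = kbAB
    # dB/dt = kfAB A - kbAB B - kfBC B + kbBC C
    M[1, 0] = kfAB
    M[1, 1] = -kbAB - kfBC
    M[1, 2] = kbBC
    # dC/dt = kfBC B - kbBC C - kfCD C + kbCD D
    M[2, 1] = kfBC
    M[2, 2] = -kbBC - kfCD
    M[2, 3] = kbCD
    # dD/dt = kfCD C - kbCD D
    M[3, 2] = kfCD
    M[3, 3] = -kbCD
    return M


def rk4_batch(
    Ms: np.ndarray,
    p0: np.ndarray,
    t_max: float,
    dt: float,
    sample_stride: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-step classical RK4 for a batch of linear systems dp/dt = M p.

    Returns (times, P) with P of shape (batch, n_samples, 4), sampled every
    ``sample_stride`` steps (including t = 0).
    """
    Ms = np.asarray(Ms, dtype=float)
    B = Ms.shape[0]
    p = np.broadcast_to(np.asarray(p0, dtype=float), (B, 4)).copy()
    n_steps = int(round(t_max / dt))

    def f(state):
        return np.einsum("bij,bj->bi", Ms, state)

    out = [p.copy()]
    ts = [0.0]
    for s in range(1, n_steps + 1):
        k1 = f(p)
        k2 = f(p + 0.5 * dt * k1)
        k3 = f(p + 0.5 * dt * k2)
        k4 = f(p + dt * k3)
        p = p + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if s % sample_stride == 0:
            out.append(p.copy())
            ts.append(s * dt)
    return np.asarray(ts), np.stack(out, axis=1)


def random_tau_sets(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """n random time-constant sets (ps), log-uniform in [lo, hi]."""
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n, 6)))


def brute_force_water_count(frame, residue_number: int, cutoff: float = 5.0) -> int:
    """O(N^2) reference water count: explicit loops, no vectorized distance."""
    water_names = {"HOH", "WAT", "SOL", "TIP3"}
    res_atoms = [
        frame.coord[i]
        for i in range(frame.n_atoms)
        if frame.res_id[i] == residue_number
        and frame.res_name[i] not in water_names
        and str(frame.element[i]).upper() != "H"
    ]
    if not res_atoms:
        raise ValueError(f"residue {residue_number} absent")
    hits = set()
    for i in range(frame.n_atoms):
        if frame.res_name[i] not in water_names:
            continue
        key = (frame.chain_id[i], int(frame.res_id[i]))
        for ra in res_atoms:
            d = float(np.sqrt(np.sum((frame.coord[i] - ra) ** 2)))
            if d <= cutoff + 1e-9:
                hits.add(key)
                break
    return len(hits)


def brute_force_edge(frame, resA: int, resB: int) -> float:
    """O(N^2) reference side-chain heavy-atom minimum distance."""
    backbone = {"N", "CA", "C", "O", "OXT"}
    water_names = {"HOH", "WAT", "SOL", "TIP3"}

    def atoms(res):
        return [
            frame.coord[i]
            for i in range(frame.n_atoms)
            if frame.res_id[i] == res
            and frame.res_name[i] not in water_names
            and str(frame.element[i]).upper() != "H"
            and frame.atom_name[i] not in backbone
        ]

    best = np.inf
    for a in atoms(resA):
        for b in atoms(resB):
            d = float(np.sqrt(np.sum((a - b) ** 2)))
            best = min(best, d)
    return best
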