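"""Reversible four-state kinetics of electron-hole transfer along the Trp tetrad.

After photoexcitation of the FAD chromophore in cryptochrome 4, an electron
hole migrates along a conserved chain of four tryptophan residues,
Trp_A -> Trp_B -> Trp_C -> Trp_D.  The occupation of the hole on site X
corresponds to the radical-pair state [FAD.- TrpX.+].  This module implements
the linear chain of reversible first-order transfer reactions

    A <=> B <=> C <=> D

with six rate constants (forward/backward for each neighbouring pair),
propagates the resulting master equation exactly, computes the chain
equilibrium, and recovers the rate constants from ensemble-averaged
occupation curves by multi-start nonlinear least squares.

Units: time in picoseconds, rates in 1/ps, throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

#: Site labels of the tryptophan tetrad, ordered from the FAD-proximal site.
SITES: tuple[str, ...] = ("A", "B", "C", "D")

#: Residue numbers of the tetrad in Atlantic herring cryptochrome 4 (ChCry4).
SITE_RESIDUES: dict[str, int] = {"A": 396, "B": 373, "C": 319, "D": 370}
RESIDUE_SITES: dict[int, str] = {r: s for s, r in SITE_RESIDUES.items()}

#: Canonical ordering of the six rate constants.
RATE_KEYS: tuple[str, ...] = ("kfAB", "kbAB", "kfBC", "kbBC", "kfCD", "kbCD")
TAU_KEYS: tuple[str, ...] = tuple("tau_" + k[1:] for k in RATE_KEYS)

#: Characteristic transfer time constants (ps) of the ChCry4 tryptophan chain,
#: obtained by fitting this kinetic model to ensemble-averaged QM/MM hole
#: occupations.  Used as the package-wide reference parameter set.
CHCRY4_TIME_CONSTANTS_PS: dict[str, float] = {
    "tau_fAB": 23.0,
    "tau_bAB": 141.0,
    "tau_fBC": 149.0,
    "tau_bBC": 82.0,
    "tau_fCD": 57.0,
    "tau_bCD": 240.0,
}


@dataclass(frozen=True)
class RateConstants:
    """The six transfer rate constants of the reversible Trp-tetrad chain.

    ``kfXY`` is the forward hole-transfer rate from site X to site Y,
    ``kbXY`` the corresponding backward rate, all in 1/ps.  Rates must be
    finite and non-negative; zero rates are allowed (irreversible or frozen
    steps).
    """

    kfAB: float
    kbAB: float
    kfBC: float
    kbBC: float
    kfCD: float
    kbCD: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = float(getattr(self, f.name))
            if not np.isfinite(v) or v < 0.0:
                raise ValueError(
                    f"rate constant {f.name} must be finite and >= 0, got {v!r}"
                )
            object.__setattr__(self, f.name, v)

    def as_array(self) -> np.ndarray:
        """Rates as an array ordered like :data:`RATE_KEYS`."""
        return np.array([getattr(self, k) for k in RATE_KEYS], dtype=float)

    @classmethod
    def from_array(cls, k: Sequence[float]) -> "RateConstants":
        k = np.asarray(k, dtype=float)
        if k.shape != (6,):
            raise ValueError(f"expected 6 rates, got shape {k.shape}")
        return cls(*k)

    @classmethod
    def from_time_constants(cls, tau: Mapping[str, float] | Sequence[float]) -> "RateConstants":
        """Build from time constants (ps), the reciprocal view of the rates.

        Accepts a mapping with keys ``tau_fAB`` ... ``tau_bCD`` (or the bare
        rate keys) or a sequence ordered like :data:`RATE_KEYS`.  All time
        constants must be strictly positive.
        """
        if isinstance(tau, Mapping):
            vals = []
            for tk, rk in zip(TAU_KEYS, RATE_KEYS):
                if tk in tau:
                    vals.append(float(tau[tk]))
                elif rk in tau:
                    vals.append(float(tau[rk]))
                else:
                    raise ValueError(f"missing time constant {tk}")
        else:
            vals = [float(v) for v in tau]
            if len(vals) != 6:
                raise ValueError(f"expected 6 time constants, got {len(vals)}")
        arr = np.asarray(vals, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError("time constants must be finite and > 0")
        return cls.from_array(1.0 / arr)

    def as_tau_array(self) -> np.ndarray:
        """Time constants (ps); ``inf`` where the rate is zero."""
        k = self.as_array()
        with np.errstate(divide="ignore"):
            return np.where(k > 0, 1.0 / np.where(k > 0, k, 1.0), np.inf)

    def time_constants(self) -> dict[str, float]:
        """Time constants keyed ``tau_fAB`` ... ``tau_bCD`` (ps)."""
        return dict(zip(TAU_KEYS, self.as_tau_array()))

    def to_dict(self) -> dict[str, float]:
        return dict(zip(RATE_KEYS, self.as_array()))

    def replace(self, **kwargs: float) -> "RateConstants":
        d = self.to_dict()
        d.update(kwargs)
        return RateConstants(**d)


def chcry4_rates() -> RateConstants:
    """The reference ChCry4 rate constants (inverted time constants)."""
    return RateConstants.from_time_constants(CHCRY4_TIME_CONSTANTS_PS)


def _validate_grid(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ValueError("time grid must be a non-empty 1-d array")
    if not np.all(np.isfinite(times)):
        raise ValueError("time grid must be finite")
    if times[0] != 0.0:
        raise ValueError(f"time grid must start at 0 ps, got {times[0]}")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("time grid must be strictly increasing")
    return times


@dataclass(frozen=True)
class OccupationTrace:
    """Time-resolved occupations A(t), B(t), C(t), D(t) on a common ps grid.

    ``occ`` has shape ``(n_times, 4)`` with columns ordered A, B, C, D.
    Each row is a distribution: entries in [0, 1] and summing to 1 (within
    1e-6).  Use :meth:`from_raw` for approximately-normalized input such as
    QM/MM populations, which renormalizes rows deviating by at most 0.05.
    """

    times: np.ndarray
    occ: np.ndarray
    sim_id: str | None = None

    def __post_init__(self) -> None:
        times = _validate_grid(self.times)
        occ = np.asarray(self.occ, dtype=float)
        if occ.shape != (times.size, 4):
            raise ValueError(f"occ must have shape ({times.size}, 4), got {occ.shape}")
        if not np.all(np.isfinite(occ)):
            raise ValueError("occupations must be finite")
        if occ.min() < -1e-9 or occ.max() > 1.0 + 1e-9:
            raise ValueError("occupations must lie in [0, 1] (tolerance 1e-9)")
        row_sums = occ.sum(axis=1)
        if np.max(np.abs(row_sums - 1.0)) > 1e-6:
            raise ValueError(
                "occupations must sum to 1 at every time point (tolerance 1e-6); "
                "use OccupationTrace.from_raw for approximately normalized data"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "occ", occ)

    @classmethod
    def from_raw(
        cls,
        times: Sequence[float],
        occ: Sequence[Sequence[float]],
        sim_id: str | None = None,
        tol: float = 0.05,
    ) -> "OccupationTrace":
        """Build a trace from raw, approximately normalized occupation data.

        Rows whose sum deviates from 1 by at most ``tol`` are renormalized
        (with a logged warning); larger deviations raise.  Values slightly
        outside [0, 1] (by at most ``tol``) are clipped before renormalizing.
        """
        times = np.asarray(times, dtype=float)
        occ = np.asarray(occ, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != 4:
            raise ValueError(f"occ must have shape (n, 4), got {occ.shape}")
        if occ.min() < -tol or occ.max() > 1.0 + tol:
            raise ValueError(f"raw occupations outside [-{tol}, 1+{tol}]")
        occ = np.clip(occ, 0.0, 1.0)
        row_sums = occ.sum(axis=1)
        dev = np.max(np.abs(row_sums - 1.0))
        if dev > tol:
            raise ValueError(
                f"occupation sums deviate from 1 by {dev:.3g} (> {tol}); refusing to renormalize"
            )
        if dev > 1e-9:
            logger.warning("renormalizing occupations (max sum deviation %.3g)", dev)
        occ = occ / row_sums[:, None]
        return cls(times=times, occ=occ, sim_id=sim_id)

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    def site(self, label: str) -> np.ndarray:
        """Occupation series of one site ('A', 'B', 'C' or 'D')."""
        return self.occ[:, SITES.index(label)]


def _generator_matrix(k: np.ndarray) -> np.ndarray:
    kfAB, kbAB, kfBC, kbBC, kfCD, kbCD = k
    return np.array(
        [
            [-kfAB, kbAB, 0.0, 0.0],
            [kfAB, -(kbAB + kfBC), kbBC, 0.0],
            [0.0, kfBC, -(kbBC + kfCD), kbCD],
            [0.0, 0.0, kfCD, -kbCD],
        ]
    )


def build_generator(rates: RateConstants) -> np.ndarray:
    """Generator matrix M (1/ps) of the master equation dp/dt = M p.

    p = (A, B, C, D).  Columns sum to zero (probability conservation) and
    only nearest-neighbour off-diagonal entries are non-zero (chain topology).
    """
    if not isinstance(rates, RateConstants):
        rates = RateConstants.from_array(np.asarray(rates, dtype=float))
    return _generator_matrix(rates.as_array())


def _validate_p0(p0: Sequence[float] | None) -> np.ndarray:
    if p0 is None:
        return np.array([1.0, 0.0, 0.0, 0.0])
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (4,):
        raise ValueError(f"p0 must be a 4-vector, got shape {p0.shape}")
    if not np.all(np.isfinite(p0)) or np.any(p0 < 0):
        raise ValueError("p0 must be non-negative and finite")
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError(f"p0 must sum to 1 (tolerance 1e-9), got {p0.sum()!r}")
    return p0


def _propagate_occ(M: np.ndarray, p0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Exact propagation of dp/dt = M p; returns occupations shape (n, 4).

    Uses the eigendecomposition of the generator (exact for the linear
    system).  If the eigenvector matrix is ill-conditioned (near-degenerate
    spectrum) or conservation degrades, falls back to stepwise dense matrix
    exponentials, which handle defective generators and arbitrary stiffness.
    """
    ok = False
    P = None
    try:
        w, V = np.linalg.eig(M)
        if np.linalg.cond(V) < 1e8:
            c = np.linalg.solve(V, p0.astype(complex))
            P = ((V * c) @ np.exp(np.outer(w, times))).real.T
            ok = np.max(np.abs(P.sum(axis=1) - 1.0)) < 1e-8
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        ok = False
    if not ok:
        P = np.empty((times.size, 4))
        P[0] = p0
        p = p0.astype(float)
        cache: dict[float, np.ndarray] = {}
        for i, dt in enumerate(np.diff(times)):
            key = float(dt)
            step = cache.get(key)
            if step is None:
                step = cache[key] = expm(M * dt)
            p = step @ p
            P[i + 1] = p
    P = np.clip(P, 0.0, 1.0)
    P /= P.sum(axis=1, keepdims=True)
    return P


def propagate(
    rates: RateConstants,
    times: Sequence[float],
    p0: Sequence[float] | None = None,
    sim_id: str | None = None,
) -> OccupationTrace:
    """Solve the four-state master equation on a ps grid.

    Parameters
    ----------
    rates:
        The six transfer rate constants (1/ps).
    times:
        Strictly increasing grid starting at 0 ps.
    p0:
        Initial distribution over (A, B, C, D).  Defaults to (1, 0, 0, 0),
        the hole starting on Trp_A after the initial FAD <- Trp_A electron
        transfer has completed.
    """
    times = _validate_grid(np.asarray(times, dtype=float))
    p0 = _validate_p0(p0)
    M = build_generator(rates)
    occ = _propagate_occ(M, p0, times)
    return OccupationTrace(times=times, occ=occ, sim_id=sim_id)


def steady_state(rates: RateConstants) -> np.ndarray:
    """Equilibrium distribution of the reversible chain.

    For the linear chain with all six rates strictly positive the stationary
    distribution is the detailed-balance closed form
    (1, K1, K1 K2, K1 K2 K3)/Z with K1 = kfAB/kbAB, K2 = kfBC/kbBC,
    K3 = kfCD/kbCD.
    """
    k = rates.as_array()
    if np.any(k <= 0):
        raise ValueError(
            "steady_state requires all six rates strictly positive (reversible "
            "chain); for irreversible chains propagate to large t instead"
        )
    K1 = rates.kfAB / rates.kbAB
    K2 = rates.kfBC / rates.kbBC
    K3 = rates.kfCD / rates.kbCD
    v = np.array([1.0, K1, K1 * K2, K1 * K2 * K3])
    return v / v.sum()


@dataclass(frozen=True)
class KineticFit:
    """Result of fitting the four-state model to an occupation trace.

    ``per_parameter_spread`` is the population standard deviation of each
    recovered rate across the successful multi-start optimizations, a cheap
    dispersion proxy for identifiability (large spread = the data do not pin
    the parameter down).
    """

    rates: RateConstants
    residual_norm: float
    n_points: int
    converged: bool
    per_parameter_spread: np.ndarray
    n_starts: int
    n_starts_succeeded: int
    seed: int

    def __post_init__(self) -> None:
        if self.residual_norm < 0:
            raise ValueError("residual_norm must be >= 0")
        spread = np.asarray(self.per_parameter_spread, dtype=float)
        if spread.shape != (6,) or np.any(spread < 0):
            raise ValueError("per_parameter_spread must be 6 non-negative values")
        object.__setattr__(self, "per_parameter_spread", spread)

    def time_constants(self) -> dict[str, float]:
        return self.rates.time_constants()


def fit_rates(
    trace: OccupationTrace,
    init: RateConstants | None = None,
    n_starts: int = 16,
    seed: int = 0,
    p0: Sequence[float] | None = None,
    tau_init_range_ps: tuple[float, float] = (1.0, 1000.0),
    max_nfev: int = 4000,
) -> KineticFit:
    """Recover the six rate constants from an occupation trace.

    Minimizes the sum of squared residuals between the trace and the master-
    equation solution started from ``p0`` (default (1,0,0,0)), over all four
    site curves with equal weights.  The optimization works on log time
    constants, which enforces positivity without explicit bounds and puts the
    order-of-magnitude spread of the rates on a common scale.  ``n_starts``
    log-uniform initial guesses with time constants in ``tau_init_range_ps``
    are drawn from ``seed``; an explicit ``init`` is tried as an extra start.
    Ties between equally good optima are broken by residual norm, then by the
    lexicographically smallest rate vector, making the result deterministic.

    Never raises on non-convergence: if no start converges the best attempt
    is returned with ``converged=False``.
    """
    if not isinstance(trace, OccupationTrace):
        raise TypeError("trace must be an OccupationTrace")
    if trace.n_points < 20:
        raise ValueError(f"need at least 20 time points to fit, got {trace.n_points}")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    times = trace.times
    target = trace.occ
    p0_arr = _validate_p0(p0)

    # clamp time constants to [1e-8, 1e12] ps so stray optimizer steps cannot
    # overflow the rate matrix; the objective is flat beyond the clamp
    log_tau_lo, log_tau_hi = np.log(1e-8), np.log(1e12)

    def residuals(log_tau: np.ndarray) -> np.ndarray:
        k = np.exp(-np.clip(log_tau, log_tau_lo, log_tau_hi))
        P = _propagate_occ(_generator_matrix(k), p0_arr, times)
        return (P - target).ravel()

    lo, hi = np.log(tau_init_range_ps[0]), np.log(tau_init_range_ps[1])
    rng = np.random.default_rng(seed)
    starts = list(rng.uniform(lo, hi, size=(n_starts, 6)))
    if init is not None:
        k0 = init.as_array()
        if np.any(k0 <= 0):
            raise ValueError("init rates must be strictly positive (log parameterization)")
        starts.insert(0, np.log(1.0 / k0))

    results = []
    for x0 in starts:
        try:
            res = least_squares(
                residuals,
                x0,
                method="lm",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=max_nfev,
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.debug("fit start failed: %s", exc)
            continue
        results.append(res)
        logger.debug(
            "fit start: cost=%.6g status=%d taus=%s",
            res.cost,
            res.status,
            np.exp(np.clip(res.x, log_tau_lo, log_tau_hi)),
        )

    if not results:
        # every optimizer call blew up; report the least-bad raw start
        norms = [float(np.linalg.norm(residuals(x0))) for x0 in starts]
        i = int(np.argmin(norms))
        return KineticFit(
            rates=RateConstants.from_array(np.exp(-starts[i])),
            residual_norm=norms[i],
            n_points=trace.n_points,
            converged=False,
            per_parameter_spread=np.zeros(6),
            n_starts=n_starts,
            n_starts_succeeded=0,
            seed=seed,
        )

    succeeded = [r for r in results if r.status > 0]
    pool = succeeded if succeeded else results
    for r in pool:
        r.x = np.clip(r.x, log_tau_lo, log_tau_hi)
    best = min(pool, key=lambda r: (r.cost, tuple(np.exp(-r.x))))
    rate_sets = np.exp(-np.array([r.x for r in pool]))
    spread = rate_sets.std(axis=0, ddof=0)
    return KineticFit(
        rates=RateConstants.from_array(np.exp(-best.x)),
        residual_norm=float(np.linalg.norm(best.fun)),
        n_points=trace.n_points,
        converged=bool(succeeded),
        per_parameter_spread=spread,
        n_starts=n_starts,
        n_starts_succeeded=len(succeeded),
        seed=seed,
    )
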