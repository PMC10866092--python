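"""Minimum control energy for brain-state transitions on a structural connectome.

Neural dynamics are modeled as linear and time-invariant,

    dx/dt = A* x(t) + B u(t),

where x is the vector of regional percent-change FOS values (the brain
state), A* is the stabilized structural connectome, and B selects (and
weights) the regions receiving control input.  The cheapest input
driving x0 to xf in time T has energy

    E = v' W(T)^+ v,    v = xf - e^{A*T} x0,

with the controllability Gramian W(T) = int_0^T e^{A*t} B B' e^{A*'t} dt.
The Gramian is integrated with Simpson's rule on a uniform grid of
matrix exponentials; for diagonal B = diag(w) the Gramian decomposes as
W = sum_j w_j^2 W_j over per-column Gramians W_j, so reweighting or
suppressing control inputs is exact algebra on precomputed pieces.

Suppression analysis removes one region (or a set) from the control set
and reports the percent increase in minimum energy; receptor-weighted
control sets B's diagonal to normalized receptor expression; persistence
energy is the special case x0 = xf (the cost of holding a state against
the drift).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import expm

from .synthio import Connectome, ReceptorMap

#: relative pseudo-inverse cutoff for the Gramian
PINV_RCOND = 1e-10
#: relative reachability residual above which a transition is flagged
UNREACHABLE_TOL = 1e-6


def normalize_system(connectome: Connectome | np.ndarray, c: float = 1.0) -> np.ndarray:
    """Stabilize a nonnegative adjacency matrix: A* = A/(lambda_max + c) - I.

    lambda_max is the largest real eigenvalue (the spectral radius for a
    nonnegative matrix), so every eigenvalue of A* has negative real
    part and the free dynamics decay.
    """
    A = connectome.A if isinstance(connectome, Connectome) else np.asarray(connectome, dtype=float)
    if A.size == 0:
        raise ValueError("empty matrix")
    if np.any(A < 0):
        raise ValueError("adjacency must be nonnegative")
    lam = float(np.max(np.linalg.eigvals(A).real))
    return A / (lam + c) - np.eye(A.shape[0])


@dataclass
class ControlSpec:
    """Control problem configuration.

    B_weights: diagonal control weights (None = full control, all ones);
    T: time horizon; n_steps: Simpson grid size (odd, >= 3);
    c: normalization constant for A*; suppression_floor: weight assigned
    to suppressed regions (0 drops the control column).
    """

    B_weights: np.ndarray | None = None
    T: float = 1.0
    n_steps: int = 1001
    c: float = 1.0
    suppression_floor: float = 0.0

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.n_steps < 3 or self.n_steps % 2 == 0:
            raise ValueError("n_steps must be an odd integer >= 3")
        if self.B_weights is not None:
            w = np.asarray(self.B_weights, dtype=float)
            if np.any(w < 0) or not np.any(w > 0):
                raise ValueError("B_weights must be >= 0 with at least one positive entry")
            self.B_weights = w


@dataclass
class EnergyResult:
    """Minimum control energy with conditioning diagnostics."""

    energy: float
    residual: float
    gramian_cond: float
    unreachable: bool = False
    t: np.ndarray | None = None
    u: np.ndarray | None = None
    x: np.ndarray | None = None


class ControlSystem:
    """Precomputed Gramian machinery for one stabilized system.

    Builds the matrix-exponential grid, the per-column Gramians W_j, and
    e^{A*T} once; every subsequent energy evaluation (any diagonal
    control weighting, any state pair) reuses them.
    """

    def __init__(self, Astar: np.ndarray, spec: ControlSpec | None = None):
        Astar = np.asarray(Astar, dtype=float)
        if Astar.ndim != 2 or Astar.shape[0] != Astar.shape[1]:
            raise ValueError("Astar must be square")
        self.Astar = Astar
        self.spec = spec or ControlSpec()
        n = Astar.shape[0]
        K = self.spec.n_steps
        h = self.spec.T / (K - 1)
        step = expm(Astar * h)
        M = np.empty((K, n, n))
        M[0] = np.eye(n)
        for k in range(1, K):
            M[k] = M[k - 1] @ step
        self.t_grid = np.linspace(0.0, self.spec.T, K)
        self.M = M
        self.eAT = M[-1]
        # Simpson weights
        s = np.ones(K)
        s[1:-1:2] = 4.0
        s[2:-1:2] = 2.0
        s *= h / 3.0
        self._simpson = s
        # per-column Gramians: W_j[a,b] = int M[:,a,j] M[:,b,j] dt
        self.WJ = np.einsum("k,kaj,kbj->jab", s, M, M, optimize=True)
        self._cache: dict[bytes, tuple[np.ndarray, np.ndarray, float]] = {}

    @property
    def n(self) -> int:
        return self.Astar.shape[0]

    def _weights(self, weights) -> np.ndarray:
        if weights is None:
            weights = self.spec.B_weights
        if weights is None:
            return np.ones(self.n)
        w = np.asarray(weights, dtype=float)
        if w.shape != (self.n,):
            raise ValueError(f"weights must have length {self.n}")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be >= 0 with at least one positive entry")
        return w

    def gramian(self, weights=None) -> np.ndarray:
        """Controllability Gramian W(T) for B = diag(weights)."""
        w = self._weights(weights)
        return np.einsum("j,jab->ab", w**2, self.WJ, optimize=True)

    def _gramian_inv(self, weights=None):
        w = self._weights(weights)
        key = w.tobytes()
        if key not in self._cache:
            W = self.gramian(w)
            sv = np.linalg.svd(W, compute_uv=False)
            cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
            self._cache[key] = (W, np.linalg.pinv(W, rcond=PINV_RCOND, hermitian=True), cond)
        return self._cache[key]

    def energy(self, x0, xf, weights=None, return_trajectories: bool = False) -> EnergyResult:
        """Minimum energy driving x0 to xf over the horizon T."""
        x0 = np.asarray(x0, dtype=float)
        xf = np.asarray(xf, dtype=float)
        if x0.shape != (self.n,) or xf.shape != (self.n,):
            raise ValueError(f"states must have length {self.n}")
        if not (np.all(np.isfinite(x0)) and np.all(np.isfinite(xf))):
            raise ValueError("states must be finite")
        w = self._weights(weights)
        W, Wp, cond = self._gramian_inv(w)
        v = xf - self.eAT @ x0
        energy = float(v @ Wp @ v)
        nv = np.linalg.norm(v)
        residual = float(np.linalg.norm(W @ Wp @ v - v) / nv) if nv > 0 else 0.0
        res = EnergyResult(
            energy=max(energy, 0.0),
            residual=residual,
            gramian_cond=cond,
            unreachable=residual > UNREACHABLE_TOL,
        )
        if return_trajectories:
            lam = Wp @ v
            # u*(t) = B' e^{A*'(T-t)} W^+ v; M[K-1-k] = e^{A*(T - t_k)}
            U = np.array([w * (self.M[-1 - k].T @ lam) for k in range(len(self.t_grid))])
            # x(t) = M(t) [x0 + int_0^t M(s)^{-1} B u(s) ds]
            g = np.array(
                [np.linalg.solve(self.M[k], w * U[k]) for k in range(len(self.t_grid))]
            )
            h = self.t_grid[1] - self.t_grid[0]
            acc = np.zeros_like(x0)
            X = np.empty_like(U)
            X[0] = x0
            for k in range(1, len(self.t_grid)):
                acc = acc + 0.5 * h * (g[k - 1] + g[k])
                X[k] = self.M[k] @ (x0 + acc)
            res.t, res.u, res.x = self.t_grid, U, X
        return res

    def pairwise_energies(self, X0: np.ndarray, Xf: np.ndarray, weights=None) -> np.ndarray:
        """Energy matrix for every (row of X0) -> (row of Xf) transition."""
        X0 = np.atleast_2d(np.asarray(X0, dtype=float))
        Xf = np.atleast_2d(np.asarray(Xf, dtype=float))
        if X0.shape[1] != self.n or Xf.shape[1] != self.n:
            raise ValueError(f"state rows must have length {self.n}")
        _, Wp, _ = self._gramian_inv(self._weights(weights))
        P = X0 @ self.eAT.T  # rows: e^{A*T} x0
        a = np.einsum("ja,ab,jb->j", Xf, Wp, Xf)
        b = np.einsum("ia,ab,ib->i", P, Wp, P)
        C = P @ Wp @ Xf.T
        E = a[None, :] + b[:, None] - 2.0 * C
        return np.maximum(E, 0.0)


def minimum_control_energy(Astar, spec: ControlSpec | None, x0, xf, **kw) -> EnergyResult:
    """One-shot minimum control energy (see :class:`ControlSystem`)."""
    sys = Astar if isinstance(Astar, ControlSystem) else ControlSystem(Astar, spec)
    return sys.energy(x0, xf, **kw)


def persistence_energy(Astar, spec: ControlSpec | None, x, **kw) -> EnergyResult:
    """Energy required to hold state x over the horizon (x0 = xf = x)."""
    return minimum_control_energy(Astar, spec, x, x, **kw)


@dataclass
class SuppressionProfile:
    """Percent increase in minimum energy when each region is removed
    from the control set, relative to full control."""

    percent_increase: np.ndarray
    full_energy: float
    unreachable: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


def suppression_profile(Astar, spec: ControlSpec | None, x0, xf) -> SuppressionProfile:
    """Influence of each region on the transition energy.

    For each region k the k-th control weight is replaced by the
    suppression floor (default 0, dropping the column) and the energy
    recomputed; the profile entry is 100 * (E_suppressed / E_full - 1).
    An unreachable suppressed transition yields +inf with a flag.
    """
    sys = Astar if isinstance(Astar, ControlSystem) else ControlSystem(Astar, spec)
    spec = sys.spec
    base_w = sys._weights(None)
    full = sys.energy(x0, xf)
    if full.unreachable or full.energy == 0:
        raise ValueError("full-control energy not computable for this transition")
    n = sys.n
    pct = np.empty(n)
    unreach = np.zeros(n, dtype=bool)
    for k in range(n):
        w = base_w.copy()
        w[k] = spec.suppression_floor
        res = sys.energy(x0, xf, weights=w)
        if res.unreachable:
            pct[k] = np.inf
            unreach[k] = True
        else:
            pct[k] = 100.0 * (res.energy / full.energy - 1.0)
    return SuppressionProfile(percent_increase=pct, full_energy=full.energy, unreachable=unreach)


@dataclass
class SetSuppressionResult:
    """Energy with a whole region set suppressed, against a random-subset null."""

    energy: float
    percent_increase: float
    full_energy: float
    null_percent_increase: np.ndarray
    t_stat: float
    p_value: float


def suppress_set(
    Astar,
    spec: ControlSpec | None,
    x0,
    xf,
    target_set,
    n_random_sets: int = 100,
    seed: int = 0,
) -> SetSuppressionResult:
    """Suppress a set of regions and compare with equally sized random subsets.

    The null distribution suppresses ``n_random_sets`` subsets of the
    same size drawn from the regions outside the target set.  The
    reported one-sample t statistic is (target effect - null mean) /
    (null SD / sqrt(n)), positive when the target set is more
    influential than random subsets.
    """
    sys = Astar if isinstance(Astar, ControlSystem) else ControlSystem(Astar, spec)
    spec = sys.spec
    target = np.asarray(sorted(set(int(i) for i in np.atleast_1d(target_set))))
    if target.size == 0:
        raise ValueError("target_set must be nonempty")
    if target.size >= sys.n:
        raise ValueError("target_set must be a strict subset of the regions")
    if target.min() < 0 or target.max() >= sys.n:
        raise ValueError("target_set indices out of range")
    base_w = sys._weights(None)
    full = sys.energy(x0, xf)
    if full.energy == 0:
        raise ValueError("full-control energy is zero")

    def pct_with_suppressed(idx):
        w = base_w.copy()
        w[idx] = spec.suppression_floor
        return sys.energy(x0, xf, weights=w).energy / full.energy * 100.0 - 100.0

    target_pct = pct_with_suppressed(target)
    rng = np.random.default_rng(seed)
    pool = np.setdiff1d(np.arange(sys.n), target)
    if pool.size < target.size:
        raise ValueError("not enough non-target regions for the null subsets")
    null = np.array(
        [pct_with_suppressed(rng.choice(pool, size=target.size, replace=False)) for _ in range(n_random_sets)]
    )
    se = null.std(ddof=1) / np.sqrt(n_random_sets)
    t_stat = float((target_pct - null.mean()) / se) if se > 0 else np.inf
    p = float(2.0 * stats.t.sf(abs(t_stat), df=n_random_sets - 1)) if np.isfinite(t_stat) else 0.0
    return SetSuppressionResult(
        energy=full.energy * (1.0 + target_pct / 100.0),
        percent_increase=float(target_pct),
        full_energy=full.energy,
        null_percent_increase=null,
        t_stat=t_stat,
        p_value=p,
    )


def receptor_weights(receptor_map: ReceptorMap, receptor: str, floor: float = 1e-6) -> np.ndarray:
    """Normalized control weights for one receptor: density / max, floored."""
    v = np.asarray(receptor_map.density[receptor], dtype=float)
    m = v.max()
    if m <= 0:
        raise ValueError(f"receptor {receptor!r} has no positive density")
    return np.maximum(v / m, floor)


def receptor_weighted_energy(
    Astar,
    receptor_map: ReceptorMap,
    x0,
    xf,
    receptor: str,
    spec: ControlSpec | None = None,
) -> EnergyResult:
    """Transition energy with control inputs weighted by receptor expression."""
    sys = Astar if isinstance(Astar, ControlSystem) else ControlSystem(Astar, spec)
    return sys.energy(x0, xf, weights=receptor_weights(receptor_map, receptor))


def pairwise_transition_energies(Astar, spec: ControlSpec | None, acute_states, chronic_states):
    """Energy for every acute-replicate -> chronic-replicate transition.

    Accepts BootstrapSet objects or plain (n, N) arrays; returns the
    (n_acute, n_chronic) energy matrix.
    """
    sys = Astar if isinstance(Astar, ControlSystem) else ControlSystem(Astar, spec)
    X0 = getattr(acute_states, "replicates", acute_states)
    Xf = getattr(chronic_states, "replicates", chronic_states)
    return sys.pairwise_energies(X0, Xf)
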