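"""1-D reaction-diffusion simulator with no-flux boundaries.

The full model adds Fickian diffusion to the reaction terms of
:mod:`.model_core` on an interval [0, l] with homogeneous Neumann
(no-flux) boundary conditions:

    N_t = D1 N_xx + eps (1 - N/K) N - a phi(N) P
    P_t = D2 P_xx - M(P) P + b phi(N) P,      N_x = P_x = 0 at x = 0, l.

Space is discretised by second-order central differences on a
node-centred grid (method of lines); the resulting stiff ODE system is
integrated adaptively with a banded Jacobian.  The module also provides
trajectory diagnostics for the three long-time theorems verified by the
test-suite: dissipativity (an absorbing box bounds every trajectory),
the extinction/permanence dichotomy (decided by the sign of
``b phi(K) - gamma`` alone, independently of diffusion), and empirical
persistence margins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .exceptions import (DiagnosticsError, DomainError, ParameterError,
                         SimulationError)
from .model_core import ModelParams, mortality
from .responses import ResponseSpec

__all__ = [
    "Grid1D",
    "FieldPair",
    "Trajectory",
    "DissipativityVerdict",
    "RegimeVerdict",
    "laplacian_neumann",
    "simulate",
    "dissipativity_check",
    "persistence_margins",
    "regime_check",
    "predator_bound_M0",
]

#: values in [-CLAMP_FLOOR, 0) are clamped to 0; anything below aborts
CLAMP_FLOOR = 1e-10

#: tail predator maximum below this counts as extinction
EXTINCTION_THRESHOLD = 1e-6


@dataclass(frozen=True)
class Grid1D:
    """Uniform node-centred grid on [0, length], endpoints included."""

    length: float
    n: int = 201

    def __post_init__(self):
        if not (self.length > 0):
            raise ParameterError("grid length must be positive")
        if self.n < 16:
            raise ParameterError(f"grid needs at least 16 nodes, got {self.n}")

    @property
    def dx(self) -> float:
        return self.length / (self.n - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n)

    @property
    def quad_weights(self) -> np.ndarray:
        """Trapezoidal quadrature weights (sum to ``length``)."""
        w = np.full(self.n, self.dx)
        w[0] = w[-1] = 0.5 * self.dx
        return w


@dataclass
class FieldPair:
    """Prey and predator density fields on a grid."""

    N: np.ndarray
    P: np.ndarray

    def __post_init__(self):
        self.N = np.asarray(self.N, float)
        self.P = np.asarray(self.P, float)
        if self.N.shape != self.P.shape:
            raise ParameterError("N and P fields must have the same shape")
        if not (np.all(np.isfinite(self.N)) and np.all(np.isfinite(self.P))):
            raise DomainError("fields must be finite")

    @classmethod
    def constant(cls, grid: Grid1D, N0: float, P0: float) -> "FieldPair":
        return cls(np.full(grid.n, float(N0)), np.full(grid.n, float(P0)))


@dataclass
class Trajectory:
    """Saved time evolution of a reaction-diffusion run."""

    times: np.ndarray
    N: np.ndarray  # (n_times, n_nodes)
    P: np.ndarray
    grid: Grid1D
    params: ModelParams
    meta: dict = field(default_factory=dict)
    energy: Optional[np.ndarray] = None  # filled by the lyapunov module

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def snapshot(self, i: int) -> FieldPair:
        return FieldPair(self.N[i].copy(), self.P[i].copy())

    @property
    def summaries(self) -> pd.DataFrame:
        d = {
            "t": self.times,
            "minN": self.N.min(axis=1), "maxN": self.N.max(axis=1),
            "minP": self.P.min(axis=1), "maxP": self.P.max(axis=1),
            "meanN": self.N.mean(axis=1), "meanP": self.P.mean(axis=1),
            "varN": self.N.var(axis=1), "varP": self.P.var(axis=1),
        }
        if self.energy is not None and len(self.energy) == len(self.times):
            d["energy"] = self.energy
        return pd.DataFrame(d)

    def tail_mask(self, window: float = 0.2) -> np.ndarray:
        """Tail selector: last ``window`` fraction of saved times after a
        burn-in of ``max(10, 0.1 t_end)`` time units."""
        if not (0 < window < 1):
            raise ParameterError("window must lie in (0, 1)")
        burn = max(10.0, 0.1 * self.t_end)
        eligible = np.nonzero(self.times >= burn)[0]
        if eligible.size == 0:
            raise DiagnosticsError(
                "trajectory too short for tail diagnostics "
                f"(needs times beyond burn-in {burn:g})")
        k = eligible[int(math.floor((1.0 - window) * eligible.size))]
        return np.arange(len(self.times)) >= k


@dataclass(frozen=True)
class DissipativityVerdict:
    """Tail bounds versus the absorbing box [0, K] x [0, M0]."""

    M0: float
    tail_max_N: float
    tail_max_P: float
    holds_N: bool
    holds_P: bool
    tol: float

    @property
    def holds(self) -> bool:
        return self.holds_N and self.holds_P


@dataclass(frozen=True)
class RegimeVerdict:
    """Extinction/permanence dichotomy, decided by sign(b phi(K) - gamma)."""

    regime: str  # "permanent" | "extinction"
    margin: float  # b phi(K) - gamma
    note: str = ("verdict independent of the diffusion coefficients D1, D2")


def laplacian_neumann(values: np.ndarray, grid: Grid1D) -> np.ndarray:
    """Second-order Laplacian with mirrored ghost nodes (zero flux).

    The ghost value at index -1 equals the value at index 1 (and
    symmetrically on the right), so constant fields map to zero exactly
    and the discrete operator is symmetric w.r.t. the trapezoidal inner
    product.
    """
    v = np.asarray(values, float)
    if v.shape[-1] != grid.n:
        raise ParameterError("field length does not match grid")
    if grid.n < 3:
        raise ParameterError("Laplacian needs at least 3 nodes")
    out = np.empty_like(v)
    out[..., 1:-1] = v[..., 2:] - 2.0 * v[..., 1:-1] + v[..., :-2]
    out[..., 0] = 2.0 * (v[..., 1] - v[..., 0])
    out[..., -1] = 2.0 * (v[..., -2] - v[..., -1])
    return out / grid.dx**2


def simulate(params: ModelParams, spec: ResponseSpec, grid: Grid1D,
             init: FieldPair, t_end: float, *,
             rtol: float = 1e-8, atol: float = 1e-11,
             save_every: float = 1.0, method: str = "LSODA",
             meta: Optional[dict] = None) -> Trajectory:
    """Method-of-lines integration of the reaction-diffusion system.

    The 2n-dimensional state interleaves (N_i, P_i) per node so the
    discrete Jacobian is banded with bandwidth 2, which the stiff solver
    exploits.  Saved snapshots are clamped: values in [-1e-10, 0) are set
    to 0; anything below -1e-10 aborts with a hint to tighten solver
    tolerances (masking a genuine instability would defeat the
    nonnegativity theory being verified).
    """
    if not (t_end > 0):
        raise ParameterError("t_end must be positive")
    if init.N.shape != (grid.n,):
        raise ParameterError("initial fields do not match the grid")
    if np.any(init.N < 0) or np.any(init.P < 0):
        raise DomainError("initial fields must be nonnegative")

    dx2 = grid.dx**2
    e, K, a, b = params.eps, params.K, params.a, params.b
    g, d = params.gamma, params.delta
    D1, D2 = params.D1, params.D2
    phi = spec.phi

    def rhs(t, y):
        N = y[0::2]
        P = y[1::2]
        lapN = np.empty_like(N)
        lapN[1:-1] = N[2:] - 2.0 * N[1:-1] + N[:-2]
        lapN[0] = 2.0 * (N[1] - N[0])
        lapN[-1] = 2.0 * (N[-2] - N[-1])
        lapP = np.empty_like(P)
        lapP[1:-1] = P[2:] - 2.0 * P[1:-1] + P[:-2]
        lapP[0] = 2.0 * (P[1] - P[0])
        lapP[-1] = 2.0 * (P[-2] - P[-1])
        ph = phi(N)
        out = np.empty_like(y)
        out[0::2] = D1 * lapN / dx2 + e * (1.0 - N / K) * N - a * ph * P
        out[1::2] = D2 * lapP / dx2 - (g + d * P) / (1.0 + P) * P + b * ph * P
        return out

    y0 = np.empty(2 * grid.n)
    y0[0::2] = init.N
    y0[1::2] = init.P
    t_eval = np.arange(0.0, t_end + 0.5 * save_every, save_every)
    t_eval = t_eval[t_eval <= t_end]
    if t_eval[-1] < t_end:
        t_eval = np.append(t_eval, t_end)

    kw = dict(method=method, rtol=rtol, atol=atol, t_eval=t_eval)
    if method in ("LSODA",):
        kw.update(lband=2, uband=2)
    sol = solve_ivp(rhs, (0.0, float(t_end)), y0, **kw)
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else 0.0
        raise SimulationError(
            f"PDE solver failed at t={last_t:g}: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        bad = np.nonzero(~np.all(np.isfinite(sol.y), axis=0))[0]
        raise SimulationError(
            f"non-finite values detected; last valid saved time "
            f"t={sol.t[bad[0] - 1] if bad[0] else 0.0:g}")

    N = sol.y[0::2].T.copy()
    P = sol.y[1::2].T.copy()
    worst = min(N.min(), P.min())
    if worst < -CLAMP_FLOOR:
        raise SimulationError(
            f"field dropped to {worst:.3g} < -{CLAMP_FLOOR:g}; "
            "tighten rtol/atol (nonnegativity violated beyond solver noise)")
    np.clip(N, 0.0, None, out=N)
    np.clip(P, 0.0, None, out=P)

    m = dict(meta or {})
    m.setdefault("solver", dict(method=method, rtol=rtol, atol=atol))
    return Trajectory(times=sol.t.copy(), N=N, P=P, grid=grid,
                      params=params, meta=m)


def predator_bound_M0(params: ModelParams, spec: ResponseSpec) -> float:
    """The dissipativity bound M0 = eps (K+1) / (a phi(K+1)).

    Together with K for the prey it defines an absorbing box: every
    nonnegative solution eventually satisfies
    limsup max_x N <= K and limsup max_x P <= M0.
    """
    return params.eps * (params.K + 1.0) / (
        params.a * float(spec.phi(params.K + 1.0)))


def dissipativity_check(traj: Trajectory, params: ModelParams,
                        spec: ResponseSpec, tol: float = 1e-3,
                        window: float = 0.2) -> DissipativityVerdict:
    """Verify the trajectory tail lies inside the absorbing box."""
    mask = traj.tail_mask(window)
    M0 = predator_bound_M0(params, spec)
    tmN = float(traj.N[mask].max())
    tmP = float(traj.P[mask].max())
    return DissipativityVerdict(
        M0=M0, tail_max_N=tmN, tail_max_P=tmP,
        holds_N=tmN <= params.K + tol, holds_P=tmP <= M0 + tol, tol=tol)


def persistence_margins(traj: Trajectory,
                        window: float = 0.2) -> Tuple[float, float, float, float]:
    """Empirical persistence bounds (q, Q, w, W) over the tail window.

    q/Q bound the prey field from below/above, w/W the predator field,
    minima and maxima taken over all nodes and tail times.  In a
    permanent regime all four are strictly positive; these margins feed
    the global-stability condition checker.
    """
    mask = traj.tail_mask(window)
    return (float(traj.N[mask].min()), float(traj.N[mask].max()),
            float(traj.P[mask].min()), float(traj.P[mask].max()))


def regime_check(params: ModelParams, spec: ResponseSpec) -> RegimeVerdict:
    """Extinction/permanence verdict from the sign of b phi(K) - gamma.

    The system is permanent (both species persist uniformly, for any
    diffusion coefficients) iff b phi(K) > gamma; otherwise the
    prey-only state (K, 0) attracts all nonnegative initial data and the
    predator dies out.  The boundary case b phi(K) = gamma belongs to
    the extinction branch.
    """
    margin = -params.gamma + params.b * float(spec.phi(params.K))
    return RegimeVerdict(
        regime="permanent" if margin > 0 else "extinction",
        margin=float(margin))
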