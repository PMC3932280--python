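"""The nonspatial (reduced ODE) predator-prey model.

The reaction part of the model is

    dN/dt = eps (1 - N/K) N - a phi(N) P
    dP/dt = -M(P) P + b phi(N) P

with logistic prey growth, general functional response ``phi`` (see
:mod:`.responses`) and a density-dependent predator mortality

    M(P) = (gamma + delta P) / (1 + P),

which rises from ``gamma`` at low predator density towards the maximal
mortality ``delta`` (0 < gamma < delta).  This module provides the
right-hand side, the prey nullcline, equilibrium location and
classification, and stiff ODE integration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .exceptions import DomainError, ParameterError, SimulationError
from .responses import ResponseSpec

__all__ = [
    "ModelParams",
    "Equilibrium",
    "mortality",
    "mortality_prime",
    "prey_nullcline_f",
    "prey_nullcline_fprime",
    "ode_rhs",
    "find_equilibria",
    "jacobian",
    "classify",
    "integrate_ode",
]

#: |trace| or |det| below this is treated as numerically zero (nonhyperbolic)
NONHYPERBOLIC_TOL = 1e-12

#: residual threshold above which jacobian() warns the point is not an equilibrium
EQUILIBRIUM_RESIDUAL_WARN = 1e-8


@dataclass(frozen=True)
class ModelParams:
    """The eight scalar model coefficients.

    eps    prey intrinsic growth rate (1/time)
    K      prey carrying capacity (density)
    a      predation (capture) coefficient
    b      conversion coefficient (prey consumed -> predators produced)
    gamma  predator mortality at low predator density (1/time)
    delta  maximal predator mortality (1/time); gamma < delta
    D1,D2  diffusion coefficients of prey and predator (length^2/time)

    Pass ``validate=False`` to bypass the sign constraints (e.g. to study
    the predation-free limit a = 0).
    """

    eps: float
    K: float
    a: float
    b: float
    gamma: float
    delta: float
    D1: float = 0.0
    D2: float = 0.0
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self):
        if not self.validate:
            return
        for nm in ("eps", "K", "a", "b"):
            if not (getattr(self, nm) > 0):
                raise ParameterError(f"{nm} must be positive, got {getattr(self, nm)}")
        if self.D1 < 0 or self.D2 < 0:
            raise ParameterError("diffusion coefficients must be nonnegative")
        if not (0 < self.gamma < self.delta):
            raise ParameterError(
                f"mortality must satisfy 0 < gamma < delta, got "
                f"gamma={self.gamma}, delta={self.delta}")


@dataclass
class Equilibrium:
    """A steady state of the reduced ODE with its linearisation."""

    N0: float
    P0: float
    label: str  # "E1" (origin), "E2" (prey-only), "E3" (coexistence)
    jac: Optional[np.ndarray] = None
    trace: Optional[float] = None
    det: Optional[float] = None
    eigenvalues: Optional[Tuple[complex, complex]] = None
    classification: Optional[str] = None
    prop1_certificate: bool = False
    residual: float = 0.0

    @property
    def point(self) -> Tuple[float, float]:
        return (self.N0, self.P0)

    @property
    def stable(self) -> Optional[bool]:
        if self.classification is None or self.classification == "nonhyperbolic":
            return None
        return self.classification.startswith("stable")


def mortality(P, params: ModelParams):
    """Predator per-capita mortality M(P) = (gamma + delta P)/(1 + P).

    Increases monotonically from gamma at P=0 towards delta as P grows,
    so gamma <= M(P) < delta for all P >= 0.
    """
    P = np.asarray(P, float)
    if np.any(P < 0):
        raise DomainError("predator density must be nonnegative")
    out = (params.gamma + params.delta * P) / (1.0 + P)
    return out if out.ndim else float(out)


def mortality_prime(P, params: ModelParams):
    """M'(P) = (delta - gamma)/(1 + P)^2 > 0."""
    P = np.asarray(P, float)
    if np.any(P < 0):
        raise DomainError("predator density must be nonnegative")
    out = (params.delta - params.gamma) / (1.0 + P) ** 2
    return out if out.ndim else float(out)


def prey_nullcline_f(N, params: ModelParams, spec: ResponseSpec):
    """Prey nullcline f(N) = eps (1 - N/K) N / (a phi(N)).

    On the nullcline dN/dt = a phi(N) (f(N) - P) vanishes.  At N = 0 the
    removable singularity is filled with the limit eps / (a phi'(0)) when
    phi'(0) > 0.  f(K) = 0.
    """
    scalar = np.ndim(N) == 0
    N = np.atleast_1d(np.asarray(N, float))
    if np.any(N < 0):
        raise DomainError("prey density must be nonnegative")
    out = np.empty_like(N)
    zero = N == 0.0
    if np.any(zero):
        d0 = float(spec.dphi(0.0))
        if d0 <= 0:
            raise DomainError(
                "f(0) limit eps/(a*phi'(0)) undefined: phi'(0) <= 0")
        out[zero] = params.eps / (params.a * d0)
    pos = ~zero
    if np.any(pos):
        ph = np.asarray(spec.phi(N[pos]), float)
        if np.any(ph <= 0):
            raise DomainError("phi(N) must be positive for N > 0 on the nullcline")
        out[pos] = params.eps * (1.0 - N[pos] / params.K) * N[pos] / (params.a * ph)
    return float(out[0]) if scalar else out


def prey_nullcline_fprime(N, params: ModelParams, spec: ResponseSpec):
    """Derivative f'(N) of the prey nullcline, by the quotient rule.

    f' = [eps (1 - 2N/K) phi(N) - eps (1 - N/K) N phi'(N)] / (a phi(N)^2).
    """
    scalar = np.ndim(N) == 0
    N = np.atleast_1d(np.asarray(N, float))
    ph = np.asarray(spec.phi(N), float)
    dph = np.asarray(spec.dphi(N), float)
    if np.any(ph <= 0):
        raise DomainError("f'(N) requires phi(N) > 0")
    e, K, a = params.eps, params.K, params.a
    num = e * (1.0 - 2.0 * N / K) * ph - e * (1.0 - N / K) * N * dph
    out = num / (a * ph**2)
    return float(out[0]) if scalar else out


def ode_rhs(N, P, params: ModelParams, spec: ResponseSpec):
    """Reaction terms (dN/dt, dP/dt) of the reduced system."""
    N = np.asarray(N, float)
    P = np.asarray(P, float)
    if np.any(N < 0) or np.any(P < 0):
        raise DomainError("densities must be nonnegative")
    ph = np.asarray(spec.phi(N), float)
    dN = params.eps * (1.0 - N / params.K) * N - params.a * ph * P
    dP = -mortality(P, params) * P + params.b * ph * P
    if dN.ndim:
        return dN, dP
    return float(dN), float(dP)


def _interior_g(N, params: ModelParams, spec: ResponseSpec):
    """g(N) = b phi(N) - M(f(N)); interior equilibria are its roots in (0,K)."""
    f = prey_nullcline_f(N, params, spec)
    return params.b * np.asarray(spec.phi(N), float) - mortality(f, params)


def find_equilibria(params: ModelParams, spec: ResponseSpec,
                    scan_n: int = 10_000) -> List[Equilibrium]:
    """All equilibria of the reduced system, classified.

    E1 = (0, 0) and E2 = (K, 0) always exist.  Interior (coexistence)
    equilibria are intersections of the prey nullcline P = f(N) with the
    predator nullcline M(P) = b phi(N); their N-coordinates are roots of
    g(N) = b phi(N) - M(f(N)) on (0, K), located by a uniform sign-change
    scan refined with Brent's method.  When b phi(K) <= gamma no interior
    equilibrium exists (the predator cannot persist); hump-shaped
    responses can produce several, all of which are returned sorted by N0.
    """
    eqs = [Equilibrium(0.0, 0.0, "E1"), Equilibrium(float(params.K), 0.0, "E2")]

    eps_N = 1e-9 * params.K
    Ns = np.linspace(eps_N, params.K - eps_N, int(scan_n))
    g = _interior_g(Ns, params, spec)
    sign = np.sign(g)
    roots: List[float] = []
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        r = brentq(lambda N: float(_interior_g(N, params, spec)),
                   Ns[i], Ns[i + 1], xtol=1e-15, rtol=8.9e-16)
        roots.append(float(r))
    # exact grid zeros (rare): accept them directly
    for i in np.nonzero(g == 0.0)[0]:
        roots.append(float(Ns[i]))
    for N0 in sorted(set(roots)):
        P0 = float(prey_nullcline_f(N0, params, spec))
        if P0 <= 0:
            continue
        eqs.append(Equilibrium(N0, P0, "E3"))

    out = []
    for eq in eqs:
        res = ode_rhs(eq.N0, eq.P0, params, spec)
        eq.residual = max(abs(res[0]), abs(res[1]))
        eq.jac = jacobian(eq.point, params, spec, _label=eq.label)
        eq = classify(eq, params)
        out.append(eq)
    return out


def jacobian(point: Tuple[float, float], params: ModelParams,
             spec: ResponseSpec, _label: Optional[str] = None) -> np.ndarray:
    """Jacobian of the reduced system at an equilibrium.

    Boundary equilibria get their closed-form (triangular) matrices:
    diag(eps, -gamma) at the origin and, at (K, 0), an upper-triangular
    matrix with diagonal (-eps, -gamma + b phi(K)).  At interior points
    the entries are

        J11 = a phi(N0) f'(N0),      J12 = -a phi(N0),
        J21 = b P0 phi'(N0),         J22 = -P0 M'(P0),

    with f' the analytic derivative of the prey nullcline.
    """
    N0, P0 = float(point[0]), float(point[1])
    res = ode_rhs(max(N0, 0.0), max(P0, 0.0), params, spec)
    if max(abs(res[0]), abs(res[1])) > EQUILIBRIUM_RESIDUAL_WARN:
        warnings.warn(
            f"jacobian evaluated at non-equilibrium point ({N0}, {P0}); "
            f"residual {max(abs(res[0]), abs(res[1])):.3g}", stacklevel=2)

    label = _label
    if label is None:
        if N0 == 0.0 and P0 == 0.0:
            label = "E1"
        elif P0 == 0.0 and abs(N0 - params.K) <= 1e-12 * params.K:
            label = "E2"
        else:
            label = "E3"

    if label == "E1":
        return np.array([[params.eps, 0.0], [0.0, -params.gamma]])
    if label == "E2":
        phK = float(spec.phi(params.K))
        return np.array([[-params.eps, -params.a * phK],
                         [0.0, -params.gamma + params.b * phK]])

    ph = float(spec.phi(N0))
    dph = float(spec.dphi(N0))
    fprime = float(prey_nullcline_fprime(N0, params, spec))
    return np.array([
        [params.a * ph * fprime, -params.a * ph],
        [params.b * P0 * dph, -P0 * mortality_prime(P0, params)],
    ])


def classify(eq: Equilibrium, params: ModelParams) -> Equilibrium:
    """Fill trace/det/eigenvalues and the topological classification.

    Saddle when det < 0; otherwise the sign of the trace decides
    stability and the discriminant node vs spiral.  |trace| or |det|
    below 1e-12 yields "nonhyperbolic" (no stability claim).  When the
    equilibrium is interior with N0 in [K/2, K] the coexistence state is
    provably locally stable (the nullcline slope f'(N0) <= 0 there); the
    certificate flag records this and is cross-checked against the
    numerical classification.
    """
    if eq.jac is None:
        raise ParameterError("classify requires eq.jac to be computed")
    J = np.asarray(eq.jac, float)
    tr = float(np.trace(J))
    det = float(np.linalg.det(J))
    eig = np.linalg.eigvals(J)
    eq.trace, eq.det = tr, det
    eq.eigenvalues = (complex(eig[0]), complex(eig[1]))

    if abs(det) < NONHYPERBOLIC_TOL or (det > 0 and abs(tr) < NONHYPERBOLIC_TOL):
        eq.classification = "nonhyperbolic"
    elif det < 0:
        eq.classification = "saddle"
    else:
        disc = tr * tr - 4.0 * det
        kind = "node" if disc >= 0 else "spiral"
        eq.classification = ("stable-" if tr < 0 else "unstable-") + kind

    eq.prop1_certificate = (
        eq.label == "E3" and params.K / 2.0 <= eq.N0 <= params.K)
    if eq.prop1_certificate and eq.classification not in (
            "stable-node", "stable-spiral", "nonhyperbolic"):
        raise RuntimeError(
            f"coexistence equilibrium with N0={eq.N0} in [K/2, K] classified "
            f"as {eq.classification}; this contradicts the stability "
            "guarantee and indicates a numerical defect")
    return eq


def integrate_ode(params: ModelParams, spec: ResponseSpec,
                  init: Tuple[float, float], t_end: float, *,
                  rtol: float = 1e-9, atol: float = 1e-12,
                  method: str = "LSODA",
                  t_eval: Optional[Sequence[float]] = None,
                  save_every: float = 1.0) -> pd.DataFrame:
    """Integrate the reduced ODE from ``init`` up to ``t_end``.

    Uses an adaptive stiff solver at tight tolerances (the Lyapunov
    diagnostics downstream need a smoothly decreasing energy).  Returns a
    DataFrame with columns ``t, N, P``.
    """
    if not (t_end > 0):
        raise ParameterError("t_end must be positive")
    N0, P0 = float(init[0]), float(init[1])
    if N0 < 0 or P0 < 0:
        raise DomainError("initial densities must be nonnegative")

    def rhs(t, y):
        N = max(y[0], 0.0)
        P = max(y[1], 0.0)
        return ode_rhs(N, P, params, spec)

    if t_eval is None:
        t_eval = np.arange(0.0, t_end + 0.5 * save_every, save_every)
        t_eval = t_eval[t_eval <= t_end]
        if t_eval[-1] < t_end:
            t_eval = np.append(t_eval, t_end)
    sol = solve_ivp(rhs, (0.0, float(t_end)), [N0, P0], method=method,
                    rtol=rtol, atol=atol, t_eval=np.asarray(t_eval, float))
    if not sol.success:
        raise SimulationError(f"ODE solver failed: {sol.message}")
    N = np.clip(sol.y[0], 0.0, None)
    P = np.clip(sol.y[1], 0.0, None)
    return pd.DataFrame({"t": sol.t, "N": N, "P": P})
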