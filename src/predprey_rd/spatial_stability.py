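"""Linearised stability over Neumann modes and the no-pattern certificate.

Linearising the reaction-diffusion system about a homogeneous steady
state U0 and expanding in the eigenfunctions of -d^2/dx^2 with no-flux
boundary conditions (eigenvalues lambda_j = (j pi / l)^2 on an interval
of length l) decouples the dynamics into 2x2 mode systems

    ds_j/dt = B_j s_j,     B_j = A - lambda_j diag(D1, D2),

with A the reaction Jacobian.  U0 is linearly stable iff every B_j is
Hurwitz.  Only finitely many modes can destabilise: beyond an analytic
cutoff both the trace and determinant conditions hold automatically.
A diffusion-driven (Turing) instability corresponds to det B < 0 on an
interval of lambda while A itself is stable; under the sign pattern of
the coexistence equilibrium with N0 in [K/2, K] this cannot happen.

The module also evaluates a sufficient condition excluding nonconstant
positive steady states ("patterns") outright: when gamma < b phi(K) <
delta, every positive steady state obeys the a-priori bounds
max N <= K, max P <= K0 = (b phi(K) - gamma)/(delta - b phi(K)), and if

    mu1 D1 > eps + a L / 2 + (a + b/2) K0 H,
    mu1 D2 > -gamma + b L + a L / 2 + (b/2) K0 H,

with mu1 the smallest positive Neumann eigenvalue, then no nonconstant
positive steady state exists.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .exceptions import ParameterError
from .model_core import Equilibrium, ModelParams
from .responses import ResponseSpec

__all__ = [
    "ModeReport",
    "StabilityReport",
    "NonexistenceVerdict",
    "neumann_spectrum",
    "linearized_matrix",
    "mode_cutoff",
    "homogeneous_stability",
    "turing_scan",
    "nonexistence_check",
]

NONHYPERBOLIC_TOL = 1e-12


@dataclass(frozen=True)
class ModeReport:
    """Stability data for a single spatial mode."""

    j: Optional[int]
    lam: float
    B: np.ndarray
    trace: float
    det: float
    eigenvalues: Tuple[complex, complex]
    stable: bool


@dataclass(frozen=True)
class StabilityReport:
    """Mode-wise linear stability of a homogeneous steady state."""

    modes: Tuple[ModeReport, ...]
    stable: Optional[bool]  # None when some mode is nonhyperbolic
    cutoff: float
    prop12_certificate: bool  # True when N0 in [K/2, K]
    length: float


@dataclass(frozen=True)
class NonexistenceVerdict:
    """Certificate excluding nonconstant positive steady states."""

    K0: float
    mu1: float
    threshold_D1: float
    threshold_D2: float
    applicable: bool  # gamma < b phi(K) < delta
    holds: bool
    bound_N: float  # a-priori bound max N <= K
    bound_P: float  # a-priori bound max P <= K0


def neumann_spectrum(length: float, j_max: int) -> np.ndarray:
    """Eigenvalues lambda_j = (j pi / length)^2, j = 0..j_max."""
    if not (length > 0):
        raise ParameterError("length must be positive")
    if j_max < 1:
        raise ParameterError("j_max must be >= 1")
    j = np.arange(j_max + 1)
    return (j * math.pi / length) ** 2


def linearized_matrix(A: np.ndarray, lam: float, D1: float, D2: float,
                      j: Optional[int] = None) -> ModeReport:
    """Mode matrix B = A - lambda diag(D1, D2) with its spectrum."""
    if lam < 0:
        raise ParameterError("lambda must be nonnegative")
    A = np.asarray(A, float)
    B = A - lam * np.diag([D1, D2])
    tr = float(np.trace(B))
    det = float(np.linalg.det(B))
    eig = np.linalg.eigvals(B)
    return ModeReport(j=j, lam=float(lam), B=B, trace=tr, det=det,
                      eigenvalues=(complex(eig[0]), complex(eig[1])),
                      stable=bool(max(eig.real) < 0.0))


def _det_coeffs(A: np.ndarray, D1: float, D2: float):
    """det B(lambda) = c2 lambda^2 + c1 lambda + c0."""
    c2 = D1 * D2
    c1 = -(A[0, 0] * D2 + A[1, 1] * D1)
    c0 = float(np.linalg.det(A))
    return c2, c1, c0


def mode_cutoff(A: np.ndarray, D1: float, D2: float) -> float:
    """Analytic lambda beyond which every mode is stable.

    trace B(lambda) = trace A - lambda (D1 + D2) is negative for all
    lambda > trace(A)/(D1+D2); det B(lambda) is an upward parabola in
    lambda when D1 D2 > 0, so it is positive beyond its largest real
    root.  The cutoff is the max of the two with a 10% margin.  For
    D1 D2 = 0 the determinant is affine in lambda and its root (if the
    slope is positive) is used instead; if the determinant can only
    decrease, infinity is returned (some mode is eventually unstable).
    """
    A = np.asarray(A, float)
    cands = [0.0]
    trA = float(np.trace(A))
    if D1 + D2 > 0:
        if trA > 0:
            cands.append(trA / (D1 + D2))
    elif trA >= 0:
        return math.inf if trA > 0 else 0.0
    c2, c1, c0 = _det_coeffs(A, D1, D2)
    if c2 > 0:
        disc = c1 * c1 - 4.0 * c2 * c0
        if disc >= 0:
            cands.append((-c1 + math.sqrt(disc)) / (2.0 * c2))
    elif c1 > 0:
        if c0 < 0:
            cands.append(-c0 / c1)
    elif c1 < 0:
        return math.inf  # det B decreases without bound: instability at large lambda
    else:
        if c0 <= 0:
            return math.inf
    return 1.1 * max(cands)


def homogeneous_stability(params: ModelParams, spec: ResponseSpec,
                          eq: Equilibrium, length: float) -> StabilityReport:
    """Mode-by-mode linear stability of an interior homogeneous state.

    Scans every Neumann mode with lambda_j up to the analytic cutoff
    (beyond which stability is automatic); overall verdict is the
    conjunction.  When N0 lies in [K/2, K] stability is guaranteed for
    every diffusion pair -- the scan is cross-checked against that
    certificate.  Degenerate diffusion (D1 D2 = 0) falls back to a fixed
    scan up to lambda = 1e4 / length^2.
    """
    if eq.label != "E3":
        raise ParameterError("homogeneous_stability requires an interior equilibrium")
    if eq.jac is None:
        raise ParameterError("equilibrium must carry its Jacobian")
    A = np.asarray(eq.jac, float)
    D1, D2 = params.D1, params.D2

    cut = mode_cutoff(A, D1, D2)
    if not math.isfinite(cut):
        cut = 1e4 / length**2
    if D1 * D2 == 0.0 and (D1 + D2) > 0.0:
        cut = max(cut, 1e4 / length**2)

    j_max = int(math.ceil(math.sqrt(cut) * length / math.pi)) if cut > 0 else 0
    lams = neumann_spectrum(length, max(j_max, 1))
    if D1 == D2 == 0.0:
        lams = lams[:1]  # diffusion-free: every mode sees the same matrix A
    modes = tuple(linearized_matrix(A, lam, D1, D2, j=j)
                  for j, lam in enumerate(lams))

    stable: Optional[bool] = all(m.stable for m in modes)
    if any(abs(m.det) < NONHYPERBOLIC_TOL for m in modes):
        stable = None  # nonhyperbolic mode: inconclusive

    cert = params.K / 2.0 <= eq.N0 <= params.K
    if cert and stable is False:
        raise RuntimeError(
            "mode scan found an unstable mode although N0 in [K/2, K] "
            "guarantees stability; numerical defect")
    return StabilityReport(modes=modes, stable=stable, cutoff=cut,
                           prop12_certificate=cert, length=float(length))


def turing_scan(A: np.ndarray, D1: float, D2: float,
                lambda_grid: Optional[Sequence[float]] = None
                ) -> Optional[Tuple[float, float]]:
    """Interval of lambda with det(A - lambda D) < 0, if any.

    A diffusion-driven instability of an ODE-stable state requires
    det B(lambda) < 0 on a window of lambda.  The determinant is scanned
    on a logarithmic grid (default 1e4 points in [1e-3, 1e3]) and window
    edges are refined by root bracketing.  Returns ``None`` when no
    window exists -- in particular under the stable coexistence sign
    pattern (A11, A22, A12 < 0, A21 > 0) or when D1 = D2 = 0.
    """
    A = np.asarray(A, float)
    eigA = np.linalg.eigvals(A)
    if max(eigA.real) >= 0:
        warnings.warn("turing_scan called with an ODE-unstable matrix",
                      stacklevel=2)
    if D1 == 0.0 and D2 == 0.0:
        return None
    if lambda_grid is None:
        lambda_grid = np.logspace(-3.0, 3.0, 10_000)
    lams = np.asarray(lambda_grid, float)
    c2, c1, c0 = _det_coeffs(A, D1, D2)
    det = c2 * lams**2 + c1 * lams + c0
    neg = det < 0.0
    if not neg.any():
        return None

    def detf(lam):
        return c2 * lam * lam + c1 * lam + c0

    i0 = int(np.argmax(neg))
    i1 = len(neg) - 1 - int(np.argmax(neg[::-1]))
    lo = (brentq(detf, lams[i0 - 1], lams[i0]) if i0 > 0 and det[i0 - 1] > 0
          else float(lams[i0]))
    hi = (brentq(detf, lams[i1], lams[i1 + 1])
          if i1 + 1 < len(lams) and det[i1 + 1] > 0 else float(lams[i1]))
    return (float(lo), float(hi))


def nonexistence_check(params: ModelParams, spec: ResponseSpec,
                       length: float) -> NonexistenceVerdict:
    """Evaluate the diffusion-threshold certificate excluding patterns.

    Applicable when gamma < b phi(K) < delta.  Then K0 = (b phi(K) -
    gamma)/(delta - b phi(K)) bounds every positive steady-state
    predator field, and the two threshold inequalities on mu1 D1 and
    mu1 D2 (with mu1 = (pi/length)^2, the continuum value) certify that
    only constant positive steady states exist.  Outside the
    applicability window the verdict is void (holds = False).
    """
    if not (length > 0):
        raise ParameterError("length must be positive")
    mu1 = (math.pi / length) ** 2
    bphiK = params.b * float(spec.phi(params.K))
    applicable = params.gamma < bphiK < params.delta
    if applicable:
        K0 = (bphiK - params.gamma) / (params.delta - bphiK)
    else:
        K0 = math.nan
    L, H = spec.L, spec.H
    if applicable:
        th1 = params.eps + params.a * L / 2.0 + (params.a + params.b / 2.0) * K0 * H
        th2 = (-params.gamma + params.b * L + params.a * L / 2.0
               + (params.b / 2.0) * K0 * H)
        holds = (mu1 * params.D1 > th1) and (mu1 * params.D2 > th2)
    else:
        th1 = th2 = math.nan
        holds = False
    return NonexistenceVerdict(
        K0=K0, mu1=mu1, threshold_D1=th1, threshold_D2=th2,
        applicable=applicable, holds=holds,
        bound_N=float(params.K), bound_P=K0)
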