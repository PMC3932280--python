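"""Functional responses and their structural hypotheses.

A functional response ``phi(N)`` gives the per-predator prey consumption
rate as a function of prey density N.  The dynamical theory implemented in
this package applies to any response satisfying five structural hypotheses:

(i)    phi is C^1 with phi(0) = 0;
(ii)   N -> phi(N)/N is decreasing on (0, inf) and bounded by a constant
       ``Mtilde``;
(iii)  phi is bounded: 0 <= phi(N) <= L;
(iv)   the derivative is bounded: |phi'(N)| <= H;
(v)    phi is increasing on [0, l] with the carrying capacity K < l.

Holling type II (saturating, monotone) and the simplified Holling type IV
(hump-shaped, nonmonotone) responses satisfy all five with closed-form
constants; arbitrary user responses are certified numerically on a grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .exceptions import DomainError, HypothesisError, ParameterError

__all__ = [
    "ResponseSpec",
    "HypothesisReport",
    "holling1",
    "holling2",
    "holling4",
    "generic_response",
    "response_from_expression",
    "verify_hypotheses",
]

#: safety inflation applied to grid-estimated suprema (they are lower bounds
#: of the true suprema; the inflation makes them usable as certified bounds)
GRID_SAFETY = 1.01

#: relative tolerance for the central-difference C^1 check on generic specs
C1_RTOL = 1e-4


@dataclass(frozen=True)
class ResponseSpec:
    """A functional response with its derivative and hypothesis constants.

    Attributes
    ----------
    name:
        Text label (used in configs and reports).
    phi, dphi:
        The response and its derivative, vectorised over numpy arrays.
    Mtilde:
        Upper bound for phi(N)/N (per-unit-density consumption).
    L:
        Upper bound for phi (saturation level).
    H:
        Upper bound for |phi'|.
    l:
        Right end of the interval on which phi is increasing;
        ``math.inf`` for globally increasing responses.
    closed_form:
        True when the constants are analytic, False when grid-estimated.
    nonsmooth_points:
        Grid points where the supplied derivative disagrees with a
        central-difference estimate (kinks); empty for C^1 responses.
    """

    name: str
    phi: Callable[[np.ndarray], np.ndarray]
    dphi: Callable[[np.ndarray], np.ndarray]
    Mtilde: float
    L: float
    H: float
    l: float
    closed_form: bool = True
    nonsmooth_points: tuple = field(default_factory=tuple)

    def __call__(self, N):
        return self.phi(N)


@dataclass(frozen=True)
class HypothesisReport:
    """Outcome of checking hypotheses (i)-(v) for a (response, K) pair."""

    h1: bool
    h2: bool
    h3: bool
    h4: bool
    h5: bool
    witnesses: dict
    constants_used: tuple  # (Mtilde, L, H, l)
    K_tested: float

    @property
    def all_satisfied(self) -> bool:
        return self.h1 and self.h2 and self.h3 and self.h4 and self.h5

    def __bool__(self) -> bool:  # convenience: ``if report: ...``
        return self.all_satisfied


def _as_array_fn(f):
    """Wrap a scalar callable so it maps arrays elementwise via numpy."""

    def wrapped(N):
        arr = np.asarray(N, dtype=float)
        out = np.asarray(f(arr), dtype=float)
        return out if np.ndim(N) else float(out)

    return wrapped


def holling2(beta: float) -> ResponseSpec:
    """Holling type II (Michaelis-Menten) response ``phi(N) = N/(beta+N)``.

    Saturating and monotone increasing; constants are analytic:
    Mtilde = H = 1/beta (both attained at N=0), L = 1 (the horizontal
    asymptote), and phi is increasing everywhere (l = +inf).
    """
    if not (beta > 0):
        raise ParameterError(f"holling2 requires beta > 0, got {beta}")
    b = float(beta)
    return ResponseSpec(
        name=f"holling2(beta={b:g})",
        phi=lambda N: np.asarray(N, float) / (b + np.asarray(N, float)),
        dphi=lambda N: b / (b + np.asarray(N, float)) ** 2,
        Mtilde=1.0 / b,
        L=1.0,
        H=1.0 / b,
        l=math.inf,
    )


def holling4(beta: float) -> ResponseSpec:
    """Simplified Holling type IV response ``phi(N) = N/(beta+N^2)``.

    Hump-shaped: increases up to N = sqrt(beta) where it peaks at
    1/(2 sqrt(beta)), then decreases (prey-interference / group defence).
    Constants: Mtilde = 1/beta, L = 1/(2 sqrt(beta)), H = 1/beta
    (|phi'| is largest at N = 0), l = sqrt(beta).
    """
    if not (beta > 0):
        raise ParameterError(f"holling4 requires beta > 0, got {beta}")
    b = float(beta)

    def phi(N):
        N = np.asarray(N, float)
        return N / (b + N**2)

    def dphi(N):
        N = np.asarray(N, float)
        return (b - N**2) / (b + N**2) ** 2

    return ResponseSpec(
        name=f"holling4(beta={b:g})",
        phi=phi,
        dphi=dphi,
        Mtilde=1.0 / b,
        L=1.0 / (2.0 * math.sqrt(b)),
        H=1.0 / b,
        l=math.sqrt(b),
    )


def holling1(slope: float, saturation: float, *, N_max: Optional[float] = None,
             grid_n: int = 100_001) -> ResponseSpec:
    """Piecewise-linear (Holling type I) response.

    ``phi(N) = slope * N`` for ``N <= saturation/slope`` and
    ``phi(N) = saturation`` beyond.  The kink makes it fail the C^1
    hypothesis; the spec is built through the numeric certification path so
    the nondifferentiable point is detected and recorded.
    """
    if not (slope > 0 and saturation > 0):
        raise ParameterError("holling1 requires positive slope and saturation")
    knee = saturation / slope

    def phi(N):
        N = np.asarray(N, float)
        return np.minimum(slope * N, saturation)

    def dphi(N):
        N = np.asarray(N, float)
        return np.where(N < knee, slope, 0.0)

    spec = generic_response(phi, dphi, N_max=N_max or 10.0 * knee, grid_n=grid_n)
    return ResponseSpec(
        name=f"holling1(slope={slope:g}, saturation={saturation:g})",
        phi=spec.phi,
        dphi=spec.dphi,
        Mtilde=spec.Mtilde,
        L=spec.L,
        H=spec.H,
        l=spec.l,
        closed_form=False,
        nonsmooth_points=spec.nonsmooth_points,
    )


def generic_response(phi: Callable, dphi: Optional[Callable] = None, *,
                     N_max: float = 1e3, grid_n: int = 100_000,
                     name: str = "generic") -> ResponseSpec:
    """Build a :class:`ResponseSpec` for a user response by grid estimation.

    The hypothesis constants Mtilde, L, H are suprema over [0, N_max]
    estimated on a uniform grid of ``grid_n`` points and inflated by 1%;
    ``l`` is the largest grid point up to which phi is nondecreasing.
    Closed-form responses give these constants exactly -- the grid estimate
    is the finite surrogate for everything else.

    Points where the supplied derivative disagrees with a central
    difference (relative tolerance 1e-4) are recorded as kinks; the
    hypothesis checker uses them to fail the C^1 test.

    Parameters
    ----------
    phi:
        The response, callable on arrays over [0, N_max].
    dphi:
        Its derivative; when omitted, a central-difference estimate on the
        grid is used (and no kink detection is possible).
    """
    if grid_n < 1_000:
        raise ParameterError(f"grid_n must be >= 1000, got {grid_n}")
    if not (N_max > 0):
        raise ParameterError(f"N_max must be positive, got {N_max}")

    phi_v = _as_array_fn(phi)
    grid = np.linspace(0.0, float(N_max), int(grid_n))
    vals = np.asarray(phi_v(grid), float)
    if not np.all(np.isfinite(vals)):
        raise DomainError("phi produced non-finite values on the sampling grid")
    if abs(float(vals[0])) > 1e-14:
        raise HypothesisError(f"phi(0) must be 0, got {vals[0]!r}")
    if np.max(vals) <= 0.0:
        raise HypothesisError(
            "degenerate response: phi vanishes identically, Mtilde undefined")

    h = grid[1] - grid[0]
    fd = np.gradient(vals, h)
    nonsmooth: tuple = ()
    if dphi is not None:
        dphi_v = _as_array_fn(dphi)
        dvals = np.asarray(dphi_v(grid), float)
        if not np.all(np.isfinite(dvals)):
            raise DomainError("dphi produced non-finite values on the grid")
        # interior central differences; O(h^2) accurate away from kinks
        cd = (vals[2:] - vals[:-2]) / (2.0 * h)
        scale = np.maximum(np.abs(dvals[1:-1]), np.max(np.abs(dvals)))
        # tolerance has an O(h) floor: the FD error near a smooth extremum
        # is h^2 * |phi'''|, but we only certify to C1_RTOL relative
        bad = np.abs(cd - dvals[1:-1]) > np.maximum(C1_RTOL * scale, 10.0 * h)
        nonsmooth = tuple(grid[1:-1][bad])
    else:
        dvals = fd

    Mtilde = float(np.max(vals[1:] / grid[1:])) * GRID_SAFETY
    L = float(np.max(vals)) * GRID_SAFETY
    H = float(np.max(np.abs(dvals))) * GRID_SAFETY

    # l: largest grid point up to which phi is nondecreasing
    dec = np.nonzero(np.diff(vals) < -1e-14 * max(1.0, L))[0]
    l = math.inf if dec.size == 0 else float(grid[dec[0]])

    dphi_final = _as_array_fn(dphi) if dphi is not None else (
        lambda N: np.interp(np.asarray(N, float), grid, fd))
    return ResponseSpec(
        name=name,
        phi=phi_v,
        dphi=dphi_final,
        Mtilde=Mtilde,
        L=L,
        H=H,
        l=l,
        closed_form=False,
        nonsmooth_points=nonsmooth,
    )


def response_from_expression(expr: str, *, N_max: float = 1e3,
                             grid_n: int = 100_000) -> ResponseSpec:
    """Build a response from an arithmetic expression in the variable ``N``.

    The expression is parsed symbolically (no attribute access, no function
    calls outside a whitelist of elementary functions), differentiated
    exactly, and then certified through :func:`generic_response`.
    """
    import re

    import sympy

    # character whitelist before parsing: arithmetic, names, parentheses
    if not re.fullmatch(r"[0-9a-zA-Z_+\-*/(). ^]*", expr) or "__" in expr:
        raise ParameterError(
            f"response expression {expr!r} contains forbidden characters")

    N = sympy.Symbol("N", nonnegative=True)
    allowed = {
        "N": N,
        "exp": sympy.exp, "log": sympy.log, "sqrt": sympy.sqrt,
        "sin": sympy.sin, "cos": sympy.cos, "tanh": sympy.tanh,
        "pi": sympy.pi, "E": sympy.E, "Min": sympy.Min, "Max": sympy.Max,
    }
    try:
        sym = sympy.sympify(expr, locals=allowed, evaluate=True)
    except (sympy.SympifyError, SyntaxError, TypeError) as exc:
        raise ParameterError(f"cannot parse response expression {expr!r}: {exc}")
    if not isinstance(sym, sympy.Expr):
        raise ParameterError(f"{expr!r} is not an arithmetic expression")
    bad = sym.free_symbols - {N}
    if bad:
        raise ParameterError(f"unknown symbols in response expression: {bad}")
    unknown_fns = {f.func.__name__ for f in sym.atoms(sympy.Function)
                   if f.func.__name__ not in allowed}
    if unknown_fns:
        raise ParameterError(
            f"unknown functions in response expression: {unknown_fns}")
    dsym = sympy.diff(sym, N)
    phi = sympy.lambdify(N, sym, modules="numpy")
    dphi = sympy.lambdify(N, dsym, modules="numpy")
    return generic_response(phi, dphi, N_max=N_max, grid_n=grid_n,
                            name=f"expr:{expr}")


def verify_hypotheses(spec: ResponseSpec, K: float,
                      grid_n: int = 100_000) -> HypothesisReport:
    """Check hypotheses (i)-(v) for ``spec`` against carrying capacity ``K``.

    All checks are numeric, on a uniform grid over
    ``[0, max(10 K, 10 l)]`` (the factor-10 extension probes behaviour well
    beyond the dynamically relevant range).  Violations are reported with a
    witness point, never raised.  Hypothesis (v) requires strict ``K < l``.
    """
    if not (K > 0):
        raise ParameterError(f"K must be positive, got {K}")

    upper = 10.0 * K
    if math.isfinite(spec.l):
        upper = max(upper, 10.0 * spec.l)
    grid = np.linspace(0.0, upper, int(grid_n))
    vals = np.asarray(spec.phi(grid), float)
    dvals = np.asarray(spec.dphi(grid), float)
    witnesses: dict = {}

    # (i) C^1 with phi(0) = 0
    h1 = abs(float(vals[0])) <= 1e-14 and len(spec.nonsmooth_points) == 0
    if not h1:
        witnesses["h1"] = (float(spec.nonsmooth_points[0])
                           if spec.nonsmooth_points else 0.0)

    # (ii) phi(N)/N nonincreasing and bounded by Mtilde
    ratio = vals[1:] / grid[1:]
    tol2 = 1e-12 * max(1.0, spec.Mtilde)
    increasing = np.nonzero(np.diff(ratio) > tol2)[0]
    above = np.nonzero(ratio > spec.Mtilde * (1.0 + 1e-9) + 1e-15)[0]
    h2 = increasing.size == 0 and above.size == 0
    if not h2:
        idx = increasing[0] + 1 if increasing.size else above[0] + 1
        witnesses["h2"] = float(grid[idx])

    # (iii) 0 <= phi <= L
    tol3 = 1e-9 * max(1.0, spec.L)
    bad3 = np.nonzero((vals < -tol3) | (vals > spec.L + tol3))[0]
    h3 = bad3.size == 0
    if not h3:
        witnesses["h3"] = float(grid[bad3[0]])

    # (iv) |phi'| <= H
    tol4 = 1e-9 * max(1.0, spec.H)
    bad4 = np.nonzero(np.abs(dvals) > spec.H + tol4)[0]
    h4 = bad4.size == 0
    if not h4:
        witnesses["h4"] = float(grid[bad4[0]])

    # (v) phi increasing on [0, l] with K < l (strict)
    h5 = K < spec.l
    if h5 and math.isfinite(spec.l):
        on = grid <= spec.l
        dec = np.nonzero(np.diff(vals[on]) < -1e-12 * max(1.0, spec.L))[0]
        if dec.size:
            h5 = False
            witnesses["h5"] = float(grid[dec[0]])
    elif not h5:
        witnesses["h5"] = float(K)

    return HypothesisReport(
        h1=h1, h2=h2, h3=h3, h4=h4, h5=h5,
        witnesses=witnesses,
        constants_used=(spec.Mtilde, spec.L, spec.H, spec.l),
        K_tested=float(K),
    )
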