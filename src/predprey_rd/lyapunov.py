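"""Lyapunov-energy diagnostics for global stability of coexistence.

For an interior equilibrium (N0, P0), the energy functional

    E(t) = Integral_0^l [ N - N0 - N0 ln(N/N0)
                        + P - P0 - P0 ln(P/P0) ] dx

is nonnegative and vanishes exactly at the equilibrium.  Along
solutions of the reaction-diffusion system it decreases whenever two
algebraic conditions on the model constants and on a-priori solution
bounds (q <= N <= Q, w <= P <= W in the tail) hold, certifying global
asymptotic stability of the coexistence state.  The printed form of
those conditions is typographically ambiguous in its source; the
checker therefore evaluates a documented default reading (parse "A"),
keeps the alternative reading selectable, and always pairs the symbolic
verdict with a direct empirical energy-descent test, which is treated
as the authoritative diagnostic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .exceptions import DomainError, ParameterError
from .model_core import Equilibrium, ModelParams, find_equilibria
from .rd_sim import FieldPair, Grid1D, Trajectory, persistence_margins, regime_check
from .responses import ResponseSpec

__all__ = [
    "LyapunovSeries",
    "GlobalStabilityVerdict",
    "energy_E",
    "energy_series",
    "condition60_check",
    "global_stability_verdict",
]

#: dE/dt <= SLOPE_TOL_FACTOR * max(E) counts as nonincreasing
SLOPE_TOL_FACTOR = 1e-8


@dataclass
class LyapunovSeries:
    """Energy along a trajectory with descent statistics."""

    times: np.ndarray
    E_values: np.ndarray
    dE_estimates: np.ndarray
    monotone_fraction: float
    truncated: bool = False  # True when positivity failed mid-trajectory


@dataclass
class GlobalStabilityVerdict:
    """Symbolic + empirical global-stability report."""

    bounds: Tuple[float, float, float, float]  # (q, Q, w, W)
    condition_parse: str
    cond1_value: float
    cond2_value: float
    symbolic_holds: Optional[bool]  # None when the symbolic branch is refused
    empirical_holds: Optional[bool] = None
    refusal_reason: Optional[str] = None

    @property
    def combined(self) -> str:
        sym = {True: "symbolic+", False: "symbolic-", None: "symbolic?"}
        emp = {True: "empirical+", False: "empirical-", None: "empirical?"}
        return f"{sym[self.symbolic_holds]} {emp[self.empirical_holds]}"


def energy_E(fields: FieldPair, eq: Equilibrium, grid: Grid1D) -> float:
    """Energy of a field pair relative to an interior equilibrium.

    Trapezoidal quadrature of the pointwise integrand
    x - x0 - x0 ln(x/x0) (applied to both species), which is strictly
    convex with minimum 0 at x = x0; hence E >= 0 with equality iff the
    fields equal the equilibrium everywhere.
    """
    if eq.label != "E3" or eq.N0 <= 0 or eq.P0 <= 0:
        raise ParameterError("energy requires an interior equilibrium")
    N, P = fields.N, fields.P
    if np.any(N <= 0) or np.any(P <= 0):
        raise DomainError("energy undefined for nonpositive field values")
    integrand = (N - eq.N0 - eq.N0 * np.log(N / eq.N0)
                 + P - eq.P0 - eq.P0 * np.log(P / eq.P0))
    return float(grid.quad_weights @ integrand)


def energy_series(traj: Trajectory, eq: Equilibrium,
                  slope_tol_factor: float = SLOPE_TOL_FACTOR) -> LyapunovSeries:
    """Energy at every saved time, with finite-difference descent check.

    The series is truncated (with a warning) at the first snapshot
    containing a nonpositive value -- e.g. once the predator crosses the
    positivity floor in an extinction run, where the logarithm is
    undefined.  ``monotone_fraction`` is the fraction of steps whose
    slope is below ``slope_tol_factor * max(E)`` (absorbing quadrature
    noise).  The energy column is also attached to the trajectory.
    """
    n_ok = len(traj.times)
    for i in range(len(traj.times)):
        if np.any(traj.N[i] <= 0) or np.any(traj.P[i] <= 0):
            n_ok = i
            warnings.warn(
                f"energy series truncated at t={traj.times[i]:g}: "
                "nonpositive field value (logarithm undefined)", stacklevel=2)
            break
    if n_ok < 2:
        raise DomainError("fewer than two saved times with positive fields")

    times = traj.times[:n_ok]
    E = np.array([energy_E(traj.snapshot(i), eq, traj.grid)
                  for i in range(n_ok)])
    dE = np.gradient(E, times)
    steps = np.diff(E) / np.diff(times)
    tol = slope_tol_factor * float(E.max())
    frac = float(np.mean(steps <= tol)) if steps.size else 1.0
    traj.energy = np.concatenate([E, np.full(len(traj.times) - n_ok, np.nan)])
    return LyapunovSeries(times=times, E_values=E, dE_estimates=dE,
                          monotone_fraction=frac,
                          truncated=n_ok < len(traj.times))


def condition60_check(params: ModelParams, spec: ResponseSpec,
                      eq: Equilibrium,
                      bounds: Tuple[float, float, float, float],
                      parse: str = "A") -> GlobalStabilityVerdict:
    """Evaluate the two algebraic global-stability conditions.

    With (q, Q, w, W) the tail bounds on prey and predator, parse "A"
    reads the conditions as

        cond1 = (q + N0) eps / (K Q) - eps q - a Mtilde/2 - b P0 H/(2 w)
        cond2 = gamma / W - b L w - b P0 H/(2 w) - a Mtilde/2

    and requires both to be positive.  Parse "B" replaces the first
    fraction by (q + N0) eps Q / K (the other defensible reading of the
    same collapsed expression).  The verdict records which parse was
    used; neither is asserted as uniquely correct, and the empirical
    energy-descent test is the authoritative companion diagnostic.
    """
    q, Q, w, W = map(float, bounds)
    if not (q > 0 and w > 0 and Q >= q and W >= w):
        raise ParameterError(
            f"bounds must satisfy 0 < q <= Q and 0 < w <= W, got {bounds}")
    if eq.label != "E3":
        raise ParameterError("condition check requires an interior equilibrium")
    e, K, a, b, g = params.eps, params.K, params.a, params.b, params.gamma
    Mt, L, H = spec.Mtilde, spec.L, spec.H
    N0, P0 = eq.N0, eq.P0

    if parse == "A":
        lead = (q + N0) * e / (K * Q)
    elif parse == "B":
        lead = (q + N0) * e * Q / K
    else:
        raise ParameterError(f"unknown condition parse {parse!r}")
    cond1 = lead - e * q - a * Mt / 2.0 - b * P0 * H / (2.0 * w)
    cond2 = g / W - b * L * w - b * P0 * H / (2.0 * w) - a * Mt / 2.0
    return GlobalStabilityVerdict(
        bounds=(q, Q, w, W), condition_parse=parse,
        cond1_value=float(cond1), cond2_value=float(cond2),
        symbolic_holds=bool(cond1 > 0 and cond2 > 0))


def global_stability_verdict(params: ModelParams, spec: ResponseSpec,
                             eq: Equilibrium, traj: Trajectory, *,
                             parse: str = "A",
                             safety: float = 0.1) -> GlobalStabilityVerdict:
    """Combine the symbolic condition check with empirical energy descent.

    Bounds (q, Q, w, W) come from :func:`persistence_margins` with a
    safety margin (lower bounds deflated, upper bounds inflated by 10%).
    The empirical verdict requires a near-monotone energy
    (monotone_fraction >= 0.99), terminal spatial variance < 1e-8 in
    both fields, and a terminal state within 1e-2 of the equilibrium.
    The symbolic branch is refused when the interior equilibrium is not
    unique (the underlying theory presumes uniqueness).
    """
    if regime_check(params, spec).regime != "permanent":
        raise ParameterError(
            "global stability analysis requires the permanent regime")
    interior = [e for e in find_equilibria(params, spec) if e.label == "E3"]

    q, Q, w, W = persistence_margins(traj)
    bounds = ((1.0 - safety) * q, (1.0 + safety) * Q,
              (1.0 - safety) * w, (1.0 + safety) * W)

    if len(interior) != 1:
        verdict = GlobalStabilityVerdict(
            bounds=bounds, condition_parse=parse,
            cond1_value=math.nan, cond2_value=math.nan,
            symbolic_holds=None,
            refusal_reason=(f"{len(interior)} interior equilibria; the "
                            "symbolic certificate presumes uniqueness"))
    else:
        verdict = condition60_check(params, spec, eq, bounds, parse=parse)

    series = energy_series(traj, eq)
    term_var = max(float(traj.N[-1].var()), float(traj.P[-1].var()))
    term_dist = max(abs(float(traj.N[-1].mean()) - eq.N0),
                    abs(float(traj.P[-1].mean()) - eq.P0))
    verdict.empirical_holds = bool(
        series.monotone_fraction >= 0.99
        and not series.truncated
        and term_var < 1e-8
        and term_dist < 1e-2)
    return verdict
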