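"""Preset parameter regimes and synthetic initial data.

Each preset realises the hypotheses of one of the dynamical theorems on
a concrete parameter set, so the whole theory can be exercised
end-to-end: a locally/globally stable coexistence state, predator
extinction, permanence under both monotone and hump-shaped responses,
the no-pattern diffusion certificate, and a deliberate hypothesis
violation.  Initial data are smooth seeded cosine perturbations, which
satisfy the no-flux boundary conditions exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Dict, Optional, Tuple

import numpy as np

from .exceptions import ParameterError
from .model_core import ModelParams
from .rd_sim import FieldPair, Grid1D
from .responses import ResponseSpec, holling2, holling4, verify_hypotheses

__all__ = ["Scenario", "preset", "preset_names", "random_init"]

#: number of cosine modes used by the initial-data generator
INIT_MODES = 5


@dataclass(frozen=True)
class Scenario:
    """A named, fully resolved experiment configuration."""

    name: str
    params: ModelParams
    response: ResponseSpec
    grid: Grid1D
    init_base: Tuple[float, float]
    init_amplitude: float
    init_seed: int
    t_end: float
    expected_regime: str  # "permanent" | "extinction"
    hypotheses_ok: bool = True  # False for deliberately violating presets

    def make_init(self, seed: Optional[int] = None) -> FieldPair:
        return random_init(self.grid, self.init_seed if seed is None else seed,
                           self.init_base, self.init_amplitude)


def _mk(name, *, gamma, delta, D1=0.1, D2=0.1, response=None, K=2.0,
        base=(1.0, 1.0), expected="permanent", hyp_ok=True, amplitude=0.5):
    return Scenario(
        name=name,
        params=ModelParams(eps=1.0, K=K, a=1.0, b=1.0, gamma=gamma,
                           delta=delta, D1=D1, D2=D2),
        response=response if response is not None else holling2(1.0),
        grid=Grid1D(length=math.pi, n=201),
        init_base=base,
        init_amplitude=amplitude,
        init_seed=0,
        t_end=500.0,
        expected_regime=expected,
        hypotheses_ok=hyp_ok,
    )


def _build_presets() -> Dict[str, Scenario]:
    return {
        # coexistence equilibrium at exactly (1, 1); N0 in [K/2, K] so the
        # local-stability certificate applies for any diffusion
        "clean_stable": _mk("clean_stable", gamma=0.4, delta=0.6),
        # b phi(K) = 2/3 < gamma: the predator cannot persist
        "extinction": _mk("extinction", gamma=0.9, delta=1.2,
                          expected="extinction"),
        # permanence with a saturating (monotone) response
        "permanent_h2": _mk("permanent_h2", gamma=0.5, delta=0.7),
        # permanence with a hump-shaped response; K=2 < l=3 keeps the
        # monotone-range hypothesis satisfied
        "permanent_h4": _mk("permanent_h4", gamma=0.1, delta=0.2,
                            response=holling4(9.0)),
        # diffusion strong enough for the no-pattern certificate:
        # thresholds are 4.5 and 2.1 on a domain of length pi (mu1 = 1)
        "nonexistence_cert": _mk("nonexistence_cert", gamma=0.4, delta=0.8,
                                 D1=5.0, D2=3.0),
        # K=3 exceeds the increasing range l=2 of holling4(4):
        # the monotone-range hypothesis fails by construction
        "hypothesis_fail_h4": _mk("hypothesis_fail_h4", gamma=0.1, delta=0.2,
                                  K=3.0, response=holling4(4.0),
                                  hyp_ok=False),
    }


_PRESETS = _build_presets()


def preset_names() -> Tuple[str, ...]:
    return tuple(_PRESETS)


def preset(name: str) -> Scenario:
    """Look up a preset scenario by name."""
    try:
        sc = _PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; valid presets: {', '.join(_PRESETS)}")
    report = verify_hypotheses(sc.response, sc.params.K, grid_n=20_000)
    if report.all_satisfied != sc.hypotheses_ok:
        raise RuntimeError(
            f"preset {name!r} hypothesis status {report.all_satisfied} "
            f"contradicts its declaration {sc.hypotheses_ok}")
    return sc


def random_init(grid: Grid1D, seed: int, base: Tuple[float, float],
                amplitude: float) -> FieldPair:
    """Seeded smooth positive perturbation of constant base densities.

    Each field is ``base * (1 + amplitude * s(x))`` where s is a random
    combination of cosine modes 1..5 (zero slope at both ends, hence
    Neumann-compatible) normalised so |s| < 1 deterministically.  With
    amplitude < 1 the fields are strictly positive; amplitude 0 gives
    constant fields.  Identical seeds give identical fields.
    """
    if not (0.0 <= amplitude < 1.0):
        raise ParameterError(
            f"amplitude must lie in [0, 1) to keep fields positive, "
            f"got {amplitude}")
    bN, bP = float(base[0]), float(base[1])
    if bN <= 0 or bP <= 0:
        raise ParameterError("base densities must be strictly positive")
    rng = np.random.default_rng(seed)
    x = grid.x
    fields = []
    for b in (bN, bP):
        c = rng.uniform(-1.0, 1.0, INIT_MODES)
        total = np.abs(c).sum()
        # strictness factor keeps |s| < 1 even if all modes align at x=0
        c *= amplitude * (1.0 - 1e-9) / max(total, 1e-300)
        s = np.zeros_like(x)
        for j in range(1, INIT_MODES + 1):
            s += c[j - 1] * np.cos(j * math.pi * x / grid.length)
        fields.append(b * (1.0 + s))
    return FieldPair(fields[0], fields[1])
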