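"""Temperature-pressure phase diagrams of a two-polymorph system.

With fixed (athermal) volumes, the free-energy difference between two
polymorphs is affine in pressure at each temperature:

    Delta F(T, p) = Delta F(T, 0) + p * Delta V * conv

so the coexistence boundary p*(T) — the locus where Delta F = 0 — has a
closed-form root at every temperature where Delta F changes sign over the
pressure window.  A generic bisection fallback exists for future models
where Delta F is not affine in p.

Free-energy differences smaller in magnitude than a configurable threshold
(default 0.1 kJ/mol per formula, a typical uncertainty of harmonic DFT
rankings) are flagged in an "uncertain" mask: within that band the
predicted ranking should not be trusted.

The module also encodes the experimentally constructed topological
boundary for the acetaminophen form I / form II system,
p(MPa) = -0.3182 T(K) + 394.25 (Espeau et al.), for comparison, and a
Table-style helper for signed percentage errors of computed cell volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from . import units
from .mode_data import ModeSet
from .thermo import IDENTITY_SCALING, ScalingScheme, gibbs_free_energy

__all__ = [
    "PhaseDiagram",
    "UNCERTAINTY_THRESHOLD_KJMOL",
    "DEFAULT_T_GRID",
    "DEFAULT_P_GRID",
    "delta_f_grid",
    "extract_boundary",
    "reference_boundary",
    "volume_percent_error",
]

#: |Delta F| at or below this (kJ/mol per formula) counts as uncertain.
UNCERTAINTY_THRESHOLD_KJMOL = 0.1

#: Reference topological boundary p(MPa) = slope * T + intercept.
REFERENCE_SLOPE_MPA_PER_K = -0.3182
REFERENCE_INTERCEPT_MPA = 394.25

DEFAULT_T_GRID = np.arange(0.0, 400.0 + 2.5, 5.0)      # K, endpoints inclusive
DEFAULT_P_GRID = np.arange(0.0, 1000.0 + 5.0, 10.0)    # MPa


@dataclass
class PhaseDiagram:
    """Delta F(T, p) = F_a - F_b per formula on a regular grid.

    ``boundary`` holds (T, p*) coexistence points; ``uncertain_mask`` marks
    nodes with |Delta F| <= the uncertainty threshold.  ``delta_f0`` and
    ``delta_pv_slope`` store the affine decomposition
    Delta F(T, p) = delta_f0(T) + p * delta_pv_slope used for closed-form
    root finding.
    """

    temperatures: np.ndarray
    pressures: np.ndarray
    delta_f: np.ndarray                 # (nT, nP)
    delta_f0: np.ndarray                # (nT,), Delta F at p = 0
    delta_pv_slope: float               # kJ/mol per formula per MPa
    labels: Tuple[str, str]
    uncertainty_threshold: float = UNCERTAINTY_THRESHOLD_KJMOL
    boundary: List[Tuple[float, float]] = field(default_factory=list)

    @property
    def uncertain_mask(self) -> np.ndarray:
        return np.abs(self.delta_f) <= self.uncertainty_threshold

    def delta_f_at(self, temperature: float, pressure: float) -> float:
        """Delta F from the affine model; temperature must be a grid node."""
        idx = np.flatnonzero(np.isclose(self.temperatures, temperature))
        if idx.size != 1:
            raise ValueError(f"temperature {temperature} is not a grid node")
        return float(self.delta_f0[idx[0]] + pressure * self.delta_pv_slope)


def delta_f_grid(
    a: ModeSet,
    b: ModeSet,
    t_grid: Sequence[float] = DEFAULT_T_GRID,
    p_grid: Sequence[float] = DEFAULT_P_GRID,
    scheme_a: ScalingScheme = IDENTITY_SCALING,
    scheme_b: ScalingScheme = IDENTITY_SCALING,
    uncertainty_threshold: float = UNCERTAINTY_THRESHOLD_KJMOL,
) -> PhaseDiagram:
    """Delta F = F_a - F_b per formula at every (T, p) node.

    Exploits the affinity of F in p under constant volume: the full surface
    is the p = 0 curve plus ``p * Delta(V/z) * conv``.  The boundary is left
    unfilled; see :func:`extract_boundary`.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    p_grid = np.asarray(p_grid, dtype=float)
    fa = gibbs_free_energy(a, t_grid, pressure=0.0, scheme=scheme_a)
    fb = gibbs_free_energy(b, t_grid, pressure=0.0, scheme=scheme_b)
    delta_f0 = fa.f[:, 0] - fb.f[:, 0]
    slope = (
        fa.volume_per_formula - fb.volume_per_formula
    ) * units.KJMOL_PER_MPA_A3
    delta_f = delta_f0[:, None] + p_grid[None, :] * slope
    return PhaseDiagram(
        temperatures=t_grid,
        pressures=p_grid,
        delta_f=delta_f,
        delta_f0=delta_f0,
        delta_pv_slope=slope,
        labels=(a.cell.label, b.cell.label),
        uncertainty_threshold=uncertainty_threshold,
    )


def extract_boundary(
    pd: PhaseDiagram,
    delta_f_func: Optional[Callable[[float, float], float]] = None,
) -> List[Tuple[float, float]]:
    """Coexistence points (T, p*) with Delta F(T, p*) = 0, one per
    temperature at most.

    For the affine constant-volume model the root is closed-form and exact;
    only temperatures where Delta F changes sign across the pressure window
    yield a point.  Passing ``delta_f_func(T, p)`` switches to bisection for
    models where Delta F is not affine in p.  The boundary is stored on the
    diagram and returned.
    """
    p_lo, p_hi = float(pd.pressures[0]), float(pd.pressures[-1])
    points: List[Tuple[float, float]] = []
    for it, t in enumerate(pd.temperatures):
        if delta_f_func is not None:
            f_lo, f_hi = delta_f_func(t, p_lo), delta_f_func(t, p_hi)
        else:
            f_lo = pd.delta_f0[it] + p_lo * pd.delta_pv_slope
            f_hi = pd.delta_f0[it] + p_hi * pd.delta_pv_slope
        if f_lo == 0.0 and f_hi == 0.0:
            continue  # degenerate column: no isolated coexistence point
        if f_lo == 0.0:
            points.append((float(t), p_lo))
        elif f_hi == 0.0:
            points.append((float(t), p_hi))
        elif f_lo * f_hi < 0:
            if delta_f_func is not None:
                root = brentq(lambda p: delta_f_func(t, p), p_lo, p_hi, xtol=1e-12)
            else:
                # exact root of the affine relation
                root = -pd.delta_f0[it] / pd.delta_pv_slope
            points.append((float(t), float(root)))
    pd.boundary = points
    return points


def reference_boundary(temperature: float) -> float:
    """Experimental topological form I / form II boundary, MPa.

    Evaluates p(MPa) = -0.3182 T(K) + 394.25.  The line extrapolates
    outside the experimental window (negative pressures are returned
    as-is; callers clip to the physical window).
    """
    return REFERENCE_SLOPE_MPA_PER_K * temperature + REFERENCE_INTERCEPT_MPA


def volume_percent_error(v_dft: float, v_exp: float) -> float:
    """Signed percentage error of a computed cell volume, 100 (V - V_exp)/V_exp."""
    if v_exp <= 0:
        raise ValueError("reference volume must be positive")
    return 100.0 * (v_dft - v_exp) / v_exp
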