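"""Fold + cusp ("binary flip") landscape: normal forms, critical points, fates.

The landscape is a two-dimensional gradient-like flow built by merging the two
generic catastrophes of one- and two-parameter gradient systems:

* a **fold** (saddle-node) on the y-axis, ``f_fold(u, c) = -u^2 - c``, offset
  by ``M``, which creates/destroys the attractor representing the tertiary
  (non-vulval) fate as ``c`` crosses zero;
* a **cusp** on the invariant line ``y = 0``,
  ``f_cusp(x, a, b) = -4x^3 - 2ax - b``, whose discriminant
  ``delta = 8a^3 + 27b^2`` controls whether both vulval attractors (primary at
  x<0, secondary at x>0) exist.

The merged field is::

    x' = tau * [ H(-y) f_cusp(x, a, b) - (1 - H(-y)) x ]
    y' = tau * [ y f_fold(y - M, c) ]

with ``H`` a (possibly smoothed) unit step.  The step convention is
``H(u) = 1 for u >= 0``: the cusp branch governs ``y <= 0`` and the plain
contraction ``-x`` governs ``y > 0``.  This is the only convention under which
the critical points ``(0, M +- sqrt(-c))`` are exact equilibria of the merged
field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Fate",
    "PointKind",
    "VulvalState",
    "Stratum",
    "LandscapeParams",
    "CriticalPoint",
    "LandscapeRegion",
    "fold_rhs",
    "cusp_rhs",
    "cusp_discriminant",
    "smooth_step",
    "combined_rhs",
    "find_critical_points",
    "classify_landscape",
    "assign_fate",
]

#: default tolerance for deciding a parameter sits on a bifurcation stratum
STRATUM_TOL = 1e-9
#: default radius around an attractor at which a trajectory is declared converged
CONVERGENCE_RADIUS = 1e-3


class Fate(str, Enum):
    PRIMARY = "primary"
    SECONDARY = "secondary"
    TERTIARY = "tertiary"
    NONE = "none"
    UNASSIGNED = "unassigned"


class PointKind(str, Enum):
    ATTRACTOR = "attractor"
    SADDLE = "saddle"
    DEGENERATE = "degenerate"


class VulvalState(str, Enum):
    BISTABLE = "bistable"
    ONLY_PRIMARY = "only_primary"
    ONLY_SECONDARY = "only_secondary"
    DEGENERATE = "degenerate"


class Stratum(str, Enum):
    INTERIOR = "interior"
    ON_FOLD_LINE = "on_fold_line"
    ON_CUSP_LINE = "on_cusp_line"


def _check_finite(*vals: float) -> None:
    for v in vals:
        if not math.isfinite(v):
            raise ValueError(f"non-finite input: {v!r}")


@dataclass(frozen=True)
class LandscapeParams:
    """Control parameters of the merged landscape.

    Parameters
    ----------
    a, b : float
        Cusp unfolding and asymmetry parameters (dimensionless).
    c : float
        Fold parameter; ``c < 0`` creates the tertiary attractor pair on the
        y-axis at ``y = M +- sqrt(-c)``.
    M : float
        Vertical offset of the fold pair (phase-space units).
    tau : float
        Positive rate constant multiplying the drift (1/time).
    smoothing_width : float
        Non-negative width of the smoothed step; 0 means the sharp step.
    """

    a: float
    b: float
    c: float
    M: float
    tau: float = 1.0
    smoothing_width: float = 0.0

    def __post_init__(self) -> None:
        _check_finite(self.a, self.b, self.c, self.M, self.tau, self.smoothing_width)
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.smoothing_width < 0:
            raise ValueError("smoothing_width must be non-negative")


@dataclass(frozen=True)
class CriticalPoint:
    position: tuple[float, float]
    kind: PointKind
    fate: Fate
    eigenvalues: tuple[float, float] = field(default=(np.nan, np.nan), compare=False)


@dataclass(frozen=True)
class LandscapeRegion:
    has_tertiary: bool
    vulval_state: VulvalState
    stratum: Stratum


def fold_rhs(x: float, c: float) -> float:
    """Normal-form fold rate of change, ``-x**2 - c``."""
    _check_finite(x, c)
    return -x * x - c


def cusp_rhs(x: float, a: float, b: float) -> float:
    """Normal-form cusp rate of change, ``-4x**3 - 2ax - b``."""
    _check_finite(x, a, b)
    return -4.0 * x**3 - 2.0 * a * x - b


def cusp_discriminant(a: float, b: float) -> float:
    """Cusp discriminant ``8a^3 + 27b^2``.

    Negative: three cusp equilibria (two attractors and a saddle); zero: two
    (one degenerate); positive: a single attractor.
    """
    _check_finite(a, b)
    return 8.0 * a**3 + 27.0 * b**2


def smooth_step(u: float | np.ndarray, width: float) -> float | np.ndarray:
    """Logistic approximation of the unit step H(u); exact step at width 0."""
    if width == 0.0:
        return np.where(np.asarray(u) >= 0.0, 1.0, 0.0)[()]
    return 0.5 * (1.0 + np.tanh(np.asarray(u) / (2.0 * width)))[()]


def combined_rhs(state: Sequence[float], lp: LandscapeParams) -> tuple[float, float]:
    """Velocity ``tau * (f1, f2)`` of the merged landscape at ``state``.

    With a positive ``smoothing_width`` the step is centered ``sqrt(width)``
    above the invariant line ``y = 0``: the offset vanishes with the width
    while the step value on the line tends to 1, so the smoothed geometry
    converges to the sharp-step closed forms as the width goes to zero.
    """
    x, y = float(state[0]), float(state[1])
    _check_finite(x, y)
    w = lp.smoothing_width
    h = float(smooth_step(-(y - math.sqrt(w)) if w > 0.0 else -y, w))
    f1 = h * cusp_rhs(x, lp.a, lp.b) - (1.0 - h) * x
    f2 = y * fold_rhs(y - lp.M, lp.c)
    return lp.tau * f1, lp.tau * f2


def _cusp_roots(a: float, b: float, tol: float = 1e-9) -> list[float]:
    """Real roots of f_cusp(x, a, b) = 0, deduplicated near degeneracies."""
    roots = np.roots([-4.0, 0.0, -2.0 * a, -b])
    real = sorted(float(r.real) for r in roots if abs(r.imag) < 1e-7)
    out: list[float] = []
    for r in real:
        if not out or abs(r - out[-1]) > tol:
            out.append(r)
    return out


def _fold_branch_eig(y: float, lp: LandscapeParams) -> float:
    """d/dy [y * f_fold(y - M, c)] evaluated at y."""
    return fold_rhs(y - lp.M, lp.c) + y * (-2.0 * (y - lp.M))


def _kind_from_eigs(ex: float, ey: float, tol: float) -> PointKind:
    if abs(ex) <= tol or abs(ey) <= tol:
        return PointKind.DEGENERATE
    if ex < 0 and ey < 0:
        return PointKind.ATTRACTOR
    return PointKind.SADDLE


def find_critical_points(
    lp: LandscapeParams,
    tol: float = STRATUM_TOL,
    eig_tol: float = 1e-7,
) -> list[CriticalPoint]:
    """All critical points of the merged field (sharp-step geometry).

    With ``c < 0`` the y-axis carries the fold pair ``(0, M +- sqrt(-c))``
    (upper point: tertiary attractor; lower: the top saddle) whenever those
    lie in the ``y > 0`` region where the contraction branch ``x' = -x``
    applies.  The invariant line ``y = 0`` carries the cusp roots, with fates
    assigned by the sign of x (x < 0: primary; x > 0: secondary).  Points on
    a bifurcation stratum are returned flagged degenerate, never dropped.
    """
    pts: list[CriticalPoint] = []
    if lp.c < tol:  # includes the degenerate c ~ 0 case
        s = math.sqrt(max(-lp.c, 0.0))
        for y in (lp.M + s, lp.M - s):
            # off the cusp line the x-branch is the contraction -x (eig -1);
            # a fold point with y <= 0 is only an equilibrium if b = 0
            if y > 0.0 or abs(lp.b) <= tol:
                ex = -1.0 if y > 0.0 else -12.0 * 0.0 - 2.0 * lp.a
                ey = lp.tau * _fold_branch_eig(y, lp)
                ex *= lp.tau
                if abs(lp.c) <= tol and y == lp.M + s:
                    kind = PointKind.DEGENERATE
                else:
                    kind = _kind_from_eigs(ex, ey, eig_tol)
                fate = Fate.TERTIARY if (kind is PointKind.ATTRACTOR and y > 0) else Fate.NONE
                pts.append(CriticalPoint((0.0, y), kind, fate, (ex, ey)))
                if abs(lp.c) <= tol:
                    break  # merged pair: report once
    delta = cusp_discriminant(lp.a, lp.b)
    ey0 = lp.tau * fold_rhs(-lp.M, lp.c)  # transverse eigenvalue on y = 0
    for x in _cusp_roots(lp.a, lp.b, tol=1e-6):
        ex = lp.tau * (-12.0 * x * x - 2.0 * lp.a)
        kind = _kind_from_eigs(ex, ey0, eig_tol)
        if abs(delta) <= tol:
            # on the cusp line the repeated root is the degenerate one
            if abs(-12.0 * x * x - 2.0 * lp.a) <= 1e-6:
                kind = PointKind.DEGENERATE
        if kind is PointKind.ATTRACTOR and x < -tol:
            fate = Fate.PRIMARY
        elif kind is PointKind.ATTRACTOR and x > tol:
            fate = Fate.SECONDARY
        else:
            fate = Fate.NONE
        pts.append(CriticalPoint((x, 0.0), kind, fate, (ex, ey0)))
    return pts


def classify_landscape(
    lp: LandscapeParams | tuple[float, float, float],
    tol: float = STRATUM_TOL,
) -> LandscapeRegion:
    """Stability region of the control point (pure function of ``a, b, c``)."""
    if isinstance(lp, LandscapeParams):
        a, b, c = lp.a, lp.b, lp.c
    else:
        a, b, c = lp
    delta = cusp_discriminant(a, b)
    if abs(delta) <= tol:
        state = VulvalState.DEGENERATE
    elif delta < 0:
        state = VulvalState.BISTABLE
    elif b > tol:
        state = VulvalState.ONLY_PRIMARY
    elif b < -tol:
        state = VulvalState.ONLY_SECONDARY
    else:  # delta > 0 with b ~ 0 forces a > 0: single attractor at x = 0
        state = VulvalState.DEGENERATE
    if abs(c) <= tol:
        stratum = Stratum.ON_FOLD_LINE
    elif abs(delta) <= tol:
        stratum = Stratum.ON_CUSP_LINE
    else:
        stratum = Stratum.INTERIOR
    return LandscapeRegion(has_tertiary=c < -tol, vulval_state=state, stratum=stratum)


def assign_fate(
    state: Sequence[float],
    lp_final: LandscapeParams,
    radius: float = CONVERGENCE_RADIUS,
    dt: float | None = None,
    max_steps: int = 200_000,
) -> Fate:
    """Fate of ``state`` under the noise-free flow of ``lp_final``.

    Integrates the deterministic field until the trajectory comes within
    ``radius`` of an attractor (returning that attractor's fate) or the step
    budget is exhausted (returning :data:`Fate.UNASSIGNED`).  Equidistant or
    non-convergent trajectories are never assigned arbitrarily.
    """
    from ._kernel import relax_to_attractor  # local import: numba compile cost
    from .simulate import _relax_geometry

    attractors = [p for p in find_critical_points(lp_final) if p.kind is PointKind.ATTRACTOR]
    if not attractors:
        raise ValueError("landscape has no attractors; invalid final landscape")
    ax = np.array([p.position[0] for p in attractors])
    ay = np.array([p.position[1] for p in attractors])
    geom = _relax_geometry(lp_final.a, lp_final.b, lp_final.c, lp_final.M,
                           ax, ay, lp_final.smoothing_width)
    if dt is None:
        dt = 0.005 / lp_final.tau
    idx = relax_to_attractor(
        float(state[0]), float(state[1]),
        lp_final.a, lp_final.b, lp_final.c, lp_final.M, lp_final.tau,
        lp_final.smoothing_width, dt, max_steps, radius, ax, ay, geom,
    )
    if idx < 0:
        return Fate.UNASSIGNED
    return attractors[idx].fate
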