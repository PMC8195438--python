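"""Affine map from signal levels (theta_E, theta_N) to control parameters.

The landscape's control point ``(a, b, c)`` is an affine function of the
scaled signals::

    (a, b, c)^T = m @ (s * theta_E, l * theta_N)^T + q

with ``m`` a 3x2 matrix of entries bounded by ``|m_ij| < 1`` and ``s, l > 0``
the scalings of EGF and Notch into control space.  The image of signal space
is the plane ``pi_T: A a + B b + C c = D`` whose coefficients are the 2x2
minors of ``m``.  Composed with the landscape classification this yields the
*fate map*: the partition of the (theta_E, theta_N) quadrant by which
attractors exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape import LandscapeRegion, VulvalState, classify_landscape

__all__ = [
    "AffineSignalMap",
    "SignalLevels",
    "control_from_signals",
    "plane_coefficients",
    "fate_map_region",
    "check_map_constraints",
    "REFERENCE_PROFILES",
]

#: signal profiles that constrain the map: the zero-signal origin, the
#: Notch-null / 2x WT EGF line (two anchor cells) and the Notch-null / WT EGF
#: line.  WT EGF saturates at theta_E = 1 on the competence clock.
REFERENCE_PROFILES: dict[str, tuple[float, float]] = {
    "origin": (0.0, 0.0),
    "notch_null_2x_egf": (2.0, 0.0),
    "notch_null_wt_egf": (1.0, 0.0),
}


@dataclass(frozen=True)
class SignalLevels:
    theta_E: float
    theta_N: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta_E) and np.isfinite(self.theta_N)):
            raise ValueError("signal levels must be finite")
        if self.theta_E < 0 or self.theta_N < 0:
            raise ValueError("signal levels must be non-negative")


@dataclass(frozen=True)
class AffineSignalMap:
    """3x2 matrix ``m``, offset ``q`` and signal scalings ``s, l``."""

    m: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    q: tuple[float, float, float]
    s: float
    l: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.m, dtype=float)
        if arr.shape != (2, 3) and arr.shape != (3, 2):
            raise ValueError("m must be a 3x2 matrix")
        if arr.shape == (2, 3):
            raise ValueError("m must be 3x2 (rows a, b, c; columns EGF, Notch)")
        if np.any(np.abs(arr) >= 1.0):
            raise ValueError("all |m_ij| must be < 1")
        if self.s <= 0 or self.l <= 0:
            raise ValueError("scalings s and l must be positive")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.m, dtype=float)

    @property
    def offset(self) -> np.ndarray:
        return np.asarray(self.q, dtype=float)


def _as_signals(sig: SignalLevels | tuple[float, float]) -> SignalLevels:
    if isinstance(sig, SignalLevels):
        return sig
    return SignalLevels(*sig)


def control_from_signals(
    smap: AffineSignalMap, sig: SignalLevels | tuple[float, float]
) -> tuple[float, float, float]:
    """Control parameters ``(a, b, c)`` for a signal profile."""
    sig = _as_signals(sig)
    v = np.array([smap.s * sig.theta_E, smap.l * sig.theta_N])
    a, b, c = smap.matrix @ v + smap.offset
    return float(a), float(b), float(c)


def plane_coefficients(smap: AffineSignalMap) -> tuple[float, float, float, float]:
    """Coefficients (A, B, C, D) of the image plane ``Aa + Bb + Cc = D``.

    (A, B, C) are the 2x2 minors of ``m`` (a normal of its column space) and
    ``D = A q1 + B q2 + C q3`` anchors the plane at the offset, so every
    control point produced by :func:`control_from_signals` satisfies the
    equation identically.
    """
    (m11, m12), (m21, m22), (m31, m32) = smap.m
    A = m31 * m22 - m21 * m32
    B = m11 * m32 - m31 * m12
    C = m12 * m21 - m11 * m22
    q1, q2, q3 = smap.q
    D = A * q1 + B * q2 + C * q3
    return A, B, C, D


def fate_map_region(
    smap: AffineSignalMap, sig: SignalLevels | tuple[float, float]
) -> LandscapeRegion:
    """Stability region of the landscape at a point of the fate map."""
    return classify_landscape(control_from_signals(smap, sig))


def is_tristable(region: LandscapeRegion) -> bool:
    return region.has_tertiary and region.vulval_state is VulvalState.BISTABLE


def check_map_constraints(
    smap: AffineSignalMap,
    M: float | None = None,
    reference_profiles: dict[str, tuple[float, float]] | None = None,
    signal_range: tuple[float, float] = (3.0, 3.0),
    grid: int = 7,
) -> tuple[bool, list[str]]:
    """Constraints the map must satisfy to describe vulval patterning.

    (i) the zero-signal origin is tristable (all three fates coexist; with
    ``M`` given, additionally the fold pair sits above the cusp line,
    ``M > sqrt(-c)``, so the tertiary basin is well formed);
    (ii) increasing signals can exit the tristable region;
    (iii) the Notch-null / 2x WT EGF profile lies outside the tristable
    region; (iv) so does the Notch-null / WT EGF profile.

    Returns ``(passed, violations)``.  Used as the indicator factor of the
    ABC prior.
    """
    profiles = dict(REFERENCE_PROFILES)
    if reference_profiles:
        profiles.update(reference_profiles)
    violations: list[str] = []

    origin = fate_map_region(smap, profiles["origin"])
    if not is_tristable(origin):
        violations.append("origin is not tristable")
    elif M is not None:
        _, _, c0 = control_from_signals(smap, profiles["origin"])
        if M <= np.sqrt(-c0):
            violations.append("fold pair not above the cusp line at the origin (M <= sqrt(-c))")

    if is_tristable(fate_map_region(smap, profiles["notch_null_2x_egf"])):
        violations.append("Notch-null / 2x WT EGF profile is tristable")
    if is_tristable(fate_map_region(smap, profiles["notch_null_wt_egf"])):
        violations.append("Notch-null / WT EGF profile is tristable")

    te = np.linspace(0.0, signal_range[0], grid)
    tn = np.linspace(0.0, signal_range[1], grid)
    if all(is_tristable(fate_map_region(smap, (e, n))) for e in te for n in tn):
        violations.append("signals never drive the system out of the tristable region")

    return (not violations), violations
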