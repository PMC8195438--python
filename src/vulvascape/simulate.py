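"""Stochastic simulation of the three coupled VPCs and outcome estimation.

Cells start at the zero-signal tertiary attractor ``(0, M + sqrt(-q3))``,
evolve by Euler-Maruyama under the signal-dependent landscape over the
competence window ``t in [0, t_end]``, and are then assigned a fate by
noise-free relaxation under the zero-signal landscape: the attractor reached
defines the fate, and trajectories that reach none within budget (or blow
up) are *unassigned* -- an outcome the fitting distance penalizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernel
from .landscape import Fate, LandscapeParams, PointKind, find_critical_points
from .manifest import vector_to_map, vector_to_signaling
from .signal_map import control_from_signals
from .signaling import CELLS, ExperimentalCondition, egf_level, notch_received

__all__ = [
    "OutcomeTable",
    "SimulationSettings",
    "em_step",
    "simulate_lineage",
    "simulate_trajectory",
    "estimate_outcome",
    "simulate_pulse_protocol",
]

FATE_CODES = {0: Fate.UNASSIGNED, 1: Fate.PRIMARY, 2: Fate.SECONDARY, 3: Fate.TERTIARY}
#: default smoothing width of the step function used during SDE integration
SDE_SMOOTHING = 1e-3


@dataclass(frozen=True)
class SimulationSettings:
    """Numerical settings of the simulator.

    ``dt`` is the Euler-Maruyama step on the competence clock (normalized to
    ``t_end = 1``); ``relax_steps`` bounds the noise-free fate relaxation;
    ``radius`` is the attractor convergence radius.
    """

    dt: float = 1e-3
    t_end: float = 1.0
    relax_steps: int = 3000  # at twice the SDE step: a 6-unit horizon
    radius: float = 1e-3
    smoothing_width: float = SDE_SMOOTHING

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")


@dataclass(frozen=True)
class OutcomeTable:
    """Simulated fate proportions per cell for one condition."""

    condition_id: str
    proportions: np.ndarray  # (3 cells, 4): p1, p2, p3, p_unassigned
    n_reps: int
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.proportions,
            index=list(CELLS),
            columns=["p1", "p2", "p3", "p_unassigned"],
        )

    def proportion(self, cell: str, fate: Fate) -> float:
        col = {Fate.PRIMARY: 0, Fate.SECONDARY: 1, Fate.TERTIARY: 2, Fate.UNASSIGNED: 3}[fate]
        return float(self.proportions[CELLS.index(cell), col])


def _pack_condition(cond: ExperimentalCondition) -> np.ndarray:
    if isinstance(cond.notch_receptor_factor, str) or isinstance(cond.notch_ectopic, str):
        raise ValueError(f"{cond.id}: unresolved modifiers; call .resolve() first")
    packed = np.zeros(7)
    packed[0] = cond.egf_multiplier
    packed[1] = cond.notch_receptor_factor
    packed[2] = cond.notch_ectopic
    packed[3] = np.inf if cond.ablation_time is None else cond.ablation_time
    for i, cell in enumerate(CELLS):
        packed[4 + i] = 1.0 if cell in cond.egf_mosaic_cells else 0.0
    return packed


def _relax_geometry(a: float, b: float, c: float, M: float,
                    ax: np.ndarray, ay: np.ndarray,
                    smoothing_width: float) -> np.ndarray:
    """Basin-structure summary enabling exact early fate calls in the kernel.

    Layout: [fold flag, y_saddle, tertiary idx, cusp root count, x_saddle,
    left idx, right idx, zone height].  The zone height is where the
    smoothed step argument reaches -6 (step saturated: 1-D cusp flow); the
    fold/zone exits are enabled only when the top saddle sits above the
    zone, so the y-flow below it is monotonically downward.
    """
    geom = np.zeros(8)
    w = smoothing_width
    zone = (np.sqrt(w) - 12.0 * w) if w > 0.0 else 0.0
    geom[7] = zone
    y_saddle = M - np.sqrt(-c) if c < 0 else np.inf
    descending_below = (c >= 0) or (y_saddle > zone)
    if c < 0 and y_saddle > zone:
        tert = [j for j in range(len(ax)) if ax[j] == 0.0 and ay[j] > 0.0]
        if tert:
            geom[0] = 1.0
            geom[1] = y_saddle
            geom[2] = tert[0]
    if descending_below:
        roots = np.sort(np.array(_cusp_roots_cached(a, b)))
        on_line = [j for j in range(len(ax)) if ay[j] == 0.0]
        if len(roots) == 3 and len(on_line) == 2:
            geom[3] = 3.0
            geom[4] = roots[1]
            left = min(on_line, key=lambda j: ax[j])
            right = max(on_line, key=lambda j: ax[j])
            geom[5] = left
            geom[6] = right
        elif len(roots) == 1 and len(on_line) == 1:
            geom[3] = 1.0
            geom[6] = on_line[0]
    return geom


def _cusp_roots_cached(a: float, b: float) -> list[float]:
    from .landscape import _cusp_roots

    return _cusp_roots(a, b)


def _zero_signal_attractors(theta: np.ndarray, smoothing_width: float = SDE_SMOOTHING):
    """Attractors and relaxation geometry of the zero-signal landscape."""
    t = np.asarray(theta, dtype=float)
    lp = LandscapeParams(a=t[7], b=t[8], c=t[9], M=t[10], tau=t[0])
    pts = [p for p in find_critical_points(lp) if p.kind is PointKind.ATTRACTOR]
    if not pts:
        raise ValueError("zero-signal landscape has no attractors")
    ax = np.array([p.position[0] for p in pts])
    ay = np.array([p.position[1] for p in pts])
    code = {Fate.PRIMARY: 1, Fate.SECONDARY: 2, Fate.TERTIARY: 3, Fate.NONE: 0}
    afate = np.array([code[p.fate] for p in pts], dtype=np.int8)
    geom = _relax_geometry(t[7], t[8], t[9], t[10], ax, ay, smoothing_width)
    return ax, ay, afate, geom


def em_step(
    states: np.ndarray,
    t: float,
    theta: np.ndarray,
    cond: ExperimentalCondition,
    dt: float,
    rng: np.random.Generator,
    smoothing_width: float = SDE_SMOOTHING,
    n1_sign: int = -1,
) -> np.ndarray:
    """One Euler-Maruyama step of the coupled three-cell system.

    Reference implementation in plain Python mirroring the compiled kernel;
    ``states`` is a (3, 2) array of cell states, returned advanced to
    ``t + dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    theta = np.asarray(theta, dtype=float)
    smap = vector_to_map(theta)
    sp = vector_to_signaling(theta, n1_sign=n1_sign)
    tau, M = theta[0], theta[10]
    out = np.array(states, dtype=float)
    noise = rng.standard_normal((3, 2))
    for i, cell in enumerate(CELLS):
        te = egf_level(cell, t, sp, cond)
        tn = notch_received(cell, states, sp, cond, t)
        a, b, c = control_from_signals(smap, (te, tn))
        lp = LandscapeParams(a=a, b=b, c=c, M=M, tau=tau, smoothing_width=smoothing_width)
        from .landscape import combined_rhs

        f1, f2 = combined_rhs(states[i], lp)
        out[i, 0] = states[i][0] + f1 * dt + sp.sigma_dif * np.sqrt(dt) * noise[i, 0]
        out[i, 1] = states[i][1] + f2 * dt + sp.sigma_dif * np.sqrt(dt) * noise[i, 1]
    return out


def simulate_lineage(
    cond: ExperimentalCondition,
    theta: np.ndarray,
    seed: int = 0,
    settings: SimulationSettings | None = None,
    n1_sign: int = -1,
) -> dict[str, Fate]:
    """One stochastic realization; returns the fate of each cell."""
    out = estimate_outcome(cond, theta, n_reps=1, seed=seed, settings=settings,
                           n1_sign=n1_sign, _return_codes=True)
    return {cell: FATE_CODES[int(out[0, i])] for i, cell in enumerate(CELLS)}


def simulate_trajectory(
    cond: ExperimentalCondition,
    theta: np.ndarray,
    seed: int = 0,
    settings: SimulationSettings | None = None,
    stride: int = 10,
    rep: int = 0,
    n1_sign: int = -1,
) -> pd.DataFrame:
    """One stochastic realization recorded as a tidy frame.

    Columns: rep, cell, t, x, y, theta_E, theta_N, a, b, c -- one row per
    cell per recorded step (every ``stride``-th step).  Uses the reference
    Python stepper, so it is meant for inspection and plotting rather than
    ensemble estimation.
    """
    from .manifest import vector_to_map, vector_to_signaling
    from .signaling import egf_level, notch_received

    settings = settings or SimulationSettings()
    theta = np.asarray(theta, dtype=float)
    smap = vector_to_map(theta)
    sp = vector_to_signaling(theta, n1_sign=n1_sign)
    y0 = theta[10] + np.sqrt(max(-theta[9], 0.0))
    states = np.array([[0.0, y0]] * 3)
    rng = np.random.default_rng(seed)
    rows = []
    n_steps = int(np.ceil(settings.t_end / settings.dt))
    for k in range(n_steps + 1):
        t = k * settings.dt
        if k % stride == 0 or k == n_steps:
            for i, cell in enumerate(CELLS):
                te = egf_level(cell, t, sp, cond)
                tn = notch_received(cell, states, sp, cond, t)
                a, b, c = control_from_signals(smap, (te, tn))
                rows.append({"rep": rep, "cell": cell, "t": t,
                             "x": states[i, 0], "y": states[i, 1],
                             "theta_E": te, "theta_N": tn,
                             "a": a, "b": b, "c": c})
        if k < n_steps:
            states = em_step(states, t, theta, cond, settings.dt, rng,
                             smoothing_width=settings.smoothing_width,
                             n1_sign=n1_sign)
    return pd.DataFrame(rows)


def estimate_outcome(
    cond: ExperimentalCondition,
    theta: np.ndarray,
    n_reps: int = 100,
    seed: int = 0,
    settings: SimulationSettings | None = None,
    n1_sign: int = -1,
    _return_codes: bool = False,
):
    """Empirical fate proportions over ``n_reps`` independent simulations."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    settings = settings or SimulationSettings()
    theta = np.asarray(theta, dtype=float)
    ax, ay, afate, geom = _zero_signal_attractors(theta, settings.smoothing_width)
    codes = _kernel.simulate_condition(
        theta[:22], _pack_condition(cond), n_reps, settings.dt, settings.t_end,
        int(seed), settings.smoothing_width, settings.relax_steps,
        settings.radius, ax, ay, afate, geom, n1_sign,
    )
    if _return_codes:
        return codes
    props = np.zeros((3, 4))
    for i in range(3):
        for rep_fate, col in ((1, 0), (2, 1), (3, 2), (0, 3)):
            props[i, col] = np.mean(codes[:, i] == rep_fate)
    return OutcomeTable(condition_id=cond.id, proportions=props, n_reps=n_reps, seed=int(seed))


def simulate_pulse_protocol(
    theta: np.ndarray,
    pulses: list[tuple[str, float, float, float]],
    n_reps: int = 150,
    seed: int = 0,
    settings: SimulationSettings | None = None,
    isolated: bool = True,
) -> OutcomeTable:
    """Ensemble of isolated cells under a scripted signal schedule.

    ``pulses`` rows are ``(signal, level, t_start, t_end)`` with signal in
    ``{"egf", "notch"}``.  Isolated cells have no autocrine or paracrine
    Notch coupling; only the scripted levels are received.  Returns an
    :class:`OutcomeTable` whose single meaningful row repeats across cells.
    """
    if not isolated:
        raise NotImplementedError("only isolated-cell pulse protocols are supported")
    settings = settings or SimulationSettings()
    theta = np.asarray(theta, dtype=float)
    chan = {"egf": 0.0, "notch": 1.0}
    arr = np.zeros((len(pulses), 4))
    for j, (sig, level, t0, t1) in enumerate(pulses):
        if t1 <= t0:
            raise ValueError("pulse end must follow pulse start")
        arr[j] = (chan[sig], level, t0, t1)
    for c in (0.0, 1.0):  # overlapping pulses per channel are not meaningful
        rows = arr[arr[:, 0] == c]
        order = np.argsort(rows[:, 2])
        rows = rows[order]
        for r0, r1 in zip(rows[:-1], rows[1:]):
            if r1[2] < r0[3]:
                raise ValueError("overlapping pulses on one signal channel")
    ax, ay, afate, geom = _zero_signal_attractors(theta, settings.smoothing_width)
    t_end = max(settings.t_end, float(arr[:, 3].max()) if len(pulses) else settings.t_end)
    codes = _kernel.simulate_pulses(
        theta[:22], arr, n_reps, settings.dt, t_end, int(seed),
        settings.smoothing_width, settings.relax_steps, settings.radius,
        ax, ay, afate, geom,
    )
    props = np.zeros((3, 4))
    for rep_fate, col in ((1, 0), (2, 1), (3, 2), (0, 3)):
        props[:, col] = np.mean(codes == rep_fate)
    return OutcomeTable(condition_id="pulse_protocol", proportions=props,
                        n_reps=n_reps, seed=int(seed))
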