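"""Signal time courses received by P4-6.p and experimental perturbations.

Only P4.p, P5.p and P6.p are modeled: the pattern is assumed symmetric
around the anchor cell (P7.p mirrors P5.p, P8.p mirrors P4.p) and P3.p is
taken to be tertiary-fated.  EGF from the anchor cell attenuates by a factor
``gamma`` per cell position and rises in time as a sigmoid ``sigma(t)``;
Notch is produced by the cells themselves as a sigmoidal function ``L`` of
their state, increasing toward the primary basin, and each cell receives the
sum of its neighbors' (paracrine) plus ``alpha`` times its own (autocrine)
production, attenuated by receptor downregulation ``l_d L``.  Anchor-cell
ablation freezes EGF production and decays both signals exponentially.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CELLS",
    "ABLATION_STAGES",
    "SignalingParams",
    "ExperimentalCondition",
    "egf_sigmoid",
    "egf_level",
    "notch_production",
    "notch_received",
]

CELLS = ("P4.p", "P5.p", "P6.p")
FATE_NAMES = ("primary", "secondary", "tertiary")

#: ablation stage -> time on the competence clock t in [0, 1].  The six
#: reported stages are ordered but not timed; defaults are evenly spaced.
ABLATION_STAGES: dict[str, float] = {
    "L2_lethargus": 0.0,
    "early_L3": 1.0 / 6.0,
    "DU_divided": 2.0 / 6.0,
    "VU_divided": 3.0 / 6.0,
    "tertiary_divided": 4.0 / 6.0,
    "two_cell_stage": 5.0 / 6.0,
}


@dataclass(frozen=True)
class SignalingParams:
    """Parameters of the EGF/Notch signaling model.

    gamma : EGF spatial attenuation per cell position (0 < gamma <= 1)
    H_E, M_E : slope (1/time) and offset of the EGF sigmoid
    n0, n1_norm : offset and gradient magnitude of Notch production;
        the gradient vector is ``n1_sign * (n1_norm, 0)`` with
        ``n1_sign = -1`` so production rises toward the primary basin (x < 0)
    alpha : autocrine weight (>= 0)
    l_d : receptor-downregulation strength (in [0, 1])
    lambda_E, lambda_N : post-ablation exponential decay rates (1/time)
    sigma_dif : diffusion coefficient of the phase-space noise
    """

    gamma: float
    H_E: float
    M_E: float
    n0: float
    n1_norm: float
    alpha: float
    l_d: float
    lambda_E: float
    lambda_N: float
    sigma_dif: float
    n1_sign: int = -1

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if not 0 <= self.l_d <= 1:
            raise ValueError("l_d must be in [0, 1]")
        if self.n1_norm < 0:
            raise ValueError("n1_norm must be non-negative")
        if self.sigma_dif < 0:
            raise ValueError("sigma_dif must be non-negative")
        if self.n1_sign not in (-1, 1):
            raise ValueError("n1_sign must be +-1")


@dataclass(frozen=True)
class ExperimentalCondition:
    """One perturbation line: signal modifiers plus observed fate proportions.

    ``egf_dose`` may be a number, ``"fit"`` (overexpression level fitted as a
    nuisance parameter) or ``"hypomorph"`` (multiplied by the fitted
    EGF-hypomorph factor).  ``notch_receptor_factor`` may be a number or
    ``"reduced"`` (the fitted Notch reduction factor);
    ``notch_ectopic`` a number or ``"fit"`` (the fitted ectopic constant).
    ``observed`` maps cell name -> (p1, p2, p3) probabilities, or ``None``
    for cells missing from the record (ablation rows lack P4.p).
    """

    id: str
    egf_dose: float | str = 1.0
    notch_receptor_factor: float | str = 1.0
    notch_ectopic: float | str = 0.0
    lin3_half: bool = False
    egf_mosaic_cells: frozenset[str] = frozenset()
    n_anchor_cells: int = 1
    ablation_stage: str | None = None
    observed: Mapping[str, tuple[float, float, float] | None] = field(default_factory=dict)
    training: bool = False

    def __post_init__(self) -> None:
        for mod in (self.egf_dose, self.notch_receptor_factor, self.notch_ectopic):
            if isinstance(mod, (int, float)) and mod < 0:
                raise ValueError(f"{self.id}: modifiers must be non-negative")
        if self.n_anchor_cells not in (1, 2):
            raise ValueError(f"{self.id}: n_anchor_cells must be 1 or 2")
        if self.ablation_stage is not None and self.ablation_stage not in ABLATION_STAGES:
            raise ValueError(f"{self.id}: unknown ablation stage {self.ablation_stage!r}")
        unknown = set(self.egf_mosaic_cells) - set(CELLS)
        if unknown:
            raise ValueError(f"{self.id}: unknown mosaic cells {sorted(unknown)}")
        for cell, probs in self.observed.items():
            if cell not in CELLS:
                raise ValueError(f"{self.id}: unknown cell {cell!r}")
            if probs is not None and abs(sum(probs) - 1.0) > 1e-6:
                raise ValueError(f"{self.id}: fates of {cell} do not sum to 1: {probs}")

    @property
    def ablation_time(self) -> float | None:
        if self.ablation_stage is None:
            return None
        return ABLATION_STAGES[self.ablation_stage]

    @property
    def needs_modifiers(self) -> tuple[str, ...]:
        """Names of fitted modifier constants this condition depends on."""
        needed = []
        if self.egf_dose == "fit":
            needed.append("ju1100_dose")
        if self.egf_dose == "hypomorph":
            needed.append("egf_hypomorph")
        if self.notch_receptor_factor == "reduced":
            needed.append("notch_reduction")
        if self.notch_ectopic == "fit":
            needed.append("ectopic_notch")
        return tuple(needed)

    def resolve(self, modifiers: Mapping[str, float] | None = None) -> "ExperimentalCondition":
        """Replace symbolic modifiers by concrete values."""
        modifiers = dict(modifiers or {})
        kw: dict = {}
        if self.egf_dose == "fit":
            kw["egf_dose"] = float(modifiers["ju1100_dose"])
        elif self.egf_dose == "hypomorph":
            kw["egf_dose"] = float(modifiers["egf_hypomorph"])
        if self.notch_receptor_factor == "reduced":
            kw["notch_receptor_factor"] = float(modifiers["notch_reduction"])
        if self.notch_ectopic == "fit":
            kw["notch_ectopic"] = float(modifiers["ectopic_notch"])
        return replace(self, **kw) if kw else self

    @property
    def egf_multiplier(self) -> float:
        """Total multiplicative factor on the EGF signal."""
        if isinstance(self.egf_dose, str):
            raise ValueError(f"{self.id}: unresolved egf_dose {self.egf_dose!r}")
        return self.egf_dose * self.n_anchor_cells * (0.5 if self.lin3_half else 1.0)


def egf_sigmoid(t: float, H_E: float, M_E: float) -> float:
    """EGF time course ``sigma(t) = (1 + tanh(H_E t + M_E)) / 2``."""
    return 0.5 * (1.0 + math.tanh(H_E * t + M_E))


def egf_level(
    cell: str,
    t: float,
    sp: SignalingParams,
    cond: ExperimentalCondition,
    timecourse=None,
) -> float:
    """EGF signal received by ``cell`` at time ``t`` under ``cond``.

    ``timecourse`` is a pluggable ``sigma(t)``; the default is the fitted
    sigmoid.  After anchor-cell ablation, production is frozen at the
    ablation time and the ligand decays at rate ``lambda_E``.
    """
    if cell not in CELLS:
        raise KeyError(f"unknown cell {cell!r}")
    if timecourse is None:
        timecourse = lambda tt: egf_sigmoid(tt, sp.H_E, sp.M_E)
    t_abl = cond.ablation_time
    decay = 1.0
    t_clock = t
    if t_abl is not None and t > t_abl:
        decay = math.exp(-sp.lambda_E * (t - t_abl))
        t_clock = t_abl
    power = 2 - CELLS.index(cell)  # gamma^2, gamma, 1 for P4, P5, P6
    level = timecourse(t_clock) * sp.gamma**power * cond.egf_multiplier * decay
    if cell in cond.egf_mosaic_cells:
        return 0.0
    return level


def notch_production(state: Sequence[float], sp: SignalingParams) -> float:
    """Notch production ``L(x) = (1 + tanh(n0 + n1 . x)) / 2`` of one cell."""
    x = float(state[0])
    return 0.5 * (1.0 + math.tanh(sp.n0 + sp.n1_sign * sp.n1_norm * x))


def notch_received(
    cell: str,
    states: Sequence[Sequence[float]],
    sp: SignalingParams,
    cond: ExperimentalCondition,
    t: float = 0.0,
) -> float:
    """Notch signal received by ``cell`` given all three cell states.

    Sum of paracrine (neighbors) and ``alpha``-weighted autocrine production,
    attenuated by receptor downregulation ``1 - l_d L(x_i)``; boundary rule:
    P4.p's outer neighbor contributes 0, P6.p's outer neighbor mirrors P5.p.
    The receptor factor multiplies, the ectopic constant adds, and a zero
    receptor factor (Notch null) silences the pathway entirely.
    """
    if cell not in CELLS:
        raise KeyError(f"unknown cell {cell!r}")
    if isinstance(cond.notch_receptor_factor, str) or isinstance(cond.notch_ectopic, str):
        raise ValueError(f"{cond.id}: unresolved Notch modifiers")
    i = CELLS.index(cell)
    L = [notch_production(s, sp) for s in states]
    left = 0.0 if i == 0 else L[i - 1]
    right = L[1] if i == 2 else L[i + 1]
    base = (1.0 - sp.l_d * L[i]) * (left + sp.alpha * L[i] + right)
    if cond.notch_receptor_factor == 0.0:
        return 0.0
    level = base * cond.notch_receptor_factor + cond.notch_ectopic
    t_abl = cond.ablation_time
    if t_abl is not None and t > t_abl:
        level *= math.exp(-sp.lambda_N * (t - t_abl))
    return level
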