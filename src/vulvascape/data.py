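"""Reference condition tables, I/O, synthetic observations and run config.

The built-in fixture transcribes the published compilation of vulval fate
proportions for 21 experimental conditions (wild type, signaling mutants and
anchor-cell ablation series).  Fates are ordered (primary, secondary,
tertiary); proportions are stored as probabilities and only converted to
percentages for display.  Anchor-cell ablation rows record P5.p and P6.p
only.  Nine conditions are flagged as the training set, the rest as
validation, mirroring the published split.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .signaling import CELLS, ExperimentalCondition

__all__ = [
    "builtin_reference_conditions",
    "validation_reference_table",
    "load_conditions",
    "save_conditions",
    "generate_synthetic_observations",
    "count_probability_entries",
    "RunConfig",
]

_P = lambda p1, p2, p3: (p1 / 100.0, p2 / 100.0, p3 / 100.0)
_WT = {"P4.p": _P(0, 0, 100), "P5.p": _P(0, 100, 0), "P6.p": _P(100, 0, 0)}


def builtin_reference_conditions() -> list[ExperimentalCondition]:
    """The 21-row reference condition table (171 probability entries).

    Training rows (``training=True``): the six fully penetrant phenotypes,
    the EGF-overexpression line JU1100, and two of the six anchor-cell
    ablation stages.  Symbolic modifiers (``"fit"``, ``"reduced"``,
    ``"hypomorph"``) mark perturbation strengths that are fitted, not
    measured.
    """
    C = ExperimentalCondition
    rows = [
        C("WT", observed=_WT, training=True),
        C("let-23 mosaic", egf_mosaic_cells=frozenset({"P5.p"}), observed=_WT,
          training=True),
        C("half lin-3", lin3_half=True, observed=_WT, training=True),
        C("half lin-12", notch_receptor_factor=0.5, observed=_WT, training=True),
        C("Notch null 2AC", notch_receptor_factor=0.0, n_anchor_cells=2,
          observed={"P4.p": _P(0, 0, 100), "P5.p": _P(100, 0, 0), "P6.p": _P(100, 0, 0)},
          training=True),
        C("Notch null", notch_receptor_factor=0.0,
          observed={"P4.p": _P(0, 0, 100), "P5.p": _P(0, 0, 100), "P6.p": _P(100, 0, 0)},
          training=True),
        C("JU1100", egf_dose="fit",
          observed={"P4.p": _P(18, 46, 36), "P5.p": _P(45.5, 54.5, 0), "P6.p": _P(96, 4, 0)},
          training=True),
        C("JU1107", egf_dose=2.75,
          observed={"P4.p": _P(2, 15, 83), "P5.p": _P(19, 81, 0), "P6.p": _P(100, 0, 0)}),
        C("JU2039", notch_receptor_factor="reduced",
          observed={"P4.p": _P(0, 0, 100), "P5.p": _P(1, 89, 10), "P6.p": _P(100, 0, 0)}),
        C("JU2113", egf_dose=1.25, notch_receptor_factor="reduced",
          observed={"P4.p": _P(4, 6, 90), "P5.p": _P(18, 70, 12), "P6.p": _P(100, 0, 0)}),
        C("JU2091", egf_dose=1.25, notch_ectopic="fit",
          observed={"P4.p": _P(0, 0, 100), "P5.p": _P(0, 100, 0), "P6.p": _P(100, 0, 0)}),
        C("JU2089", egf_dose=1.79, notch_ectopic="fit",
          observed={"P4.p": _P(0, 6, 94), "P5.p": _P(1, 99, 0), "P6.p": _P(100, 0, 0)}),
        C("JU2092", egf_dose=2.75, notch_ectopic="fit",
          observed={"P4.p": _P(5, 24, 71), "P5.p": _P(0, 100, 0), "P6.p": _P(100, 0, 0)}),
        C("CB1417", egf_dose="hypomorph",
          observed={"P4.p": _P(0, 0, 100), "P5.p": _P(1, 99, 0), "P6.p": _P(54, 0, 46)}),
        C("JU2095", egf_dose="hypomorph", notch_ectopic="fit",
          observed={"P4.p": _P(0, 1, 99), "P5.p": _P(0, 15, 85), "P6.p": _P(72, 0, 28)}),
        C("ablation L2 lethargus", ablation_stage="L2_lethargus",
          observed={"P5.p": _P(0, 0, 100), "P6.p": _P(0, 0, 100)}, training=True),
        C("ablation early L3", ablation_stage="early_L3",
          observed={"P5.p": _P(1.5, 21, 77.5), "P6.p": _P(18, 18, 64)}),
        C("ablation DU divided", ablation_stage="DU_divided",
          observed={"P5.p": _P(0, 54.63, 45.37), "P6.p": _P(31, 38, 31)}, training=True),
        C("ablation VU divided", ablation_stage="VU_divided",
          observed={"P5.p": _P(4, 90, 6), "P6.p": _P(52, 48, 0)}),
        C("ablation 3deg divided", ablation_stage="tertiary_divided",
          observed={"P5.p": _P(1, 99, 0), "P6.p": _P(65, 35, 0)}),
        C("ablation 2-cell stage", ablation_stage="two_cell_stage",
          observed={"P5.p": _P(1, 99, 0), "P6.p": _P(93, 7, 0)}),
    ]
    n = count_probability_entries(rows)
    if n != 171 or len(rows) != 21:
        raise AssertionError(f"fixture integrity violated: {len(rows)} rows, {n} entries")
    return rows


def count_probability_entries(conditions: Iterable[ExperimentalCondition]) -> int:
    return sum(
        3 for cond in conditions for probs in cond.observed.values() if probs is not None
    )


def validation_reference_table() -> pd.DataFrame:
    """Published simulated mean +- SD for the validation rows (metadata only).

    These depend on the original study's posterior and are reference
    metadata, not fit targets.
    """
    rows = [
        ("JU1107", "P4.p", (3, 5), (25, 18), (72, 19)),
        ("JU1107", "P5.p", (25, 18), (75, 18), (0, 0)),
        ("JU1107", "P6.p", (99, 3), (1, 1), (0, 0)),
        ("JU2039", "P4.p", (0, 0), (0, 1), (99, 1)),
        ("JU2039", "P5.p", (16, 8), (80, 10), (4, 4)),
        ("JU2039", "P6.p", (99, 1), (1, 1), (0, 0)),
        ("JU2113", "P4.p", (1, 1), (3, 3), (98, 3)),
        ("JU2113", "P5.p", (25, 12), (76, 12), (0, 1)),
        ("JU2113", "P6.p", (100, 1), (0, 1), (0, 0)),
        ("JU2091", "P4.p", (0, 1), (5, 7), (95, 7)),
        ("JU2091", "P5.p", (1, 1), (99, 1), (0, 0)),
        ("JU2091", "P6.p", (99, 1), (1, 1), (0, 0)),
        ("JU2089", "P4.p", (1, 1), (8, 10), (91, 10)),
        ("JU2089", "P5.p", (2, 2), (98, 2), (0, 0)),
        ("JU2089", "P6.p", (99, 1), (1, 1), (0, 0)),
        ("JU2092", "P4.p", (4, 5), (34, 20), (62, 21)),
        ("JU2092", "P5.p", (20, 16), (80, 16), (0, 0)),
        ("JU2092", "P6.p", (99, 2), (1, 1), (0, 0)),
        ("CB1417", "P4.p", (0, 0), (1, 1), (99, 1)),
        ("CB1417", "P5.p", (2, 2), (44, 20), (54, 21)),
        ("CB1417", "P6.p", (55, 20), (10, 7), (35, 22)),
        ("JU2095", "P4.p", (0, 1), (3, 5), (97, 5)),
        ("JU2095", "P5.p", (1, 2), (65, 16), (34, 16)),
        ("JU2095", "P6.p", (61, 16), (34, 15), (5, 9)),
    ]
    recs = []
    for cid, cell, p1, p2, p3 in rows:
        recs.append({
            "id": cid, "cell": cell,
            "p1_mean": p1[0], "p1_sd": p1[1],
            "p2_mean": p2[0], "p2_sd": p2[1],
            "p3_mean": p3[0], "p3_sd": p3[1],
        })
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# serialization

_FATE_COLS = [f"{cell.split('.')[0].lower()}_{f}" for cell in CELLS for f in (1, 2, 3)]


def _cond_to_record(cond: ExperimentalCondition) -> dict:
    rec: dict = {
        "id": cond.id,
        "egf_dose": cond.egf_dose,
        "lin3_half": cond.lin3_half,
        "notch_receptor_factor": cond.notch_receptor_factor,
        "notch_ectopic": cond.notch_ectopic,
        "mosaic": ";".join(sorted(cond.egf_mosaic_cells)),
        "n_ac": cond.n_anchor_cells,
        "ablation_stage": cond.ablation_stage or "",
        "training": cond.training,
    }
    for cell in CELLS:
        key = cell.split(".")[0].lower()
        probs = cond.observed.get(cell)
        for k in range(3):
            rec[f"{key}_{k + 1}"] = None if probs is None else probs[k]
    return rec


def _record_to_cond(rec: Mapping, row: int) -> ExperimentalCondition:
    def _mod(v):
        if isinstance(v, str) and v not in ("", "nan"):
            try:
                return float(v)
            except ValueError:
                return v
        return float(v)

    observed: dict[str, tuple[float, float, float] | None] = {}
    for cell in CELLS:
        key = cell.split(".")[0].lower()
        vals = [rec.get(f"{key}_{k + 1}") for k in range(3)]
        if all(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
            continue
        probs = tuple(float(v) for v in vals)
        if abs(sum(probs) - 1.0) > 1e-6:
            raise ValueError(f"row {row} ({rec.get('id')}): fates of {cell} sum to {sum(probs)}")
        observed[cell] = probs
    mosaic = rec.get("mosaic")
    if not isinstance(mosaic, str):  # None or NaN from an empty CSV cell
        mosaic = ""
    stage = rec.get("ablation_stage")
    if not isinstance(stage, str) or not stage:
        stage = None
    return ExperimentalCondition(
        id=str(rec["id"]),
        egf_dose=_mod(rec.get("egf_dose", 1.0)),
        notch_receptor_factor=_mod(rec.get("notch_receptor_factor", 1.0)),
        notch_ectopic=_mod(rec.get("notch_ectopic", 0.0)),
        lin3_half=bool(rec.get("lin3_half", False)),
        egf_mosaic_cells=frozenset(c for c in mosaic.split(";") if c),
        n_anchor_cells=int(rec.get("n_ac", 1)),
        ablation_stage=stage,
        observed=observed,
        training=bool(rec.get("training", False)),
    )


def save_conditions(conditions: Sequence[ExperimentalCondition], path: str | Path) -> None:
    """Write a condition table as CSV or JSON (by file extension)."""
    path = Path(path)
    records = [_cond_to_record(c) for c in conditions]
    if path.suffix == ".json":
        path.write_text(json.dumps(records, indent=1))
    elif path.suffix == ".csv":
        pd.DataFrame(records).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported extension {path.suffix!r} (use .csv or .json)")


def load_conditions(path: str | Path) -> list[ExperimentalCondition]:
    """Read a condition table written by :func:`save_conditions`."""
    path = Path(path)
    if path.suffix == ".json":
        records = json.loads(path.read_text())
    elif path.suffix == ".csv":
        df = pd.read_csv(path)
        records = df.to_dict("records")
    else:
        raise ValueError(f"unsupported extension {path.suffix!r} (use .csv or .json)")
    out = []
    for row, rec in enumerate(records, start=1):
        try:
            out.append(_record_to_cond(rec, row))
        except (KeyError, TypeError) as exc:
            raise ValueError(f"row {row}: malformed record ({exc})") from exc
    return out


def generate_synthetic_observations(
    theta_true: np.ndarray,
    conditions: Sequence[ExperimentalCondition],
    n_reps: int = 400,
    seed: int = 0,
    settings=None,
    modifiers: Mapping[str, float] | None = None,
) -> list[ExperimentalCondition]:
    """Condition set whose observations are replaced by simulator output.

    Unassigned outcomes are folded out by renormalizing over the three fates
    (observations are fate proportions among assigned cells).  Enables
    parameter-recovery studies with no external data.
    """
    from dataclasses import replace

    from .manifest import satisfies_constraints
    from .simulate import estimate_outcome

    theta_true = np.asarray(theta_true, dtype=float)
    if not satisfies_constraints(theta_true):
        raise ValueError("theta_true violates the signal-map constraints")
    ss = np.random.SeedSequence([int(seed), 0xD0C5])
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(conditions))]
    out = []
    for cond, cseed in zip(conditions, child_seeds):
        # the returned table records the concrete modifiers actually used
        resolved = cond.resolve(modifiers)
        table = estimate_outcome(resolved, theta_true, n_reps=n_reps, seed=cseed,
                                 settings=settings)
        observed = {}
        for cell in cond.observed:
            i = CELLS.index(cell)
            p = table.proportions[i, :3]
            total = p.sum()
            if total <= 0:  # all unassigned: degenerate, keep uniform
                observed[cell] = (1 / 3, 1 / 3, 1 / 3)
            else:
                observed[cell] = tuple(float(v / total) for v in p)
        out.append(replace(resolved, observed=observed))
    return out


@dataclass(frozen=True)
class RunConfig:
    """Simulator + ABC settings serialized into every run manifest."""

    dt: float = 1e-3
    t_end: float = 1.0
    n_reps: int = 24
    n_particles: int = 128
    n_generations: int = 14
    quantile: float = 0.3
    seed: int = 0
    workers: int = 1
    extras: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def manifest(self) -> dict:
        d = asdict(self)
        d["config_hash"] = self.config_hash()
        return d
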