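"""Fitted-parameter manifest, flat priors and parameter-vector packing.

The default model has 22 fitted parameters: 1 rate constant (``tau``),
10 landscape-map parameters (the 3x2 matrix ``m``, offset ``q`` and fold
offset ``M``) and 11 signaling parameters.  All priors are flat on finite
supports; supports not fixed by the model's structure are reconstructions
chosen for a competence clock on t in [0, 1] (see docs/methods.md).  The
joint prior additionally carries an indicator: the signal map constraints of
:func:`vulvascape.signal_map.check_map_constraints`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_map import AffineSignalMap, check_map_constraints
from .signaling import SignalingParams

__all__ = [
    "ManifestEntry",
    "ParameterManifest",
    "parameter_manifest",
    "default_prior_bounds",
    "vector_to_map",
    "vector_to_signaling",
    "vector_to_dict",
    "dict_to_vector",
]

# (name, partition, low, high, units)
_DEFAULT_ENTRIES: list[tuple[str, str, float, float, str]] = [
    ("tau", "time", 1.0, 30.0, "1/time"),
    ("m11", "landscape", -1.0, 1.0, "dimensionless"),
    ("m12", "landscape", -1.0, 1.0, "dimensionless"),
    ("m21", "landscape", -1.0, 1.0, "dimensionless"),
    ("m22", "landscape", -1.0, 1.0, "dimensionless"),
    ("m31", "landscape", -1.0, 1.0, "dimensionless"),
    ("m32", "landscape", -1.0, 1.0, "dimensionless"),
    ("q1", "landscape", -3.0, 0.0, "dimensionless"),
    ("q2", "landscape", -1.0, 1.0, "dimensionless"),
    ("q3", "landscape", -3.0, 0.0, "dimensionless"),
    ("M", "landscape", 0.3, 3.0, "phase units"),
    ("s", "signaling", 0.1, 10.0, "control units per EGF unit"),
    ("l", "signaling", 0.1, 10.0, "control units per Notch unit"),
    ("gamma", "signaling", 0.01, 1.0, "dimensionless"),
    ("H_E", "signaling", 2.0, 20.0, "1/time"),
    ("M_E", "signaling", -10.0, 0.0, "dimensionless"),
    ("n0", "signaling", -4.0, 1.0, "dimensionless"),
    ("n1", "signaling", 0.0, 10.0, "1/phase unit"),
    ("alpha", "signaling", 0.0, 2.0, "dimensionless"),
    ("l_d", "signaling", 0.0, 1.0, "dimensionless"),
    ("sigma_dif", "signaling", 0.0, 0.5, "phase units / sqrt(time)"),
    ("lambda", "signaling", 2.0, 20.0, "1/time"),
]


@dataclass(frozen=True)
class ManifestEntry:
    name: str
    partition: str
    low: float
    high: float
    units: str = ""


class ParameterManifest:
    """Ordered list of fitted parameters with flat-prior supports."""

    def __init__(self, entries: list[ManifestEntry], default_profile: bool = True):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names in manifest")
        if default_profile:
            counts = {
                p: sum(e.partition == p for e in entries)
                for p in ("time", "landscape", "signaling")
            }
            if counts != {"time": 1, "landscape": 10, "signaling": 11}:
                raise ValueError(
                    f"default manifest must partition 1/10/11, got {counts}"
                )
        self.entries = list(entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([e.low for e in self.entries])
        hi = np.array([e.high for e in self.entries])
        return lo, hi

    def index(self, name: str) -> int:
        return self.names.index(name)

    def partition_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.entries:
            out[e.partition] = out.get(e.partition, 0) + 1
        return out

    def extended(self, name: str, low: float, high: float,
                 partition: str = "nuisance", units: str = "") -> "ParameterManifest":
        """A new manifest with one extra fitted parameter appended."""
        return ParameterManifest(
            self.entries + [ManifestEntry(name, partition, low, high, units)],
            default_profile=False,
        )


def parameter_manifest() -> ParameterManifest:
    """The default 22-entry manifest (1 time + 10 landscape + 11 signaling)."""
    return ParameterManifest([ManifestEntry(*e) for e in _DEFAULT_ENTRIES])


def default_prior_bounds() -> tuple[np.ndarray, np.ndarray]:
    m = parameter_manifest()
    return m.bounds


def vector_to_map(theta: np.ndarray) -> AffineSignalMap:
    """The affine signal map encoded in a parameter vector."""
    t = np.asarray(theta, dtype=float)
    return AffineSignalMap(
        m=((t[1], t[2]), (t[3], t[4]), (t[5], t[6])),
        q=(t[7], t[8], t[9]),
        s=t[11],
        l=t[12],
    )


def vector_to_signaling(theta: np.ndarray, n1_sign: int = -1) -> SignalingParams:
    t = np.asarray(theta, dtype=float)
    return SignalingParams(
        gamma=t[13], H_E=t[14], M_E=t[15], n0=t[16], n1_norm=t[17],
        alpha=t[18], l_d=t[19], lambda_E=t[21], lambda_N=t[21],
        sigma_dif=t[20], n1_sign=n1_sign,
    )


def vector_to_dict(theta: np.ndarray, manifest: ParameterManifest | None = None) -> dict[str, float]:
    manifest = manifest or parameter_manifest()
    t = np.asarray(theta, dtype=float)
    if t.shape[0] < len(manifest):
        raise ValueError("parameter vector shorter than manifest")
    return dict(zip(manifest.names, (float(v) for v in t)))


def dict_to_vector(d: dict[str, float], manifest: ParameterManifest | None = None) -> np.ndarray:
    manifest = manifest or parameter_manifest()
    return np.array([float(d[n]) for n in manifest.names])


def satisfies_constraints(theta: np.ndarray) -> bool:
    """Joint prior constraint: the map admits vulval patterning geometry."""
    t = np.asarray(theta, dtype=float)
    if t[9] >= 0:  # c at the origin must be negative before anything else
        return False
    try:
        smap = vector_to_map(t)
    except ValueError:
        return False
    ok, _ = check_map_constraints(smap, M=float(t[10]))
    return ok
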