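"""Bundled reference parameter vector.

``data/reference_particle.json`` holds one parameter vector obtained by this
package's own desk-scale ABC SMC fit to the training conditions (it is a
stand-in for a posterior particle of a full-scale fit, not a published
value).  It reproduces the wild-type 3-2-1 pattern and is used as the
default particle for demonstrations and predictions.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .manifest import parameter_manifest

__all__ = ["reference_particle", "reference_modifiers"]


def _load() -> dict:
    path = resources.files("vulvascape").joinpath("data/reference_particle.json")
    return json.loads(path.read_text())


def reference_particle() -> np.ndarray:
    """The bundled fitted parameter vector (22 entries, manifest order)."""
    payload = _load()
    manifest = parameter_manifest()
    return np.array([float(payload["parameters"][n]) for n in manifest.names])


def reference_modifiers() -> dict[str, float]:
    """Fitted perturbation-strength constants bundled with the particle."""
    return {k: float(v) for k, v in _load()["modifiers"].items()}
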