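"""Packaged defaults: scaling anchors and the published weight vector.

The seven percentage indicators use H = 100 and M = 50, which makes the
ability value simply the percentage divided by 100.  Speech energy and
speech speed need cohort-level anchors because their raw units (dB,
events per minute) have no universal "best" value; the shipped defaults
were calibrated once from the spread of the packaged six-subject
reference table and should be overridden for cohorts recorded under
different conditions.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from .rubric import INDICATOR_NAMES, PERCENTAGE_INDICATORS, AbilityScaling


def default_scalings() -> dict[str, AbilityScaling]:
    """Per-indicator H/M anchors; all indicators treated as increasing."""
    scalings = {
        name: AbilityScaling(H=100.0, M=50.0) for name in PERCENTAGE_INDICATORS
    }
    scalings["speech_energy"] = AbilityScaling(H=80.0, M=55.0)
    scalings["speech_speed"] = AbilityScaling(H=60.0, M=30.0)
    return scalings


def load_factor_model() -> dict:
    """The packaged published factor model (loadings, coefficients, weights)."""
    ref = resources.files("fuzzycomm.data").joinpath("factor_model.json")
    with ref.open("r", encoding="utf-8") as fh:
        model = json.load(fh)
    assert model["indicator_order"] == list(INDICATOR_NAMES)
    return model


def default_weights() -> np.ndarray:
    """The published indicator weight vector, renormalized to unit sum.

    The printed four-decimal values sum to 1.0001; renormalizing moves
    each component by about 1e-5, well below the printed precision.
    """
    w = np.asarray(load_factor_model()["weights"], dtype=float)
    return w / w.sum()
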