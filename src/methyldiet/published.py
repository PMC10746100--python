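"""Bundled published score weights and interaction-model coefficients.

Two precisions of the per-diet weights are shipped: the full-precision
regression coefficients (three decimals) and the two-decimal variants used
in the published score formulas.  The two-decimal variants are truncated,
not rounded, from the full-precision values (e.g. 6.259 -> 6.25), so the
two sets are distinct fixtures rather than derivable from one another.
"""

from __future__ import annotations

import json
from importlib import resources

from .errors import InputError
from .scoring import DietScoreWeights

_PRECISIONS = ("full", "table7")


def _load_json(name: str) -> dict:
    ref = resources.files("methyldiet").joinpath("data", name)
    with ref.open("r") as fh:
        return json.load(fh)


def load_published_weights(diet: str, precision: str = "table7") -> DietScoreWeights:
    """Load the bundled weight set for one diet.

    Parameters
    ----------
    diet
        'MHP' (15 CpGs) or 'LF' (11 CpGs).
    precision
        'table7' for the two-decimal score-formula weights, 'full' for the
        three-decimal regression coefficients.
    """
    if diet not in ("MHP", "LF"):
        raise InputError(f"unknown diet {diet!r}")
    if precision not in _PRECISIONS:
        raise InputError(f"unknown precision {precision!r}; choose from {_PRECISIONS}")
    payload = _load_json(f"weights_{diet.lower()}_{precision}.json")
    return DietScoreWeights.from_dict(payload)


def load_published_interaction_coefficients() -> dict:
    """Published fixed-effect coefficients (with SEs where printed) of the
    diet x score interaction model, for worked examples.

    No coefficient covariance was published, so this fixture supports
    point predictions only; SE-based inference requires a fitted model.
    """
    return _load_json("interaction_coefficients.json")
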