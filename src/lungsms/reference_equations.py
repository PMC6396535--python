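"""Predicted total lung capacity from reference equations.

The shipped defaults are the ECSC/ERS summary equations for adults,
linear in standing height with gender-specific coefficients
(male: 7.99·H − 7.08 L, female: 6.60·H − 5.79 L, H in meters).  They are
stored as a JSON configuration file rather than in code, so a different
reference population can be dropped in without touching computation paths.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Mapping, Optional

from .errors import DomainError, SchemaError
from .io import normalize_gender

_DEFAULTS: Optional[dict] = None


def load_default_tlc_coefficients() -> dict:
    """Load the shipped TLC reference coefficient table."""
    global _DEFAULTS
    if _DEFAULTS is None:
        text = resources.files("lungsms.data").joinpath("tlc_reference.json").read_text()
        _DEFAULTS = json.loads(text)
    return _DEFAULTS


def load_tlc_coefficients(path: str) -> dict:
    """Load a user-supplied TLC coefficient table and validate its schema."""
    with open(path) as fh:
        table = json.load(fh)
    for gender in ("male", "female"):
        entry = table.get(gender)
        if not isinstance(entry, Mapping) or not {"height_slope", "intercept"} <= set(entry):
            raise SchemaError(
                f"TLC coefficient table must define height_slope and intercept "
                f"for {gender!r}"
            )
    return table


def predicted_tlc(gender: str, height: float,
                  coefficients: Optional[Mapping] = None) -> float:
    """Predicted TLC in liters for a subject of given gender and height [m].

    Raises
    ------
    DomainError
        If gender or height is missing, or height is outside (1.0, 2.5) m.
    """
    if gender is None or height is None:
        raise DomainError("predicted TLC requires both gender and height")
    g = normalize_gender(gender)
    h = float(height)
    if not (1.0 < h < 2.5):
        raise DomainError(f"height {h} m outside the supported (1.0, 2.5) m range")
    table = coefficients if coefficients is not None else load_default_tlc_coefficients()
    entry = table[g]
    return float(entry["height_slope"]) * h + float(entry["intercept"])
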