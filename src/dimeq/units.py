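"""Concentration unit handling.

All concentrations are carried internally in molar (M).  I/O boundaries
accept explicitly tagged nM/uM/mM values and convert once, on entry.
"""

from __future__ import annotations

from .errors import ValidationError

#: multiplicative factor to molar for each accepted unit tag
_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}


def to_molar(value: float, unit: str) -> float:
    """Convert ``value`` expressed in ``unit`` to molar."""
    try:
        factor = _TO_MOLAR[unit]
    except KeyError:
        raise ValidationError(
            f"unknown concentration unit {unit!r}; expected one of {sorted(_TO_MOLAR)}"
        ) from None
    return float(value) * factor


def from_molar(value: float, unit: str) -> float:
    """Convert a molar ``value`` to ``unit``."""
    try:
        factor = _TO_MOLAR[unit]
    except KeyError:
        raise ValidationError(
            f"unknown concentration unit {unit!r}; expected one of {sorted(_TO_MOLAR)}"
        ) from None
    return float(value) / factor
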