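"""Unit handling.

All internal quantities are SI (meters, seconds, siemens per meter, amperes,
volts).  Configuration files and the CLI accept strings with explicit unit
suffixes ("200 um", "1 mA", "430 us") which are converted on input.
"""

from __future__ import annotations

import re

# multiplier to SI base unit, keyed by suffix
_UNITS = {
    # length -> m
    "m": 1.0, "cm": 1e-2, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9,
    # time -> s
    "s": 1.0, "ms": 1e-3, "us": 1e-6, "µs": 1e-6, "ns": 1e-9,
    # current -> A
    "A": 1.0, "mA": 1e-3, "uA": 1e-6, "µA": 1e-6, "nA": 1e-9,
    # voltage -> V
    "V": 1.0, "mV": 1e-3, "uV": 1e-6, "µV": 1e-6,
    # charge -> C
    "C": 1.0, "mC": 1e-3, "uC": 1e-6, "µC": 1e-6, "nC": 1e-9,
    # conductivity -> S/m
    "S/m": 1.0, "mS/m": 1e-3,
}

_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([a-zA-Zµ/]*)\s*$")


def parse_quantity(value: float | int | str, default_unit: str | None = None) -> float:
    """Convert ``value`` to SI.

    Bare numbers are interpreted in ``default_unit`` (or SI if None);
    strings may carry any suffix from the supported table.
    """
    if isinstance(value, (int, float)):
        scale = _UNITS[default_unit] if default_unit else 1.0
        return float(value) * scale
    m = _QUANTITY_RE.match(value)
    if not m:
        raise ValueError(f"cannot parse quantity {value!r}")
    num, unit = m.groups()
    if not unit:
        scale = _UNITS[default_unit] if default_unit else 1.0
    elif unit in _UNITS:
        scale = _UNITS[unit]
    else:
        raise ValueError(f"unknown unit {unit!r} in {value!r}")
    return float(num) * scale
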