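"""Small helpers for unit-carrying config values.

Config files state dimensional quantities as strings with explicit units
("400 um", "3 mm", "115 um/s", "24 h").  Internally everything is SI
(metres, seconds, mol, cells).  Bare numbers are accepted and taken as SI.
"""

from __future__ import annotations

import re

_LENGTH = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9, "cm": 1e-2}
_TIME = {"s": 1.0, "min": 60.0, "h": 3600.0, "d": 86400.0}
_VELOCITY = {
    f"{lu}/{tu}": lf / tf for lu, lf in _LENGTH.items() for tu, tf in _TIME.items()
}
_ANGLE = {"deg": 1.0, "degree": 1.0, "degrees": 1.0}

_NUM_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([^\s]*)\s*$")


def _parse(value, table: dict[str, float], kind: str) -> float:
    if isinstance(value, (int, float)):
        return float(value)
    m = _NUM_RE.match(str(value))
    if not m:
        raise ValueError(f"cannot parse {kind} quantity {value!r}")
    num, unit = m.groups()
    unit = unit.replace("s-1", "/s").replace("s^-1", "/s").replace(" ", "")
    if unit == "":
        return float(num)
    if unit not in table:
        raise ValueError(f"unknown {kind} unit {unit!r} in {value!r}")
    return float(num) * table[unit]


def parse_length(value) -> float:
    """Parse a length to metres ('400 um' -> 4e-4)."""
    return _parse(value, _LENGTH, "length")


def parse_time(value) -> float:
    """Parse a duration to seconds ('24 h' -> 86400)."""
    return _parse(value, _TIME, "time")


def parse_velocity(value) -> float:
    """Parse a velocity to m/s ('115 um/s' -> 1.15e-4)."""
    return _parse(value, _VELOCITY, "velocity")


def parse_angle_deg(value) -> float:
    """Parse an angle to degrees (bare numbers are degrees)."""
    if isinstance(value, (int, float)):
        return float(value)
    m = _NUM_RE.match(str(value))
    if not m:
        raise ValueError(f"cannot parse angle {value!r}")
    num, unit = m.groups()
    if unit and unit not in _ANGLE:
        raise ValueError(f"unknown angle unit {unit!r}")
    return float(num)
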