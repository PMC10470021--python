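"""Duration handling.

Killing times appear in the literature in minutes ("90 minutes"), hours
("4 hours") and days ("6.6 days"); the model works internally in days.
"""

from __future__ import annotations

import re

from .errors import DomainError

#: Conversion factors to days. "m" alone is deliberately unsupported
#: (ambiguous between minutes and months).
_TO_DAYS = {
    "d": 1.0,
    "day": 1.0,
    "days": 1.0,
    "h": 1.0 / 24.0,
    "hr": 1.0 / 24.0,
    "hour": 1.0 / 24.0,
    "hours": 1.0 / 24.0,
    "min": 1.0 / 1440.0,
    "mins": 1.0 / 1440.0,
    "minute": 1.0 / 1440.0,
    "minutes": 1.0 / 1440.0,
}

_DURATION_RE = re.compile(r"^\s*([0-9.eE+-]+)\s*([a-zA-Z]+)\s*$")


def to_days(value: float, unit: str) -> float:
    """Convert ``value`` expressed in ``unit`` to days."""
    try:
        factor = _TO_DAYS[unit.lower()]
    except KeyError:
        raise DomainError(
            f"unknown duration unit {unit!r}; use one of {sorted(set(_TO_DAYS))}"
        ) from None
    return float(value) * factor


def parse_duration(text: str | float) -> float:
    """Parse a duration like ``"90 min"``, ``"1.5h"`` or ``"6.6 days"`` to days.

    A bare number is taken to already be in days.
    """
    if isinstance(text, (int, float)):
        return float(text)
    m = _DURATION_RE.match(text)
    if m is None:
        raise DomainError(f"cannot parse duration {text!r} (expected '<number> <unit>')")
    return to_days(float(m.group(1)), m.group(2))
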