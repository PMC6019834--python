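"""Small shared helpers: display rounding and metadata stamps."""
from __future__ import annotations

import hashlib
import json
import math
from typing import Any

import numpy as np


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention of the report tables.

    Python's built-in ``round`` is banker's rounding; clinical tables
    conventionally print -2.968 as -3.0 and -7.75 as -7.8.
    """
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def display1(x: float) -> str:
    """Format a value at 1 decimal for table output."""
    v = round_half_away(x, 1)
    if math.isnan(v):
        return ""
    return f"{v:.1f}"


def config_hash(obj: Any) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""

    def _default(o: Any):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return vars(o)
        return str(o)

    payload = json.dumps(obj, sort_keys=True, default=_default)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
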