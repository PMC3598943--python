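"""Small shared helpers: half-up rounding and deterministic hashing."""

from __future__ import annotations

import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at ``ndigits`` decimals.

    Python's built-in round() is banker's rounding; printed report
    percentages use conventional half-up rounding instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: float, total: float, ndigits: int = 2) -> float:
    """100*count/total, half-up rounded; 0.0 for an empty total."""
    if total == 0:
        return 0.0
    return round_half_up(100.0 * count / total, ndigits)


def config_digest(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
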