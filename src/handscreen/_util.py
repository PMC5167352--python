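"""Small shared helpers."""

from __future__ import annotations

import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal
from typing import Any


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as clinical tables are printed.

    Python's built-in ``round`` uses banker's rounding, which would turn
    10.5% into 10%; printed report tables round half up.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def config_hash(obj: Any) -> str:
    """Short stable hash of a JSON-serialisable configuration mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
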