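"""Small shared helpers."""

from __future__ import annotations

import decimal
from typing import Any

import numpy as np
import pandas as pd


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (table-style rounding).

    Python's built-in ``round`` is banker's rounding; printed clinical
    tables conventionally round 0.5 up, so report comparisons use this.
    """
    if not np.isfinite(x):
        return x
    q = decimal.Decimal(10) ** -ndigits
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def as_mapping(record: Any) -> Any:
    """Return an attribute-or-key accessor view of a record.

    Accepts a dataclass-style object (attribute access), a ``pandas.Series``
    or a plain mapping; returns a callable ``get(field)`` that yields the
    value or ``None``/NaN for missing fields.
    """
    if isinstance(record, (dict, pd.Series)):
        def get(field: str):
            v = record.get(field, None)
            return v
    else:
        def get(field: str):
            return getattr(record, field, None)
    return get


def is_missing(value: Any) -> bool:
    if value is None:
        return True
    try:
        return bool(pd.isna(value))
    except (TypeError, ValueError):
        return False


def check_rng(seed) -> np.random.Generator:
    """Coerce a seed or Generator into a numpy Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("a seed is required for stochastic operations")
    return np.random.default_rng(seed)
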