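"""Percentage formatting with truncation semantics.

Report percentages are *truncated*, not rounded, to the requested number of
decimals (115/181 prints as 63.53, 95/181 as 52.48).  Integer arithmetic
keeps the truncation exact.
"""

from __future__ import annotations

__all__ = ["format_percent", "truncate_percent"]


def format_percent(numerator: int, denominator: int, decimals: int = 2) -> str:
    """Truncated percentage string, e.g. ``format_percent(115, 181, 2)`` -> ``'63.53'``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    if decimals < 0:
        raise ValueError("decimals must be non-negative")
    scaled = numerator * 100 * 10**decimals // denominator
    if decimals == 0:
        return str(scaled)
    digits = str(scaled).rjust(decimals + 1, "0")
    return f"{digits[:-decimals]}.{digits[-decimals:]}"


def truncate_percent(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Truncated percentage as a float (same semantics as :func:`format_percent`)."""
    return float(format_percent(numerator, denominator, decimals))
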