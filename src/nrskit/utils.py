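"""Shared report arithmetic."""

from __future__ import annotations


def percent(part: float, whole: float, decimals: int = 2) -> float:
    """Percentage of ``part`` in ``whole`` rounded for reporting."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return round(100.0 * part / whole, decimals)
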