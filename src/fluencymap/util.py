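"""Small shared helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["round_half_up", "percent_display"]


def round_half_up(x):
    """Round to nearest integer with ties away from zero on the positive side.

    Matches how study tables print percentages (16.67 → 17, 15.7 → 16);
    numpy's banker's rounding would send 0.5 ties to even instead.
    """
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, np.floor(x + 0.5), np.ceil(x - 0.5))
    if out.shape == ():
        return float(out)
    return out


def percent_display(numerator: float, denominator: float) -> int:
    """Integer percent, half-up, as printed in descriptive tables."""
    if denominator == 0:
        raise ZeroDivisionError("percent of an empty group is undefined")
    return int(round_half_up(100.0 * numerator / denominator))
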