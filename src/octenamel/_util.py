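"""Shared numeric helpers."""

from __future__ import annotations

import numpy as np


def round_half_up(x):
    """Round to the nearest integer with ties going up (0.5 -> 1).

    Deterministic across platforms, unlike banker's rounding. Intensities
    here are non-negative, so "up" and "away from zero" coincide.
    """
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def round1_half_up(x: float) -> float:
    """Round to one decimal place, half up (used for reported percentages)."""
    return float(np.floor(x * 10.0 + 0.5) / 10.0)
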