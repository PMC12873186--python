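"""Breathing-period statistics per analysis window."""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

__all__ = ["RespIndices", "breath_stats"]


@dataclass
class RespIndices:
    mean_bb: float  # s
    std_bb: float  # s, sample SD
    n_intervals: int


def breath_stats(bb, min_intervals=5):
    """Mean and sample SD of breath-to-breath intervals in a window.

    ``bb`` are inter-breath intervals (s) fully inside the window (intervals
    straddling the window edge are excluded upstream, which keeps the SD
    unbiased).  Fewer than ``min_intervals`` intervals yields missing values
    with a warning rather than an error, mirroring how short or noisy
    windows are propagated as exclusions.
    """
    bb = np.asarray(bb, dtype=float)
    if bb.size < min_intervals:
        warnings.warn(
            f"only {bb.size} breath intervals in window (< {min_intervals}); "
            "reporting missing values")
        return RespIndices(float("nan"), float("nan"), int(bb.size))
    return RespIndices(float(np.mean(bb)), float(np.std(bb, ddof=1)), int(bb.size))
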