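"""Time-domain HRV indices on a windowed RR series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TimeDomainIndices", "time_domain"]


@dataclass
class TimeDomainIndices:
    mean_rr: float  # ms
    std_rr: float  # ms, sample SD (n-1)
    rmssd: float  # ms, sqrt(mean(diff(rr)^2))


def time_domain(rr):
    """meanRR, stdRR and RMSSD of an RR interval window.

    ``rr`` is a sequence of RR intervals in ms.  stdRR uses the sample
    (n-1) convention; RMSSD is the root mean square of successive interval
    differences.  Windows of at least 60 intervals are recommended for
    short-term analysis; fewer than 2 intervals is an error.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise ValueError(f"need at least 2 RR intervals, got {rr.size}")
    d = np.diff(rr)
    return TimeDomainIndices(
        mean_rr=float(np.mean(rr)),
        std_rr=float(np.std(rr, ddof=1)),
        rmssd=float(np.sqrt(np.mean(d**2))),
    )
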