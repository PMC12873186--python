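"""Nonlinear HRV indices: sample entropy, detrended fluctuation analysis,
and Poincare-plot standard deviations.

Conventions
-----------
* Sample entropy uses the Chebyshev distance, embedding dimension ``m`` and
  tolerance ``r = r_frac * SD`` of the analyzed window, self-matches
  excluded.  ``SamEn = -ln(A/B)`` where B counts template matches of length
  m and A of length m+1 over the same N-m template starting points.
* Poincare SD1/SD2 are computed from the lag-1 scatter via the algebraic
  identities rather than a geometric ellipse fit.  The lag-1 difference
  term uses the uncentered mean square so that SD1 = RMSSD/sqrt(2) is exact,
  and the variance term uses the population (n) convention so that
  SD1^2 + SD2^2 = 2 var(rr) is exact.
* DFA integrates the mean-centered series, removes a per-box linear trend
  (non-overlapping boxes, every integer box size in range) and regresses
  log F(n) on log n over the two ranges 4-12 (a1) and 12-64 (a2) beats.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

__all__ = ["NonlinearIndices", "sample_entropy", "dfa", "poincare"]


@dataclass
class NonlinearIndices:
    samen: float
    a1: float
    a2: float
    sd1: float
    sd2: float
    sd_ratio: float  # SD1/SD2


def sample_entropy(x, m=2, r_frac=0.2):
    """Sample entropy of a series (dimensionless).

    Returns NaN (a missing value, not +-inf) when either template count is
    zero, which can happen on very short or very irregular windows.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise ValueError(f"need at least {m + 2} samples, got {n}")
    r = r_frac * np.std(x)
    # N - m templates for both lengths so the counts are comparable
    n_templ = n - m
    emb_m = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templ]
    emb_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:n_templ]

    def _count(emb):
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=-1)
        iu = np.triu_indices(emb.shape[0], k=1)
        return int(np.count_nonzero(d[iu] <= r))

    b = _count(emb_m)
    a = _count(emb_m1)
    if a == 0 or b == 0:
        warnings.warn("sample entropy undefined (no template matches); returning NaN")
        return float("nan")
    return float(-np.log(a / b))


def _fluctuation(y, n):
    """RMS residual of per-box linear detrending at box size n.

    The residual mean square uses an (n - 1) normalization per box; the
    degrees-of-freedom correction removes most of the small-box upward
    bias of least-squares detrending (white noise then scales with
    a1 ~ 0.52 over boxes 4-12, versus ~0.61 with the naive 1/n).
    """
    nb = y.size // n
    if nb < 2:
        return np.nan
    boxes = y[: nb * n].reshape(nb, n)
    t = np.arange(n, dtype=float)
    X = np.column_stack([np.ones(n), t])
    # residual projector I - X (X'X)^-1 X'
    proj = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
    res = boxes @ proj.T
    return float(np.sqrt(np.sum(res**2) / (nb * (n - 1))))


def dfa(x, short_range=(4, 12), long_range=(12, 64)):
    """DFA scaling exponents (a1, a2) of an RR window.

    a1 is fitted over box sizes 4-12 beats, a2 over 12-64 beats.  When the
    series is shorter than twice the largest box, a2 cannot be estimated
    and is returned as NaN with a warning; a degenerate series (zero
    fluctuation after detrending, e.g. a pure ramp) also yields NaN.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 * short_range[1]:
        raise ValueError(f"need at least {2 * short_range[1]} samples for a1")
    y = np.cumsum(x - np.mean(x))

    def _slope(lo, hi):
        ns = np.arange(lo, hi + 1)
        fs = np.array([_fluctuation(y, n) for n in ns])
        ok = np.isfinite(fs) & (fs > 0)
        if ok.sum() < 2:
            return float("nan")
        return float(np.polyfit(np.log(ns[ok]), np.log(fs[ok]), 1)[0])

    a1 = _slope(*short_range)
    if x.size < 2 * long_range[1]:
        warnings.warn(
            f"series too short for a2 (need {2 * long_range[1]} samples); returning NaN")
        a2 = float("nan")
    else:
        a2 = _slope(*long_range)
    return a1, a2


def poincare(rr):
    """Poincare SD1, SD2 and their ratio from the lag-1 scatter.

    SD1^2 = mean(diff^2)/2 and SD2^2 = 2 var(rr) - SD1^2 (population
    variance), so SD1 = RMSSD/sqrt(2) and SD1^2 + SD2^2 = 2 var(rr) hold
    exactly.  A constant series gives (0, 0, NaN).
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 3:
        raise ValueError(f"need at least 3 intervals, got {rr.size}")
    v = np.var(rr)  # population
    msd = np.mean(np.diff(rr) ** 2)
    sd1 = np.sqrt(msd / 2.0)
    sd2sq = 2.0 * v - msd / 2.0
    sd2 = np.sqrt(max(sd2sq, 0.0))
    ratio = sd1 / sd2 if sd2 > 0 else float("nan")
    return float(sd1), float(sd2), float(ratio)
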