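"""Raw-trace preprocessing: R-peak detection, RR correction, respiration
filtering and breath detection, respirogram construction, EDA conditioning,
and central-window extraction.

The stages mirror a standard short-term HRV pipeline: a Pan-Tompkins QRS
detector produces beat times; the tachogram is cleaned by a deterministic
median-filter rule (an automated surrogate for manual beat inspection); the
respiration belt signal is low-pass filtered at 10 Hz, downsampled to 64 Hz
and band-passed 0.05-1 Hz before positive-peak breath detection (minimum
spacing 1.5 s, i.e. a 40 breaths/min ceiling, prominence 0.2 on the
amplitude-normalized trace); the respirogram samples the conditioned
respiration at each R peak; EDA is low-pass filtered at 2.5 Hz, downsampled
to 16 Hz and z-scored.  All filters are zero-phase (symmetric FIR applied
by 'same' convolution, or forward-backward IIR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .exceptions import EmptyResultError, SignalQualityError, WindowError

__all__ = [
    "RRSeries", "Respirogram", "BreathSeries", "CleanEDA",
    "detect_r_peaks", "correct_rr", "preprocess_respiration",
    "detect_breaths", "build_respirogram", "preprocess_eda",
    "extract_central_window",
]

RESP_RATE_OUT = 64.0  # Hz, conditioned respiration rate
EDA_RATE_OUT = 16.0  # Hz, conditioned EDA rate
MIN_BREATH_SPACING = 1.5  # s <-> max 40 respirations/min


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RRSeries:
    """Tachogram: beat times (s) and RR intervals (ms), rr[k] spans beats
    k -> k+1.  ``flags`` marks per-interval correction status."""

    beat_times: np.ndarray  # (n+1,) s
    rr: np.ndarray  # (n,) ms
    flags: np.ndarray = field(default=None)  # (n,) 0=original 1=interpolated 2=removed

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(self.rr.size, dtype=np.int8)
        if self.rr.size != self.beat_times.size - 1:
            raise ValueError("len(rr) must be len(beat_times) - 1")

    @classmethod
    def from_beat_times(cls, beat_times):
        bt = np.asarray(beat_times, dtype=float)
        return cls(beat_times=bt, rr=np.diff(bt) * 1000.0)

    @property
    def n_corrected(self):
        return int(np.count_nonzero(self.flags == 1))


@dataclass
class Respirogram:
    """Respiration amplitude sampled at each R peak."""

    beat_times: np.ndarray  # (n+1,) s
    values: np.ndarray  # (n+1,) a.u.

    def __post_init__(self):
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.beat_times.size:
            raise ValueError("one respirogram value per beat")


@dataclass
class BreathSeries:
    """Breath peak times (s) and breath-to-breath intervals (s)."""

    peak_times: np.ndarray
    bb: np.ndarray

    def __post_init__(self):
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.bb = np.asarray(self.bb, dtype=float)


@dataclass
class CleanEDA:
    """Conditioned EDA: z-scored conductance at 16 Hz."""

    samples: np.ndarray
    fs: float = EDA_RATE_OUT
    mean_: float = 0.0  # pre-normalization mean, for unit bookkeeping
    sd_: float = 1.0  # pre-normalization SD

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg, fs):
    """Pan-Tompkins R-peak detection.

    Band-pass (5-15 Hz), differentiate, square, moving-window integrate
    (150 ms), then apply adaptive signal/noise thresholds with search-back
    for missed beats; peak times are refined to the local extremum of the
    band-passed trace and a 200 ms refractory period is enforced.

    Returns strictly increasing peak times in seconds.
    """
    ecg = np.asarray(ecg, dtype=float)
    if fs < 250:
        raise ValueError(f"fs must be >= 250 Hz to resolve the R peak (got {fs})")
    if ecg.size < 10 * fs:
        raise ValueError("need at least 10 s of ECG")

    sos = sps.butter(3, [5.0, 15.0], btype="band", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, ecg)
    deriv = np.gradient(bp)
    sq = deriv**2
    win = max(int(round(0.150 * fs)), 1)
    mwi = sps.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(0.2 * fs))
    cand, props = sps.find_peaks(mwi, distance=refractory)
    if cand.size == 0 or np.max(mwi) <= 0:
        raise EmptyResultError("no QRS candidates found (flat or empty trace)")

    # adaptive thresholding on the integrated signal
    init = mwi[: int(2 * fs)]
    spki = float(np.max(init)) * 0.5
    npki = float(np.mean(init)) * 0.5
    accepted = []
    last = -np.inf
    rr_hist = []

    def _thr():
        return npki + 0.25 * (spki - npki)

    for idx in cand:
        pk = mwi[idx]
        if pk > _thr():
            if accepted and rr_hist:
                avg_rr = np.mean(rr_hist[-8:])
                gap = idx - accepted[-1]
                if gap > 1.66 * avg_rr:
                    # search back in the skipped stretch at half threshold
                    lo, hi = accepted[-1] + refractory, idx - refractory
                    if hi > lo:
                        seg = [c for c in cand if lo <= c <= hi]
                        for c in seg:
                            if mwi[c] > 0.5 * _thr():
                                accepted.append(c)
                                rr_hist.append(accepted[-1] - accepted[-2])
                                spki = 0.25 * mwi[c] + 0.75 * spki
                                break
            if accepted:
                rr_hist.append(idx - accepted[-1])
            accepted.append(idx)
            spki = 0.125 * pk + 0.875 * spki
            last = idx
        else:
            npki = 0.125 * pk + 0.875 * npki

    if not accepted:
        raise EmptyResultError(
            f"no peaks above threshold (max MWI {np.max(mwi):.3g}, thr {_thr():.3g})")

    # refine to the band-passed extremum near each integrated peak
    half = int(round(0.10 * fs))
    refined = []
    for idx in accepted:
        lo, hi = max(idx - half, 0), min(idx + half + 1, ecg.size)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    refined = np.unique(refined)
    # enforce refractory: keep the larger of any pair closer than 200 ms
    keep = []
    for idx in refined:
        if keep and idx - keep[-1] < refractory:
            if np.abs(bp[idx]) > np.abs(bp[keep[-1]]):
                keep[-1] = idx
        else:
            keep.append(idx)
    return np.asarray(keep, dtype=float) / fs


# ---------------------------------------------------------------------------
# RR correction
# ---------------------------------------------------------------------------

def correct_rr(rr_raw, threshold=0.3, window=9, policy="interpolate",
               max_fraction=0.2):
    """Flag and repair artifactual RR intervals.

    Intervals deviating more than ``threshold`` (fraction) from the running
    median of ``window`` neighbors are either linearly interpolated from the
    surrounding good intervals (default) or marked removed.  The rule is
    iterated to a fixpoint (a repaired spike can expose a borderline
    neighbor), which makes the operation idempotent.  If more than
    ``max_fraction`` of intervals are flagged in total the segment is
    rejected with :class:`SignalQualityError`, mirroring exclusion of
    low-quality recordings.
    """
    if policy not in ("interpolate", "remove"):
        raise ValueError(f"unknown policy {policy!r}")
    rr = np.asarray(rr_raw.rr, dtype=float)
    n = rr.size
    if n < window:
        return RRSeries(rr_raw.beat_times.copy(), rr.copy())

    out = rr.copy()
    flags = np.zeros(n, dtype=np.int8)
    for _ in range(20):
        med = sps.medfilt(out, kernel_size=window)
        # medfilt zero-pads the edges; use local medians there instead
        edge = window // 2
        med[:edge] = np.median(out[:window])
        med[-edge:] = np.median(out[-window:])
        med = np.where(med > 0, med, np.median(out))
        bad = np.abs(out - med) > threshold * med
        frac = (bad | (flags != 0)).mean()
        if frac > max_fraction:
            raise SignalQualityError(
                f"{frac:.0%} of RR intervals flagged (> {max_fraction:.0%}); "
                "segment rejected")
        if not bad.any():
            break
        good = np.where(~bad)[0]
        if policy == "interpolate" and good.size >= 2:
            out[bad] = np.interp(np.where(bad)[0], good, out[good])
            flags[bad] = 1
        else:
            flags[bad] = 2
            break
    return RRSeries(rr_raw.beat_times.copy(), out, flags)


# ---------------------------------------------------------------------------
# respiration
# ---------------------------------------------------------------------------

def _kaiser_lowpass(x, fs, cutoff, width_hz=None, atten_db=60.0):
    """Zero-phase FIR low-pass: symmetric Kaiser-window kernel applied with
    'same' FFT convolution (linear phase compensated exactly)."""
    if width_hz is None:
        width_hz = cutoff / 2.0
    numtaps, beta = sps.kaiserord(atten_db, width_hz / (0.5 * fs))
    numtaps |= 1  # odd length -> integer group delay, exact zero phase
    taps = sps.firwin(numtaps, cutoff, window=("kaiser", beta), fs=fs)
    # reflect-pad so the kernel never sees an artificial step at the edges
    half = numtaps // 2
    xp = np.pad(x, half, mode="reflect")
    return sps.fftconvolve(xp, taps, mode="same")[half:half + x.size]


def preprocess_respiration(resp, fs):
    """Condition a raw respiration trace to the 64 Hz band-passed signal.

    Low-pass at 10 Hz (zero-phase Kaiser FIR, >= 60 dB stop-band),
    downsample to 64 Hz, band-pass 0.05-1 Hz (4th-order Butterworth,
    forward-backward).  Requires at least 60 s of signal so the band-pass
    transient does not dominate.
    """
    resp = np.asarray(resp, dtype=float)
    if resp.size < 60 * fs:
        raise ValueError("need at least 60 s of respiration signal")
    factor = fs / RESP_RATE_OUT
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"fs {fs} is not an integer multiple of {RESP_RATE_OUT} Hz")
    lp = _kaiser_lowpass(resp, fs, cutoff=10.0, width_hz=4.0)
    ds = lp[:: int(round(factor))]
    sos = sps.butter(4, [0.05, 1.0], btype="band", fs=RESP_RATE_OUT, output="sos")
    return sps.sosfiltfilt(sos, ds)


def detect_breaths(filtered_resp, fs=RESP_RATE_OUT, prominence=0.2,
                   min_distance=MIN_BREATH_SPACING):
    """Detect breaths as positive peaks of the conditioned respiration.

    Prominence is interpreted on the max-abs-normalized trace; the minimum
    peak spacing of 1.5 s corresponds to a 40 breaths/min ceiling.  Fewer
    than 2 peaks yields an empty series (downstream features report
    missing values).
    """
    x = np.asarray(filtered_resp, dtype=float)
    scale = np.max(np.abs(x))
    if scale <= 0:
        return BreathSeries(np.array([]), np.array([]))
    xn = x / scale
    peaks, _ = sps.find_peaks(xn, prominence=prominence,
                              distance=max(int(round(min_distance * fs)), 1))
    times = peaks / fs
    if times.size < 2:
        return BreathSeries(times, np.array([]))
    return BreathSeries(times, np.diff(times))


def build_respirogram(filtered_resp, beat_times, fs=RESP_RATE_OUT):
    """Sample the conditioned respiration at each R peak (nearest sample)."""
    x = np.asarray(filtered_resp, dtype=float)
    bt = np.asarray(beat_times, dtype=float)
    idx = np.round(bt * fs).astype(int)
    if np.any(idx < 0) or np.any(idx >= x.size):
        raise ValueError("beat time outside the respiration trace span")
    return Respirogram(beat_times=bt, values=x[idx])


# ---------------------------------------------------------------------------
# EDA
# ---------------------------------------------------------------------------

def preprocess_eda(eda, fs):
    """Condition raw EDA: zero-phase 2.5 Hz low-pass (Kaiser FIR),
    downsample to 16 Hz, z-score over the full recording."""
    eda = np.asarray(eda, dtype=float)
    factor = fs / EDA_RATE_OUT
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"fs {fs} is not an integer multiple of {EDA_RATE_OUT} Hz")
    lp = _kaiser_lowpass(eda, fs, cutoff=2.5, width_hz=1.0)
    ds = lp[:: int(round(factor))]
    mu = float(np.mean(ds))
    sd = float(np.std(ds))
    # guard against pure roundoff "variance" of a constant trace
    if sd <= 1e-10 * max(abs(mu), 1.0):
        raise ValueError("zero-variance EDA trace; cannot z-score")
    return CleanEDA(samples=(ds - mu) / sd, fs=EDA_RATE_OUT, mean_=mu, sd_=sd)


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def _window_bounds(phase_bounds, width):
    t0, t1 = float(phase_bounds[0]), float(phase_bounds[1])
    if t1 - t0 < width - 1e-9:
        raise WindowError(
            f"phase of {t1 - t0:.1f} s shorter than the {width:.0f} s analysis window")
    mid = 0.5 * (t0 + t1)
    return mid - width / 2.0, mid + width / 2.0


def extract_central_window(series, phase_bounds, width=240.0):
    """Restrict a series to the central ``width`` seconds of a phase.

    The window is centered on the arithmetic midpoint of the phase span and
    is applied uniformly to all series types before feature computation:

    * :class:`RRSeries` -> beats inside the window and the intervals between
      consecutive kept beats;
    * :class:`Respirogram` -> values at the kept beats;
    * :class:`BreathSeries` -> intervals whose both endpoints lie inside;
    * :class:`CleanEDA` -> the sample slice (fs-aligned);
    * a plain ``(times, values)`` tuple -> masked values.
    """
    lo, hi = _window_bounds(phase_bounds, width)
    if isinstance(series, RRSeries):
        mask = (series.beat_times >= lo) & (series.beat_times <= hi)
        bt = series.beat_times[mask]
        if bt.size < 2:
            return RRSeries(bt, np.array([]), np.array([], dtype=np.int8))
        # keep intervals between consecutive kept beats
        imask = mask[:-1] & mask[1:]
        return RRSeries(bt, series.rr[imask], series.flags[imask])
    if isinstance(series, Respirogram):
        mask = (series.beat_times >= lo) & (series.beat_times <= hi)
        return Respirogram(series.beat_times[mask], series.values[mask])
    if isinstance(series, BreathSeries):
        pt = series.peak_times
        mask = (pt >= lo) & (pt <= hi)
        kept = pt[mask]
        bb = np.diff(kept) if kept.size >= 2 else np.array([])
        return BreathSeries(kept, bb)
    if isinstance(series, CleanEDA):
        i0 = int(np.ceil(lo * series.fs))
        i1 = int(np.floor(hi * series.fs)) + 1
        i0 = max(i0, 0)
        i1 = min(i1, series.samples.size)
        return CleanEDA(series.samples[i0:i1], series.fs, series.mean_, series.sd_)
    if isinstance(series, tuple) and len(series) == 2:
        t, v = np.asarray(series[0]), np.asarray(series[1])
        mask = (t >= lo) & (t <= hi)
        return t[mask], v[mask]
    raise TypeError(f"unsupported series type {type(series).__name__}")
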