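"""Assembly of the subject x phase feature table.

Two routes produce identical table layouts:

* the **raw route** runs the complete chain on a recorded/synthesized
  session: R-peak detection, RR correction, respiration conditioning,
  breath detection, respirogram sampling, EDA conditioning and
  decomposition, then all indices on the central four minutes of each
  phase;
* the **beat route** starts from beat-level series (tachogram,
  respirogram, breath times, SCR events) — the generator's recorded truth
  realizations — skipping the raw-trace detectors.  It exists for large
  simulation studies where synthesizing and re-detecting thousands of raw
  traces adds cost but no information about the stages under study.

Feature columns: meanRR, stdRR, RMSSD (ms); LF, HF (ms^2), LF_HF, LFnorm,
HFnorm (%); PCOH (RSA index), PNCOH (ms^2), PNCOH_PCOH; SamEn, a1, a2;
SD1, SD2 (s), SD1_SD2; meanBB, stdBB (s); nSCR (per minute), SCR, AmpSum
(normalized units).  Nonlinear Poincare indices are computed on the RR
series in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import hrv_nonlinear as nl
from . import hrv_time as td
from . import resp_features as rf
from . import spectral as sp
from .eda_features import EDADecomposer, phasic_features
from .preprocess import (BreathSeries, Respirogram, RRSeries,
                         build_respirogram, correct_rr, detect_breaths,
                         detect_r_peaks, extract_central_window,
                         preprocess_eda, preprocess_respiration)

__all__ = ["FeatureConfig", "phase_features", "session_feature_rows",
           "truth_feature_rows", "assemble_feature_table",
           "cohort_feature_table"]

FEATURE_COLUMNS = (
    "meanRR", "stdRR", "RMSSD", "LF", "HF", "LF_HF", "LFnorm", "HFnorm",
    "PCOH", "PNCOH", "PNCOH_PCOH", "SamEn", "a1", "a2", "SD1", "SD2",
    "SD1_SD2", "meanBB", "stdBB", "nSCR", "SCR", "AmpSum",
)


@dataclass
class FeatureConfig:
    """Knobs of the feature extraction chain."""

    window: float = 240.0  # s, central analysis window per phase
    order_range: tuple = (7, 15)  # AR order range
    correction_threshold: float = 0.3  # RR median-filter rule
    prominence: float = 0.2  # breath peak prominence
    scr_min_amplitude: float = 0.01  # normalized units
    samen_m: int = 2
    samen_r: float = 0.2
    nonlinear_units: str = "s"  # "s" or "ms" for Poincare/DFA/SamEn input


def _nan_features():
    return {k: float("nan") for k in FEATURE_COLUMNS}


def phase_features(rr_win, respirogram_win, breaths_win, eda_feats,
                   config=None):
    """All indices of one windowed phase.

    ``rr_win``/``respirogram_win``/``breaths_win`` are the windowed series;
    ``eda_feats`` an :class:`EDAPhasicFeatures` (or None).  Stages that
    cannot run (too few beats, unstable AR fit) contribute missing values
    and a warning instead of failing the whole row.
    """
    cfg = config or FeatureConfig()
    out = _nan_features()

    rr = np.asarray(rr_win.rr, dtype=float)
    if rr.size >= 60:
        t = td.time_domain(rr)
        out.update(meanRR=t.mean_rr, stdRR=t.std_rr, RMSSD=t.rmssd)

        scale = 1000.0 if cfg.nonlinear_units == "s" else 1.0
        rr_nl = rr / scale
        try:
            out["SamEn"] = nl.sample_entropy(rr_nl, m=cfg.samen_m, r_frac=cfg.samen_r)
        except ValueError as e:
            warnings.warn(f"sample entropy skipped: {e}")
        try:
            a1, a2 = nl.dfa(rr_nl)
            out.update(a1=a1, a2=a2)
        except ValueError as e:
            warnings.warn(f"DFA skipped: {e}")
        sd1, sd2, ratio = nl.poincare(rr_nl)
        out.update(SD1=sd1, SD2=sd2, SD1_SD2=ratio)

        rr_d = sp.detrend_linear(rr)
        T = float(np.mean(rr)) / 1000.0
        try:
            ar = sp.fit_ar(rr_d, p_range=cfg.order_range, T=T)
            bands = ar.band_powers()
            out.update(LF=bands.lf, HF=bands.hf, LF_HF=bands.lf_hf,
                       LFnorm=bands.lf_norm, HFnorm=bands.hf_norm)
        except ValueError as e:
            warnings.warn(f"univariate AR skipped: {e}")
        if respirogram_win is not None and respirogram_win.values.size == rr.size + 1:
            resp_d = sp.detrend_linear(respirogram_win.values[:-1])
            try:
                biv = sp.fit_bivar_ar(rr_d, resp_d, p_range=cfg.order_range, T=T)
                out.update(PCOH=biv.pcoh_, PNCOH=biv.pncoh_, PNCOH_PCOH=biv.ratio_)
            except ValueError as e:
                warnings.warn(f"bivariate AR skipped: {e}")
    else:
        warnings.warn(f"only {rr.size} RR intervals in window; HRV indices missing")

    if breaths_win is not None:
        r = rf.breath_stats(breaths_win.bb)
        out.update(meanBB=r.mean_bb, stdBB=r.std_bb)

    if eda_feats is not None:
        out.update(nSCR=eda_feats.nscr_per_min, SCR=eda_feats.scr_mean,
                   AmpSum=eda_feats.amp_sum)
    return out


# ---------------------------------------------------------------------------
# raw route
# ---------------------------------------------------------------------------

def session_feature_rows(session, config=None):
    """Run the full chain on one session; one row dict per phase."""
    cfg = config or FeatureConfig()
    peaks = detect_r_peaks(session.ecg, session.fs_ecg)
    rr_raw = RRSeries.from_beat_times(peaks)
    rr_all = correct_rr(rr_raw, threshold=cfg.correction_threshold)

    filt = preprocess_respiration(session.resp, session.fs_resp)
    breaths = detect_breaths(filt, prominence=cfg.prominence)
    respirogram = build_respirogram(filt, rr_all.beat_times)

    clean = preprocess_eda(session.eda, session.fs_eda)
    eda_dec = EDADecomposer(min_amplitude=cfg.scr_min_amplitude).fit(clean)
    decomposition = eda_dec.decomposition()

    rows = []
    for phase, bounds in session.phase_bounds.items():
        rr_w = extract_central_window(rr_all, bounds, cfg.window)
        rg_w = extract_central_window(respirogram, bounds, cfg.window)
        br_w = extract_central_window(breaths, bounds, cfg.window)
        mid = 0.5 * (bounds[0] + bounds[1])
        win = (mid - cfg.window / 2, mid + cfg.window / 2)
        ef = phasic_features(decomposition, win)
        row = {"subject": session.subject_id, "group": session.group,
               "phase": phase}
        row.update(phase_features(rr_w, rg_w, br_w, ef, cfg))
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# beat route
# ---------------------------------------------------------------------------

def _true_breath_peaks(onsets):
    """Peak times of the sinusoidal cycle model: quarter period into each
    cycle."""
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 2:
        return np.array([])
    return onsets[:-1] + 0.25 * np.diff(onsets)


def truth_feature_rows(truth, config=None, with_eda=True, eda_noise_sd=0.005,
                       eda_fs=256.0, phases=None):
    """Feature rows from a subject's beat-level truth realizations.

    EDA features still run through the conditioning + decomposition chain
    (per-phase trace synthesized from the true SCR events); set
    ``with_eda=False`` to skip them entirely.
    """
    from .synthetic import PHASES, generate_beats, synthesize_eda

    cfg = config or FeatureConfig()
    if set(truth.rr.keys()) != set(PHASES):
        generate_beats(truth)
    rows = []
    rng = np.random.default_rng(truth.seed + 7)
    for phase in (phases or PHASES):
        p = truth.phases[phase]
        bounds = (0.0, p.duration)
        bt = truth.beat_times[phase]
        rr_series = RRSeries(np.append(bt, bt[-1] + truth.rr[phase][-1] / 1000.0),
                             truth.rr[phase])
        rg = Respirogram(rr_series.beat_times,
                         np.append(truth.respirogram[phase],
                                   truth.respirogram[phase][-1]))
        br = BreathSeries(_true_breath_peaks(truth.breath_onsets[phase]), np.array([]))
        br = BreathSeries(br.peak_times, np.diff(br.peak_times))

        rr_w = extract_central_window(rr_series, bounds, cfg.window)
        rg_w = extract_central_window(rg, bounds, cfg.window)
        br_w = extract_central_window(br, bounds, cfg.window)

        ef = None
        if with_eda:
            trace = synthesize_eda(truth.scr_events[phase], truth.tonic_slope,
                                   p.duration, fs=eda_fs, noise_sd=eda_noise_sd,
                                   seed=int(rng.integers(2**31)))
            clean = preprocess_eda(trace, eda_fs)
            dec = EDADecomposer(min_amplitude=cfg.scr_min_amplitude).fit(clean)
            mid = p.duration / 2
            ef = phasic_features(dec.decomposition(),
                                 (mid - cfg.window / 2, mid + cfg.window / 2))
        row = {"subject": truth.subject_id, "group": truth.group, "phase": phase}
        row.update(phase_features(rr_w, rg_w, br_w, ef, cfg))
        rows.append(row)
    return rows


def assemble_feature_table(rows):
    """Tidy subject x phase DataFrame from row dicts."""
    df = pd.DataFrame(rows)
    lead = ["subject", "group", "phase"]
    return df[lead + [c for c in FEATURE_COLUMNS if c in df.columns]]


def cohort_feature_table(cohort, config=None, route="auto", **kwargs):
    """Feature table of a list of sessions or truths."""
    rows = []
    for item in cohort:
        if route == "raw" or (route == "auto" and hasattr(item, "ecg")):
            rows.extend(session_feature_rows(item, config))
        else:
            rows.extend(truth_feature_rows(item, config, **kwargs))
    return assemble_feature_table(rows)
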