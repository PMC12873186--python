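"""Synthetic multi-subject session generator with known ground truth.

The generator realizes the two-component HRV model the analysis assumes:
each beat's RR interval is a phase-level mean plus a respiration-driven
(coherent) part and an independent AR(2) noise (not-coherent) part,

    RR(n) = meanRR + g * resp(n - lag) + e(n),

where ``resp`` is the respirogram (unit-RMS quasi-periodic respiration
sampled at the beats), ``g`` the respiration-to-RR gain in ms, and ``e`` an
AR(2) process with a low-frequency resonance so the univariate LF band is
non-empty.  The coupling acts with a one-beat lag by default, which keeps
the innovations of the two channels uncorrelated — the regime in which the
coherent/not-coherent power split of the bivariate AR model is exactly
defined; ``lag=0`` (instantaneous) is available.

Raw traces are synthesized on top of the beat-level truth: an ECG as a
template R deflection placed at the cumulative beat times (2048 Hz), a
respiration belt trace as a unit sinusoid of the breathing phase (2048 Hz),
and EDA as tonic drift plus Bateman-kernel responses at known event times
(256 Hz).  Group/phase effects (task tachycardia, reduced RR variability
and respiratory period, larger electrodermal responses, an extra MIST
effect in the STRESS group) are configurable; their default signs follow
the stress-physiology expectations and their magnitudes are configuration,
not claims.

Everything is driven by ``numpy.random.default_rng`` seed sequences:
identical seeds give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .eda_features import bateman_kernel

__all__ = [
    "PHASES", "PhaseParams", "EffectConfig", "SyntheticTruth", "Session",
    "generate_rr_with_respiration", "synthesize_ecg", "synthesize_respiration",
    "synthesize_eda", "make_truth", "generate_session", "generate_cohort",
    "generate_beat_cohort",
]

PHASES = ("REST", "MIST", "MGT", "VS")
GROUPS = ("STRESS", "CONTROL")

ECG_FS = 2048.0
RESP_FS = 2048.0
EDA_FS = 256.0

_MIN_BREATH_PERIOD = 1.5  # s, detector floor
_RR_BOUNDS = (300.0, 2000.0)  # ms, physiologic clip


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class PhaseParams:
    """Generating parameters of one protocol phase for one subject."""

    mean_rr: float  # ms
    noise_var: float  # ms^2, process variance of the AR noise
    gain: float  # ms per unit respirogram amplitude
    breath_period_mean: float  # s
    breath_period_sd: float  # s
    scr_rate: float  # events per minute
    scr_amp_mean: float  # conductance units
    duration: float  # s

    def validate(self):
        if self.noise_var <= 0:
            raise ValueError("noise variance must be > 0")
        if not (2.0 <= self.breath_period_mean <= 12.0):
            raise ValueError("breath period mean must lie in [2, 12] s")
        if self.breath_period_sd < 0:
            raise ValueError("breath period SD must be >= 0")
        if self.duration < 240.0:
            raise ValueError("phase durations must be >= 4 min")
        if self.scr_rate < 0 or self.scr_amp_mean < 0:
            raise ValueError("SCR rate and amplitude must be >= 0")


@dataclass
class EffectConfig:
    """Cohort-level generating configuration.

    ``*_task`` values apply to MIST/MGT/VS; the MIST-specific extra RR drop
    applies only to the STRESS group.  Between-subject variability is a
    multiplicative log-normal jitter of coefficient ``between_cv`` on the
    positive parameters and an additive normal spread on meanRR.
    """

    rr_rest: float = 750.0  # ms
    rr_between_sd: float = 60.0  # ms
    rr_task_delta: float = -35.0  # ms, tasks vs REST
    rr_mist_stress_extra: float = -30.0  # ms, STRESS group during MIST only
    noise_var_rest: float = 2100.0  # ms^2
    noise_var_task: float = 1400.0
    gain_rest: float = 23.0  # ms
    gain_task: float = 16.0
    breath_mean_rest: float = 3.9  # s
    breath_mean_task: float = 3.2
    breath_sd_rest: float = 1.0  # s
    breath_sd_task: float = 0.75
    scr_rate_rest: float = 6.0  # per min
    scr_rate_task: float = 10.0
    scr_amp_rest: float = 0.3  # conductance units
    scr_amp_task: float = 0.5
    suds_pre: float = 30.0
    suds_post_mist_delta_control: float = 5.0
    suds_post_mist_delta_stress: float = 25.0
    suds_sd: float = 10.0
    cortisol_mean: float = 0.26  # ug/dL
    cortisol_cv: float = 0.5
    durations: tuple = (300.0, 360.0, 300.0, 300.0)  # REST, MIST, MGT, VS (s)
    between_cv: float = 0.15
    ar_pole_modulus: float = 0.85  # AR(2) noise resonance sharpness
    ar_pole_freq: float = 0.09  # Hz, low-frequency resonance
    coupling_lag: int = 1  # beats
    eda_noise_sd: float = 0.005  # conductance units at the raw rate
    ecg_noise_sd: float = 0.0  # fraction of R amplitude
    tonic_slope: float = 0.002  # conductance units / s

    @classmethod
    def null(cls, **overrides):
        """No systematic phase or group effects (type-I-error studies)."""
        cfg = cls(rr_task_delta=0.0, rr_mist_stress_extra=0.0,
                  noise_var_task=2100.0, gain_task=23.0,
                  breath_mean_task=3.9, breath_sd_task=1.0,
                  scr_rate_task=6.0, scr_amp_task=0.3,
                  suds_post_mist_delta_stress=5.0)
        return replace(cfg, **overrides)


@dataclass
class SyntheticTruth:
    """Per-subject generating parameters and recorded realizations."""

    subject_id: str
    group: str
    phases: dict  # phase -> PhaseParams
    suds: dict  # collection point -> score (0-100)
    cortisol: tuple  # (t0, t1, t2) ug/dL
    seed: int
    coupling_lag: int = 1
    ar_pole_modulus: float = 0.85
    ar_pole_freq: float = 0.09
    tonic_slope: float = 0.002
    # realizations, filled during generation (per phase)
    beat_times: dict = field(default_factory=dict)  # phase -> s (relative)
    rr: dict = field(default_factory=dict)  # phase -> ms
    respirogram: dict = field(default_factory=dict)  # phase -> unit amplitude
    breath_onsets: dict = field(default_factory=dict)  # phase -> s (relative)
    scr_events: dict = field(default_factory=dict)  # phase -> [(t_rel, amp)]
    coherent_fraction: dict = field(default_factory=dict)  # phase -> [0, 1]

    def validate(self):
        for p in self.phases.values():
            p.validate()


@dataclass
class Session:
    """Raw multimodal recording of one subject."""

    subject_id: str
    group: str
    ecg: np.ndarray  # a.u. at fs_ecg
    resp: np.ndarray  # a.u. at fs_resp
    eda: np.ndarray  # conductance units at fs_eda
    fs_ecg: float
    fs_resp: float
    fs_eda: float
    phase_bounds: dict  # phase -> (t0, t1) s
    suds: dict
    cortisol: tuple

    def validate(self):
        dur = max(b[1] for b in self.phase_bounds.values())
        for name, x, fs in (("ecg", self.ecg, self.fs_ecg),
                            ("resp", self.resp, self.fs_resp),
                            ("eda", self.eda, self.fs_eda)):
            if np.any(~np.isfinite(x)):
                raise ValueError(f"{name} contains non-finite samples")
            if abs(x.size / fs - dur) > 1.0:
                raise ValueError(f"{name} length inconsistent with phase bounds")


# ---------------------------------------------------------------------------
# breathing phase helper
# ---------------------------------------------------------------------------

def _draw_breath_onsets(period_mean, period_sd, duration, rng):
    """Cycle onset times covering [0, duration]; periods truncated >= 1.5 s."""
    if not (2.0 <= period_mean <= 12.0):
        raise ValueError("breath period mean must lie in [2, 12] s "
                         "(below 2 s is under the detectability floor)")
    n = int(np.ceil(duration / max(period_mean - 3 * period_sd, _MIN_BREATH_PERIOD))) + 3
    if period_sd > 0:
        periods = np.maximum(rng.normal(period_mean, period_sd, n), _MIN_BREATH_PERIOD)
    else:
        periods = np.full(n, period_mean)
    onsets = np.concatenate([[0.0], np.cumsum(periods)])
    return onsets[onsets <= duration + 2 * period_mean]


def _breath_phase(t, onsets):
    """Continuous cycle index at times t (piecewise-linear in each cycle)."""
    return np.interp(t, onsets, np.arange(onsets.size, dtype=float))


@njit(cache=True)
def _beat_loop(mean_rr, gain, lag, e, onsets, duration):
    """Sequential beat placement with respirogram coupling.

    Returns (beat_times, rr_ms, respirogram) where rr[k] is the interval
    from beat k to beat k+1 and respirogram[k] the unit-RMS respiration
    amplitude at beat k.
    """
    nmax = e.size
    times = np.empty(nmax)
    rr = np.empty(nmax)
    resp = np.empty(nmax)
    t = 0.0
    k = 0
    non = onsets.size
    while k < nmax:
        # locate t in the onset grid (piecewise-linear cycle index)
        if t <= onsets[0]:
            idx = 0.0
        elif t >= onsets[non - 1]:
            idx = float(non - 1)
        else:
            j = np.searchsorted(onsets, t) - 1
            idx = j + (t - onsets[j]) / (onsets[j + 1] - onsets[j])
        r = np.sqrt(2.0) * np.sin(2.0 * np.pi * idx)
        resp[k] = r
        r_eff = resp[k - lag] if k >= lag else r
        rr_k = mean_rr + gain * r_eff + e[k]
        if rr_k < 300.0:
            rr_k = 300.0
        elif rr_k > 2000.0:
            rr_k = 2000.0
        times[k] = t
        rr[k] = rr_k
        t += rr_k / 1000.0
        k += 1
        if t > duration:
            break
    return times[:k], rr[:k], resp[:k]


def _ar2_noise(n, process_var, rho, f_hz, T, rng):
    """AR(2) noise with poles at modulus rho and frequency f_hz, scaled to
    the requested process variance; 500-sample burn-in discarded."""
    from scipy.signal import lfilter

    if process_var <= 0:
        raise ValueError("noise variance must be > 0")
    w = 2.0 * np.pi * f_hz * T
    p1, p2 = 2.0 * rho * np.cos(w), -(rho**2)
    varfac = (1.0 - p2) / ((1.0 + p2) * ((1.0 - p2) ** 2 - p1**2))
    innov_sd = np.sqrt(process_var / varfac)
    e = lfilter([1.0], [1.0, -p1, -p2], rng.standard_normal(n + 500) * innov_sd)
    return e[500:]


# ---------------------------------------------------------------------------
# primitive generators
# ---------------------------------------------------------------------------

def generate_rr_with_respiration(truth, phase, seed=None, rng=None):
    """Generate the beat-aligned RR series and respirogram of one phase.

    Realizes ``RR(n) = meanRR + g * resp(n - lag) + e(n)`` and records the
    realized coherent-power fraction ``var(g * resp_used) / var(RR - mean)``
    in ``truth.coherent_fraction[phase]``.  Returns ``(rr_ms, respirogram)``;
    beat times and breath onsets are stored in the truth object.
    """
    p = truth.phases[phase]
    p.validate()
    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else truth.seed)
    onsets = _draw_breath_onsets(p.breath_period_mean, p.breath_period_sd,
                                 p.duration, rng)
    T = p.mean_rr / 1000.0
    nmax = int(np.ceil(p.duration / (_RR_BOUNDS[0] / 1000.0))) + 2
    e = _ar2_noise(nmax, p.noise_var, truth.ar_pole_modulus,
                   truth.ar_pole_freq, T, rng)
    bt, rr, resp = _beat_loop(p.mean_rr, p.gain, int(truth.coupling_lag),
                              e, onsets, p.duration)
    lag = int(truth.coupling_lag)
    resp_used = resp if lag == 0 else np.concatenate([resp[:1].repeat(lag), resp[:-lag]])
    denom = np.var(rr)
    truth.coherent_fraction[phase] = float(
        p.gain**2 * np.var(resp_used) / denom) if denom > 0 else 0.0
    truth.beat_times[phase] = bt
    truth.rr[phase] = rr
    truth.respirogram[phase] = resp
    truth.breath_onsets[phase] = onsets
    return rr, resp


def synthesize_ecg(rr_ms, fs=ECG_FS, noise_sd=0.0, seed=None, beat_times=None):
    """Synthetic single-lead ECG from an RR series.

    A template R deflection (Gaussian, 10 ms SD, unit amplitude) is placed
    at the cumulative RR times over a zero baseline, with optional additive
    white noise (``noise_sd`` in units of the R amplitude).  Returns
    ``(trace, peak_times)``; the true peak times are retained for detector
    validation.
    """
    rr_ms = np.asarray(rr_ms, dtype=float)
    if fs < 250:
        raise ValueError("fs must be >= 250 Hz (R peak undersampled)")
    if rr_ms.size == 0:
        raise ValueError("empty RR series")
    if beat_times is None:
        # physiologic bounds apply to a true RR series; explicit beat times
        # (e.g. spanning phase-boundary gaps) bypass the check
        if np.any((rr_ms < _RR_BOUNDS[0]) | (rr_ms > _RR_BOUNDS[1])):
            raise ValueError(f"RR intervals must lie in {_RR_BOUNDS} ms")
        beat_times = np.concatenate([[0.0], np.cumsum(rr_ms) / 1000.0])
    n = int(round(beat_times[-1] * fs)) + 1
    trace = np.zeros(n)
    sigma = 0.010  # s
    half = int(round(4 * sigma * fs))
    tt = np.arange(-half, half + 1) / fs
    template = np.exp(-(tt**2) / (2 * sigma**2))
    for t in beat_times:
        c = int(round(t * fs))
        lo, hi = max(c - half, 0), min(c + half + 1, n)
        trace[lo:hi] += template[lo - (c - half): hi - (c - half)]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_sd, n)
    return trace, beat_times


def synthesize_respiration(period_mean, period_sd, duration, fs=RESP_FS, seed=None):
    """Quasi-periodic respiration trace with known cycle onsets.

    Concatenated sinusoid-like cycles whose periods are drawn with the
    stated mean/SD (truncated at the 1.5 s detectability floor).  Returns
    ``(trace, onsets)``.
    """
    rng = np.random.default_rng(seed)
    onsets = _draw_breath_onsets(period_mean, period_sd, duration, rng)
    t = np.arange(int(round(duration * fs))) / fs
    return np.sin(2.0 * np.pi * _breath_phase(t, onsets)), onsets


def synthesize_eda(scr_events, tonic_slope, duration, fs=EDA_FS, noise_sd=0.0,
                   seed=None, tau1=0.75, tau2=2.0, baseline=4.0):
    """Synthetic EDA: linear tonic drift + Bateman-kernel SCRs + noise."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    trace = baseline + tonic_slope * t
    h = bateman_kernel(fs, tau1, tau2)
    for ev_t, amp in scr_events:
        if not (0.0 <= ev_t < duration):
            raise ValueError(f"SCR event time {ev_t} outside [0, {duration})")
        if amp < 0:
            raise ValueError("SCR amplitudes must be >= 0")
        i = int(round(ev_t * fs))
        seg = h[: n - i]
        trace[i : i + seg.size] += amp * seg
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_sd, n)
    return trace


# ---------------------------------------------------------------------------
# subjects and cohorts
# ---------------------------------------------------------------------------

def _jitter(rng, value, cv):
    """Multiplicative log-normal jitter with unit median."""
    return value * np.exp(rng.normal(0.0, cv)) if cv > 0 else value


def make_truth(subject_id, group, config=None, seed=0):
    """Draw one subject's generating parameters from an :class:`EffectConfig`."""
    cfg = config or EffectConfig()
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    rng = np.random.default_rng(seed)
    base_rr = cfg.rr_rest + rng.normal(0.0, cfg.rr_between_sd)
    base_rr = float(np.clip(base_rr, 550.0, 1100.0))
    cv = cfg.between_cv
    subj = dict(
        noise_var=_jitter(rng, cfg.noise_var_rest, cv),
        gain=_jitter(rng, cfg.gain_rest, cv),
        breath_mean=float(np.clip(_jitter(rng, cfg.breath_mean_rest, cv), 2.2, 11.0)),
        breath_sd=_jitter(rng, cfg.breath_sd_rest, cv),
        scr_rate=_jitter(rng, cfg.scr_rate_rest, cv),
        scr_amp=_jitter(rng, cfg.scr_amp_rest, cv),
    )
    # phase effects as ratios of the cohort-level REST/task parameters
    def ratio(task_v, rest_v):
        return task_v / rest_v if rest_v != 0 else 1.0

    phases = {}
    for ph, dur in zip(PHASES, cfg.durations):
        task = ph != "REST"
        mean_rr = base_rr + (cfg.rr_task_delta if task else 0.0)
        if ph == "MIST" and group == "STRESS":
            mean_rr += cfg.rr_mist_stress_extra
        phases[ph] = PhaseParams(
            mean_rr=float(np.clip(mean_rr, *_RR_BOUNDS)),
            noise_var=subj["noise_var"] * (ratio(cfg.noise_var_task, cfg.noise_var_rest) if task else 1.0),
            gain=subj["gain"] * (ratio(cfg.gain_task, cfg.gain_rest) if task else 1.0),
            breath_period_mean=float(np.clip(
                subj["breath_mean"] * (ratio(cfg.breath_mean_task, cfg.breath_mean_rest) if task else 1.0),
                2.0, 12.0)),
            breath_period_sd=subj["breath_sd"] * (ratio(cfg.breath_sd_task, cfg.breath_sd_rest) if task else 1.0),
            scr_rate=subj["scr_rate"] * (ratio(cfg.scr_rate_task, cfg.scr_rate_rest) if task else 1.0),
            scr_amp_mean=subj["scr_amp"] * (ratio(cfg.scr_amp_task, cfg.scr_amp_rest) if task else 1.0),
            duration=float(dur),
        )
    suds_pre = float(np.clip(rng.normal(cfg.suds_pre, cfg.suds_sd), 0, 100))
    d_mist = (cfg.suds_post_mist_delta_stress if group == "STRESS"
              else cfg.suds_post_mist_delta_control)
    suds = {
        "pre": suds_pre,
        "post_mist": float(np.clip(suds_pre + rng.normal(d_mist, cfg.suds_sd), 0, 100)),
        "post_mgt": float(np.clip(suds_pre + rng.normal(d_mist / 2.0, cfg.suds_sd), 0, 100)),
    }
    lcv = np.sqrt(np.log(1.0 + cfg.cortisol_cv**2))
    mu = np.log(cfg.cortisol_mean) - lcv**2 / 2.0
    cortisol = tuple(float(np.exp(rng.normal(mu, lcv))) for _ in range(3))
    truth = SyntheticTruth(
        subject_id=str(subject_id), group=group, phases=phases, suds=suds,
        cortisol=cortisol, seed=int(seed), coupling_lag=cfg.coupling_lag,
        ar_pole_modulus=cfg.ar_pole_modulus, ar_pole_freq=cfg.ar_pole_freq,
        tonic_slope=cfg.tonic_slope,
    )
    truth.validate()
    return truth


def _draw_scr_events(p, rng, margin=25.0):
    """Poisson SCR events within one phase (times relative to phase start).

    Events are kept ``margin`` seconds away from the phase edges so that
    every response and its decomposition support lie inside the phase.
    """
    span = p.duration - 2 * margin
    if span <= 0 or p.scr_rate <= 0:
        return []
    n = rng.poisson(p.scr_rate * span / 60.0)
    times = np.sort(rng.uniform(margin, p.duration - margin, n))
    # enforce a minimal 2 s spacing for identifiability bookkeeping
    kept = []
    for t in times:
        if not kept or t - kept[-1] >= 2.0:
            kept.append(float(t))
    amps = rng.gamma(4.0, p.scr_amp_mean / 4.0, len(kept))
    return [(t, float(a)) for t, a in zip(kept, amps)]


def generate_beats(truth, rng=None):
    """Generate beat-level realizations (RR, respirogram, breaths, SCR
    events) for every phase of one subject."""
    rng = rng or np.random.default_rng(truth.seed)
    for ph in PHASES:
        generate_rr_with_respiration(truth, ph, rng=rng)
        truth.scr_events[ph] = _draw_scr_events(truth.phases[ph], rng)
    return truth


def generate_session(truth, effect_config=None, rng=None):
    """Render the raw multimodal traces of one subject from its truth.

    Phases are laid out contiguously; beat-level realizations are generated
    first (if not already present) and the raw ECG, respiration and EDA
    traces are synthesized on top of them.
    """
    cfg = effect_config or EffectConfig()
    rng = rng or np.random.default_rng(truth.seed)
    if set(truth.rr.keys()) != set(PHASES):
        generate_beats(truth, rng=rng)
    bounds = {}
    t0 = 0.0
    for ph in PHASES:
        d = truth.phases[ph].duration
        bounds[ph] = (t0, t0 + d)
        t0 += d
    total = t0

    # ECG from the global beat times
    beat_times = np.concatenate([truth.beat_times[ph] + bounds[ph][0] for ph in PHASES])
    ecg, _ = synthesize_ecg(np.diff(beat_times) * 1000.0, fs=ECG_FS,
                            noise_sd=cfg.ecg_noise_sd,
                            seed=rng.integers(2**31), beat_times=beat_times)
    nt = int(round(total * ECG_FS)) + 1
    if ecg.size < nt:
        ecg = np.concatenate([ecg, np.zeros(nt - ecg.size)])
    if cfg.ecg_noise_sd > 0:
        pass  # noise already added inside synthesize_ecg

    # respiration from the global breathing phase
    t = np.arange(int(round(total * RESP_FS))) / RESP_FS
    resp = np.zeros(t.size)
    for ph in PHASES:
        lo, hi = bounds[ph]
        m = (t >= lo) & (t < hi)
        resp[m] = np.sin(2.0 * np.pi * _breath_phase(t[m] - lo, truth.breath_onsets[ph]))

    # EDA from the global SCR event list
    events = [(ev + bounds[ph][0], a) for ph in PHASES for ev, a in truth.scr_events[ph]]
    eda = synthesize_eda(events, truth.tonic_slope, total, fs=EDA_FS,
                         noise_sd=cfg.eda_noise_sd, seed=rng.integers(2**31))

    sess = Session(subject_id=truth.subject_id, group=truth.group,
                   ecg=ecg, resp=resp, eda=eda,
                   fs_ecg=ECG_FS, fs_resp=RESP_FS, fs_eda=EDA_FS,
                   phase_bounds=bounds, suds=dict(truth.suds),
                   cortisol=tuple(truth.cortisol))
    sess.validate()
    return sess


def _cohort_truths(n_per_group, config, seed):
    cfg = config or EffectConfig()
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.generate_state(2 * n_per_group) >> 1  # keep < 2**31
    truths = []
    k = 0
    for group in GROUPS:
        for i in range(n_per_group):
            sid = f"{group[0]}{i + 1:03d}"
            truths.append(make_truth(sid, group, cfg, seed=int(subject_seeds[k])))
            k += 1
    return truths


def generate_beat_cohort(n_per_group, effect_config=None, seed=0):
    """Beat-level cohort: truths with realized RR/respirogram/breath/SCR
    series but no raw traces.  This is the fast path for large simulation
    studies; the raw-trace path exercises the detectors as well."""
    truths = _cohort_truths(n_per_group, effect_config, seed)
    for tr in truths:
        generate_beats(tr)
    return truths


def generate_cohort(n_per_group, effect_config=None, seed=0):
    """Full cohort of raw sessions plus their generating truths."""
    cfg = effect_config or EffectConfig()
    truths = _cohort_truths(n_per_group, cfg, seed)
    sessions = [generate_session(tr, cfg) for tr in truths]
    return sessions, truths
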