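import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_ar2_series(n, rho=0.85, f_hz=0.09, T=0.8, var=900.0, seed=0):
    """AR(2) series with a low-frequency resonance, scaled to ``var``."""
    from scipy.signal import lfilter

    rng = np.random.default_rng(seed)
    w = 2 * np.pi * f_hz * T
    p1, p2 = 2 * rho * np.cos(w), -(rho**2)
    varfac = (1 - p2) / ((1 + p2) * ((1 - p2) ** 2 - p1**2))
    x = lfilter([1.0], [1.0, -p1, -p2],
                rng.standard_normal(n + 500) * np.sqrt(var / varfac))
    return x[500:]


def make_coupled_pair(n, gain, noise_var, seed, T=0.8, period=4.0,
                      period_sd=0.3, lag=1):
    """RR/respirogram pair with known coherent fraction (unit-RMS resp)."""
    rng = np.random.default_rng(seed)
    periods = np.maximum(rng.normal(period, period_sd, int((n + lag) * T / period) + 10), 1.5)
    onsets = np.concatenate([[0.0], np.cumsum(periods)])
    t = np.arange(n + lag) * T
    idx = np.interp(t, onsets, np.arange(onsets.size))
    resp = np.sqrt(2.0) * np.sin(2 * np.pi * idx)
    e = make_ar2_series(n, T=T, var=noise_var, seed=seed + 10_000)
    rr = gain * resp[:n] + e
    resp_obs = resp[lag:n + lag]
    true_frac = gain**2 * np.var(resp[:n]) / np.var(rr)
    return rr, resp_obs, true_frac


def random_stable_ar(p, rng, kmax=0.95):
    """Stable AR coefficients (of A(z) = 1 + sum a_i z^-i) synthesized from
    reflection coefficients via the Levinson recursion."""
    a = np.array([])
    for k in rng.uniform(-kmax, kmax, p):
        a = np.concatenate([a + k * a[::-1], [k]]) if a.size else np.array([k])
    return a


def ar_process_variance(a, sigma2):
    """Lag-zero autocovariance of the AR model by solving the Yule-Walker
    linear system (independent oracle for the residue decomposition)."""
    p = len(a)
    af = np.concatenate(([1.0], a))
    n = p + 1
    M = np.zeros((n, n))
    for k in range(n):
        for i in range(p + 1):
            M[k, abs(k - i)] += af[i]
    b = np.zeros(n)
    b[0] = sigma2
    return float(np.linalg.solve(M, b)[0])
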