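"""Univariate and bivariate AR spectral analysis."""

import numpy as np
import pytest
from scipy.signal import lfilter

from autonomics import spectral as sp
from conftest import (ar_process_variance, make_ar2_series, make_coupled_pair,
                      random_stable_ar)


class TestDetrend:
    def test_ramp_maps_to_zero(self):
        assert np.allclose(sp.detrend_linear(np.arange(100.0) * 3 + 7), 0, atol=1e-9)

    def test_sinusoid_survives_detrending(self):
        t = np.arange(500)
        x = np.sin(2 * np.pi * t / 25)
        y = sp.detrend_linear(x + 0.05 * t + 3)
        r = np.corrcoef(x, y)[0, 1]
        assert r > 0.999


class TestFitAR:
    def test_matches_statsmodels_yule_walker(self, rng):
        from statsmodels.regression.linear_model import yule_walker

        x = make_ar2_series(3000, seed=1)
        model = sp.fit_ar(x, p_range=(8, 8), T=0.8)
        rho, s = yule_walker(x, order=8, method="mle", demean=False)
        assert np.allclose(model.coef_, -rho, atol=1e-10)
        assert model.sigma2_ == pytest.approx(s**2, rel=1e-10)

    def test_white_noise_flat_spectrum(self, rng):
        sig2 = []
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(1024) * 3.0
            m = sp.fit_ar(x, T=1.0)
            sig2.append(m.sigma2_ / np.var(x))
        # innovation variance ~ sample variance for white input
        assert np.mean(sig2) == pytest.approx(1.0, abs=0.05)

    def test_known_ar_coefficient_recovery(self):
        a_true = random_stable_ar(8, np.random.default_rng(3), kmax=0.7)
        errs = []
        for seed in range(5):
            e = np.random.default_rng(seed).standard_normal(2548)
            x = lfilter([1.0], np.concatenate(([1.0], a_true)), e)[500:]
            m = sp.fit_ar(x, p_range=(8, 8), T=1.0)
            errs.append(np.sqrt(np.mean((m.coef_ - a_true) ** 2)))
        assert np.mean(errs) < 0.05

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            sp.fit_ar(np.full(300, 800.0), T=0.8)

    def test_aic_selects_in_range_and_stable(self):
        x = make_ar2_series(400, seed=2)
        m = sp.fit_ar(x, T=0.8)
        assert 7 <= m.order_ <= 15
        roots = np.roots(np.concatenate(([1.0], m.coef_)))
        assert np.all(np.abs(roots) < 1.0)


class TestPSD:
    def test_order_zero_analog_is_flat(self):
        m = sp.ARSpectrum()
        m.coef_, m.sigma2_, m.T_ = np.array([]), 2.0, 0.8
        f, psd = m.psd()
        assert np.allclose(psd, 0.8 * 2.0)

    def test_integral_equals_process_variance(self, rng):
        # pole moduli capped at 0.95 so the 8192-point trapezoid grid
        # resolves every resonance
        for seed in range(5):
            r = np.random.default_rng(seed)
            mods = r.uniform(0.3, 0.95, 4)
            angs = r.uniform(0.1, np.pi - 0.1, 4)
            poles = np.concatenate([mods * np.exp(1j * angs),
                                    mods * np.exp(-1j * angs),
                                    r.uniform(-0.5, 0.5, 1)])
            a = np.real(np.poly(poles))[1:]
            m = sp.ARSpectrum(n_freq=8192)
            m.coef_, m.sigma2_, m.T_ = a, 1.3, 0.85
            f, psd = m.psd()
            integ = 2 * np.trapezoid(psd, f)
            assert integ == pytest.approx(ar_process_variance(a, 1.3), rel=0.01)

    def test_resonance_peak_located(self):
        # sharp AR(2) resonance at 0.10 Hz (the spectral peak converges to
        # the pole frequency as the modulus approaches 1)
        T, f0, rho = 0.8, 0.10, 0.99
        w = 2 * np.pi * f0 * T
        a = np.array([-2 * rho * np.cos(w), rho**2])
        m = sp.ARSpectrum(n_freq=2048)
        m.coef_, m.sigma2_, m.T_ = a, 1.0, T
        f, psd = m.psd()
        assert abs(f[np.argmax(psd)] - f0) < (f[2] - f[1]) + 1e-9


class TestPoleDecomposition:
    def test_component_powers_sum_to_variance(self, rng):
        for seed in range(30):
            r = np.random.default_rng(seed)
            p = int(r.integers(7, 16))
            a = random_stable_ar(p, r)
            comps = sp._pole_components(a, 2.0, 0.8)
            total = sum(c[1] for c in comps)
            assert total == pytest.approx(ar_process_variance(a, 2.0), rel=0.01)

    def test_band_powers_match_numeric_integration(self, rng):
        # well-separated (sharp) LF and HF resonances: the pole components
        # concentrate in their bands, so residue assignment and numeric
        # band integration converge
        T = 0.8
        for seed in range(20):
            r = np.random.default_rng(seed)
            poles = []
            for f0 in (0.10, 0.30):
                mod = r.uniform(0.98, 0.995)
                ang = 2 * np.pi * f0 * T
                poles += [mod * np.exp(1j * ang), mod * np.exp(-1j * ang)]
            a = np.real(np.poly(poles))[1:]
            m = sp.ARSpectrum(n_freq=32768)
            m.coef_, m.sigma2_, m.T_ = a, 1.0, T
            bands = m.band_powers()
            f, psd = m.psd()
            lf_num = sp.integrate_psd(f, psd, *sp.LF_BAND)
            hf_num = sp.integrate_psd(f, psd, *sp.HF_BAND)
            assert bands.lf == pytest.approx(lf_num, rel=0.10)
            assert bands.hf == pytest.approx(hf_num, rel=0.10)

    def test_hf_resonance_dominates_hf_norm(self):
        T = 0.8
        ang = 2 * np.pi * 0.25 * T
        poles = [0.9 * np.exp(1j * ang), 0.9 * np.exp(-1j * ang)]
        a = np.real(np.poly(poles))[1:]
        m = sp.ARSpectrum()
        m.coef_, m.sigma2_, m.T_ = a, 1.0, T
        b = m.band_powers()
        assert b.hf_norm > b.lf_norm

    def test_single_lf_resonance_concentrates_power(self):
        T = 0.8
        ang = 2 * np.pi * 0.10 * T
        poles = [0.95 * np.exp(1j * ang), 0.95 * np.exp(-1j * ang)]
        a = np.real(np.poly(poles))[1:]
        m = sp.ARSpectrum()
        m.coef_, m.sigma2_, m.T_ = a, 1.0, T
        b = m.band_powers()
        assert b.lf / b.total >= 0.90


class TestBivariateAR:
    def test_independent_channels_have_null_cross_coefficients(self):
        # two independent unit-variance white noises: every cross
        # coefficient is pure estimation noise with SE ~ 1/sqrt(N)
        n = 2048
        for seed in range(5):
            r = np.random.default_rng(seed)
            y1 = r.standard_normal(n)
            y2 = r.standard_normal(n)
            m = sp.fit_bivar_ar(y1, y2, T=0.8)
            cross = np.concatenate([[A[0, 1], A[1, 0]] for A in m.A_])
            # 4 SE bound allowing for the 2p-fold multiplicity
            assert np.max(np.abs(cross)) < 4.0 / np.sqrt(n)

    def test_known_cross_coupling_recovered(self):
        for seed in range(3):
            r = np.random.default_rng(seed)
            n = 2048
            y2 = lfilter([1.0], [1.0, -0.5], r.standard_normal(n + 1))
            y1 = 0.8 * y2[:-1] + r.standard_normal(n)
            m = sp.fit_bivar_ar(y1, y2[1:], T=0.8, p_range=(7, 15))
            # paper sign convention: Y(n) = -sum A(i) Y(n-i) + U(n)
            assert -m.A_[0][0, 1] == pytest.approx(0.8, abs=0.05)

    def test_identical_channels_rejected(self):
        x = make_ar2_series(500, seed=4)
        with pytest.raises(ValueError):
            sp.fit_bivar_ar(x, x, T=0.8)

    def test_matches_statsmodels_var_on_long_series(self):
        from statsmodels.tsa.api import VAR

        r = np.random.default_rng(7)
        n = 8192
        A1 = np.array([[0.5, 0.2], [-0.1, 0.4]])
        A2 = np.array([[-0.2, 0.0], [0.1, 0.3]])
        Y = np.zeros((n + 100, 2))
        eps = r.standard_normal((n + 100, 2))
        for t in range(2, n + 100):
            Y[t] = A1 @ Y[t - 1] + A2 @ Y[t - 2] + eps[t]
        Y = Y[100:]
        mine = sp.fit_bivar_ar(Y[:, 0], Y[:, 1], p_range=(2, 2), T=1.0)
        smod = VAR(Y).fit(2, trend="n")
        # statsmodels coefs_ are the forward Phi matrices = -A
        assert np.allclose(-mine.A_[0], smod.coefs[0], atol=0.02)
        assert np.allclose(-mine.A_[1], smod.coefs[1], atol=0.02)


class TestCoherentDecomposition:
    def test_no_respiratory_path_gives_zero_pcoh(self):
        m = sp.BivariateARDecomposer()
        # hand-built diagonal model: no cross terms at all
        m.order_ = 2
        m.A_ = np.array([np.diag([-0.5, -0.3]), np.diag([0.2, 0.1])])
        m.sigma_ = np.diag([4.0, 1.0]).astype(float)
        m.sigma_diag_ = np.array([4.0, 1.0])
        m.offdiag_corr_ = 0.0
        m.T_ = 0.8
        m.n_freq = 1024
        d = m.decompose()
        assert d.pcoh == pytest.approx(0.0, abs=1e-12)
        assert d.pncoh > 0

    def test_coherent_fraction_recovered(self):
        fracs = []
        for seed in range(25):
            rr, resp, tf = make_coupled_pair(240, 30.0, 900.0, seed)
            m = sp.fit_bivar_ar(sp.detrend_linear(rr), sp.detrend_linear(resp), T=0.8)
            d = m.decompose()
            fracs.append(d.pcoh / (d.pcoh + d.pncoh))
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.1)

    def test_power_conservation(self):
        ratios = []
        for seed in range(15):
            rr, resp, _ = make_coupled_pair(240, 30.0, 900.0, seed + 50)
            m = sp.fit_bivar_ar(sp.detrend_linear(rr), sp.detrend_linear(resp), T=0.8)
            d = m.decompose()
            ratios.append((d.pcoh + d.pncoh) / np.var(rr))
        assert np.median(ratios) == pytest.approx(1.0, abs=0.10)

    def test_respirogram_amplitude_invariance(self):
        # doubling the respirogram amplitude at fixed RR-side power must not
        # change PCOH: the model rescales the cross gain accordingly
        for seed in range(5):
            rr, resp, _ = make_coupled_pair(300, 30.0, 900.0, seed + 99)
            m1 = sp.fit_bivar_ar(sp.detrend_linear(rr), sp.detrend_linear(resp), T=0.8)
            m2 = sp.fit_bivar_ar(sp.detrend_linear(rr), sp.detrend_linear(2 * resp), T=0.8)
            assert m2.pcoh_ == pytest.approx(m1.pcoh_, rel=0.10)

    def test_fraction_monotone_in_gain(self):
        means = []
        for g in (0.0, 10.0, 30.0, 60.0):
            fr = []
            for seed in range(10):
                rr, resp, _ = make_coupled_pair(240, g, 900.0, seed + 200)
                m = sp.fit_bivar_ar(sp.detrend_linear(rr), sp.detrend_linear(resp), T=0.8)
                d = m.decompose()
                fr.append(d.pcoh / (d.pcoh + d.pncoh))
            means.append(np.mean(fr))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_stability_of_returned_models(self):
        for seed in range(5):
            rr, resp, _ = make_coupled_pair(240, 30.0, 900.0, seed + 300)
            m = sp.fit_bivar_ar(sp.detrend_linear(rr), sp.detrend_linear(resp), T=0.8)
            assert sp._var_stable(m.A_)
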