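"""Spectral decomposition: exact identities, oracles and invariants."""

import numpy as np
import pytest

from ssralpha import (ATTEND_LEFT, Epochs, SpectralSet, band_mean,
                      detrend_taper, evopow, fft_complex, itc, itcz,
                      jackknife_single_trial, onpow, to_db)
from ssralpha.spectral import MeasureMap


def _epochs(data, srate=256.0):
    data = np.asarray(data, dtype=float)
    return Epochs(data=data, srate=srate,
                  condition=np.array([ATTEND_LEFT] * data.shape[0]),
                  channel_names=[f"c{i}" for i in range(data.shape[1])])


def _sset(Z, df=0.25):
    Z = np.asarray(Z, dtype=complex)
    freqs = np.arange(Z.shape[2]) * df
    return SpectralSet(Z=Z, freqs=freqs,
                       condition=np.array([ATTEND_LEFT] * Z.shape[0]),
                       channel_names=[f"c{i}" for i in range(Z.shape[1])],
                       n_samples_orig=768)


class TestDetrendTaper:
    @pytest.mark.parametrize("signal_fn", [
        lambda t: np.full_like(t, 3.7),            # constant -> zero
        lambda t: 0.5 * t - 2.0,                   # pure ramp -> zero
    ])
    def test_constant_and_ramp_removed(self, signal_fn):
        t = np.arange(256, dtype=float)
        ep = _epochs(signal_fn(t)[None, None, :])
        out = detrend_taper(ep, taper_ratio=0.1)
        assert np.allclose(out.data, 0.0, atol=1e-9)

    def test_zero_ratio_is_rectangular(self, rng):
        x = rng.standard_normal((2, 3, 128))
        ep = _epochs(x)
        out = detrend_taper(ep, taper_ratio=0.0)
        from scipy.signal import detrend
        assert np.allclose(out.data, detrend(x, axis=-1), atol=1e-12)

    def test_bad_ratio_rejected(self, rng):
        with pytest.raises(ValueError):
            detrend_taper(_epochs(rng.standard_normal((1, 1, 8))), taper_ratio=1.5)


class TestFFT:
    def test_padding_and_grid(self):
        ep = _epochs(np.zeros((1, 1, 768)), srate=256.0)
        S = fft_complex(ep, df=0.25)
        assert S.df == 0.25
        assert len(S.freqs) == 1024 // 2 + 1          # 256/0.25 = 1024 samples
        # original-paper geometry: 3 s at 512 Hz pads to 2048 samples
        ep2 = _epochs(np.zeros((1, 1, 1536)), srate=512.0)
        S2 = fft_complex(ep2, df=0.25)
        assert len(S2.freqs) == 2048 // 2 + 1

    def test_on_grid_cosine_peaks_at_its_frequency(self):
        t = np.arange(768) / 256.0
        ep = _epochs(np.cos(2 * np.pi * 10.0 * t)[None, None, :])
        S = fft_complex(ep, df=0.25)
        k = int(np.argmax(np.abs(S.Z[0, 0])))
        assert S.freqs[k] == 10.0
        assert abs(np.abs(S.Z[0, 0, k]) - 1.0) < 0.05  # amplitude scaling

    def test_parseval_consistency(self, rng):
        """One-sided padded spectrum preserves time-domain energy."""
        x = rng.standard_normal((2, 3, 768))
        S = fft_complex(_epochs(x), df=0.25)
        n, nfft = 768, 1024
        # undo the amplitude scaling: X_k = Z_k * n / 2 (k >= 1), X_0 = Z_0 * n
        X = S.Z * n / 2.0
        X[..., 0] *= 2.0
        e_spec = (2 * np.sum(np.abs(X[..., 1:-1])**2, axis=-1)
                  + np.abs(X[..., 0])**2 + np.abs(X[..., -1])**2) / nfft
        e_time = np.sum(x**2, axis=-1)
        assert np.allclose(e_spec, e_time, rtol=1e-9)

    def test_coarse_df_rejected(self):
        ep = _epochs(np.zeros((1, 1, 768)), srate=256.0)
        with pytest.raises(ValueError):
            fft_complex(ep, df=1.0)  # padding target shorter than the trial


class TestMeasures:
    def test_single_trial_onpow_equals_evopow(self, rng):
        Z = rng.standard_normal((1, 2, 9)) + 1j * rng.standard_normal((1, 2, 9))
        S = _sset(Z)
        assert np.allclose(onpow(S).values, evopow(S).values, atol=1e-14)

    def test_identical_trials(self, rng):
        z = rng.standard_normal((1, 2, 9)) + 1j * rng.standard_normal((1, 2, 9))
        S = _sset(np.repeat(z, 5, axis=0))
        assert np.allclose(evopow(S).values, onpow(S).values, atol=1e-14)
        assert np.allclose(itc(S).values, 1.0)

    def test_opposite_phase_cancellation(self):
        z = np.ones((1, 1, 4), dtype=complex)
        S = _sset(np.concatenate([z, -z], axis=0))
        assert np.allclose(evopow(S).values, 0.0, atol=1e-14)
        assert np.all(onpow(S).values > 0)
        assert np.allclose(itc(S).values, 0.0, atol=1e-14)

    def test_onpow_phase_invariance(self, rng):
        """Ongoing power ignores per-trial phase rotations."""
        Z = rng.standard_normal((8, 2, 5)) + 1j * rng.standard_normal((8, 2, 5))
        S = _sset(Z)
        phases = np.exp(1j * rng.uniform(0, 2 * np.pi, size=(8, 1, 1)))
        S2 = _sset(Z * phases)
        assert np.allclose(onpow(S).values, onpow(S2).values, atol=1e-12)

    def test_trial_order_invariance(self, rng):
        Z = rng.standard_normal((10, 2, 5)) + 1j * rng.standard_normal((10, 2, 5))
        perm = rng.permutation(10)
        for fn in (onpow, evopow, itc):
            assert np.allclose(fn(_sset(Z)).values, fn(_sset(Z[perm])).values,
                               atol=1e-12)

    def test_evopow_equals_time_domain_average_oracle(self, montage32, rng):
        """Evoked power is numerically the power spectrum of the
        time-domain trial average."""
        x = rng.standard_normal((6, 4, 768))
        ep = detrend_taper(_epochs(x), 0.1)
        S = fft_complex(ep, df=0.25)
        ev = evopow(S).values
        avg = ep.data.mean(axis=0, keepdims=True)
        Sa = fft_complex(_epochs(avg), df=0.25)
        oracle = np.abs(Sa.Z[0]) ** 2
        assert np.max(np.abs(ev - oracle) / (oracle + 1e-30)) < 1e-9

    def test_cauchy_schwarz_evopow_le_onpow(self, rng):
        """evoPOW <= onPOW at every (channel, frequency) for random spectra."""
        for _ in range(200):
            n = rng.integers(2, 9)
            Z = rng.standard_normal((n, 3, 7)) + 1j * rng.standard_normal((n, 3, 7))
            S = _sset(Z)
            assert np.all(evopow(S).values <= onpow(S).values + 1e-12)

    def test_itc_zero_amplitude_excluded(self):
        Z = np.ones((3, 1, 2), dtype=complex)
        Z[1, 0, 0] = 0.0
        m = itc(_sset(Z))
        assert m.n_excluded == 1
        assert np.allclose(m.values, 1.0)   # remaining trials fully coherent

    def test_itc_random_phase_calibration(self, rng):
        """E[ITC^2] = 1/n under uniform random phases (Monte-Carlo)."""
        n, reps = 17, 4000
        phases = rng.uniform(0, 2 * np.pi, size=(n, reps, 1))
        S = _sset(np.exp(1j * phases))
        vals = itc(S).values[:, 0] ** 2
        se = np.std(vals) / np.sqrt(reps)
        assert abs(vals.mean() - 1.0 / n) < 3 * se + 1e-12


class TestItczToDbBand:
    def test_itcz_closed_form(self):
        m = MeasureMap(values=np.array([[1.0, 0.0]]), measure="ITC", scale="a.u.",
                       freqs=np.array([0.0, 0.25]), channel_names=["c0"])
        z = itcz(m, 10)
        assert np.allclose(z.values, [[10.0, 0.0]])
        z2 = itcz(m, 10, variant="unbiased")
        assert np.allclose(z2.values, [[8.0, -1.0]])

    def test_to_db_identities(self):
        m = MeasureMap(values=np.array([[100.0, 1.0]]), measure="onPOW",
                       scale="linear", freqs=np.array([0.0, 0.25]),
                       channel_names=["c0"])
        db = to_db(m)
        assert np.allclose(db.values, [[20.0, 0.0]])
        m10 = MeasureMap(values=10 * m.values, measure="onPOW", scale="linear",
                         freqs=m.freqs, channel_names=["c0"])
        assert np.allclose(to_db(m10).values - db.values, 10.0)

    def test_to_db_rejects_nonpositive(self):
        m = MeasureMap(values=np.array([[0.0]]), measure="onPOW", scale="linear",
                       freqs=np.array([10.0]), channel_names=["c0"])
        with pytest.raises(ValueError):
            to_db(m)

    def test_band_mean_bins(self):
        freqs = np.arange(0, 20.25, 0.25)
        vals = np.tile(freqs[None, :], (2, 1))
        m = MeasureMap(values=vals, measure="onPOW", scale="dB", freqs=freqs,
                       channel_names=["a", "b"])
        # [8, 13] at 0.25 Hz resolution covers 21 bins, mean = 10.5
        assert np.allclose(band_mean(m, (8, 13)), 10.5)
        assert np.allclose(band_mean(m, (10, 10)), 10.0)
        with pytest.raises(ValueError):
            band_mean(m, (30, 31))


class TestJackknife:
    def test_identical_trials_all_equal_full_sample(self):
        z = (1.0 + 0.5j) * np.ones((6, 2, 3), dtype=complex)
        S = _sset(z)
        jk = jackknife_single_trial(S, "itcz", freq=0.25)
        assert np.allclose(jk, (6 - 1) * 1.0**2)

    def test_leave_one_out_matches_brute_force(self, rng):
        """Jackknife estimates equal direct recomputation on each subset."""
        n = 7
        Z = rng.standard_normal((n, 2, 5)) + 1j * rng.standard_normal((n, 2, 5))
        S = _sset(Z)
        for measure, kw in (("itcz", dict(freq=0.5)),
                            ("evopow", dict(freq=0.5)),
                            ("onpow_band", dict(band=(0.25, 1.0)))):
            jk = jackknife_single_trial(S, measure, **kw)
            for i in range(n):
                sub = _sset(np.delete(Z, i, axis=0))
                if measure == "itcz":
                    direct = itcz(itc(sub), n - 1).values[:, 2]
                elif measure == "evopow":
                    direct = to_db(evopow(sub)).values[:, 2]
                else:
                    direct = band_mean(to_db(onpow(sub)), (0.25, 1.0))
                assert np.allclose(jk[i], direct, atol=1e-12)

    def test_too_few_trials_rejected(self, rng):
        Z = rng.standard_normal((2, 1, 3)) + 0j
        with pytest.raises(ValueError):
            jackknife_single_trial(_sset(Z), "evopow", freq=0.25)


def test_conundrum_spectral_signature(montage32):
    """Ongoing power shows one broad alpha peak without resolvable SSR
    lines, while evoked power and ITCz show distinct 10 and 12 Hz peaks."""
    from ssralpha import SimParams, generate_epochs
    epochs, _ = generate_epochs(SimParams(seed=2), montage32)
    S = fft_complex(detrend_taper(epochs))
    Sa = S.select(ATTEND_LEFT)
    on = onpow(Sa).values.mean(axis=0)
    ev = evopow(Sa).values
    zc = itcz(itc(Sa), Sa.n_trials).values
    k10, k12 = S.freq_index(10.0), S.freq_index(12.0)
    k9, k11, k13 = S.freq_index(9.0), S.freq_index(11.0), S.freq_index(13.0)
    # evoked power and ITCz: sharp lines at the driving frequencies,
    # evaluated at the channel where each line peaks
    for spec in (ev, zc):
        c10, c12 = np.argmax(spec[:, k10]), np.argmax(spec[:, k12])
        assert spec[c10, k10] > 3 * max(spec[c10, k9], spec[c10, k11])
        assert spec[c12, k12] > 3 * max(spec[c12, k11], spec[c12, k13])
    # ongoing power: SSR lines not resolvable against the broad alpha hump
    assert on[k10] < 1.6 * on[k9]
    assert on[k12] < 1.6 * on[k11]
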