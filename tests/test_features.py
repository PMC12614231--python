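"""Feature extractors against closed forms and invariance properties."""
import math

import numpy as np
import pytest

from voiceinv.features import (
    FEATURE_NAMES,
    UnvoicedError,
    ZScoreStats,
    cpp,
    estimate_f0,
    extract_features,
    flow_pulse_metrics,
    harmonic_differences,
    hnr,
    shr,
    spl_from_source,
    zscore_apply,
    zscore_fit,
    zscore_invert,
)
from voiceinv.source import AIR_DENSITY, SourceSignal

FS = 16000.0


def _sig(flow, fs=FS):
    return SourceSignal.from_flow(np.asarray(flow, dtype=float), fs)


def _sig_with_derivative(deriv, fs=FS):
    deriv = np.asarray(deriv, dtype=float)
    return SourceSignal(
        flow=np.cumsum(deriv) / fs,
        sample_rate=fs,
        derivative=deriv,
        duration=len(deriv) / fs,
    )


class TestF0:
    def test_ideal_pulse_train(self):
        fs = 44100.0
        x = (np.arange(int(0.5 * fs)) % 441 == 0).astype(float)
        assert abs(estimate_f0(_sig(x, fs)) - 100.0) < 0.5

    def test_pure_sine(self):
        fs = 44100.0
        t = np.arange(int(0.5 * fs)) / fs
        assert abs(estimate_f0(_sig(np.sin(2 * np.pi * 220 * t), fs)) - 220.0) < 0.5

    def test_white_noise_unvoiced(self, rng):
        with pytest.raises(UnvoicedError):
            estimate_f0(_sig(rng.standard_normal(8000)))

    def test_dc_offset_irrelevant(self):
        fs = 44100.0
        t = np.arange(int(0.5 * fs)) / fs
        x = np.sin(2 * np.pi * 150 * t)
        assert abs(estimate_f0(_sig(x + 5.0, fs)) - estimate_f0(_sig(x, fs))) < 0.01


class TestHarmonicDifferences:
    def test_two_component_closed_form(self):
        t = np.arange(int(0.5 * FS)) / FS
        deriv = np.sin(2 * np.pi * 200 * t) + 0.5 * np.sin(2 * np.pi * 400 * t)
        h1h2, *_ = harmonic_differences(_sig_with_derivative(deriv), 200.0)
        assert abs(h1h2 - 20 * math.log10(2.0)) < 0.1

    def test_equal_harmonics_give_zero(self):
        imp = np.zeros(int(0.5 * FS))
        imp[:: int(FS / 200)] = 1.0  # impulse train: flat harmonic spectrum
        h1h2, h1h4, *_ = harmonic_differences(_sig_with_derivative(imp), 200.0)
        assert abs(h1h2) < 0.1 and abs(h1h4) < 0.1

    def test_scale_invariance(self):
        t = np.arange(int(0.5 * FS)) / FS
        deriv = sum(
            a * np.sin(2 * np.pi * 180 * k * t)
            for k, a in [(1, 1.0), (2, 0.4), (4, 0.2), (11, 0.1), (28, 0.05)]
        )
        one = harmonic_differences(_sig_with_derivative(deriv), 180.0)
        ten = harmonic_differences(_sig_with_derivative(10 * deriv), 180.0)
        np.testing.assert_allclose(one, ten, atol=1e-6)

    def test_nyquist_guard(self):
        t = np.arange(int(0.5 * 9000)) / 9000
        with pytest.raises(ValueError):
            harmonic_differences(
                _sig_with_derivative(np.sin(2 * np.pi * 200 * t), 9000.0), 200.0
            )


class TestCPP:
    def test_white_noise_low(self, rng):
        assert cpp(_sig(rng.standard_normal(int(0.5 * FS)))) < 5.0

    def test_noise_injection_lowers_cpp(self, clean_signal, rng):
        clean = cpp(clean_signal)
        snr10 = clean_signal.flow + rng.standard_normal(
            len(clean_signal.flow)
        ) * clean_signal.flow.std() * 10 ** (-0.5)
        assert cpp(_sig(snr10)) < clean

    def test_scale_invariance(self, clean_signal):
        scaled = _sig(clean_signal.flow * 10.0)
        assert abs(cpp(scaled) - cpp(clean_signal)) < 0.01

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            cpp(_sig(np.ones(100)))


class TestHNR:
    def test_noiseless_capped(self):
        x = np.tile(np.sin(2 * np.pi * np.arange(80) / 80), 50)
        assert hnr(_sig(x), FS / 80) == 60.0

    def test_equal_power_mixture_near_zero(self, rng):
        x = np.tile(np.sin(2 * np.pi * np.arange(80) / 80), 100)
        noise = rng.standard_normal(len(x))
        noise *= np.sqrt(np.mean(x**2) / np.mean(noise**2))
        assert abs(hnr(_sig(x + noise), FS / 80)) < 0.5

    def test_monotone_in_noise(self, rng):
        x = np.tile(np.sin(2 * np.pi * np.arange(80) / 80), 100)
        noise = rng.standard_normal(len(x))
        values = [hnr(_sig(x + s * noise), FS / 80) for s in (0.1, 0.2, 0.4)]
        assert values[0] > values[1] > values[2]


class TestSHR:
    def test_clean_train_has_no_subharmonics(self, clean_signal, base_params):
        from voiceinv.source import f0_closed_form

        assert shr(clean_signal, f0_closed_form(base_params)) < 0.05

    def test_alternating_amplitude_raises_shr(self, clean_signal, base_params):
        from voiceinv.source import f0_closed_form

        f0 = f0_closed_form(base_params)
        period = int(round(FS / f0))
        x = clean_signal.flow.copy()
        dc = x.min()
        for k in range(len(x) // period):
            if k % 2:
                seg = slice(k * period, (k + 1) * period)
                x[seg] = dc + 0.5 * (x[seg] - dc)
        modulated = shr(_sig(x), f0)
        assert modulated > shr(clean_signal, f0)

    def test_bounded(self, clean_signal, base_params, rng):
        from voiceinv.source import f0_closed_form

        f0 = f0_closed_form(base_params)
        noisy = _sig(clean_signal.flow + 0.3 * rng.standard_normal(len(clean_signal.flow)))
        assert 0.0 <= shr(noisy, f0) <= 1.0


class TestFlowPulseMetrics:
    def test_constant_flow_degenerate(self):
        q = flow_pulse_metrics(_sig(np.full(4000, 0.2)), 100.0)
        qmean, qamp, cq, mfdr, mfar = q
        assert qmean == pytest.approx(0.2)
        assert qamp == 0.0 and mfdr == 0.0 and mfar == 0.0
        assert cq == 1.0

    @pytest.mark.parametrize("oq,amp", [(0.5, 0.3), (0.6, 0.5), (0.4, 0.2)])
    def test_triangle_closed_forms(self, oq, amp):
        period = 160
        n_open = int(oq * period)
        half = n_open // 2
        one = np.zeros(period)
        one[:half] = np.linspace(0, amp, half, endpoint=False)
        one[half:n_open] = np.linspace(amp, 0, n_open - half, endpoint=False)
        sig = _sig(np.tile(one, 20))
        qmean, qamp, cq, mfdr, mfar = flow_pulse_metrics(sig, FS / period)
        oq_eff = n_open / period
        slope = 2 * amp / (oq_eff * period / FS)
        assert qamp == pytest.approx(amp, rel=0.02)
        # 5% amplitude threshold trims 5% of the open phase
        assert cq == pytest.approx(1 - 0.95 * oq_eff, abs=0.02)
        assert mfdr == pytest.approx(slope, rel=0.02)
        assert mfar == pytest.approx(slope, rel=0.02)

    def test_dc_offset_translation(self, clean_signal, base_params):
        from voiceinv.source import f0_closed_form

        f0 = f0_closed_form(base_params)
        a = flow_pulse_metrics(clean_signal, f0)
        b = flow_pulse_metrics(_sig(clean_signal.flow + 0.7), f0)
        assert b[0] == pytest.approx(a[0] + 0.7, abs=1e-9)
        np.testing.assert_allclose(b[1:], a[1:], rtol=1e-9)

    def test_bad_f0_rejected(self, clean_signal):
        with pytest.raises(ValueError):
            flow_pulse_metrics(clean_signal, 0.0)


class TestSPL:
    def test_monopole_closed_form(self):
        t = np.arange(int(0.5 * FS)) / FS
        a = 1e-3  # m^3/s^2
        deriv_lps = a * 1000.0 * np.sin(2 * np.pi * 1000 * t)  # stored unit L/s^2
        sig = SourceSignal(
            flow=np.cumsum(deriv_lps) / FS,
            sample_rate=FS,
            derivative=deriv_lps,
            duration=0.5,
        )
        expected = 20 * math.log10(
            (AIR_DENSITY * a / (4 * math.pi * 0.3)) / math.sqrt(2) / 20e-6
        )
        assert abs(spl_from_source(sig) - expected) < 0.1

    def test_doubling_amplitude_adds_6db(self, clean_signal):
        doubled = _sig(clean_signal.flow * 2.0)
        assert spl_from_source(doubled) - spl_from_source(clean_signal) == pytest.approx(
            20 * math.log10(2), abs=0.01
        )

    def test_inverse_distance_law(self, clean_signal):
        assert spl_from_source(clean_signal, 0.3) - spl_from_source(
            clean_signal, 0.6
        ) == pytest.approx(20 * math.log10(2), abs=0.01)


class TestExtractFeatures:
    def test_deterministic_and_complete(self, clean_signal):
        a = extract_features(clean_signal)
        b = extract_features(clean_signal)
        assert a == b
        vec = a.to_array()
        assert vec.shape == (14,)
        assert np.all(np.isfinite(vec))

    def test_pure_noise_raises_structured_error(self, rng):
        with pytest.raises(UnvoicedError):
            extract_features(_sig(rng.standard_normal(8000)))

    def test_field_order_matches_schema(self, clean_signal):
        f = extract_features(clean_signal)
        assert FEATURE_NAMES == tuple(f.__dataclass_fields__)


class TestZScore:
    def test_simple_column(self):
        stats = zscore_fit(np.array([[1.0], [2.0], [3.0]]), ["a"])
        assert stats.mean[0] == 2.0
        assert stats.sd[0] == pytest.approx(1.0)
        assert zscore_apply(stats, np.array([[2.0]]))[0, 0] == 0.0

    def test_round_trip_identity(self, rng):
        X = rng.normal(3.0, 5.0, size=(50, 4))
        stats = zscore_fit(X)
        Xz = zscore_apply(stats, X)
        np.testing.assert_allclose(Xz.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Xz.std(axis=0, ddof=1), 1.0, rtol=1e-12)
        np.testing.assert_allclose(zscore_invert(stats, Xz), X, rtol=1e-12)

    def test_zero_variance_named(self):
        X = np.ones((10, 2))
        X[:, 0] = np.arange(10)
        with pytest.raises(ValueError, match="colB"):
            zscore_fit(X, ["colA", "colB"])

    def test_stats_round_trip_dict(self):
        stats = zscore_fit(np.random.default_rng(0).normal(size=(20, 3)))
        again = ZScoreStats.from_dict(stats.to_dict())
        np.testing.assert_array_equal(stats.mean, again.mean)
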