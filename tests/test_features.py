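import numpy as np
import pytest

import oracles
from asfemg.features import fractal, hht, sets, spectral, stockwell, timedomain, wavelet
from asfemg.segment import Segment

FS = 1000.0


def _sine(freq, n=90, fs=FS, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs)


# ---------------------------------------------------------------------------
# example-based checks
# ---------------------------------------------------------------------------


class TestTemporalMoments:
    def test_alternating_window(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        assert timedomain.temporal_moment(x, 4) == 1.0
        assert timedomain.temporal_moment(x, 5) == 0.0

    def test_zeros(self):
        assert timedomain.temporal_moment(np.zeros(10), 4) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            timedomain.temporal_moment(np.array([]), 4)


class TestLcard:
    def test_constant_is_one_class(self):
        assert timedomain.lcard(np.full(50, 0.7)) == pytest.approx(np.log(2))

    def test_merge_below_threshold(self):
        assert timedomain.lcard(np.array([0.0, 0.0005, 0.5])) == pytest.approx(np.log(3))

    def test_huge_threshold_merges_everything(self, rng):
        assert timedomain.lcard(rng.standard_normal(90), threshold=1e9) == pytest.approx(
            np.log(2)
        )


class TestHHT:
    def test_pure_tone_frequency_recovered(self):
        assert hht.hht_feature(_sine(100), FS) == pytest.approx(100, rel=0.05)

    def test_zero_window(self):
        assert hht.hht_feature(np.zeros(90), FS) == 0.0

    def test_tone_with_slow_trend(self):
        x = _sine(50) + 0.1 * _sine(5)
        assert hht.hht_feature(x, FS) == pytest.approx(50, rel=0.10)


class TestWaveletEnergy:
    def test_zero_window(self):
        assert wavelet.wavelet_energy_feature(np.zeros(90)) == 0.0

    def test_quadratic_scaling(self, rng):
        x = rng.standard_normal(90)
        base = wavelet.wavelet_energy_feature(x)
        assert wavelet.wavelet_energy_feature(3 * x) == pytest.approx(9 * base, rel=1e-9)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            wavelet.wavelet_energy_feature(np.zeros(4), wavelet_name="db8")


class TestTimeDomainSuite:
    def test_small_window_arithmetic(self):
        td = timedomain.time_domain_suite(np.array([1.0, 2.0, 3.0, 4.0]))
        assert td["SSI"] == 30.0
        assert td["WL"] == 3.0
        assert td["AAC"] == pytest.approx(3 / 4)

    def test_constant_window_closed_forms(self):
        c = 0.4
        x = np.full(90, c)
        assert timedomain.aac(x) == 0.0
        assert timedomain.wl(x) == 0.0
        assert timedomain.lrmsv(x, 2) == pytest.approx(np.log(c))

    def test_zero_window_guards(self):
        x = np.zeros(90)
        assert timedomain.ssi(x) == 0.0
        assert timedomain.asr(x) == 0.0
        assert timedomain.mfl(x) == timedomain.LOG_ZERO_SENTINEL
        assert timedomain.lrmsv(x, 2) == timedomain.LOG_ZERO_SENTINEL

    def test_kurtosis_matches_scipy_bias_corrected(self, rng):
        from scipy.stats import kurtosis

        x = rng.standard_normal(90)
        assert timedomain.kurtosis_feature(x) == pytest.approx(
            kurtosis(x, fisher=True, bias=False), rel=1e-10
        )

    def test_kurtosis_constant_rejected(self):
        with pytest.raises(ValueError):
            timedomain.kurtosis_feature(np.ones(90))


class TestHjorth:
    def test_sinusoid_complexity_near_one(self):
        assert timedomain.hjorth_complexity(_sine(50, n=200)) == pytest.approx(1.0, rel=0.02)

    def test_white_noise_exceeds_one(self, rng):
        assert timedomain.hjorth_complexity(rng.standard_normal(500)) > 1.0

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            timedomain.hjorth_complexity(np.ones(90))


class TestSpectral:
    def test_zero_window_all_zero(self):
        sp = spectral.spectral_suite(np.zeros(90), FS)
        assert sp["MMDF"] == 0 and sp["SMD"] == 0 and sp["SMN"] == 0 and sp["MMNF"] == 0
        assert np.all(sp["MASP"] == 0)

    def test_tone_centroids_at_tone_frequency(self):
        sp = spectral.spectral_suite(_sine(100, n=500), FS)
        bin_hz = FS / 500
        assert abs(sp["SMN"] - 100) <= bin_hz
        assert abs(sp["MMNF"] - 100) <= bin_hz

    def test_parseval_smd_is_half_power(self, rng):
        x = rng.standard_normal(90)
        sp = spectral.spectral_suite(x, FS)
        power = np.mean((x - x.mean()) ** 2)
        assert sp["SMD"] == pytest.approx(power / 2, rel=1e-6)


class TestArLpc:
    def test_ar3_parameter_recovery(self):
        rng = np.random.default_rng(0)
        coef = [0.5, -0.3, 0.1]
        x = np.zeros(4196)
        e = rng.standard_normal(4196)
        for i in range(3, 4196):
            x[i] = coef[0] * x[i - 1] + coef[1] * x[i - 2] + coef[2] * x[i - 3] + e[i]
        out = spectral.ar_lpc(x[100:])
        assert np.allclose(out["AR3"][1:], coef, atol=0.05)

    def test_white_noise_coefficients_near_zero(self, rng):
        out = spectral.ar_lpc(rng.standard_normal(4096))
        assert np.all(np.abs(out["AR3"][1:]) < 0.1)

    def test_constant_window_singular(self):
        with pytest.raises(ValueError):
            spectral.ar_lpc(np.ones(90))


class TestStftStockwell:
    def test_zero_windows(self):
        assert spectral.stft_feature(np.zeros(90), FS) == 0.0
        assert stockwell.stockwell_feature(np.zeros(90), FS) == 0.0

    def test_linear_scaling(self, rng):
        x = rng.standard_normal(90)
        assert spectral.stft_feature(5 * x, FS) == pytest.approx(
            5 * spectral.stft_feature(x, FS), rel=1e-10
        )
        assert stockwell.stockwell_feature(5 * x, FS) == pytest.approx(
            5 * stockwell.stockwell_feature(x, FS), rel=1e-10
        )

    def test_dominant_stft_row_at_tone_frequency(self):
        f, rows = spectral.stft_mean_rows(_sine(100, n=256), FS)
        bin_hz = f[1] - f[0]
        assert abs(f[np.argmax(rows)] - 100) <= bin_hz


class TestHiguchi:
    def test_straight_line_dimension_one(self):
        assert fractal.higuchi_fd(np.arange(100, dtype=float)) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_dimension_two(self):
        x = np.random.default_rng(3).standard_normal(1024)
        assert fractal.higuchi_fd(x) == pytest.approx(2.0, abs=0.1)

    def test_constant_convention(self):
        assert fractal.higuchi_fd(np.ones(90)) == 1.0


class TestFer4:
    def _seg(self, x):
        return Segment(x=np.asarray(x, float), label="fist", peak_time_s=0.0,
                       channel_names=("FCR", "FCU", "APB", "EDC"))

    def test_identical_channels(self):
        seg = self._seg(np.ones((4, 90)))
        assert np.allclose(sets.fer4(seg), 1.0)

    def test_fcr_twice_edc(self):
        x = np.ones((4, 90))
        x[0] *= 2
        assert np.allclose(sets.fer4(self._seg(x)), [1.0, 0.5, 0.5, 0.5])

    def test_silent_edc_rejected(self):
        x = np.ones((4, 90))
        x[3] = 0
        with pytest.raises(ValueError, match="EDC"):
            sets.fer4(self._seg(x))


# ---------------------------------------------------------------------------
# vector assembly
# ---------------------------------------------------------------------------


def _segment(rng):
    return Segment(
        x=0.3 * rng.standard_normal((4, 90)),
        label="fist",
        peak_time_s=1.0,
        channel_names=("FCR", "FCU", "APB", "EDC"),
        fs_hz=FS,
    )


@pytest.mark.parametrize("name,length", [("ASF4", 20), ("ASF14NP", 56), ("ASF24P", 136)])
def test_vector_lengths_and_names(name, length, rng):
    vec, names = sets.extract_vector(_segment(rng), name)
    assert vec.size == length
    assert len(names) == length
    assert len(set(names)) == length
    assert np.all(np.isfinite(vec))


def test_extraction_bit_identical(rng):
    seg = _segment(rng)
    v1, _ = sets.extract_vector(seg, "ASF24P")
    v2, _ = sets.extract_vector(seg, "ASF24P")
    assert np.array_equal(v1, v2)


def test_component_error_carries_context(rng):
    seg = _segment(rng)
    seg.x[3] = 0.0  # silent EDC: constant channel breaks KT
    with pytest.raises(RuntimeError, match="channel 'EDC'"):
        sets.extract_vector(seg, "ASF24P")


# ---------------------------------------------------------------------------
# brute-force oracle equivalence on random windows
# ---------------------------------------------------------------------------

SCALAR_ORACLES = {
    "TM4": (lambda x: timedomain.temporal_moment(x, 4), lambda x: oracles.tm(x, 4)),
    "TM5": (lambda x: timedomain.temporal_moment(x, 5), lambda x: oracles.tm(x, 5)),
    "LCARD": (timedomain.lcard, oracles.lcard),
    "LRMSV2": (lambda x: timedomain.lrmsv(x, 2), lambda x: oracles.lrmsv(x, 2)),
    "LRMSV3": (lambda x: timedomain.lrmsv(x, 3), lambda x: oracles.lrmsv(x, 3)),
    "ASM": (timedomain.asm, oracles.asm),
    "ASR": (timedomain.asr, oracles.asr),
    "AAC": (timedomain.aac, oracles.aac),
    "SSI": (timedomain.ssi, oracles.ssi),
    "KT": (timedomain.kurtosis_feature, oracles.kurtosis),
    "SD": (timedomain.sd_population, oracles.sd_pop),
    "MFL": (timedomain.mfl, oracles.mfl),
    "WL": (timedomain.wl, oracles.wl),
    "MMAV2": (timedomain.mmav2, oracles.mmav2),
    "MMAV5": (timedomain.mmav5, oracles.mmav5),
    "MHW": (timedomain.mhw, oracles.mhw),
    "HPC": (timedomain.hjorth_complexity, oracles.hjorth_complexity),
    "HFD": (fractal.higuchi_fd, oracles.higuchi_fd),
}


@pytest.mark.parametrize("name", sorted(SCALAR_ORACLES))
def test_scalar_features_match_bruteforce(name, windows):
    ours, ref = SCALAR_ORACLES[name]
    for x in windows:
        assert ours(x) == pytest.approx(ref(list(x)), rel=1e-8, abs=1e-12)


def test_spectral_features_match_direct_dft(windows):
    for x in windows[:25]:
        got = spectral.spectral_suite(x, FS)
        want = oracles.spectral(list(x), FS)
        for key in ("MMDF", "SMD", "SMN", "MMNF"):
            assert got[key] == pytest.approx(want[key], rel=1e-8)
        assert np.allclose(got["MASP"], want["MASP"], rtol=1e-8)


def test_ar_lpc_match_toeplitz_solve(windows):
    for x in windows[:25]:
        got = spectral.ar_lpc(x)
        assert np.allclose(got["AR3"][1:], oracles.yule_walker(x), rtol=1e-8, atol=1e-10)
        assert got["AR3"][0] == pytest.approx(np.mean(x), rel=1e-12)
        assert np.allclose(got["LPC3"], oracles.lpc(x), rtol=1e-8, atol=1e-10)


def test_stft_matches_direct_dft(windows):
    for x in windows[:10]:
        assert spectral.stft_feature(x, FS) == pytest.approx(
            oracles.stft_mean(list(x), FS), rel=1e-8
        )


def test_stockwell_matches_direct_definition(windows):
    for x in windows[:5]:
        assert stockwell.stockwell_feature(x, FS) == pytest.approx(
            oracles.stockwell_mean(x), rel=1e-8
        )


@pytest.mark.parametrize("wname", ["db4", "db8"])
def test_wavelet_packets_match_convolution_cascade(wname, windows):
    level = wavelet.decomposition_level(90)
    for x in windows[:25]:
        got = wavelet.node_energies(x, wname, mode="packet")
        want = oracles.wavelet_packet_energies(x, wname, level)
        assert np.allclose(np.sort(got), np.sort(want), rtol=1e-8)


def test_hht_reduction_matches_direct_hilbert(windows):
    for x in windows[:25]:
        imfs = hht.emd(x)
        assert imfs
        assert hht.hht_feature(x, FS) == pytest.approx(
            oracles.hilbert_weighted_freq(imfs[0], FS), rel=1e-8
        )


def test_fer4_matches_loop_oracle(rng):
    for _ in range(20):
        seg = _segment(rng)
        assert np.allclose(sets.fer4(seg), oracles.fer4(seg.x), rtol=1e-12)


def test_scale_behaviours(windows):
    x = windows[0]
    assert timedomain.ssi(3 * x) == pytest.approx(9 * timedomain.ssi(x), rel=1e-10)
    assert timedomain.mhw(3 * x) == pytest.approx(9 * timedomain.mhw(x), rel=1e-10)
    assert fractal.higuchi_fd(5 * x) == pytest.approx(fractal.higuchi_fd(x), rel=1e-6)
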