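import numpy as np
import pytest

import _oracles as oracle
from conftest import FS, random_spectrogram
from ecoeq import (
    AudioSegment,
    IndexConfig,
    Spectrogram,
    aci,
    acoustic_entropy_h,
    adi,
    aei,
    bi,
    compute_all,
    dsc,
    ndsi,
    spectrogram,
    zcr,
)
from ecoeq.indices import DegenerateSignalError, EmptyBandError


class TestSpectrogram:
    def test_resolutions_at_standard_settings(self):
        seg = AudioSegment(np.random.default_rng(0).standard_normal(4 * FS), FS)
        spec = spectrogram(seg, nfft=1024)
        assert np.allclose(np.diff(spec.freqs), 46.875)
        assert np.allclose(np.diff(spec.times), 1024 / FS)
        assert np.isclose(1024 / FS, 0.021333, atol=1e-6)

    def test_pure_tone_concentrates_in_nearest_bin(self):
        t = np.arange(2 * FS) / FS
        seg = AudioSegment(0.5 * np.sin(2 * np.pi * 2000.0 * t), FS)
        spec = spectrogram(seg, nfft=1024)
        peak_bins = np.argmax(spec.amp, axis=0)
        expected = int(round(2000.0 / 46.875))
        assert np.all(peak_bins == expected)

    def test_zeros_give_zero_amp_and_floored_db(self):
        spec = spectrogram(AudioSegment(np.zeros(4096), FS), nfft=1024)
        assert np.all(spec.amp == 0)
        assert np.all(spec.db == -200.0)

    def test_relative_db_maximum_is_zero(self, white_noise_10s):
        spec = spectrogram(white_noise_10s, nfft=1024)
        assert spec.db.max() == 0.0


def _as_lists(spec):
    return list(spec.freqs), [list(row) for row in spec.amp]


class TestOracleEquivalence:
    """Every index matches an independent naive-loop oracle on random fixtures."""

    CFG = dict(fmin=32.0, fmax=224.0, band_width=32.0, threshold_db=-20.0)

    @pytest.mark.parametrize("seed", range(100))
    def test_all_indices_match_brute_force(self, seed):
        spec = random_spectrogram(seed)
        freqs, amp = _as_lists(spec)
        fr = spec.sample_rate / spec.nfft
        c = self.CFG
        assert aci(spec, c["fmin"], c["fmax"]) == pytest.approx(
            oracle.oracle_aci(freqs, amp, c["fmin"], c["fmax"]), rel=1e-9, abs=1e-12
        )
        assert adi(spec, c["fmin"], c["fmax"], c["band_width"], c["threshold_db"]) == pytest.approx(
            oracle.oracle_adi(freqs, amp, c["fmin"], c["fmax"], c["band_width"], c["threshold_db"], fr),
            rel=1e-9, abs=1e-12,
        )
        assert aei(spec, c["fmin"], c["fmax"], c["band_width"], c["threshold_db"]) == pytest.approx(
            oracle.oracle_aei(freqs, amp, c["fmin"], c["fmax"], c["band_width"], c["threshold_db"], fr),
            rel=1e-9, abs=1e-12,
        )
        assert bi(spec, c["fmin"], c["fmax"]) == pytest.approx(
            oracle.oracle_bi(freqs, amp, c["fmin"], c["fmax"]), rel=1e-9, abs=1e-12
        )
        assert ndsi(spec, (16.0, 112.0), (112.0, 240.0)) == pytest.approx(
            oracle.oracle_ndsi(freqs, amp, (16.0, 112.0), (112.0, 240.0)),
            rel=1e-9, abs=1e-12,
        )
        assert dsc(spec, c["fmin"], c["fmax"]) == pytest.approx(
            oracle.oracle_dsc(freqs, amp, c["fmin"], c["fmax"]), rel=1e-9, abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_zcr_matches_brute_force_count(self, seed):
        rng = np.random.default_rng(seed)
        samples = rng.uniform(-1, 1, 2000)
        seg = AudioSegment(samples, 1000)
        assert zcr(seg) == pytest.approx(
            oracle.oracle_zcr(list(samples), 1000), rel=1e-12
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_entropy_matches_naive_normalized_entropies(self, seed):
        from scipy.signal import hilbert

        rng = np.random.default_rng(seed)
        seg = AudioSegment(rng.uniform(-0.5, 0.5, 512), 1000)
        spec = random_spectrogram(seed + 1000)
        hf = oracle.oracle_normalized_entropy(list(spec.amp.mean(axis=1)))
        ht = oracle.oracle_normalized_entropy(list(np.abs(hilbert(seg.samples))))
        assert acoustic_entropy_h(seg, spec) == pytest.approx(hf * ht, rel=1e-9)


class TestAci:
    def test_temporally_constant_spectrogram_scores_zero(self):
        spec = random_spectrogram(1)
        const = Spectrogram(
            freqs=spec.freqs, times=spec.times,
            amp=np.tile(spec.amp[:, :1], (1, 16)),
            nfft=spec.nfft, sample_rate=spec.sample_rate,
        )
        assert aci(const, 0, 240) == 0.0

    def test_alternating_row_matches_hand_ratio(self):
        # single active row a,0,a,0,... over T=8 frames:
        # sum|diff| = 7a, sum amp = 4a -> ACI = 7/4
        amp = np.zeros((16, 8))
        amp[3, ::2] = 0.6
        spec = Spectrogram(
            freqs=np.arange(16) * 16.0, times=np.arange(8) * 0.0625,
            amp=amp, nfft=30, sample_rate=480,
        )
        assert aci(spec, 0, 240) == pytest.approx(7.0 / 4.0)

    def test_invariant_under_global_scaling(self):
        spec = random_spectrogram(2)
        scaled = Spectrogram(
            freqs=spec.freqs, times=spec.times, amp=spec.amp * 10,
            nfft=spec.nfft, sample_rate=spec.sample_rate,
        )
        assert aci(scaled, 0, 240) == pytest.approx(aci(spec, 0, 240), rel=1e-12)

    def test_empty_band_raises(self):
        with pytest.raises(EmptyBandError):
            aci(random_spectrogram(3), 1000.0, 2000.0)


class TestAdiAei:
    @staticmethod
    def _uniform_spec(value_db=0.0):
        amp = np.ones((16, 16))
        return Spectrogram(
            freqs=np.arange(16) * 16.0, times=np.arange(16) * 0.0625,
            amp=amp, nfft=30, sample_rate=480,
        )

    def test_even_occupancy_maximizes_adi_and_zeroes_aei(self):
        spec = self._uniform_spec()
        n_bands = int((240 - 16) // 32)
        assert adi(spec, 16, 240, 32, -50) == pytest.approx(np.log(n_bands))
        assert aei(spec, 16, 240, 32, -50) == pytest.approx(0.0, abs=1e-12)

    def test_single_occupied_band_gives_zero_adi(self):
        amp = np.full((16, 16), 1e-12)
        amp[2, :] = 1.0  # only band containing 32 Hz is above threshold
        spec = Spectrogram(
            freqs=np.arange(16) * 16.0, times=np.arange(16) * 0.0625,
            amp=amp, nfft=30, sample_rate=480,
        )
        assert adi(spec, 16, 240, 32, -50) == 0.0

    def test_one_hot_gini_closed_form(self):
        # 20 bands, one occupied -> Gini = 1 - 1/20
        amp = np.full((21, 16), 1e-12)
        amp[5, :] = 1.0
        spec = Spectrogram(
            freqs=np.arange(21) * 16.0, times=np.arange(16) * 0.0625,
            amp=amp, nfft=30, sample_rate=480,
        )
        assert aei(spec, 0, 320, 16, -50) == pytest.approx(0.95, rel=1e-9)

    def test_threshold_is_relative_so_global_offset_irrelevant(self):
        spec = random_spectrogram(4)
        scaled = Spectrogram(
            freqs=spec.freqs, times=spec.times, amp=spec.amp * 0.01,
            nfft=spec.nfft, sample_rate=spec.sample_rate,
        )
        args = (16, 240, 32, -20)
        assert adi(scaled, *args) == pytest.approx(adi(spec, *args), rel=1e-12)
        assert aei(scaled, *args) == pytest.approx(aei(spec, *args), rel=1e-12)

    def test_band_width_larger_than_range_raises(self):
        with pytest.raises(ValueError):
            adi(random_spectrogram(5), 16, 112, 200, -50)


class TestBi:
    def test_flat_mean_spectrum_scores_zero(self):
        spec = TestAdiAei._uniform_spec()
        assert bi(spec, 0, 240) == pytest.approx(0.0, abs=1e-12)

    def test_single_tone_area_matches_hand_integration(self):
        floor = 10 ** (-10.0 / 20.0)  # one row 10 dB above a flat floor
        amp = np.full((16, 16), floor)
        amp[8, :] = 1.0
        spec = Spectrogram(
            freqs=np.arange(16) * 16.0, times=np.arange(16) * 0.0625,
            amp=amp, nfft=30, sample_rate=480,
        )
        assert bi(spec, 0, 240) == pytest.approx(10.0 * 16.0 / 1000.0, rel=1e-9)

    def test_invariant_under_constant_db_offset(self):
        spec = random_spectrogram(6)
        spec2 = Spectrogram(
            freqs=spec.freqs, times=spec.times, amp=spec.amp * 3.16,
            nfft=spec.nfft, sample_rate=spec.sample_rate,
        )
        assert bi(spec2, 16, 240) == pytest.approx(bi(spec, 16, 240), rel=1e-9)


class TestNdsi:
    @staticmethod
    def _band_spec(rows):
        amp = np.zeros((16, 8))
        amp[rows, :] = 1.0
        return Spectrogram(
            freqs=np.arange(16) * 16.0, times=np.arange(8) * 0.0625,
            amp=amp, nfft=30, sample_rate=480,
        )

    def test_all_power_in_bio_band_gives_plus_one(self):
        assert ndsi(self._band_spec([10, 12]), (16, 112), (112, 240)) == 1.0

    def test_all_power_in_anthro_band_gives_minus_one(self):
        assert ndsi(self._band_spec([2, 4]), (16, 112), (112, 240)) == -1.0

    def test_equal_band_powers_give_zero(self):
        assert ndsi(self._band_spec([2, 10]), (16, 112), (112, 240)) == 0.0

    def test_silent_bands_give_zero(self):
        amp = np.zeros((16, 8))
        spec = Spectrogram(
            freqs=np.arange(16) * 16.0, times=np.arange(8) * 0.0625,
            amp=amp, nfft=30, sample_rate=480,
        )
        assert ndsi(spec, (16, 112), (112, 240)) == 0.0

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError):
            ndsi(self._band_spec([2]), (16, 128), (112, 240))

    def test_invariant_under_scaling(self):
        spec = random_spectrogram(7)
        scaled = Spectrogram(
            freqs=spec.freqs, times=spec.times, amp=spec.amp * 5,
            nfft=spec.nfft, sample_rate=spec.sample_rate,
        )
        bands = ((16, 112), (112, 240))
        assert ndsi(scaled, *bands) == pytest.approx(ndsi(spec, *bands), rel=1e-12)


class TestAcousticEntropy:
    def test_white_noise_is_nearly_maximally_entropic(self, white_noise_10s):
        spec = spectrogram(white_noise_10s, nfft=1024)
        h = acoustic_entropy_h(white_noise_10s, spec)
        assert 0.95 < h <= 1.0

    def test_pure_tone_has_low_entropy(self):
        t = np.arange(5 * FS) / FS
        seg = AudioSegment(0.5 * np.sin(2 * np.pi * 3000.0 * t), FS)
        h = acoustic_entropy_h(seg, spectrogram(seg, nfft=1024))
        assert h < 0.3

    def test_always_within_unit_interval(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            seg = AudioSegment(rng.uniform(-0.3, 0.3, 8192), FS)
            h = acoustic_entropy_h(seg, spectrogram(seg, nfft=1024))
            assert 0.0 <= h <= 1.0

    def test_all_zero_signal_raises(self):
        seg = AudioSegment(np.zeros(4096), FS)
        with pytest.raises(DegenerateSignalError):
            acoustic_entropy_h(seg, spectrogram(seg, nfft=1024))


class TestDsc:
    FR = 46.875

    def test_pure_tone_centroid_at_tone_frequency(self):
        # bin-centered tone so window leakage stays symmetric around it
        f0 = 43 * self.FR  # 2015.625 Hz
        t = np.arange(2 * FS) / FS
        seg = AudioSegment(0.5 * np.sin(2 * np.pi * f0 * t), FS)
        spec = spectrogram(seg, nfft=1024)
        assert dsc(spec, 500, 12000) == pytest.approx(f0, abs=self.FR)

    def test_two_equal_tones_average_to_midpoint(self):
        f1, f2 = 43 * self.FR, 85 * self.FR
        t = np.arange(2 * FS) / FS
        x = 0.3 * np.sin(2 * np.pi * f1 * t) + 0.3 * np.sin(2 * np.pi * f2 * t)
        spec = spectrogram(AudioSegment(x, FS), nfft=1024)
        assert dsc(spec, 500, 12000) == pytest.approx((f1 + f2) / 2, abs=self.FR)

    def test_band_limited_noise_centroid_near_band_midpoint(self):
        from scipy.signal import butter, sosfilt

        rng = np.random.default_rng(13)
        sos = butter(8, [4000, 8000], btype="bandpass", fs=FS, output="sos")
        x = sosfilt(sos, rng.standard_normal(10 * FS))
        spec = spectrogram(AudioSegment(0.1 * x, FS), nfft=1024)
        assert dsc(spec, 3000, 9000) == pytest.approx(6000.0, rel=0.05)

    def test_scale_invariance(self):
        spec = random_spectrogram(8)
        scaled = Spectrogram(
            freqs=spec.freqs, times=spec.times, amp=spec.amp * 7,
            nfft=spec.nfft, sample_rate=spec.sample_rate,
        )
        assert dsc(scaled, 16, 240) == pytest.approx(dsc(spec, 16, 240), rel=1e-12)


class TestZcr:
    def test_1khz_sine_crosses_2000_times_per_second(self, sine_1khz):
        assert zcr(sine_1khz) == pytest.approx(2000, abs=2)

    def test_constant_positive_signal_never_crosses(self):
        assert zcr(AudioSegment(np.full(1000, 0.2), FS)) == 0.0

    def test_alternating_signs_cross_at_every_sample(self):
        x = np.tile([1.0, -1.0], FS // 2)
        assert zcr(AudioSegment(x, FS)) == FS - 1

    def test_dc_offset_suppresses_crossings(self, sine_1khz):
        biased = sine_1khz.with_samples(sine_1khz.samples + 0.6)
        assert zcr(biased) == 0.0


class TestComputeAll:
    def test_range_invariants_hold_on_synthetic_scene(self):
        from ecoeq import generate_scene

        scene = generate_scene(duration=10.0, seed=3)
        cfg = IndexConfig()
        r = compute_all(scene, cfg)
        assert -1.0 <= r.ndsi <= 1.0
        assert 0.0 <= r.h <= 1.0
        assert 0.0 <= r.aei <= 1.0
        n_bands = int(
            (cfg.adi_aei_fmax - cfg.adi_aei_fmin)
            // max(cfg.adi_aei_band_width, 46.875)
        )
        assert 0.0 <= r.adi <= np.log(n_bands)
        assert r.zcr_per_s >= 0
        assert cfg.dsc_fmin <= r.dsc_hz <= cfg.dsc_fmax
        assert r.config_hash == cfg.hash()

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = IndexConfig(adi_aei_band_width=1000.0, bi_fmin=2000.0)
        path = cfg.to_yaml(tmp_path / "cfg.yaml")
        assert IndexConfig.from_yaml(path) == cfg
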