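"""Cleaning pipeline: filters, line removal, ICA, epoching, rejection."""

import numpy as np
import pytest
from scipy import stats
from scipy.signal import periodogram

from conftest import make_recording
from ppaeeg import preprocess as pp
from ppaeeg import synthdata as sd


def tone(freq, fs=500.0, duration=10.0, n_ch=2):
    t = np.arange(int(duration * fs)) / fs
    return np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))


def tone_power(x, fs, freq):
    freqs, psd = periodogram(x, fs=fs)
    return psd[np.argmin(np.abs(freqs - freq))]


class TestSelectTimeRanges:
    def test_length_arithmetic(self, clean_recording):
        out = pp.select_time_ranges(clean_recording, [(10.0, 40.0)])
        assert out.duration == pytest.approx(30.0)

    def test_identity_on_full_range(self, clean_recording):
        out = pp.select_time_ranges(clean_recording, [(0.0, clean_recording.duration)])
        assert np.array_equal(out.data, clean_recording.data)

    def test_overlap_rejected(self, clean_recording):
        with pytest.raises(ValueError):
            pp.select_time_ranges(clean_recording, [(0, 10), (5, 15)])

    def test_empty_and_out_of_range_rejected(self, clean_recording):
        with pytest.raises(ValueError):
            pp.select_time_ranges(clean_recording, [])
        with pytest.raises(ValueError):
            pp.select_time_ranges(clean_recording, [(0, 1e6)])

    def test_annotations_reindexed(self, clean_recording):
        rec = clean_recording.copy_with(annotations=[(15.0, 16.0, "ev")])
        out = pp.select_time_ranges(rec, [(10.0, 20.0)])
        assert out.annotations == [(5.0, 6.0, "ev")]


class TestFilters:
    def test_highpass_removes_dc(self):
        rec = make_recording(np.full((2, 5000), 10.0))
        out = pp.highpass(rec, 1.0)
        assert np.abs(out.data).max() < 0.1  # <1% of input

    def test_lowpass_passband_preserved(self):
        rec = make_recording(tone(10))
        out = pp.lowpass(rec, 40.0)
        mid = slice(1000, 4000)  # avoid edge transients
        ratio = out.data[0, mid].std() / rec.data[0, mid].std()
        assert abs(1 - ratio) < 0.05

    def test_lowpass_attenuates_60hz(self):
        rec = make_recording(tone(60))
        out = pp.lowpass(rec, 40.0)
        before = tone_power(rec.data[0], 500.0, 60.0)
        after = tone_power(out.data[0], 500.0, 60.0)
        assert 10 * np.log10(before / after) >= 20

    def test_linearity(self, rng):
        a = make_recording(rng.standard_normal((2, 4000)))
        b = make_recording(rng.standard_normal((2, 4000)))
        ab = make_recording(a.data + b.data)
        out = pp.highpass(ab).data
        parts = pp.highpass(a).data + pp.highpass(b).data
        assert np.allclose(out, parts, atol=1e-9)

    def test_cutoff_above_nyquist_rejected(self):
        rec = make_recording(tone(10))
        with pytest.raises(ValueError):
            pp.lowpass(rec, 300.0)

    def test_sample_count_unchanged(self, clean_recording):
        assert pp.highpass(clean_recording).n_samples == clean_recording.n_samples


class TestRemoveLineNoise:
    def test_tone_removed_signal_preserved(self):
        fs, t = 500.0, np.arange(10000) / 500.0
        x = np.sin(2 * np.pi * 50 * t) + np.sin(2 * np.pi * 10 * t)
        rec = make_recording(np.tile(x, (2, 1)), fs=fs)
        out = pp.remove_line_noise(rec)
        p50 = tone_power(out.data[0], fs, 50) / tone_power(rec.data[0], fs, 50)
        p10 = tone_power(out.data[0], fs, 10) / tone_power(rec.data[0], fs, 10)
        assert 10 * np.log10(1 / p50) >= 20
        assert abs(10 * np.log10(p10)) < 1

    def test_near_noop_without_line(self, rng):
        # band-limited noise genuinely free of 50 Hz content
        from scipy.signal import butter, sosfiltfilt

        sos = butter(8, 30.0, btype="lowpass", fs=500.0, output="sos")
        x = sosfiltfilt(sos, rng.standard_normal((2, 10000)), axis=1)
        rec = make_recording(x)
        out = pp.remove_line_noise(rec)
        rms = np.sqrt(np.mean(x**2))
        assert np.abs(out.data - x).max() < 0.01 * rms

    def test_line_above_nyquist_rejected(self):
        rec = make_recording(tone(10, fs=80.0), fs=80.0)
        with pytest.raises(ValueError):
            pp.remove_line_noise(rec, line_freq=50.0)

    def test_window_longer_than_signal_rejected(self):
        rec = make_recording(np.zeros((2, 100)) + np.random.default_rng(0).normal(size=(2, 100)))
        with pytest.raises(ValueError):
            pp.remove_line_noise(rec, window_s=4.0)


class TestRereference:
    def test_constant_channels(self):
        rec = make_recording(np.vstack([np.ones(100), 3 * np.ones(100)]))
        out = pp.rereference_average(rec)
        assert np.allclose(out.data[0], -1) and np.allclose(out.data[1], 1)
        assert out.reference == "average"

    def test_idempotent(self, rng):
        rec = make_recording(rng.standard_normal((32, 1000)))
        once = pp.rereference_average(rec)
        twice = pp.rereference_average(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_column_means_vanish(self, rng):
        rec = make_recording(rng.standard_normal((32, 1000)))
        out = pp.rereference_average(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10

    def test_single_channel_rejected(self):
        rec = make_recording(np.zeros((1, 100)) + 1.0)
        with pytest.raises(ValueError):
            pp.rereference_average(rec)


class TestICA:
    def test_recovers_supergaussian_sources(self, rng):
        n = 20000
        S = rng.laplace(size=(3, n))  # super-Gaussian
        A = np.array([[1.0, 0.5, 0.3], [0.2, 1.0, 0.4], [0.3, 0.2, 1.0]])
        rec = make_recording(A @ S, fs=500.0)
        dec = pp.decompose_ica(rec, n_components=3, seed=0)
        # match each true source to its best-correlated recovered source
        for i in range(3):
            corrs = [
                abs(np.corrcoef(S[i], dec.sources[j])[0, 1]) for j in range(3)
            ]
            assert max(corrs) > 0.95

    def test_full_rank_reconstruction(self, rng):
        data = rng.standard_normal((4, 5000))
        rec = make_recording(data, fs=500.0)
        dec = pp.decompose_ica(rec, n_components=4, seed=0)
        recon = dec.reconstruct()
        rel = np.sqrt(np.mean((recon - data) ** 2)) / np.std(data)
        assert rel < 1e-6

    def test_determinism(self, rng):
        data = rng.standard_normal((4, 5000))
        d1 = pp.decompose_ica(make_recording(data), seed=1)
        d2 = pp.decompose_ica(make_recording(data), seed=1)
        assert np.allclose(d1.sources, d2.sources)

    def test_constant_channel_rejected(self, rng):
        data = rng.standard_normal((3, 1000))
        data[1] = 5.0
        with pytest.raises(ValueError):
            pp.decompose_ica(make_recording(data))


class TestRejectComponents:
    def test_blink_cleaning_restores_frontal_kurtosis(self):
        """Cleaned frontal kurtosis falls back toward the blink-free twin's."""
        kw = dict(
            group_sizes={"CG": 1},
            duration=60.0,
            band_power_profile={"CG": dict(sd.CG_BAND_PROFILE)},
            connectivity_profile={"CG": sd.ring_precision(32)},
            seed=11,
        )
        blinky = sd.CohortSpec(artifact_rates=sd.ArtifactRates(15.0, 0, 0), **kw)
        quiet = sd.CohortSpec(artifact_rates=sd.ArtifactRates(0, 0, 0), **kw)
        rec_b = sd.generate_recording(blinky, "CG", 0)
        rec_q = sd.generate_recording(quiet, "CG", 0)
        fidx = [rec_b.channel_names.index(c) for c in ("Fp1", "Fp2")]

        pre = pp.rereference_average(pp.highpass(rec_b))
        dec = pp.decompose_ica(pre, seed=0)
        cleaned, removed = pp.reject_components(dec)
        assert removed, "expected at least one blink component"
        k_clean = stats.kurtosis(cleaned.data[fidx], axis=1).mean()
        k_dirty = stats.kurtosis(pre.data[fidx], axis=1).mean()
        twin = pp.rereference_average(pp.highpass(rec_q))
        k_twin = stats.kurtosis(twin.data[fidx], axis=1).mean()
        assert k_dirty > k_twin + 1.0  # blinks raised kurtosis
        assert abs(k_clean - k_twin) < 0.2 * max(abs(k_dirty - k_twin), 1.0)

    def test_noop_when_nothing_flagged(self, rng):
        rec = make_recording(rng.standard_normal((4, 5000)))
        dec = pp.decompose_ica(rec, n_components=4, seed=0)
        out, removed = pp.reject_components(dec, kurtosis_thresh=50.0)
        assert removed == []
        assert np.allclose(out.data, dec.reconstruct(), atol=1e-9)

    def test_zero_threshold_rejected(self, rng):
        rec = make_recording(rng.standard_normal((4, 5000)))
        dec = pp.decompose_ica(rec, n_components=4, seed=0)
        with pytest.raises(ValueError):
            pp.reject_components(dec, kurtosis_thresh=0.0)


class TestEpoching:
    def test_exact_count(self, rng):
        rec = make_recording(rng.standard_normal((2, 10000)))
        es = pp.epoch(rec)
        assert es.epochs.shape == (20, 2, 500)

    def test_trailing_remainder_discarded(self, rng):
        rec = make_recording(rng.standard_normal((2, 10450)))
        assert pp.epoch(rec).n_epochs == 20

    def test_too_short_rejected(self, rng):
        rec = make_recording(rng.standard_normal((2, 250)))
        with pytest.raises(ValueError):
            pp.epoch(rec)

    def test_epochs_are_contiguous_nonoverlapping(self, rng):
        rec = make_recording(rng.standard_normal((1, 1500)))
        es = pp.epoch(rec)
        assert np.array_equal(es.concatenated(), rec.data[:, :1500])


class TestRejectEpochs:
    def test_spiky_epochs_dropped(self, rng):
        data = rng.standard_normal((12, 2, 500)) * 10
        data[3, 0, 100] = 500.0
        data[7, 1, 20] = -500.0
        from conftest import make_epochs

        es = make_epochs(data)
        kept, n_rej = pp.reject_epochs(es, reject_uV=100.0)
        assert (kept.n_epochs, n_rej) == (10, 2)

    def test_infinite_threshold_keeps_all(self, rng):
        from conftest import make_epochs

        es = make_epochs(rng.standard_normal((5, 2, 500)))
        kept, n_rej = pp.reject_epochs(es, reject_uV=np.inf)
        assert kept.n_epochs == 5 and n_rej == 0

    def test_threshold_below_floor_errors(self, rng):
        from conftest import make_epochs

        es = make_epochs(rng.standard_normal((5, 2, 500)) * 100)
        with pytest.raises(ValueError):
            pp.reject_epochs(es, reject_uV=1e-6)


class TestFullPipeline:
    def test_end_to_end_determinism(self, small_spec):
        rec = sd.generate_recording(small_spec, "CG", 0)
        es1, _ = pp.run_pipeline(rec)
        es2, _ = pp.run_pipeline(rec)
        assert np.array_equal(es1.epochs, es2.epochs)

    def test_channel_count_and_fs_preserved(self, small_spec):
        rec = sd.generate_recording(small_spec, "nfvPPA", 1)
        es, log = pp.run_pipeline(rec)
        assert es.n_channels == rec.n_channels
        assert es.fs == rec.fs
        assert es.n_times == int(rec.fs)
        assert log.n_epochs == es.n_epochs
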