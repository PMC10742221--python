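import numpy as np
import pytest
import scipy.signal

from skillstate import preprocess as pp
from skillstate.io import Recording, RunManifest, ValidationError
from skillstate.spline import laplacian_matrix
from skillstate.synth import SimulationSpec, simulate_subject


def make_rec(data, fs=500.0, events=()):
    names = [f"ch{i}" for i in range(data.shape[1])]
    return Recording(np.asarray(data, float), fs, names, list(events))


def sine(freq, fs, dur, n_ch=1, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return np.tile(amp * np.sin(2 * np.pi * freq * t)[:, None], (1, n_ch))


class TestResample:
    def test_10s_at_500hz_becomes_2500_rows(self):
        rec = make_rec(np.random.default_rng(0).standard_normal((5000, 32)))
        out = pp.resample(rec, 250.0)
        assert out.data.shape == (2500, 32)
        assert out.fs == 250.0

    def test_sine_amplitude_preserved_within_1pct(self):
        rec = make_rec(sine(10, 500, 10))
        out = pp.resample(rec, 250.0)
        mid = out.data[500:-500, 0]
        ref = sine(10, 250, 10)[500:-500, 0]
        assert np.abs(np.abs(mid).max() - 1.0) < 0.01
        assert np.corrcoef(mid, ref)[0, 1] > 0.9999

    def test_event_rescaling(self):
        rec = make_rec(np.zeros((10000, 2)), events=[(5000, "start")])
        assert pp.resample(rec, 250.0).events == [(2500, "start")]

    def test_upsampling_rejected(self):
        with pytest.raises(ValidationError):
            pp.resample(make_rec(np.zeros((100, 2))), 1000.0)


class TestHighpass:
    def test_dc_removed(self):
        rec = make_rec(np.full((5000, 2), 42.0))
        out = pp.highpass(rec, 1.0)
        assert np.abs(out.data).max() < 1e-6 * 42.0

    def test_10hz_passband_attenuation_below_1pct(self):
        rec = make_rec(sine(10, 500, 20))
        out = pp.highpass(rec, 1.0)
        assert np.abs(out.data[2000:-2000]).max() > 0.99

    def test_01hz_stopband_attenuation_above_90pct(self):
        rec = make_rec(sine(0.1, 500, 40))
        out = pp.highpass(rec, 1.0)
        assert np.abs(out.data[5000:-5000]).max() < 0.1


def band_power(x, fs, lo, hi):
    f, p = scipy.signal.welch(x, fs, nperseg=min(len(x), 4096))
    return p[(f >= lo) & (f <= hi)].sum()


class TestLineNoise:
    def test_pure_60hz_suppressed_to_1pct_power(self):
        rec = make_rec(sine(60, 500, 20))
        out = pp.remove_line_noise(rec, 60.0)
        assert np.mean(out.data**2) <= 0.01 * np.mean(rec.data**2)

    def test_broadband_power_change_below_5pct(self):
        rng = np.random.default_rng(0)
        rec = make_rec(rng.standard_normal((10000, 3)))
        out = pp.remove_line_noise(rec, 60.0)
        p0 = np.mean(rec.data**2)
        assert abs(np.mean(out.data**2) - p0) / p0 < 0.05

    def test_line_at_or_above_nyquist_rejected(self):
        rec = make_rec(np.zeros((1000, 2)), fs=250.0)
        with pytest.raises(ValidationError):
            pp.remove_line_noise(rec, 200.0)


class TestBadChannels:
    def test_flatline_channel_flagged(self, montage):
        rng = np.random.default_rng(0)
        spec = SimulationSpec(montage=montage, task_s=6, rest_s=5,
                              pre_trigger_s=1, seed=0)
        rec = simulate_subject(spec, "expert", 0, 0)
        rec.data[:, 4] = 3.14
        assert 4 in pp.detect_bad_channels(rec, montage)

    def test_white_noise_channel_flagged(self, montage):
        spec = SimulationSpec(montage=montage, task_s=6, rest_s=5,
                              pre_trigger_s=1, seed=1)
        rec = simulate_subject(spec, "expert", 0, 0)
        rms = rec.data.std()
        rec.data[:, 7] = np.random.default_rng(1).standard_normal(
            rec.n_samples) * rms
        assert 7 in pp.detect_bad_channels(rec, montage)

    def test_clean_recording_zero_flags(self, montage):
        # mirror the pipeline: mains interference is removed before the
        # neighbour-correlation criterion is applied
        spec = SimulationSpec(montage=montage, task_s=6, rest_s=5,
                              pre_trigger_s=1, bad_channel_prob=0.0, seed=2)
        rec = simulate_subject(spec, "novice", 0, 0)
        rec = pp.remove_line_noise(rec, spec.line_freq)
        assert pp.detect_bad_channels(rec, montage) == set()

    def test_short_recording_rejected(self, montage):
        rec = make_rec(np.zeros((1000, 32)))
        rec.channel_names = montage.labels
        with pytest.raises(ValidationError):
            pp.detect_bad_channels(rec, montage)


class TestInterpolation:
    def test_constant_field_reproduced(self, montage):
        data = np.full((100, 32), 5.0)
        rec = Recording(data, 250.0, montage.labels)
        out = pp.interpolate_channels(rec, montage, {3})
        np.testing.assert_allclose(out.data[:, 3], 5.0, atol=1e-6)

    def test_leave_one_out_on_smooth_topography(self, montage, bank):
        """A smooth scalp map interpolated from the remaining electrodes
        correlates >= 0.95 with the original channel."""
        rng = np.random.default_rng(0)
        coef = rng.standard_normal((200, 1))
        data = coef * bank[1][None, :] * 10  # smooth dipole topography
        rec = Recording(data, 250.0, montage.labels)
        out = pp.interpolate_channels(rec, montage, {10})
        r = np.corrcoef(out.data[:, 10], data[:, 10])[0, 1]
        assert r >= 0.95

    def test_all_channels_flagged_rejected(self, montage):
        rec = Recording(np.zeros((100, 32)), 250.0, montage.labels)
        with pytest.raises(ValidationError):
            pp.interpolate_channels(rec, montage, set(range(32)))


@pytest.mark.parametrize("n_flags,ok", [(0, True), (4, True), (5, False),
                                        (7, False)])
def test_subject_admissibility_threshold(n_flags, ok):
    assert pp.subject_admissible(set(range(n_flags))) is ok


class TestAverageReference:
    def test_column_means_zero(self):
        rng = np.random.default_rng(0)
        rec = make_rec(rng.standard_normal((100, 5)) + 3)
        out = pp.average_reference(rec)
        np.testing.assert_allclose(out.data.mean(axis=1), 0, atol=1e-9)
        assert out.reference == "common-average"

    def test_idempotent(self):
        rec = make_rec(np.random.default_rng(1).standard_normal((50, 4)))
        once = pp.average_reference(rec)
        twice = pp.average_reference(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_single_channel_maps_to_zero(self):
        out = pp.average_reference(make_rec(np.ones((10, 1))))
        np.testing.assert_array_equal(out.data, 0)


class TestASR:
    def _clean_rec(self, montage, seed=0, dur=40):
        spec = SimulationSpec(montage=montage, task_s=dur - 8, rest_s=6,
                              pre_trigger_s=2, seed=seed)
        rec = simulate_subject(spec, "expert", 0, 0)
        return pp.average_reference(pp.resample(rec, 250.0))

    def test_clean_data_passes_nearly_unchanged(self, montage):
        rec = self._clean_rec(montage)
        calib = Recording(rec.data[-30 * 250 :], 250.0, rec.channel_names)
        head = Recording(rec.data[: 10 * 250], 250.0, rec.channel_names)
        out = pp.asr_clean(head, calib, cutoff=20.0)
        rel = np.sqrt(np.mean((out.data - head.data) ** 2)
                      ) / np.sqrt(np.mean(head.data**2))
        assert rel < 0.05

    def test_burst_rms_reduced_at_least_half(self, montage):
        rec = self._clean_rec(montage, seed=1)
        calib = Recording(rec.data[-30 * 250 :].copy(), 250.0,
                          rec.channel_names)
        head = rec.data[: 10 * 250].copy()
        sl = slice(1000, 1125)  # 0.5 s burst on 3 channels
        head[sl, :3] += 200.0 * np.hanning(125)[:, None]
        noisy = Recording(head, 250.0, rec.channel_names)
        out = pp.asr_clean(noisy, calib, cutoff=20.0)
        rms_before = np.sqrt(np.mean(head[sl, :3] ** 2))
        rms_after = np.sqrt(np.mean(out.data[sl, :3] ** 2))
        assert rms_after <= 0.5 * rms_before

    def test_infinite_cutoff_is_identity(self, montage):
        rec = self._clean_rec(montage, seed=2)
        calib = Recording(rec.data[-7500:], 250.0, rec.channel_names)
        out = pp.asr_clean(rec, calib, cutoff=np.inf)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_calibration_shorter_than_window_rejected(self):
        with pytest.raises(ValidationError):
            pp.asr_calibrate(np.zeros((10, 4)), fs=250.0)


class TestSurfaceLaplacian:
    def test_constant_topography_maps_to_zero(self, montage):
        rec = Recording(np.full((20, 32), 7.0), 250.0, montage.labels)
        out = pp.surface_laplacian(rec, montage)
        assert np.abs(out.data).max() < 1e-6

    def test_degree1_harmonic_eigenrelation(self, montage):
        """The Laplace-Beltrami operator maps a degree-1 spherical
        harmonic to n(n+1)=2 times itself (CSD sign convention, unit
        radius)."""
        z = montage.positions[:, 2]
        L = laplacian_matrix(montage.positions, head_radius_m=1.0)
        out = L @ z
        assert np.corrcoef(out, z)[0, 1] > 0.999
        scale = (out @ z) / (z @ z)
        assert scale == pytest.approx(2.0, rel=0.05)

    def test_linearity(self, montage):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((30, 32))
        y = rng.standard_normal((30, 32))
        rec = lambda d: Recording(d, 250.0, montage.labels)
        lap = lambda d: pp.surface_laplacian(rec(d), montage).data
        np.testing.assert_allclose(
            lap(2.0 * x + 3.0 * y), 2.0 * lap(x) + 3.0 * lap(y), atol=1e-9
        )


class TestEpochs:
    def test_three_triggers_three_epochs(self):
        data = np.random.default_rng(0).standard_normal((30 * 250, 4))
        rec = make_rec(data, fs=250.0,
                       events=[(0, "start"), (2500, "start"), (5000, "start")])
        es = pp.extract_task_epochs(rec, "start", 0.0, 10.0)
        assert es.epochs.shape == (3, 2500, 4)

    def test_trigger_at_end_truncation_error(self):
        rec = make_rec(np.zeros((1000, 2)), fs=250.0, events=[(900, "start")])
        with pytest.raises(ValidationError):
            pp.extract_task_epochs(rec, "start", 0.0, 10.0)

    def test_negative_onset_starts_before_trigger(self):
        data = np.arange(5000, dtype=float)[:, None] * np.ones((1, 2))
        rec = make_rec(data, fs=250.0, events=[(1000, "start")])
        es = pp.extract_task_epochs(rec, "start", -2.0, 4.0)
        assert es.epochs[0, 0, 0] == 500.0  # 2 s x 250 Hz before trigger


class TestPipeline:
    def test_stage_order_matches_canonical_chain(self, montage):
        spec = SimulationSpec(montage=montage, task_s=12, rest_s=35,
                              pre_trigger_s=3, seed=0)
        rec = simulate_subject(spec, "expert", 0, 0)
        manifest = RunManifest()
        cfg = pp.PreprocessConfig(calibration_s=30.0)
        epochs, qc = pp.run_pipeline(rec, montage, cfg, manifest)
        assert manifest.stages == pp.PIPELINE_ORDER
        assert qc["admissible"]
        assert epochs.epochs.shape == (1, 2500, 32)
        assert not np.isnan(epochs.epochs).any()
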