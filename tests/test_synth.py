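import numpy as np
import pytest
from scipy.signal import correlate, correlation_lags, spectrogram, welch

from usvloc.geometry import MicArrayGeometry, default_scene, propagation_delay
from usvloc.recording import MultiChannelRecording
from usvloc.synth import (add_sensor_noise, gen_tracks, make_usv_schedule,
                          propagate_to_mics, render_scene, snout_distances,
                          synth_chirp)

FS = 250e3


class TestSynthChirp:
    def test_pure_tone_peak(self):
        w = synth_chirp(70e3, 70e3, 50e-3, FS)
        f = np.fft.rfftfreq(len(w), 1 / FS)
        peak = f[np.argmax(np.abs(np.fft.rfft(w)))]
        assert abs(peak - 70e3) < 200

    def test_sample_count(self):
        assert len(synth_chirp(60e3, 80e3, 0.05, FS)) == 12_500

    def test_ridge_within_sweep_band(self):
        w = synth_chirp(50e3, 80e3, 60e-3, FS)
        f, t, S = spectrogram(w, fs=FS, nperseg=512, noverlap=384)
        ridge = f[np.argmax(S, axis=0)]
        interior = slice(2, -2)  # skip taper edges
        assert ridge[interior].min() > 48e3
        assert ridge[interior].max() < 82e3

    def test_unit_peak_and_taper(self):
        w = synth_chirp(60e3, 70e3, 20e-3, FS)
        assert np.abs(w).max() <= 1.0 + 1e-12
        assert abs(w[0]) < 1e-6 and abs(w[-1]) < 1e-3

    @pytest.mark.parametrize("f0,f1", [(0.0, 50e3), (50e3, 130e3)])
    def test_rejects_out_of_band(self, f0, f1):
        with pytest.raises(ValueError):
            synth_chirp(f0, f1, 0.01, FS)


class TestPropagate:
    def test_equidistant_channels_identical(self):
        arr = MicArrayGeometry([[100, 0, 300], [-100, 0, 300]], "pair")
        rec = propagate_to_mics(synth_chirp(60e3, 70e3, 5e-3, FS),
                                [0, 0, 0], arr, 343e3, FS)
        assert np.allclose(rec.data[0], rec.data[1], atol=1e-9)

    def test_inverse_distance_amplitude(self):
        arr = MicArrayGeometry([[0, 0, 200], [0, 0, 400]], "pair")
        rec = propagate_to_mics(synth_chirp(60e3, 70e3, 5e-3, FS),
                                [0, 0, 0], arr, 343e3, FS)
        rms = np.sqrt((rec.data ** 2).mean(axis=1))
        assert np.isclose(rms[0] / rms[1], 2.0, rtol=0.01)

    def test_tdoa_matches_geometry(self):
        """Cross-correlation lag equals the geometric TDOA within half a
        sample (noise-free forward model)."""
        arr = MicArrayGeometry([[-250, -210, 121], [250, 210, 121]], "pair")
        src = np.array([80.0, -40.0, 10.0])
        rec = propagate_to_mics(synth_chirp(55e3, 75e3, 20e-3, FS),
                                src, arr, 343e3, FS)
        cc = correlate(rec.data[0], rec.data[1])
        lag = correlation_lags(rec.n_samples, rec.n_samples)[np.argmax(cc)]
        tau = propagation_delay(src, arr.positions, 343e3)
        assert abs(lag / FS - (tau[0] - tau[1])) <= 1 / (2 * FS)


class TestSensorNoise:
    @staticmethod
    def _tone_rec():
        w = synth_chirp(70e3, 70e3, 0.2, FS)
        return MultiChannelRecording(np.tile(w, (4, 1)), FS), float(np.mean(w**2))

    def test_infinite_snr_is_identity(self):
        rec, p = self._tone_rec()
        out = add_sensor_noise(rec, "cam64", np.inf, rng=0, signal_power=p)
        assert out.data is rec.data

    @pytest.mark.parametrize("model", ["cam64", "usm4"])
    def test_requested_snr_met(self, model):
        rec, p = self._tone_rec()
        out = add_sensor_noise(rec, model, 10.0, rng=1, signal_power=p)
        noise = out.data[0] - rec.data[0]
        f, Ps = welch(rec.data[0], FS, nperseg=4096)
        f, Pn = welch(noise, FS, nperseg=4096)
        band = (f >= 30e3) & (f <= 110e3)
        snr = 10 * np.log10(np.trapezoid(Ps[band], f[band]) /
                            np.trapezoid(Pn[band], f[band]))
        assert abs(snr - 10.0) < 0.5

    def test_mems_noise_floor_rises(self):
        rec, p = self._tone_rec()
        out = add_sensor_noise(rec, "cam64", 10.0, rng=2, signal_power=p)
        noise = out.data[1] - rec.data[1]
        f, Pn = welch(noise, FS, nperseg=4096)
        p90 = Pn[np.argmin(abs(f - 90e3))]
        p50 = Pn[np.argmin(abs(f - 50e3))]
        assert p90 > p50


class TestTracks:
    def test_positions_within_platform(self, scene):
        for tr in gen_tracks(3, 30, profile="free", seed=4, scene=scene):
            assert scene.platform.contains(tr.snout).all()
            assert scene.platform.contains(tr.head_center).all()

    def test_seed_reproducibility(self):
        a = gen_tracks(2, 10, seed=7)
        b = gen_tracks(2, 10, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x.snout, y.snout)

    def test_close_contact_fraction(self):
        """Close-contact profile keeps most frames within 10 cm
        snout-snout distance, as in real courtship interactions."""
        fracs = [(snout_distances(gen_tracks(2, 40, profile="close",
                                             seed=s)) < 100).mean()
                 for s in range(4)]
        assert min(fracs) >= 0.70

    def test_far_profile_separates(self):
        d = snout_distances(gen_tracks(2, 40, profile="far", seed=3))
        assert np.median(d) > 100


@pytest.fixture(scope="module")
def bundle():
    tracks = gen_tracks(2, 4.0, profile="close", seed=5)
    sched = make_usv_schedule(tracks, 6, (0.3, 3.7), seed=6)
    return render_scene(tracks, sched, seed=7, duration=4.0)


class TestRenderScene:
    def test_ground_truth_conservation(self, bundle):
        assert len(bundle.ground_truth) == 6
        for ev in bundle.ground_truth:
            assert 0 < ev.onset < ev.offset < 4.0

    def test_recording_shapes(self, bundle):
        assert bundle.recordings["cam64"].n_channels == 64
        assert bundle.recordings["usm4"].n_channels == 4
        assert bundle.recordings["usm4"].sample_rate == 250e3

    def test_click_interval_encodes_clock(self, bundle):
        from usvloc.pipeline import recover_clock_map
        cm = recover_clock_map(bundle)
        drift_true = 1 / bundle.params["clock_drift"]
        off_true = -bundle.params["clock_offset"] / bundle.params["clock_drift"]
        assert abs(cm.drift - drift_true) < 1e-5
        assert abs(cm.offset - off_true) < 1e-3

    def test_zero_usvs_still_valid(self):
        tracks = gen_tracks(1, 1.0, seed=1)
        b = render_scene(tracks, [], seed=2, duration=1.0)
        assert b.ground_truth == []
        assert b.recordings["cam64"].n_samples > 0

    def test_seeded_reproducibility(self):
        tracks = gen_tracks(2, 2.0, seed=9)
        sched = make_usv_schedule(tracks, 3, (0.3, 1.7), seed=10)
        a = render_scene(tracks, sched, seed=11, duration=2.0)
        b = render_scene(tracks, sched, seed=11, duration=2.0)
        assert np.array_equal(a.recordings["usm4"].data,
                              b.recordings["usm4"].data)
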