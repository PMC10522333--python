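import numpy as np
import pytest
from scipy.signal import resample

from usvloc.beamform import (coarse_scan, fine_scan, localize_cam64,
                             segment_spectra, steered_power_map)
from usvloc.geometry import (MicArrayGeometry, default_scene, grid_nodes,
                             propagation_delay)
from usvloc.preprocess import UsvSegment
from usvloc.synth import propagate_to_mics, synth_chirp

FS = 250e3
C = 343e3


def render_segment(src, scene, f0=55e3, f1=75e3, dur=50e-3):
    rec = propagate_to_mics(synth_chirp(f0, f1, dur, FS), src,
                            scene.cam64, C, FS)
    seg = UsvSegment(0.0, rec.duration, min(f0, f1) - 5e3, max(f0, f1) + 5e3)
    return seg, rec


def time_domain_argmax(signals, fs, mics, nodes_xy, z, c, up=8):
    """Independent shift-and-sum oracle: upsample, integer-shift, sum power."""
    n = signals.shape[1]
    ups = resample(signals, n * up, axis=1)
    best, best_p = None, -1.0
    for k, (x, y) in enumerate(nodes_xy):
        tau = propagation_delay([x, y, z], mics, c)
        shifts = np.round((tau - tau.min()) * fs * up).astype(int)
        L = n * up - shifts.max()
        acc = np.zeros(L)
        for m in range(len(mics)):
            acc += ups[m, shifts[m]:shifts[m] + L]
        p = float((acc ** 2).sum())
        if p > best_p:
            best, best_p = k, p
    return best


class TestSteeredPower:
    def test_single_mic_constant_field(self, rng):
        spec = (rng.standard_normal(5) + 1j * rng.standard_normal(5))[None, :]
        freqs = 50e3 + 500.0 * np.arange(5)
        nodes = grid_nodes(np.arange(-50, 51, 25.0), np.arange(-50, 51, 25.0))
        p = steered_power_map(spec, freqs, np.array([[0, 0, 465.0]]),
                              nodes, 10.0, C)
        assert np.allclose(p, p[0])
        assert np.isclose(p[0], (np.abs(spec) ** 2).sum())

    def test_global_time_shift_invariance(self, scene):
        seg, rec = render_segment([30.0, -40.0, 10.0], scene)
        spec, freqs = segment_spectra(seg, rec)
        nodes = grid_nodes(np.arange(-50, 51, 10.0), np.arange(-90, 1, 10.0))
        p1 = steered_power_map(spec, freqs, scene.cam64.positions, nodes,
                               10.0, C)
        shift = np.exp(-2j * np.pi * freqs * 123e-6)  # same shift, all chans
        p2 = steered_power_map(spec * shift[None, :], freqs,
                               scene.cam64.positions, nodes, 10.0, C)
        assert np.allclose(p1, p2, rtol=1e-9)

    def test_nonnegative(self, scene):
        seg, rec = render_segment([0.0, 0.0, 10.0], scene)
        spec, freqs = segment_spectra(seg, rec)
        nodes = grid_nodes(np.arange(-20, 21, 10.0), np.arange(-20, 21, 10.0))
        p = steered_power_map(spec, freqs, scene.cam64.positions, nodes,
                              10.0, C)
        assert (p >= 0).all()

    def test_empty_frequency_set_raises(self, scene):
        with pytest.raises(ValueError):
            steered_power_map(np.zeros((4, 0)), np.array([]),
                              scene.cam64.positions,
                              np.zeros((1, 2)), 10.0, C)

    def test_matches_time_domain_oracle(self, rng):
        """Frequency-domain argmax == brute-force shift-and-sum argmax."""
        for trial in range(5):
            mics = np.column_stack([rng.uniform(-120, 120, 6),
                                    rng.uniform(-120, 120, 6),
                                    np.full(6, 400.0)])
            xa = np.arange(-60, 61, 20.0)
            nodes = grid_nodes(xa, xa)
            src_xy = nodes[rng.integers(len(nodes))]
            rec = propagate_to_mics(synth_chirp(55e3, 70e3, 8e-3, FS),
                                    [*src_xy, 10.0],
                                    MicArrayGeometry(mics, "test"), C, FS)
            seg = UsvSegment(0.0, rec.duration, 50e3, 75e3)
            spec, freqs = segment_spectra(seg, rec, max_freqs=48)
            p = steered_power_map(spec, freqs, mics, nodes, 10.0, C)
            k_freq = int(np.argmax(p))
            k_time = time_domain_argmax(rec.data, FS, mics, nodes, 10.0, C)
            assert k_freq == k_time


class TestScans:
    def test_coarse_grid_shape(self, scene):
        seg, rec = render_segment([0.0, 0.0, 10.0], scene)
        field = coarse_scan(seg, rec, scene)
        assert field.values.shape == (41, 51)  # inclusive 10 mm nodes

    def test_coarse_peak_near_source(self, scene):
        src = np.array([80.0, -40.0, 10.0])
        seg, rec = render_segment(src, scene)
        field = coarse_scan(seg, rec, scene)
        assert np.linalg.norm(field.peak_xy - src[:2]) <= 10.0

    def test_source_beyond_platform_edge_localized(self, scene):
        src = np.array([220.0, 0.0, 10.0])  # 20 mm beyond the platform
        seg, rec = render_segment(src, scene)
        est = localize_cam64(seg, rec, scene)
        assert np.linalg.norm(est.origin - src[:2]) < 2.0

    def test_fine_window_shape(self, scene):
        seg, rec = render_segment([0.0, 0.0, 10.0], scene)
        field = fine_scan(seg, rec, scene, center=(0.0, 0.0))
        assert field.values.shape == (31, 31)  # 30 mm inclusive at 1 mm

    def test_fine_centroid_accuracy(self, scene):
        src = np.array([-57.3, 33.8, 10.0])
        seg, rec = render_segment(src, scene)
        est = localize_cam64(seg, rec, scene)
        assert np.linalg.norm(est.origin - src[:2]) <= 1.5

    def test_split_half_consistency(self, scene):
        """Two halves of the same call localize to the same origin."""
        src = np.array([25.0, 60.0, 10.0])
        rec = propagate_to_mics(synth_chirp(55e3, 75e3, 60e-3, FS), src,
                                scene.cam64, C, FS)
        halves = [UsvSegment(0.0, 0.03, 50e3, 80e3),
                  UsvSegment(0.03, 0.06, 50e3, 80e3)]
        origins = [localize_cam64(s, rec, scene).origin for s in halves]
        assert np.linalg.norm(origins[0] - origins[1]) <= 1.0


class TestFieldSnr:
    def test_single_hot_cell_formula(self):
        """One cell = v, N-1 zeros: SNR = N / sqrt(N-1)."""
        from usvloc.beamform import SoundFieldEstimate, field_snr
        N = 2000
        vals = np.zeros(N)
        vals[3] = 7.5
        field = SoundFieldEstimate(
            x_axis=np.arange(50.0), y_axis=np.arange(40.0),
            values=vals.reshape(40, 50), peak_xy=np.zeros(2),
            centroid_xy=np.zeros(2),
            snr=float(vals.max() / vals.std()))
        assert np.isclose(field_snr(field), N / np.sqrt(N - 1), rtol=1e-12)

    def test_scale_invariance(self, scene):
        seg, rec = render_segment([0.0, 0.0, 10.0], scene)
        f1 = coarse_scan(seg, rec, scene)
        rec.data *= 3.0
        f2 = coarse_scan(seg, rec, scene)
        assert np.isclose(f1.snr, f2.snr, rtol=1e-9)

    def test_constant_field_degenerate(self):
        from usvloc.beamform import _field_estimate
        f = _field_estimate(np.arange(5.0), np.arange(4.0), np.ones(20))
        assert f.degenerate


class TestTranslationEquivariance:
    def test_shifted_source_shifts_argmax(self, scene):
        shift = np.array([30.0, -20.0])
        args = []
        for s in (np.array([10.0, 10.0]), np.array([10.0, 10.0]) + shift):
            seg, rec = render_segment([*s, 10.0], scene)
            field = coarse_scan(seg, rec, scene)
            args.append(field.peak_xy)
        assert np.allclose(args[1] - args[0], shift, atol=1e-9)


class TestVeryHighFrequencyWeakness:
    def test_vhf_call_has_lower_snr_under_mems_noise(self, scene):
        """Calls above 90 kHz hit the rising MEMS noise floor (and the
        95 kHz analysis cap) and grade worse than mid-band calls at the
        same source level and the same absolute noise level."""
        from usvloc.synth import add_sensor_noise
        recs = {name: propagate_to_mics(synth_chirp(f0, f1, 50e-3, FS),
                                        [0.0, 0.0, 10.0], scene.cam64, C, FS)
                for name, (f0, f1) in {"mid": (55e3, 70e3),
                                       "vhf": (95e3, 108e3)}.items()}
        p_ref = float((recs["mid"].data ** 2).mean())
        snrs = {}
        for name, (f0, f1) in {"mid": (55e3, 70e3),
                               "vhf": (95e3, 108e3)}.items():
            rec = add_sensor_noise(recs[name], "cam64", 0.0, rng=5,
                                   signal_power=p_ref)
            seg = UsvSegment(0.0, rec.duration, f0 - 5e3,
                             min(f1 + 5e3, 95e3))
            snrs[name] = coarse_scan(seg, rec, scene).snr
        assert snrs["vhf"] < 0.6 * snrs["mid"]
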