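import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from usvloc.assign import (AssignmentResult, CalibrationScale,
                           assign_dataset, calibrate_sigma,
                           estimate_systematic_offset, hybrid_select,
                           mouth_point, mpi)
from usvloc.beamform import LocalizationEstimate


def est(x, y, unc=0.02, method="cam64", snr=None):
    return LocalizationEstimate(origin=np.array([x, y], dtype=float),
                                uncertainty=unc, method=method, snr=snr)


class TestMouthPoint:
    def test_zero_fraction_is_snout(self):
        assert np.allclose(mouth_point([3, 4], [9, 4], 0.0), [3, 4])

    def test_manual_fraction(self):
        assert np.allclose(mouth_point([0, 0], [10, 0], 0.02), [0.2, 0])

    def test_automatic_fraction_ahead_of_snout(self):
        assert np.allclose(mouth_point([0, 0], [10, 0], -0.15), [-1.5, 0])

    def test_coincident_markers_raise(self):
        with pytest.raises(ValueError):
            mouth_point([1, 1], [1, 1], 0.02)


class TestMpi:
    def test_single_mouse_in_range(self):
        assert mpi([0, 0], [[10, 0]], 5.0)[0] == 1.0

    def test_equidistant_pair_symmetric(self):
        v = mpi([0, 0], [[10, 0], [-10, 0]], 5.0)
        assert np.allclose(v, [0.5, 0.5])

    def test_gaussian_example(self):
        # estimate (0,0); mice at 5 mm and 30 mm; sigma = 4.8
        v = mpi([0, 0], [[5, 0], [30, 0]], 4.8)
        expected = np.exp(-25 / 46.08) / (np.exp(-25 / 46.08)
                                          + np.exp(-900 / 46.08))
        assert np.isclose(v[0], expected, rtol=1e-12)
        assert v[0] > 1 - 1e-8

    def test_all_out_of_range(self):
        v = mpi([0, 0], [[60, 0], [0, 70]], 5.0)
        assert np.all(v == 0)

    @settings(deadline=None, max_examples=200)
    @given(st.integers(1, 3), st.floats(1.0, 20.0), st.integers(0, 10_000))
    def test_normalization_and_monotonicity(self, n_mice, sigma, seed):
        rng = np.random.default_rng(seed)
        mouths = rng.uniform(-35, 35, (n_mice, 2))  # all inside the gate
        v = mpi([0.0, 0.0], mouths, sigma)
        assert np.isclose(v.sum(), 1.0)
        # moving mouse 0 closer never decreases its MPI
        closer = mouths.copy()
        closer[0] *= 0.5
        v2 = mpi([0.0, 0.0], closer, sigma)
        assert v2[0] >= v[0] - 1e-12


class TestCalibration:
    def test_scale_arithmetic(self):
        assert np.isclose(calibrate_sigma([0.02], [4.0]), 200.0)

    def test_already_calibrated(self):
        assert np.isclose(calibrate_sigma([3.0, 5.0], [4.0, 4.0]), 1.0)

    def test_homogeneity(self):
        s1 = calibrate_sigma([0.01, 0.03], [2.0, 6.0])
        s2 = calibrate_sigma([0.05, 0.15], [2.0, 6.0])
        assert np.isclose(s2, s1 / 5.0)

    def test_zero_mean_raises(self):
        with pytest.raises(ValueError):
            calibrate_sigma([0.0, 0.0], [4.0])


class TestHybridSelect:
    MOUTHS = np.array([[4.0, 0.0], [40.0, 0.0]])

    def test_both_reliable_smaller_residual_wins(self):
        r = hybrid_select(0, {"cam64": est(0, 0), "slim": est(-8, 0, 0.02,
                                                             "slim")},
                          self.MOUTHS, {"cam64": 3.0, "slim": 3.0})
        assert r.method == "cam64" and r.mouse_id == 0
        assert np.isclose(r.residual_mm, 4.0)

    def test_one_reliable(self):
        # slim sharp near mouse 0; cam64 halfway between both mice -> low MPI
        r = hybrid_select(0, {"cam64": est(22, 0), "slim": est(3, 0, 0.02,
                                                              "slim")},
                          self.MOUTHS, {"cam64": 15.0, "slim": 3.0})
        assert r.method == "slim" and r.mouse_id == 0

    def test_none_reliable_low_mpi(self):
        mouths = np.array([[10.0, 0.0], [-10.0, 0.0]])
        r = hybrid_select(0, {"cam64": est(0, 0), "slim": est(0, 1, 0.02,
                                                             "slim")},
                          mouths, {"cam64": 8.0, "slim": 8.0})
        assert not r.assigned
        assert r.reason == "low-MPI"

    def test_distance_gate(self):
        mouths = np.array([[200.0, 0.0]])
        r = hybrid_select(0, {"cam64": est(0, 0), "slim": None},
                          mouths, {"cam64": 3.0})
        assert not r.assigned
        assert r.reason == "distance-gate"

    def test_no_estimates(self):
        r = hybrid_select(0, {"cam64": None, "slim": None}, self.MOUTHS, {})
        assert r.reason == "no-estimate"


class TestSystematicOffset:
    def test_injected_bias_recovered(self, rng):
        mouths = rng.uniform(-100, 100, (200, 2))
        origins = mouths + [2.0, 0.0] + 0.3 * rng.standard_normal((200, 2))
        off = estimate_systematic_offset(origins, mouths)
        assert np.allclose(off, [2.0, 0.0], atol=0.15)
        resid = (origins - off) - mouths
        assert np.allclose(resid.mean(axis=0), 0.0, atol=1e-9)

    def test_unbiased_near_zero(self, rng):
        mouths = rng.uniform(-100, 100, (300, 2))
        origins = mouths + 0.8 * rng.standard_normal((300, 2))
        off = estimate_systematic_offset(origins, mouths)
        assert np.linalg.norm(off) < 0.5

    def test_too_few_assignments(self):
        assert estimate_systematic_offset(np.zeros((3, 2)),
                                          np.zeros((3, 2))) is None


class TestAssignDataset:
    def test_threshold_consistency(self, small_run):
        """Every assignment satisfies the MPI threshold and distance gate."""
        for r in small_run["assignments"]:
            if r.assigned:
                assert r.mpi_per_method[r.method].max() > 0.95
                assert r.residual_mm <= 50.0

    def test_hybrid_superset(self, small_bundle, small_run):
        """Hybrid assigns at least every call either method alone assigns."""
        segs = small_run["segments"]
        ests = small_run["estimates"]
        hybrid_ids = {r.usv_index for r in small_run["assignments"]
                      if r.assigned}
        n = len(segs)
        for solo in ("cam64", "slim"):
            other = "slim" if solo == "cam64" else "cam64"
            results = assign_dataset(segs,
                                     ests[solo] if solo == "cam64" else [None] * n,
                                     ests[solo] if solo == "slim" else [None] * n,
                                     small_bundle.tracks)
            solo_ids = {r.usv_index for r in results if r.assigned}
            assert solo_ids <= hybrid_ids | solo_ids  # sanity
            assert len(hybrid_ids) >= len(solo_ids)

    def test_correct_emitter_when_separated(self, small_bundle, small_run):
        """With well-separated snouts the assigned emitter matches truth."""
        from usvloc.assign import min_snout_distance_at
        s2t = small_run["segment_to_truth"]
        n_ok = n_tot = 0
        for r in small_run["assignments"]:
            if not r.assigned or s2t[r.usv_index] is None:
                continue
            ev = small_bundle.ground_truth[s2t[r.usv_index]]
            if min_snout_distance_at(small_bundle.tracks, ev.midpoint) < 25:
                continue
            n_tot += 1
            n_ok += int(r.mouse_id == ev.emitter_id)
        assert n_tot == 0 or n_ok / n_tot >= 0.99

    def test_no_mice_in_range(self, small_bundle, small_run):
        """Moving all tracks off the platform unassigns everything."""
        import copy
        far_tracks = copy.deepcopy(small_bundle.tracks)
        for tr in far_tracks:
            tr.snout += 5000.0
            tr.head_center += 5000.0
        segs = small_run["segments"]
        res = assign_dataset(segs, small_run["estimates"]["cam64"],
                             small_run["estimates"]["slim"], far_tracks,
                             calibration=CalibrationScale(
                                 {"cam64": 100.0, "slim": 1.0}))
        assert all(not r.assigned for r in res)
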