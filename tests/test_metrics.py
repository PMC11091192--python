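"""Shape descriptors, unit mapping, distance series and contact times."""

import numpy as np
import pytest

from chrom4d.metrics import (
    ContactTimeSeries,
    contact_times,
    cooccurrence_fraction,
    distance_series,
    gyration_shape,
    hull_volume,
    map_length_scale,
    map_time_scale,
    smooth_series,
)
from chrom4d.state import Conformation, Trajectory
from conftest import brute_gyration_tensor


def _rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(7)).as_matrix()


class TestGyrationShape:
    def test_collinear_chain_anisotropy_one(self):
        x = np.zeros((12, 3))
        x[:, 0] = np.arange(12)
        s = gyration_shape(x)
        assert s.anisotropy == pytest.approx(1.0, abs=1e-12)
        assert s.asphericity > 0

    def test_octahedron_is_isotropic(self):
        x = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                      [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)
        s = gyration_shape(x)
        assert s.anisotropy == pytest.approx(0.0, abs=1e-12)
        assert s.asphericity == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_sum_definition(self, rng):
        x = rng.normal(size=(10, 3))
        s = gyration_shape(x)
        np.testing.assert_allclose(s.tensor, brute_gyration_tensor(x), atol=1e-12)

    def test_trace_equals_rg_squared(self, rng):
        x = rng.normal(size=(25, 3))
        s = gyration_shape(x)
        rg2 = np.mean(np.sum((x - x.mean(0)) ** 2, axis=1))
        assert s.rg2 == pytest.approx(rg2, rel=1e-12)

    def test_rigid_motion_invariance(self, rng):
        x = rng.normal(size=(15, 3))
        R = _rotation(rng)
        y = x @ R.T + np.array([5.0, -3.0, 2.0])
        a, b = gyration_shape(x), gyration_shape(y)
        assert a.anisotropy == pytest.approx(b.anisotropy, abs=1e-10)
        assert a.asphericity == pytest.approx(b.asphericity, abs=1e-10)

    def test_single_bead_rejected(self):
        with pytest.raises(ValueError):
            gyration_shape(np.zeros((1, 3)))


class TestHullVolume:
    def test_unit_tetrahedron(self):
        x = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        assert hull_volume(x) == pytest.approx(1.0 / 6.0, rel=1e-12)

    def test_cube_with_rotation(self, rng):
        corners = np.array([[i, j, k] for i in (0, 2) for j in (0, 2) for k in (0, 2)],
                           dtype=float)
        R = _rotation(rng)
        assert hull_volume(corners) == pytest.approx(8.0, rel=1e-12)
        assert hull_volume(corners @ R.T) == pytest.approx(8.0, rel=1e-9)

    def test_physical_units_scaling(self):
        x = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        assert hull_volume(x, sigma_nm=30.0) == pytest.approx(27_000 / 6.0, rel=1e-9)

    def test_coplanar_rejected(self):
        x = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="degenerate"):
            hull_volume(x)


class TestUnitMapping:
    def test_locus_scale_is_thirty_nm(self):
        assert map_length_scale(500.0) == pytest.approx(29.62, abs=0.01)

    def test_identity_limit(self):
        assert map_length_scale(6.6e9) == pytest.approx(7000.0)

    def test_cube_root_scaling(self):
        assert map_length_scale(1000.0) == pytest.approx(
            map_length_scale(500.0) * 2 ** (1 / 3), rel=1e-12)

    def test_invalid_g(self):
        with pytest.raises(ValueError):
            map_length_scale(0.0)
        with pytest.raises(ValueError):
            map_length_scale(1e10)

    def test_tau_scales_cubically_in_sigma(self):
        assert map_time_scale(sigma_nm=60.0) == pytest.approx(
            8 * map_time_scale(sigma_nm=30.0), rel=1e-12)

    def test_tau_linear_in_viscosity(self):
        assert map_time_scale(eta_Pa_s=4e-4) == pytest.approx(
            2 * map_time_scale(eta_Pa_s=2e-4), rel=1e-12)


def _toy_traj(dists):
    """Trajectory of 2 beads at controlled distances along x."""
    frames = []
    for k, d in enumerate(dists):
        beads = np.array([[0.0, 0, 0], [d, 0, 0]])
        frames.append(Conformation(beads=beads, time=k + 1))
    return Trajectory(frames=frames, sample_interval=1000)


class TestDistanceSeries:
    def test_hand_computed_distances(self):
        traj = _toy_traj([1.0, 2.5, 4.0])
        ser = distance_series(traj, 0, 1, sigma_nm=30.0)
        np.testing.assert_allclose(ser.distances_nm, [30.0, 75.0, 120.0])
        assert ser.mean == pytest.approx(75.0)

    def test_static_conformation_constant(self):
        ser = distance_series(_toy_traj([2.0, 2.0, 2.0]), 0, 1)
        assert ser.sd == 0.0

    def test_identical_indices_warns_and_zeros(self):
        with pytest.warns(UserWarning):
            ser = distance_series(_toy_traj([1.0, 2.0]), 1, 1)
        np.testing.assert_array_equal(ser.distances_nm, 0.0)

    def test_bad_index(self):
        with pytest.raises(ValueError):
            distance_series(_toy_traj([1.0]), 0, 5)


class TestSmoothing:
    def test_constant_unchanged(self):
        y = np.full(30, 4.2)
        np.testing.assert_allclose(smooth_series(y, 7), y)

    def test_linear_ramp_unchanged(self):
        y = np.linspace(0, 10, 40)
        np.testing.assert_allclose(smooth_series(y, 9, order=1), y, atol=1e-9)

    def test_variance_reduction_on_noise(self, rng):
        t = np.linspace(0, 6 * np.pi, 300)
        y = np.sin(t) + rng.normal(scale=0.5, size=t.size)
        sm = smooth_series(y, 21)
        assert np.var(sm - np.sin(t)) < np.var(y - np.sin(t))

    def test_window_validation(self):
        y = np.ones(10)
        with pytest.raises(ValueError):
            smooth_series(y, 4)
        with pytest.raises(ValueError):
            smooth_series(y, 11)
        with pytest.raises(ValueError):
            smooth_series(y, 5, order=5)


class TestContactTimes:
    def test_all_below_single_edge_run(self):
        ct = contact_times(np.full(10, 50.0), threshold_nm=150.0)
        assert ct.durations.size == 0 and ct.gaps.size == 0
        assert ct.edge_runs.sum() == 10
        ct_inc = contact_times(np.full(10, 50.0), include_edges=True)
        assert list(ct_inc.durations) == [10]

    def test_run_length_hand_count(self):
        # below-below-above-below: durations [2, 1], gap [1] (edges included)
        y = np.array([100.0, 100.0, 200.0, 100.0])
        ct = contact_times(y, threshold_nm=150.0, include_edges=True)
        assert sorted(ct.durations) == [1, 2]
        assert list(ct.gaps) == [1]

    def test_never_below_gives_empty_contacts(self):
        ct = contact_times(np.full(8, 500.0), include_edges=True)
        assert ct.durations.size == 0
        assert ct.mean_contact_time is None
        assert list(ct.gaps) == [8]

    def test_runs_tile_series_exactly(self, rng):
        for _ in range(20):
            y = rng.choice([100.0, 200.0], size=rng.integers(1, 60))
            ct = contact_times(y, threshold_nm=150.0)
            total = ct.durations.sum() + ct.gaps.sum() + ct.edge_runs.sum()
            assert total == y.size

    def test_physical_time_conversion(self):
        ser = ContactTimeSeries(distances_nm=np.array([10.0, 10.0, 300.0, 10.0, 10.0, 300.0]),
                                frame_interval_s=0.5e-3)
        ct = contact_times(ser, threshold_nm=150.0)
        assert ct.mean_contact_time == pytest.approx(2 * 0.5e-3)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            contact_times(np.array([]))


class TestCooccurrence:
    def test_always_together_is_one(self):
        pos = np.zeros((5, 6, 3))
        assert cooccurrence_fraction(pos, [0, 2, 4], threshold=1.0) == 1.0

    def test_pinned_apart_is_zero(self):
        pos = np.zeros((4, 3, 3))
        pos[:, 1, 0] = 100.0
        pos[:, 2, 0] = 200.0
        assert cooccurrence_fraction(pos, [0, 1, 2], threshold=5.0) == 0.0

    def test_matches_brute_force_frame_scan(self, rng):
        pos = rng.normal(scale=3.0, size=(50, 8, 3))
        els = [1, 4, 6]
        thr = 4.0
        got = cooccurrence_fraction(pos, els, threshold=thr)
        count = 0
        for f in range(50):
            ok = True
            for a in range(3):
                for b in range(a + 1, 3):
                    if np.linalg.norm(pos[f, els[a]] - pos[f, els[b]]) >= thr:
                        ok = False
            count += ok
        assert got == pytest.approx(count / 50)

    def test_validation(self):
        pos = np.zeros((2, 5, 3))
        with pytest.raises(ValueError):
            cooccurrence_fraction(pos, [1], threshold=1.0)
        with pytest.raises(ValueError):
            cooccurrence_fraction(pos, [1, 1, 2], threshold=1.0)
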