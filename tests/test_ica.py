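import numpy as np
import pytest

from dsaflow import (DSASeries, TimeGrid, ValidationError, assign_phases,
                     decompose, detect_two_peaks, fix_signs, flatten_series,
                     unflatten_map)
from dsaflow.ica import ComponentSet

from conftest import matched_abs_corr


def _mini_series(frames):
    grid = TimeGrid(np.arange(frames.shape[0], dtype=float) * 0.5)
    return DSASeries(frames=frames, grid=grid)


class TestFlatten:
    def test_row_major_bookkeeping(self):
        frames = np.arange(3 * 16 * 16, dtype=float).reshape(3, 16, 16)
        data, shape = flatten_series(_mini_series(frames))
        assert data.shape == (3, 256)
        # entry (1, k) is pixel (k // 16, k % 16) of frame 1
        assert data[1, 16 * 2 + 5] == frames[1, 2, 5]
        assert shape == (16, 16)

    def test_unflatten_inverts_bit_exact(self):
        frames = np.random.default_rng(0).random((4, 16, 20))
        data, shape = flatten_series(_mini_series(frames))
        for t in range(4):
            np.testing.assert_array_equal(unflatten_map(data[t], shape),
                                          frames[t])

    def test_constant_frame_gives_constant_row(self):
        frames = np.ones((3, 16, 16))
        frames[1] *= 7.0
        data, _ = flatten_series(_mini_series(frames))
        assert np.ptp(data[1]) == 0.0 and data[1][0] == 7.0


def _rank3_mixture(seed=0, noise=0.0, T=40, shape=(24, 24)):
    """Exact sum of 3 outer products: sparse independent maps x courses.

    The maps satisfy the decomposition's assumptions — each pixel joins
    each support independently, so the sources really are independent —
    and the courses have comparable peak density, as calibrated contrast
    loads do in practice."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 12, T)

    def bump(t0, a, b):
        x = np.clip(t - t0, 0, None)
        c = x ** a * np.exp(-x / b)
        return c / c.max()

    courses = np.stack([bump(0.5, 4, 0.3), bump(1.0, 3, 1.2), bump(4.0, 3, 1.0)])
    p = shape[0] * shape[1]
    maps = (rng.random((3, p)) < 0.08) * rng.lognormal(0, 0.5, (3, p))
    data = courses.T @ maps
    if noise:
        data = data + rng.normal(0, noise * data.max(), data.shape)
    return data, courses, maps, shape


class TestDecompose:
    def test_recovers_noiseless_rank3_sources(self):
        data, courses, _, shape = _rank3_mixture(seed=1)
        comps = decompose(data, shape, seed=1)
        truth = {i: courses[i] for i in range(3)}
        best = matched_abs_corr(comps.time_courses, truth)
        assert min(best.values()) >= 0.99

    def test_reconstruction_error_below_5pct(self):
        data, *_, shape = _rank3_mixture(seed=2)
        comps = decompose(data, shape, seed=2)
        centered = data - comps.mean_course[:, None]
        rel = np.linalg.norm(centered - comps.reconstruct()) / np.linalg.norm(centered)
        assert rel <= 0.05

    def test_same_seed_is_bit_identical(self):
        data, *_, shape = _rank3_mixture(seed=3)
        a = decompose(data, shape, seed=7)
        b = decompose(data, shape, seed=7)
        np.testing.assert_array_equal(a.time_courses, b.time_courses)
        np.testing.assert_array_equal(a.spatial_maps, b.spatial_maps)

    def test_rank1_data_flagged_not_crashed(self):
        t = np.linspace(0, 1, 30)
        data = np.outer(t, np.ones(64))
        comps = decompose(data, (8, 8), seed=0, max_iter=50)
        assert comps.time_courses.shape == (3, 30)  # degenerate but intact

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValidationError):
            decompose(np.ones((2, 64)), (8, 8), seed=0)


class TestFixSigns:
    def _comps(self, courses):
        maps = np.random.default_rng(0).normal(size=(3, 4, 4))
        return ComponentSet(spatial_maps=maps,
                            time_courses=np.asarray(courses, dtype=float),
                            mean_course=np.zeros(3))

    def test_negative_dominant_course_flipped(self):
        comps = self._comps([[0, -5, -1], [0, 5, 1], [1, -1, 0.5]])
        fixed = fix_signs(comps)
        np.testing.assert_array_equal(fixed.time_courses[0], [0, 5, 1])
        np.testing.assert_array_equal(fixed.time_courses[1], [0, 5, 1])
        np.testing.assert_array_equal(fixed.spatial_maps[0],
                                      -comps.spatial_maps[0])
        np.testing.assert_array_equal(fixed.spatial_maps[1],
                                      comps.spatial_maps[1])

    def test_reconstruction_invariant_bit_exact(self):
        comps = self._comps([[0, -5, -1], [0, 5, 1], [1, -1, 0.5]])
        np.testing.assert_array_equal(fix_signs(comps).reconstruct(),
                                      comps.reconstruct())


class TestAssignPhases:
    def _comps(self, courses, energies=(1.0, 1.0, 1.0)):
        maps = np.stack([np.full((4, 4), np.sqrt(e / 16.0)) for e in energies])
        return ComponentSet(spatial_maps=maps,
                            time_courses=np.asarray(courses, dtype=float),
                            mean_course=np.zeros(4))

    def test_ordered_by_time_to_peak(self):
        grid = TimeGrid(np.array([0.0, 2.0, 4.5, 7.0]))
        comps = self._comps([[0, 0, 1, 0],   # TTP 4.5 -> capillary
                             [0, 0, 0, 1],   # TTP 7.0 -> venous
                             [0, 1, 0, 0]])  # TTP 2.0 -> arterial
        labeled = assign_phases(comps, grid)
        assert labeled.phase_labels == ("capillary", "venous", "arterial")

    def test_ttp_tie_broken_by_map_energy(self):
        grid = TimeGrid(np.array([0.0, 3.0, 6.0, 9.0]))
        comps = self._comps([[0, 1, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]],
                            energies=(5.0, 10.0, 1.0))
        labeled = assign_phases(comps, grid)
        # higher-energy tied component takes the earlier phase
        assert labeled.phase_labels == ("capillary", "arterial", "venous")

    def test_grid_length_mismatch(self):
        comps = self._comps([[0, 1, 0, 0]] * 3)
        with pytest.raises(ValidationError):
            assign_phases(comps, TimeGrid(np.array([0.0, 1.0])))

    def test_easy_phantom_labels_match_ground_truth(self, easy_phantom):
        series, truth = easy_phantom
        data, shape = flatten_series(series)
        comps = assign_phases(fix_signs(decompose(data, shape, seed=11)),
                              series.grid)
        for phase in ("arterial", "capillary", "venous"):
            r = abs(np.corrcoef(comps.course_for(phase),
                                truth.courses[phase])[0, 1])
            assert r >= 0.99, phase


class TestTwoPeakDetector:
    def test_bimodal_curve_flagged(self):
        t = np.linspace(0, 12, 60)
        curve = np.exp(-0.5 * ((t - 3) / 0.6) ** 2) \
            + 0.8 * np.exp(-0.5 * ((t - 7) / 1.0) ** 2)
        assert detect_two_peaks(curve)

    def test_single_bolus_not_flagged(self):
        t = np.linspace(0, 12, 60)
        x = np.clip(t - 1, 0, None)
        assert not detect_two_peaks(x ** 3 * np.exp(-x / 1.2))

    def test_flat_curve_not_flagged(self):
        assert not detect_two_peaks(np.zeros(30))
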