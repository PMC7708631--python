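"""Gaze statistics: saccade records, angles, joint density, summaries."""

import numpy as np
import pytest

from scenewalk.core import Fixation, Scanpath
from scenewalk.stats import (
    binned_by_turning_angle,
    distribution_summaries,
    normalized_joint_density,
    saccades_from_path,
    saccades_from_paths,
    turning_angle,
)


def _path(points, dur=0.25, subject="s0", image="img"):
    return Scanpath(tuple(Fixation(x, y, dur) for x, y in points),
                    subject=subject, image=image)


class TestSaccadeRecords:
    def test_two_fixations_one_record_without_turning(self):
        recs = saccades_from_path(_path([(0.0, 0.0), (3.0, 4.0)]))
        assert len(recs) == 1
        assert recs[0].amplitude == pytest.approx(5.0)
        assert recs[0].turning is None

    def test_single_fixation_yields_no_saccades(self):
        assert saccades_from_path(_path([(1.0, 1.0)])) == []

    def test_collinear_equal_steps_all_forward(self):
        recs = saccades_from_path(_path([(0, 0), (1, 0), (2, 0), (3, 0)]))
        assert [r.turning for r in recs] == [None, 0.0, 0.0]

    def test_direction_convention_zero_is_rightward(self):
        recs = saccades_from_path(_path([(0, 0), (2, 0), (2, 2)]))
        assert recs[0].direction == pytest.approx(0.0)
        assert recs[1].direction == pytest.approx(90.0)

    def test_preceding_duration_is_launch_fixation_duration(self):
        p = Scanpath((Fixation(0, 0, 0.1), Fixation(1, 0, 0.9)))
        assert saccades_from_path(p)[0].preceding_duration == pytest.approx(0.1)


class TestTurningAngle:
    @pytest.mark.parametrize("prev,nxt,expected", [
        ((1, 0), (1, 0), 0.0),
        ((1, 0), (0, 1), 90.0),
        ((1, 0), (-1, 0), 180.0),
        ((1, 0), (0, -1), -90.0),
        ((0, 1), (1, 1), -45.0),
    ])
    def test_signed_convention(self, prev, nxt, expected):
        assert turning_angle(prev, nxt) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            turning_angle((0, 0), (1, 0))

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=2), rng.normal(size=2)
            t = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
            assert turning_angle(R @ a, R @ b) == pytest.approx(
                turning_angle(a, b), abs=1e-9)


class TestJointDensity:
    def test_exact_return_lands_at_minus_one_zero(self):
        H, edges, _ = normalized_joint_density(
            [_path([(0, 0), (2, 0), (0, 0)])])
        centers = 0.5 * (edges[:-1] + edges[1:])
        i, j = np.unravel_index(H.argmax(), H.shape)
        assert centers[i] == pytest.approx(-1.0, abs=0.051)
        assert centers[j] == pytest.approx(0.0, abs=0.051)

    def test_forward_equal_amplitude_lands_at_one_zero(self):
        H, edges, _ = normalized_joint_density(
            [_path([(0, 0), (2, 0), (4, 0)])])
        centers = 0.5 * (edges[:-1] + edges[1:])
        i, j = np.unravel_index(H.argmax(), H.shape)
        assert centers[i] == pytest.approx(1.0, abs=0.051)
        assert centers[j] == pytest.approx(0.0, abs=0.051)

    def test_hand_transform_of_offset_pair(self):
        # previous saccade (1,1)->(3,1), next lands at (5,1): normalized (1, 0)
        H, edges, _ = normalized_joint_density(
            [_path([(1, 1), (3, 1), (5, 1)])])
        centers = 0.5 * (edges[:-1] + edges[1:])
        i, j = np.unravel_index(H.argmax(), H.shape)
        assert (centers[i], centers[j]) == pytest.approx((1.0, 0.0), abs=0.051)

    def test_rotation_and_scale_invariance_of_normalized_coordinates(self):
        # the same geometry, rotated 90 degrees and doubled, lands in the
        # same normalized bin
        H1, _, _ = normalized_joint_density([_path([(0, 0), (2, 0), (3, 1)])])
        H2, _, _ = normalized_joint_density([_path([(0, 0), (0, 4), (-2, 6)])])
        assert np.array_equal(H1, H2)

    def test_zero_amplitude_previous_saccade_skipped_with_count(self):
        H, _, skipped = normalized_joint_density(
            [_path([(0, 0), (0, 0), (1, 0), (2, 0)])])
        assert skipped == 1


class TestBinnedByTurningAngle:
    def test_all_forward_path_occupies_single_zero_bin(self):
        recs = saccades_from_path(_path([(0, 0), (1, 0), (2, 0), (3, 0)]))
        tab = binned_by_turning_angle(recs, value="amplitude", n_boot=0)
        assert len(tab) == 1
        assert tab.iloc[0]["bin_lo"] == 0.0

    def test_duplicated_dataset_has_identical_means(self):
        p = _path([(0, 0), (1, 0), (1.5, 1.2), (0.3, 0.6), (2, 2)])
        recs = saccades_from_path(p)
        t1 = binned_by_turning_angle(recs, value="amplitude", n_boot=0)
        t2 = binned_by_turning_angle(recs + recs, value="amplitude", n_boot=0)
        assert np.allclose(t1["mean"], t2["mean"])

    def test_angles_folded_symmetrically(self):
        left = saccades_from_path(_path([(0, 0), (1, 0), (1, 1)]))    # +90
        right = saccades_from_path(_path([(0, 0), (1, 0), (1, -1)]))  # -90
        t = binned_by_turning_angle(left + right, value="amplitude", n_boot=0)
        assert len(t) == 1 and t.iloc[0]["n"] == 2


class TestDistributionSummaries:
    def _records(self, subjects=("a", "b")):
        rng = np.random.default_rng(1)
        paths = []
        for s in subjects:
            pts = rng.uniform(0, 20, size=(12, 2))
            paths.append(_path([tuple(p) for p in pts], subject=s))
        return saccades_from_paths(paths)

    def test_histograms_normalized_per_subject(self):
        out = distribution_summaries(self._records(), n_boot=0)
        for key in ("amplitude", "absolute_angle", "turning_angle"):
            assert out[key]["mean"].sum() == pytest.approx(1.0)

    def test_identical_subjects_zero_width_band(self):
        rng = np.random.default_rng(2)
        pts = [tuple(p) for p in rng.uniform(0, 20, size=(10, 2))]
        paths = [_path(pts, subject="a"), _path(pts, subject="b")]
        out = distribution_summaries(saccades_from_paths(paths), n_boot=100)
        amp = out["amplitude"]
        assert np.allclose(amp["lo"], amp["hi"])

    def test_single_subject_band_omitted(self):
        out = distribution_summaries(self._records(subjects=("solo",)), n_boot=100)
        assert out["amplitude"]["lo"].isna().all()

    def test_oculomotor_potential_raises_cardinal_direction_mass(self):
        """Paired simulation on a uniform image: enabling the oculomotor
        potential increases absolute-angle mass in the four cardinal bins
        (the grid itself already favors cardinal directions, so the
        comparison is against a psi = 0 control, not a flat histogram)."""
        from scenewalk.core import Grid, ModelParams
        from scenewalk.simulate import SimConfig, simulate_scanpath

        grid = Grid(n_x=64, n_y=64)
        S = np.full(grid.shape, 1.0 / grid.n_cells)
        ext = ModelParams.extended_defaults()
        masses = {}
        for key, params in (("on", ext),
                            ("off", ext.with_updates(log_psi=float("-inf")))):
            rng = np.random.default_rng(8)
            paths = [simulate_scanpath(S, params, SimConfig(n_fixations=40),
                                       grid, rng=rng) for _ in range(50)]
            dirs = np.array([r.direction for r in saccades_from_paths(paths)])
            h, _ = np.histogram(dirs, bins=np.arange(0, 361, 10))
            h = h / h.sum()
            masses[key] = h[[0, 9, 18, 27]].sum()
        assert masses["on"] > masses["off"]

    def test_translation_invariance_of_amplitude_and_turning(self):
        rng = np.random.default_rng(1)
        paths, paths_shifted = [], []
        for s in ("a", "b"):
            pts = rng.uniform(0, 20, size=(12, 2))
            paths.append(_path([tuple(p) for p in pts], subject=s))
            paths_shifted.append(_path([(x + 100, y - 42) for x, y in pts],
                                       subject=s))
        r1 = saccades_from_paths(paths)
        r2 = saccades_from_paths(paths_shifted)
        assert np.allclose([a.amplitude for a in r1], [a.amplitude for a in r2])
        assert np.allclose(
            [a.turning for a in r1 if a.turning is not None],
            [a.turning for a in r2 if a.turning is not None])
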