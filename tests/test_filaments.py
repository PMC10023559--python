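"""Tracks, periodic picking, duplicate removal, doublet numbering."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from axosta import filaments, io
from axosta.filaments import FilamentTrack


def straight_track(length_ang=20000.0, fid="f"):
    return FilamentTrack(np.array([[0.0, 0.0, 0.0], [length_ang, 0.0, 0.0]]),
                         filament_id=fid)


class TestPickAlong:
    def test_count_on_2um_track_at_24nm(self):
        """floor(2000/24)+1 = 84 records on a straight 2-um track."""
        picks = filaments.pick_along(straight_track(20000.0), 240.0)
        assert len(picks) == 84

    def test_spacing_equal_to_length(self):
        picks = filaments.pick_along(straight_track(500.0), 500.0)
        assert len(picks) == 2

    def test_arc_spacing_on_quarter_circle(self):
        """On a curved track the interval is measured along the arc."""
        r = 50000.0  # 5 um radius
        t = np.linspace(0, np.pi / 2, 4000)
        pts = np.column_stack([r * np.sin(t), r * (1 - np.cos(t)), 0 * t])
        picks = filaments.pick_along(FilamentTrack(pts), 240.0)
        pos = picks[io.POSITION_COLUMNS].to_numpy()
        gaps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        # chord is marginally shorter than arc; 0.1-nm agreement expected
        assert np.all(np.abs(gaps - 240.0) < 1.0)

    def test_orientation_follows_tangent(self):
        picks = filaments.pick_along(straight_track(1000.0), 250.0)
        rot = io.euler_to_matrix(
            *picks.loc[0, io.EULER_COLUMNS].to_numpy(dtype=float)
        )
        np.testing.assert_allclose(rot @ [1, 0, 0], [1, 0, 0], atol=1e-10)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            FilamentTrack(np.array([[0, 0, 0], [0, 0, 0]]))


def _brute_force_keep(positions, scores, min_dist):
    """Greedy-by-score oracle evaluated by direct pairwise checking."""
    order = np.argsort(-scores, kind="stable")
    kept = []
    for i in order:
        if all(np.linalg.norm(positions[i] - positions[j]) >= min_dist
               for j in kept):
            kept.append(i)
    return sorted(kept)


def _max_weight_oracle(positions, scores, min_dist):
    """Exhaustive best-subset (max total score) under the distance rule."""
    n = len(positions)
    best, best_score = [], -np.inf
    for r in range(n + 1):
        for subset in combinations(range(n), r):
            if all(np.linalg.norm(positions[a] - positions[b]) >= min_dist
                   for a, b in combinations(subset, 2)):
                s = scores[list(subset)].sum()
                if s > best_score:
                    best, best_score = list(subset), s
    return best


def _make_table(positions, scores):
    t = io.new_particle_table(len(positions))
    t[io.POSITION_COLUMNS] = np.asarray(positions, dtype=float)
    t["score"] = scores
    return t


class TestRemoveDuplicates:
    def test_three_point_line(self):
        """0/20/50 nm with scores 0.9/0.8/0.7 at 40 nm keeps the ends."""
        t = _make_table([[0, 0, 0], [200, 0, 0], [500, 0, 0]],
                        np.array([0.9, 0.8, 0.7]))
        out = filaments.remove_duplicates(t, 400.0)
        assert sorted(out["pos_x"]) == [0.0, 500.0]

    def test_zero_distance_keeps_all(self):
        t = _make_table(np.random.default_rng(0).uniform(0, 10, (8, 3)),
                        np.linspace(1, 0, 8))
        assert len(filaments.remove_duplicates(t, 0.0)) == 8

    def test_coincident_records_keep_best(self):
        t = _make_table(np.zeros((5, 3)), np.array([0.1, 0.9, 0.5, 0.3, 0.2]))
        out = filaments.remove_duplicates(t, 10.0)
        assert len(out) == 1
        assert out["score"].iloc[0] == 0.9

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_greedy_oracle_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        pos = rng.uniform(0, 100, (n, 3))
        scores = rng.uniform(0, 1, n)
        t = _make_table(pos, scores)
        out = filaments.remove_duplicates(t, 30.0)
        kept = _brute_force_keep(pos, scores, 30.0)
        np.testing.assert_allclose(
            out[io.POSITION_COLUMNS].to_numpy(), pos[kept]
        )

    def test_greedy_is_maximal(self):
        rng = np.random.default_rng(7)
        pos = rng.uniform(0, 60, (12, 3))
        t = _make_table(pos, rng.uniform(0, 1, 12))
        out = filaments.remove_duplicates(t, 25.0)
        kept_pos = out[io.POSITION_COLUMNS].to_numpy()
        for p in pos:
            if not any(np.allclose(p, q) for q in kept_pos):
                dists = np.linalg.norm(kept_pos - p, axis=1)
                assert dists.min() < 25.0

    def test_agrees_with_optimal_on_separable_instance(self):
        """On well-separated clusters greedy attains the optimum."""
        rng = np.random.default_rng(3)
        centers = np.array([[0, 0, 0], [100, 0, 0], [0, 100, 0]])
        pos = np.concatenate([c + rng.uniform(-5, 5, (3, 3)) for c in centers])
        scores = rng.uniform(0, 1, len(pos))
        t = _make_table(pos, scores)
        out = filaments.remove_duplicates(t, 30.0)
        opt = _max_weight_oracle(pos, scores, 30.0)
        assert out["score"].sum() == pytest.approx(scores[opt].sum())

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            filaments.remove_duplicates(_make_table([[0, 0, 0]], [1.0]), -1.0)


def _ring_axes(center, radius, angles_deg, axis_len=2000.0):
    axes = []
    for i, a in enumerate(np.deg2rad(angles_deg)):
        off = center + radius * np.array([0.0, np.cos(a), np.sin(a)])
        axes.append(FilamentTrack(
            np.array([off, off + [axis_len, 0, 0]]), filament_id=f"ax{i}"
        ))
    return axes


class TestAssignDoubletNumbers:
    def setup_method(self):
        self.center = np.array([0.0, 0.0, 0.0])
        self.angles = np.arange(9) * 40.0
        self.cp = FilamentTrack(np.array([[0.0, 0, 0], [2000.0, 0, 0]]))
        self.normal = np.array([0.0, 1.0, 0.0])

    def test_canonical_geometry(self):
        axes = _ring_axes(self.center, 1000.0, self.angles)
        nums = filaments.assign_doublet_numbers(axes, self.cp, self.normal)
        assert [nums[f"ax{i}"] for i in range(9)] == list(range(1, 10))

    def test_invariant_under_rigid_rotation(self):
        rot = io.euler_to_matrix(37.0, 22.0, -14.0)
        axes = _ring_axes(self.center, 1000.0, self.angles)
        axes_r = [FilamentTrack((rot @ ax.points.T).T, filament_id=ax.filament_id)
                  for ax in axes]
        cp_r = FilamentTrack((rot @ self.cp.points.T).T)
        nums = filaments.assign_doublet_numbers(axes_r, cp_r, rot @ self.normal)
        assert [nums[f"ax{i}"] for i in range(9)] == list(range(1, 10))

    def test_mirror_with_flipped_polarity(self):
        """Mirroring reverses the handedness; flipping polarity restores
        the numbering."""
        mirror = np.diag([1.0, 1.0, -1.0])
        axes = _ring_axes(self.center, 1000.0, self.angles)
        axes_m = [FilamentTrack((mirror @ ax.points.T).T,
                                filament_id=ax.filament_id) for ax in axes]
        cp_m = FilamentTrack((mirror @ self.cp.points.T).T)
        nums = filaments.assign_doublet_numbers(
            axes_m, cp_m, mirror @ self.normal, polarity=-1
        )
        assert [nums[f"ax{i}"] for i in range(9)] == list(range(1, 10))

    def test_bijection_onto_1_to_9(self):
        axes = _ring_axes(self.center, 900.0, self.angles + 13.0)
        nums = filaments.assign_doublet_numbers(axes, self.cp, self.normal)
        assert sorted(nums.values()) == list(range(1, 10))

    def test_wrong_count_rejected(self):
        axes = _ring_axes(self.center, 1000.0, self.angles[:8])
        with pytest.raises(ValueError, match="9"):
            filaments.assign_doublet_numbers(axes, self.cp, self.normal)

    def test_nonparallel_axes_rejected(self):
        axes = _ring_axes(self.center, 1000.0, self.angles)
        tilted = FilamentTrack(np.array([[0, 1000, 0], [1000, 2500, 0]]),
                               filament_id="ax0")
        with pytest.raises(ValueError, match="parallel"):
            filaments.assign_doublet_numbers([tilted] + axes[1:], self.cp,
                                             self.normal)


class TestMeasurePairOffset:
    def _tables(self, offsets_by_tomo, repeat=960.0, n=10):
        a_rows, b_rows = [], []
        for tomo, off in offsets_by_tomo.items():
            xs = np.arange(n) * repeat
            ta = io.new_particle_table(n)
            ta["tomogram_id"] = tomo
            ta["pos_x"] = xs
            tb = io.new_particle_table(n)
            tb["tomogram_id"] = tomo
            tb["pos_x"] = xs + off
            a_rows.append(ta)
            b_rows.append(tb)
        return (pd.concat(a_rows, ignore_index=True),
                pd.concat(b_rows, ignore_index=True))

    def test_consistent_20nm_offset(self):
        a, b = self._tables({f"t{i}": 200.0 for i in range(10)})
        res = filaments.measure_pair_offset(a, b, 960.0, axis_dir=[1, 0, 0])
        assert res.mean_ang == pytest.approx(200.0, abs=10.0)
        assert res.sd_ang < 10.0

    def test_identical_tables(self):
        a, b = self._tables({"t0": 0.0, "t1": 0.0})
        res = filaments.measure_pair_offset(a, a, 960.0, axis_dir=[1, 0, 0])
        assert res.mean_ang == pytest.approx(0.0, abs=1e-9)
        assert res.sd_ang == pytest.approx(0.0, abs=1e-9)

    def test_uniform_offsets_show_no_consistency(self):
        rng = np.random.default_rng(5)
        a, b = self._tables({f"t{i}": rng.uniform(0, 960.0) for i in range(12)})
        res = filaments.measure_pair_offset(a, b, 960.0, axis_dir=[1, 0, 0])
        # circular sd of uniform phases is large compared to a bridged pair
        assert res.sd_ang > 100.0

    def test_empty_rejected(self):
        a, _ = self._tables({"t0": 0.0})
        with pytest.raises(ValueError):
            filaments.measure_pair_offset(a.iloc[:0], a, 960.0)
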