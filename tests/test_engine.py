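"""Extraction, masked alignment, averaging, FSC, periodicity."""

import numpy as np
import pytest
from scipy import ndimage

from axosta import engine, io, phantom
from axosta.engine import apply_pose, rotate_map
from axosta.io import Volume, euler_to_matrix, new_particle_table


@pytest.fixture
def toy_volume(rng):
    data = ndimage.gaussian_filter(rng.normal(size=(40, 40, 60)), 1.5)
    return Volume(data.astype(np.float32), 20.0)


def _single_record(x, y, z, alpha=0.0, beta=0.0, gamma=0.0):
    t = new_particle_table(1)
    t.loc[0, io.POSITION_COLUMNS] = [x, y, z]
    t.loc[0, io.EULER_COLUMNS] = [alpha, beta, gamma]
    return t


class TestExtract:
    def test_identity_orientation_is_a_crop(self, toy_volume):
        t = _single_record(30 * 20.0, 20 * 20.0, 20 * 20.0)
        stack, kept = engine.extract(toy_volume, t, 16)
        assert len(kept) == 1
        crop = toy_volume.data[12:28, 12:28, 22:38]
        np.testing.assert_allclose(stack[0], crop, atol=1e-5)

    def test_edge_record_dropped(self, toy_volume):
        t = _single_record(1 * 20.0, 20 * 20.0, 20 * 20.0)
        stack, kept = engine.extract(toy_volume, t, 16)
        assert len(kept) == 0
        assert stack.shape == (0, 16, 16, 16)

    def test_partial_extraction_pads_with_zeros(self, toy_volume):
        t = _single_record(0.0, 20 * 20.0, 20 * 20.0)
        stack, kept = engine.extract(toy_volume, t, 16, allow_partial=True)
        assert len(kept) == 1
        assert np.all(stack[0][:, :, :7] == 0.0)

    def test_rotated_extraction_matches_rotated_crop(self, toy_volume):
        """A record rotated 90 deg about the box x-axis equals the
        90-deg-rotated crop within interpolation error."""
        center = (30 * 20.0, 20 * 20.0, 20 * 20.0)
        # odd box: the rotation centre voxel coincides with the box centre
        plain, _ = engine.extract(toy_volume, _single_record(*center), 17)
        rot90 = np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])
        ang = io.matrix_to_euler(rot90)
        rotated, _ = engine.extract(
            toy_volume, _single_record(*center, *ang), 17
        )
        # sampling the tomogram through R equals rotating the plain crop
        expected = rotate_map(plain[0], rot90.T)
        core = (slice(3, -3),) * 3
        np.testing.assert_allclose(rotated[0][core], expected[core], atol=1e-3)

    def test_box_larger_than_tomogram_rejected(self, toy_volume):
        with pytest.raises(ValueError, match="box"):
            engine.extract(toy_volume, _single_record(0, 0, 0), 128)

    def test_coarser_output_voxel(self, toy_volume):
        t = _single_record(30 * 20.0, 20 * 20.0, 20 * 20.0)
        stack, _ = engine.extract(toy_volume, t, 8, out_voxel_ang=40.0)
        assert stack.shape == (1, 8, 8, 8)


@pytest.fixture(scope="module")
def reference():
    return phantom.render_decorated_average(
        phantom.DecorationFlags(), 30.0, (32, 32, 32)
    )


@pytest.fixture(scope="module")
def focus_mask(reference):
    m = ndimage.gaussian_filter(reference.data, 1.5) > 0.05 * reference.data.max()
    m = ndimage.binary_dilation(m, iterations=2).astype(np.float32)
    for axis in range(3):
        sl = [slice(None)] * 3
        sl[axis] = slice(0, 4)
        m[tuple(sl)] = 0
        sl[axis] = slice(-4, None)
        m[tuple(sl)] = 0
    return Volume(m, 30.0)


class TestAlign:
    def test_identity_scores_one(self, reference, focus_mask):
        stack = reference.data[None]
        t = new_particle_table(1)
        out = engine.align(stack, t, reference, focus_mask, angular_step=0.0,
                           shift_limit_ang=60.0)
        assert out["score"].iloc[0] == pytest.approx(1.0, abs=1e-3)
        np.testing.assert_allclose(
            out.loc[0, io.POSITION_COLUMNS].to_numpy(dtype=float), 0.0,
            atol=1.0,
        )

    def test_constructed_shift_recovered(self, reference, focus_mask):
        shifted = ndimage.shift(reference.data, (5, -2, 3), order=1)
        t = new_particle_table(1)
        out = engine.align(shifted[None], t, reference, focus_mask,
                           angular_step=0.0, shift_limit_ang=200.0)
        rec = out.loc[0, io.POSITION_COLUMNS].to_numpy(dtype=float) / 30.0
        np.testing.assert_allclose(rec, [3, -2, 5], atol=1.0)
        assert out["score"].iloc[0] > 0.99

    def test_noise_scores_well_separated(self, reference, focus_mask, rng):
        noise = rng.normal(0, 1, (20,) + reference.data.shape).astype(np.float32)
        t = new_particle_table(20)
        out = engine.align(noise, t, reference, focus_mask, angular_step=0.0,
                           shift_limit_ang=100.0)
        matched = engine.align(reference.data[None], new_particle_table(1),
                               reference, focus_mask, angular_step=0.0,
                               shift_limit_ang=100.0)
        gap = matched["score"].iloc[0] - out["score"].mean()
        assert gap > 3 * out["score"].std()

    def test_empty_mask_rejected(self, reference):
        empty = Volume(np.zeros_like(reference.data), 30.0)
        with pytest.raises(ValueError, match="mask"):
            engine.align(reference.data[None], new_particle_table(1),
                         reference, empty)

    def test_pose_recovery_at_low_snr(self, reference, focus_mask):
        """>=95% of poses recovered within 1 voxel / twice the final
        angular step on SNR-0.1 phantom subvolumes (coarse-then-fine)."""
        vox = 30.0
        rng = np.random.default_rng(3)
        sd = phantom.noise_sd_for_snr(reference.data, 0.1)
        n = 24
        true_ang = rng.uniform(-8, 8, n)
        true_shift = rng.uniform(-2, 2, (n, 3))
        stack = np.empty((n,) + reference.data.shape, np.float32)
        for i in range(n):
            img = rotate_map(reference.data, euler_to_matrix(true_ang[i], 0, 0))
            img = ndimage.shift(img, true_shift[i][::-1], order=1)
            stack[i] = img + rng.normal(0, sd, reference.data.shape)
        table = new_particle_table(n)
        coarse = engine.align(stack, table, reference, focus_mask,
                              angular_step=8.0, angular_range=8.0,
                              shift_limit_ang=3.2 * vox)
        corrected = np.empty_like(stack)
        for i in range(n):
            rot = euler_to_matrix(
                *coarse.loc[i, io.EULER_COLUMNS].to_numpy(dtype=float)
            )
            dt = coarse.loc[i, io.POSITION_COLUMNS].to_numpy(dtype=float)
            corrected[i] = apply_pose(stack[i], rot, dt, vox)
        fine = engine.align(corrected, coarse, reference, focus_mask,
                            angular_step=2.0, angular_range=2.0,
                            shift_limit_ang=1.5 * vox)
        hits = 0
        for i in range(n):
            pos = fine.loc[i, io.POSITION_COLUMNS].to_numpy(dtype=float)
            shift_err = np.abs(pos / vox - true_shift[i]).max()
            r_rec = euler_to_matrix(
                *fine.loc[i, io.EULER_COLUMNS].to_numpy(dtype=float)
            )
            r_true = euler_to_matrix(true_ang[i], 0, 0)
            cosang = (np.trace(r_rec.T @ r_true) - 1) / 2
            ang_err = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if shift_err <= 1.0 and ang_err <= 4.0:
                hits += 1
        assert hits / n >= 0.95


class TestAverage:
    def test_identical_boxes(self, rng):
        box = rng.normal(size=(8, 8, 8)).astype(np.float32)
        stack = np.repeat(box[None], 5, axis=0)
        t = new_particle_table(5)
        mean, _, _ = engine.average(stack, t)
        np.testing.assert_allclose(mean, box, atol=1e-6)

    def test_noise_suppression_scales_with_sqrt_n(self, rng):
        box = ndimage.gaussian_filter(rng.normal(size=(16, 16, 16)), 2)
        sigma, n = 0.5, 64
        stack = (box[None] + rng.normal(0, sigma, (n, 16, 16, 16))).astype(
            np.float32
        )
        t = new_particle_table(n)
        t["half_set"] = [1, 2] * (n // 2)
        mean, h1, h2 = engine.average(stack, t)
        resid = (mean - box).std()
        assert resid == pytest.approx(sigma / np.sqrt(n), rel=0.2)
        assert h1 is not None and h2 is not None
        curve = engine.fsc(Volume(h1, 20.0), Volume(h2, 20.0))
        assert np.all(curve.values[:3] > 0.8)

    def test_permutation_invariance(self, rng):
        stack = rng.normal(size=(10, 6, 6, 6)).astype(np.float32)
        t = new_particle_table(10)
        perm = rng.permutation(10)
        m1, _, _ = engine.average(stack, t)
        m2, _, _ = engine.average(stack[perm], t.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(m1, m2, atol=1e-6)

    def test_wedge_weighted_average_restores_density(self, rng):
        """Wedge-compensated averaging over many orientations fills the
        missing cone that any single subvolume lacks."""
        box = ndimage.gaussian_filter(rng.normal(size=(16, 16, 16)), 2)
        n = 12
        mask = engine.wedge_mask(box.shape, 48.0)
        t = new_particle_table(n)
        stack = np.empty((n, 16, 16, 16), np.float32)
        for i in range(n):
            ang = i * 180.0 / n
            rot = euler_to_matrix(0.0, ang, 0.0)
            # content as seen after extraction at orientation rot
            view = rotate_map(box, rot.T)
            wedged = np.real(np.fft.ifftn(np.fft.fftn(view) * mask))
            stack[i] = rotate_map(wedged, rot)
            t.loc[i, io.EULER_COLUMNS] = io.matrix_to_euler(rot)
        full, _, _ = engine.average(stack, t, wedge_halfangle=48.0)
        plain, _, _ = engine.average(stack, t)
        corr_w = np.corrcoef(full[4:-4].ravel(), box[4:-4].ravel())[0, 1]
        corr_p = np.corrcoef(plain[4:-4].ravel(), box[4:-4].ravel())[0, 1]
        assert corr_w > 0.8
        assert corr_w >= corr_p - 0.05

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            engine.average(np.empty((0, 4, 4, 4)), new_particle_table(0))


class TestFSC:
    def test_identical_maps_give_unit_curve_and_nyquist(self, rng):
        v = Volume(rng.normal(size=(24, 24, 24)).astype(np.float32), 10.0)
        curve = engine.fsc(v, v)
        np.testing.assert_allclose(curve.values, 1.0, atol=1e-6)
        assert engine.resolution_at(curve) == pytest.approx(20.0)

    def test_independent_noise_decorrelates(self, rng):
        a = Volume(rng.normal(size=(24, 24, 24)).astype(np.float32), 10.0)
        b = Volume(rng.normal(size=(24, 24, 24)).astype(np.float32), 10.0)
        curve = engine.fsc(a, b)
        assert np.all(np.abs(curve.values[1:]) < 0.5)
        # the reported resolution is far worse than for matched maps
        assert engine.resolution_at(curve) > 40.0

    def test_matches_snr_closed_form(self, rng):
        """FSC of truth+noise halves follows SNR/(SNR+1) per shell,
        with per-shell SNR = signal power / (sigma^2 * Nvox)."""
        shape = (32, 32, 32)
        nvox = np.prod(shape)
        truth = ndimage.gaussian_filter(rng.normal(size=shape), 1.0)
        sigma = truth.std()
        a = Volume((truth + rng.normal(0, sigma, shape)).astype(np.float32), 10.0)
        b = Volume((truth + rng.normal(0, sigma, shape)).astype(np.float32), 10.0)
        curve = engine.fsc(a, b)
        ft = np.fft.fftn(truth)
        freqs = np.meshgrid(*[np.fft.fftfreq(s, d=10.0) for s in shape],
                            indexing="ij")
        radius = np.sqrt(sum(f * f for f in freqs))
        edges = np.linspace(0, 0.05, len(curve.values) + 1)
        shell = np.clip(np.digitize(radius, edges) - 1, 0,
                        len(curve.values) - 1)
        counts = np.bincount(shell.ravel(), minlength=len(curve.values))
        p_signal = np.bincount(shell.ravel(), (np.abs(ft) ** 2).ravel(),
                               minlength=len(curve.values)) / counts
        snr = p_signal / (sigma**2 * nvox)
        expected = snr / (snr + 1.0)
        err = np.abs(curve.values[1:-2] - expected[1:-2])
        assert err.mean() < 0.1

    def test_mismatched_grids_rejected(self, rng):
        a = Volume(rng.normal(size=(8, 8, 8)).astype(np.float32), 10.0)
        b = Volume(rng.normal(size=(10, 10, 10)).astype(np.float32), 10.0)
        with pytest.raises(ValueError):
            engine.fsc(a, b)


class TestPeriodicity:
    def test_pure_96nm_cosine(self):
        x = np.arange(0, 20000, 20.0)
        trace = np.cos(2 * np.pi * x / 960.0)
        spec = engine.periodicity(trace, 20.0, (600.0, 1500.0))
        assert spec.dominant_ang == pytest.approx(960.0, abs=10.0)

    def test_window_selects_minor_period(self):
        """With a stronger 32-nm component and a 20-60 nm window the
        dominant period is 32 nm even though 96 nm is also present."""
        x = np.arange(0, 20000, 20.0)
        trace = 0.5 * np.cos(2 * np.pi * x / 960.0) + np.cos(2 * np.pi * x / 320.0)
        spec = engine.periodicity(trace, 20.0, (200.0, 600.0))
        assert spec.dominant_ang == pytest.approx(320.0, abs=10.0)

    def test_flat_trace_has_no_period(self):
        spec = engine.periodicity(np.ones(1000), 20.0, (600.0, 1500.0))
        assert spec.dominant_ang is None

    def test_window_too_large_rejected(self):
        with pytest.raises(ValueError):
            engine.periodicity(np.ones(100), 20.0, (100.0, 2000.0))


class TestWedgeMask:
    def test_no_wedge_at_90(self):
        assert engine.wedge_mask((8, 8, 8), 90.0).min() == 1.0

    def test_cone_fraction_grows_with_halfangle(self):
        m48 = engine.wedge_mask((32, 32, 32), 48.0).mean()
        m70 = engine.wedge_mask((32, 32, 32), 70.0).mean()
        assert 0.3 < m48 < 0.8
        assert m70 > m48
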