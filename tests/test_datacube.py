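import math

import numpy as np
import pytest
import scipy.sparse as sp

from msinmf import datacube
from msinmf.datacube import (
    ROISelection,
    assign_pixels,
    bin_scan,
    build_mz_axis,
    dense_storage_gib,
    extracted_ion_image,
    grid_line,
    roi_mean_spectrum,
    tic_image,
)
from msinmf.phantom import ScanEvent, StageTrack

from conftest import PHANTOM_AXIS_KW


# ---------------------------------------------------------------------------
# axis
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def full_axis():
    # full-resolution axis: bin width 0.0005 Th at m/z 850
    return build_mz_axis(400.0, 1000.0, 850.0, 0.0005, 0.001)


@pytest.fixture(scope="module")
def coarse_axis():
    return build_mz_axis(**PHANTOM_AXIS_KW)


@pytest.fixture(scope="module")
def fine_axis():
    # sigma wider than the bin width so windows span many channels
    return build_mz_axis(840.0, 860.0, 850.0, 0.0005, 0.001)


class TestMzAxis:
    def test_bin_width_at_reference(self, full_axis):
        j = np.argmin(np.abs(full_axis.centers - 850.0))
        width = full_axis.centers[j] * full_axis.r
        assert width == pytest.approx(0.0005, abs=1e-7)

    def test_constant_relative_spacing(self, full_axis):
        rng = np.random.default_rng(0)
        j = rng.integers(0, full_axis.n_channels - 1, size=100)
        ratios = full_axis.centers[j + 1] / full_axis.centers[j]
        assert np.all(np.abs(ratios - (1 + full_axis.r)) < 1e-12)

    def test_channel_count_closed_form_and_enumeration(self, full_axis):
        r = 0.0005 / 850.0
        closed_form = math.ceil(math.log(1000.0 / 400.0) / math.log1p(r))
        # independent oracle: enumerate centers by repeated multiplication
        # until the next center would reach mz_hi
        n, c = 0, 400.0
        while c < 1000.0:
            c *= 1 + r
            n += 1
        assert closed_form == n
        assert full_axis.n_channels == closed_form
        # note: computed count, not the (apparently transposed) published-style
        # figure of 1,557,764
        assert full_axis.n_channels == 1_557_695

    def test_bounds(self, full_axis):
        assert full_axis.centers[0] >= full_axis.mz_lo
        assert full_axis.centers[-1] <= full_axis.mz_hi * (1 + full_axis.r)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_mz_axis(-1.0, 1000.0)
        with pytest.raises(ValueError):
            build_mz_axis(1000.0, 400.0)
        with pytest.raises(ValueError):
            build_mz_axis(400.0, 1000.0, ref_bin_width=0.0)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def dense_gaussian_oracle(mz, intensity, axis):
    """Brute-force reference: full-axis Gaussian window, truncated at 4 sigma,
    renormalized. Written independently of bin_scan's windowed code path."""
    out = np.zeros(axis.n_channels)
    for m, inten in zip(mz, intensity):
        if not (axis.mz_lo <= m <= axis.mz_hi):
            continue
        sigma = axis.ref_sigma / axis.ref_mz * m
        d = axis.centers - m
        keep = np.abs(d) <= 4 * sigma
        if not keep.any():
            out[np.argmin(np.abs(d))] += inten
            continue
        w = np.zeros(axis.n_channels)
        w[keep] = np.exp(-d[keep] ** 2 / (2 * sigma ** 2))
        out += inten * w / w.sum()
    return out


class TestBinScan:
    def test_empty_scan_is_zero(self, coarse_axis):
        v = bin_scan(ScanEvent(0.0, [], []), coarse_axis)
        assert v.nnz == 0

    def test_intensity_preserved(self, coarse_axis):
        rng = np.random.default_rng(5)
        mz = np.sort(rng.uniform(420, 980, 30))
        inten = rng.uniform(1, 100, 30)
        v = bin_scan(ScanEvent(0.0, mz, inten), coarse_axis)
        assert v.sum() == pytest.approx(inten.sum(), rel=1e-12)

    def test_out_of_range_dropped(self, coarse_axis):
        v = bin_scan(ScanEvent(0.0, [350.0, 500.0, 1100.0], [1.0, 2.0, 3.0]), coarse_axis)
        assert v.sum() == pytest.approx(2.0, rel=1e-12)

    def test_single_peak_matches_dense_oracle(self, fine_axis):
        v = bin_scan(ScanEvent(0.0, [850.0], [100.0]), fine_axis)
        oracle = dense_gaussian_oracle([850.0], [100.0], fine_axis)
        assert (oracle > 0).sum() > 5  # window genuinely spans channels
        np.testing.assert_allclose(v.toarray().ravel(), oracle, atol=1e-12)

    def test_multi_peak_matches_dense_oracle(self, fine_axis):
        rng = np.random.default_rng(1)
        mz = np.sort(rng.uniform(845, 855, 10))
        inten = rng.uniform(1, 50, 10)
        v = bin_scan(ScanEvent(0.0, mz, inten), fine_axis)
        oracle = dense_gaussian_oracle(mz, inten, fine_axis)
        np.testing.assert_allclose(v.toarray().ravel(), oracle, atol=1e-10)

    def test_non_negative(self, coarse_axis):
        rng = np.random.default_rng(2)
        mz = np.sort(rng.uniform(420, 980, 20))
        v = bin_scan(ScanEvent(0.0, mz, rng.uniform(0, 10, 20)), coarse_axis)
        assert v.data.min() >= 0


# ---------------------------------------------------------------------------
# pixel assignment and gridding
# ---------------------------------------------------------------------------

def _track(n_lines=2, width=1000.0, velocity=100.0, step=200.0):
    samples, windows = [], []
    t = 0.0
    for line in range(n_lines):
        y = (line + 0.5) * step
        samples.append((t, 0.0, y))
        samples.append((t + width / velocity, width, y))
        windows.append((line, t, t + width / velocity))
        t += width / velocity + 1.0
    return StageTrack(np.array(samples), velocity, step, tuple(windows))


class TestAssignPixels:
    def test_constant_velocity_equal_spacing(self):
        track = _track()
        times = np.array([0.5, 2.5, 4.5, 6.5, 8.5])
        a = assign_pixels(track, times, pitch_x_um=100.0)
        np.testing.assert_allclose(np.diff(a.x_um), 100.0 * 2.0)

    def test_out_of_window_scans_discarded(self):
        track = _track()
        times = np.array([0.5, 10.5, 11.5])  # 10.5 falls in the settle gap
        a = assign_pixels(track, times, pitch_x_um=100.0)
        assert list(a.scan_index) == [0, 2]
        assert list(a.line_index) == [0, 1]

    def test_grid_point_on_scan_is_identity(self):
        axis = build_mz_axis(**PHANTOM_AXIS_KW)
        s1 = bin_scan(ScanEvent(0.0, [500.0], [10.0]), axis)
        s2 = bin_scan(ScanEvent(1.0, [600.0], [20.0]), axis)
        spectra = sp.vstack([s1, s2])
        out = grid_line(spectra, np.array([100.0, 300.0]), np.array([100.0, 200.0, 300.0]))
        np.testing.assert_allclose(out[0].toarray(), s1.toarray())
        np.testing.assert_allclose(out[2].toarray(), s2.toarray())
        np.testing.assert_allclose(out[1].toarray(), 0.5 * (s1 + s2).toarray())

    def test_jittered_scans_match_brute_force_interpolation(self):
        rng = np.random.default_rng(3)
        n_scans, n_chan = 12, 40
        x = np.sort(rng.uniform(0, 1000, n_scans))
        dense = rng.uniform(0, 5, (n_scans, n_chan))
        grid = np.sort(rng.uniform(x[0], x[-1], 20))
        out = grid_line(sp.csr_matrix(dense), x, grid)
        # oracle: per-channel np.interp
        oracle = np.vstack([np.interp(grid, x, dense[:, c]) for c in range(n_chan)]).T
        np.testing.assert_allclose(out.toarray(), oracle, atol=1e-12)

    def test_single_scan_line_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            grid_line(sp.csr_matrix((1, 10)), np.array([5.0]), np.array([5.0]))


# ---------------------------------------------------------------------------
# cube assembly and views
# ---------------------------------------------------------------------------

class TestCube:
    def test_shape_and_conservation(self, noisy_phantom, noisy_cube):
        _, labels, _, stream, _ = noisy_phantom
        cube, _ = noisy_cube
        assert (cube.rows, cube.cols) == labels.shape
        total_in = sum(
            scan.intensity[(scan.mz >= 400.0) & (scan.mz <= 1000.0)].sum()
            for scan in stream)
        assert cube.values.sum() == pytest.approx(total_in, rel=1e-9)

    def test_values_non_negative(self, noisy_cube):
        cube, _ = noisy_cube
        assert cube.values.data.min() >= 0

    def test_nnz_fraction_matches_dense_recount(self, random_cube):
        cube, dense = random_cube
        assert cube.nnz_fraction == pytest.approx(
            (dense != 0).sum() / dense.size, rel=1e-12)

    def test_dense_storage_published_case(self):
        assert dense_storage_gib(805, 59, 2556741) == 904

    def test_noise_free_argmax_is_region_base_peak(self, clean_phantom, clean_cube):
        spec, labels, profiles, _, _ = clean_phantom
        cube, _ = clean_cube
        V = cube.values
        argmax = np.asarray(V.argmax(axis=1)).ravel().reshape(labels.shape)
        for label, peaks in profiles.items():
            base_mz = next(p.mz for p in peaks if p.rel_intensity == 1.0)
            expected = cube.axis.index_of(base_mz)
            got = np.unique(argmax[labels == label])
            assert np.all(np.abs(got - expected) <= 1)

    def test_round_trip_pixel_coordinates(self, clean_phantom):
        # zero jitter: scans land exactly on pixel centers, so the assigned
        # grid reproduces the phantom geometry
        spec, labels, _, stream, track = clean_phantom
        a = assign_pixels(track, stream.times, pitch_x_um=spec.pixel_pitch_um)
        assert len(a.grid_x_um) == labels.shape[1]
        expected = (np.arange(labels.shape[1]) + 0.5) * spec.pixel_pitch_um
        np.testing.assert_allclose(a.grid_x_um, expected, atol=1e-9)


class TestTicImage:
    def test_single_nonzero_element(self, random_cube):
        cube, _ = random_cube
        vals = sp.csr_matrix(([7.5], ([13], [42])), shape=cube.values.shape)
        single = datacube.DataCube(vals, cube.rows, cube.cols, cube.axis, 200.0, 200.0)
        img = tic_image(single)
        assert img[13 // 5, 13 % 5] == 7.5
        assert img.sum() == 7.5

    def test_matches_dense_oracle(self, random_cube):
        cube, dense = random_cube
        np.testing.assert_allclose(
            tic_image(cube), dense.sum(axis=1).reshape(5, 5), atol=1e-12)

    def test_positive_on_tissue_zero_off(self, clean_cube):
        cube, labels = clean_cube
        img = tic_image(cube)
        assert (img[labels > 0] > 0).all()
        assert img[labels == 0].max() == 0.0


class TestExtractedIonImage:
    def test_full_axis_window_equals_tic(self, random_cube):
        cube, _ = random_cube
        img = extracted_ion_image(cube, 700.0, 1000.0)
        np.testing.assert_allclose(img, tic_image(cube), atol=1e-12)

    def test_matches_dense_channel_selection(self, random_cube):
        cube, dense = random_cube
        target, tol = 500.0, 30.0
        sel = np.abs(cube.axis.centers - target) <= tol
        oracle = dense[:, sel].sum(axis=1).reshape(5, 5)
        np.testing.assert_allclose(
            extracted_ion_image(cube, target, tol), oracle, atol=1e-12)

    def test_pi_ion_contrast_healthy_vs_cyst(self, noisy_cube):
        # the dominant membrane-lipid ion is depleted in the cyst
        cube, labels = noisy_cube
        img = extracted_ion_image(cube, 885.5499, 0.01)
        healthy = img[(labels == 1) | (labels == 2)].mean()
        cyst = img[labels == 4].mean()
        assert healthy > cyst

    def test_empty_window_rejected_naming_nearest(self, random_cube):
        cube, _ = random_cube
        with pytest.raises(ValueError, match="nearest center"):
            extracted_ion_image(cube, 500.0, 1e-6)


class TestRoiMeanSpectrum:
    def test_single_pixel_identity(self, random_cube):
        cube, dense = random_cube
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 3] = True
        out = roi_mean_spectrum(cube, ROISelection(mask=mask))
        np.testing.assert_allclose(out, dense[2 * 5 + 3], atol=1e-12)

    def test_mean_consistency_with_tic(self, random_cube):
        cube, _ = random_cube
        mask = np.ones((5, 5), dtype=bool)
        out = roi_mean_spectrum(cube, ROISelection(mask=mask))
        assert out.sum() == pytest.approx(tic_image(cube).mean(), rel=1e-12)

    def test_ellipse_matches_brute_force(self, random_cube):
        cube, dense = random_cube
        roi = ROISelection(center=(2.0, 2.0), semi_axes=(1.6, 2.1))
        rr, cc = np.mgrid[0:5, 0:5]
        mask = ((rr - 2.0) / 1.6) ** 2 + ((cc - 2.0) / 2.1) ** 2 <= 1.0
        oracle = dense[mask.ravel()].mean(axis=0)
        np.testing.assert_allclose(
            roi_mean_spectrum(cube, roi), oracle, atol=1e-12)

    def test_empty_roi_rejected(self, random_cube):
        cube, _ = random_cube
        with pytest.raises(ValueError, match="no pixels"):
            roi_mean_spectrum(cube, ROISelection(mask=np.zeros((5, 5), dtype=bool)))
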