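"""Sparse image-cube construction from stage-tracked centroid scans.

A raster acquisition yields a stream of centroided mass scans plus a stage
position log.  This module bins each scan onto a common logarithmically
spaced m/z axis with a small Gaussian window per centroid, assigns scans to
spatial positions along each first-pass raster line, interpolates line
spectra onto a regular x grid, and stacks the lines into a non-negative
sparse cube (rows x cols x channels).  Downstream views: TIC images,
extracted-ion images, and ROI mean spectra.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .phantom import ScanEvent, ScanStream, StageTrack

log = logging.getLogger(__name__)

__all__ = [
    "MzAxis",
    "DataCube",
    "PixelMatrix",
    "ROISelection",
    "build_mz_axis",
    "bin_scan",
    "assign_pixels",
    "grid_line",
    "assemble_cube",
    "build_cube",
    "tic_image",
    "extracted_ion_image",
    "roi_mean_spectrum",
    "dense_storage_bytes",
    "dense_storage_gib",
]


# ---------------------------------------------------------------------------
# m/z axis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MzAxis:
    """Log-spaced m/z axis with constant relative bin width.

    Channel centers satisfy ``centers[j] = mz_lo * (1 + r)**j`` with
    ``r = ref_bin_width / ref_mz``, so the local bin width at center m is
    ``r * m`` (e.g. 0.0005 Th at m/z 850 for the default parameters).  The
    Gaussian binning sigma scales the same way: ``sigma(m) = ref_sigma/ref_mz * m``.
    """

    mz_lo: float
    mz_hi: float
    ref_mz: float
    ref_bin_width: float
    ref_sigma: float
    centers: np.ndarray = field(repr=False)

    @property
    def r(self) -> float:
        """Relative bin width (dimensionless)."""
        return self.ref_bin_width / self.ref_mz

    @property
    def n_channels(self) -> int:
        return len(self.centers)

    def sigma(self, mz) -> np.ndarray:
        return (self.ref_sigma / self.ref_mz) * np.asarray(mz, dtype=float)

    def bin_width(self, mz) -> np.ndarray:
        return self.r * np.asarray(mz, dtype=float)

    def index_of(self, mz) -> np.ndarray:
        """Index of the channel center nearest (in log space) to each m/z."""
        mz = np.asarray(mz, dtype=float)
        j = np.rint(np.log(mz / self.mz_lo) / math.log1p(self.r)).astype(int)
        return np.clip(j, 0, self.n_channels - 1)


def build_mz_axis(
    mz_lo: float,
    mz_hi: float,
    ref_mz: float = 850.0,
    ref_bin_width: float = 0.0005,
    ref_sigma: float = 0.001,
) -> MzAxis:
    """Construct a log-spaced axis covering [mz_lo, mz_hi].

    The channel count is ``ceil(ln(mz_hi/mz_lo) / ln(1+r))`` so the last
    center lies within one relative step of ``mz_hi``.
    """
    if mz_lo <= 0 or mz_hi <= mz_lo:
        raise ValueError(f"need 0 < mz_lo < mz_hi, got ({mz_lo}, {mz_hi})")
    if ref_bin_width <= 0 or ref_sigma <= 0 or ref_mz <= 0:
        raise ValueError("reference m/z, bin width and sigma must be positive")
    r = ref_bin_width / ref_mz
    n = math.ceil(math.log(mz_hi / mz_lo) / math.log1p(r))
    j = np.arange(n)
    centers = mz_lo * np.exp(j * math.log1p(r))
    return MzAxis(mz_lo, mz_hi, ref_mz, ref_bin_width, ref_sigma, centers)


# ---------------------------------------------------------------------------
# scan binning
# ---------------------------------------------------------------------------

def bin_scan(scan: ScanEvent, axis: MzAxis) -> sp.csr_matrix:
    """Deposit a centroided scan onto the axis as a 1 x n_channels sparse row.

    Each in-range centroid (m, I) spreads I over the channels whose centers
    lie within 4 sigma(m) of m, with Gaussian weights renormalized to sum to
    one (intensity preserving).  When the bin width exceeds the window (no
    center within 4 sigma) the full intensity goes to the nearest center.
    Out-of-range centroids are dropped and counted in the log.
    """
    if axis.n_channels == 0:
        raise ValueError("empty m/z axis")
    mz = np.asarray(scan.mz, dtype=float)
    inten = np.asarray(scan.intensity, dtype=float)
    in_range = (mz >= axis.mz_lo) & (mz <= axis.mz_hi)
    n_dropped = int((~in_range).sum())
    if n_dropped:
        log.debug("bin_scan: dropped %d out-of-range centroids", n_dropped)
    mz, inten = mz[in_range], inten[in_range]
    if mz.size == 0:
        return sp.csr_matrix((1, axis.n_channels))

    log1pr = math.log1p(axis.r)
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    sig = axis.sigma(mz)
    # window bounds in channel-index space
    j_lo = np.ceil(np.log(np.maximum(mz - 4 * sig, axis.mz_lo * 0.5) / axis.mz_lo) / log1pr)
    j_hi = np.floor(np.log((mz + 4 * sig) / axis.mz_lo) / log1pr)
    j_lo = np.clip(j_lo, 0, axis.n_channels - 1).astype(int)
    j_hi = np.clip(j_hi, 0, axis.n_channels - 1).astype(int)
    nearest = axis.index_of(mz)
    for m, I, s, lo, hi, near in zip(mz, inten, sig, j_lo, j_hi, nearest):
        j = np.arange(lo, hi + 1)
        c = axis.centers[j]
        keep = np.abs(c - m) <= 4 * s
        j, c = j[keep], c[keep]
        if j.size == 0:
            cols.append(np.array([near]))
            vals.append(np.array([I]))
            continue
        w = np.exp(-((c - m) ** 2) / (2 * s * s))
        w /= w.sum()
        cols.append(j)
        vals.append(I * w)
    col = np.concatenate(cols)
    val = np.concatenate(vals)
    row = np.zeros_like(col)
    out = sp.csr_matrix((val, (row, col)), shape=(1, axis.n_channels))
    out.sum_duplicates()
    return out


# ---------------------------------------------------------------------------
# pixel assignment and line gridding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PixelAssignment:
    """First-pass scan positions and the common regular x grid."""

    scan_index: np.ndarray   # indices into the original scan list
    line_index: np.ndarray   # raster line of each kept scan
    x_um: np.ndarray         # interpolated stage x of each kept scan
    grid_x_um: np.ndarray    # regular grid shared by all lines
    pitch_x_um: float


def assign_pixels(
    track: StageTrack,
    scan_times: Sequence[float],
    pitch_x_um: float,
) -> PixelAssignment:
    """Locate first-pass scans along the raster and lay out the x grid.

    Scans outside every first-pass window are discarded.  x(t) is linearly
    interpolated between bracketing track samples.  The grid starts at the
    smallest assigned x and steps by ``pitch_x_um`` up to the largest.
    """
    if pitch_x_um <= 0:
        raise ValueError("pitch_x_um must be positive")
    times = np.asarray(scan_times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("scan times must be sorted")
    t_track = track.samples[:, 0]
    x_track = track.samples[:, 1]
    keep_idx, keep_line = [], []
    for i, t in enumerate(times):
        for line, t0, t1 in track.pass_windows:
            if t0 <= t <= t1:
                keep_idx.append(i)
                keep_line.append(line)
                break
    if not keep_idx:
        raise ValueError("no scans fall inside any first-pass window")
    keep_idx = np.asarray(keep_idx)
    keep_line = np.asarray(keep_line)
    x = np.interp(times[keep_idx], t_track, x_track)
    x_min, x_max = float(x.min()), float(x.max())
    n_grid = int(math.floor((x_max - x_min) / pitch_x_um + 1e-9)) + 1
    grid = x_min + pitch_x_um * np.arange(n_grid)
    return PixelAssignment(keep_idx, keep_line, x, grid, float(pitch_x_um))


def grid_line(
    spectra: sp.spmatrix,
    x_um: np.ndarray,
    grid_x_um: np.ndarray,
) -> sp.csr_matrix:
    """Channel-wise linear interpolation of one line's scans onto the grid.

    ``spectra`` is (n_scans x channels), rows ordered by time; ``x_um`` the
    scan positions.  Grid points outside the line's x span get zero spectra
    (padding, logged by the caller).  A line needs >= 2 scans.
    """
    x = np.asarray(x_um, dtype=float)
    if x.size < 2:
        raise ValueError(f"line has {x.size} scan(s); need at least 2 to interpolate")
    order = np.argsort(x, kind="stable")
    x = x[order]
    spectra = sp.csr_matrix(spectra)[order]
    rows = []
    for g in grid_x_um:
        if g < x[0] or g > x[-1]:
            rows.append(sp.csr_matrix((1, spectra.shape[1])))
            continue
        k = int(np.searchsorted(x, g, side="right")) - 1
        if k >= x.size - 1:
            k = x.size - 2
        x0, x1 = x[k], x[k + 1]
        if x1 == x0:
            rows.append(spectra[k])
            continue
        frac = (g - x0) / (x1 - x0)
        rows.append(spectra[k] * (1 - frac) + spectra[k + 1] * frac)
    return sp.vstack(rows, format="csr")


# ---------------------------------------------------------------------------
# cube
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PixelMatrix:
    """Row-major pixel-vectorized view of a cube: (rows*cols) x channels."""

    V: sp.csr_matrix
    rows: int
    cols: int

    @property
    def n_pixels(self) -> int:
        return self.rows * self.cols

    def image(self, values: np.ndarray) -> np.ndarray:
        """Reshape a per-pixel vector back to a rows x cols image."""
        return np.asarray(values).reshape(self.rows, self.cols)


@dataclass(frozen=True)
class DataCube:
    """Non-negative sparse intensity cube over (row, col, channel).

    Stored as a CSR matrix of shape (rows*cols, channels) in row-major
    pixel order (row 0 = smallest y, col 0 = smallest x).
    """

    values: sp.csr_matrix = field(repr=False)
    rows: int
    cols: int
    axis: MzAxis
    pixel_pitch_x_um: float
    pixel_pitch_y_um: float

    def __post_init__(self) -> None:
        if self.values.shape != (self.rows * self.cols, self.axis.n_channels):
            raise ValueError("cube value matrix shape mismatch")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("cube intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.rows, self.cols, self.axis.n_channels)

    @property
    def nnz_fraction(self) -> float:
        dense = self.rows * self.cols * self.axis.n_channels
        return self.values.nnz / dense if dense else 0.0

    @property
    def dense_storage_bytes(self) -> int:
        return dense_storage_bytes(self.rows, self.cols, self.axis.n_channels)

    def pixel_matrix(self) -> PixelMatrix:
        return PixelMatrix(self.values, self.rows, self.cols)


def dense_storage_bytes(rows: int, cols: int, channels: int, itemsize: int = 8) -> int:
    """Bytes needed to hold the cube densely at ``itemsize`` bytes/element."""
    return rows * cols * channels * itemsize


def dense_storage_gib(rows: int, cols: int, channels: int, itemsize: int = 8) -> int:
    """Dense storage in binary gigabytes (2**30 bytes), truncated to int."""
    return dense_storage_bytes(rows, cols, channels, itemsize) // 2**30


def assemble_cube(
    line_spectra: Sequence[tuple[int, sp.spmatrix]],
    axis: MzAxis,
    pitch_x_um: float,
    pitch_y_um: float,
) -> DataCube:
    """Stack per-line gridded spectra into a cube, rows ordered by line.

    All lines must share the axis and grid pitch.  Ragged lines are padded
    with explicit zero pixels (logged).
    """
    if not line_spectra:
        raise ValueError("no lines to assemble")
    ordered = sorted(line_spectra, key=lambda t: t[0])
    n_cols = max(m.shape[0] for _, m in ordered)
    blocks = []
    for line, m in ordered:
        m = sp.csr_matrix(m)
        if m.shape[0] < n_cols:
            log.warning("line %d has %d of %d grid points; padding with zeros", line, m.shape[0], n_cols)
            pad = sp.csr_matrix((n_cols - m.shape[0], m.shape[1]))
            m = sp.vstack([m, pad], format="csr")
        blocks.append(m)
    V = sp.vstack(blocks, format="csr")
    cube = DataCube(V, rows=len(ordered), cols=n_cols, axis=axis,
                    pixel_pitch_x_um=pitch_x_um, pixel_pitch_y_um=pitch_y_um)
    log.info(
        "assembled cube %s: dense-equivalent %.1f MiB, nnz fraction %.3g",
        cube.shape, cube.dense_storage_bytes / 2**20, cube.nnz_fraction,
    )
    return cube


def build_cube(
    stream: ScanStream,
    track: StageTrack,
    axis: MzAxis,
    pitch_x_um: float | None = None,
    pitch_y_um: float | None = None,
) -> DataCube:
    """End-to-end: bin scans, assign pixels, grid each line, assemble.

    ``pitch_x_um`` defaults to stage velocity times the median scan period
    (roughly square pixels); ``pitch_y_um`` defaults to the track line step.
    """
    times = stream.times
    if pitch_x_um is None:
        period = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
        pitch_x_um = track.velocity_x_um_s * period
    if pitch_y_um is None:
        pitch_y_um = track.line_step_um
    assignment = assign_pixels(track, times, pitch_x_um)
    binned = {int(i): bin_scan(stream.scans[int(i)], axis) for i in assignment.scan_index}
    lines = []
    for line in np.unique(assignment.line_index):
        sel = assignment.line_index == line
        idx = assignment.scan_index[sel]
        x = assignment.x_um[sel]
        spectra = sp.vstack([binned[int(i)] for i in idx], format="csr")
        lines.append((int(line), grid_line(spectra, x, assignment.grid_x_um)))
    return assemble_cube(lines, axis, float(pitch_x_um), float(pitch_y_um))


# ---------------------------------------------------------------------------
# views
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROISelection:
    """Pixel subset: explicit boolean mask, or an ellipse in pixel units."""

    mask: np.ndarray | None = None
    center: tuple[float, float] | None = None   # (row, col)
    semi_axes: tuple[float, float] | None = None  # (row, col) semi-axes

    def resolve(self, rows: int, cols: int) -> np.ndarray:
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != (rows, cols):
                raise ValueError(f"mask shape {mask.shape} != image shape {(rows, cols)}")
        else:
            if self.center is None or self.semi_axes is None:
                raise ValueError("ROI needs either a mask or ellipse parameters")
            r0, c0 = self.center
            ar, ac = self.semi_axes
            rr, cc = np.mgrid[0:rows, 0:cols]
            mask = ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0
        if not mask.any():
            raise ValueError("ROI selects no pixels")
        return mask


def tic_image(cube: DataCube) -> np.ndarray:
    """Total ion current: per-pixel sum over channels."""
    tic = np.asarray(cube.values.sum(axis=1)).ravel()
    return tic.reshape(cube.rows, cube.cols)


def extracted_ion_image(cube: DataCube, target_mz: float, tol_mz: float) -> np.ndarray:
    """Sum of channels with centers in the closed window target +/- tol."""
    centers = cube.axis.centers
    sel = (centers >= target_mz - tol_mz) & (centers <= target_mz + tol_mz)
    if not sel.any():
        nearest = centers[np.argmin(np.abs(centers - target_mz))]
        raise ValueError(
            f"no channel centers in [{target_mz - tol_mz}, {target_mz + tol_mz}]; "
            f"nearest center is {nearest:.6f}"
        )
    img = np.asarray(cube.values[:, np.flatnonzero(sel)].sum(axis=1)).ravel()
    return img.reshape(cube.rows, cube.cols)


def roi_mean_spectrum(cube: DataCube, roi: ROISelection) -> np.ndarray:
    """Channel-wise arithmetic mean spectrum over the ROI pixels."""
    mask = roi.resolve(cube.rows, cube.cols).ravel()
    sub = cube.values[np.flatnonzero(mask)]
    return np.asarray(sub.sum(axis=0)).ravel() / mask.sum()
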