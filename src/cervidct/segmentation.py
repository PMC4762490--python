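"""Elliptical VOI placement and histogram-peak global thresholding.

The analysis volume is a fixed ellipse replicated across a contiguous run
of slices (an elliptical prism).  Binarization uses a single global
threshold computed as the arithmetic mean of the two dominant modes of the
VOI gray-level histogram: the empty-space (dark) peak and the mineralised
bone (bright) peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import GeometryError, ParameterError, SegmentationError
from .io_formats import VoxelVolume
from .phantoms import BinaryVolume


@dataclass(frozen=True)
class EllipseROI:
    """In-plane ellipse. Coordinates in mm; x is the column direction, y the
    row direction; ``angle_deg`` rotates the major axis from +x toward +y."""

    center_mm: tuple[float, float]
    semi_minor_mm: float
    semi_major_mm: float
    angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.semi_minor_mm <= self.semi_major_mm:
            raise ParameterError(
                f"need 0 < semi_minor <= semi_major, got "
                f"{self.semi_minor_mm}/{self.semi_major_mm}"
            )

    @property
    def area_mm2(self) -> float:
        return math.pi * self.semi_minor_mm * self.semi_major_mm


@dataclass(frozen=True)
class VOIDescriptor:
    """Elliptical prism: ROI area × slice count × slice thickness."""

    roi: EllipseROI
    slice_start: int
    slice_count: int
    slice_thickness_mm: float

    def __post_init__(self) -> None:
        if self.slice_count < 1:
            raise ParameterError(f"slice_count must be >= 1, got {self.slice_count}")
        if not self.slice_thickness_mm > 0:
            raise ParameterError("slice_thickness_mm must be > 0")

    @property
    def area_mm2(self) -> float:
        return self.roi.area_mm2

    @property
    def volume_mm3(self) -> float:
        return self.area_mm2 * self.slice_count * self.slice_thickness_mm


@dataclass
class VOI:
    """A VOI extraction result: the sliced subvolume, its boolean mask and
    the geometric descriptor."""

    volume: VoxelVolume
    mask: np.ndarray = field(repr=False)
    descriptor: VOIDescriptor


@dataclass
class GrayHistogram:
    """Integer gray-level counts over the VOI voxels."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ParameterError("histogram counts must be a nonempty 1D array")

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())


def ellipse_mask_2d(
    roi: EllipseROI, shape: tuple[int, int], voxel_size_mm: float
) -> np.ndarray:
    """Boolean in-plane mask: true where the voxel centre lies inside the
    ellipse.  Voxel centre of pixel (row i, col j) is at ((j+.5)s, (i+.5)s)."""
    rows, cols = shape
    s = voxel_size_mm
    cx, cy = roi.center_mm
    a, b = roi.semi_major_mm, roi.semi_minor_mm
    th = math.radians(roi.angle_deg)
    # axis-aligned bounding half-extents of the rotated ellipse
    hx = math.hypot(a * math.cos(th), b * math.sin(th))
    hy = math.hypot(a * math.sin(th), b * math.cos(th))
    if cx - hx < 0 or cy - hy < 0 or cx + hx > cols * s or cy + hy > rows * s:
        raise GeometryError(
            f"ellipse (centre {cx:.3f},{cy:.3f} mm, extents ±{hx:.3f}/±{hy:.3f} mm) "
            f"exceeds the {cols * s:.3f}×{rows * s:.3f} mm image frame"
        )
    y = (np.arange(rows) + 0.5) * s - cy
    x = (np.arange(cols) + 0.5) * s - cx
    xx, yy = np.meshgrid(x, y)  # (rows, cols)
    u = xx * math.cos(th) + yy * math.sin(th)
    v = -xx * math.sin(th) + yy * math.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def extract_voi(
    volume: VoxelVolume,
    roi: EllipseROI,
    slice_start: int,
    slice_count: int,
) -> VOI:
    """Apply the same ellipse to each slice in the range, returning the
    sliced subvolume, the replicated boolean mask and the descriptor."""
    if slice_count < 1:
        raise ParameterError(f"slice_count must be >= 1, got {slice_count}")
    n = volume.data.shape[0]
    if slice_start < 0 or slice_start + slice_count > n:
        raise ParameterError(
            f"slice range [{slice_start}, {slice_start + slice_count}) outside stack of {n}"
        )
    mask2d = ellipse_mask_2d(roi, volume.data.shape[1:], volume.voxel_size_mm)
    sub = VoxelVolume(
        data=volume.data[slice_start : slice_start + slice_count],
        voxel_size_um=volume.voxel_size_um,
        origin_slice=volume.origin_slice + slice_start,
    )
    mask = np.broadcast_to(mask2d, sub.data.shape).copy()
    desc = VOIDescriptor(
        roi=roi,
        slice_start=slice_start,
        slice_count=slice_count,
        slice_thickness_mm=volume.voxel_size_mm,
    )
    return VOI(volume=sub, mask=mask, descriptor=desc)


def compute_histogram(volume: VoxelVolume, mask: np.ndarray | None = None) -> GrayHistogram:
    """Gray-level histogram over the masked voxels; bins are the integer
    levels of the stored dtype (so ``counts.size`` is 256 or 65536)."""
    if mask is None:
        vals = volume.data.ravel()
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != volume.data.shape:
            raise ParameterError("mask shape must match volume shape")
        if not mask.any():
            raise ParameterError("empty mask")
        vals = volume.data[mask]
    nbins = int(np.iinfo(volume.data.dtype).max) + 1
    return GrayHistogram(np.bincount(vals.ravel(), minlength=nbins))


def _default_peak_params(nbins: int) -> tuple[int, int]:
    if nbins <= 256:
        return 5, max(1, round(0.2 * nbins))
    return 257, max(1, round(0.2 * nbins))


def find_peaks(
    hist: GrayHistogram,
    smooth_window: int | None = None,
    min_separation: int | None = None,
    min_prominence_frac: float = 0.05,
) -> tuple[int, int]:
    """Locate the empty-space (dark) and bone (bright) modes.

    The histogram is smoothed with a centred moving average, then the two
    most prominent local maxima at least ``min_separation`` levels apart
    are returned, low level first.  Peak plateaus break ties toward the
    extreme (lowest level for the dark peak, highest for the bright one).
    Raises :class:`SegmentationError` when fewer than two maxima qualify.
    """
    counts = hist.counts.astype(float)
    nbins = counts.size
    w_def, sep_def = _default_peak_params(nbins)
    w = smooth_window if smooth_window is not None else w_def
    sep = min_separation if min_separation is not None else sep_def
    if w < 1 or w % 2 == 0:
        raise ParameterError(f"smooth_window must be odd and >= 1, got {w}")
    kernel = np.ones(w)
    sm = np.convolve(counts, kernel, mode="same") / np.convolve(
        np.ones(nbins), kernel, mode="same"
    )
    # pad so maxima at the histogram ends count as peaks
    padded = np.r_[-1.0, sm, -1.0]
    idx, props = signal.find_peaks(
        padded, distance=max(1, sep), prominence=min_prominence_frac * sm.max()
    )
    idx = idx - 1
    if idx.size < 2:
        raise SegmentationError(
            f"histogram not bimodal: {idx.size} qualifying peak(s) found"
        )
    order = np.argsort(props["prominences"])[::-1]
    top2 = np.sort(idx[order[:2]])
    low, high = int(top2[0]), int(top2[1])

    def _plateau(i: int, toward: int) -> int:
        while 0 <= i + toward < nbins and sm[i + toward] == sm[i]:
            i += toward
        return i

    return _plateau(low, -1), _plateau(high, +1)


def compute_threshold(empty_space_peak_level: float, bone_peak_level: float) -> float:
    """Global threshold: arithmetic mean of the two peak levels (carried at
    half-level precision)."""
    if not empty_space_peak_level < bone_peak_level:
        raise ParameterError(
            f"empty-space peak ({empty_space_peak_level}) must be below bone peak "
            f"({bone_peak_level})"
        )
    return (empty_space_peak_level + bone_peak_level) / 2.0


def binarize(
    volume: VoxelVolume, threshold_level: float, mask: np.ndarray | None = None
) -> BinaryVolume:
    """Foreground ⇔ intensity ≥ threshold and inside the mask; the mask is
    carried into the returned :class:`BinaryVolume`."""
    vmax = np.iinfo(volume.data.dtype).max
    if not 0 <= threshold_level <= vmax + 1:
        raise ParameterError(f"threshold {threshold_level} outside dtype range [0, {vmax}]")
    fg = volume.data >= threshold_level
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != volume.data.shape:
            raise ParameterError("mask shape must match volume shape")
        fg = fg & mask
    return BinaryVolume(data=fg, voxel_size_um=volume.voxel_size_um, mask=mask)


def segment(
    volume: VoxelVolume,
    roi: EllipseROI,
    slice_start: int,
    slice_count: int,
    smooth_window: int | None = None,
    min_separation: int | None = None,
    min_prominence_frac: float = 0.05,
) -> tuple[BinaryVolume, VOIDescriptor, dict]:
    """Convenience chain: VOI → histogram → peaks → threshold → binarize.

    Returns the binary volume (mask carried), the VOI descriptor, and a
    diagnostics dict (peak levels, threshold, VOI volume)."""
    voi = extract_voi(volume, roi, slice_start, slice_count)
    hist = compute_histogram(voi.volume, voi.mask)
    lo, hi = find_peaks(hist, smooth_window, min_separation, min_prominence_frac)
    thr = compute_threshold(lo, hi)
    binary = binarize(voi.volume, thr, voi.mask)
    diag = {
        "empty_space_peak_level": lo,
        "bone_peak_level": hi,
        "threshold_level": thr,
        "voi_volume_mm3": voi.descriptor.volume_mm3,
        "voi_voxel_count": int(voi.mask.sum()),
    }
    return binary, voi.descriptor, diag
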