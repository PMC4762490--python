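"""Synthetic structures with analytically known morphometry.

Three families of generators:

* ideal geometric solids (parallel plates, rods, spheres) whose thickness,
  fill fraction, surface area and structure-model index have closed forms —
  the calibration fixtures for the morphometry estimators;
* a sponge-like random trabecular phantom (Gaussian-filtered white noise
  thresholded at a quantile) with a tunable characteristic scale and an
  exact fill fraction;
* feature-table cohorts drawn from per-species biomarker moments, used to
  emulate the two study corpora when only means and SDs are published.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError
from .io_formats import BIOMARKERS, SPECIES, FeatureTable, VoxelVolume

#: biomarkers that cannot be negative; draws below zero are truncated
_NONNEGATIVE = ("bv_tv", "tb_n", "tb_th", "tb_sp")


@dataclass
class BinaryVolume:
    """Segmented 3D grid: ``True`` marks mineralised tissue.

    ``mask`` (optional, same shape) restricts analysis to a volume of
    interest; foreground outside the mask is ignored by all morphometry.
    """

    data: np.ndarray
    voxel_size_um: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ParameterError(f"binary volume must be 3D, got ndim={self.data.ndim}")
        if not self.voxel_size_um > 0:
            raise ParameterError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ParameterError(
                    f"mask shape {self.mask.shape} != data shape {self.data.shape}"
                )

    @property
    def voxel_size_mm(self) -> float:
        return float(self.voxel_size_um) / 1000.0

    def effective_mask(self) -> np.ndarray:
        """The analysis mask (all-true when no VOI was set)."""
        if self.mask is None:
            return np.ones(self.data.shape, dtype=bool)
        return self.mask

    def foreground(self) -> np.ndarray:
        """Mineralised voxels restricted to the mask."""
        return self.data & self.effective_mask()


@dataclass
class SpeciesMoments:
    """Per-species mean/SD for each biomarker, plus the corpus sample sizes.

    ``means`` and ``sds`` are DataFrames indexed by species with the six
    biomarker columns; ``n`` maps species to the corpus sample count.
    """

    means: pd.DataFrame = field(repr=False)
    sds: pd.DataFrame = field(repr=False)
    n: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for df_name, df in (("means", self.means), ("sds", self.sds)):
            missing = set(BIOMARKERS) - set(df.columns)
            if missing:
                raise ParameterError(f"{df_name} missing biomarkers: {sorted(missing)}")
        missing_sp = set(SPECIES) - set(self.means.index)
        if missing_sp:
            raise ParameterError(f"moments missing species: {sorted(missing_sp)}")
        if (self.sds.loc[:, list(BIOMARKERS)].to_numpy() < 0).any():
            raise ParameterError("SDs must be >= 0")

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "SpeciesMoments":
        """Build from long-format rows (species, n, biomarker, mean, sd)."""
        means = df.pivot(index="species", columns="biomarker", values="mean")
        sds = df.pivot(index="species", columns="biomarker", values="sd")
        n = {sp: int(sub["n"].iloc[0]) for sp, sub in df.groupby("species")}
        return cls(means=means, sds=sds, n=n)


def load_moments(corpus: str) -> SpeciesMoments:
    """Load the published per-species biomarker moments for a corpus.

    ``corpus`` is ``"modern"`` (17 red deer, 22 reindeer) or
    ``"archaeological"`` (23 red deer, 27 reindeer).
    """
    if corpus not in ("modern", "archaeological"):
        raise ParameterError(f"unknown corpus {corpus!r}")
    ref = resources.files("cervidct.data") / f"moments_{corpus}.csv"
    with resources.as_file(ref) as path:
        return SpeciesMoments.from_long_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# geometric phantoms
# ---------------------------------------------------------------------------


def _voxels(value_mm: float, voxel_size_um: float) -> float:
    return value_mm * 1000.0 / voxel_size_um


def make_plate_phantom(
    thickness_mm: float,
    spacing_mm: float,
    dims: tuple[int, int, int],
    voxel_size_um: float,
    axis: int = 0,
) -> BinaryVolume:
    """Parallel slabs of constant thickness separated by constant gaps.

    Slab normals point along ``axis``; slabs span the full lateral extent.
    The ideal geometry is sampled at voxel centres (a voxel is foreground
    when its centre falls inside a slab), so non-integer thicknesses
    alternate between the two neighbouring whole-voxel widths and the fill
    fraction approaches thickness/(thickness+spacing) up to truncation of
    the last period at the grid edge.  Thickness and spacing must each be
    at least 3 voxels.
    """
    t = _voxels(thickness_mm, voxel_size_um)
    s = _voxels(spacing_mm, voxel_size_um)
    if t < 3 or s < 3:
        raise ParameterError(
            f"plate thickness/spacing must each be >= 3 voxels, got {t:.2f}/{s:.2f}"
        )
    # half a gap leads the pattern so no slab butts against the grid face
    # (a slab cut by the frame would read as artificially thick)
    centers = np.arange(dims[axis]) + 0.5 - s / 2.0
    profile = (centers % (t + s)) < t
    shape = [1, 1, 1]
    shape[axis] = dims[axis]
    data = np.broadcast_to(profile.reshape(shape), tuple(dims)).copy()
    return BinaryVolume(data=data, voxel_size_um=voxel_size_um)


def _center_coords(dims, voxel_size_um):
    # voxel-center coordinates relative to the grid centre, in voxels
    return np.meshgrid(
        *[np.arange(n) - (n - 1) / 2.0 for n in dims], indexing="ij", sparse=True
    )


def make_rod_phantom(
    radius_mm: float,
    dims: tuple[int, int, int],
    voxel_size_um: float,
    axis: int = 0,
) -> BinaryVolume:
    """Solid circular cylinder spanning the grid's full length along ``axis``.

    The cross-section must fit strictly inside the lateral dims with a
    margin of at least 2 voxels; radius must be at least 5 voxels.
    """
    r = _voxels(radius_mm, voxel_size_um)
    if r < 5:
        raise ParameterError(f"rod radius must be >= 5 voxels, got {r:.2f}")
    lateral = [dims[a] for a in range(3) if a != axis]
    for n in lateral:
        if r + 2 > (n - 1) / 2.0:
            raise ParameterError(
                f"rod radius {r:.1f} vx + 2 vx margin exceeds half-extent of dim {n}"
            )
    coords = _center_coords(dims, voxel_size_um)
    lat = [coords[a] for a in range(3) if a != axis]
    data = (lat[0] ** 2 + lat[1] ** 2) <= r**2
    return BinaryVolume(data=np.broadcast_to(data, tuple(dims)).copy(),
                        voxel_size_um=voxel_size_um)


def make_sphere_phantom(
    radius_mm: float,
    dims: tuple[int, int, int],
    voxel_size_um: float,
) -> BinaryVolume:
    """Solid ball centred in the grid (radius >= 5 voxels, margin >= 2)."""
    r = _voxels(radius_mm, voxel_size_um)
    if r < 5:
        raise ParameterError(f"sphere radius must be >= 5 voxels, got {r:.2f}")
    for n in dims:
        if r + 2 > (n - 1) / 2.0:
            raise ParameterError(
                f"sphere radius {r:.1f} vx + 2 vx margin exceeds half-extent of dim {n}"
            )
    x, y, z = _center_coords(dims, voxel_size_um)
    data = (x**2 + y**2 + z**2) <= r**2
    return BinaryVolume(data=data, voxel_size_um=voxel_size_um)


def make_trabecular_phantom(
    correlation_length_mm: float,
    fill_fraction: float,
    dims: tuple[int, int, int],
    voxel_size_um: float,
    seed: int = 0,
) -> BinaryVolume:
    """Sponge-like random binary structure with an exact fill fraction.

    White noise is smoothed with an isotropic Gaussian of standard
    deviation ``correlation_length_mm`` and thresholded at the quantile
    that leaves ``fill_fraction`` of the voxels foreground.  Larger
    correlation lengths give thicker trabeculae and wider separations at
    the same fill.
    """
    if not 0.0 < fill_fraction < 1.0:
        raise ParameterError(f"fill_fraction must be in (0, 1), got {fill_fraction}")
    sigma_vx = _voxels(correlation_length_mm, voxel_size_um)
    if sigma_vx <= 0:
        raise ParameterError("correlation_length_mm must be > 0")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(size=tuple(dims))
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_vx)
    cut = np.quantile(smooth, 1.0 - fill_fraction)
    return BinaryVolume(data=smooth >= cut, voxel_size_um=voxel_size_um)


def render_grayscale(
    binary: BinaryVolume,
    bg_level: float,
    fg_level: float,
    noise_sd: float,
    seed: int = 0,
    dtype: str | np.dtype = np.uint8,
) -> VoxelVolume:
    """Render a binary structure as a noisy grayscale stack.

    Background voxels are drawn around ``bg_level`` and mineralised ones
    around ``fg_level`` (Gaussian noise, clipped to the dtype range) —
    mirroring a reconstruction where the darkest gray levels are empty
    space and the brightest are dense mineralised tissue.
    """
    dtype = np.dtype(dtype)
    if dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
        raise ParameterError(f"dtype must be uint8/uint16, got {dtype}")
    vmax = np.iinfo(dtype).max
    if not (0 <= bg_level < fg_level <= vmax):
        raise ParameterError(
            f"need 0 <= bg_level < fg_level <= {vmax}, got {bg_level}/{fg_level}"
        )
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    img = np.where(binary.data, float(fg_level), float(bg_level))
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, vmax).astype(dtype)
    return VoxelVolume(data=img, voxel_size_um=binary.voxel_size_um)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(
    moments: SpeciesMoments,
    n_per_species: int | dict[str, int] | None = None,
    correlation: np.ndarray | None = None,
    seed: int = 0,
    corpus: str = "synthetic",
) -> FeatureTable:
    """Draw a labelled cohort from per-species biomarker moments.

    Each species' biomarker vector is multivariate normal with the stated
    means and SDs; biomarkers are independent unless a 6×6 ``correlation``
    matrix is given (applied within each species).  BV/TV is clipped to
    [0, 100] and other nonnegative biomarkers are truncated at 0 (a warning
    is emitted if more than 0.1% of draws are truncated).

    ``n_per_species`` defaults to the corpus sample sizes stored in
    ``moments``.
    """
    if n_per_species is None:
        if not moments.n:
            raise ParameterError("moments carry no sample sizes; pass n_per_species")
        n_map = dict(moments.n)
    elif isinstance(n_per_species, dict):
        n_map = {sp: int(n_per_species[sp]) for sp in SPECIES}
    else:
        n_map = {sp: int(n_per_species) for sp in SPECIES}
    if min(n_map.values()) < 2:
        raise ParameterError("need n_per_species >= 2 for every species")

    chol = None
    if correlation is not None:
        corr = np.asarray(correlation, dtype=float)
        if corr.shape != (6, 6) or not np.allclose(corr, corr.T, atol=1e-10):
            raise ParameterError("correlation must be a symmetric 6x6 matrix")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ParameterError("correlation must have unit diagonal")
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-10:
            raise ParameterError("correlation matrix is not positive semi-definite")
        # PSD square root tolerates singular matrices (e.g. duplicated features)
        w, v = np.linalg.eigh(corr)
        chol = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    rng = np.random.default_rng(seed)
    records, truncated, total = [], 0, 0
    for sp in sorted(SPECIES):
        n = n_map[sp]
        mu = moments.means.loc[sp, list(BIOMARKERS)].to_numpy(dtype=float)
        sd = moments.sds.loc[sp, list(BIOMARKERS)].to_numpy(dtype=float)
        z = rng.standard_normal(size=(n, 6))
        if chol is not None:
            z = z @ chol.T
        x = mu + sd * z
        for j, bm in enumerate(BIOMARKERS):
            if bm in _NONNEGATIVE:
                below = x[:, j] < 0
                truncated += int(below.sum())
                total += n
                x[below, j] = 0.0
        j_bv = BIOMARKERS.index("bv_tv")
        x[:, j_bv] = np.clip(x[:, j_bv], 0.0, 100.0)
        for i in range(n):
            rec = {
                "sample_id": f"sim_{sp}_{i:04d}",
                "species": sp,
                "corpus": corpus,
                "anatomical_location": "",
            }
            rec.update({bm: x[i, j] for j, bm in enumerate(BIOMARKERS)})
            records.append(rec)
    if total and truncated / total > 1e-3:
        warnings.warn(
            f"{truncated}/{total} nonnegative biomarker draws truncated at 0",
            stacklevel=2,
        )
    return FeatureTable.from_records(records)
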