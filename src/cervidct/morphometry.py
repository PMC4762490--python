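"""The six trabecular microarchitecture biomarkers.

All estimators operate on a :class:`~cervidct.phantoms.BinaryVolume` and
respect its VOI mask: voxels outside the mask belong to neither phase, and
inscribed spheres are truncated at the mask boundary (the VOI ellipse crops
structures; the resulting edge bias is shared with the measurement protocol
this reproduces).

Definitions
-----------
BV/TV   foreground voxel fraction of the mask, in percent.
Tb.Th   volume-weighted mean local thickness of the mineralised phase (mm);
        local thickness at a voxel is the diameter of the largest sphere
        that is fully contained in the phase and covers the voxel
        (Hildebrand–Rüegsegger, model independent).
Tb.Sp   the same quantity for the background phase within the mask (mm).
Tb.N    (BV/TV)/Tb.Th — the plate-model trabecular number (mm⁻¹).
SMI     6·V·S′/S², the structure model index; S′ is the surface-area
        derivative under dilation, estimated by displacing the triangulated
        surface one voxel along its outward normals and re-measuring the
        area.  Calibrated to 0 for plates, 3 for rods, 4 for spheres;
        negative on concave, well-connected surfaces.
Tb.Pf   (S₁−S₂)/(V₁−V₂) under the same one-voxel dilation: convex isolated
        structures give positive values, concave connected meshes negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import EvaluationError, ParameterError
from .phantoms import BinaryVolume
from .segmentation import VOIDescriptor

#: version tag recorded in every profile's provenance
ALGORITHM_TAG = (
    "cervidct-0.1: HR local thickness (EDT sphere covering); plate-model Tb.N; "
    "EDT-offset SMI/Tb.Pf (one-voxel dilation)"
)


@dataclass
class ThicknessMap:
    """Per-voxel local thickness of one phase, in mm (0 off-phase)."""

    values_mm: np.ndarray = field(repr=False)
    phase: str = "foreground"
    voxel_size_um: float = 0.0

    def phase_values(self) -> np.ndarray:
        return self.values_mm[self.values_mm > 0]

    def mean_mm(self) -> float:
        return float(self.phase_values().mean())


@dataclass
class MorphometricProfile:
    """The six biomarkers for one sample, in the reported units."""

    bv_tv: float
    tb_n: float
    tb_th: float
    tb_sp: float
    tb_pf: float
    smi: float
    descriptor: VOIDescriptor | None = None
    algorithm: str = ALGORITHM_TAG
    warnings: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "bv_tv": self.bv_tv,
            "tb_n": self.tb_n,
            "tb_th": self.tb_th,
            "tb_sp": self.tb_sp,
            "tb_pf": self.tb_pf,
            "smi": self.smi,
        }


def _phase_mask(binary: BinaryVolume, phase: str) -> np.ndarray:
    mask = binary.effective_mask()
    if phase == "foreground":
        return binary.data & mask
    if phase == "background":
        return ~binary.data & mask
    raise ParameterError(f"phase must be 'foreground' or 'background', got {phase!r}")


def bv_tv(binary: BinaryVolume) -> float:
    """Bone volume fraction: 100 × foreground voxels / mask voxels."""
    mask = binary.effective_mask()
    total = int(mask.sum())
    if total == 0:
        raise ParameterError("empty mask")
    return 100.0 * int((binary.data & mask).sum()) / total


def local_thickness(binary: BinaryVolume, phase: str = "foreground") -> ThicknessMap:
    """Model-independent local thickness of one phase.

    Every voxel of the phase is assigned the diameter of the largest
    inscribed sphere covering it.  Sphere radii come from the Euclidean
    distance transform (distance to the nearest off-phase voxel centre,
    which overshoots the half-voxel-recessed phase boundary, hence the
    diameter of a sphere of centre distance d is 2d−1 voxels).  Covering is
    resolved exactly by sweeping the distinct radii in descending order and
    testing coverage with one complementary distance transform per radius.
    """
    pm = _phase_mask(binary, phase)
    if not pm.any():
        raise ParameterError(f"{phase} phase is empty within the mask")
    d = ndimage.distance_transform_edt(pm)
    # exact squared radii (EDT distances are square roots of integers)
    d2 = np.rint(d * d).astype(np.int64)
    tau_vox = np.zeros(pm.shape, dtype=float)
    centers = np.zeros(pm.shape, dtype=bool)
    for r2 in np.unique(d2[pm])[::-1]:
        if r2 == 0:
            continue
        centers |= d2 == r2
        dist = ndimage.distance_transform_edt(~centers)
        dist2 = np.rint(dist * dist).astype(np.int64)
        covered = pm & (tau_vox == 0) & (dist2 < r2)
        tau_vox[covered] = 2.0 * np.sqrt(r2) - 1.0
    return ThicknessMap(
        values_mm=tau_vox * binary.voxel_size_mm,
        phase=phase,
        voxel_size_um=binary.voxel_size_um,
    )


def tb_th(binary: BinaryVolume) -> float:
    """Mean local thickness of the mineralised phase (mm)."""
    return local_thickness(binary, "foreground").mean_mm()


def tb_sp(binary: BinaryVolume) -> float:
    """Mean local thickness of the empty-space phase within the mask (mm)."""
    return local_thickness(binary, "background").mean_mm()


def tb_n(binary: BinaryVolume) -> float:
    """Plate-model trabecular number: (BV/TV)/Tb.Th, in mm⁻¹."""
    th = tb_th(binary)
    if th == 0:
        raise EvaluationError("Tb.Th is zero; Tb.N undefined")
    return (bv_tv(binary) / 100.0) / th


def _touches_boundary(fg: np.ndarray, mask: np.ndarray) -> bool:
    # open surface: foreground on the array faces or against the VOI mask edge
    for ax in range(3):
        first = np.take(fg, 0, axis=ax)
        last = np.take(fg, -1, axis=ax)
        if first.any() or last.any():
            return True
    eroded = ndimage.binary_erosion(mask)
    return bool((fg & ~eroded).any())


#: standard deviation (voxels) of the Gaussian applied to the 0/1 field
#: before meshing; suppresses the voxelization staircase (which otherwise
#: inflates sphere areas by ~10%) while moving the surface < 0.1 voxel
_MESH_SIGMA = 1.0


def _mesh_foreground(fg: np.ndarray):
    """Marching-cubes triangulation of the foreground boundary.

    Meshes the 0.5 level of the Gaussian-smoothed indicator field (falling
    back to the raw 0/1 field for structures too small to survive
    smoothing).  Returns vertices (voxel units), faces and outward unit
    normals.
    """
    field = ndimage.gaussian_filter(fg.astype(np.float32), _MESH_SIGMA)
    if not (field.min() < 0.5 < field.max()):
        field = fg.astype(np.float32)
    verts, faces, normals, _ = measure.marching_cubes(field, level=0.5)
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    n = normals / norm
    # orient outward (toward decreasing field); the gradient sign is
    # globally consistent, so one mean test suffices
    fwd = ndimage.map_coordinates(field, (verts + 0.5 * n).T, order=1)
    bwd = ndimage.map_coordinates(field, (verts - 0.5 * n).T, order=1)
    if np.mean(fwd - bwd) > 0:
        n = -n
    return verts, faces, n


def _mesh_area(verts: np.ndarray, faces: np.ndarray) -> float:
    tri = verts[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return float(np.linalg.norm(cross, axis=1).sum() / 2.0)


def surface_mesh_area_volume(binary: BinaryVolume) -> tuple[float, float]:
    """Triangulated surface area (mm²) and voxel-count volume (mm³).

    Structures touching the mask or image boundary leave the mesh open
    there; callers see that through :func:`profile`'s warning flag.
    """
    fg = binary.foreground()
    if not fg.any():
        raise ParameterError("empty foreground")
    s_mm = binary.voxel_size_mm
    volume = float(fg.sum()) * s_mm**3
    if fg.all():
        raise EvaluationError("foreground fills the volume; no surface to mesh")
    verts, faces, _ = _mesh_foreground(fg)
    return _mesh_area(verts, faces) * s_mm**2, volume


def smi(binary: BinaryVolume, dilation_step_voxels: float = 1.0) -> float:
    """Structure model index, 6·V·S′/S².

    S and V are taken at the native surface; S′ = (S(Δr) − S)/Δr is
    estimated by displacing every mesh vertex by Δr along its outward
    normal and re-measuring the triangle area.  Plates score 0, rods 3,
    spheres 4; concave (inward-curving) surfaces score negative because
    dilation shrinks them.
    """
    if dilation_step_voxels <= 0:
        raise ParameterError("dilation_step_voxels must be > 0")
    fg = binary.foreground()
    if not fg.any():
        raise ParameterError("empty foreground")
    if not (~fg & binary.effective_mask()).any():
        raise ParameterError("foreground fills the mask; SMI undefined")
    s_mm = binary.voxel_size_mm
    verts, faces, n = _mesh_foreground(fg)
    s0 = _mesh_area(verts, faces) * s_mm**2
    s1 = _mesh_area(verts + dilation_step_voxels * n, faces) * s_mm**2
    dr_mm = dilation_step_voxels * s_mm
    v = float(fg.sum()) * s_mm**3
    return 6.0 * v * ((s1 - s0) / dr_mm) / s0**2


def tb_pf(binary: BinaryVolume, dilation_step_voxels: float = 1.0) -> float:
    """Trabecular bone pattern factor (mm⁻¹): (S₁−S₂)/(V₁−V₂) where
    subscript 1 is the native structure and 2 the structure after a
    morphological dilation by ``dilation_step_voxels`` (Euclidean ball,
    restricted to the mask).  Dilation closes the gaps of a concave
    connected mesh, so its surface shrinks while its volume grows —
    negative values; isolated convex structures give positive values."""
    if dilation_step_voxels <= 0:
        raise ParameterError("dilation_step_voxels must be > 0")
    fg = binary.foreground()
    if not fg.any():
        raise ParameterError("empty foreground")
    mask = binary.effective_mask()
    s_mm = binary.voxel_size_mm
    dilated = (fg | (ndimage.distance_transform_edt(~fg) <= dilation_step_voxels)) & mask
    v1 = float(fg.sum()) * s_mm**3
    v2 = float(dilated.sum()) * s_mm**3
    if v2 == v1:
        raise EvaluationError("dilation produced no growth; Tb.Pf undefined")
    verts1, faces1, _ = _mesh_foreground(fg)
    s1 = _mesh_area(verts1, faces1) * s_mm**2
    if dilated.all():
        raise EvaluationError("dilation fills the volume; Tb.Pf undefined")
    verts2, faces2, _ = _mesh_foreground(dilated)
    s2 = _mesh_area(verts2, faces2) * s_mm**2
    return (s1 - s2) / (v1 - v2)


def profile(
    binary: BinaryVolume,
    descriptor: VOIDescriptor | None = None,
    dilation_step_voxels: float = 1.0,
) -> MorphometricProfile:
    """Assemble all six biomarkers (atomic: any failure propagates).

    Tb.Th's thickness map is computed once and reused for Tb.N.
    """
    mask = binary.effective_mask()
    fg = binary.data & mask
    if not fg.any() or not (~binary.data & mask).any():
        raise ParameterError("profile requires both phases nonempty within the mask")
    warns: list[str] = []
    if _touches_boundary(fg, mask):
        warns.append("open_surface: foreground touches the mask/image boundary")
    bv = bv_tv(binary)
    th_map = local_thickness(binary, "foreground")
    th = th_map.mean_mm()
    sp = local_thickness(binary, "background").mean_mm()
    n = (bv / 100.0) / th
    return MorphometricProfile(
        bv_tv=bv,
        tb_n=n,
        tb_th=th,
        tb_sp=sp,
        tb_pf=tb_pf(binary, dilation_step_voxels),
        smi=smi(binary, dilation_step_voxels),
        descriptor=descriptor,
        warnings=tuple(warns),
    )
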