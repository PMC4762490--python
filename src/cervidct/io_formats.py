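"""Image-stack and feature-table I/O.

All unit conventions live here: stacks carry an isotropic voxel size in µm
(anisotropic input is rejected, never resampled), axis 0 is always the
cross-section (slice) axis, and every physical quantity downstream is in mm
(Tb.Th/Tb.Sp in mm, Tb.N/Tb.Pf in mm⁻¹, BV/TV in percent, SMI unitless).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError, FormatError, ParameterError

#: canonical biomarker column order (also the CSV column order)
BIOMARKERS = ("bv_tv", "tb_n", "tb_th", "tb_sp", "tb_pf", "smi")

#: exact feature-table CSV header
FEATURE_COLUMNS = (
    "sample_id",
    "species",
    "corpus",
    "anatomical_location",
) + BIOMARKERS

SPECIES = ("red_deer", "reindeer")
CORPORA = ("modern", "archaeological", "synthetic")

_INT_DTYPES = (np.uint8, np.uint16)


@dataclass
class VoxelVolume:
    """A raw micro-CT stack: 3D intensity grid with isotropic voxel size.

    Parameters
    ----------
    data
        3D unsigned-integer array, slice axis first.
    voxel_size_um
        Edge length of the (isotropic) cubic voxel, in µm.
    origin_slice
        Index of the first slice relative to the original acquisition.
    """

    data: np.ndarray
    voxel_size_um: float
    origin_slice: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ParameterError(
                f"volume must be 3D with all dims >= 1, got shape {self.data.shape}"
            )
        if self.data.dtype not in _INT_DTYPES:
            raise ParameterError(
                f"intensity dtype must be uint8 or uint16, got {self.data.dtype}"
            )
        if not self.voxel_size_um > 0:
            raise ParameterError(f"voxel_size_um must be > 0, got {self.voxel_size_um}")

    @property
    def voxel_size_mm(self) -> float:
        return float(self.voxel_size_um) / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def read_stack(path, voxel_size_um: float | None = None) -> VoxelVolume:
    """Read a multi-page TIFF, a directory of single-slice TIFFs, or a raw
    uint8/uint16 file with a JSON sidecar, into a :class:`VoxelVolume`.

    The slice axis comes first.  If the TIFF metadata does not record the
    voxel size, ``voxel_size_um`` must be supplied; an explicit argument
    always wins over metadata.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FormatError(f"no TIFF slices found in directory {path}")
        slices, meta_vox = [], None
        for f in files:
            arr, v = _read_tiff_pages(f)
            if arr.shape[0] != 1:
                raise FormatError(f"slice file {f.name} has {arr.shape[0]} pages, expected 1")
            slices.append(arr[0])
            meta_vox = meta_vox if meta_vox is not None else v
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:
            raise FormatError(f"mixed slice dimensions in {path}: {sorted(shapes)}")
        dtypes = {s.dtype for s in slices}
        if len(dtypes) > 1:
            raise FormatError(f"mixed slice dtypes in {path}: {sorted(map(str, dtypes))}")
        data = np.stack(slices, axis=0)
    elif path.suffix.lower() == ".raw" or path.with_suffix(path.suffix + ".json").exists():
        return _read_raw(path, voxel_size_um)
    else:
        data, meta_vox = _read_tiff_pages(path)

    vox = voxel_size_um if voxel_size_um is not None else meta_vox
    if vox is None:
        raise ConfigurationError(
            f"{path}: voxel size absent from TIFF metadata and no voxel_size_um given"
        )
    if data.dtype not in _INT_DTYPES:
        raise FormatError(f"{path}: unsupported intensity dtype {data.dtype}")
    return VoxelVolume(data=data, voxel_size_um=float(vox))


def _read_tiff_pages(path: Path) -> tuple[np.ndarray, float | None]:
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            vox = _voxel_size_from_tiff(tif)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 2D/3D grayscale TIFF, got ndim={data.ndim}")
    return data, vox


def _voxel_size_from_tiff(tif: tifffile.TiffFile) -> float | None:
    # JSON description written by write_stack
    if tif.shaped_metadata:
        for md in tif.shaped_metadata:
            if isinstance(md, dict) and "voxel_size_um" in md:
                return float(md["voxel_size_um"])
    page = tif.pages[0]
    desc = page.description or ""
    if desc:
        try:
            md = json.loads(desc)
            if isinstance(md, dict) and "voxel_size_um" in md:
                return float(md["voxel_size_um"])
        except json.JSONDecodeError:
            pass
    # fall back to resolution tags (pixels per resolution unit)
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags["ResolutionUnit"].value
    except KeyError:
        return None
    num, den = xres if isinstance(xres, tuple) else (xres, 1)
    if num == 0:
        return None
    um_per_unit = {2: 25400.0, 3: 10000.0}.get(int(unit))  # inch / cm
    if um_per_unit is None:
        return None
    return um_per_unit * den / num


def write_stack(volume: VoxelVolume, path) -> None:
    """Write a volume as a multi-page TIFF whose metadata records the voxel
    size (JSON description plus centimetre-based resolution tags), so that
    ``read_stack(write_stack(v))`` reproduces ``v`` bit-exactly."""
    path = Path(path)
    if not path.parent.is_dir():
        raise OSError(f"parent directory does not exist: {path.parent}")
    px_per_cm = 10000.0 / volume.voxel_size_um
    tifffile.imwrite(
        path,
        volume.data,
        metadata={"voxel_size_um": float(volume.voxel_size_um)},
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


def _read_raw(path: Path, voxel_size_um: float | None) -> VoxelVolume:
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FormatError(f"raw volume {path} lacks JSON sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    try:
        shape = tuple(int(s) for s in meta["shape"])
        dtype = np.dtype(meta["dtype"])
    except (KeyError, TypeError) as exc:
        raise FormatError(f"sidecar {sidecar} missing shape/dtype: {exc}") from exc
    vox = voxel_size_um if voxel_size_um is not None else meta.get("voxel_size_um")
    if vox is None:
        raise ConfigurationError(f"{path}: voxel size absent from sidecar and argument")
    data = np.fromfile(path, dtype=dtype)
    if data.size != int(np.prod(shape)):
        raise FormatError(
            f"{path}: {data.size} voxels on disk but sidecar shape {shape} "
            f"implies {int(np.prod(shape))}"
        )
    return VoxelVolume(data=data.reshape(shape), voxel_size_um=float(vox))


def write_raw(volume: VoxelVolume, path) -> None:
    """Write raw little-endian voxel data plus a JSON sidecar."""
    path = Path(path)
    volume.data.tofile(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "shape": list(volume.data.shape),
                "dtype": volume.data.dtype.name,
                "voxel_size_um": float(volume.voxel_size_um),
            },
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Labelled samples × the six trabecular biomarkers.

    Thin wrapper over a :class:`pandas.DataFrame` with the fixed column set
    ``sample_id, species, corpus, anatomical_location, bv_tv, tb_n, tb_th,
    tb_sp, tb_pf, smi``.  Species is ``red_deer``/``reindeer`` or the empty
    string for unknown.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in FEATURE_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"feature table missing mandatory column {col!r}")
        df = df.loc[:, list(FEATURE_COLUMNS)].reset_index(drop=True)
        for col in ("species", "corpus", "anatomical_location"):
            df[col] = df[col].fillna("").astype(str)
        for col in BIOMARKERS:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise FormatError(f"non-numeric value in column {col!r} at row {row}")
            df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample_id {dup!r}")
        bad_sp = ~df["species"].isin(SPECIES + ("",))
        if bad_sp.any():
            raise FormatError(f"unknown species label {df.loc[bad_sp, 'species'].iloc[0]!r}")
        vals = df["bv_tv"].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise FormatError("bv_tv outside [0, 100]")
        for col in ("tb_n", "tb_th", "tb_sp"):
            if (df[col].dropna() < 0).any():
                raise FormatError(f"{col} must be >= 0")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def species(self) -> np.ndarray:
        return self.df["species"].to_numpy()

    def matrix(self) -> np.ndarray:
        """The (n_samples, 6) biomarker matrix in canonical column order."""
        return self.df.loc[:, list(BIOMARKERS)].to_numpy(dtype=float)

    def subset(self, mask) -> "FeatureTable":
        return FeatureTable(self.df.loc[np.asarray(mask)].reset_index(drop=True))

    @classmethod
    def from_records(cls, records) -> "FeatureTable":
        return cls(pd.DataFrame.from_records(records, columns=list(FEATURE_COLUMNS)))


def read_feature_table(path) -> FeatureTable:
    """Read a feature-table CSV (exact header, '.' decimal separator)."""
    try:
        df = pd.read_csv(path, dtype={"sample_id": str}, keep_default_na=True)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse CSV {path}: {exc}") from exc
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write the feature table as CSV; unknown species become empty fields.

    Round-trips to full stored precision (float values use repr)."""
    df = table.df.copy()
    df.to_csv(path, index=False, float_format=None)
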