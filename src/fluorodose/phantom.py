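"""Voxel phantoms: CT ingestion, HU segmentation, skin-layer extraction.

Geometry convention (used package-wide): 0-based voxel indices, voxel
centers at ``origin + (index + 0.5) * spacing``, millimeters internally,
room frame centered on the C-arm isocenter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .materials import Material

__all__ = [
    "VoxelPhantom",
    "FormatError",
    "load_ct",
    "save_raw",
    "hu_to_material",
    "synth_ct_torso",
    "extract_skin_mask",
]


class FormatError(ValueError):
    """Malformed or inconsistent CT input."""


@dataclass
class VoxelPhantom:
    """CT-derived voxel grid with material ids, densities and a skin mask.

    Arrays are C-ordered ``(nx, ny, nz)``; ``spacing`` and ``origin`` are in
    mm, with ``origin`` the corner of voxel (0,0,0) relative to isocenter.
    """

    hu: np.ndarray                     # int16-compatible HU values
    spacing: np.ndarray                # mm, (3,)
    origin: np.ndarray                 # mm, (3,)
    material_id: np.ndarray = field(default=None)  # uint8 Material values
    density: np.ndarray = field(default=None)      # g/cm^3
    skin_mask: np.ndarray = field(default=None)    # bool

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.hu.ndim != 3:
            raise ValueError("hu must be a 3-D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if self.material_id is None:
            self.material_id, self.density = hu_to_material(self.hu)
        if self.skin_mask is None:
            self.skin_mask = extract_skin_mask(self)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape

    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower corner, upper corner) of the grid in room mm."""
        lo = self.origin.copy()
        return lo, lo + self.spacing * np.asarray(self.shape)

    def translated(self, offset_mm) -> "VoxelPhantom":
        """Same grid shifted rigidly by ``offset_mm`` (table motion)."""
        return VoxelPhantom(
            hu=self.hu, spacing=self.spacing,
            origin=self.origin + np.asarray(offset_mm, dtype=float),
            material_id=self.material_id, density=self.density,
            skin_mask=self.skin_mask,
        )


# HU -> density anchors: piecewise-linear, continuous, monotone.
_HU_ANCHORS = np.array([-1000.0, 0.0, 1000.0, 3000.0])
_RHO_ANCHORS = np.array([0.0012, 1.000, 1.80, 3.40])


def hu_to_material(hu):
    """Map Hounsfield units to (material id, mass density g/cm^3).

    Segmentation: HU < −900 air; −900 ≤ HU < −200 lung; −200 ≤ HU < 150
    soft tissue; HU ≥ 150 bone.  Density follows a continuous piecewise-linear
    calibration anchored at ρ(−1000)=0.0012, ρ(0)=1.000, ρ(1000)=1.80.
    Out-of-range HU are clamped to [−1024, 3000].
    """
    h = np.clip(np.asarray(hu, dtype=float), -1024.0, 3000.0)
    mat = np.full(h.shape, Material.SOFT_TISSUE, dtype=np.uint8)
    mat[h < -900] = Material.AIR
    mat[(h >= -900) & (h < -200)] = Material.LUNG
    mat[h >= 150] = Material.BONE
    rho = np.interp(h, _HU_ANCHORS, _RHO_ANCHORS)
    rho = np.maximum(rho, 0.0012)
    if np.ndim(hu) == 0:
        return Material(int(mat)), float(rho)
    return mat, rho


def extract_skin_mask(phantom: VoxelPhantom, layer_mm: float = 3.0) -> np.ndarray:
    """Skin layer: non-air voxels within ``layer_mm`` of the air interface.

    The base shell is every non-air voxel 6-adjacent to an air voxel; the
    layer is grown inward with a Euclidean distance transform so a thicker
    ``layer_mm`` always yields a superset.
    """
    if layer_mm <= 0:
        raise ValueError("layer_mm must be positive")
    tissue = phantom.material_id != Material.AIR
    if not tissue.any():
        return np.zeros(phantom.shape, dtype=bool)
    air = ~tissue
    # pad so the volume boundary counts as air
    air_p = np.pad(air, 1, constant_values=True)
    struct = ndimage.generate_binary_structure(3, 1)
    near_air = ndimage.binary_dilation(air_p, structure=struct)[1:-1, 1:-1, 1:-1]
    shell = tissue & near_air
    if layer_mm <= float(phantom.spacing.min()):
        return shell
    # distance from each tissue voxel to the nearest shell voxel
    dist = ndimage.distance_transform_edt(~shell, sampling=phantom.spacing)
    return tissue & (dist <= layer_mm - float(phantom.spacing.min()) + 1e-9)


def synth_ct_torso(nx: int = 128, ny: int = 128, nz: int = 64,
                   spacing_mm: float = 3.0, seed: int = 0) -> VoxelPhantom:
    """Synthetic torso CT standing in for a body-phantom scan.

    An elliptical soft-tissue cylinder (half-axes ~0.42·X, ~0.30·Y of the
    volume) holds two lung ellipsoids (−750 HU) and a posterior spine column
    (+700 HU), surrounded by air.  Small seeded HU noise (σ=20) texturizes
    tissue.  The grid is centered on the isocenter, so a PA beam from an
    under-table tube at 72 cm reaches the posterior skin at ≈60 cm for the
    default sizes.
    """
    if min(nx, ny, nz) < 32:
        raise ValueError("dimensions must be at least 32 voxels per axis")
    rng = np.random.default_rng(seed)
    sp = float(spacing_mm)
    shape = (nx, ny, nz)
    origin = -0.5 * sp * np.asarray(shape, dtype=float)
    x = origin[0] + (np.arange(nx) + 0.5) * sp
    y = origin[1] + (np.arange(ny) + 0.5) * sp
    z = origin[2] + (np.arange(nz) + 0.5) * sp
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    # torso semi-axes, mm; the anterior-posterior semi-axis is 120 mm for the
    # default 128 @ 3 mm grid, placing the posterior skin 60 cm from an
    # under-table PA source at 72 cm.
    ax, ay = 0.42 * nx * sp, 0.3125 * ny * sp
    body = (X / ax) ** 2 + (Y / ay) ** 2 <= 1.0

    hu = np.full(shape, -1000.0)
    hu[body] = 30.0

    lung_a = np.array([0.16 * nx * sp, 0.16 * ny * sp, 0.35 * nz * sp])
    for sx in (-1.0, 1.0):
        c = np.array([sx * 0.18 * nx * sp, 0.03 * ny * sp, 0.0])
        lung = (((X - c[0]) / lung_a[0]) ** 2 + ((Y - c[1]) / lung_a[1]) ** 2
                + ((Z - c[2]) / lung_a[2]) ** 2) <= 1.0
        hu[lung & body] = -750.0

    spine_r = 0.06 * nx * sp
    spine = (X ** 2 + (Y + 0.20 * ny * sp) ** 2) <= spine_r ** 2
    hu[spine & body] = 700.0

    noise = rng.normal(0.0, 20.0, size=shape)
    hu[body] += noise[body]
    return VoxelPhantom(hu=hu.astype(np.int16), spacing=(sp, sp, sp), origin=origin)


# ---------------------------------------------------------------------------
# I/O: raw container (int16 HU + JSON sidecar) and DICOM series


def save_raw(phantom: VoxelPhantom, path: str | Path) -> None:
    """Write ``<path>.raw`` (little-endian int16 HU, x-fastest) + ``<path>.json``."""
    path = Path(path)
    hu = np.asarray(phantom.hu, dtype="<i2")
    # x-fastest order: write Fortran-ordered bytes
    path.with_suffix(".raw").write_bytes(np.asfortranarray(hu).tobytes(order="F"))
    sidecar = {
        "shape": list(phantom.shape),
        "spacing_mm": list(map(float, phantom.spacing)),
        "origin_mm": list(map(float, phantom.origin)),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_ct(path: str | Path, spacing_override=None) -> VoxelPhantom:
    """Load a CT volume from a DICOM series directory or the raw container.

    ``path`` may be a directory of DICOM slices, or the stem/raw/json path of
    the documented raw container (``<name>.raw`` little-endian int16 HU in
    x-fastest order plus ``<name>.json`` with shape, spacing_mm, origin_mm).
    """
    path = Path(path)
    if path.is_dir():
        return _load_dicom_series(path, spacing_override)
    stem = path.with_suffix("")
    raw_p, json_p = stem.with_suffix(".raw"), stem.with_suffix(".json")
    if not raw_p.exists() or not json_p.exists():
        raise FormatError(f"raw container incomplete: need {raw_p} and {json_p}")
    meta = json.loads(json_p.read_text())
    for key in ("shape", "spacing_mm", "origin_mm"):
        if key not in meta:
            raise FormatError(f"sidecar missing field '{key}'")
    shape = tuple(meta["shape"])
    data = np.frombuffer(raw_p.read_bytes(), dtype="<i2")
    if data.size != int(np.prod(shape)):
        raise FormatError("raw payload size does not match sidecar shape")
    hu = data.reshape(shape, order="F")
    spacing = spacing_override if spacing_override is not None else meta["spacing_mm"]
    return VoxelPhantom(hu=hu.copy(), spacing=spacing, origin=meta["origin_mm"])


def _load_dicom_series(directory: Path, spacing_override=None) -> VoxelPhantom:
    import pydicom

    files = sorted(directory.glob("*.dcm")) or sorted(
        p for p in directory.iterdir() if p.is_file())
    if not files:
        raise FormatError(f"no DICOM files in {directory}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    dz = np.diff(zs)
    if len(dz) and (dz.max() - dz.min()) > 0.01 * max(abs(dz).max(), 1e-6):
        raise FormatError("inconsistent slice spacing (missing or duplicated slice?)")
    first = slices[0]
    px = [float(v) for v in first.PixelSpacing]
    spacing = (px[1], px[0], float(dz[0]) if len(dz) else 1.0)
    if spacing_override is not None:
        spacing = spacing_override
    vol = np.stack(
        [s.pixel_array * float(getattr(s, "RescaleSlope", 1.0))
         + float(getattr(s, "RescaleIntercept", 0.0)) for s in slices], axis=-1)
    # pixel_array is (row=y, col=x); reorder to (x, y, z)
    hu = np.ascontiguousarray(np.transpose(vol, (1, 0, 2)))
    ipp = [float(v) for v in first.ImagePositionPatient]
    origin = np.array([ipp[0], ipp[1], zs[0]]) - 0.5 * np.asarray(spacing)
    return VoxelPhantom(hu=hu.astype(np.int16), spacing=spacing, origin=origin)
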