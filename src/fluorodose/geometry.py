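"""C-arm geometry, beam frustum and room layout.

Room frame: right-handed, origin at the isocenter, +x patient-left,
+y patient-anterior (up for a supine patient), +z cranial.  The PA pose
(lateral 0°, cranio-caudal 0°) puts the x-ray source under the table at
(0, −siso, 0) and the detector above the patient.  Lateral rotation
(RAO−/LAO+) is about +z, applied after the cranio-caudal rotation about +x:
``source = R_z(lat) @ R_x(cc) @ (0, −siso, 0)``.  Angles are degrees at every
public interface and radians only inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import Material
from .phantom import VoxelPhantom

__all__ = [
    "CArmPose",
    "BeamFrustum",
    "RoomModel",
    "carm_pose_to_source",
    "beam_frustum",
    "entrance_ssd",
    "NoEntranceError",
]

LATERAL_RANGE = (-90.0, 90.0)
CAUDCRAN_RANGE = (-30.0, 30.0)


class NoEntranceError(RuntimeError):
    """The central beam axis does not intersect the phantom surface."""


@dataclass(frozen=True)
class CArmPose:
    """C-arm orientation plus table displacement.

    ``lateral_deg``: RAO(−)/LAO(+); ``caudcran_deg``: caudal(−)/cranial(+);
    both limited to the precomputed-table coverage (±90°, ±30°).
    ``table_offset_mm`` is the table displacement from its calibrated
    reference as a room-frame (x=lateral, y=vertical, z=longitudinal)
    vector; it displaces the phantom, never the C-arm.
    """

    lateral_deg: float = 0.0
    caudcran_deg: float = 0.0
    sid_cm: float = 100.0
    siso_cm: float = 72.0
    table_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not LATERAL_RANGE[0] <= self.lateral_deg <= LATERAL_RANGE[1]:
            raise ValueError(f"lateral angle {self.lateral_deg} outside ±90°")
        if not CAUDCRAN_RANGE[0] <= self.caudcran_deg <= CAUDCRAN_RANGE[1]:
            raise ValueError(f"cranio-caudal angle {self.caudcran_deg} outside ±30°")
        if not self.sid_cm > self.siso_cm > 0:
            raise ValueError("require sid > siso > 0")


@dataclass(frozen=True)
class BeamFrustum:
    """Square-pyramid beam volume from the focal spot to the detector field."""

    source_xyz: np.ndarray          # mm
    detector_center_xyz: np.ndarray  # mm
    axis_unit: np.ndarray
    fov_at_detector_cm: float
    sid_cm: float
    corners: np.ndarray             # (4, 3) detector-plane corners, mm

    @property
    def half_angle_rad(self) -> float:
        return float(np.arctan(self.fov_at_detector_cm / 2.0 / self.sid_cm))

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal in-plane detector axes (e1, e2)."""
        a = self.axis_unit
        helper = np.array([0.0, 0.0, 1.0])
        if abs(a @ helper) > 0.9:
            helper = np.array([1.0, 0.0, 0.0])
        e1 = np.cross(a, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(a, e1)
        return e1, e2

    def contains(self, points_mm) -> np.ndarray:
        """Membership test: inside the pyramid between source and detector plane."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float)) - self.source_xyz
        d = p @ self.axis_unit
        e1, e2 = self.basis()
        sid_mm = self.sid_cm * 10.0
        half = self.fov_at_detector_cm * 10.0 / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            u = (p @ e1) / d * sid_mm
            v = (p @ e2) / d * sid_mm
        ok = (d > 0) & (np.abs(u) <= half + 1e-9) & (np.abs(v) <= half + 1e-9)
        return ok if np.asarray(points_mm).ndim > 1 else bool(ok[0])


def _rot_x(rad: float) -> np.ndarray:
    c, s = np.cos(rad), np.sin(rad)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_z(rad: float) -> np.ndarray:
    c, s = np.cos(rad), np.sin(rad)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def carm_pose_to_source(pose: CArmPose):
    """(source, detector center, axis unit vector) in room mm for ``pose``."""
    rot = _rot_z(np.deg2rad(pose.lateral_deg)) @ _rot_x(np.deg2rad(pose.caudcran_deg))
    source = rot @ np.array([0.0, -pose.siso_cm * 10.0, 0.0])
    axis = -source / np.linalg.norm(source)
    detector = source + axis * pose.sid_cm * 10.0
    return source, detector, axis


def beam_frustum(pose: CArmPose, fov_cm: float) -> BeamFrustum:
    """Square beam pyramid for ``pose`` with field side ``fov_cm`` at the detector."""
    if fov_cm <= 0:
        raise ValueError("fov must be positive")
    source, detector, axis = carm_pose_to_source(pose)
    frustum = BeamFrustum(source_xyz=source, detector_center_xyz=detector,
                          axis_unit=axis, fov_at_detector_cm=float(fov_cm),
                          sid_cm=pose.sid_cm, corners=np.zeros((4, 3)))
    e1, e2 = frustum.basis()
    half = fov_cm * 10.0 / 2.0
    corners = np.array([detector + su * half * e1 + sv * half * e2
                        for su, sv in ((-1, -1), (1, -1), (1, 1), (-1, 1))])
    return BeamFrustum(source_xyz=source, detector_center_xyz=detector,
                       axis_unit=axis, fov_at_detector_cm=float(fov_cm),
                       sid_cm=pose.sid_cm, corners=corners)


def entrance_ssd(pose: CArmPose, phantom: VoxelPhantom, step_mm: float = 0.25) -> float:
    """Source-to-surface distance (cm) along the central axis.

    Ray-marches from the source toward the isocenter at ``step_mm`` and
    returns the distance to the first skin voxel of the (table-displaced)
    phantom.  Raises :class:`NoEntranceError` if the axis never meets skin.
    """
    source, _, axis = carm_pose_to_source(pose)
    ph = phantom.translated(pose.table_offset_mm)
    lo, hi = ph.bounds()
    sid_mm = pose.sid_cm * 10.0
    ts = np.arange(0.0, sid_mm, step_mm)
    pts = source[None, :] + ts[:, None] * axis[None, :]
    inside = np.all((pts >= lo) & (pts < hi), axis=1)
    if not inside.any():
        raise NoEntranceError("central axis misses the phantom grid")
    idx = ((pts[inside] - lo) / ph.spacing).astype(np.int64)
    hits = ph.skin_mask[idx[:, 0], idx[:, 1], idx[:, 2]]
    if not hits.any():
        raise NoEntranceError("central axis does not intersect the skin surface")
    t_hit = ts[inside][hits.argmax()]
    return float(t_hit) / 10.0


@dataclass(frozen=True)
class RoomModel:
    """Interventional-suite geometry: air box, walls, patient-table slab.

    ``size_m`` is the inner (air) box; walls of ``wall_thickness_cm`` of a
    concrete-equivalent material surround it.  The table slab is a thin
    low-density plate under the patient.  The box is centered on the
    isocenter laterally and longitudinally; ``floor_below_iso_m`` sets how
    far below the isocenter the floor lies.
    """

    size_m: tuple[float, float, float] = (6.0, 3.0, 6.0)
    wall_thickness_cm: float = 20.0
    wall_material: Material = Material.BONE   # concrete-equivalent (similar Z_eff)
    wall_density: float = 2.3                 # g/cm^3
    floor_below_iso_m: float = 1.2
    table_size_mm: tuple[float, float, float] = (500.0, 20.0, 2500.0)
    table_gap_mm: float = 200.0               # patient surface to table top
    table_material: Material = Material.SOFT_TISSUE  # carbon-fiber-like plate
    table_density: float = 0.30
    air_density: float = 0.0012
    walls_enabled: bool = True
    table_enabled: bool = True

    def inner_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        sx, sy, sz = (s * 1000.0 for s in self.size_m)
        floor = self.floor_below_iso_m * 1000.0
        lo = np.array([-sx / 2, -floor, -sz / 2])
        hi = np.array([sx / 2, sy - floor, sz / 2])
        return lo, hi

    def outer_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.inner_bounds()
        t = self.wall_thickness_cm * 10.0
        return lo - t, hi + t

    def table_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        w, th, ln = self.table_size_mm
        top = -self.table_gap_mm
        lo = np.array([-w / 2, top - th, -ln / 2])
        hi = np.array([w / 2, top, ln / 2])
        return lo, hi
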