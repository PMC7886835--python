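"""Monte Carlo dose engine: skin-dose grids and room air-kerma grids.

Photons are sampled from the filtered tube spectrum, transported by
Woodcock (delta) tracking through the voxel phantom and analytically
through the room's homogeneous regions, and scored in the kerma
approximation: energy transferred at photoelectric and Compton events is
deposited locally (secondary-electron ranges are well under a voxel below
150 keV).  Uncertainty comes from batch statistics: the run is split into
``n_batches`` independent batches and the per-voxel relative standard
error of the batch means is reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import h5py
import numpy as np

from . import _transport
from .conditions import FluoroConditions
from .geometry import CArmPose, NoEntranceError, RoomModel, beam_frustum
from .materials import Material, fine_grid
from .phantom import VoxelPhantom
from .spectrum import Spectrum, generate_spectrum

__all__ = [
    "MCConfig",
    "DoseGrid",
    "TubeCalibration",
    "klein_nishina_sample",
    "simulate_skin_dose",
    "simulate_air_kerma",
    "dose_rate_scale",
    "save_dose_grid",
    "load_dose_grid",
]

KEV_TO_J = 1.602176634e-16
MEC2_KEV = _transport.MEC2_KEV


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo run parameters.

    ``n_photons`` defaults to 10^7 for skin-dose runs; air-kerma grids use a
    reduced desk-scale default of 10^6.  ``cutoff_keV`` is the 5 keV photon
    cutoff below which remaining energy is deposited locally.
    """

    n_photons: int = 10_000_000
    cutoff_keV: float = 5.0
    n_batches: int = 10
    seed: int = 0
    rayleigh_enabled: bool = False
    estimator: str = "collision"   # "collision" (kerma estimator) | "analog"

    def __post_init__(self) -> None:
        if not self.n_photons >= self.n_batches >= 2:
            raise ValueError("require n_photons >= n_batches >= 2")
        if self.cutoff_keV < 5.0:
            raise ValueError("cutoff below the 5 keV table floor")
        if self.estimator not in ("collision", "analog"):
            raise ValueError("estimator must be 'collision' or 'analog'")

    def batch_seeds(self) -> np.ndarray:
        return np.random.SeedSequence(self.seed).generate_state(self.n_batches)

    def batch_sizes(self) -> np.ndarray:
        base, extra = divmod(self.n_photons, self.n_batches)
        return np.array([base + (i < extra) for i in range(self.n_batches)])


@dataclass
class DoseGrid:
    """Per-voxel dose (Gy per source photon) with relative uncertainty."""

    dose_per_photon: np.ndarray
    rel_uncertainty: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    n_photons_run: int
    kind: str = "skin"          # "skin" | "air"
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.dose_per_photon.shape

    def peak(self) -> tuple[tuple[int, int, int], float, float]:
        """(voxel index, dose per photon, relative uncertainty) at the maximum."""
        idx = np.unravel_index(int(np.argmax(self.dose_per_photon)),
                               self.dose_per_photon.shape)
        return idx, float(self.dose_per_photon[idx]), float(self.rel_uncertainty[idx])

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin_mm[axis] + (np.arange(n) + 0.5) * self.spacing_mm[axis]


@dataclass(frozen=True)
class TubeCalibration:
    """Bridge from per-photon scores to clinical rates.

    ``photons_per_mAs`` is the facility-calibrated tube output (source
    photons emitted into the collimated field per mA·s); the default of 1
    leaves scores in per-photon units scaled only by mA.  ``pulse_width_s``
    enables pulsed-mode duty cycling (duty = fps × pulse width); unset means
    continuous fluoroscopy (duty 1).
    """

    photons_per_mAs: float = 1.0
    pulse_width_s: float | None = None

    def __post_init__(self) -> None:
        if self.photons_per_mAs <= 0:
            raise ValueError("calibration constant must be positive")

    def duty(self, fps: float) -> float:
        if self.pulse_width_s is None:
            return 1.0
        return min(1.0, fps * self.pulse_width_s)


def dose_rate_scale(dose_per_photon, conditions: FluoroConditions,
                    calibration: TubeCalibration = TubeCalibration()):
    """Convert Gy/photon to Gy/s: dose × photons_per_mAs × mA × duty."""
    return (np.asarray(dose_per_photon) * calibration.photons_per_mAs
            * conditions.ma * calibration.duty(conditions.fps))


def klein_nishina_sample(energy_keV: float, rng: np.random.Generator,
                         size: int | None = None):
    """Sample Compton scattering from the Klein-Nishina cross section.

    Kahn's two-branch rejection method; returns ``(energy_out_keV,
    cos_theta)`` scalars, or arrays when ``size`` is given.  The scattered
    energy obeys E' = E / (1 + (E/m_e c²)(1 − cosθ)) exactly.
    """
    a = energy_keV / MEC2_KEV
    n = 1 if size is None else int(size)
    eta = np.empty(n)
    todo = np.ones(n, dtype=bool)
    while todo.any():
        m = int(todo.sum())
        r1, r2, r3 = rng.random((3, m))
        branch1 = r1 <= (1 + 2 * a) / (9 + 2 * a)
        eta_t = np.where(branch1, 1 + 2 * a * r2, (1 + 2 * a) / (1 + 2 * a * r2))
        cost_t = 1 - (eta_t - 1) / a
        acc1 = r3 <= 4 * (1 / eta_t - 1 / eta_t**2)
        acc2 = r3 <= 0.5 * (cost_t**2 + 1 / eta_t)
        accept = np.where(branch1, acc1, acc2)
        idx = np.flatnonzero(todo)[accept]
        eta[idx] = eta_t[accept]
        todo[idx] = False
    cost = 1 - (eta - 1) / a
    e_out = energy_keV / eta
    if size is None:
        return float(e_out[0]), float(cost[0])
    return e_out, cost


@lru_cache(maxsize=1)
def _fine_tables():
    energies, mu, mutr, fpe, fco, fra = fine_grid()
    return (energies,
            np.ascontiguousarray(mu), np.ascontiguousarray(mutr),
            np.ascontiguousarray(fpe), np.ascontiguousarray(fco),
            np.ascontiguousarray(fra))


def _majorant(mu_rho_fine: np.ndarray, mat: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Energy-wise majorant linear attenuation over the phantom volume."""
    max_rho = np.zeros(mu_rho_fine.shape[0])
    for m in np.unique(mat):
        max_rho[m] = rho[mat == m].max()
    mu_maj = (mu_rho_fine * max_rho[:, None]).max(axis=0)
    return np.maximum(mu_maj, 1e-8)


def _spectrum_arrays(spectrum: Spectrum):
    return np.ascontiguousarray(spectrum.cdf()), np.ascontiguousarray(
        spectrum.energy_bins.astype(np.float64))


def _frustum_arrays(pose: CArmPose, fov_cm: float):
    fr = beam_frustum(pose, fov_cm)
    e1, e2 = fr.basis()
    half_mm = fov_cm * 10.0 / 2.0
    return (fr.source_xyz.astype(np.float64), e1.astype(np.float64),
            e2.astype(np.float64), fr.detector_center_xyz.astype(np.float64),
            half_mm, fr)


def simulate_skin_dose(phantom: VoxelPhantom, pose: CArmPose,
                       conditions: FluoroConditions,
                       mc_config: MCConfig = MCConfig(),
                       spectrum: Spectrum | None = None) -> DoseGrid:
    """Skin-dose grid (Gy per source photon) on the phantom lattice.

    Deposited energy is scored in every voxel for exact energy bookkeeping;
    the returned grid carries dose only on the skin mask.  Raises
    :class:`NoEntranceError` when the beam axis misses the phantom grid.
    """
    ph = phantom.translated(pose.table_offset_mm)
    src, e1, e2, det, half_mm, fr = _frustum_arrays(pose, conditions.fov_cm)
    lo, hi = ph.bounds()
    t0, t1 = _aabb(src, fr.axis_unit, lo, hi)
    if t1 <= max(t0, 0.0):
        raise NoEntranceError("beam axis does not intersect the phantom grid")

    energies, mu, mutr, fpe, fco, fra = _fine_tables()
    e0, inv_de = energies[0], 1.0 / (energies[1] - energies[0])
    mat = np.ascontiguousarray(ph.material_id, dtype=np.uint8)
    rho = np.ascontiguousarray(ph.density, dtype=np.float64)
    mu_maj = _majorant(mu, mat, rho)
    if spectrum is None:
        spectrum = generate_spectrum(conditions.kvp, conditions.filter_cu_mm)
    cdf, ebins = _spectrum_arrays(spectrum)

    sizes = mc_config.batch_sizes()
    seeds = mc_config.batch_seeds()
    nvox = mat.size
    fc_bin_mm = 1.0
    n_fc = 513
    firstcol = np.zeros(n_fc, dtype=np.int64)
    batch_gy = np.zeros((mc_config.n_batches, nvox))
    emitted = deposited = escaped = 0.0
    vol_cm3 = ph.voxel_volume_cm3()
    mass_g = rho.ravel() * vol_cm3
    for b in range(mc_config.n_batches):
        edep = np.zeros(nvox)
        kscore = np.zeros(nvox)
        em, dep, esc = _transport.skin_dose_kernel(
            np.int64(seeds[b] & 0x7FFFFFFF), np.int64(sizes[b]),
            src, e1, e2, det, half_mm, cdf, ebins,
            mat, rho, lo.astype(np.float64), ph.spacing.astype(np.float64),
            mu, fpe, fco, mu_maj, e0, inv_de,
            mc_config.cutoff_keV, mc_config.rayleigh_enabled,
            edep, mutr, kscore, firstcol, fc_bin_mm)
        emitted += em
        deposited += dep
        escaped += esc
        if mc_config.estimator == "collision":
            # keV·cm³/g -> Gy: mass-independent kerma estimator
            batch_gy[b] = kscore * (KEV_TO_J * 1000.0) / vol_cm3 / sizes[b]
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                batch_gy[b] = edep * (KEV_TO_J * 1000.0) / mass_g / sizes[b]

    mean = batch_gy.mean(axis=0)
    se = batch_gy.std(axis=0, ddof=1) / np.sqrt(mc_config.n_batches)
    rel = np.zeros_like(mean)
    nz = mean > 0
    rel[nz] = se[nz] / mean[nz]

    skin = ph.skin_mask.ravel()
    mean[~skin] = 0.0
    rel[~skin] = 0.0
    return DoseGrid(
        dose_per_photon=mean.reshape(ph.shape),
        rel_uncertainty=rel.reshape(ph.shape),
        spacing_mm=ph.spacing.copy(), origin_mm=lo.copy(),
        n_photons_run=int(sizes.sum()), kind="skin",
        meta={"emitted_keV": emitted, "deposited_keV": deposited,
              "escaped_keV": escaped, "kvp": conditions.kvp,
              "filter_cu_mm": conditions.filter_cu_mm,
              "seed": mc_config.seed, "n_batches": mc_config.n_batches,
              "estimator": mc_config.estimator,
              "first_collision_hist": firstcol,
              "first_collision_bin_mm": fc_bin_mm},
    )


def _aabb(p, d, lo, hi):
    """(t_entry, t_exit) of a ray with an axis-aligned box; exit < entry means miss."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = (lo - p) / d
        tb = (hi - p) / d
    near = np.where(np.abs(d) < 1e-12, -np.inf, np.minimum(ta, tb))
    far = np.where(np.abs(d) < 1e-12,
                   np.where((p >= lo) & (p < hi), np.inf, -np.inf),
                   np.maximum(ta, tb))
    return float(np.max(near)), float(np.min(far))


def simulate_air_kerma(room: RoomModel, phantom: VoxelPhantom | None,
                       pose: CArmPose, conditions: FluoroConditions,
                       grid_spacing_cm: float = 10.0,
                       mc_config: MCConfig = MCConfig(n_photons=1_000_000),
                       isotropic_source: bool = False,
                       lattice_bounds=None,
                       spectrum: Spectrum | None = None) -> DoseGrid:
    """Air-kerma grid (Gy per source photon) on a coarse room lattice.

    Track-length estimation: every air path segment contributes
    ℓ·E·(μ_tr/ρ)_air to the cells it crosses.  Photons scatter off the
    phantom, the table slab and (single or multiple bounces) the concrete-
    equivalent walls, per the room model flags.
    """
    energies, mu, mutr, fpe, fco, fra = _fine_tables()
    e0, inv_de = energies[0], 1.0 / (energies[1] - energies[0])

    if phantom is not None:
        ph = phantom.translated(pose.table_offset_mm)
        mat = np.ascontiguousarray(ph.material_id, dtype=np.uint8)
        rho = np.ascontiguousarray(ph.density, dtype=np.float64)
        ph_lo = ph.bounds()[0].astype(np.float64)
        ph_sp = ph.spacing.astype(np.float64)
        mu_maj = _majorant(mu, mat, rho)
    else:
        mat = np.zeros((1, 1, 1), dtype=np.uint8)
        rho = np.full((1, 1, 1), room.air_density)
        ph_lo = np.zeros(3)
        ph_sp = np.ones(3)
        mu_maj = np.maximum(mu[Material.AIR] * room.air_density, 1e-8)

    inner_lo, inner_hi = (b.astype(np.float64) for b in room.inner_bounds())
    outer_lo, outer_hi = (b.astype(np.float64) for b in room.outer_bounds())
    tb_lo, tb_hi = (b.astype(np.float64) for b in room.table_bounds())

    if lattice_bounds is None:
        lat_lo, lat_hi = inner_lo.copy(), inner_hi.copy()
    else:
        lat_lo = np.asarray(lattice_bounds[0], dtype=np.float64)
        lat_hi = np.asarray(lattice_bounds[1], dtype=np.float64)
    sp = grid_spacing_cm * 10.0
    lat_shape = np.maximum(((lat_hi - lat_lo) / sp).astype(np.int64), 1)
    lat_sp = (lat_hi - lat_lo) / lat_shape

    src, e1, e2, det, half_mm, _ = _frustum_arrays(pose, conditions.fov_cm)
    if spectrum is None:
        spectrum = generate_spectrum(conditions.kvp, conditions.filter_cu_mm)
    cdf, ebins = _spectrum_arrays(spectrum)
    mutr_air = np.ascontiguousarray(mutr[Material.AIR])

    sizes = mc_config.batch_sizes()
    seeds = mc_config.batch_seeds()
    ncell = int(np.prod(lat_shape))
    vol_cm3 = float(np.prod(lat_sp)) / 1000.0
    batch_kerma = np.zeros((mc_config.n_batches, ncell))
    for b in range(mc_config.n_batches):
        accum = np.zeros(ncell)
        _transport.air_kerma_kernel(
            np.int64(seeds[b] & 0x7FFFFFFF), np.int64(sizes[b]),
            src, e1, e2, det, half_mm, isotropic_source,
            cdf, ebins, mat, rho, ph_lo, ph_sp, phantom is not None,
            mu, fpe, fco, mu_maj, e0, inv_de,
            inner_lo, inner_hi, outer_lo, outer_hi,
            room.walls_enabled and room.wall_thickness_cm > 0,
            np.uint8(room.wall_material), room.wall_density,
            tb_lo, tb_hi, room.table_enabled,
            np.uint8(room.table_material), room.table_density,
            room.air_density, mutr_air,
            mc_config.cutoff_keV, mc_config.rayleigh_enabled,
            lat_lo, lat_sp, lat_shape, accum)
        # keV·cm²/g per cell -> Gy per photon
        batch_kerma[b] = accum * (KEV_TO_J * 1000.0) / vol_cm3 / sizes[b]

    mean = batch_kerma.mean(axis=0)
    se = batch_kerma.std(axis=0, ddof=1) / np.sqrt(mc_config.n_batches)
    rel = np.zeros_like(mean)
    nz = mean > 0
    rel[nz] = se[nz] / mean[nz]
    shape = tuple(int(s) for s in lat_shape)
    return DoseGrid(
        dose_per_photon=mean.reshape(shape), rel_uncertainty=rel.reshape(shape),
        spacing_mm=lat_sp, origin_mm=lat_lo, n_photons_run=int(sizes.sum()),
        kind="air",
        meta={"kvp": conditions.kvp, "filter_cu_mm": conditions.filter_cu_mm,
              "fov_cm": conditions.fov_cm, "sid_cm": conditions.sid_cm,
              "seed": mc_config.seed, "n_batches": mc_config.n_batches,
              "isotropic_source": isotropic_source},
    )


# ---------------------------------------------------------------------------
# persistence

_SCHEMA_VERSION = 1


def _jsonable(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        if isinstance(v, np.ndarray):
            out[k] = v.tolist()
        elif isinstance(v, (np.integer, np.floating)):
            out[k] = v.item()
        else:
            out[k] = v
    return out


def save_dose_grid(grid: DoseGrid, path: str | Path, json_sidecar: bool = False) -> None:
    """Write the documented HDF5 container (/dose, /rel_unc, /meta attrs)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("dose", data=grid.dose_per_photon)
        f.create_dataset("rel_unc", data=grid.rel_uncertainty)
        m = f.create_group("meta")
        m.attrs["schema_version"] = _SCHEMA_VERSION
        m.attrs["spacing_mm"] = grid.spacing_mm
        m.attrs["origin_mm"] = grid.origin_mm
        m.attrs["n_photons_run"] = grid.n_photons_run
        m.attrs["kind"] = grid.kind
        m.attrs["meta_json"] = json.dumps(_jsonable(grid.meta))
    if json_sidecar:
        side = {"spacing_mm": list(map(float, grid.spacing_mm)),
                "origin_mm": list(map(float, grid.origin_mm)),
                "n_photons_run": grid.n_photons_run, "kind": grid.kind,
                "meta": _jsonable(grid.meta)}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=1))


def load_dose_grid(path: str | Path) -> DoseGrid:
    with h5py.File(path, "r") as f:
        m = f["meta"]
        if int(m.attrs["schema_version"]) != _SCHEMA_VERSION:
            raise ValueError(f"unsupported dose-grid schema {m.attrs['schema_version']}")
        return DoseGrid(
            dose_per_photon=f["dose"][()], rel_uncertainty=f["rel_unc"][()],
            spacing_mm=np.asarray(m.attrs["spacing_mm"]),
            origin_mm=np.asarray(m.attrs["origin_mm"]),
            n_photons_run=int(m.attrs["n_photons_run"]),
            kind=str(m.attrs["kind"]), meta=json.loads(m.attrs["meta_json"]))


def export_skin_points(grid: DoseGrid, skin_mask: np.ndarray,
                       path: str | Path) -> int:
    """CSV point list (x_mm, y_mm, z_mm, dose_Gy) of the skin layer."""
    idx = np.argwhere(skin_mask)
    centers = grid.origin_mm + (idx + 0.5) * grid.spacing_mm
    dose = grid.dose_per_photon[skin_mask]
    arr = np.column_stack([centers, dose])
    header = "x_mm,y_mm,z_mm,dose_Gy"
    np.savetxt(path, arr, delimiter=",", header=header, comments="")
    return arr.shape[0]
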