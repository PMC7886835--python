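"""Precomputed angular air-kerma lookup table and eye-lens dose conversion.

Workflow: a table of room air-kerma grids is precomputed over the C-arm
angular range (lateral −90°…90°, cranio-caudal −30°…30°), persisted to
HDF5, and queried at run time by multilinear interpolation — bilinear over
the two gantry angles, trilinear over room position — then scaled by the
current tube current.  The eye-lens dose rate is the interpolated air-kerma
rate times the scalar ICRP conversion factor 1.550 Gy/Gy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .conditions import FluoroConditions
from .geometry import CArmPose, RoomModel
from .mc import MCConfig, TubeCalibration, dose_rate_scale, simulate_air_kerma
from .phantom import VoxelPhantom

__all__ = [
    "AirDoseTable",
    "EyeLensDose",
    "EYE_LENS_CONVERSION",
    "precompute_table",
    "query_air_kerma",
    "eyelens_dose_rate",
    "save_table",
    "load_table",
    "FingerprintError",
]

#: ICRP air-kerma -> eye-lens dose conversion factor, Gy/Gy
EYE_LENS_CONVERSION = 1.550

_SCHEMA_VERSION = 1


class FingerprintError(ValueError):
    """Query conditions do not match the beam the table was built for."""


class AngleRangeError(ValueError):
    """Angles outside the precomputed coverage; no extrapolation."""


@dataclass
class AirDoseTable:
    """Air kerma per source photon on (lateral, cranio-caudal, x, y, z)."""

    lateral_nodes: np.ndarray      # deg, ascending, spanning -90..90
    caudcran_nodes: np.ndarray     # deg, ascending, spanning -30..30
    lattice_origin_mm: np.ndarray
    lattice_spacing_mm: np.ndarray
    kerma_per_photon: np.ndarray   # (n_lat, n_cc, nx, ny, nz), Gy/photon
    fingerprint: tuple             # (kvp, filter_cu_mm, fov_cm, sid_cm)
    meta: dict = field(default_factory=dict)
    complete: bool = True
    _interp: RegularGridInterpolator | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for nodes, span in ((self.lateral_nodes, (-90.0, 90.0)),
                            (self.caudcran_nodes, (-30.0, 30.0))):
            if not np.all(np.diff(nodes) > 0):
                raise ValueError("angle nodes must be strictly ascending")
            if nodes[0] > span[0] or nodes[-1] < span[1]:
                raise ValueError(f"angle nodes must span {span}")
        if np.any(self.kerma_per_photon < 0):
            raise ValueError("kerma must be nonnegative")

    def lattice_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        shape = self.kerma_per_photon.shape[2:]
        return tuple(
            self.lattice_origin_mm[k] + (np.arange(shape[k]) + 0.5)
            * self.lattice_spacing_mm[k]
            for k in range(3))

    def interpolator(self) -> RegularGridInterpolator:
        if self._interp is None:
            ax = self.lattice_axes()
            self._interp = RegularGridInterpolator(
                (self.lateral_nodes, self.caudcran_nodes, *ax),
                self.kerma_per_photon, method="linear",
                bounds_error=True)
        return self._interp


@dataclass(frozen=True)
class EyeLensDose:
    """Air-kerma rate at the observer and the derived eye-lens dose rate."""

    air_kerma_rate: float           # Gy/s
    lens_dose_rate: float           # Gy/s
    conversion_factor: float = EYE_LENS_CONVERSION


def eyelens_dose_rate(air_kerma_rate: float) -> EyeLensDose:
    """Eye-lens dose rate = 1.550 × air-kerma rate (ICRP scalar factor)."""
    if air_kerma_rate < 0:
        raise ValueError("air-kerma rate must be nonnegative")
    return EyeLensDose(air_kerma_rate=float(air_kerma_rate),
                       lens_dose_rate=EYE_LENS_CONVERSION * float(air_kerma_rate))


def node_seed(base_seed: int, i_lat: int, i_cc: int) -> int:
    """Deterministic per-node seed derived from the table build seed."""
    return int(np.random.SeedSequence([base_seed, i_lat, i_cc])
               .generate_state(1)[0] & 0x7FFFFFFF)


def precompute_table(room: RoomModel, phantom: VoxelPhantom | None,
                     conditions: FluoroConditions,
                     lat_step_deg: float = 15.0, cc_step_deg: float = 15.0,
                     mc_config: MCConfig = MCConfig(n_photons=1_000_000),
                     grid_spacing_cm: float = 10.0,
                     sid_cm: float | None = None, siso_cm: float = 72.0,
                     checkpoint_path: str | Path | None = None,
                     progress: bool = False) -> AirDoseTable:
    """Build the angular air-kerma table by running the MC at every node.

    Node seeds derive deterministically from ``mc_config.seed`` and the node
    indices, so a rebuild with the same seed is bit-identical and any single
    node equals a standalone :func:`simulate_air_kerma` run with that node's
    derived seed.  With ``checkpoint_path`` the build is resumable: finished
    nodes are flushed to disk and skipped on restart.
    """
    for step, span in ((lat_step_deg, 180.0), (cc_step_deg, 60.0)):
        if step <= 0 or abs(round(span / step) * step - span) > 1e-9:
            raise ValueError(f"step {step}° must evenly divide {span}°")
    lat_nodes = np.arange(-90.0, 90.0 + lat_step_deg / 2, lat_step_deg)
    cc_nodes = np.arange(-30.0, 30.0 + cc_step_deg / 2, cc_step_deg)
    sid = conditions.sid_cm if sid_cm is None else sid_cm

    table = None
    if checkpoint_path is not None and Path(checkpoint_path).exists():
        table = load_table(checkpoint_path, allow_incomplete=True)
        if (not np.array_equal(table.lateral_nodes, lat_nodes)
                or not np.array_equal(table.caudcran_nodes, cc_nodes)
                or table.fingerprint != conditions.fingerprint()):
            raise ValueError("checkpoint does not match the requested build")
    done = (set(map(tuple, table.meta.get("done_nodes", [])))
            if table is not None else set())

    kerma = table.kerma_per_photon if table is not None else None
    origin = spacing = None
    for i, lat in enumerate(lat_nodes):
        for j, cc in enumerate(cc_nodes):
            if (i, j) in done:
                continue
            pose = CArmPose(lateral_deg=float(lat), caudcran_deg=float(cc),
                            sid_cm=sid, siso_cm=siso_cm)
            cfg = MCConfig(n_photons=mc_config.n_photons,
                           cutoff_keV=mc_config.cutoff_keV,
                           n_batches=mc_config.n_batches,
                           seed=node_seed(mc_config.seed, i, j),
                           rayleigh_enabled=mc_config.rayleigh_enabled)
            grid = simulate_air_kerma(room, phantom, pose, conditions,
                                      grid_spacing_cm=grid_spacing_cm,
                                      mc_config=cfg)
            if kerma is None:
                origin, spacing = grid.origin_mm, grid.spacing_mm
                kerma = np.zeros((lat_nodes.size, cc_nodes.size, *grid.shape))
                table = AirDoseTable(
                    lateral_nodes=lat_nodes, caudcran_nodes=cc_nodes,
                    lattice_origin_mm=origin, lattice_spacing_mm=spacing,
                    kerma_per_photon=kerma,
                    fingerprint=conditions.fingerprint(),
                    meta={"n_photons": mc_config.n_photons,
                          "seed": mc_config.seed, "done_nodes": []},
                    complete=False)
            kerma[i, j] = grid.dose_per_photon
            done.add((i, j))
            table.meta["done_nodes"] = sorted(done)
            if progress:
                print(f"node ({lat:+.0f}°, {cc:+.0f}°) done "
                      f"[{len(done)}/{lat_nodes.size * cc_nodes.size}]")
            if checkpoint_path is not None:
                save_table(table, checkpoint_path)
    table.complete = len(done) == lat_nodes.size * cc_nodes.size
    if table.complete:
        table.meta.pop("done_nodes", None)
    if checkpoint_path is not None:
        save_table(table, checkpoint_path)
    return table


def query_air_kerma(table: AirDoseTable, lateral_deg: float, caudcran_deg: float,
                    position_xyz_mm, conditions: FluoroConditions,
                    calibration: TubeCalibration = TubeCalibration()) -> float:
    """Air-kerma rate (Gy/s) at a room position under current conditions.

    Multilinear interpolation of the stored per-photon kerma, scaled by tube
    current (and pulse duty).  Returns 0 when the beam is off.  Raises
    :class:`AngleRangeError` outside the angular coverage and
    :class:`FingerprintError` when (kvp, filter, fov, sid) differ from the
    table build.
    """
    if conditions.fingerprint() != tuple(table.fingerprint):
        raise FingerprintError(
            f"table built for {table.fingerprint}, queried with "
            f"{conditions.fingerprint()}")
    if not (table.lateral_nodes[0] <= lateral_deg <= table.lateral_nodes[-1]):
        raise AngleRangeError(f"lateral angle {lateral_deg}° outside table range")
    if not (table.caudcran_nodes[0] <= caudcran_deg <= table.caudcran_nodes[-1]):
        raise AngleRangeError(f"cranio-caudal angle {caudcran_deg}° outside table range")
    if not conditions.beam_on:
        return 0.0
    p = np.asarray(position_xyz_mm, dtype=float)
    kerma = float(table.interpolator()((lateral_deg, caudcran_deg, *p)))
    return float(dose_rate_scale(kerma, conditions, calibration))


def save_table(table: AirDoseTable, path: str | Path) -> None:
    """Persist to the documented HDF5 schema (/kerma 5-D, node arrays, /meta)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("kerma", data=table.kerma_per_photon)
        f.create_dataset("lat_nodes", data=table.lateral_nodes)
        f.create_dataset("cc_nodes", data=table.caudcran_nodes)
        m = f.create_group("meta")
        m.attrs["schema_version"] = _SCHEMA_VERSION
        m.attrs["lattice_origin_mm"] = table.lattice_origin_mm
        m.attrs["lattice_spacing_mm"] = table.lattice_spacing_mm
        m.attrs["fingerprint"] = json.dumps(list(table.fingerprint))
        m.attrs["complete"] = bool(table.complete)
        m.attrs["meta_json"] = json.dumps(
            {k: v for k, v in table.meta.items()})


def load_table(path: str | Path, allow_incomplete: bool = False) -> AirDoseTable:
    """Load a table written by :func:`save_table`; schema-checked."""
    try:
        with h5py.File(path, "r") as f:
            if "kerma" not in f or "meta" not in f:
                raise ValueError(f"{path} is not an air-dose table file")
            m = f["meta"]
            if int(m.attrs["schema_version"]) != _SCHEMA_VERSION:
                raise ValueError(
                    f"unsupported table schema {m.attrs['schema_version']}")
            complete = bool(m.attrs["complete"])
            if not complete and not allow_incomplete:
                raise ValueError(f"{path} is an incomplete (checkpoint) table")
            meta = json.loads(m.attrs["meta_json"])
            meta["done_nodes"] = [tuple(n) for n in meta.get("done_nodes", [])]
            if not meta["done_nodes"]:
                meta.pop("done_nodes")
            return AirDoseTable(
                lateral_nodes=f["lat_nodes"][()],
                caudcran_nodes=f["cc_nodes"][()],
                lattice_origin_mm=np.asarray(m.attrs["lattice_origin_mm"]),
                lattice_spacing_mm=np.asarray(m.attrs["lattice_spacing_mm"]),
                kerma_per_photon=f["kerma"][()],
                fingerprint=tuple(json.loads(m.attrs["fingerprint"])),
                meta=meta, complete=complete)
    except OSError as exc:
        raise ValueError(f"cannot read air-dose table {path}: {exc}") from exc
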