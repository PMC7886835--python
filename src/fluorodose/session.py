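"""Session orchestration: streams in, hologram-ready dose payloads out.

Consumes a fluoroscopic-condition stream and an observer head-position
stream (both timestamp-ordered), accumulates patient skin dose by running
(or cache-hitting) the skin-dose Monte Carlo per distinct beam fingerprint,
queries the precomputed air-dose table for the observer's eye-lens dose
rate, and emits one serializable payload per condition tick.  During
beam-off intervals no dose accumulates, but payloads still carry the
eye-lens rate the latest conditions *would* produce, flagged ``predicted``,
so the observer sees the exposure risk before the beam turns on.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import matplotlib
import numpy as np

from .airdose import AirDoseTable, eyelens_dose_rate, query_air_kerma
from .conditions import FluoroConditions
from .geometry import CArmPose, RoomModel, beam_frustum
from .mc import DoseGrid, MCConfig, TubeCalibration, simulate_skin_dose
from .phantom import VoxelPhantom

__all__ = [
    "ObserverState",
    "HologramPayload",
    "SessionConfig",
    "SessionState",
    "StreamError",
    "run_session",
    "accumulate_dose",
    "make_payload",
    "render_offline",
]


class StreamError(RuntimeError):
    """Out-of-order timestamps or incompatible inputs in a session stream."""


@dataclass(frozen=True)
class ObserverState:
    """Tracked head position of the observing health professional."""

    timestamp_s: float
    head_position_xyz_mm: tuple[float, float, float]
    valid: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "ObserverState":
        return cls(timestamp_s=float(d["timestamp_s"]),
                   head_position_xyz_mm=tuple(d["head_position_xyz_mm"]),
                   valid=bool(d.get("valid", True)))


@dataclass
class HologramPayload:
    """One visualization record: skin-dose surface, beam frustum, lens dose."""

    timestamp_s: float
    skin_points: np.ndarray        # (n, 4): x, y, z [mm], cumulative dose [Gy]
    skin_colors: np.ndarray        # (n, 3) RGB in [0, 1]
    colorbar: tuple[float, float, str]   # (min, max, "linear" | "log")
    frustum_corners: np.ndarray    # (4, 3) detector-plane corners, mm
    frustum_source: np.ndarray     # (3,)
    eyelens_air_kerma_rate: float | None   # Gy/s
    eyelens_dose_rate: float | None        # Gy/s
    eyelens_predicted: bool = False
    conditions_stale: bool = False

    def to_json_dict(self) -> dict:
        return {
            "timestamp_s": self.timestamp_s,
            "skin_points": self.skin_points.tolist(),
            "skin_colors": np.round(self.skin_colors, 6).tolist(),
            "colorbar": list(self.colorbar),
            "frustum_corners": self.frustum_corners.tolist(),
            "frustum_source": self.frustum_source.tolist(),
            "eyelens_air_kerma_rate": self.eyelens_air_kerma_rate,
            "eyelens_dose_rate": self.eyelens_dose_rate,
            "eyelens_predicted": self.eyelens_predicted,
            "conditions_stale": self.conditions_stale,
        }


@dataclass
class SessionConfig:
    """Everything a session needs besides the two input streams."""

    phantom: VoxelPhantom
    airdose_table: AirDoseTable | None = None
    room: RoomModel = field(default_factory=RoomModel)
    calibration: TubeCalibration = field(default_factory=TubeCalibration)
    skin_mc: MCConfig = field(default_factory=lambda: MCConfig(n_photons=100_000))
    siso_cm: float = 72.0
    period_s: float = 0.2          # duration assumed for the final record
    colormap: str = "inferno"
    color_scale: str = "linear"    # "linear" | "log"
    latest_only: bool = False      # show only the most recent run, no accumulation
    seed: int = 0


@dataclass
class SessionState:
    """Mutable per-session state: cumulative grid, caches, last records."""

    config: SessionConfig
    cumulative_gy: np.ndarray = None
    last_conditions: FluoroConditions | None = None
    last_observer: ObserverState | None = None
    mc_cache: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cumulative_gy is None:
            self.cumulative_gy = np.zeros(self.config.phantom.shape)


def _pose_fingerprint(cond: FluoroConditions) -> tuple:
    return (cond.fingerprint(), round(cond.lateral_deg, 2),
            round(cond.caudcran_deg, 2),
            tuple(round(v, 1) for v in cond.table_offset_mm))


def _cached_skin_run(state: SessionState, cond: FluoroConditions) -> DoseGrid:
    key = _pose_fingerprint(cond)
    if key not in state.mc_cache:
        cfg = state.config
        pose = CArmPose(lateral_deg=cond.lateral_deg, caudcran_deg=cond.caudcran_deg,
                        sid_cm=cond.sid_cm, siso_cm=cfg.siso_cm,
                        table_offset_mm=cond.table_offset_mm)
        # stable per-fingerprint seed so replays are bit-identical
        sub = zlib.crc32(repr(key).encode()) & 0x7FFFFFFF
        mc = MCConfig(n_photons=cfg.skin_mc.n_photons,
                      cutoff_keV=cfg.skin_mc.cutoff_keV,
                      n_batches=cfg.skin_mc.n_batches,
                      seed=int(np.random.SeedSequence([cfg.seed, sub])
                               .generate_state(1)[0] & 0x7FFFFFFF),
                      rayleigh_enabled=cfg.skin_mc.rayleigh_enabled)
        state.mc_cache[key] = simulate_skin_dose(cfg.phantom, pose, cond, mc)
    return state.mc_cache[key]


def accumulate_dose(cumulative_gy: np.ndarray, increment: DoseGrid,
                    duration_s: float, conditions: FluoroConditions,
                    calibration: TubeCalibration = TubeCalibration()) -> np.ndarray:
    """Add ``increment`` (Gy/photon) × output × mA × duty × duration in place."""
    if cumulative_gy.shape != increment.dose_per_photon.shape:
        raise ValueError("cumulative grid and increment on different lattices")
    if duration_s < 0:
        raise ValueError("duration must be nonnegative")
    scale = (calibration.photons_per_mAs * conditions.ma
             * calibration.duty(conditions.fps) * duration_s)
    cumulative_gy += increment.dose_per_photon * scale
    return cumulative_gy


def make_payload(state: SessionState, timestamp_s: float,
                 stale: bool = False) -> HologramPayload:
    """Snapshot the session into one hologram payload."""
    cfg = state.config
    cond = state.last_conditions
    ph = cfg.phantom
    mask = ph.skin_mask
    idx = np.argwhere(mask)
    centers = ph.bounds()[0] + (idx + 0.5) * ph.spacing
    dose = state.cumulative_gy[mask]
    vmax = float(dose.max()) if dose.size else 0.0
    cmap = matplotlib.colormaps[cfg.colormap]
    if cfg.color_scale == "log" and vmax > 0:
        pos = dose[dose > 0]
        vmin = float(pos.min()) if pos.size else vmax
        with np.errstate(divide="ignore"):
            norm = np.where(dose > 0,
                            (np.log10(np.maximum(dose, vmin)) - np.log10(vmin))
                            / max(np.log10(vmax) - np.log10(vmin), 1e-12), 0.0)
        bar = (vmin, vmax, "log")
    else:
        norm = dose / vmax if vmax > 0 else np.zeros_like(dose)
        bar = (0.0, vmax, "linear")
    colors = cmap(np.clip(norm, 0.0, 1.0))[:, :3]

    pose = CArmPose(lateral_deg=cond.lateral_deg, caudcran_deg=cond.caudcran_deg,
                    sid_cm=cond.sid_cm, siso_cm=cfg.siso_cm,
                    table_offset_mm=cond.table_offset_mm)
    fr = beam_frustum(pose, cond.fov_cm)

    kerma_rate = lens_rate = None
    predicted = False
    obs = state.last_observer
    if obs is not None and obs.valid and cfg.airdose_table is not None:
        # during beam-off the rate the latest conditions would produce
        query_cond = cond if cond.beam_on else cond.but(beam_on=True)
        predicted = not cond.beam_on
        kerma_rate = query_air_kerma(cfg.airdose_table, cond.lateral_deg,
                                     cond.caudcran_deg, obs.head_position_xyz_mm,
                                     query_cond, cfg.calibration)
        lens_rate = eyelens_dose_rate(kerma_rate).lens_dose_rate
    return HologramPayload(
        timestamp_s=timestamp_s,
        skin_points=np.column_stack([centers, dose]),
        skin_colors=colors, colorbar=bar,
        frustum_corners=fr.corners, frustum_source=fr.source_xyz,
        eyelens_air_kerma_rate=kerma_rate, eyelens_dose_rate=lens_rate,
        eyelens_predicted=predicted, conditions_stale=stale)


def _as_conditions(rec) -> tuple[FluoroConditions, bool]:
    if isinstance(rec, FluoroConditions):
        return rec, False
    stale = bool(rec.get("stale", False))
    return FluoroConditions.from_dict(rec), stale


def run_session(config: SessionConfig,
                condition_stream: Iterable,
                observer_stream: Iterable = (),
                ) -> tuple[list[HologramPayload], DoseGrid]:
    """Run a full session; returns (payloads, final cumulative dose grid).

    Each condition record covers the interval to the next record (the last
    one covers ``config.period_s``).  Records with the beam on trigger a
    skin-dose Monte Carlo for their (conditions, pose) fingerprint — cached,
    so repeats are exact — scaled into Gy by tube output × mA × duration and
    added to the cumulative grid.  Gap markers emit no payload.
    """
    if config.airdose_table is not None and config.airdose_table.fingerprint:
        pass  # fingerprint is validated per query
    state = SessionState(config=config)
    observers = [o if isinstance(o, ObserverState) else ObserverState.from_dict(o)
                 for o in observer_stream]
    if any(observers[i].timestamp_s > observers[i + 1].timestamp_s
           for i in range(len(observers) - 1)):
        raise StreamError("observer stream not timestamp-ordered")
    records = []
    for rec in condition_stream:
        if isinstance(rec, dict) and rec.get("gap"):
            continue
        records.append(_as_conditions(rec))
    times = [c.timestamp_s for c, _ in records]
    if any(times[i] > times[i + 1] for i in range(len(times) - 1)):
        raise StreamError("condition stream not timestamp-ordered")

    payloads: list[HologramPayload] = []
    obs_i = 0
    for k, (cond, stale) in enumerate(records):
        t = cond.timestamp_s
        duration = (times[k + 1] - t) if k + 1 < len(records) else config.period_s
        while obs_i < len(observers) and observers[obs_i].timestamp_s <= t:
            state.last_observer = observers[obs_i]
            obs_i += 1
        state.last_conditions = cond
        if cond.beam_on:
            grid = _cached_skin_run(state, cond)
            if config.latest_only:
                state.cumulative_gy[:] = 0.0
            accumulate_dose(state.cumulative_gy, grid, duration, cond,
                            config.calibration)
        payloads.append(make_payload(state, t, stale))

    final = DoseGrid(
        dose_per_photon=state.cumulative_gy.copy(),
        rel_uncertainty=np.zeros_like(state.cumulative_gy),
        spacing_mm=config.phantom.spacing.copy(),
        origin_mm=config.phantom.bounds()[0].copy(),
        n_photons_run=sum(g.n_photons_run for g in state.mc_cache.values()),
        kind="skin",
        meta={"cumulative_Gy": True, "seed": config.seed})
    return payloads, final


def write_payloads_jsonl(payloads: Iterable[HologramPayload],
                         path: str | Path) -> None:
    with open(path, "w") as f:
        for p in payloads:
            f.write(json.dumps(p.to_json_dict()) + "\n")


def render_offline(phantom: VoxelPhantom, cumulative_grid: DoseGrid,
                   pose: CArmPose, out_path: str | Path,
                   fov_cm: float = 20.0, colormap: str = "inferno") -> Path:
    """Documentation rendering: skin surface colored by dose + beam wireframe."""
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mask = phantom.skin_mask
    if not mask.any() or cumulative_grid.dose_per_photon.size == 0:
        raise ValueError("nothing to render: empty skin mask or dose grid")
    idx = np.argwhere(mask)
    centers = phantom.bounds()[0] + (idx + 0.5) * phantom.spacing
    dose = cumulative_grid.dose_per_photon[mask]
    fr = beam_frustum(pose, fov_cm)

    fig = plt.figure(figsize=(7, 6), dpi=110)
    ax = fig.add_subplot(111, projection="3d")
    sc = ax.scatter(centers[:, 0], centers[:, 2], centers[:, 1], c=dose,
                    cmap=colormap, s=3, linewidths=0)
    for c in fr.corners:
        ax.plot([fr.source_xyz[0], c[0]], [fr.source_xyz[2], c[2]],
                [fr.source_xyz[1], c[1]], color="tab:cyan", lw=0.8)
    loop = np.vstack([fr.corners, fr.corners[:1]])
    ax.plot(loop[:, 0], loop[:, 2], loop[:, 1], color="tab:cyan", lw=0.8)
    ax.set_xlabel("x [mm]")
    ax.set_ylabel("z [mm]")
    ax.set_zlabel("y [mm]")
    fig.colorbar(sc, ax=ax, shrink=0.6, label="skin dose [Gy]")
    out_path = Path(out_path)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path
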