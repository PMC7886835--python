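"""Fluoroscopic-condition snapshots: one record of the x-ray system state."""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace


@dataclass(frozen=True)
class FluoroConditions:
    """One snapshot of the fluoroscopy system state.

    Defaults reproduce the study beam: 76 kV, 2.5 mA, 20×20 cm field of
    view, SID 100 cm, 15 frames/s, 0.3 mm Cu added filtration, PA gantry.
    """

    kvp: float = 76.0
    ma: float = 2.5
    fov_cm: float = 20.0
    sid_cm: float = 100.0
    lateral_deg: float = 0.0
    caudcran_deg: float = 0.0
    fps: float = 15.0
    filter_cu_mm: float = 0.3
    beam_on: bool = True
    irradiation_time_s: float = 0.0
    table_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        if not 40.0 <= self.kvp <= 150.0:
            raise ValueError(f"kvp {self.kvp} outside 40-150 kV")
        if self.beam_on and self.ma <= 0:
            raise ValueError("mA must be positive while the beam is on")
        if not 1 <= self.fps <= 30:
            raise ValueError("frame rate outside 1-30 fps")

    def fingerprint(self) -> tuple:
        """Beam-quality fingerprint a precomputed air-dose table is bound to."""
        return (round(self.kvp, 3), round(self.filter_cu_mm, 4),
                round(self.fov_cm, 2), round(self.sid_cm, 2))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["table_offset_mm"] = list(self.table_offset_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FluoroConditions":
        d = dict(d)
        d["table_offset_mm"] = tuple(d.get("table_offset_mm", (0.0, 0.0, 0.0)))
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})

    def but(self, **kw) -> "FluoroConditions":
        return replace(self, **kw)
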