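"""Virtual transcatheter edge-to-edge repair (TEER).

A device grasps both leaflets over an interval of the coaptation line and
closes the coaptation gap there — and only there: defects are clipped to
the portion outside the grasped interval, splitting into residual
sub-defects (the classic double orifice for a central grasp on a wide
defect), with no other change to valve morphology and no annular
remodeling.  The grasped interval is occupied by device/leaflet tissue in
both phases, so it also blocks the same stretch of the diastolic opening —
the mechanism behind iatrogenic mitral stenosis after clipping.

Device grasping widths are configuration defaults (the clinically used
device families differ mainly in grasping width); they are assumptions,
not manufacturer dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from ._implicit import _subtract_intervals
from .synthetic_anatomy import (
    AnatomyValidationError,
    CoaptationDefect,
    DeviceRecord,
    ValveAnatomy,
)

__all__ = ["DeviceSpec", "DEVICE_GRASPING_WIDTHS", "implant_device", "residual_orifice_inventory"]

#: Assumed grasping widths (mm) per device family.
DEVICE_GRASPING_WIDTHS = {
    "Pascal": 6.0,
    "PascalAce": 4.0,
    "XTw": 6.0,
    "XTr": 6.0,
    "XT": 6.0,
    "NT": 4.0,
    "NTr": 4.0,
}


@dataclass(frozen=True)
class DeviceSpec:
    """An edge-to-edge device at a position along the coaptation line."""

    label: str
    position_s: float
    grasping_width: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label not in DEVICE_GRASPING_WIDTHS:
            raise ValueError(
                f"unknown device label {self.label!r}; "
                f"known: {sorted(DEVICE_GRASPING_WIDTHS)}"
            )
        if self.grasping_width is not None and self.grasping_width <= 0:
            raise ValueError("grasping_width must be positive")

    @property
    def width(self) -> float:
        return (
            self.grasping_width
            if self.grasping_width is not None
            else DEVICE_GRASPING_WIDTHS[self.label]
        )

    @property
    def interval(self) -> tuple[float, float]:
        return (self.position_s - 0.5 * self.width, self.position_s + 0.5 * self.width)


def implant_device(anatomy: ValveAnatomy, device: DeviceSpec) -> ValveAnatomy:
    """Return a new anatomy with the device's grasped interval sealed.

    Every defect's gap is closed over ``[position_s − width/2,
    position_s + width/2]``; defects are split into residual sub-defects
    outside that interval.  All other anatomy parameters are unchanged.
    Implanting an identical device again is a no-op (idempotent).
    """
    L = anatomy.coaptation_line_length
    if not (0.0 <= device.position_s <= L):
        raise AnatomyValidationError(
            f"device position {device.position_s:.1f} mm lies outside the "
            f"coaptation line [0, {L:.1f}] mm"
        )
    g0, g1 = device.interval
    g0, g1 = max(0.0, g0), min(L, g1)

    new_defects: list[CoaptationDefect] = []
    for d in anatomy.defects:
        for s0, s1 in _subtract_intervals([(d.s_min, d.s_max)], [(g0, g1)]):
            if s1 - s0 > 1e-9:
                new_defects.append(
                    CoaptationDefect(
                        center_s=0.5 * (s0 + s1),
                        width=s1 - s0,
                        gap_height=d.gap_height,
                    )
                )

    record = DeviceRecord(
        label=device.label, position_s=device.position_s, grasping_width=device.width
    )
    devices = anatomy.devices if record in anatomy.devices else anatomy.devices + (record,)
    grasped = _merge_intervals(list(anatomy.grasped_intervals) + [(g0, g1)])
    return replace(
        anatomy,
        defects=tuple(new_defects),
        devices=devices,
        grasped_intervals=tuple(grasped),
    )


def residual_orifice_inventory(
    anatomy: ValveAnatomy,
) -> list[tuple[float, float, float, float]]:
    """Residual regurgitant slits as (position, width, gap, area) tuples.

    One entry per open slit; the areas sum to the total anatomic
    regurgitant orifice area.  A sealed valve yields an empty list.
    """
    return [
        (d.center_s, d.width, d.gap_height, d.area) for d in anatomy.open_defects
    ]


def _merge_intervals(intervals):
    ivs = sorted((lo, hi) for lo, hi in intervals if hi > lo)
    merged: list[tuple[float, float]] = []
    for lo, hi in ivs:
        if merged and lo <= merged[-1][1] + 1e-12:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged
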