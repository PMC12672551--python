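"""CFD endpoints: regurgitant flow/volume, EROA, peak velocity, gradient.

The regurgitant flow is the velocity flux through the left-atrial outlet
of a converged systolic solve; the per-beat regurgitant volume scales that
steady rate by the systolic duration.  The effective regurgitant orifice
area follows the continuity definition used clinically, EROA = Q/V_max
(ml/s divided by m/s gives mm² exactly).  The diastolic transvalvular
gradient is the difference of area-averaged static pressures on planes a
fixed offset from the leaflet tips on either side, in mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .domain_builder import ComputationalDomain
from .flow_solver import FlowField, patch_flux
from .units import MMHG_TO_PA

__all__ = [
    "HemodynamicReport",
    "regurgitant_flow",
    "regurgitant_volume",
    "eroa_cfd",
    "peak_velocity",
    "mean_diastolic_gradient",
]

#: Default offset (mm) of the pressure-averaging planes from the leaflet
#: tips when computing the diastolic gradient.
GRADIENT_PLANE_OFFSET = 5.0


class PhaseError(ValueError):
    """Raised when an endpoint is computed on the wrong cardiac phase."""


@dataclass(frozen=True)
class HemodynamicReport:
    """Endpoints of one simulated case (single phase pair)."""

    Q_reg: float  # ml/s, systolic regurgitant flow through the LA outlet
    RV: float  # ml/beat
    EROA: float  # mm²
    V_max: float  # m/s
    MPG_dia: float  # mmHg
    converged_sys: bool = True
    converged_dia: bool = True
    reynolds_sys: float = float("nan")
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("Q_reg", "RV", "EROA", "V_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_dict(self) -> dict:
        return {
            "Q_reg_ml_s": self.Q_reg,
            "RV_ml": self.RV,
            "EROA_mm2": self.EROA,
            "V_max_m_s": self.V_max,
            "MPG_dia_mmHg": self.MPG_dia,
            "converged_sys": self.converged_sys,
            "converged_dia": self.converged_dia,
            "reynolds_sys": self.reynolds_sys,
        }


def regurgitant_flow(field: FlowField, domain: ComputationalDomain) -> float:
    """Regurgitant flow (ml/s): outward flux through the OUTLET_LA patch."""
    if field.phase != "systole":
        raise PhaseError("regurgitant flow is defined on the systolic field")
    if "OUTLET_LA" not in domain.patches:
        raise ValueError("domain has no OUTLET_LA patch")
    return max(patch_flux(field, domain, "OUTLET_LA"), 0.0)


def regurgitant_volume(Q_reg: float, t_sys: float) -> float:
    """Per-beat regurgitant volume (ml) from the steady systolic rate."""
    if Q_reg < 0:
        raise ValueError("Q_reg must be >= 0")
    if t_sys <= 0:
        raise ValueError("t_sys must be positive")
    return Q_reg * t_sys


def eroa_cfd(Q_reg: float, V_max: float) -> float:
    """Continuity EROA (mm²): regurgitant flow over peak jet velocity."""
    if Q_reg < 0:
        raise ValueError("Q_reg must be >= 0")
    if Q_reg == 0:
        return 0.0
    if V_max <= 0:
        raise ValueError("V_max must be positive when Q_reg > 0")
    return Q_reg / V_max  # (ml/s) / (m/s) == mm²


def _region_mask(domain: ComputationalDomain, region: str) -> np.ndarray:
    F = domain.fluid_mask
    if region == "all":
        return F
    z_or = domain.meta.get("z_orifice")
    if z_or is None:
        raise ValueError(f"region {region!r} needs orifice metadata on the domain")
    zs = domain.cell_centers_1d(2)
    xs = domain.cell_centers_1d(0)
    xlo, xhi = domain.meta.get("valve_x_limits", (xs[0], xs[-1]))
    in_x = ((xs >= xlo - 5.0) & (xs <= xhi + 5.0))[:, None, None]
    if region == "valve":
        in_z = (np.abs(zs - z_or) <= 3.0)[None, None, :]
    elif region == "jet":
        # downstream side of the orifice: atrial for systole, ventricular
        # for diastole, within a 20 mm reach
        lo, hi = (z_or, z_or + 20.0) if domain.phase == "systole" else (z_or - 20.0, z_or)
        in_z = ((zs >= lo) & (zs <= hi))[None, None, :]
    else:
        raise ValueError(f"unknown region {region!r}")
    return F & in_x & in_z


def peak_velocity(field: FlowField, domain: ComputationalDomain, region: str = "jet") -> float:
    """Maximum velocity magnitude (m/s) over fluid cells in a region."""
    mask = _region_mask(domain, region)
    if not mask.any():
        raise ValueError(f"region {region!r} contains no fluid cells")
    return float(field.speed()[mask].max())


def mean_diastolic_gradient(
    field: FlowField,
    domain: ComputationalDomain,
    plane_offset: float = GRADIENT_PLANE_OFFSET,
    plane_z: Optional[tuple[float, float]] = None,
) -> float:
    """Transvalvular diastolic pressure gradient, mmHg.

    Area-averaged pressure on an atrial-side plane minus a ventricular-side
    plane, each ``plane_offset`` mm from the leaflet tips (overridable via
    explicit ``plane_z = (z_atrial, z_ventricular)``).  Positive for
    forward (atrium → ventricle) flow.
    """
    if field.phase != "diastole":
        raise PhaseError("the diastolic gradient is defined on the diastolic field")
    if plane_z is not None:
        z_a, z_v = plane_z
    else:
        z_top = domain.meta.get("z_coapt", 0.0)
        z_bot = domain.meta.get("z_chan", 0.0)
        z_a, z_v = z_top + plane_offset, z_bot - plane_offset
    zs = domain.cell_centers_1d(2)
    if not (zs[0] <= z_v < z_a <= zs[-1]):
        raise ValueError("gradient planes fall outside the domain")

    def plane_pressure(z_plane: float) -> float:
        k = int(np.argmin(np.abs(zs - z_plane)))
        sel = domain.fluid_mask[:, :, k]
        xs = domain.cell_centers_1d(0)
        xlo, xhi = domain.meta.get("valve_x_limits", (xs[0], xs[-1]))
        sel_x = sel & ((xs >= xlo) & (xs <= xhi))[:, None]
        if sel_x.any():
            sel = sel_x
        if not sel.any():
            raise ValueError(f"no fluid cells on plane z={z_plane:.1f} mm")
        return float(np.nanmean(field.pressure[:, :, k][sel]))

    dp = plane_pressure(z_a) - plane_pressure(z_v)
    return dp / MMHG_TO_PA
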