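"""Parametric mitral apparatus geometries and synthetic cohorts.

This module is the stand-in for patient-specific CT segmentation: it
describes the mitral annulus, leaflet funnel, coaptation defects, LVOT and
chamber extents with a handful of parameters, generates watertight flow-
cavity surfaces for either cardiac phase, and samples whole synthetic
cohorts whose annulus statistics match the measured population values
(systolic annulus area 1595 ± 379 mm², perimeter 141 ± 16 mm).

Geometry model
--------------
* The annulus is a planar ellipse; its semi-axes are solved from the
  (area, perimeter) pair via Ramanujan's perimeter approximation.  The two
  printed quantities determine the two axes.
* The leaflets form a straight-walled funnel from the annulus ellipse down
  to the coaptation line.  In systole the funnel is sealed except for
  rectangular slit orifices (one per :class:`CoaptationDefect`, width ×
  gap_height); in diastole it opens into a single orifice whose area
  defaults to ``diastolic_open_fraction`` × diastolic annulus area.
* The LVOT is a straight circular tube leaving the ventricular chamber
  beside the annulus; it is only open in systole.

Axis convention: the valve axis is +z toward the atrium, the annulus plane
is z = 0, and the coaptation line runs along x.  All lengths in mm.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import trimesh
import yaml
from scipy.optimize import brentq
from scipy.stats import truncnorm

__all__ = [
    "CoaptationDefect",
    "DeviceRecord",
    "ValveAnatomy",
    "PopulationModel",
    "make_valve_anatomy",
    "sample_population",
    "anatomy_to_surface",
    "ellipse_axes_from_area_perimeter",
    "ramanujan_perimeter",
    "anatomy_to_dict",
    "anatomy_from_dict",
    "save_anatomy_yaml",
    "load_anatomy_yaml",
]

#: Relative tolerance for annulus area/perimeter mutual consistency.
PERIMETER_CONSISTENCY_TOL = 0.05


class AnatomyValidationError(ValueError):
    """Raised when a ValveAnatomy parameter violates its constraints."""


def ramanujan_perimeter(a: float, b: float) -> float:
    """Ellipse perimeter, Ramanujan's second approximation (semi-axes mm)."""
    h = ((a - b) / (a + b)) ** 2 if (a + b) > 0 else 0.0
    return float(np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h))))


def ellipse_axes_from_area_perimeter(area: float, perimeter: float) -> tuple[float, float]:
    """Solve ellipse semi-axes (a >= b) from area and perimeter.

    The circle of equal area has the smallest possible perimeter; a
    requested perimeter slightly below that bound (within the 5%
    consistency tolerance) is clamped to the circle.  Larger mismatches
    raise :class:`AnatomyValidationError`.
    """
    if area <= 0:
        raise AnatomyValidationError("annulus area must be positive")
    if perimeter <= 0:
        raise AnatomyValidationError("annulus perimeter must be positive")
    r_circle = np.sqrt(area / np.pi)
    p_circle = 2.0 * np.pi * r_circle

    if perimeter <= p_circle:
        if (p_circle - perimeter) / perimeter > PERIMETER_CONSISTENCY_TOL:
            raise AnatomyValidationError(
                f"annulus perimeter {perimeter:.1f} mm is below the circle "
                f"minimum {p_circle:.1f} mm for area {area:.0f} mm² by more "
                f"than {PERIMETER_CONSISTENCY_TOL:.0%}"
            )
        return r_circle, r_circle

    # b = k*a with fixed area; perimeter decreases monotonically in k on (0, 1].
    def perim_of_ratio(k: float) -> float:
        a = np.sqrt(area / (np.pi * k))
        return ramanujan_perimeter(a, k * a)

    k_lo = 0.05
    if perim_of_ratio(k_lo) < perimeter:
        raise AnatomyValidationError(
            f"annulus perimeter {perimeter:.1f} mm is too large for area "
            f"{area:.0f} mm² (axis ratio would fall below {k_lo})"
        )
    k = brentq(lambda kk: perim_of_ratio(kk) - perimeter, k_lo, 1.0, xtol=1e-12)
    a = float(np.sqrt(area / (np.pi * k)))
    return a, k * a


@dataclass(frozen=True)
class CoaptationDefect:
    """A rectangular slit in the systolic coaptation.

    ``center_s`` is the slit centre along the coaptation line (mm from its
    anterolateral end), ``width`` its extent along the line and
    ``gap_height`` the leaflet separation across it.  ``gap_height == 0``
    denotes a sealed segment.
    """

    center_s: float
    width: float
    gap_height: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise AnatomyValidationError("defect width must be positive")
        if self.gap_height < 0:
            raise AnatomyValidationError("defect gap_height must be non-negative")

    @property
    def s_min(self) -> float:
        return self.center_s - 0.5 * self.width

    @property
    def s_max(self) -> float:
        return self.center_s + 0.5 * self.width

    @property
    def area(self) -> float:
        """Anatomic slit area, mm²."""
        return self.width * self.gap_height


@dataclass(frozen=True)
class DeviceRecord:
    """An implanted edge-to-edge device (label + grasped interval)."""

    label: str
    position_s: float
    grasping_width: float


_POSITIVE_FIELDS = (
    "annulus_area_sys",
    "annulus_area_dia",
    "annulus_perimeter_sys",
    "annulus_perimeter_dia",
    "leaflet_length",
    "coaptation_line_length",
    "lvot_diameter",
    "t_sys",
    "t_dia",
)


@dataclass(frozen=True)
class ValveAnatomy:
    """Parametric description of one mitral apparatus and flow cavity.

    Lengths in mm, areas mm², volumes ml, durations s.  ``chamber_extents``
    holds the (atrial, ventricular) chamber depths the flow domain is
    truncated at.  ``grasped_intervals`` records coaptation-line intervals
    occupied by device tissue (solid in both phases).
    """

    annulus_area_sys: float = 1595.0
    annulus_area_dia: float = 1630.0
    annulus_perimeter_sys: float = 141.0
    annulus_perimeter_dia: float = 144.0
    leaflet_length: float = 10.0
    coaptation_line_length: float = 38.0
    defects: tuple[CoaptationDefect, ...] = ()
    lvot_diameter: float = 20.0
    stroke_volume: float = 70.0
    t_sys: float = 0.35
    t_dia: float = 0.65
    chamber_extents: tuple[float, float] = (25.0, 25.0)
    diastolic_open_fraction: float = 0.65
    grasped_intervals: tuple[tuple[float, float], ...] = ()
    devices: tuple[DeviceRecord, ...] = ()

    def __post_init__(self) -> None:
        for name in _POSITIVE_FIELDS:
            if getattr(self, name) <= 0:
                raise AnatomyValidationError(f"{name} must be positive")
        if self.stroke_volume < 0:
            raise AnatomyValidationError("stroke_volume must be non-negative")
        if min(self.chamber_extents) <= 0:
            raise AnatomyValidationError("chamber_extents must be positive")
        if not 0 < self.diastolic_open_fraction <= 1:
            raise AnatomyValidationError("diastolic_open_fraction must lie in (0, 1]")
        object.__setattr__(self, "defects", tuple(self.defects))
        object.__setattr__(
            self, "grasped_intervals", tuple(tuple(g) for g in self.grasped_intervals)
        )
        object.__setattr__(self, "devices", tuple(self.devices))
        L = self.coaptation_line_length
        for d in self.defects:
            if d.s_min < -1e-9 or d.s_max > L + 1e-9:
                raise AnatomyValidationError(
                    f"defect [{d.s_min:.1f}, {d.s_max:.1f}] mm lies outside the "
                    f"coaptation line [0, {L:.1f}] mm"
                )
        # Area/perimeter mutual consistency for both phases (raises if the
        # pair cannot be realised by any ellipse within tolerance).
        ellipse_axes_from_area_perimeter(self.annulus_area_sys, self.annulus_perimeter_sys)
        ellipse_axes_from_area_perimeter(self.annulus_area_dia, self.annulus_perimeter_dia)

    # -- derived quantities -------------------------------------------------

    def annulus_axes(self, phase: str) -> tuple[float, float]:
        """Annulus ellipse semi-axes (a, b) for the given phase, mm."""
        _check_phase(phase)
        if phase == "systole":
            return ellipse_axes_from_area_perimeter(
                self.annulus_area_sys, self.annulus_perimeter_sys
            )
        return ellipse_axes_from_area_perimeter(
            self.annulus_area_dia, self.annulus_perimeter_dia
        )

    @property
    def open_defects(self) -> tuple[CoaptationDefect, ...]:
        return tuple(d for d in self.defects if d.gap_height > 0 and d.width > 0)

    @property
    def anatomic_orifice_area_sys(self) -> float:
        """Total systolic regurgitant slit area under the slit model, mm²."""
        return float(sum(d.area for d in self.open_defects))

    def with_defects(self, defects: Sequence[CoaptationDefect]) -> "ValveAnatomy":
        return replace(self, defects=tuple(defects))


def _check_phase(phase: str) -> None:
    if phase not in ("systole", "diastole"):
        raise ValueError(f"phase must be 'systole' or 'diastole', got {phase!r}")


def make_valve_anatomy(**params) -> ValveAnatomy:
    """Build a validated :class:`ValveAnatomy`; omitted parameters default.

    Defaults follow the measured population means (systolic annulus area
    1595 mm², perimeter 141 mm), stroke volume 70 ml and phase durations
    t_sys 0.35 s / t_dia 0.65 s (heart rate 60 min⁻¹).  ``defects`` may be
    given as CoaptationDefect instances or ``(center_s, width, gap_height)``
    mappings/tuples.
    """
    defects = params.pop("defects", ())
    coerced = []
    for d in defects:
        if isinstance(d, CoaptationDefect):
            coerced.append(d)
        elif isinstance(d, dict):
            coerced.append(CoaptationDefect(**d))
        else:
            coerced.append(CoaptationDefect(*d))
    known = {f.name for f in dataclasses.fields(ValveAnatomy)}
    unknown = set(params) - known
    if unknown:
        raise AnatomyValidationError(f"unknown anatomy parameters: {sorted(unknown)}")
    if "chamber_extents" in params:
        params["chamber_extents"] = tuple(params["chamber_extents"])
    return ValveAnatomy(defects=tuple(coerced), **params)


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationModel:
    """Distributional model for synthetic cohorts.

    Annulus areas are drawn from truncated normals with the measured cohort
    moments; the perimeter is then derived from the sampled area and a
    per-patient annulus axis ratio k ~ U(axis_ratio_range) through
    Ramanujan's formula, so that each sampled annulus is geometrically
    self-consistent and larger annuli get proportionally larger perimeters
    (the resulting cohort perimeter moments reproduce the measured
    141 ± 16 mm).  Every truncated normal is floored at mean − 3·SD or the
    physiologic minimum, whichever is larger.
    """

    annulus_area_sys: tuple[float, float] = (1595.0, 379.0)
    area_dia_over_sys: tuple[float, float] = (1630.0 / 1595.0, 0.01)
    axis_ratio_range: tuple[float, float] = (0.75, 1.0)
    stroke_volume: tuple[float, float] = (70.0, 15.0)
    leaflet_length: tuple[float, float] = (10.0, 2.0)
    lvot_diameter: tuple[float, float] = (20.0, 2.0)
    #: coaptation line length per systolic semi-major axis.
    coaptation_line_factor: float = 1.7
    n_defects: int = 1
    defect_width: tuple[float, float] = (8.0, 3.0)
    defect_gap: tuple[float, float] = (5.0, 1.5)
    #: defect centre as a fraction of the coaptation line.
    defect_center_frac: tuple[float, float] = (0.5, 0.12)
    t_sys: float = 0.35
    t_dia: float = 0.65
    #: chamber truncation depths (atrial, ventricular) for sampled cases, mm
    chamber_extents: tuple[float, float] = (20.0, 20.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "annulus_area_sys",
            "area_dia_over_sys",
            "stroke_volume",
            "leaflet_length",
            "lvot_diameter",
            "defect_width",
            "defect_gap",
            "defect_center_frac",
        ):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise AnatomyValidationError(f"{name} SD must be non-negative")
            if mean <= 0 and name != "defect_center_frac":
                raise AnatomyValidationError(f"{name} mean must be positive")
        lo, hi = self.axis_ratio_range
        if not (0 < lo <= hi <= 1):
            raise AnatomyValidationError("axis_ratio_range must satisfy 0 < lo <= hi <= 1")


#: Physiologic floors used by the truncated-normal sampler (same units as
#: the corresponding parameter).
PHYSIOLOGIC_FLOORS = {
    "annulus_area_sys": 400.0,
    "area_dia_over_sys": 0.8,
    "stroke_volume": 15.0,
    "leaflet_length": 4.0,
    "lvot_diameter": 12.0,
    "defect_width": 1.5,
    "defect_gap": 0.5,
    "defect_center_frac": 0.05,
}


def truncated_normal_draws(
    mean: float, sd: float, floor: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n values from N(mean, sd) truncated below at max(floor, mean−3sd)."""
    if sd == 0:
        return np.full(n, mean)
    lo = max(floor, mean - 3.0 * sd)
    a = (lo - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def truncated_normal_moments(mean: float, sd: float, floor: float) -> tuple[float, float]:
    """Analytic (mean, sd) of the floored truncated normal used in sampling."""
    if sd == 0:
        return mean, 0.0
    lo = max(floor, mean - 3.0 * sd)
    a = (lo - mean) / sd
    m, v = truncnorm.stats(a, np.inf, loc=mean, scale=sd, moments="mv")
    return float(m), float(np.sqrt(v))


def sample_population(model: PopulationModel, n: int) -> list[ValveAnatomy]:
    """Draw ``n`` synthetic anatomies from ``model`` (reproducible by seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(model.seed)

    def draws(name: str) -> np.ndarray:
        mean, sd = getattr(model, name)
        return truncated_normal_draws(mean, sd, PHYSIOLOGIC_FLOORS[name], n, rng)

    area_sys = draws("annulus_area_sys")
    ratio_dia = draws("area_dia_over_sys")
    sv = draws("stroke_volume")
    leaflet = draws("leaflet_length")
    lvot = draws("lvot_diameter")
    lo, hi = model.axis_ratio_range
    k = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, lo)

    widths = np.stack([draws("defect_width") for _ in range(max(model.n_defects, 1))])
    gaps = np.stack([draws("defect_gap") for _ in range(max(model.n_defects, 1))])
    fracs = np.stack([draws("defect_center_frac") for _ in range(max(model.n_defects, 1))])

    anatomies: list[ValveAnatomy] = []
    for i in range(n):
        a_sys = float(np.sqrt(area_sys[i] / (np.pi * k[i])))
        p_sys = ramanujan_perimeter(a_sys, k[i] * a_sys)
        area_dia = float(area_sys[i] * ratio_dia[i])
        a_dia = float(np.sqrt(area_dia / (np.pi * k[i])))
        p_dia = ramanujan_perimeter(a_dia, k[i] * a_dia)
        line = model.coaptation_line_factor * a_sys
        defects = []
        for j in range(model.n_defects):
            w = float(min(widths[j, i], 0.9 * line))
            c = float(np.clip(fracs[j, i] * line, 0.5 * w, line - 0.5 * w))
            defects.append(CoaptationDefect(center_s=c, width=w, gap_height=float(gaps[j, i])))
        anatomies.append(
            ValveAnatomy(
                annulus_area_sys=float(area_sys[i]),
                annulus_area_dia=area_dia,
                annulus_perimeter_sys=p_sys,
                annulus_perimeter_dia=p_dia,
                leaflet_length=float(leaflet[i]),
                coaptation_line_length=float(line),
                defects=tuple(defects),
                lvot_diameter=float(lvot[i]),
                stroke_volume=float(sv[i]),
                t_sys=model.t_sys,
                t_dia=model.t_dia,
                chamber_extents=tuple(model.chamber_extents),
            )
        )
    return anatomies


# ---------------------------------------------------------------------------
# Surface generation
# ---------------------------------------------------------------------------


def anatomy_to_surface(
    anatomy: ValveAnatomy, phase: str, pitch: float = 0.6
) -> trimesh.Trimesh:
    """Closed, oriented triangle surface of the flow cavity for one phase.

    The cavity level-set is sampled on a Cartesian grid of the given pitch
    (mm) and triangulated with marching cubes; the result is watertight
    (every edge shared by exactly two triangles) and deterministic for
    identical parameters.
    """
    from . import _implicit
    from skimage import measure

    _check_phase(phase)
    model = _implicit.CavityModel(anatomy, phase)
    (lo, hi) = model.bounds
    # one solid padding layer on every side so marching cubes closes the caps
    xs = np.arange(lo[0] - pitch, hi[0] + 2 * pitch, pitch)
    ys = np.arange(lo[1] - pitch, hi[1] + 2 * pitch, pitch)
    zs = np.arange(lo[2] - pitch, hi[2] + 2 * pitch, pitch)
    vol = model.field(xs, ys, zs)
    vol[0, :, :] = vol[-1, :, :] = 1.0
    vol[:, 0, :] = vol[:, -1, :] = 1.0
    vol[:, :, 0] = vol[:, :, -1] = 1.0
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0)
    verts = verts * pitch + np.array([xs[0], ys[0], zs[0]])
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    trimesh.repair.fix_normals(mesh)
    if not mesh.is_watertight:
        mesh.update_faces(mesh.nondegenerate_faces())
        mesh.merge_vertices()
    return mesh


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------


def anatomy_to_dict(anatomy: ValveAnatomy) -> dict:
    d = dataclasses.asdict(anatomy)
    d["defects"] = [dataclasses.asdict(x) for x in anatomy.defects]
    d["devices"] = [dataclasses.asdict(x) for x in anatomy.devices]
    d["chamber_extents"] = list(anatomy.chamber_extents)
    d["grasped_intervals"] = [list(g) for g in anatomy.grasped_intervals]
    return d


def anatomy_from_dict(d: dict) -> ValveAnatomy:
    d = dict(d)
    defects = tuple(CoaptationDefect(**x) for x in d.pop("defects", []))
    devices = tuple(DeviceRecord(**x) for x in d.pop("devices", []))
    grasped = tuple(tuple(g) for g in d.pop("grasped_intervals", []))
    if "chamber_extents" in d:
        d["chamber_extents"] = tuple(d["chamber_extents"])
    return ValveAnatomy(defects=defects, devices=devices, grasped_intervals=grasped, **d)


def save_anatomy_yaml(anatomy: ValveAnatomy, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(anatomy_to_dict(anatomy), fh, sort_keys=True)


def load_anatomy_yaml(path) -> ValveAnatomy:
    with open(path) as fh:
        return anatomy_from_dict(yaml.safe_load(fh))


def anatomy_to_json(anatomy: ValveAnatomy) -> str:
    return json.dumps(anatomy_to_dict(anatomy), sort_keys=True)


def anatomy_from_json(s: str) -> ValveAnatomy:
    return anatomy_from_dict(json.loads(s))
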