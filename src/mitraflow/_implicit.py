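"""Implicit (level-set) model of the transvalvular flow cavity.

One continuous scalar field per anatomy and phase, negative inside the
blood pool.  The same field backs both surface triangulation (marching
cubes) and direct voxelization, so the two routes agree by construction.

Cavity layout along the valve axis (+z toward the atrium, annulus at z=0):

    z = +H_a   atrial cap           (open: LA patch; LVOT tube cap in systole)
    z = 0      annulus ellipse
    z = -Lf    coaptation line      (leaflet funnel tapers to it)
    z = -Lf-Ls coaptation channel   (slit orifices / diastolic opening)
    z = -Lf-Ls-H_v ventricular cap  (open: LV patch)

The leaflet funnel interpolates a superellipse cross-section from the
annulus ellipse (exponent 2) to a rounded rectangle at the coaptation line
(exponent 6).  Regurgitant orifices are rectangular channels through the
coaptation zone of depth ``COAPT_ZONE_DEPTH``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_anatomy import ValveAnatomy

#: Depth of the coaptation (slit) channel along z, mm.
COAPT_ZONE_DEPTH = 3.0
#: Lateral wall margin added around the footprint, mm.
WALL_MARGIN = 2.0
#: Gap of solid tissue between annulus and LVOT tube, mm.
LVOT_STANDOFF = 3.0
#: Minimum full width of the tent bottom cross-section in systole, mm.
MIN_TENT_BOTTOM_WIDTH = 4.0


def _superellipse(x, y, sx, sy, p):
    """Level value of |x/sx|^p + |y/sy|^p = 1, roughly distance-scaled (mm)."""
    q = np.abs(x / sx) ** p + np.abs(y / sy) ** p - 1.0
    return q * np.minimum(sx, sy) / p


def _slab(z, zlo, zhi):
    return np.maximum(zlo - z, z - zhi)


def _box(dx, dy, dz, hx, hy, hz):
    return np.maximum.reduce([np.abs(dx) - hx, np.abs(dy) - hy, np.abs(dz) - hz])


@dataclass
class OrificeRegion:
    """One opening through the coaptation channel."""

    center_x: float
    center_y: float
    half_width: float  # along x, mm
    half_gap: float  # along y, mm

    @property
    def area(self) -> float:
        return 4.0 * self.half_width * self.half_gap


class CavityModel:
    """Precomputed implicit cavity for one (anatomy, phase) pair."""

    def __init__(self, anatomy: ValveAnatomy, phase: str):
        if phase not in ("systole", "diastole"):
            raise ValueError(f"phase must be 'systole' or 'diastole', got {phase!r}")
        self.anatomy = anatomy
        self.phase = phase

        self.a, self.b = anatomy.annulus_axes(phase)
        a_sys, _ = anatomy.annulus_axes("systole")
        a_dia, _ = anatomy.annulus_axes("diastole")
        a_ref = max(a_sys, a_dia)

        self.c = anatomy.coaptation_line_length
        self.Lf = anatomy.leaflet_length
        self.Ls = COAPT_ZONE_DEPTH
        self.H_a, self.H_v = anatomy.chamber_extents
        self.z_coapt = -self.Lf  # top of coaptation channel
        self.z_chan = -self.Lf - self.Ls  # bottom of coaptation channel
        self.z_bot = self.z_chan - self.H_v
        self.z_top = self.H_a
        self.z_orifice = 0.5 * (self.z_coapt + self.z_chan)

        # LVOT tube (open in systole only)
        self.r_lvot = 0.5 * anatomy.lvot_diameter
        self.x_lvot = a_ref + self.r_lvot + LVOT_STANDOFF
        self.has_lvot = phase == "systole"

        # Ventricular chamber footprint: superellipse spanning annulus + LVOT
        self.xc_v = 0.5 * (-a_ref + self.x_lvot + self.r_lvot)
        self.Av = 0.5 * (self.x_lvot + self.r_lvot + a_ref) + WALL_MARGIN
        self.Bv = max(self.b, self.r_lvot) + WALL_MARGIN

        # Phase-specific coaptation channel openings
        self.grasped = [
            (max(0.0, g0), min(self.c, g1)) for g0, g1 in anatomy.grasped_intervals
        ]
        if phase == "systole":
            gaps = [d.gap_height for d in anatomy.open_defects] or [0.0]
            self.tent_bottom_width = max(MIN_TENT_BOTTOM_WIDTH, 1.2 * max(gaps))
            self.orifices = [
                OrificeRegion(
                    center_x=d.center_s - 0.5 * self.c,
                    center_y=0.0,
                    half_width=0.5 * d.width,
                    half_gap=0.5 * d.gap_height,
                )
                for d in anatomy.open_defects
            ]
        else:
            open_area = anatomy.diastolic_open_fraction * anatomy.annulus_area_dia
            w_d = open_area / self.c
            w_d = min(w_d, 1.8 * self.b)  # keep the opening inside the annulus shadow
            self.tent_bottom_width = w_d
            self.orifices = [
                OrificeRegion(
                    center_x=0.5 * (s0 + s1) - 0.5 * self.c,
                    center_y=0.0,
                    half_width=0.5 * (s1 - s0),
                    half_gap=0.5 * w_d,
                )
                for s0, s1 in _subtract_intervals([(0.0, self.c)], self.grasped)
                if s1 - s0 > 1e-9
            ]

        lo = np.array(
            [self.xc_v - self.Av - WALL_MARGIN, -self.Bv - WALL_MARGIN, self.z_bot]
        )
        hi = np.array(
            [self.xc_v + self.Av + WALL_MARGIN, self.Bv + WALL_MARGIN, self.z_top]
        )
        self.bounds = (lo, hi)

    # -- membership helpers used for boundary labeling ----------------------

    def la_column(self, x, y):
        """True where a (x, y) column opens into the atrial cap."""
        return (x / self.a) ** 2 + (y / self.b) ** 2 <= 1.0

    def lvot_column(self, x, y):
        if not self.has_lvot:
            return np.zeros(np.broadcast(x, y).shape, dtype=bool)
        return (x - self.x_lvot) ** 2 + y**2 <= self.r_lvot**2

    # -- level set ----------------------------------------------------------

    def value(self, x, y, z):
        """Level-set value at points (negative = fluid)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)

        parts = []
        # atrial chamber
        parts.append(
            np.maximum(_superellipse(x, y, self.a, self.b, 2.0), _slab(z, 0.0, self.z_top))
        )
        # leaflet funnel (tent): superellipse morphing with depth
        t = np.clip(-z / self.Lf, 0.0, 1.0)
        sx = (1.0 - t) * self.a + t * (0.5 * self.c)
        sy = (1.0 - t) * self.b + t * (0.5 * self.tent_bottom_width)
        p = 2.0 + 4.0 * t
        parts.append(
            np.maximum(_superellipse(x, y, sx, sy, p), _slab(z, self.z_coapt, 0.0))
        )
        # coaptation channel openings
        zc = 0.5 * (self.z_coapt + self.z_chan)
        hz = 0.5 * (self.z_coapt - self.z_chan) + 0.25
        for o in self.orifices:
            if o.half_gap <= 0 or o.half_width <= 0:
                continue
            chan = _box(x - o.center_x, y - o.center_y, z - zc, o.half_width, o.half_gap, hz)
            if self.phase == "diastole" and self.grasped:
                for g0, g1 in self.grasped:
                    gx = 0.5 * (g0 + g1) - 0.5 * self.c
                    gh = 0.5 * (g1 - g0)
                    block = _box(x - gx, y, z - zc, gh, 1e4, hz + 1.0)
                    chan = np.maximum(chan, -block)
            parts.append(chan)
        # ventricular chamber
        parts.append(
            np.maximum(
                _superellipse(x - self.xc_v, y, self.Av, self.Bv, 4.0),
                _slab(z, self.z_bot, self.z_chan),
            )
        )
        # LVOT tube (systole)
        if self.has_lvot:
            rho = np.sqrt((x - self.x_lvot) ** 2 + y**2) - self.r_lvot
            parts.append(np.maximum(rho, _slab(z, self.z_chan, self.z_top)))
        return np.minimum.reduce(parts)

    def field(self, xs, ys, zs) -> np.ndarray:
        """Sample the level set on the tensor grid xs × ys × zs."""
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        return self.value(X, Y, Z)

    def contains(self, x, y, z) -> np.ndarray:
        """Point-in-cavity test; ties (value == 0) resolve toward solid."""
        return self.value(x, y, z) < 0.0


def _subtract_intervals(base, cuts):
    """Subtract a list of intervals from a list of intervals (1-d, sorted)."""
    result = list(base)
    for c0, c1 in cuts:
        nxt = []
        for s0, s1 in result:
            if c1 <= s0 or c0 >= s1:
                nxt.append((s0, s1))
                continue
            if s0 < c0:
                nxt.append((s0, c0))
            if c1 < s1:
                nxt.append((c1, s1))
        result = nxt
    return sorted(result)
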