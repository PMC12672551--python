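"""Voxelized computational domains with labeled boundaries.

A :class:`ComputationalDomain` is a uniform Cartesian grid of cubic cells;
fluid cells are those whose centers fall inside the cavity (ties toward
solid), giving a stairstep immersed representation of the walls.  Openings
sit on the grid's z boundary planes: the atrial cap and (in systole) the
LVOT tube cap at the top, the ventricular cap at the bottom.  Boundary
faces are grouped into named patches; :func:`label_boundaries` assigns the
phase-specific roles — systole has one inlet (left ventricle) and two
outlets (left atrium and LVOT), diastole one inlet (left atrium) and one
outlet on the ventricular side.

Grid convention: 0-based cell indices, cell-centered coordinates,
isotropic spacing in mm, valve axis = +z toward the atrium.  A face along
axis ``d`` with index ``f`` separates cells ``f-1`` and ``f`` along that
axis (boundary faces have ``f`` equal to 0 or the cell count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh
from scipy import ndimage

from ._implicit import CavityModel, OrificeRegion
from .synthetic_anatomy import ValveAnatomy

__all__ = [
    "FacePatch",
    "ComputationalDomain",
    "voxelize",
    "voxelize_anatomy",
    "label_boundaries",
    "orifice_area",
    "box_channel",
    "orifice_plate",
    "load_stl",
    "write_vtk",
]

#: Minimum number of cells across an orifice before the domain is flagged
#: as under-resolved.
MIN_ORIFICE_CELLS = 4

_SIX_CONN = ndimage.generate_binary_structure(3, 1)


class DomainError(ValueError):
    pass


@dataclass
class FacePatch:
    """A set of boundary faces sharing one axis and outward direction."""

    axis: int  # 0=x, 1=y, 2=z
    sign: int  # +1: exterior on the +axis side of the face
    faces: np.ndarray  # (N, 3) integer face coordinates

    @property
    def n_faces(self) -> int:
        return int(len(self.faces))

    def area(self, spacing: float) -> float:
        return self.n_faces * spacing**2


@dataclass
class ComputationalDomain:
    spacing: float  # mm
    origin: np.ndarray  # (3,) coordinates of cell (0,0,0) center, mm
    fluid_mask: np.ndarray  # (nx, ny, nz) bool
    phase: Optional[str] = None
    patches: dict = field(default_factory=dict)  # role -> FacePatch (after labeling)
    openings: dict = field(default_factory=dict)  # anatomical name -> FacePatch
    meta: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fluid_mask.shape

    @property
    def n_fluid(self) -> int:
        return int(self.fluid_mask.sum())

    @property
    def fluid_volume(self) -> float:
        """Fluid volume in mm³ (cell count × spacing³)."""
        return self.n_fluid * self.spacing**3

    def cell_centers_1d(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + self.spacing * np.arange(n)

    def z_of_face(self, kf: int) -> float:
        return self.origin[2] + (kf - 0.5) * self.spacing


# ---------------------------------------------------------------------------
# Voxelization of triangle surfaces (z-column ray parity)
# ---------------------------------------------------------------------------


def load_stl(path) -> trimesh.Trimesh:
    """Load an STL surface (binary or ASCII autodetected)."""
    mesh = trimesh.load(path, force="mesh")
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise DomainError(f"no triangle surface found in {path}")
    return mesh


def _column_crossings(mesh: trimesh.Trimesh, xs: np.ndarray, ys: np.ndarray):
    """z-values where vertical lines through (xs × ys) cross the surface.

    Returns a dict {(i, j): sorted ndarray of z}.  Grid lines are assumed
    to be jittered off any mesh vertex/edge by the caller.
    """
    tri = mesh.triangles  # (n, 3, 3)
    crossings: dict = {}
    nx, ny = len(xs), len(ys)
    x0, dx = xs[0], xs[1] - xs[0] if nx > 1 else 1.0
    y0, dy = ys[0], ys[1] - ys[0] if ny > 1 else 1.0
    for t in tri:
        txmin, tymin = t[:, 0].min(), t[:, 1].min()
        txmax, tymax = t[:, 0].max(), t[:, 1].max()
        i0 = max(0, int(np.ceil((txmin - x0) / dx)))
        i1 = min(nx - 1, int(np.floor((txmax - x0) / dx)))
        j0 = max(0, int(np.ceil((tymin - y0) / dy)))
        j1 = min(ny - 1, int(np.floor((tymax - y0) / dy)))
        if i1 < i0 or j1 < j0:
            continue
        gx = xs[i0 : i1 + 1]
        gy = ys[j0 : j1 + 1]
        PX, PY = np.meshgrid(gx, gy, indexing="ij")
        # 2-d barycentric test in the xy projection
        ax, ay = t[0, 0], t[0, 1]
        bx, by = t[1, 0], t[1, 1]
        cx, cy = t[2, 0], t[2, 1]
        d = (by - cy) * (ax - cx) + (cx - bx) * (ay - cy)
        if abs(d) < 1e-14:
            continue  # degenerate in projection (vertical triangle)
        l1 = ((by - cy) * (PX - cx) + (cx - bx) * (PY - cy)) / d
        l2 = ((cy - ay) * (PX - cx) + (ax - cx) * (PY - cy)) / d
        l3 = 1.0 - l1 - l2
        inside = (l1 > 0) & (l2 > 0) & (l3 > 0)
        if not inside.any():
            continue
        z = l1 * t[0, 2] + l2 * t[1, 2] + l3 * t[2, 2]
        ii, jj = np.nonzero(inside)
        for a_i, a_j, a_z in zip(ii + i0, jj + j0, z[inside]):
            crossings.setdefault((int(a_i), int(a_j)), []).append(float(a_z))
    return {k: np.sort(v) for k, v in crossings.items()}


def voxelize(surface: trimesh.Trimesh, spacing: float) -> ComputationalDomain:
    """Voxelize a watertight triangle surface into a flow domain.

    Fluid cells are those whose centers lie inside the surface (ray-parity
    along z columns).  Isolated pockets of fewer than 8 cells are removed.
    No boundary patches are assigned; use :func:`label_boundaries` or the
    anatomy-aware :func:`voxelize_anatomy` route for that.
    """
    if surface is None or not isinstance(surface, trimesh.Trimesh) or len(surface.faces) == 0:
        raise DomainError("voxelize requires a non-empty triangle surface")
    if spacing <= 0:
        raise DomainError("spacing must be positive")
    if not surface.is_watertight:
        edges = surface.edges_sorted
        _, counts = np.unique(edges, axis=0, return_counts=True)
        n_open = int((counts != 2).sum())
        raise DomainError(
            f"surface is not watertight: {n_open} edges are not shared by "
            f"exactly two triangles"
        )
    lo, hi = surface.bounds
    origin = lo + 0.5 * spacing
    n = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    # jitter grid lines off mesh vertices/edges to keep ray parity robust
    xs = origin[0] + spacing * np.arange(n[0]) + 1.23456789e-4 * spacing
    ys = origin[1] + spacing * np.arange(n[1]) + 0.98765432e-4 * spacing
    zs = origin[2] + spacing * np.arange(n[2])
    fluid = np.zeros(tuple(n), dtype=bool)
    crossings = _column_crossings(surface, xs, ys)
    for (i, j), zhits in crossings.items():
        fluid[i, j, :] = (np.searchsorted(zhits, zs) % 2) == 1
    fluid = _drop_small_components(fluid, min_cells=8)
    dom = ComputationalDomain(spacing=float(spacing), origin=np.asarray(origin, float), fluid_mask=fluid)
    dom.meta["source"] = "surface"
    return dom


def _drop_small_components(fluid: np.ndarray, min_cells: int) -> np.ndarray:
    labels, nlab = ndimage.label(fluid, structure=_SIX_CONN)
    if nlab <= 1:
        return fluid
    counts = np.bincount(labels.ravel())
    keep = np.zeros(nlab + 1, dtype=bool)
    keep[1:] = counts[1:] >= min_cells
    return keep[labels]


# ---------------------------------------------------------------------------
# Direct anatomy voxelization (implicit route)
# ---------------------------------------------------------------------------


def voxelize_anatomy(
    anatomy: ValveAnatomy, phase: str, spacing: float
) -> ComputationalDomain:
    """Voxelize the implicit flow cavity of an anatomy for one phase.

    The grid spans the cavity bounding box exactly in z so that the atrial
    and ventricular caps coincide with the grid boundary; opening patches
    are identified there and stored under anatomical names ('ATRIAL',
    'LVOT', 'VENT') for :func:`label_boundaries` to map to phase roles.
    """
    if spacing <= 0:
        raise DomainError("spacing must be positive")
    model = CavityModel(anatomy, phase)
    lo, hi = model.bounds
    span_z = model.z_top - model.z_bot
    nz = max(int(round(span_z / spacing)), 1)
    nx = max(int(np.ceil((hi[0] - lo[0]) / spacing)), 1)
    ny = max(int(np.ceil((hi[1] - lo[1]) / spacing)), 1)
    # center the z-grid in the cavity span so both cap layers keep their
    # cell centers strictly inside the fluid
    origin = np.array(
        [
            lo[0] + 0.5 * spacing,
            lo[1] + 0.5 * spacing,
            model.z_bot + 0.5 * (span_z - (nz - 1) * spacing),
        ]
    )
    xs = origin[0] + spacing * np.arange(nx)
    ys = origin[1] + spacing * np.arange(ny)
    zs = origin[2] + spacing * np.arange(nz)
    fluid = model.field(xs, ys, zs) < 0.0

    # keep only components that reach a cap (removes isolated pockets)
    labels, nlab = ndimage.label(fluid, structure=_SIX_CONN)
    if nlab > 1:
        cap_labels = set(np.unique(labels[:, :, 0])) | set(np.unique(labels[:, :, -1]))
        cap_labels.discard(0)
        keep = np.zeros(nlab + 1, dtype=bool)
        for lab in cap_labels:
            keep[lab] = True
        fluid = keep[labels]

    dom = ComputationalDomain(
        spacing=float(spacing), origin=origin, fluid_mask=fluid
    )
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    def _cap_patch(k_cell: int, face_index: int, sign: int, column_mask: np.ndarray):
        sel = fluid[:, :, k_cell] & column_mask
        ii, jj = np.nonzero(sel)
        faces = np.column_stack([ii, jj, np.full(ii.shape, face_index)])
        return FacePatch(axis=2, sign=sign, faces=faces)

    la = _cap_patch(nz - 1, nz, +1, model.la_column(X, Y))
    if la.n_faces:
        dom.openings["ATRIAL"] = la
    lv = _cap_patch(0, 0, -1, np.ones_like(X, dtype=bool))
    if lv.n_faces:
        dom.openings["VENT"] = lv
    if model.has_lvot:
        lvot = _cap_patch(nz - 1, nz, +1, model.lvot_column(X, Y))
        if lvot.n_faces:
            dom.openings["LVOT"] = lvot

    dom.meta.update(
        source="anatomy",
        anatomy_phase=phase,
        z_orifice=model.z_orifice,
        z_coapt=model.z_coapt,
        z_chan=model.z_chan,
        orifice_regions=list(model.orifices),
        valve_x_limits=(-0.5 * model.c - 2.0, 0.5 * model.c + 2.0),
        t_sys=anatomy.t_sys,
        t_dia=anatomy.t_dia,
    )
    for o in model.orifices:
        n_cells = (2 * o.half_width / spacing) * (2 * o.half_gap / spacing)
        if 0 < o.area and n_cells < MIN_ORIFICE_CELLS:
            dom.warnings.append(
                f"orifice at x={o.center_x:.1f} mm resolved by only "
                f"{n_cells:.1f} cells (< {MIN_ORIFICE_CELLS}); results will be coarse"
            )
    return dom


def label_boundaries(domain: ComputationalDomain, phase: str) -> ComputationalDomain:
    """Assign phase-specific inlet/outlet roles to the opening patches.

    Systole: INLET on the ventricular cap, OUTLET_LA on the atrial cap,
    OUTLET_LVOT on the LVOT cap (1 inlet + 2 outlets).  Diastole: INLET on
    the atrial cap and a single outlet (labeled OUTLET_LVOT) on the
    ventricular/outflow side (1 inlet + 1 outlet).
    """
    if phase not in ("systole", "diastole"):
        raise DomainError(f"phase must be 'systole' or 'diastole', got {phase!r}")
    ops = domain.openings
    missing = [name for name in ("ATRIAL", "VENT") if name not in ops]
    if phase == "systole" and "LVOT" not in ops:
        missing.append("LVOT")
    if missing:
        raise DomainError(f"expected opening patch(es) not found: {missing}")
    if phase == "systole":
        domain.patches = {
            "INLET": ops["VENT"],
            "OUTLET_LA": ops["ATRIAL"],
            "OUTLET_LVOT": ops["LVOT"],
        }
    else:
        if "LVOT" in ops:
            raise DomainError("diastolic domain must not expose an open LVOT cap")
        domain.patches = {"INLET": ops["ATRIAL"], "OUTLET_LVOT": ops["VENT"]}
    domain.phase = phase
    n_out = sum(1 for k in domain.patches if k.startswith("OUTLET"))
    assert (phase == "systole" and n_out == 2) or (phase == "diastole" and n_out == 1)
    return domain


def orifice_area(domain: ComputationalDomain, plane_z: Optional[float] = None) -> float:
    """Fluid cross-section area (mm²) across a z-plane in the valve region.

    Counts fluid-fluid cell faces crossing the plane, restricted to the
    coaptation-line footprint (the LVOT tube, which also crosses mid-domain
    planes, is excluded via the stored valve-region x-limits).
    """
    if plane_z is None:
        if "z_orifice" not in domain.meta:
            raise DomainError("no orifice plane stored in domain metadata")
        plane_z = domain.meta["z_orifice"]
    z0 = domain.origin[2] - 0.5 * domain.spacing
    z1 = z0 + domain.shape[2] * domain.spacing
    if not (z0 < plane_z < z1):
        raise DomainError(f"plane z={plane_z:.2f} mm lies outside the domain [{z0:.2f}, {z1:.2f}]")
    kf = int(round((plane_z - domain.origin[2]) / domain.spacing + 0.5))
    kf = min(max(kf, 1), domain.shape[2] - 1)
    sel = domain.fluid_mask[:, :, kf - 1] & domain.fluid_mask[:, :, kf]
    if "valve_x_limits" in domain.meta:
        xlo, xhi = domain.meta["valve_x_limits"]
        xs = domain.cell_centers_1d(0)
        sel = sel & ((xs >= xlo) & (xs <= xhi))[:, None]
    return float(sel.sum()) * domain.spacing**2


# ---------------------------------------------------------------------------
# Benchmark domains
# ---------------------------------------------------------------------------


def box_channel(
    n_cells: tuple[int, int, int],
    spacing: float,
    phase: str = "diastole",
    inlet_name: str = "INLET",
    outlet_name: str = "OUTLET_LVOT",
) -> ComputationalDomain:
    """All-fluid rectangular duct with flow along z (benchmark geometry)."""
    nx, ny, nz = n_cells
    fluid = np.ones((nx, ny, nz), dtype=bool)
    dom = ComputationalDomain(
        spacing=float(spacing),
        origin=np.array([0.5, 0.5, 0.5]) * spacing,
        fluid_mask=fluid,
        phase=phase,
    )
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    bottom = np.column_stack([ii.ravel(), jj.ravel(), np.zeros(nx * ny, int)])
    top = np.column_stack([ii.ravel(), jj.ravel(), np.full(nx * ny, nz)])
    dom.patches = {
        inlet_name: FacePatch(axis=2, sign=-1, faces=bottom),
        outlet_name: FacePatch(axis=2, sign=+1, faces=top),
    }
    dom.meta["source"] = "box_channel"
    return dom


def orifice_plate(
    n_cells: tuple[int, int, int],
    spacing: float,
    orifice_half_cells: tuple[int, int],
    plate_thickness_cells: int = 2,
    phase: str = "diastole",
) -> ComputationalDomain:
    """Duct with a mid-height solid plate pierced by a rectangular orifice."""
    dom = box_channel(n_cells, spacing, phase=phase)
    nx, ny, nz = n_cells
    k0 = nz // 2 - plate_thickness_cells // 2
    hw, hg = orifice_half_cells
    plate = np.ones((nx, ny), dtype=bool)
    plate[nx // 2 - hw : nx // 2 + hw, ny // 2 - hg : ny // 2 + hg] = False
    for k in range(k0, k0 + plate_thickness_cells):
        dom.fluid_mask[:, :, k] &= ~plate
    dom.meta["z_orifice"] = dom.origin[2] + (k0 + 0.5 * plate_thickness_cells - 0.5) * spacing
    dom.meta["orifice_regions"] = [
        OrificeRegion(
            center_x=dom.origin[0] + (nx / 2 - 0.5) * spacing,
            center_y=dom.origin[1] + (ny / 2 - 0.5) * spacing,
            half_width=hw * spacing,
            half_gap=hg * spacing,
        )
    ]
    return dom


# ---------------------------------------------------------------------------
# VTK output (legacy ASCII structured points)
# ---------------------------------------------------------------------------


def write_vtk(path, domain: ComputationalDomain, flow_field=None) -> None:
    """Write the fluid mask (and optionally a solved field) as legacy VTK."""
    nx, ny, nz = domain.shape
    sp = domain.spacing
    lines = [
        "# vtk DataFile Version 3.0",
        "mitraflow domain",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        f"ORIGIN {domain.origin[0] - sp / 2:.6g} {domain.origin[1] - sp / 2:.6g} {domain.origin[2] - sp / 2:.6g}",
        f"SPACING {sp:.6g} {sp:.6g} {sp:.6g}",
        f"CELL_DATA {nx * ny * nz}",
        "SCALARS fluid_mask int 1",
        "LOOKUP_TABLE default",
    ]
    mask = domain.fluid_mask.astype(int)
    lines.append(" ".join(map(str, mask.ravel(order="F"))))
    if flow_field is not None:
        p = np.where(domain.fluid_mask, flow_field.pressure, 0.0)
        lines += ["SCALARS pressure_pa float 1", "LOOKUP_TABLE default"]
        lines.append(" ".join(f"{v:.6g}" for v in p.ravel(order="F")))
        uc, vc, wc = flow_field.cell_velocities()
        lines += ["VECTORS velocity_m_s float"]
        vec = np.stack(
            [uc.ravel(order="F"), vc.ravel(order="F"), wc.ravel(order="F")], axis=1
        )
        lines.append("\n".join(f"{a:.6g} {b:.6g} {c:.6g}" for a, b, c in vec))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
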