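"""Steady incompressible laminar flow on voxelized domains.

Blood is treated as an incompressible Newtonian fluid (density
1060 kg·m⁻³, dynamic viscosity 0.004 Pa·s) and each cardiac phase is
solved as a separate steady state with laminar inlet flow: a uniform plug
velocity on the inlet patch (phase flow rate = stroke volume / phase
duration) and fixed pressures on the outlet patches (systole: left atrium
10 mmHg and LVOT 80 mmHg, with the 120 mmHg ventricular value serving only
as the reporting reference; diastole: a single gauge-zero outlet, so only
pressure differences are meaningful there).

Numerics: pseudo-transient Chorin projection on a staggered (MAC) grid —
first-order upwind convection, central diffusion, and an exact pressure
Poisson solve (sparse LU) each pseudo-step with Dirichlet pressure at
outlet faces and zero normal gradient at walls and velocity inlets.
No-slip applies on all immersed walls; selected domain-box wall
orientations can be declared free-slip (symmetry), which the plane-channel
benchmarks use.  The scheme conserves mass discretely: on a converged
field every cell's divergence is at solver precision and the global
|inflow − outflow| imbalance is checked against 1%.

The solver always attempts a laminar steady solution regardless of the
Reynolds number (reported in the diagnostics); no turbulence model, no
transient and no fluid–structure interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import NamedTuple, Optional

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import splu

from .domain_builder import ComputationalDomain
from .units import MM_TO_M, MMHG_TO_PA, M3_TO_ML

__all__ = [
    "FluidProperties",
    "BoundaryConditions",
    "NumericsConfig",
    "FlowField",
    "FlowRates",
    "derive_flow_rates",
    "solve_steady",
    "check_mass_balance",
    "patch_flux",
    "SolverError",
]

# face type codes on the staggered grids
_SOLID, _INTERIOR, _WALL, _INLET, _OUTLET = 0, 1, 2, 3, 4

_AXIS_NAMES = ("x", "y", "z")


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood model (SI units)."""

    density: float = 1060.0  # kg·m⁻³
    dynamic_viscosity: float = 0.004  # Pa·s

    def __post_init__(self) -> None:
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("density and dynamic_viscosity must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density


@dataclass(frozen=True)
class BoundaryConditions:
    """Patch boundary conditions for one phase.

    ``patch_bcs`` maps a domain patch name to either ``("velocity", Q)``
    with Q in ml/s (uniform inward plug over the patch) or
    ``("pressure", p)`` with p in mmHg (fixed static pressure).
    """

    phase: str
    patch_bcs: dict
    reference_pressure_mmhg: float = 0.0

    def __post_init__(self) -> None:
        for name, (kind, value) in self.patch_bcs.items():
            if kind not in ("velocity", "pressure"):
                raise ValueError(f"unknown BC kind {kind!r} on patch {name!r}")
            if kind == "velocity" and value < 0:
                raise ValueError(f"inlet flow rate on {name!r} must be >= 0")
        if not any(kind == "pressure" for kind, _ in self.patch_bcs.values()):
            raise ValueError("at least one pressure patch is required")

    @classmethod
    def systole(
        cls,
        inlet_flow_rate: float,
        p_la: float = 10.0,
        p_lvot: float = 80.0,
        p_lv_reference: float = 120.0,
    ) -> "BoundaryConditions":
        """Systolic setup: LV velocity inlet, LA and LVOT pressure outlets."""
        return cls(
            phase="systole",
            patch_bcs={
                "INLET": ("velocity", inlet_flow_rate),
                "OUTLET_LA": ("pressure", p_la),
                "OUTLET_LVOT": ("pressure", p_lvot),
            },
            reference_pressure_mmhg=p_lv_reference,
        )

    @classmethod
    def diastole(cls, inlet_flow_rate: float, p_out: float = 0.0) -> "BoundaryConditions":
        """Diastolic setup: atrial velocity inlet, single gauge-zero outlet."""
        return cls(
            phase="diastole",
            patch_bcs={
                "INLET": ("velocity", inlet_flow_rate),
                "OUTLET_LVOT": ("pressure", p_out),
            },
        )

    @property
    def inlet_flow_rate(self) -> float:
        return sum(v for k, v in self.patch_bcs.values() if k == "velocity")

    @property
    def outlet_pressures(self) -> dict:
        return {n: v for n, (k, v) in self.patch_bcs.items() if k == "pressure"}


@dataclass(frozen=True)
class NumericsConfig:
    cfl: float = 0.4
    rtol: float = 1e-5  # relative per-step velocity change
    max_iter: int = 5000
    div_tol: float = 1e-6  # normalized per-cell divergence on converged fields
    ramp_steps: int = 50
    mass_tol: float = 0.01
    slip_axes: tuple = ()  # wall-normal axes treated as symmetry planes
    #: relative drift of windowed means below which a statistically
    #: stationary (limit-cycle) solution counts as the steady state; the
    #: returned field is then the window time-average.
    stat_tol: float = 5e-3
    stat_window: int = 100

    def __post_init__(self) -> None:
        if min(self.cfl, self.rtol, self.div_tol, self.mass_tol) <= 0:
            raise ValueError("tolerances and CFL must be positive")
        for ax in self.slip_axes:
            if ax not in _AXIS_NAMES:
                raise ValueError(f"slip axis must be one of {_AXIS_NAMES}")


class FlowRates(NamedTuple):
    Q_sys: float  # ml/s
    Q_dia: float  # ml/s


def derive_flow_rates(stroke_volume: float, t_sys: float, t_dia: float) -> FlowRates:
    """Mean phase flow rates: stroke volume divided by phase duration."""
    if stroke_volume < 0:
        raise ValueError("stroke_volume must be >= 0")
    if t_sys <= 0 or t_dia <= 0:
        raise ValueError("phase durations must be positive")
    return FlowRates(Q_sys=stroke_volume / t_sys, Q_dia=stroke_volume / t_dia)


@dataclass
class FlowField:
    """Face-centered velocities (m/s) and cell pressures (Pa)."""

    u: np.ndarray  # (nx+1, ny, nz)
    v: np.ndarray  # (nx, ny+1, nz)
    w: np.ndarray  # (nx, ny, nz+1)
    pressure: np.ndarray  # (nx, ny, nz), NaN outside fluid
    converged: bool
    residuals: np.ndarray
    mass_imbalance: float
    phase: Optional[str] = None
    meta: dict = dc_field(default_factory=dict)

    def cell_velocities(self):
        uc = 0.5 * (self.u[:-1] + self.u[1:])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        wc = 0.5 * (self.w[:, :, :-1] + self.w[:, :, 1:])
        return uc, vc, wc

    def speed(self) -> np.ndarray:
        uc, vc, wc = self.cell_velocities()
        return np.sqrt(uc**2 + vc**2 + wc**2)

    def save_residuals_csv(self, path) -> None:
        """Write the per-iteration residual history as a two-column CSV."""
        with open(path, "w") as fh:
            fh.write("iteration,residual\n")
            for i, r in enumerate(self.residuals, start=1):
                fh.write(f"{i},{r:.8e}\n")


# ---------------------------------------------------------------------------


def _face_shapes(shape):
    nx, ny, nz = shape
    return (nx + 1, ny, nz), (nx, ny + 1, nz), (nx, ny, nz + 1)


def _build_face_types(domain: ComputationalDomain, bc: BoundaryConditions):
    """Classify staggered faces and collect per-patch face metadata."""
    F = domain.fluid_mask
    shapes = _face_shapes(F.shape)
    types = []
    for d in range(3):
        pad = [(0, 0)] * 3
        pad[d] = (1, 1)
        Fp = np.pad(F, pad, constant_values=False)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[d] = slice(0, shapes[d][d])
        sl_hi[d] = slice(1, shapes[d][d] + 1)
        left = Fp[tuple(sl_lo)]
        right = Fp[tuple(sl_hi)]
        t = np.zeros(shapes[d], dtype=np.int8)
        t[left & right] = _INTERIOR
        t[left ^ right] = _WALL
        types.append(t)

    patch_info = {}
    for name, patch in domain.patches.items():
        if name not in bc.patch_bcs:
            raise SolverError(f"no boundary condition given for patch {name!r}")
        kind, value = bc.patch_bcs[name]
        t = types[patch.axis]
        f = patch.faces
        idx = (f[:, 0], f[:, 1], f[:, 2])
        if not np.all(t[idx] == _WALL):
            raise SolverError(f"patch {name!r} contains non-boundary faces")
        t[idx] = _INLET if kind == "velocity" else _OUTLET
        patch_info[name] = dict(kind=kind, value=value, patch=patch)
    return types, patch_info


def _component_check(domain, patch_info):
    """Freeze fluid components with no pressure outlet (no solution there)."""
    F = domain.fluid_mask
    labels, nlab = ndimage.label(F, structure=ndimage.generate_binary_structure(3, 1))
    has_pressure = np.zeros(nlab + 1, dtype=bool)
    has_inflow = np.zeros(nlab + 1, dtype=bool)
    for info in patch_info.values():
        patch = info["patch"]
        for fc in patch.faces:
            cell = fc.copy()
            if info["patch"].sign > 0:
                cell[patch.axis] -= 1
            lab = labels[tuple(cell)]
            if info["kind"] == "pressure":
                has_pressure[lab] = True
            elif info["value"] > 0:
                has_inflow[lab] = True
    bad = has_inflow & ~has_pressure
    if bad.any():
        raise SolverError(
            "a fluid component receives inflow but has no pressure outlet"
        )
    frozen = ~has_pressure[labels] & F
    return F & ~frozen, frozen


def solve_steady(
    domain: ComputationalDomain,
    fluid: FluidProperties | None = None,
    bc: BoundaryConditions | None = None,
    num: NumericsConfig | None = None,
) -> FlowField:
    """Solve steady laminar incompressible flow on a labeled domain.

    Returns a converged :class:`FlowField` or, if the iteration budget is
    exhausted, a field flagged non-converged (never silently accepted).
    """
    fluid = fluid or FluidProperties()
    num = num or NumericsConfig()
    if bc is None:
        raise SolverError("boundary conditions are required")
    if domain.phase is not None and bc.phase != domain.phase:
        raise SolverError(
            f"boundary-condition phase {bc.phase!r} does not match domain "
            f"phase {domain.phase!r}"
        )
    if not domain.patches:
        raise SolverError("domain has no labeled boundary patches")

    h = domain.spacing * MM_TO_M
    rho, nu = fluid.density, fluid.kinematic_viscosity
    types, patch_info = _build_face_types(domain, bc)
    F_active, frozen = _component_check(domain, patch_info)
    F = F_active
    nx, ny, nz = F.shape

    # deactivate faces of frozen components
    for d in range(3):
        pad = [(0, 0)] * 3
        pad[d] = (1, 1)
        Fp = np.pad(F, pad, constant_values=False)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[d] = slice(0, F.shape[d] + 1)
        sl_hi[d] = slice(1, F.shape[d] + 2)
        touch = Fp[tuple(sl_lo)] | Fp[tuple(sl_hi)]
        types[d][~touch] = _SOLID

    # --- inlet values -------------------------------------------------------
    vel = [np.zeros(s) for s in _face_shapes(F.shape)]
    inlet_speeds = []  # (axis, idx, inward_value)
    p_patches = []  # (axis, idx, sign, p_pa, cell_idx)
    for name, info in patch_info.items():
        patch = info["patch"]
        f = patch.faces
        idx = (f[:, 0], f[:, 1], f[:, 2])
        live = types[patch.axis][idx] != _SOLID
        f = f[live]
        idx = (f[:, 0], f[:, 1], f[:, 2])
        if info["kind"] == "velocity":
            area = len(f) * (domain.spacing * MM_TO_M) ** 2  # m²
            if area == 0:
                raise SolverError(f"velocity patch {name!r} has zero area")
            speed = (info["value"] * 1e-6) / area  # ml/s -> m³/s over area
            inward = -patch.sign * speed
            inlet_speeds.append((patch.axis, idx, inward))
        else:
            cells = f.copy()
            if patch.sign > 0:
                cells[:, patch.axis] -= 1
            p_patches.append(
                (patch.axis, idx, patch.sign, info["value"] * MMHG_TO_PA, cells)
            )

    # --- pressure Poisson matrix -------------------------------------------
    cell_id = -np.ones(F.shape, dtype=np.int64)
    n_cells = int(F.sum())
    if n_cells == 0:
        raise SolverError("domain has no fluid cells")
    cell_id[F] = np.arange(n_cells)
    inv_h2 = 1.0 / h**2
    rows, cols, vals = [], [], []
    diag = np.zeros(n_cells)
    for d in range(3):
        t = types[d]
        # interior faces connect two fluid cells
        fidx = np.argwhere(t == _INTERIOR)
        lo = fidx.copy()
        lo[:, d] -= 1
        a = cell_id[tuple(lo.T)]
        b2 = cell_id[tuple(fidx.T)]
        rows += [a, b2]
        cols += [b2, a]
        vals += [np.full(len(a), inv_h2), np.full(len(a), inv_h2)]
        np.add.at(diag, a, -inv_h2)
        np.add.at(diag, b2, -inv_h2)
    for axis, idx, sign, p_pa, cells in p_patches:
        cid = cell_id[tuple(cells.T)]
        np.add.at(diag, cid, -2.0 * inv_h2)
    rows.append(np.arange(n_cells))
    cols.append(np.arange(n_cells))
    vals.append(diag)
    A = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_cells, n_cells),
    ).tocsc()
    lu = splu(A)

    # --- outlet face helper indices ----------------------------------------
    outlet_meta = []
    for axis, idx, sign, p_pa, cells in p_patches:
        nb = np.array(idx).T.copy()
        nb[:, axis] -= sign  # one face inward along the same axis
        outlet_meta.append((axis, idx, tuple(nb.T), sign, p_pa, cell_id[tuple(cells.T)]))

    # precomputed interior-face -> cell-pair indices for the projection step
    proj_idx = []
    for d in range(3):
        fidx = np.argwhere(types[d] == _INTERIOR)
        hi_id = cell_id[tuple(fidx.T)]
        lo = fidx.copy()
        lo[:, d] -= 1
        lo_id = cell_id[tuple(lo.T)]
        proj_idx.append((tuple(fidx.T), hi_id, lo_id))

    # --- time stepping -------------------------------------------------------
    p_values = [p for _, _, _, p, _ in p_patches]
    p_mean = float(np.mean(p_values))
    dp_scale = max(max(p_values) - min(p_values), 1.0)
    v_bc_scale = max(
        np.sqrt(2.0 * dp_scale / rho),
        max((abs(s) for _, _, s in inlet_speeds), default=0.0),
        1e-3,
    )
    gs = [1.0 if _AXIS_NAMES[d] in num.slip_axes else -1.0 for d in range(3)]
    interior_masks = [t == _INTERIOR for t in types]
    valid_masks = [t != _SOLID for t in types]

    def apply_inlets(ramp):
        for axis, idx, inward in inlet_speeds:
            vel[axis][idx] = ramp * inward

    def compute_divergence():
        div = (
            (vel[0][1:] - vel[0][:-1])
            + (vel[1][:, 1:] - vel[1][:, :-1])
            + (vel[2][:, :, 1:] - vel[2][:, :, :-1])
        ) / h
        return div

    p3d = np.full(F.shape, np.nan)
    p_vec = np.full(n_cells, p_mean)
    residuals = []
    vmax = v_bc_scale
    converged = False
    stationary = False
    # window accumulators for the limit-cycle (statistical steady state) path
    W = max(num.stat_window, 10)
    win_vel = [np.zeros_like(a) for a in vel]
    win_p = np.zeros(n_cells)
    win_n = 0
    win_vmax = 0.0
    win_qout = 0.0
    prev_stats = None
    stat_hits = 0
    area_m2 = h * h
    it = 0
    for it in range(1, num.max_iter + 1):
        # convective (3 components worst case) and diffusive stability limits
        dt = num.cfl * min(
            h / (3.0 * max(vmax, 0.05 * v_bc_scale)), h * h / (6.0 * nu)
        )
        ramp = min(1.0, it / max(num.ramp_steps, 1))
        apply_inlets(ramp)
        old = [a.copy() for a in vel]

        stars = []
        for d in range(3):
            stars.append(
                _momentum_star(
                    d, vel, types, interior_masks, valid_masks, gs, h, nu, dt
                )
            )
        for d in range(3):
            vel[d][interior_masks[d]] = stars[d][interior_masks[d]]
        apply_inlets(ramp)
        # outlet faces: zero-gradient copy of the same-axis inward neighbor
        for axis, idx, nb_idx, sign, p_pa, cid in outlet_meta:
            vel[axis][idx] = vel[axis][nb_idx]

        div = compute_divergence()
        rhs = (rho / dt) * np.where(F, div, 0.0)[F]
        for axis, idx, nb_idx, sign, p_pa, cid in outlet_meta:
            p_eff = p_mean + ramp * (p_pa - p_mean)
            np.add.at(rhs, cid, -2.0 * inv_h2 * p_eff)
        p_vec = lu.solve(rhs)
        p3d[F] = p_vec

        # project interior faces
        for d in range(3):
            fidx_t, hi_id, lo_id = proj_idx[d]
            vel[d][fidx_t] -= (dt / rho) * (p_vec[hi_id] - p_vec[lo_id]) / h
        # project outlet faces (one-sided half-cell gradient)
        for axis, idx, nb_idx, sign, p_pa, cid in outlet_meta:
            p_eff = p_mean + ramp * (p_pa - p_mean)
            grad = sign * (p_eff - p_vec[cid]) * 2.0 / h
            vel[axis][idx] = vel[axis][idx] - (dt / rho) * grad

        vmax = max(float(np.max(np.abs(a))) for a in vel)
        change = max(float(np.max(np.abs(a - o))) for a, o in zip(vel, old))
        # floor the scale so quiescent (zero-flow) states can converge
        resid = change / max(vmax, 1e-3 * v_bc_scale)
        residuals.append(resid)
        if not np.isfinite(vmax) or vmax > 100.0 * v_bc_scale:
            raise SolverError(
                f"solver diverged at iteration {it} (|v|max = {vmax:.3g} m/s); "
                f"reduce the CFL number or refine the grid"
            )
        if it > num.ramp_steps + 5 and resid < num.rtol:
            converged = True
            break
        # windowed statistics (engaged after the ramp)
        if it > num.ramp_steps:
            for d in range(3):
                win_vel[d] += vel[d]
            win_p += p_vec
            win_vmax += vmax
            q = 0.0
            for axis, idx, nb_idx, sign, p_pa, cid in outlet_meta:
                q += sign * float(np.sum(vel[axis][idx])) * area_m2
            win_qout += q
            win_n += 1
            if win_n == W:
                stats = (win_vmax / W, win_qout / W)
                if prev_stats is not None:
                    d_v = abs(stats[0] - prev_stats[0]) / (abs(stats[0]) + 1e-30)
                    d_q = abs(stats[1] - prev_stats[1]) / (abs(stats[1]) + 1e-30)
                    stat_hits = stat_hits + 1 if max(d_v, d_q) < num.stat_tol else 0
                prev_stats = stats
                if stat_hits >= 2:
                    for d in range(3):
                        vel[d] = win_vel[d] / W
                    p_vec = win_p / W
                    p3d[F] = p_vec
                    apply_inlets(1.0)
                    converged = True
                    stationary = True
                    break
                for d in range(3):
                    win_vel[d][:] = 0.0
                win_p[:] = 0.0
                win_vmax = win_qout = 0.0
                win_n = 0

    imbalance = _global_imbalance(vel, domain, types, h)
    div = compute_divergence()
    vmax = max(float(np.max(np.abs(a))) for a in vel)
    div_norm = float(np.max(np.abs(np.where(F, div, 0.0)))) * h / max(
        vmax, 1e-3 * v_bc_scale
    )
    converged = converged and imbalance <= num.mass_tol

    field = FlowField(
        u=vel[0],
        v=vel[1],
        w=vel[2],
        pressure=p3d,
        converged=converged,
        residuals=np.asarray(residuals),
        mass_imbalance=imbalance,
        phase=bc.phase,
        meta=dict(
            iterations=it,
            dt=dt,
            stationary_cycle=stationary,
            div_norm=div_norm,
            reference_pressure_mmhg=bc.reference_pressure_mmhg,
            reynolds=_reynolds(vmax, domain, fluid),
            frozen_cells=int(frozen.sum()),
        ),
    )
    return field


def _momentum_star(d, vel, types, interior_masks, valid_masks, gs, h, nu, dt):
    """Provisional velocity for the faces normal to axis ``d``.

    Works in a permuted frame where the face-normal axis is first; upwind
    convection, central diffusion with mirrored ghosts for tangential
    neighbors lying inside walls (sign −1 no-slip, +1 free-slip).
    """
    t1, t2 = [a for a in range(3) if a != d]
    perm = (d, t1, t2)
    U = np.transpose(vel[d], perm)
    V1 = np.transpose(vel[t1], perm)
    V2 = np.transpose(vel[t2], perm)
    TU = np.transpose(valid_masks[d], perm)
    g1, g2 = gs[t1], gs[t2]

    def shift(a, axis, step):
        out = np.zeros_like(a)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        if step > 0:
            src[axis] = slice(step, None)
            dst[axis] = slice(0, -step)
        else:
            src[axis] = slice(0, step)
            dst[axis] = slice(-step, None)
        out[tuple(dst)] = a[tuple(src)]
        return out

    # neighbors along the normal axis (always physically valid; walls hold 0)
    U_e, U_w = shift(U, 0, 1), shift(U, 0, -1)

    # tangential neighbors with ghost mirroring across walls
    def tangential(axis, g):
        nb = shift(U, axis, 1)
        ok = shift(TU, axis, 1)
        nb_hi = np.where(ok, nb, g * U)
        nb = shift(U, axis, -1)
        ok = shift(TU, axis, -1)
        nb_lo = np.where(ok, nb, g * U)
        return nb_lo, nb_hi

    U_s1, U_n1 = tangential(1, g1)
    U_s2, U_n2 = tangential(2, g2)

    # advecting tangential velocities averaged to the U face.  In the
    # permuted frame V1 is staggered along axis 1 and V2 along axis 2; the
    # U face at normal index i sits between cells i-1 and i.
    def face_avg(V, axis):
        Vp = np.pad(V, ((1, 1), (0, 0), (0, 0)))
        lo = Vp[:-1]
        hi = Vp[1:]
        cell_pair = 0.5 * (lo + hi)  # averaged across the normal direction
        sl0 = [slice(None)] * 3
        sl1 = [slice(None)] * 3
        sl0[axis] = slice(0, -1)
        sl1[axis] = slice(1, None)
        return 0.5 * (cell_pair[tuple(sl0)] + cell_pair[tuple(sl1)])

    V1f = face_avg(V1, 1)
    V2f = face_avg(V2, 2)

    dUdn = np.where(U > 0, (U - U_w) / h, (U_e - U) / h)
    dUd1 = np.where(V1f > 0, (U - U_s1) / h, (U_n1 - U) / h)
    dUd2 = np.where(V2f > 0, (U - U_s2) / h, (U_n2 - U) / h)
    conv = U * dUdn + V1f * dUd1 + V2f * dUd2
    lap = (
        (U_e + U_w - 2 * U) + (U_n1 + U_s1 - 2 * U) + (U_n2 + U_s2 - 2 * U)
    ) / h**2
    star = U + dt * (nu * lap - conv)
    return np.transpose(star, np.argsort(perm))


def patch_flux(field: FlowField, domain: ComputationalDomain, name: str) -> float:
    """Signed outward volumetric flux through a patch, ml/s."""
    patch = domain.patches[name]
    vel = (field.u, field.v, field.w)[patch.axis]
    f = patch.faces
    idx = (f[:, 0], f[:, 1], f[:, 2])
    area = (domain.spacing * MM_TO_M) ** 2
    q = patch.sign * float(np.sum(vel[idx])) * area  # m³/s outward
    return q * M3_TO_ML


def check_mass_balance(field: FlowField, domain: ComputationalDomain) -> float:
    """|total inflow − total outflow| / max(total inflow, ε) over patches."""
    q_in = 0.0
    q_out = 0.0
    for name in domain.patches:
        q = patch_flux(field, domain, name)
        if q >= 0:
            q_out += q
        else:
            q_in -= q
    if q_in <= 1e-12 and q_out <= 1e-12:
        return 0.0
    return abs(q_in - q_out) / max(q_in, 1e-12)


def _global_imbalance(vel, domain, types, h):
    q_in = q_out = 0.0
    area = h * h
    for d in range(3):
        t = types[d]
        for code in (_INLET, _OUTLET):
            faces = np.argwhere(t == code)
            if len(faces) == 0:
                continue
            vals = vel[d][tuple(faces.T)]
            # determine sign per face: exterior side is where the neighbor
            # cell is missing/solid
            lo = faces.copy()
            lo[:, d] -= 1
            lo_ok = (lo[:, d] >= 0)
            lo_fluid = np.zeros(len(faces), dtype=bool)
            lo_fluid[lo_ok] = domain.fluid_mask[tuple(lo[lo_ok].T)]
            sign = np.where(lo_fluid, 1.0, -1.0)
            q = sign * vals * area
            q_out += float(q[q > 0].sum())
            q_in -= float(q[q < 0].sum())
    if q_in <= 1e-12 and q_out <= 1e-12:
        return 0.0
    return abs(q_in - q_out) / max(q_in, 1e-12)


def _reynolds(vmax, domain, fluid):
    regions = domain.meta.get("orifice_regions") or []
    areas = [r.area for r in regions if r.area > 0]
    if areas:
        d_eq = np.sqrt(4.0 * min(areas) / np.pi) * MM_TO_M
    else:
        d_eq = min(domain.shape) * domain.spacing * MM_TO_M
    return fluid.density * vmax * d_eq / fluid.dynamic_viscosity
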