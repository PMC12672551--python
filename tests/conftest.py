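"""Shared fixtures.

The expensive solver runs are session-scoped and reused across test
modules; they are deliberately coarse (1–2.5 mm voxels, truncated
chambers) to keep the suite fast while exercising the full physics.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import mitraflow as mf
from mitraflow.domain_builder import (
    box_channel,
    label_boundaries,
    orifice_plate,
    voxelize_anatomy,
)
from mitraflow.flow_solver import (
    BoundaryConditions,
    NumericsConfig,
    derive_flow_rates,
    solve_steady,
)
from mitraflow.units import MMHG_TO_PA

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_anatomy():
    """Central 8×5 mm coaptation defect on otherwise default anatomy."""
    return mf.make_valve_anatomy(defects=[(19.0, 8.0, 5.0)], chamber_extents=(15.0, 15.0))


# ---------------------------------------------------------------------------
# Analytic benchmark solves
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def poiseuille_case():
    """Plane Poiseuille: gap 2h = 2 mm along x, slip in y, flow along z.

    Driven by a pressure difference of 0.64 Pa over L = 8 mm; the analytic
    centerline velocity is Δp·h²/(2ηL) = 0.01 m/s at Re ≈ 2.7.
    """
    nx, ny, nz = 16, 3, 64
    spacing = 0.125  # = h/8 for h = 1 mm
    dom = box_channel((nx, ny, nz), spacing, phase="diastole")
    dp_pa = 0.64
    bc = BoundaryConditions(
        phase="diastole",
        patch_bcs={
            "INLET": ("pressure", dp_pa / MMHG_TO_PA),
            "OUTLET_LVOT": ("pressure", 0.0),
        },
    )
    num = NumericsConfig(rtol=1e-6, max_iter=8000, slip_axes=("y",))
    field = solve_steady(dom, bc=bc, num=num)
    params = dict(h=1e-3, L=nz * spacing * 1e-3, dp=dp_pa, eta=0.004, ny=ny, nz=nz)
    return dom, field, params


@pytest.fixture(scope="session")
def orifice_jet_case():
    """High-Re jet through a 6×6 mm orifice plate at Δp = 10 mmHg.

    The high pressure sits on the top patch so the jet forms below the
    plate, matching the diastolic (atrium-above) orientation the region
    helpers assume.
    """
    dom = orifice_plate(
        (20, 20, 24), 1.0, orifice_half_cells=(3, 3), plate_thickness_cells=2,
        phase="diastole",
    )
    dp_mmhg = 10.0
    bc = BoundaryConditions(
        phase="diastole",
        patch_bcs={"INLET": ("pressure", 0.0), "OUTLET_LVOT": ("pressure", dp_mmhg)},
    )
    field = solve_steady(dom, bc=bc, num=NumericsConfig(rtol=5e-5, max_iter=8000))
    return dom, field, dp_mmhg


# ---------------------------------------------------------------------------
# Anatomy solves
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def systolic_case(default_anatomy):
    """Converged systolic solve of the default regurgitant anatomy (2 mm)."""
    a = default_anatomy
    dom = label_boundaries(voxelize_anatomy(a, "systole", 2.0), "systole")
    rates = derive_flow_rates(a.stroke_volume, a.t_sys, a.t_dia)
    field = solve_steady(
        dom,
        bc=BoundaryConditions.systole(rates.Q_sys),
        num=NumericsConfig(rtol=2e-4, max_iter=4000),
    )
    return a, dom, field


@pytest.fixture(scope="session")
def systolic_case_high_la(default_anatomy):
    """Same anatomy with the left-atrial outlet pressure raised to 40 mmHg."""
    a = default_anatomy
    dom = label_boundaries(voxelize_anatomy(a, "systole", 2.0), "systole")
    rates = derive_flow_rates(a.stroke_volume, a.t_sys, a.t_dia)
    field = solve_steady(
        dom,
        bc=BoundaryConditions.systole(rates.Q_sys, p_la=40.0),
        num=NumericsConfig(rtol=2e-4, max_iter=4000),
    )
    return a, dom, field


@pytest.fixture(scope="session")
def diastole_pair():
    """Diastolic solves before and after an oversized (14 mm) clip.

    A reduced diastolic opening (open fraction 0.2) keeps the transvalvular
    velocities in the clinically interesting range so the gradient response
    to the clip is well resolved on the coarse grid.
    """
    base = mf.make_valve_anatomy(
        defects=[(19.0, 8.0, 5.0)],
        chamber_extents=(15.0, 15.0),
        diastolic_open_fraction=0.2,
    )
    clipped = mf.implant_device(
        base, mf.DeviceSpec("XTw", position_s=19.0, grasping_width=14.0)
    )
    num = NumericsConfig(rtol=2e-4, max_iter=4000)
    out = {}
    for name, anatomy in (("baseline", base), ("clipped", clipped)):
        dom = label_boundaries(voxelize_anatomy(anatomy, "diastole", 2.0), "diastole")
        rates = derive_flow_rates(anatomy.stroke_volume, anatomy.t_sys, anatomy.t_dia)
        field = solve_steady(dom, bc=BoundaryConditions.diastole(rates.Q_dia), num=num)
        out[name] = (anatomy, dom, field)
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """Four-patient cohort at coarse resolution (baseline + one device)."""
    from mitraflow.pipeline import run_cohort

    return run_cohort(
        {"resolution": 2.5, "numerics": {"rtol": 3e-4, "max_iter": 3000}},
        n=4,
        seed=11,
    )


# ---------------------------------------------------------------------------
# Synthetic analytic flow fields
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def point_sink_field():
    """Hemispheric point-sink field v(r) = Q/(2πr²) toward a sink point.

    Constructed on an all-fluid 40 mm box; the sink sits on the top face
    center so the converging hemisphere fills the box below it — the ideal
    geometry in which the hemispheric PISA formula is exact.
    """
    from mitraflow.flow_solver import FlowField

    n = 40
    spacing = 1.0
    dom = box_channel((n, n, n), spacing, phase="systole", outlet_name="OUTLET_LA")
    q_m3 = 110.0e-6  # 110 ml/s
    sink = np.array([n / 2 * spacing, n / 2 * spacing, n * spacing])  # top center, mm

    def face_vel(axis):
        shape = [n, n, n]
        shape[axis] += 1
        coords = [dom.origin[d] + spacing * (np.arange(shape[d]) - (0.5 if d == axis else 0.0)) for d in range(3)]
        X, Y, Z = np.meshgrid(*coords, indexing="ij")
        dx = np.stack([X - sink[0], Y - sink[1], Z - sink[2]])
        r = np.sqrt((dx**2).sum(axis=0)) * 1e-3  # m
        r = np.maximum(r, 1.5e-3)  # cap the singularity
        speed = q_m3 / (2.0 * np.pi * r**2)
        return -speed * dx[axis] * 1e-3 / r  # unit vector toward the sink

    field = FlowField(
        u=face_vel(0),
        v=face_vel(1),
        w=face_vel(2),
        pressure=np.zeros((n, n, n)),
        converged=True,
        residuals=np.array([]),
        mass_imbalance=0.0,
        phase="systole",
    )
    return dom, field, dict(q_ml=110.0, sink=sink)
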