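"""Hemodynamic endpoints: flux integrals, EROA, peak velocity, gradients."""

import numpy as np
import pytest

from mitraflow.domain_builder import box_channel, orifice_plate
from mitraflow.flow_solver import (
    BoundaryConditions,
    FlowField,
    NumericsConfig,
    patch_flux,
    solve_steady,
)
from mitraflow.hemodynamics import (
    PhaseError,
    eroa_cfd,
    mean_diastolic_gradient,
    peak_velocity,
    regurgitant_flow,
    regurgitant_volume,
)
from mitraflow.units import MMHG_TO_PA


def _uniform_flow_field(dom, w_value, phase="systole"):
    nx, ny, nz = dom.shape
    return FlowField(
        u=np.zeros((nx + 1, ny, nz)),
        v=np.zeros((nx, ny + 1, nz)),
        w=np.full((nx, ny, nz + 1), w_value),
        pressure=np.zeros((nx, ny, nz)),
        converged=True,
        residuals=np.array([]),
        mass_imbalance=0.0,
        phase=phase,
    )


class TestRegurgitantFlow:
    def test_plug_flow_flux_integral(self):
        # 1 m/s through a 40 mm² outlet: 8×5 cells at 1 mm spacing
        dom = box_channel((8, 5, 10), 1.0, phase="systole", outlet_name="OUTLET_LA")
        field = _uniform_flow_field(dom, 1.0)
        assert regurgitant_flow(field, dom) == pytest.approx(40.0)

    def test_sealed_valve_zero(self):
        dom = box_channel((4, 4, 6), 1.0, phase="systole", outlet_name="OUTLET_LA")
        field = _uniform_flow_field(dom, 0.0)
        assert regurgitant_flow(field, dom) == 0.0

    def test_wrong_phase_rejected(self):
        dom = box_channel((4, 4, 6), 1.0, phase="diastole", outlet_name="OUTLET_LA")
        field = _uniform_flow_field(dom, 1.0, phase="diastole")
        with pytest.raises(PhaseError):
            regurgitant_flow(field, dom)

    def test_conservation_on_solved_systole(self, systolic_case):
        _, dom, field = systolic_case
        q_in = -patch_flux(field, dom, "INLET")
        q_la = patch_flux(field, dom, "OUTLET_LA")
        q_lvot = patch_flux(field, dom, "OUTLET_LVOT")
        assert q_la + q_lvot == pytest.approx(q_in, rel=0.01)


class TestScalarEndpoints:
    @pytest.mark.parametrize(
        "q,t,rv", [(100.0, 0.35, 35.0), (0.0, 0.5, 0.0), (114.2857, 0.35, 40.0)]
    )
    def test_regurgitant_volume(self, q, t, rv):
        assert regurgitant_volume(q, t) == pytest.approx(rv, rel=1e-4)

    def test_regurgitant_volume_validation(self):
        with pytest.raises(ValueError):
            regurgitant_volume(-1.0, 0.35)
        with pytest.raises(ValueError):
            regurgitant_volume(10.0, 0.0)

    @pytest.mark.parametrize("q,v,area", [(60.0, 4.0, 15.0), (0.0, 1.0, 0.0)])
    def test_eroa_unit_converted_division(self, q, v, area):
        assert eroa_cfd(q, v) == pytest.approx(area)

    def test_eroa_zero_velocity_with_flow_rejected(self):
        with pytest.raises(ValueError):
            eroa_cfd(10.0, 0.0)


class TestPeakVelocity:
    def test_zero_flow_field(self):
        dom = box_channel((4, 4, 6), 1.0, phase="systole")
        assert peak_velocity(_uniform_flow_field(dom, 0.0), dom, region="all") == 0.0

    def test_matches_poiseuille_centerline(self, poiseuille_case):
        dom, field, p = poiseuille_case
        analytic = p["dp"] * p["h"] ** 2 / (2 * p["eta"] * p["L"])
        assert peak_velocity(field, dom, region="all") == pytest.approx(analytic, rel=0.03)

    def test_orifice_jet_against_bernoulli(self, orifice_jet_case):
        dom, field, dp_mmhg = orifice_jet_case
        v_torricelli = np.sqrt(2 * dp_mmhg * MMHG_TO_PA / 1060.0)
        assert peak_velocity(field, dom, region="jet") == pytest.approx(
            v_torricelli, rel=0.15
        )

    def test_unknown_region_rejected(self, poiseuille_case):
        dom, field, _ = poiseuille_case
        with pytest.raises(ValueError):
            peak_velocity(field, dom, region="atrium")


class TestEroaOnSolvedOrifice:
    def test_effective_area_below_anatomic(self, orifice_jet_case):
        """Vena-contracta physics: continuity EROA ≤ anatomic orifice area."""
        dom, field, _ = orifice_jet_case
        q_out = patch_flux(field, dom, "INLET")  # flow exits the bottom patch
        v_max = peak_velocity(field, dom, region="jet")
        anatomic = dom.meta["orifice_regions"][0].area
        assert 0 < eroa_cfd(q_out, v_max) <= anatomic


class TestDiastolicGradient:
    def test_zero_flow_zero_gradient(self):
        dom = box_channel((4, 4, 20), 1.0, phase="diastole")
        field = _uniform_flow_field(dom, 0.0, phase="diastole")
        mpg = mean_diastolic_gradient(field, dom, plane_z=(15.0, 5.0))
        assert mpg == 0.0

    def test_channel_recovers_imposed_pressure_drop(self, poiseuille_case):
        dom, field, p = poiseuille_case
        zs = dom.cell_centers_1d(2)
        z_v, z_a = zs[8], zs[-9]
        mpg = mean_diastolic_gradient(field, dom, plane_z=(z_a, z_v))
        # flow runs toward +z here, so the 'atrial' plane is downstream and
        # the drop appears with negative sign
        expected = -p["dp"] * (z_a - z_v) / (p["L"] * 1e3) / MMHG_TO_PA
        assert mpg == pytest.approx(expected, rel=0.03)

    def test_wrong_phase_rejected(self, systolic_case):
        _, dom, field = systolic_case
        with pytest.raises(PhaseError):
            mean_diastolic_gradient(field, dom)

    def test_clip_restriction_raises_gradient(self, diastole_pair):
        _, dom0, f0 = diastole_pair["baseline"]
        _, dom1, f1 = diastole_pair["clipped"]
        assert f0.converged and f1.converged
        assert mean_diastolic_gradient(f1, dom1) > mean_diastolic_gradient(f0, dom0)


class TestRotationInvariance:
    def test_orifice_endpoints_invariant_under_quarter_turn(self):
        """A 90° rotation about the flow axis permutes the grid axes; the
        solver and endpoints must not care."""
        results = {}
        # low driving pressure: a genuinely steady laminar jet, so the two
        # orientations must agree to solver precision, not just on average
        for name, half_cells, shape in (
            ("original", (3, 2), (20, 16, 20)),
            ("rotated", (2, 3), (16, 20, 20)),
        ):
            dom = orifice_plate(shape, 1.0, orifice_half_cells=half_cells, phase="diastole")
            bc = BoundaryConditions(
                phase="diastole",
                patch_bcs={"INLET": ("pressure", 0.5), "OUTLET_LVOT": ("pressure", 0.0)},
            )
            f = solve_steady(dom, bc=bc, num=NumericsConfig(rtol=1e-5, max_iter=6000))
            assert f.converged
            results[name] = (
                patch_flux(f, dom, "OUTLET_LVOT"),
                peak_velocity(f, dom, region="all"),
            )
        q0, v0 = results["original"]
        q1, v1 = results["rotated"]
        assert q0 == pytest.approx(q1, rel=1e-4)
        assert v0 == pytest.approx(v1, rel=1e-4)
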