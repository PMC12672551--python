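"""Solver verification against analytic oracles and conservation audits."""

import numpy as np
import pytest

from mitraflow.domain_builder import box_channel
from mitraflow.flow_solver import (
    BoundaryConditions,
    FluidProperties,
    NumericsConfig,
    SolverError,
    check_mass_balance,
    derive_flow_rates,
    patch_flux,
    solve_steady,
)
from mitraflow.units import MMHG_TO_PA


class TestDeriveFlowRates:
    @pytest.mark.parametrize(
        "sv,ts,td,expected",
        [
            (70.0, 0.35, 0.65, (200.0, 70.0 / 0.65)),
            (0.0, 0.3, 0.5, (0.0, 0.0)),
            (60.0, 0.3, 0.5, (200.0, 120.0)),
        ],
    )
    def test_direct_division(self, sv, ts, td, expected):
        q = derive_flow_rates(sv, ts, td)
        assert q.Q_sys == pytest.approx(expected[0])
        assert q.Q_dia == pytest.approx(expected[1])

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            derive_flow_rates(70.0, 0.0, 0.65)
        with pytest.raises(ValueError):
            derive_flow_rates(-1.0, 0.35, 0.65)


class TestPoiseuille:
    def test_centerline_velocity_within_3_percent(self, poiseuille_case):
        dom, field, p = poiseuille_case
        assert field.converged
        wc = 0.5 * (field.w[:, :, :-1] + field.w[:, :, 1:])
        w_max = wc[:, p["ny"] // 2, p["nz"] // 2].max()
        analytic = p["dp"] * p["h"] ** 2 / (2 * p["eta"] * p["L"])
        assert w_max == pytest.approx(analytic, rel=0.03)

    def test_profile_is_parabolic(self, poiseuille_case):
        dom, field, p = poiseuille_case
        wc = 0.5 * (field.w[:, :, :-1] + field.w[:, :, 1:])
        prof = wc[:, p["ny"] // 2, p["nz"] // 2]
        x = (np.arange(len(prof)) + 0.5) / len(prof) * 2.0 - 1.0  # in units of h
        fit = np.polyfit(x, prof, 2)
        pred = np.polyval(fit, x)
        assert np.max(np.abs(prof - pred)) < 0.02 * prof.max()

    def test_mass_balance_and_divergence(self, poiseuille_case):
        dom, field, _ = poiseuille_case
        assert check_mass_balance(field, dom) <= 0.01
        assert field.meta["div_norm"] <= 1e-6

    def test_refinement_error_decreases_monotonically(self):
        """Square-duct flow against its Fourier-series solution.

        The plane-Poiseuille parabola is reproduced exactly by the
        second-order stencil, so refinement convergence is checked on the
        rectangular duct whose profile is not polynomial.
        """

        def duct_max_velocity(a, b, G, eta, nterms=199):
            total = 0.0
            for n in range(1, nterms + 1, 2):
                sign = (-1) ** ((n - 1) // 2)
                total += sign * (1 - 1 / np.cosh(n * np.pi * b / (2 * a))) / n**3
            return 16 * a**2 * G / (eta * np.pi**3) * total

        dp_pa, L, eta = 0.64, 8e-3, 0.004
        analytic = duct_max_velocity(1e-3, 1e-3, dp_pa / L, eta)
        errors = []
        for nx in (4, 8, 16):
            spacing = 2.0 / nx
            nz = int(8.0 / spacing)
            dom = box_channel((nx, nx, nz), spacing, phase="diastole")
            bc = BoundaryConditions(
                phase="diastole",
                patch_bcs={
                    "INLET": ("pressure", dp_pa / MMHG_TO_PA),
                    "OUTLET_LVOT": ("pressure", 0.0),
                },
            )
            f = solve_steady(dom, bc=bc, num=NumericsConfig(rtol=1e-6, max_iter=10000))
            errors.append(abs(f.speed().max() - analytic) / analytic)
        assert errors[0] > errors[1] > errors[2]


class TestOrificeJet:
    def test_peak_velocity_within_15_percent_of_torricelli(self, orifice_jet_case):
        dom, field, dp_mmhg = orifice_jet_case
        assert field.converged
        v_torricelli = np.sqrt(2.0 * dp_mmhg * MMHG_TO_PA / 1060.0)
        v_max = field.speed()[dom.fluid_mask].max()
        assert v_max == pytest.approx(v_torricelli, rel=0.15)

    def test_mass_balance(self, orifice_jet_case):
        dom, field, _ = orifice_jet_case
        assert check_mass_balance(field, dom) <= 0.01


class TestDegenerateCases:
    def test_zero_flow_equal_pressures_gives_rest_state(self):
        dom = box_channel((6, 6, 10), 1.0, phase="diastole")
        bc = BoundaryConditions(
            phase="diastole",
            patch_bcs={"INLET": ("pressure", 5.0), "OUTLET_LVOT": ("pressure", 5.0)},
        )
        f = solve_steady(dom, bc=bc, num=NumericsConfig(rtol=1e-6, max_iter=500))
        assert f.converged
        assert f.speed().max() < 1e-10
        p = f.pressure[dom.fluid_mask]
        assert np.allclose(p, 5.0 * MMHG_TO_PA, atol=1e-6)
        assert check_mass_balance(f, dom) == 0.0

    def test_truncated_solve_flagged_non_converged(self):
        dom = box_channel((6, 6, 12), 1.0, phase="diastole")
        bc = BoundaryConditions(
            phase="diastole",
            patch_bcs={"INLET": ("velocity", 20.0), "OUTLET_LVOT": ("pressure", 0.0)},
        )
        f = solve_steady(dom, bc=bc, num=NumericsConfig(max_iter=1, ramp_steps=1))
        assert not f.converged

    def test_missing_pressure_patch_rejected(self):
        with pytest.raises(ValueError, match="pressure"):
            BoundaryConditions(
                phase="diastole", patch_bcs={"INLET": ("velocity", 10.0)}
            )

    def test_phase_mismatch_rejected(self, systolic_case):
        _, dom, _ = systolic_case
        with pytest.raises(SolverError, match="phase"):
            solve_steady(dom, bc=BoundaryConditions.diastole(50.0))

    def test_zero_area_inlet_rejected(self):
        dom = box_channel((4, 4, 8), 1.0, phase="diastole")
        dom.patches["INLET"].faces = dom.patches["INLET"].faces[:0]
        bc = BoundaryConditions(
            phase="diastole",
            patch_bcs={"INLET": ("velocity", 10.0), "OUTLET_LVOT": ("pressure", 0.0)},
        )
        with pytest.raises(SolverError, match="zero area"):
            solve_steady(dom, bc=bc)


class TestSystolicAnatomy:
    def test_converges_with_mass_balance(self, systolic_case):
        _, dom, field = systolic_case
        assert field.converged
        assert field.mass_imbalance <= 0.01
        assert field.meta["reynolds"] > 0

    def test_velocity_inlet_carries_prescribed_flow(self, systolic_case):
        a, dom, field = systolic_case
        q_in = patch_flux(field, dom, "INLET")
        assert -q_in == pytest.approx(200.0, rel=1e-6)  # inward

    def test_raising_la_pressure_reduces_regurgitation(
        self, systolic_case, systolic_case_high_la
    ):
        from mitraflow.hemodynamics import regurgitant_flow

        _, dom0, f0 = systolic_case
        _, dom1, f1 = systolic_case_high_la
        assert regurgitant_flow(f1, dom1) < regurgitant_flow(f0, dom0)


class TestFluidProperties:
    def test_defaults_are_blood(self):
        fp = FluidProperties()
        assert fp.density == 1060.0
        assert fp.dynamic_viscosity == 0.004

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            FluidProperties(density=0.0)


def test_residual_log_round_trip(poiseuille_case, tmp_path):
    _, field, _ = poiseuille_case
    path = tmp_path / "residuals.csv"
    field.save_residuals_csv(path)
    lines = path.read_text().splitlines()
    assert lines[0] == "iteration,residual"
    assert len(lines) == len(field.residuals) + 1
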