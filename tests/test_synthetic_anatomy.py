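"""Anatomy generator: validation, ellipse solving, sampling, surfaces."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, strategies as st

import mitraflow as mf
from mitraflow.domain_builder import orifice_area, voxelize_anatomy
from mitraflow.synthetic_anatomy import (
    AnatomyValidationError,
    PopulationModel,
    anatomy_from_dict,
    anatomy_from_json,
    anatomy_to_dict,
    anatomy_to_json,
    ellipse_axes_from_area_perimeter,
    load_anatomy_yaml,
    ramanujan_perimeter,
    sample_population,
    save_anatomy_yaml,
    truncated_normal_moments,
)


class TestMakeValveAnatomy:
    def test_defaults_match_population_means(self):
        a = mf.make_valve_anatomy()
        assert a.annulus_area_sys == 1595.0
        assert a.annulus_perimeter_sys == 141.0
        assert a.stroke_volume == 70.0
        assert (a.t_sys, a.t_dia) == (0.35, 0.65)

    def test_sealed_default_has_zero_orifice(self):
        a = mf.make_valve_anatomy(defects=[])
        assert a.anatomic_orifice_area_sys == 0.0

    def test_central_slit_area_is_width_times_gap(self):
        a = mf.make_valve_anatomy(defects=[(19.0, 8.0, 5.0)])
        assert a.anatomic_orifice_area_sys == pytest.approx(40.0)

    @pytest.mark.parametrize(
        "bad",
        [
            {"annulus_area_sys": -1.0},
            {"leaflet_length": 0.0},
            {"t_sys": -0.1},
            {"lvot_diameter": 0.0},
        ],
    )
    def test_nonpositive_dimension_names_field(self, bad):
        with pytest.raises(AnatomyValidationError) as exc:
            mf.make_valve_anatomy(**bad)
        assert list(bad)[0] in str(exc.value)

    def test_defect_outside_coaptation_line_rejected(self):
        with pytest.raises(AnatomyValidationError, match="coaptation line"):
            mf.make_valve_anatomy(defects=[(37.0, 8.0, 5.0)])  # extends past 38

    def test_unknown_parameter_rejected(self):
        with pytest.raises(AnatomyValidationError, match="unknown"):
            mf.make_valve_anatomy(annulus_radius=10.0)


class TestEllipseSolver:
    def test_near_circular_pair_clamps_to_circle(self):
        # the default pair's perimeter is 0.4% below the circle bound
        a, b = ellipse_axes_from_area_perimeter(1595.0, 141.0)
        assert a == pytest.approx(b)
        assert np.pi * a * b == pytest.approx(1595.0)
        assert abs(ramanujan_perimeter(a, b) - 141.0) / 141.0 < 0.05

    def test_grossly_inconsistent_pair_rejected(self):
        with pytest.raises(AnatomyValidationError):
            ellipse_axes_from_area_perimeter(1595.0, 110.0)

    @given(
        area=st.floats(500.0, 3000.0),
        k=st.floats(0.3, 0.999),
    )
    def test_round_trip_area_and_perimeter(self, area, k):
        a_true = np.sqrt(area / (np.pi * k))
        p = ramanujan_perimeter(a_true, k * a_true)
        a, b = ellipse_axes_from_area_perimeter(area, p)
        assert np.pi * a * b == pytest.approx(area, rel=1e-9)
        assert ramanujan_perimeter(a, b) == pytest.approx(p, rel=1e-9)


class TestPopulation:
    def test_zero_variance_model_gives_identical_anatomies(self):
        model = PopulationModel(
            annulus_area_sys=(1500.0, 0.0),
            area_dia_over_sys=(1.02, 0.0),
            axis_ratio_range=(0.9, 0.9),
            stroke_volume=(70.0, 0.0),
            leaflet_length=(10.0, 0.0),
            lvot_diameter=(20.0, 0.0),
            defect_width=(8.0, 0.0),
            defect_gap=(5.0, 0.0),
            defect_center_frac=(0.5, 0.0),
            seed=3,
        )
        pop = sample_population(model, 5)
        assert all(a == pop[0] for a in pop[1:])

    def test_sampling_reproducible_under_fixed_seed(self):
        a = sample_population(PopulationModel(seed=5), 20)
        b = sample_population(PopulationModel(seed=5), 20)
        assert a == b
        c = sample_population(PopulationModel(seed=6), 20)
        assert a != c

    def test_moment_recovery_at_scale(self):
        pop = sample_population(PopulationModel(seed=42), 10000)
        areas = np.array([a.annulus_area_sys for a in pop])
        perims = np.array([a.annulus_perimeter_sys for a in pop])
        assert abs(areas.mean() - 1595.0) / 1595.0 < 0.01
        assert abs(perims.mean() - 141.0) / 141.0 < 0.01
        # dispersion: sample SD matches both the quoted cohort SD (within
        # 5%) and the sampler's analytic truncated-normal SD (within 3%)
        sd = areas.std(ddof=1)
        assert abs(sd - 379.0) / 379.0 < 0.05
        _, sd_analytic = truncated_normal_moments(1595.0, 379.0, 400.0)
        assert abs(sd - sd_analytic) / sd_analytic < 0.03

    def test_every_sampled_anatomy_is_valid(self):
        pop = sample_population(PopulationModel(seed=9), 200)
        for a in pop:
            assert a.annulus_area_sys > 0
            for d in a.defects:
                assert 0 <= d.s_min and d.s_max <= a.coaptation_line_length

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            sample_population(PopulationModel(), 0)


class TestSurfaces:
    def test_watertight_and_genus_zero_single_defect(self, default_anatomy):
        mesh = mf.anatomy_to_surface(default_anatomy, "systole", pitch=0.8)
        assert mesh.is_watertight
        assert mesh.body_count == 1
        assert mesh.euler_number == 2

    def test_sealed_valve_two_separated_cavities(self):
        a = mf.make_valve_anatomy(chamber_extents=(15.0, 15.0))
        mesh = mf.anatomy_to_surface(a, "systole", pitch=0.8)
        assert mesh.is_watertight
        # atrial cavity and ventricle+LVOT cavity, each a closed genus-0 shell
        assert mesh.body_count == 2
        assert all(b.euler_number == 2 for b in mesh.split(only_watertight=False))

    def test_extra_slits_add_handles(self):
        a = mf.make_valve_anatomy(
            defects=[(12.0, 8.0, 5.0), (27.0, 4.0, 5.0)], chamber_extents=(15.0, 15.0)
        )
        mesh = mf.anatomy_to_surface(a, "systole", pitch=0.8)
        assert mesh.is_watertight
        # n parallel channels between the same two cavities give n−1 handles
        assert mesh.euler_number == 2 - 2 * (2 - 1)

    def test_diastolic_opening_area_matches_model(self, default_anatomy):
        a = default_anatomy
        mesh = mf.anatomy_to_surface(a, "diastole", pitch=0.6)
        assert mesh.is_watertight
        z_cut = -(a.leaflet_length + 1.5)  # mid coaptation channel
        section = mesh.section(plane_origin=[0, 0, z_cut], plane_normal=[0, 0, 1.0])
        area = section.to_2D()[0].area
        expected = a.diastolic_open_fraction * a.annulus_area_dia
        assert area == pytest.approx(expected, rel=0.05)

    def test_deterministic_meshes(self, default_anatomy):
        m1 = mf.anatomy_to_surface(default_anatomy, "systole", pitch=1.0)
        m2 = mf.anatomy_to_surface(default_anatomy, "systole", pitch=1.0)
        assert np.array_equal(m1.vertices, m2.vertices)
        assert np.array_equal(m1.faces, m2.faces)

    def test_invalid_phase_rejected(self, default_anatomy):
        with pytest.raises(ValueError, match="phase"):
            mf.anatomy_to_surface(default_anatomy, "mid-systole")

    def test_orifice_area_monotone_in_defect_width(self):
        areas = []
        for width in (4.0, 8.0, 12.0):
            a = mf.make_valve_anatomy(
                defects=[(19.0, width, 5.0)], chamber_extents=(12.0, 12.0)
            )
            dom = voxelize_anatomy(a, "systole", 0.8)
            areas.append(orifice_area(dom))
        assert areas[0] < areas[1] < areas[2]

    def test_stl_export_round_trip(self, default_anatomy, tmp_path):
        mesh = mf.anatomy_to_surface(default_anatomy, "systole", pitch=1.2)
        for name, ftype in (("a.stl", None), ("b.stl", "stl_ascii")):
            path = tmp_path / name
            mesh.export(path, file_type=ftype)
            back = mf.domain_builder.load_stl(path)
            assert back.is_watertight
            assert back.volume == pytest.approx(mesh.volume, rel=1e-4)


class TestSerialisation:
    def test_yaml_round_trip(self, default_anatomy, tmp_path):
        p = tmp_path / "anatomy.yaml"
        save_anatomy_yaml(default_anatomy, p)
        assert load_anatomy_yaml(p) == default_anatomy

    def test_json_round_trip_with_devices(self, default_anatomy):
        a = mf.implant_device(default_anatomy, mf.DeviceSpec("NT", position_s=19.0))
        assert anatomy_from_json(anatomy_to_json(a)) == a

    def test_dict_round_trip(self, default_anatomy):
        assert anatomy_from_dict(anatomy_to_dict(default_anatomy)) == default_anatomy
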