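import numpy as np
import pytest

from patellofem.geometry import (
    COARSE_RESOLUTION,
    ConfigurationError,
    DysplasiaParams,
    PatellaParams,
    build_knee,
    generate_patella,
    generate_trochlea,
)
from patellofem.metrics import bisect_offset, patellar_tilt, tt_tg


class TestTrochleaGenerator:
    def test_healthy_groove_positive_everywhere(self, healthy_knee):
        depths = [p.groove_depth() for p in healthy_knee.femur_grid.profiles]
        assert all(d > 0 for d in depths)

    def test_dysplastic_proximal_flat_or_convex(self, dysplastic_knee):
        prox = dysplastic_knee.femur_grid.profiles[-1]
        assert prox.groove_depth() <= 0.0

    def test_profiles_simple_polygons(self, healthy_knee, dysplastic_knee):
        for knee in (healthy_knee, dysplastic_knee):
            assert all(p.is_simple() for p in knee.femur_grid.profiles)

    def test_deterministic_with_zero_jitter(self):
        p = DysplasiaParams()
        m1, t1, lm1, _ = generate_trochlea(p, n_stations=9, n_arc=20, n_post=10, seed=1)
        m2, t2, lm2, _ = generate_trochlea(p, n_stations=9, n_arc=20, n_post=10, seed=2)
        assert np.array_equal(m1.vertices, m2.vertices)
        assert np.array_equal(t1.values, t2.values)
        assert np.array_equal(lm1["LC"], lm2["LC"])

    def test_jitter_changes_geometry_but_stays_watertight(self):
        p = DysplasiaParams()
        m1, *_ = generate_trochlea(p, n_stations=9, n_arc=20, n_post=10, seed=1,
                                   jitter=0.05)
        m2, *_ = generate_trochlea(p, n_stations=9, n_arc=20, n_post=10, seed=2,
                                   jitter=0.05)
        assert not np.array_equal(m1.vertices, m2.vertices)
        assert m1.is_watertight()

    def test_parameter_range_error_names_parameter(self):
        with pytest.raises(ConfigurationError, match="spur_height"):
            DysplasiaParams(spur_height=50.0)

    def test_too_few_stations_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_trochlea(DysplasiaParams(), n_stations=3)


@pytest.mark.parametrize("preset", ["healthy", "dysplastic_D"])
@pytest.mark.parametrize("seed", range(10))
def test_watertight_shells_across_seeds(preset, seed):
    knee = build_knee(preset, seed=seed, resolution=dict(
        n_stations=9, n_arc=20, n_post=10, n_sections=9, n_art=14, n_ant=8))
    knee.validate()  # watertight, outward, connected cartilage patch


class TestKneePresets:
    def test_required_landmarks_present(self, healthy_knee, dysplastic_knee):
        healthy_knee.validate()
        dysplastic_knee.validate()

    def test_clinical_index_targets(self, healthy_knee, dysplastic_knee):
        # dysplastic knee calibrated to TT-TG 17 mm, tilt 18, bisect 76;
        # healthy to TT-TG 9 mm, tilt 12, bisect 48.5 (start pose)
        assert tt_tg(dysplastic_knee) == pytest.approx(17.0, abs=0.5)
        assert tt_tg(healthy_knee) == pytest.approx(9.0, abs=0.5)
        assert patellar_tilt(dysplastic_knee) == pytest.approx(18.0, abs=0.5)
        assert patellar_tilt(healthy_knee) == pytest.approx(12.0, abs=0.5)
        assert bisect_offset(dysplastic_knee) == pytest.approx(76.0, abs=1.5)
        assert bisect_offset(healthy_knee) == pytest.approx(48.5, abs=1.5)

    def test_dysplastic_exceeds_healthy_malalignment(self, healthy_knee,
                                                     dysplastic_knee):
        assert tt_tg(dysplastic_knee) > tt_tg(healthy_knee)
        assert bisect_offset(dysplastic_knee) > bisect_offset(healthy_knee)

    def test_unknown_override_lists_valid_keys(self):
        with pytest.raises(ConfigurationError, match="valid keys"):
            build_knee("healthy", overrides={"nonsense_key": 1})

    def test_unknown_preset(self):
        with pytest.raises(ConfigurationError, match="valid presets"):
            build_knee("varus")

    def test_unloaded_standoff_no_overlap(self, healthy_knee):
        # placement contract: zero overlap between cartilage layers at start
        from patellofem.geometry.knee import trochlea_height_function

        h = trochlea_height_function(healthy_knee.femur_surface,
                                     healthy_knee.femur_grid)
        v = healthy_knee.patella_surface.vertices
        g = healthy_knee.femur_grid
        fx = healthy_knee.femur_surface.vertices
        xq = np.clip(v[:, 0], fx[g.vertex_ids[0, 0], 0],
                     fx[g.vertex_ids[0, g.n_arc - 1], 0])
        zq = np.clip(v[:, 2], g.z_stations[0], g.z_stations[-1])
        gap = v[:, 1] - h(xq, zq)
        assert gap.min() >= 0.0


class TestMirroring:
    def test_double_mirror_is_identity(self, healthy_knee):
        mm = healthy_knee.mirrored().mirrored()
        assert np.allclose(mm.femur_surface.vertices,
                           healthy_knee.femur_surface.vertices)
        assert np.array_equal(mm.femur_surface.triangles,
                              healthy_knee.femur_surface.triangles)
        assert mm.side == healthy_knee.side

    def test_mirror_flips_landmarks_exactly(self, healthy_knee):
        m = healthy_knee.mirrored()
        assert m.side == "left"
        lat = healthy_knee.landmarks["most_lateral_patellar_point"]
        lat_m = m.landmarks["most_lateral_patellar_point"]
        assert lat_m[0] == -lat[0]
        assert np.array_equal(lat_m[1:], lat[1:])


class TestPatellaGenerator:
    def test_lateral_ridge_offset_shifts_lateral_landmark(self, healthy_knee):
        base = PatellaParams()
        shifted = PatellaParams(center_x=base.center_x + 2.0)
        _, _, lm0, _ = generate_patella(
            base, healthy_knee.femur_surface, healthy_knee.femur_grid,
            n_sections=9, n_art=14, n_ant=8)
        _, _, lm2, _ = generate_patella(
            shifted, healthy_knee.femur_surface, healthy_knee.femur_grid,
            n_sections=9, n_art=14, n_ant=8)
        delta = lm2["most_lateral_patellar_point"] - lm0["most_lateral_patellar_point"]
        assert delta[0] == pytest.approx(2.0, abs=1e-9)

    def test_patella_wider_than_trochlea_rejected(self, healthy_knee):
        from patellofem.geometry import GeometryError

        with pytest.raises(GeometryError, match="wider"):
            generate_patella(PatellaParams(width=500.0),
                             healthy_knee.femur_surface,
                             healthy_knee.femur_grid)
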