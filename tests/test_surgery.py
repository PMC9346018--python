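import numpy as np
import pytest

from patellofem.geometry import AxialProfile
from patellofem.metrics import tt_tg
from patellofem.surgery import (
    SurgeryError,
    SurgeryParams,
    apply_trochleoplasty,
    locate_correction_planes,
    new_sulcus_point,
    tt_tg_change,
)


@pytest.fixture(scope="module")
def osteotomies(dysplastic_knee):
    return {
        f: apply_trochleoplasty(dysplastic_knee, SurgeryParams(f=f))
        for f in (0.5, 1.0, 1.5)
    }


class TestNewSulcusPoint:
    def _profile(self):
        contour = np.array(
            [[-5.0, 0.0], [0.0, 0.0], [5.0, 0.0], [5.0, -8.0], [-5.0, -8.0]]
        )
        return AxialProfile(0.0, contour, 1, 2, 0, np.array([1.0, 0.0]))

    def test_identity(self):
        s1 = new_sulcus_point(self._profile(), 0.0, 0.0)
        assert np.allclose(s1, [0.0, 0.0])

    def test_frame_convention(self):
        # +x lateral along BL, +y anterior: deepening moves posteriorly
        s1 = new_sulcus_point(self._profile(), 3.0, 2.0)
        assert np.allclose(s1, [3.0, -2.0])

    def test_exceeding_bone_stock_rejected(self):
        with pytest.raises(SurgeryError, match="bone stock"):
            new_sulcus_point(self._profile(), 0.0, 50.0)


class TestTtTgChange:
    @pytest.mark.parametrize("f,expected", [(0.5, 3.05), (1.5, 9.15), (0.0, 0.0)])
    def test_linearity(self, f, expected):
        assert tt_tg_change(SurgeryParams(f=f)) == pytest.approx(expected)

    def test_invalid_params(self):
        with pytest.raises(SurgeryError):
            SurgeryParams(L_mean=-1.0)
        with pytest.raises(SurgeryError):
            SurgeryParams(proximal_z=0.0, distal_z=5.0)


class TestCorrectionPlanes:
    def test_planes_bracket_most_of_the_groove(self, dysplastic_knee):
        pz, dz = locate_correction_planes(dysplastic_knee)
        poly = dysplastic_knee.landmarks["sulcus_polyline"]
        span = poly[:, 2].max() - poly[:, 2].min()
        assert (pz - dz) / span >= 0.6

    def test_threshold_90_gives_distal_end(self, dysplastic_knee):
        _, dz = locate_correction_planes(dysplastic_knee,
                                         notch_angle_threshold=90.0)
        poly = dysplastic_knee.landmarks["sulcus_polyline"]
        assert dz == pytest.approx(poly[:, 2].min())

    def test_proximal_plane_is_full_cover_station(self, healthy_knee):
        pz, _ = locate_correction_planes(healthy_knee)
        grid = healthy_knee.femur_grid
        cart = healthy_knee.femur_surface.cartilage_mask
        i = int(np.argmin(np.abs(grid.z_stations - pz)))
        prof = grid.profiles[i]
        cols = np.arange(prof.mc_index, prof.lc_index + 1)
        assert cart[grid.vertex_ids[i, cols]].all()

    def test_model_without_grid_rejected(self, healthy_knee):
        m = healthy_knee.copy()
        m.femur_grid = None
        with pytest.raises(SurgeryError, match="grid"):
            locate_correction_planes(m)


class TestApplyTrochleoplasty:
    def test_identity_at_zero_factor(self, dysplastic_knee):
        res = apply_trochleoplasty(dysplastic_knee, SurgeryParams(f=0.0))
        assert np.array_equal(res.model.femur_surface.vertices,
                              dysplastic_knee.femur_surface.vertices)
        assert res.wedge_volume == 0.0

    def test_displacement_locality(self, dysplastic_knee, osteotomies):
        """Maximum displacement on the groove; zero on posterior condyles
        and outside the correction band + blend."""
        res = osteotomies[1.0]
        grid = dysplastic_knee.femur_grid
        post_ids = grid.vertex_ids[:, grid.n_arc:].ravel()
        assert res.displacement[post_ids].max() == 0.0
        zs = grid.z_stations
        p = res.params
        outside = (zs < res.distal_z - p.blend - 1e-9) | (
            zs > res.proximal_z + p.blend + 1e-9)
        out_ids = grid.vertex_ids[outside].ravel()
        assert res.displacement[out_ids].max() == 0.0
        # the displacement maximum sits on the anterior (groove) arc
        arc_ids = grid.vertex_ids[:, : grid.n_arc].ravel()
        assert res.displacement.max() == res.displacement[arc_ids].max() > 0

    def test_thickness_preserved(self, dysplastic_knee, osteotomies):
        for res in osteotomies.values():
            d = np.abs(res.model.femur_thickness.values
                       - dysplastic_knee.femur_thickness.values)
            assert d.max() < 1e-3

    def test_wedge_volume_monotone_in_factor(self, osteotomies):
        w = [osteotomies[f].wedge_volume for f in (0.5, 1.0, 1.5)]
        assert w[0] < w[1] < w[2]
        assert w[0] > 0

    def test_sulcus_displacement_linear_in_factor(self, dysplastic_knee,
                                                  osteotomies):
        """Measured groove displacement at in-band stations equals
        f * (L, D) within mesh resolution."""
        pre = dysplastic_knee.landmarks["sulcus_polyline"]
        for f, res in osteotomies.items():
            post = res.model.landmarks["sulcus_polyline"]
            inband = (pre[:, 2] >= res.distal_z) & (pre[:, 2] <= res.proximal_z)
            d = post[inband] - pre[inband]
            assert np.allclose(d[:, 0], f * res.params.L_mean, atol=0.3)
            assert np.allclose(d[:, 1], -f * res.params.D_mean, atol=0.3)

    def test_tt_tg_reduction_matches_operator(self, dysplastic_knee,
                                              osteotomies):
        pre = tt_tg(dysplastic_knee)
        for f, res in osteotomies.items():
            reduction = pre - tt_tg(res.model)
            assert reduction == pytest.approx(
                tt_tg_change(res.params), abs=0.5)

    def test_postop_surface_still_watertight(self, osteotomies):
        for res in osteotomies.values():
            res.model.femur_surface.validate()

    def test_infeasible_deepening_names_station(self, dysplastic_knee):
        with pytest.raises(SurgeryError, match="station"):
            apply_trochleoplasty(dysplastic_knee,
                                 SurgeryParams(D_mean=60.0, f=1.0))

    def test_straight_contour_mode(self, dysplastic_knee):
        res = apply_trochleoplasty(
            dysplastic_knee, SurgeryParams(f=1.0, contour_mode="straight"))
        res.model.femur_surface.validate()
        assert res.wedge_volume > 0
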