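import numpy as np
import pytest
import scipy.sparse as sp

from patellofem.benchmarks import confined_compression
from patellofem.fem import (
    MaterialParams,
    assemble,
    element_stresses,
    extrude_cartilage,
    scale_thickness,
    von_mises,
)
from patellofem.geometry import SurfaceMesh, ThicknessMap


@pytest.fixture
def flat_patch():
    verts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
    return SurfaceMesh(verts, np.array([[0, 1, 2], [0, 2, 3]]),
                       np.ones(4, dtype=np.uint8))


class TestExtrusion:
    def test_prism_decomposition_counts(self, flat_patch):
        tm = extrude_cartilage(flat_patch, ThicknessMap(np.ones(4)), layers=1)
        assert tm.n_nodes == 8
        assert tm.n_elements == 6
        assert np.all(tm.volumes() > 0)

    def test_layer_count_scales_elements(self, flat_patch):
        t1 = extrude_cartilage(flat_patch, ThicknessMap(np.ones(4)), layers=1)
        t3 = extrude_cartilage(flat_patch, ThicknessMap(np.ones(4)), layers=3)
        assert t3.n_elements == 3 * t1.n_elements

    def test_node_sets_disjoint_and_complete(self, flat_patch):
        tm = extrude_cartilage(flat_patch, ThicknessMap(np.ones(4)), layers=3)
        assert not set(tm.bone_interface) & set(tm.articular_surface)
        assert not set(tm.rim) & set(tm.articular_surface)
        assert not set(tm.rim) & set(tm.bone_interface)

    def test_default_resolution_element_count_bracket(self):
        """Per-knee deformable element count brackets the reference models'
        scale (39,686 / 35,070 elements)."""
        from patellofem.geometry import build_knee

        knee = build_knee("healthy")
        tf = extrude_cartilage(knee.femur_surface, knee.femur_thickness)
        tp = extrude_cartilage(knee.patella_surface, knee.patella_thickness,
                               part="patella")
        total = tf.n_elements + tp.n_elements
        assert 20_000 <= total <= 60_000

    def test_invalid_layers(self, flat_patch):
        with pytest.raises(ValueError):
            extrude_cartilage(flat_patch, ThicknessMap(np.ones(4)), layers=0)


class TestScaleThickness:
    def test_identity(self):
        t = ThicknessMap(np.array([3.0, 2.0]))
        assert np.array_equal(scale_thickness(t, 1.0).values, t.values)

    def test_uniform_scale(self):
        t = scale_thickness(ThicknessMap(np.full(5, 3.0)), 0.6)
        assert np.allclose(t.values, 1.8)

    def test_round_trip(self):
        t = ThicknessMap(np.array([2.0, 3.0, 1.4]))
        back = scale_thickness(scale_thickness(t, 1.4), 1 / 1.4)
        assert np.allclose(back.values, t.values, rtol=1e-12)

    @pytest.mark.parametrize("factor", [0.5, 1.5, -1.0])
    def test_envelope_enforced(self, factor):
        with pytest.raises(ValueError, match="envelope"):
            scale_thickness(ThicknessMap(np.ones(3)), factor)


@pytest.fixture(scope="module")
def cube():
    verts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
    sm = SurfaceMesh(verts, np.array([[0, 1, 2], [0, 2, 3]]),
                     np.ones(4, dtype=np.uint8))
    return extrude_cartilage(sm, ThicknessMap(np.ones(4)), layers=3)


class TestElasticity:

    def test_stiffness_symmetric(self, cube, material):
        K = assemble(cube, material)
        assert abs(K - K.T).max() < 1e-10 * abs(K).max()

    def test_rigid_body_modes_zero_energy(self, cube, material):
        K = assemble(cube, material)
        for t in ([1, 0, 0], [0, 1, 0], [0.3, -2.0, 1.1]):
            u = np.tile(t, cube.n_nodes)
            assert np.abs(K @ u).max() < 1e-10

    def test_patch_test_exact(self, cube, material):
        """A linear displacement field produces a spatially uniform stress."""
        A = np.array([[0.01, 0.003, 0.0],
                      [0.002, -0.005, 0.004],
                      [0.0, 0.001, 0.02]])
        u = (cube.nodes @ A.T).ravel()
        s = element_stresses(cube, material, u)
        assert np.ptp(s, axis=0).max() < 1e-10 * np.abs(s).max()

    def test_confined_compression_modulus(self):
        """FE axial stress under uniaxial strain reproduces
        E(1-nu)/((1+nu)(1-2nu)) = 30.045 MPa to better than 0.1%."""
        out = confined_compression()
        assert out["fe_modulus"] == pytest.approx(out["oracle_modulus"],
                                                  rel=1e-3)
        # 1% strain -> 0.30045 MPa axial stress
        axial = -out["stress_voigt"][:, 2].mean()
        assert axial == pytest.approx(0.30045, abs=1e-4)

    def test_von_mises_closed_forms(self):
        # hydrostatic state -> 0; uniaxial sigma -> |sigma|
        hydro = np.array([[2.0, 2.0, 2.0, 0, 0, 0]])
        assert von_mises(hydro)[0] == pytest.approx(0.0, abs=1e-12)
        uni = np.array([[-3.1, 0, 0, 0, 0, 0]])
        assert von_mises(uni)[0] == pytest.approx(3.1)

    def test_inverted_element_rejected(self, material):
        from patellofem.fem.elasticity import shape_gradients

        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.5, 0.3, 0.0]])
        with pytest.raises(ValueError, match="element"):
            shape_gradients(nodes, np.array([[0, 1, 2, 3]]))


class TestMaterialParams:
    def test_defaults(self, material):
        assert material.E == 5.0
        assert material.nu == 0.47
        assert material.mu == 0.02

    @pytest.mark.parametrize("kwargs", [
        {"E": -1.0}, {"nu": 0.5}, {"nu": -0.1}, {"mu": -0.2},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            MaterialParams(**kwargs)

    def test_constrained_modulus_value(self, material):
        assert material.constrained_modulus == pytest.approx(30.04535, abs=1e-4)
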