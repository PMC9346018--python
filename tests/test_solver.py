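import numpy as np
import pytest

from patellofem.benchmarks import (
    foundation_indentation,
    grid_patch,
    slab_mesh,
)
from patellofem.fem import MaterialParams
from patellofem.solver import (
    RigidSphere,
    SolverSettings,
    Solution,
    detect_contact,
    residual_report,
    solve_quasistatic,
)


class TestDetectContact:
    def test_parallel_patches_open_gap(self):
        V, F = grid_patch(6, 10.0)
        pts = V + [0.0, 0.0, 1.0]
        det = detect_contact(pts, V, F, drop_boundary=False)
        assert np.allclose(det["gap"], -1.0)

    def test_parallel_patches_penetrating(self):
        V, F = grid_patch(6, 10.0)
        pts = V + [0.0, 0.0, -0.5]
        det = detect_contact(pts, V, F, drop_boundary=False)
        assert np.allclose(det["gap"], 0.5)

    def test_sphere_plane_active_radius(self):
        """Active set radius ~ sqrt(2 R delta) within one edge length."""
        n, size = 41, 12.0
        V, F = grid_patch(n, size)
        R, delta = 10.0, 0.1
        # sample the sphere surface as slave points over the patch
        pts = V.copy()
        r2 = pts[:, 0] ** 2 + pts[:, 1] ** 2
        inside = r2 < R * R
        pts = pts[inside]
        pts[:, 2] = (R - delta) - np.sqrt(R * R - r2[inside])
        det = detect_contact(pts, V, F, drop_boundary=False)
        act = det["gap"] > 0
        r_active = np.hypot(*pts[det["slave"][act], :2].T).max()
        a = np.sqrt(2 * R * delta)
        h = size / (n - 1)
        assert abs(r_active - a) <= h

    def test_degenerate_master_triangles_skipped(self):
        V = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        F = np.array([[0, 1, 2], [0, 1, 3], [1, 4, 3]])  # first face is a sliver
        det = detect_contact(np.array([[0.5, 0.4, -0.1]]), V, F,
                             drop_boundary=False)
        assert len(det["slave"]) == 1
        assert det["gap"][0] == pytest.approx(0.1)


class TestTrivialEquilibrium:
    def test_zero_load_clear_contact(self, healthy_knee, material):
        """No muscle force, no prestrain, patella clear of the femur: the
        zero-displacement state is already the equilibrium."""
        from patellofem.loading import build_load_case
        from patellofem.model import PatellofemoralModel

        model = PatellofemoralModel(
            healthy_knee, 45.0, material=material,
            loading={"muscle_total": 0.0, "prestrain": 0.0,
                     "tendon_prestrain": 0.0},
            settings=SolverSettings(n_load_steps=1), layers=1,
        )
        res = model.fit()
        assert res.solution.converged
        assert res.solution.iterations == 0
        assert np.allclose(res.solution.patella_translation,
                           res.case.start_translation)
        assert res.solution.node_pressure.max() == 0.0


class TestFoundationBenchmark:
    def test_force_balance_exact(self, foundation_result):
        sol = foundation_result["solution"]
        assert sol.converged
        rr = residual_report(sol)
        assert rr["residual_fraction_of_applied"] < 1e-6
        assert rr["net_fraction_of_applied"] < 1e-6
        # integral of recovered pressure equals the applied load
        assert sol.diagnostics["contact_total"][2] == pytest.approx(10.0,
                                                                    rel=1e-6)

    def test_peak_between_hertz_and_winkler(self, foundation_result):
        """At a/t ~ 0.6 the bonded nearly incompressible layer responds
        between the half-space (Hertz) and local-column (Winkler) limits."""
        ratio = foundation_result["ratio"]
        assert 0.55 <= ratio <= 1.0

    def test_penalty_insensitivity(self, foundation_result):
        """Doubling the penalty stiffness moves the peak by < 2%."""
        double = foundation_indentation(penalty=800.0)
        assert double["fe_peak"] == pytest.approx(
            foundation_result["fe_peak"], rel=0.02)

    def test_nonpenetration(self, foundation_result):
        sol = foundation_result["solution"]
        # residual penetration well below 1% of the 3 mm thickness
        assert sol.diagnostics["max_penetration"] < 0.03


class TestDeterminism:
    def test_bitwise_identical_reruns(self, material):
        slab = slab_mesh(13, 8.0, 2.0, 2)
        kw = dict(
            case=None, meshes=(slab, None), material=material,
            settings=SolverSettings(n_load_steps=2, penalty_stiffness=300.0),
            rigid_master=RigidSphere(np.array([0.0, 0.0, 8.02]), 8.0),
            external_force=np.array([0.0, 0.0, -5.0]),
            translation_lock=(True, True, False),
        )
        a = solve_quasistatic(**kw)
        b = solve_quasistatic(**kw)
        assert np.array_equal(a.patella_translation, b.patella_translation)
        assert np.array_equal(a.node_pressure, b.node_pressure)
        assert np.array_equal(a.u_femur, b.u_femur)
        assert a.residual_history == b.residual_history


class TestFriction:
    def test_friction_cone_and_frictionless_path(self):
        m = MaterialParams(E=5.0, nu=0.3, mu=0.02)
        slab = slab_mesh(13, 8.0, 2.0, 2)
        kw = dict(
            case=None, meshes=(slab, None), material=m,
            rigid_master=RigidSphere(np.array([0.3, 0.0, 8.02]), 8.0),
            external_force=np.array([1.0, 0.0, -5.0]),
            translation_lock=(False, True, False),
        )
        off = solve_quasistatic(
            settings=SolverSettings(n_load_steps=2, friction_enabled=False),
            **kw)
        assert np.all(off.node_tangential == 0.0)
        on = solve_quasistatic(
            settings=SolverSettings(n_load_steps=2, friction_enabled=True),
            **kw)
        tmag = np.linalg.norm(on.node_tangential, axis=1)
        assert np.all(tmag <= m.mu * on.node_pressure + 1e-9)


class TestAugmentedLagrange:
    def test_outer_loop_tightens_penetration(self, material):
        slab = slab_mesh(13, 8.0, 2.0, 2)
        kw = dict(
            case=None, meshes=(slab, None), material=material,
            rigid_master=RigidSphere(np.array([0.0, 0.0, 8.02]), 8.0),
            external_force=np.array([0.0, 0.0, -8.0]),
            translation_lock=(True, True, False),
        )
        pen = solve_quasistatic(
            settings=SolverSettings(n_load_steps=2, penalty_stiffness=100.0),
            **kw)
        al = solve_quasistatic(
            settings=SolverSettings(n_load_steps=2, penalty_stiffness=100.0,
                                    formulation="augmented_lagrange",
                                    al_penetration_tol=1e-3),
            **kw)
        assert al.converged
        assert al.diagnostics["max_penetration"] < 1e-3
        assert al.diagnostics["max_penetration"] < pen.diagnostics["max_penetration"]
        # the resultant is unchanged; only its resolution into multiplier
        # and penalty parts differs
        assert al.diagnostics["contact_total"][2] == pytest.approx(8.0, rel=1e-5)


class TestKneeSolve:
    def test_healthy_strict_convergence(self, healthy_fit_45):
        sol = healthy_fit_45.solution
        assert sol.converged and sol.status == "converged"
        rr = healthy_fit_45.force_balance()
        assert rr["residual_fraction_of_applied"] < 1e-6
        # per-family sums accumulate over thousands of nodes; allow a few
        # float ulps beyond the residual tolerance
        assert rr["net_fraction_of_applied"] < 3e-6

    def test_pressure_nonnegative_and_bounded(self, healthy_fit_45):
        sol = healthy_fit_45.solution
        assert np.all(sol.node_pressure >= 0.0)
        assert sol.node_pressure.max() < 20.0

    def test_invalid_settings(self):
        with pytest.raises(ValueError):
            SolverSettings(penalty_stiffness=-1.0)
        with pytest.raises(ValueError):
            SolverSettings(formulation="lagrange_multiplier")
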