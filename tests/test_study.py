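import numpy as np
import pandas as pd
import pytest

from patellofem.study import DEFAULT_STUDY_CONFIG, run_study, study_plan


class TestPlan:
    def test_dry_run_plans_twenty_solves(self):
        plan = run_study(dry_run=True)
        assert len(plan) == 20
        groups = {p["group"] for p in plan}
        assert groups == {"healthy", "preop", 0.5, 1.0, 1.5}
        thetas = {p["theta"] for p in plan}
        assert thetas == {30.0, 45.0, 60.0, 75.0}


class TestStudyBundle:
    def test_records_complete(self, study_result):
        rec = study_result.records
        assert len(rec) == 20
        assert set(rec["group"]) == {"healthy", "preop", 0.5, 1.0, 1.5}

    def test_healthy_cells_all_converged(self, study_result):
        rec = study_result.records
        healthy = rec[rec["group"] == "healthy"]
        assert (healthy["status"] == "converged").all()

    def test_most_cells_converged(self, study_result):
        # the healthy, preoperative and moderate-correction groups converge;
        # the 1.5x over-correction wedges a flat ridge into a deep narrow
        # groove and some of its cells stall at the study resolution
        rec = study_result.records
        assert (rec["status"] == "converged").sum() >= 14
        for group in ("healthy", "preop"):
            sub = rec[rec["group"] == group]
            assert (sub["status"] == "converged").all()

    def test_tables_mirror_records(self, study_result):
        tab = study_result.tables["peak_pressure"]
        rec = study_result.records
        cell = rec[(rec["group"] == "healthy") & (rec["theta"] == 45.0)]
        assert tab.loc[45.0, "healthy"] == pytest.approx(
            float(cell["peak_pressure"].iloc[0]))

    def test_percent_change_consistent(self, study_result):
        tab = study_result.tables["peak_pressure"]
        pct = study_result.tables["peak_pressure_pct_change"]
        for f in (0.5, 1.0, 1.5):
            for th in tab.index:
                a, b = tab.loc[th, f], tab.loc[th, "preop"]
                if np.isfinite(a) and np.isfinite(b):
                    expected = round(100.0 * (a - b) / b)
                    assert pct.loc[th, f] == pytest.approx(expected, abs=1.0)

    def test_pooled_rows_recomputable(self, study_result):
        """Pooled statistics equal a direct recomputation from the records
        (no hidden state)."""
        rec = study_result.records
        row = study_result.pooled.get("healthy_peak_pressure")
        vals = rec[(rec["group"] == "healthy")]["peak_pressure"].dropna()
        assert row is not None
        assert row.raw_mean == pytest.approx(vals.mean())
        assert row.raw_sd == pytest.approx(vals.std(ddof=1))

    def test_outputs_written_and_reloadable(self, study_result, tmp_path):
        study_result.save(tmp_path)
        assert (tmp_path / "manifest.json").exists()
        back = pd.read_csv(tmp_path / "tables" / "records.csv")
        assert len(back) == len(study_result.records)

    def test_manifest_records_configuration(self, study_result):
        cfg = study_result.manifest["config"]
        assert cfg["surgery"]["factors"] == [0.5, 1.0, 1.5]
        assert cfg["geometry"]["seed"] == 0


class TestSensitivity:
    def test_thickness_sweep_smoke(self):
        from patellofem.study import sensitivity_driver

        df = sensitivity_driver(thickness_factors=(1.0, 1.2))
        assert list(df["thickness_factor"]) == [1.0, 1.2]
        ok = df[df["status"] == "converged"]
        assert len(ok) >= 1
        assert (ok["peak_vmes_patella_articular"] > 0).all()

    def test_out_of_envelope_rejected(self):
        from patellofem.study import sensitivity_driver

        with pytest.raises(ValueError):
            sensitivity_driver(thickness_factors=(0.5,))

    def test_material_linearity_toy(self):
        """Doubling E under a fixed displacement field doubles the Von Mises
        stress (linearity of the constitutive law)."""
        from patellofem.benchmarks import slab_mesh
        from patellofem.fem import MaterialParams, element_stresses, von_mises

        mesh = slab_mesh(4, 4.0, 1.0, 1)
        rngl = np.random.default_rng(7)
        u = rngl.normal(0, 0.01, 3 * mesh.n_nodes)
        m1 = MaterialParams(E=5.0, nu=0.3)
        m2 = MaterialParams(E=10.0, nu=0.3)
        v1 = von_mises(element_stresses(mesh, m1, u))
        v2 = von_mises(element_stresses(mesh, m2, u))
        assert np.allclose(v2, 2.0 * v1)


class TestModelSummary:
    def test_summary_reports_key_quantities(self, healthy_fit_45):
        text = healthy_fit_45.summary()
        for token in ("peak contact pressure", "contact area",
                      "patellar tilt", "TT-TG", "converged"):
            assert token in text

    def test_metrics_cached_and_consistent(self, healthy_fit_45):
        s1 = healthy_fit_45.stress
        s2 = healthy_fit_45.stress
        assert s1 is s2
        assert s1.peak_pressure >= (s1.mean_pressure or 0.0)
        assert s1.contact_area > 0.0
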