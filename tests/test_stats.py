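import numpy as np
import pytest
from scipy import stats as sps

from patellofem.data import (
    MEAN_PRESSURE,
    PEAK_PRESSURE,
    PEAK_VMES,
    PRESSURE_FILM_REFERENCE,
    THETAS,
)
from patellofem.stats import (
    StatsError,
    percent_change,
    pool,
    pool_postop,
    round_half_away,
    t_test,
    t_test_summary,
)


def _postop_table(table, component=None):
    out = {}
    for f in (0.5, 1.0, 1.5):
        for th in THETAS:
            v = table[f][th]
            out[(th, f)] = v[0] if component == 0 else (
                v[1] if component == 1 else v)
    return out


class TestRounding:
    @pytest.mark.parametrize("x,nd,expected", [
        (1.965, 2, 1.97),
        (-1.965, 2, -1.97),
        (0.5, 0, 1.0),
        (1.2349, 3, 1.235),
    ])
    def test_half_away_from_zero(self, x, nd, expected):
        assert round_half_away(x, nd) == expected


class TestPool:
    def test_healthy_peak_row(self):
        row = pool(PEAK_PRESSURE["healthy"].values())
        assert (row.pooled_mean, row.pooled_sd) == (1.97, 0.16)

    def test_preop_peak_row(self):
        row = pool(PEAK_PRESSURE["preop"].values())
        assert (row.pooled_mean, row.pooled_sd) == (2.43, 0.34)

    def test_healthy_mean_row(self):
        # the four printed per-angle values pool to 0.78 (SD 0.05); the
        # published summary row shows 0.79, evidently pooled from the
        # unrounded per-angle results
        row = pool(MEAN_PRESSURE["healthy"].values())
        assert (row.pooled_mean, row.pooled_sd) == (0.78, 0.05)

    def test_preop_mean_row(self):
        row = pool(MEAN_PRESSURE["preop"].values())
        assert (row.pooled_mean, row.pooled_sd) == (1.01, 0.13)

    def test_healthy_patellar_peak_vmes_row(self):
        row = pool([v[0] for v in PEAK_VMES["healthy"].values()])
        assert (row.pooled_mean, row.pooled_sd) == (0.87, 0.12)

    def test_constant_values(self):
        row = pool([1.0, 1.0, 1.0, 1.0])
        assert (row.pooled_mean, row.pooled_sd) == (1.0, 0.0)

    def test_numpy_oracle(self, rng):
        vals = rng.normal(2.0, 0.5, 7)
        row = pool(vals)
        assert row.raw_mean == pytest.approx(np.mean(vals))
        assert row.raw_sd == pytest.approx(np.std(vals, ddof=1))

    def test_single_value_rejected(self):
        with pytest.raises(StatsError):
            pool([1.0])


class TestPoolPostop:
    def test_postop_peak_pressures(self):
        row = pool_postop(_postop_table(PEAK_PRESSURE))
        assert (row.pooled_mean, row.pooled_sd) == (3.3, 1.01)
        assert row.n == 12

    def test_postop_mean_pressures(self):
        row = pool_postop(_postop_table(MEAN_PRESSURE))
        assert (row.pooled_mean, row.pooled_sd) == (1.23, 0.17)

    def test_postop_vmes_patella_and_trochlea(self):
        pat = pool_postop(_postop_table(PEAK_VMES, component=0))
        tro = pool_postop(_postop_table(PEAK_VMES, component=1))
        assert pat.pooled_mean == 1.35
        assert tro.pooled_mean == 1.5

    def test_identical_cells(self):
        table = {(th, f): 2.0 for th in THETAS for f in (0.5, 1.0, 1.5)}
        row = pool_postop(table)
        assert (row.pooled_mean, row.pooled_sd) == (2.0, 0.0)

    def test_missing_cell_named(self):
        table = _postop_table(PEAK_PRESSURE)
        del table[(45, 1.0)]
        with pytest.raises(StatsError, match=r"45.*1\.0|\(45, 1\.0\)"):
            pool_postop(table)

    def test_flatten_consistency(self):
        table = _postop_table(PEAK_PRESSURE)
        assert pool_postop(table).raw_mean == pytest.approx(
            pool(table.values()).raw_mean)


class TestPercentChange:
    @pytest.mark.parametrize("after,before,expected", [
        (5.41, 2.61, 107),
        (3.75, 2.72, 38),
        (2.0, 2.0, 0),
    ])
    def test_printed_examples(self, after, before, expected):
        assert percent_change(after, before) == expected

    def test_invalid_reference(self):
        with pytest.raises(StatsError):
            percent_change(1.0, 0.0)


class TestTTests:
    def test_healthy_vs_preop_student(self):
        a = list(PEAK_PRESSURE["healthy"].values())
        b = list(PEAK_PRESSURE["preop"].values())
        res = t_test(a, b, welch=False)
        assert res.degrees_of_freedom == 6
        assert res.p_value == pytest.approx(0.047, abs=1e-3)
        assert abs(res.t_statistic) == pytest.approx(2.48, abs=0.01)

    def test_film_literature_welch(self):
        res = t_test_summary(1.97, 0.16, 4, *PRESSURE_FILM_REFERENCE["peak"],
                             welch=True)
        assert res.p_value == pytest.approx(0.007, abs=2e-3)
        assert res.t_statistic == pytest.approx(4.0, abs=0.1)

    def test_identical_samples(self):
        res = t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_equal_means_convention(self):
        res = t_test([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    def test_sign_symmetry(self):
        a, b = [1.0, 2.0, 3.1], [2.0, 3.0, 4.5]
        r1, r2 = t_test(a, b), t_test(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_summary_matches_raw_to_machine_precision(self, rng):
        a = rng.normal(1.0, 0.3, 6)
        b = rng.normal(1.4, 0.5, 9)
        for welch in (False, True):
            raw = t_test(a, b, welch=welch)
            summ = t_test_summary(a.mean(), a.std(ddof=1), len(a),
                                  b.mean(), b.std(ddof=1), len(b), welch=welch)
            assert summ.t_statistic == pytest.approx(raw.t_statistic, abs=1e-12)
            assert summ.p_value == pytest.approx(raw.p_value, abs=1e-12)

    def test_scipy_oracle(self, rng):
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(0.5, 2.0, 5)
        ours = t_test(a, b, welch=True)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert ours.t_statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_welch_df_not_exceeding_student(self, rng):
        a = rng.normal(0.0, 0.2, 5)
        b = rng.normal(0.0, 3.0, 7)
        welch = t_test(a, b, welch=True)
        assert welch.degrees_of_freedom <= len(a) + len(b) - 2

    def test_small_samples_rejected(self):
        with pytest.raises(StatsError):
            t_test([1.0], [1.0, 2.0])
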