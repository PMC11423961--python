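"""MAPE, comparison tables, kappa drift and annual increments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import incimort as im
from incimort.evaluate import compare_models, kappa_drift, lewis_label, mape_with_cells
from incimort.gapc import GAPCModel
from incimort.surfaces import RateSurface, group_ages


def _surf(rates, kind="incidence", sex="M", events=None, exposure=None):
    rates = np.asarray(rates, float)
    A, Y = rates.shape
    return RateSurface(kind=kind, sex=sex, ages=np.arange(50, 50 + A),
                       years=np.arange(2000, 2000 + Y), rates=rates,
                       events=events, exposure=exposure)


class TestMAPE:
    def test_perfect_fit_is_zero(self):
        s = _surf(np.full((3, 3), 0.5))
        assert im.mape(s, s) == 0.0

    def test_worked_arithmetic(self):
        obs = RateSurface(kind="x", sex="M", ages=[50], years=[2000, 2001],
                          rates=np.array([[100.0, 200.0]]))
        fit = RateSurface(kind="x", sex="M", ages=[50], years=[2000, 2001],
                          rates=np.array([[110.0, 180.0]]))
        assert im.mape(obs, fit) == pytest.approx(10.0)

    def test_zero_observed_cells_are_excluded(self):
        obs = _surf(np.array([[1.0, 0.0], [2.0, np.nan]]))
        fit = _surf(np.array([[1.1, 5.0], [2.0, 5.0]]))
        v, n = mape_with_cells(obs, fit)
        assert n == 2
        assert v == pytest.approx(np.mean([0.1, 0.0]) * 100)

    def test_no_includable_cells_raises(self):
        obs = _surf(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="no includable"):
            im.mape(obs, obs)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        o = _surf(rng.uniform(0.1, 1, (4, 5)))
        f = _surf(rng.uniform(0.1, 1, (4, 5)))
        base = im.mape(o, f)
        c = 17.3
        assert im.mape(_surf(o.rate * c), _surf(f.rate * c)) == pytest.approx(base, rel=1e-12)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(0, 10_000))
def test_mape_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    A, Y = rng.integers(2, 6), rng.integers(2, 6)
    o = rng.uniform(0.01, 1.0, (A, Y))
    f = rng.uniform(0.01, 1.0, (A, Y))
    total = 0.0
    for i in range(A):
        for j in range(Y):
            total += abs(o[i, j] - f[i, j]) / o[i, j]
    expected = total / (A * Y) * 100
    assert im.mape(_surf(o), _surf(f)) == pytest.approx(expected, rel=1e-12)


class TestDriftAndIncrements:
    def _lc_results(self, kappa, beta=None):
        Y = len(kappa)
        A = 4
        ages = np.arange(60.0, 60 + A)
        years = np.arange(2000, 2000 + Y)
        mod = GAPCModel.from_arrays(np.full((A, Y), 5.0), np.full((A, Y), 100.0), ages, years)
        params = {
            "alpha": np.full(A, -3.0),
            "beta2": np.full(A, 1 / A) if beta is None else np.asarray(beta, float),
            "kappa2": np.asarray(kappa, float),
        }
        return mod.results_from_params(params)

    def test_linear_kappa_has_unit_slope_and_r2(self):
        d = kappa_drift(self._lc_results([-1.0, 0.0, 1.0]))
        assert d.b == pytest.approx(1.0)
        assert d.r_squared == pytest.approx(1.0)

    def test_constant_kappa_has_zero_slope(self):
        d = kappa_drift(self._lc_results([2.0, 2.0, 2.0]))
        assert d.b == 0.0

    def test_increment_factor_formula(self):
        res = self._lc_results([0.0, 0.3, 0.6], beta=[0.2, 0.2, 0.3, 0.3])
        drift = kappa_drift(res)
        assert drift.b == pytest.approx(0.3)
        table = im.annual_increments(res, drift).table
        assert table.factor.iloc[0] == pytest.approx(np.exp(0.2 * 0.3))  # ~1.0618
        assert table.percent.iloc[0] == pytest.approx((np.exp(0.06) - 1) * 100)

    def test_zero_drift_gives_unit_factors(self):
        res = self._lc_results([1.0, 1.0, 1.0])
        table = im.annual_increments(res, kappa_drift(res)).table
        assert np.allclose(table.factor, 1.0)

    def test_drift_needs_kappa2(self):
        D = np.full((4, 4), 5.0)
        E = np.full((4, 4), 100.0)
        res = GAPCModel.from_arrays(D, E, np.arange(4.0), np.arange(4), kind="APC").fit(max_iter=5)
        with pytest.raises(ValueError, match="kappa2"):
            kappa_drift(res)


class TestCompareModels:
    @pytest.fixture()
    def data(self):
        rng = np.random.default_rng(4)
        ages = np.arange(45.0, 100.0)
        years = np.arange(2005, 2014)
        m = 0.002 * np.exp(0.05 * (ages - 45))[:, None] * np.exp(0.02 * (years - 2009))[None, :]
        E = np.full(m.shape, 2e4)
        surf = {}
        for sex in ("M", "F"):
            D = rng.poisson(E * m).astype(float)
            surf[sex] = RateSurface(kind="incidence", sex=sex, ages=ages, years=years,
                                    events=D, exposure=E)
        return surf

    def test_single_model_single_period_matches_direct_mape(self, data):
        rep = compare_models({"M": data["M"]}, [(2005, 2013)], ["LC"], "five_45_99")
        obs = group_ages(data["M"], "five_45_99")
        res = GAPCModel(obs, kind="LC").fit()
        assert rep.table.loc["LC", "2005-2013 M"] == pytest.approx(
            im.mape(obs, res.fitted_surface)
        )
        assert rep.table.loc["LC", "Average"] == pytest.approx(
            rep.table.drop(columns="Average").loc["LC"].mean()
        )

    def test_non_converged_fit_yields_na_cell(self, data):
        rep = compare_models({"M": data["M"]}, [(2005, 2013)], ["LC", "RH"],
                             "five_45_99", fit_options={"max_iter": 0})
        # max_iter=0 leaves every Newton fit unconverged -> NA row
        assert rep.table.drop(columns="Average").loc["LC"].isna().all()
        assert np.isnan(rep.table.loc["LC", "Average"])

    def test_report_is_deterministic(self, data):
        a = compare_models(data, [(2005, 2013), (2008, 2013)], ["LC", "CBD"], "five_45_99")
        b = compare_models(data, [(2005, 2013), (2008, 2013)], ["LC", "CBD"], "five_45_99")
        assert a.table.equals(b.table)
        assert a.summary() == b.summary()

    def test_psmr_rows_need_reference(self, data):
        with pytest.raises(ValueError, match="reference"):
            compare_models(data, [(2005, 2013)], ["PSMR"], "five_45_99")


def test_lewis_labels():
    assert lewis_label(5) == "highly accurate"
    assert lewis_label(60) == "unacceptable"
    assert lewis_label(float("nan")) == "NA"
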