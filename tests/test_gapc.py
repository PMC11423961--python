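"""GAPC model family: fitting, constraints, recovery, convergence."""

import numpy as np
import pytest
from scipy.special import expit, logit

import incimort as im
from incimort.gapc import GAPCModel, apply_constraints, fitted_rates


def _random_counts(seed=0, A=10, Y=8, exposure=1e4):
    rng = np.random.default_rng(seed)
    ages = np.arange(60.0, 60 + A)
    years = np.arange(2000, 2000 + Y)
    m = 0.02 * np.exp(rng.normal(0, 0.3, (A, Y)))
    E = np.full((A, Y), exposure)
    D = rng.poisson(E * m).astype(float)
    return D, E, ages, years


@pytest.mark.parametrize("kind", ["LC", "APC", "CBD", "RH"])
def test_loglik_never_decreases_across_sweeps(kind):
    D, E, ages, years = _random_counts(seed=2)
    res = GAPCModel.from_arrays(D, E, ages, years, kind=kind).fit()
    diffs = np.diff(res.loglik_trace)
    assert diffs.min() >= -1e-9 * (1 + abs(res.loglik))


@pytest.mark.parametrize("kind", ["LC", "APC", "RH"])
def test_constraint_transform_preserves_fitted_rates(kind):
    """Applying the identifiability constraints to arbitrary parameters must
    leave the fitted surface unchanged while hitting the sums exactly."""
    D, E, ages, years = _random_counts(seed=3)
    mod = GAPCModel.from_arrays(D, E, ages, years, kind=kind)
    rng = np.random.default_rng(7)
    A, Y, C = len(ages), len(years), len(mod.cohorts)
    params = {"alpha": rng.normal(-4, 1, A)}
    if kind in ("LC", "RH"):
        params["beta2"] = rng.normal(0.1, 0.5, A)
        params["kappa2"] = rng.normal(0, 1, Y)
    if kind == "APC":
        params["kappa1"] = rng.normal(0, 1, Y)
        params["gamma"] = rng.normal(0, 1, C)
    if kind == "RH":
        params["beta3"] = rng.normal(0.1, 0.5, A)
        params["gamma"] = rng.normal(0, 1, C)
    raw = mod.results_from_params(params)
    con = apply_constraints(raw)
    rel = np.abs(con.fitted_surface.rate - raw.fitted_surface.rate) / raw.fitted_surface.rate
    assert rel.max() < 1e-12
    if kind in ("LC", "RH"):
        assert abs(con.beta2.sum() - 1) < 1e-10
        assert abs(con.kappa2.sum()) < 1e-10
    if kind == "RH":
        assert abs(con.beta3.sum() - 1) < 1e-10
        assert abs(con.gamma.sum()) < 1e-10
    if kind == "APC":
        assert abs(con.gamma.sum()) < 1e-10
        assert abs((mod.cohorts * con.gamma).sum()) < 1e-10
    again = apply_constraints(con)  # idempotent
    for key, v in con.params.items():
        if v is not None:
            assert np.allclose(again.params[key], v, atol=1e-12)


def test_noise_free_lc_recovery(lc_truth):
    ages, years, alpha, beta, kappa, m = lc_truth
    E = np.full(m.shape, 1e5)
    D = np.round(E * m)
    res = GAPCModel.from_arrays(D, E, ages, years, kind="LC").fit()
    assert res.converged
    fit = res.fitted_surface.rate
    assert np.mean(np.abs(fit - m) / m) * 100 < 1.0
    assert np.corrcoef(res.kappa2, kappa)[0, 1] > 0.999


def test_lc_svd_agrees_with_poisson_mle(lc_truth):
    ages, years, *_, m = lc_truth
    rng = np.random.default_rng(1)
    E = np.full(m.shape, 1e5)
    D = rng.poisson(E * m).astype(float)
    mle = GAPCModel.from_arrays(D, E, ages, years, kind="LC").fit()
    svd = GAPCModel.from_arrays(D, E, ages, years, kind="LC").fit(method="lc_svd")
    gap = np.mean(np.abs(svd.fitted_surface.rate - mle.fitted_surface.rate) / mle.fitted_surface.rate)
    assert gap * 100 < 2.0


def test_apc_degenerate_truth_recovers_zero_period_and_cohort():
    ages = np.arange(50.0, 60.0)
    years = np.arange(2000, 2008)
    m = np.exp(-9 + 0.08 * ages)[:, None] * np.ones((1, len(years)))
    E = np.full(m.shape, 1e6)
    res = GAPCModel.from_arrays(E * m, E, ages, years, kind="APC").fit()
    assert res.converged
    assert np.abs(res.kappa1).max() < 1e-4
    assert np.abs(res.gamma).max() < 1e-4


class TestCBD:
    def test_fitted_logits_exactly_affine_in_age(self):
        D, E, ages, years = _random_counts(seed=5)
        res = GAPCModel.from_arrays(D, E, ages, years, kind="CBD").fit()
        lo = logit(res.fitted_surface.rate)
        x = ages - ages.mean()
        for j in range(len(years)):
            coef = np.polyfit(x, lo[:, j], 1)
            assert np.abs(np.polyval(coef, x) - lo[:, j]).max() < 1e-9

    def test_constant_rate_recovered(self):
        ages = np.arange(70.0, 80.0)
        years = np.arange(2005, 2010)
        E = np.full((10, 5), 1e5)
        D = E * 0.1
        res = GAPCModel.from_arrays(D, E, ages, years, kind="CBD").fit()
        assert res.converged
        assert np.allclose(res.fitted_surface.rate, 0.1, atol=1e-6)
        assert np.abs(res.kappa2).max() < 1e-6
        assert np.allclose(res.kappa1, logit(0.1), atol=1e-5)

    def test_fitted_values_inside_unit_interval(self):
        D, E, ages, years = _random_counts(seed=6)
        res = GAPCModel.from_arrays(D, E, ages, years, kind="CBD").fit()
        q = res.fitted_surface.rate
        assert ((q > 0) & (q < 1)).all()


def test_fitted_rates_contract_and_override():
    D, E, ages, years = _random_counts(seed=8)
    res = GAPCModel.from_arrays(D, E, ages, years, kind="LC").fit()
    assert np.array_equal(fitted_rates(res).rate, res.fitted_surface.rate)
    res.converged = False
    with pytest.raises(ValueError, match="converge"):
        fitted_rates(res)
    assert fitted_rates(res, override=True) is not None


def test_grouped_ages_use_midpoints_for_cbd():
    surf = im.RateSurface(kind="mortality", sex="M", ages=[47.0, 52.0, 57.0],
                          years=[2005, 2006, 2007],
                          events=np.full((3, 3), 10.0), exposure=np.full((3, 3), 1e3),
                          age_labels=("45-49", "50-54", "55-59"))
    mod = GAPCModel(surf, kind="CBD")
    assert mod.xbar == 52.0
    assert np.allclose(mod.x, [47, 52, 57])


def test_unidentifiable_or_invalid_inputs_raise():
    D, E, ages, years = _random_counts(seed=9)
    with pytest.raises(ValueError, match="negative"):
        GAPCModel.from_arrays(D - 1e4, E, ages, years)
    E2 = E.copy()
    E2[0, :] = 0.0  # an age with no usable cell
    with pytest.raises(ValueError, match="no usable"):
        GAPCModel.from_arrays(D, E2, ages, years)
    with pytest.raises(ValueError, match="at least 3"):
        GAPCModel.from_arrays(D[:2], E[:2], ages[:2], years)


def test_zero_cells_can_leave_the_fit_unconverged():
    """A year whose events are all zero pushes the period MLE to -inf: the
    fit must report non-convergence rather than raising."""
    D, E, ages, years = _random_counts(seed=10, exposure=50)
    D[:, 0] = 0.0
    res = GAPCModel.from_arrays(D, E, ages, years, kind="LC").fit()
    assert not res.converged


def test_results_serialization_and_summary(tmp_path):
    D, E, ages, years = _random_counts(seed=12)
    res = GAPCModel.from_arrays(D, E, ages, years, kind="LC").fit()
    out = tmp_path / "fit.json"
    res.to_json(out)
    import json

    payload = json.loads(out.read_text())
    assert payload["kind"] == "LC" and payload["converged"]
    assert len(payload["params"]["beta2"]) == len(ages)
    text = res.summary()
    assert "LC" in text and "converged" in text
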