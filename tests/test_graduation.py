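"""SMR, heterogeneity estimation and partial-SMR graduation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import incimort as im
from incimort.graduation import GraduationInput, PSMRGraduation
from incimort.surfaces import RateSurface


@pytest.mark.parametrize(
    "d, e, expected",
    [([1, 1], [1, 1], 1.0), ([2, 3], [1, 2], 5 / 3), ([0, 0], [1, 2], 0.0)],
)
def test_smr_is_total_observed_over_total_expected(d, e, expected):
    assert im.smr(GraduationInput(d, e)) == pytest.approx(expected)


def test_smr_requires_positive_expected():
    with pytest.raises(ValueError):
        GraduationInput([1, 1], [0, 0])


class TestHeterogeneity:
    def test_exact_fit_clamps_to_zero(self):
        inp = GraduationInput([2, 4], [1, 2])  # d == e * SMR exactly
        assert im.estimate_h2(inp, im.smr(inp)) == 0.0

    def test_hand_worked_example(self):
        inp = GraduationInput([4, 0], [2, 2])
        s = im.smr(inp)
        assert s == 1.0
        # ((4-2)^2 + (0-2)^2 - 4) / (1 * (4 + 4)) = 0.5
        assert im.estimate_h2(inp, s) == pytest.approx(0.5)

    def test_homogeneous_poisson_gives_near_zero_h2(self):
        """Under d_x ~ Poisson(e_x * SMR) the numerator has mean ~0, so the
        clamped estimate should be essentially zero in the median."""
        rng = np.random.default_rng(0)
        e = np.full(20, 100.0)
        vals = []
        for _ in range(200):
            d = rng.poisson(e * 1.0)
            inp = GraduationInput(d, e)
            vals.append(im.estimate_h2(inp, im.smr(inp)))
        assert np.median(vals) < 0.002


class TestPSMR:
    def test_zero_event_age_equals_smr_times_reference(self):
        u = np.array([0.01, 0.02, 0.03])
        res = PSMRGraduation([5, 0, 7], [4.0, 5.0, 6.0], u).fit()
        assert res.v[1] == pytest.approx(res.smr * u[1], rel=1e-12)
        assert res.weights[1] == 0.0

    def test_infinite_credibility_limit_recovers_raw_rates(self):
        d = np.array([5.0, 3.0, 7.0])
        e = np.array([4.0, 5.0, 6.0])
        u = np.array([0.01, 0.02, 0.03])
        res = PSMRGraduation(d, e, u, h2=1e6).fit()
        assert np.allclose(res.v, u * d / e, rtol=1e-4)

    def test_zero_total_events_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="zero total events"):
            res = PSMRGraduation([0, 0], [1.0, 2.0], [0.01, 0.02]).fit()
        assert res.degenerate
        assert np.allclose(res.v, 0.0)

    def test_monotone_credibility(self):
        """Scaling one age's d and e together (fixed d/e) moves its graduated
        value toward the raw local rate."""
        u = np.array([0.01, 0.02, 0.03])
        e0 = np.array([10.0, 10.0, 10.0])
        d0 = np.array([8.0, 12.0, 30.0])
        h2 = 0.05
        prev_gap = None
        for scale in (1.0, 4.0, 16.0):
            d, e = d0.copy(), e0.copy()
            d[0] *= scale
            e[0] *= scale
            res = PSMRGraduation(d, e, u, h2=h2).fit()
            raw = u[0] * d[0] / e[0]
            gap = abs(np.log(res.v[0]) - np.log(raw))
            if prev_gap is not None:
                assert gap < prev_gap
            prev_gap = gap

    def test_scale_equivariance(self):
        d = np.array([5.0, 3.0, 7.0])
        e = np.array([4.0, 5.0, 6.0])
        u = np.array([0.01, 0.02, 0.03])
        base = PSMRGraduation(d, e, u).fit()
        c = 3.7  # u* scaled, exposures implicitly divided so e is unchanged
        scaled = PSMRGraduation(d, e, u * c).fit()
        assert scaled.smr == base.smr and scaled.h2 == base.h2
        assert np.allclose(scaled.v, base.v * c)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=8),
    st.data(),
)
def test_graduated_log_rate_lies_between_local_and_smr(d, data):
    """Eq-style convexity: log v_x always lies weakly between the raw local
    log rate (for d_x > 0) and log(SMR * u*_x)."""
    n = len(d)
    e = data.draw(st.lists(st.floats(0.5, 50), min_size=n, max_size=n))
    u = data.draw(st.lists(st.floats(1e-4, 0.5), min_size=n, max_size=n))
    d = np.array(d, float)
    e = np.array(e)
    u = np.array(u)
    if d.sum() == 0:
        return
    res = PSMRGraduation(d, e, u).fit()
    smr_end = np.log(u * res.smr) if res.smr > 0 else None
    for i in range(n):
        ends = [smr_end[i]]
        if d[i] > 0:
            ends.append(np.log(u[i] * d[i] / e[i]))
        lo, hi = min(ends), max(ends)
        assert lo - 1e-9 <= np.log(res.v[i]) <= hi + 1e-9


class TestSurfaceGraduation:
    def _surfaces(self, factor=2.0, exposure=1e5):
        ages = np.arange(60.0, 70.0)
        years = np.arange(2005, 2010)
        ref_rate = 1e-4 * np.exp(0.09 * ages)[:, None] * np.ones((1, len(years)))
        ref = RateSurface(kind="mortality", sex="M", ages=ages, years=years, rates=ref_rate)
        ex = np.full(ref_rate.shape, exposure)
        raw = RateSurface(kind="mortality", sex="M", ages=ages, years=years,
                          events=ref_rate * factor * ex, exposure=ex)
        return raw, ref

    def test_constant_ratio_large_counts_reproduce_raw(self):
        raw, ref = self._surfaces(factor=2.0)
        grad = im.psmr_then_model(raw, ref)
        assert np.allclose(grad.rate, raw.rate, rtol=1e-6)

    def test_no_missing_cells_where_reference_positive(self):
        raw, ref = self._surfaces()
        raw.events[3, 2] = 0.0
        grad = im.psmr_then_model(raw, ref)
        assert np.isfinite(grad.rate).all()

    def test_zero_event_column_degenerates_to_zero(self):
        raw, ref = self._surfaces()
        raw.events[:, 1] = 0.0
        with pytest.warns(UserWarning):
            grad = im.psmr_then_model(raw, ref)
        assert np.allclose(grad.rate[:, 1], 0.0)
        assert (grad.rate[:, 0] > 0).all()

    def test_missing_reference_cells_raise(self):
        raw, ref = self._surfaces()
        ref.rates[0, 0] = np.nan
        with pytest.raises(ValueError, match="reference"):
            im.psmr_then_model(raw, ref)
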