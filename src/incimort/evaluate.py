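"""Model evaluation: MAPE, comparison tables, kappa drift and increments.

The comparison table mirrors the standard presentation of mortality-model
benchmarking: model rows, (period, sex) columns of in-sample fitting MAPE
percentages, and a row-average column. Non-converged fits appear as NA and
are dropped from the average.

For trend projection the Lee-Carter period index is summarized by a linear
drift kappa_t = a + b t (OLS on calendar year, centred for conditioning), and
the per-age annual increment of the rate is the factor exp(beta2_x * b).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gapc import KINDS, GAPCModel, GAPCResults
from .graduation import psmr_then_model
from .surfaces import RateSurface, group_ages

PSMR_MODELS = ("PSMR", "PSMR+LC")


def lewis_label(mape_pct: float) -> str:
    """Lewis's interpretive bands for MAPE (attached as labels only)."""
    if not np.isfinite(mape_pct):
        return "NA"
    if mape_pct < 10:
        return "highly accurate"
    if mape_pct < 20:
        return "good"
    if mape_pct <= 50:
        return "reasonable"
    return "unacceptable"


def mape(observed: RateSurface, fitted: RateSurface) -> float:
    """Mean absolute percentage error over defined, non-zero observed cells.

    Cells where the observed rate is zero or missing are excluded (the
    percentage error is undefined there); ``n`` counts included cells only.
    """
    value, _ = mape_with_cells(observed, fitted)
    return value


def mape_with_cells(observed: RateSurface, fitted: RateSurface) -> tuple[float, int]:
    if not np.array_equal(observed.ages, fitted.ages) or not np.array_equal(
        observed.years, fitted.years
    ):
        raise ValueError("observed and fitted surfaces must share age/year indices")
    obs = observed.rate
    fit = fitted.rate
    mask = np.isfinite(obs) & (obs > 0) & np.isfinite(fit)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no includable cells for MAPE (all observed zero/missing)")
    value = float(np.mean(np.abs(obs[mask] - fit[mask]) / obs[mask]) * 100.0)
    return value, n


@dataclass
class MAPEReport:
    """Fitting-MAPE table: model rows x (period, sex) columns + Average."""

    table: pd.DataFrame
    cells_used: pd.DataFrame

    @property
    def average(self) -> pd.Series:
        return self.table["Average"]

    def labelled(self) -> pd.DataFrame:
        """Cells annotated with Lewis's accuracy bands."""
        cols = [c for c in self.table.columns if c != "Average"]
        return self.table[cols].map(lewis_label)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, float_format="%.6g")

    def summary(self) -> str:
        with pd.option_context("display.width", 140, "display.float_format", "{:8.2f}".format):
            return f"Fitting MAPE (%) — NA marks non-converged fits\n{self.table.to_string()}"


def _fit_and_mape(obs: RateSurface, model: str, reference: RateSurface | None,
                  fit_options: dict) -> tuple[float, int]:
    if model in KINDS:
        res = GAPCModel(obs, kind=model).fit(**fit_options)
        if not res.converged:
            return np.nan, 0
        return mape_with_cells(obs, res.fitted_surface)
    if model in PSMR_MODELS:
        if reference is None:
            raise ValueError(f"model {model!r} needs a reference surface")
        grad = psmr_then_model(obs, reference)
        if model == "PSMR":
            return mape_with_cells(obs, grad)
        res = GAPCModel(grad, kind="LC").fit(**fit_options)
        if not res.converged:
            return np.nan, 0
        return mape_with_cells(obs, res.fitted_surface)
    raise ValueError(f"unknown model {model!r}")


def compare_models(
    data: dict[str, RateSurface],
    periods: list[tuple[int, int]],
    models: list[str],
    layout,
    reference: dict[str, RateSurface] | None = None,
    fit_options: dict | None = None,
) -> MAPEReport:
    """Fit every (model, sex, period) combination and tabulate fitting MAPE.

    ``data`` maps sex -> single-age events/exposure surface spanning all
    periods; each period is grouped to ``layout`` before fitting.
    ``reference`` (same mapping) is required when PSMR-based rows are asked
    for. Deterministic given inputs; a model whose fit does not converge in a
    cell yields NA there, and an all-NA row if it never converges.
    """
    fit_options = dict(fit_options or {})
    if any(m in PSMR_MODELS for m in models):
        missing = [s for s in data if reference is None or s not in reference]
        if missing:
            raise ValueError(f"PSMR-based models need reference surfaces for sexes {missing}")
    cols = [f"{p[0]}-{p[1]} {sex}" for p in periods for sex in data]
    values = pd.DataFrame(index=list(models), columns=cols, dtype=float)
    ncells = pd.DataFrame(0, index=list(models), columns=cols, dtype=int)
    for period in periods:
        label = f"{period[0]}-{period[1]}"
        for sex, surface in data.items():
            sub = surface.subset_years(*period)
            obs = group_ages(sub, layout)
            ref = None
            if reference is not None and sex in reference:
                ref_sub = reference[sex].subset_years(*period)
                if ref_sub.events is not None and ref_sub.exposure is not None:
                    ref = group_ages(ref_sub, layout)
                else:
                    # rates-only reference: exposure-weighted mean per group
                    ref = group_ages(ref_sub, layout, weights=sub.exposure)
            for model in models:
                try:
                    v, n = _fit_and_mape(obs, model, ref, fit_options)
                except ValueError:
                    v, n = np.nan, 0
                values.loc[model, f"{label} {sex}"] = v
                ncells.loc[model, f"{label} {sex}"] = n
    values["Average"] = values.mean(axis=1, skipna=True)
    return MAPEReport(table=values, cells_used=ncells)


@dataclass(frozen=True)
class DriftEstimate:
    """Linear drift of the period index: kappa_t = a + b*(t - t_center)."""

    a: float
    b: float
    r_squared: float
    t_center: float

    @property
    def intercept_at_year_zero(self) -> float:
        """a in the uncentred parameterization kappa = a0 + b*t."""
        return self.a - self.b * self.t_center


def kappa_drift(res: GAPCResults) -> DriftEstimate:
    """OLS of the LC-type period index kappa2 on centred calendar year."""
    if res.kappa2 is None:
        raise ValueError(f"{res.kind} fit exposes no kappa2 period index")
    t = res.model.t
    if len(t) < 2:
        raise ValueError("need at least 2 time points for a drift")
    tc = float(t.mean())
    k = res.kappa2
    if np.allclose(k, k[0]):
        return DriftEstimate(a=float(k.mean()), b=0.0, r_squared=1.0, t_center=tc)
    fit = stats.linregress(t - tc, k)
    return DriftEstimate(a=float(fit.intercept), b=float(fit.slope),
                         r_squared=float(fit.rvalue**2), t_center=tc)


@dataclass
class IncrementTable:
    """Per-age annual change factors exp(beta2_x * b) of an LC trend."""

    table: pd.DataFrame  # age_label, age, beta2, factor, percent

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.8g")

    def summary(self) -> str:
        return "Annual increments (LC drift)\n" + self.table.to_string(
            index=False, float_format=lambda v: f"{v:.4f}"
        )


def annual_increments(res: GAPCResults, drift: DriftEstimate) -> IncrementTable:
    """Annual rate-change factors per age from an LC fit and its kappa drift:
    the rate at age x multiplies by exp(beta2_x * b) per calendar year."""
    if res.beta2 is None:
        raise ValueError("annual increments need an LC-type fit with beta2")
    beta = res.beta2
    factor = np.exp(beta * drift.b)
    df = pd.DataFrame(
        {
            "age_or_group": list(res.model.surface.age_labels),
            "age": res.model.x,
            "beta2": beta,
            "factor": factor,
            "percent": (factor - 1.0) * 100.0,
        }
    ).sort_values("age", kind="stable", ignore_index=True)
    return IncrementTable(table=df)
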