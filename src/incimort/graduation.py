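"""Standardized-mortality-ratio graduation of small-population rates.

Raw age-specific rates from a small population fluctuate heavily. The partial
SMR (PSMR) graduates them by shrinking, in log space, each age's raw rate
toward the SMR-scaled reference rate:

    SMR = sum_x d_x / sum_x e_x,            e_x = exposure_x * u*_x,

    v_x = u*_x * exp{ [d_x h2 log(d_x/e_x) + (1 - d_x/D) log SMR]
                      / [d_x h2 + (1 - d_x/D)] },        D = sum_x d_x,

so log v_x is a convex combination of the raw local log rate
log(u*_x d_x/e_x) and the SMR-scaled reference log(u*_x SMR), with weight on
the local component

    w_x = d_x h2 / (d_x h2 + (1 - d_x/D)).

An age with zero observed events gets v_x = SMR * u*_x exactly (the
``0 * log 0`` term is taken as its limit 0). The heterogeneity parameter is
estimated by the method-of-moments

    h2 = max{ [sum_x (d_x - e_x SMR)^2 - sum_x d_x] / (SMR^2 sum_x e_x^2), 0 },

whose numerator has mean ~0 under a homogeneous Poisson model, so h2 ~ 0 when
the small population is just a scaled copy of the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .surfaces import RateSurface


@dataclass(frozen=True)
class GraduationInput:
    """Observed events d_x, expected events e_x = exposure_x * u*_x, and the
    reference-population rates u*_x, aligned by age."""

    d: np.ndarray
    e: np.ndarray
    u_star: np.ndarray | None = None

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        e = np.asarray(self.e, dtype=float)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "e", e)
        if d.shape != e.shape:
            raise ValueError("d and e must align")
        if (d < 0).any() or (e < 0).any():
            raise ValueError("d and e must be nonnegative")
        if not (e > 0).any():
            raise ValueError("at least one e_x must be positive")
        if self.u_star is not None:
            u = np.asarray(self.u_star, dtype=float)
            if u.shape != d.shape:
                raise ValueError("u_star must align with d")
            object.__setattr__(self, "u_star", u)


def smr(inp: GraduationInput) -> float:
    """Standardized mortality (or event) ratio: total observed / total expected."""
    tot_e = inp.e.sum()
    if tot_e <= 0:
        raise ValueError("sum of expected events is zero")
    return float(inp.d.sum() / tot_e)


def estimate_h2(inp: GraduationInput, smr_value: float) -> float:
    """Method-of-moments heterogeneity estimate (clamped at zero)."""
    if smr_value < 0:
        raise ValueError("smr must be >= 0")
    if smr_value == 0:
        return 0.0
    se2 = (inp.e**2).sum()
    if se2 <= 0:
        raise ValueError("sum of squared expected events is zero")
    num = ((inp.d - inp.e * smr_value) ** 2).sum() - inp.d.sum()
    return float(max(num / (smr_value**2 * se2), 0.0))


@dataclass
class GraduationResult:
    """PSMR fit: scalar SMR and h2, graduated rates v_x, and the per-age
    weight w_x placed on the raw local rate."""

    smr: float
    h2: float
    v: np.ndarray
    weights: np.ndarray
    degenerate: bool = False  # all-zero events: v = SMR * u* identically 0

    def summary(self) -> str:
        lines = [
            "PSMR graduation",
            f"  SMR   {self.smr:.6g}",
            f"  h^2   {self.h2:.6g}",
            f"  ages  {len(self.v)}",
        ]
        if self.degenerate:
            lines.append("  WARNING: zero total events; graduated rates are all zero")
        return "\n".join(lines)


class PSMRGraduation:
    """Model object for partial-SMR graduation of one d/e/u* vector.

    Parameters
    ----------
    d, e : arrays
        Observed and expected events by age.
    u_star : array
        Reference-population rates by age.
    h2 : float, optional
        Override the estimated heterogeneity (e.g. a floor); default is the
        method-of-moments estimate.
    h2_floor : float
        Lower bound applied to the estimate (default 0).
    """

    def __init__(self, d, e, u_star, h2: float | None = None, h2_floor: float = 0.0):
        self.input = GraduationInput(d, e, u_star)
        if self.input.u_star is None:
            raise ValueError("u_star is required for graduation")
        self._h2_override = h2
        self.h2_floor = h2_floor

    def fit(self) -> GraduationResult:
        inp = self.input
        d, e, u = inp.d, inp.e, inp.u_star
        s = smr(inp)
        total = d.sum()
        if total == 0:
            warnings.warn("zero total events: graduated rates degenerate to SMR*u* = 0")
            return GraduationResult(smr=0.0, h2=0.0, v=np.zeros_like(u), weights=np.zeros_like(u), degenerate=True)
        h2 = self._h2_override if self._h2_override is not None else max(estimate_h2(inp, s), self.h2_floor)
        with np.errstate(divide="ignore", invalid="ignore"):
            local = np.where(d > 0, d * h2 * np.log(np.where(d > 0, d, 1.0) / np.where(e > 0, e, np.nan)), 0.0)
        comp = 1.0 - d / total
        denom = d * h2 + comp
        num = local + comp * np.log(s)
        with np.errstate(divide="ignore", invalid="ignore"):
            expo = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
            w = np.where(denom > 0, d * h2 / np.where(denom > 0, denom, 1.0), np.nan)
        # denom == 0 only when d_x*h2 = 0 and d_x = total: the h2 -> 0+ limit
        # puts all weight on the local rate for the single event-carrying age
        deg = denom <= 0
        if deg.any():
            raw_log = np.where(d > 0, np.log(np.where(d > 0, d, 1.0) / np.where(e > 0, e, np.nan)), np.log(s))
            expo = np.where(deg, raw_log, expo)
            w = np.where(deg, (d > 0).astype(float), w)
        v = u * np.exp(expo)
        return GraduationResult(smr=s, h2=float(h2), v=v, weights=w)


def psmr_graduate(inp: GraduationInput, h2: float | None = None, h2_floor: float = 0.0) -> GraduationResult:
    """Functional wrapper around :class:`PSMRGraduation`."""
    return PSMRGraduation(inp.d, inp.e, inp.u_star, h2=h2, h2_floor=h2_floor).fit()


def psmr_then_model(raw: RateSurface, reference: RateSurface, h2_floor: float = 0.0) -> RateSurface:
    """Graduate a raw surface column-by-column against a reference surface.

    Each calendar year is graduated separately: e_x is that year's exposure
    times the reference rate, and SMR/h2 are estimated per year-column. The
    result is a rate surface (with pseudo events v * exposure) that downstream
    model fitting can consume like any other surface.
    """
    if not np.array_equal(raw.ages, reference.ages) or not np.array_equal(raw.years, reference.years):
        raise ValueError("raw and reference surfaces must share age/year indices")
    if raw.events is None or raw.exposure is None:
        raise ValueError("raw surface needs events and exposure")
    ref = reference.rate
    if not np.isfinite(ref).all() or (ref <= 0).any():
        raise ValueError("reference surface has missing or non-positive cells")
    A, Y = raw.shape
    v = np.zeros((A, Y))
    for j in range(Y):
        d = raw.events[:, j]
        e = raw.exposure[:, j] * ref[:, j]
        res = PSMRGraduation(d, e, ref[:, j], h2_floor=h2_floor).fit()
        v[:, j] = res.v
    return RateSurface(
        kind=raw.kind,
        sex=raw.sex,
        ages=raw.ages,
        years=raw.years,
        events=v * raw.exposure,
        exposure=raw.exposure.copy(),
        rates=v,
        age_labels=raw.age_labels,
    )
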