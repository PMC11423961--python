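"""Synthetic longitudinal claims generator with known ground truth.

The generator emulates the structure of a national-insurance longitudinal
sample: a registry of persons with sex and birth year, and annual outpatient /
refillable-prescription (RP) claim counts carrying ICD-9 diabetes family code
250 (with excludable type-1 subcodes 250x1/250x3). It simulates, per person
and calendar year and in this order: type-2 onset (age-specific reverse-U
incidence curve, quadratic in age on the logit scale), death (Gompertz baseline
times a treated or untreated hazard multiplier after onset), then the year's
claims. A person dying in year t still emits that year's events: death is
meant to be inferred downstream from the subsequent silence in the claims.

Onset cases take up regular care ("adherent") with probability
``adherence_prob``; adherent cases emit at least 4 diabetes outpatient visits
and at least 1 RP every alive year from onset on, non-adherent cases emit
diabetes-coded events in the onset year only. Everyone emits background
(non-diabetes) outpatient visits, which is what makes claim cessation an
informative death signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .panel import ClaimsPanel
from .surfaces import RateSurface

T2_CODE = "25000"
T1_CODES = ("25001", "25003")
BACKGROUND_CODE = "4659"  # generic non-diabetes outpatient diagnosis


@dataclass(frozen=True)
class IncidenceCurve:
    """Annual onset probability: quadratic in age on the logit scale.

    ``logit p(x) = logit(peak_level) - curvature * (x - peak_age)^2``, then an
    optional log-rate drift ``exp(log_drift * (t - t0))`` in calendar time.
    Defaults: 2% peak at age 75, ~0.5% at age 45, +3%/year drift.
    """

    peak_age: float = 75.0
    peak_level: float = 0.02
    curvature: float = 1.5e-3
    log_drift: float = 0.03

    def prob(self, age, dt=0.0) -> np.ndarray:
        base = expit(logit(self.peak_level) - self.curvature * (np.asarray(age, float) - self.peak_age) ** 2)
        return np.clip(base * np.exp(self.log_drift * dt), 0.0, 1.0)


@dataclass(frozen=True)
class GompertzMortality:
    """Annual death probability ``q_x = min(1, a * exp(b * x))`` with an
    optional calendar log-rate drift. Defaults give q(75) ~ 3.6%."""

    a: float = 2e-5
    b: float = 0.10
    log_drift: float = 0.02

    def prob(self, age, dt=0.0) -> np.ndarray:
        return np.clip(self.a * np.exp(self.b * np.asarray(age, float) + self.log_drift * dt), 0.0, 1.0)


@dataclass(frozen=True)
class PanelConfig:
    """All knobs of the synthetic claims generator.

    The defaults are the package's study conditions; identical (config, seed)
    pairs reproduce byte-identical panels.
    """

    n_persons: int = 200_000
    year_range: tuple[int, int] = (2003, 2013)
    age_range_at_start: tuple[int, int] = (35, 99)
    sex_ratio: float = 0.5  # proportion male
    incidence_curve: IncidenceCurve = field(default_factory=IncidenceCurve)
    baseline_mortality: GompertzMortality = field(default_factory=GompertzMortality)
    treated_multiplier: float = 1.0
    untreated_multiplier: float = 1.5
    adherence_prob: float = 0.8
    background_visit_rate: float = 6.0
    diabetes_visit_mean: float = 6.0  # adherent yearly diabetes outpatient visits, floored at 4
    rp_visit_mean: float = 2.0  # per-person annual RP count max(Poisson(mean), 1), drawn once
    onset_visit_mean: float = 2.0  # non-adherent onset-year diabetes visits = 1 + Poisson(mean)
    type1_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        def _prob(name):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")

        if self.n_persons < 1:
            raise ValueError(f"n_persons must be >= 1, got {self.n_persons!r}")
        y0, y1 = self.year_range
        if y1 < y0:
            raise ValueError(f"year_range is empty: {self.year_range!r}")
        a0, a1 = self.age_range_at_start
        if a1 < a0 or a0 < 0:
            raise ValueError(f"age_range_at_start invalid: {self.age_range_at_start!r}")
        for name in ("sex_ratio", "adherence_prob", "type1_fraction"):
            _prob(name)
        for name in ("treated_multiplier", "untreated_multiplier", "background_visit_rate",
                     "diabetes_visit_mean", "rp_visit_mean", "onset_visit_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if not (0.0 < self.incidence_curve.peak_level < 1.0):
            raise ValueError("incidence_curve.peak_level must lie in (0, 1)")
        if self.incidence_curve.curvature < 0:
            raise ValueError("incidence_curve.curvature must be >= 0")
        if self.baseline_mortality.a <= 0:
            raise ValueError("baseline_mortality.a must be > 0")

    def with_(self, **kwargs) -> "PanelConfig":
        """Functional update helper (nested fields accept plain dicts)."""
        if isinstance(kwargs.get("incidence_curve"), dict):
            kwargs["incidence_curve"] = replace(self.incidence_curve, **kwargs["incidence_curve"])
        if isinstance(kwargs.get("baseline_mortality"), dict):
            kwargs["baseline_mortality"] = replace(self.baseline_mortality, **kwargs["baseline_mortality"])
        return replace(self, **kwargs)


def generate_panel(config: PanelConfig, seed: int | None = None) -> ClaimsPanel:
    """Simulate a claims panel under ``config``.

    ``seed`` overrides ``config.seed``. Returns a :class:`ClaimsPanel` with
    per-person ground truth (onset_year, death_year, adherent).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_persons
    y0, y1 = config.year_range
    years = np.arange(y0, y1 + 1)
    a0, a1 = config.age_range_at_start

    sex_male = rng.random(n) < config.sex_ratio
    age0 = rng.integers(a0, a1 + 1, size=n)
    birth_year = y0 - age0
    adherent = rng.random(n) < config.adherence_prob
    # care intensity is a stable per-person trait: the annual RP count of an
    # adherent case is drawn once and repeated every year under care
    rp_base = np.maximum(rng.poisson(config.rp_visit_mean, n), 1)

    alive = np.ones(n, dtype=bool)
    diabetic = np.zeros(n, dtype=bool)
    onset_year = np.full(n, -1)
    death_year = np.full(n, -1)

    pid = np.arange(n)
    chunks: list[pd.DataFrame] = []

    def emit(mask_counts: np.ndarray, year: int, claim_type: str, code: str):
        sel = mask_counts > 0
        if not sel.any():
            return
        chunks.append(
            pd.DataFrame(
                {
                    "person_id": pid[sel],
                    "year": year,
                    "claim_type": claim_type,
                    "icd_code": code,
                    "n": mask_counts[sel].astype(np.int64),
                }
            )
        )

    for t in years:
        dt = float(t - y0)
        age = t - birth_year

        # 1. onset among alive, diabetes-free persons
        p_on = config.incidence_curve.prob(age, dt)
        new_onset = alive & ~diabetic & (rng.random(n) < p_on)
        diabetic |= new_onset
        onset_year[new_onset] = t

        # 2. death (multiplier applies from the onset year on)
        mult = np.where(diabetic, np.where(adherent, config.treated_multiplier, config.untreated_multiplier), 1.0)
        q = np.clip(config.baseline_mortality.prob(age, dt) * mult, 0.0, 1.0)
        dies = alive & (rng.random(n) < q)

        # 3. claims for everyone alive during t (including those dying in t)
        active = alive
        n_bg = np.where(active, rng.poisson(config.background_visit_rate, n), 0)
        adh_dm = active & diabetic & adherent
        n_dm = np.where(adh_dm, np.maximum(rng.poisson(config.diabetes_visit_mean, n), 4), 0)
        n_rp = np.where(adh_dm, rp_base, 0)
        nonadh_onset = new_onset & ~adherent
        n_dm = n_dm + np.where(nonadh_onset, 1 + rng.poisson(config.onset_visit_mean, n), 0)

        # per-event type-1 subcoding of diabetes-family claims
        k1_dm = rng.binomial(n_dm, config.type1_fraction)
        k1_rp = rng.binomial(n_rp, config.type1_fraction)
        k1a_dm = rng.binomial(k1_dm, 0.5)
        k1a_rp = rng.binomial(k1_rp, 0.5)

        emit(n_bg, t, "outpatient", BACKGROUND_CODE)
        emit(n_dm - k1_dm, t, "outpatient", T2_CODE)
        emit(k1a_dm, t, "outpatient", T1_CODES[0])
        emit(k1_dm - k1a_dm, t, "outpatient", T1_CODES[1])
        emit(n_rp - k1_rp, t, "rp", T2_CODE)
        emit(k1a_rp, t, "rp", T1_CODES[0])
        emit(k1_rp - k1a_rp, t, "rp", T1_CODES[1])

        alive &= ~dies
        death_year[dies] = t

    persons = pd.DataFrame(
        {
            "person_id": pid,
            "sex": np.where(sex_male, "M", "F"),
            "birth_year": birth_year,
            "first_year": y0,
            "last_year": y1,
        }
    )
    events = (
        pd.concat(chunks, ignore_index=True)
        if chunks
        else pd.DataFrame(columns=["person_id", "year", "claim_type", "icd_code", "n"])
    )
    truth = pd.DataFrame(
        {
            "person_id": pid,
            "onset_year": np.where(onset_year >= 0, onset_year, np.nan),
            "death_year": np.where(death_year >= 0, death_year, np.nan),
            "adherent": adherent,
        }
    )
    return ClaimsPanel(persons=persons, events=events, truth=truth)


def true_rate_surface(
    config: PanelConfig,
    kind: str,
    sex: str = "both",
    ages: np.ndarray | None = None,
    years: np.ndarray | None = None,
    population: str = "treated",
) -> RateSurface:
    """Noise-free age x year probability surface implied by the config.

    ``kind`` is ``"incidence"`` or ``"mortality"``. For mortality,
    ``population`` selects the hazard multiplier: ``"general"`` (baseline),
    ``"treated"`` or ``"untreated"``. Constant over years unless the relevant
    curve's ``log_drift`` is non-zero, in which case log-rates move linearly
    in calendar time.
    """
    y0, y1 = config.year_range
    if years is None:
        years = np.arange(y0, y1 + 1)
    years = np.asarray(years, dtype=int)
    if ages is None:
        ages = np.arange(45, 100)
    ages = np.asarray(ages, dtype=float)
    dt = (years - y0)[None, :].astype(float)
    agegrid = ages[:, None]
    if kind == "incidence":
        rates = config.incidence_curve.prob(np.broadcast_to(agegrid, (len(ages), len(years))), np.broadcast_to(dt, (len(ages), len(years))))
    elif kind == "mortality":
        mult = {
            "general": 1.0,
            "treated": config.treated_multiplier,
            "untreated": config.untreated_multiplier,
        }.get(population)
        if mult is None:
            raise ValueError(f"unknown population {population!r}")
        base = config.baseline_mortality.prob(
            np.broadcast_to(agegrid, (len(ages), len(years))),
            np.broadcast_to(dt, (len(ages), len(years))),
        )
        rates = np.clip(base * mult, 0.0, 1.0)
    else:
        raise ValueError(f"unsupported rate kind {kind!r} (use 'incidence' or 'mortality')")
    return RateSurface(kind=kind, sex=sex, ages=ages, years=years, rates=rates)
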