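"""End-to-end study pipeline: simulate -> cohort -> rates -> graduate ->
fit -> compare -> project, driven by one YAML-able configuration.

Every parameter choice is written to ``study_log.yaml`` alongside the
outputs, and all randomness flows from the single study seed, so a fixed
(config, seed) pair reproduces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (DeathTable, DiseaseCriterion, classify_diabetic,
                     death_inference_performance, infer_deaths)
from .evaluate import annual_increments, compare_models, kappa_drift
from .gapc import GAPCModel
from .panel import ClaimsPanel
from .rates import rate_surfaces
from .simulate import PanelConfig, generate_panel, true_rate_surface
from .surfaces import RateSurface, group_ages

DEFAULT_MODELS = ["LC", "APC", "PSMR", "PSMR+LC", "CBD", "RH"]


@dataclass(frozen=True)
class DeathRule:
    min_age: int = 65
    min_prior_utilization_years: int = 2
    silence_horizon: int = 2


@dataclass
class StudyConfig:
    """Full study configuration with the package's default conditions."""

    panel: PanelConfig = field(default_factory=PanelConfig)
    criterion: DiseaseCriterion = field(default_factory=DiseaseCriterion)
    comparison_criterion: DiseaseCriterion = field(
        default_factory=lambda: DiseaseCriterion(mode="rp_count", threshold=2)
    )
    death_rule: DeathRule = field(default_factory=DeathRule)
    washout_years: int = 2
    incidence_ages: tuple[int, int] = (45, 99)
    mortality_ages: tuple[int, int] = (65, 99)
    incidence_periods: list = field(
        default_factory=lambda: [(2005, 2013), (2007, 2012), (2008, 2013)]
    )
    trend_period: tuple[int, int] = (2008, 2013)
    models: list = field(default_factory=lambda: list(DEFAULT_MODELS))
    seed: int = 20240925

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        raw = dict(raw or {})
        kwargs = {}
        if "panel" in raw:
            kwargs["panel"] = PanelConfig().with_(**raw.pop("panel"))
        if "criterion" in raw:
            kwargs["criterion"] = DiseaseCriterion(**raw.pop("criterion"))
        if "comparison_criterion" in raw:
            kwargs["comparison_criterion"] = DiseaseCriterion(**raw.pop("comparison_criterion"))
        if "death_rule" in raw:
            kwargs["death_rule"] = DeathRule(**raw.pop("death_rule"))
        for key in ("washout_years", "seed", "models"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        for key in ("incidence_ages", "mortality_ages", "trend_period"):
            if key in raw:
                kwargs[key] = tuple(raw.pop(key))
        if "incidence_periods" in raw:
            kwargs["incidence_periods"] = [tuple(p) for p in raw.pop("incidence_periods")]
        if raw:
            raise ValueError(f"unknown study-config keys: {sorted(raw)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        def _plain(v):
            if isinstance(v, dict):
                return {k: _plain(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [_plain(x) for x in v]
            if isinstance(v, (np.integer,)):
                return int(v)
            if isinstance(v, (np.floating,)):
                return float(v)
            return v

        return _plain(asdict(self))


def load_config(path: str | Path) -> StudyConfig:
    return StudyConfig.from_yaml(path)


@dataclass
class StudyResult:
    """Objects and file paths produced by :func:`run_study`."""

    panel: ClaimsPanel
    deaths: DeathTable
    incidence: dict
    mortality: dict
    reports: dict
    increments: dict
    drift: dict
    criterion_comparison: pd.DataFrame
    death_performance: dict
    out_dir: Path | None


def _mortality_years(cfg: StudyConfig) -> tuple[int, int]:
    y0, y1 = cfg.panel.year_range
    return (y0 + cfg.death_rule.min_prior_utilization_years,
            y1 - cfg.death_rule.silence_horizon)


def run_study(cfg: StudyConfig, out_dir: str | Path | None = None,
              seed: int | None = None) -> StudyResult:
    """Run the whole analysis; write CSV/JSON/YAML outputs if ``out_dir``."""
    seed = cfg.seed if seed is None else seed
    panel = generate_panel(cfg.panel, seed=seed)
    status = classify_diabetic(panel, cfg.criterion)
    status_cmp = classify_diabetic(panel, cfg.comparison_criterion)
    deaths = infer_deaths(
        panel,
        min_age=cfg.death_rule.min_age,
        min_prior_utilization_years=cfg.death_rule.min_prior_utilization_years,
        silence_horizon=cfg.death_rule.silence_horizon,
    )
    y0, y1 = cfg.panel.year_range
    inc_years = (y0 + cfg.washout_years, y1)
    mort_years = _mortality_years(cfg)

    sexes = ("M", "F")
    incidence, mortality, inc_ref, mort_ref = {}, {}, {}, {}
    for sex in sexes:
        incidence[sex] = rate_surfaces(
            panel, status, "incidence", sex=sex, ages=cfg.incidence_ages,
            years=inc_years, washout_years=cfg.washout_years, deaths=deaths,
        )
        mortality[sex] = rate_surfaces(
            panel, status, "mortality", sex=sex, ages=cfg.mortality_ages,
            years=mort_years, deaths=deaths, min_age=cfg.death_rule.min_age,
        )
        inc_ref[sex] = true_rate_surface(
            cfg.panel, "incidence", sex=sex,
            ages=np.arange(cfg.incidence_ages[0], cfg.incidence_ages[1] + 1),
            years=np.arange(inc_years[0], inc_years[1] + 1),
        )
        mort_ref[sex] = true_rate_surface(
            cfg.panel, "mortality", sex=sex, population="general",
            ages=np.arange(cfg.mortality_ages[0], cfg.mortality_ages[1] + 1),
            years=np.arange(mort_years[0], mort_years[1] + 1),
        )

    reports = {
        "incidence_five": compare_models(
            incidence, cfg.incidence_periods, cfg.models, "five_45_99", reference=inc_ref
        ),
        "incidence_single": compare_models(
            incidence, cfg.incidence_periods, cfg.models, "single_45_89", reference=inc_ref
        ),
        "mortality_five": compare_models(
            mortality, [mort_years], cfg.models, "five_70_99", reference=mort_ref
        ),
        "mortality_single": compare_models(
            mortality, [mort_years], cfg.models, "single_70_89", reference=mort_ref
        ),
    }

    # LC trend: kappa drift and per-age annual increments
    increments, drift = {}, {}
    for sex in sexes:
        inc_obs = group_ages(incidence[sex].subset_years(*cfg.trend_period), "five_45_99")
        res = GAPCModel(inc_obs, kind="LC").fit()
        d = kappa_drift(res)
        drift[f"incidence_{sex}"] = d
        increments[f"incidence_{sex}"] = annual_increments(res, d)
        mort_obs = group_ages(mortality[sex], "five_70_99")
        res_m = GAPCModel(mort_obs, kind="LC").fit()
        dm = kappa_drift(res_m)
        drift[f"mortality_{sex}"] = dm
        increments[f"mortality_{sex}"] = annual_increments(res_m, dm)

    crit_cmp = criterion_comparison(panel, status, status_cmp, cfg, deaths=deaths)
    perf = death_inference_performance(panel, deaths) if panel.truth is not None else {}

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        for sex in sexes:
            incidence[sex].to_csv(out / f"incidence_{sex}.csv")
            mortality[sex].to_csv(out / f"mortality_{sex}.csv")
        for name, rep in reports.items():
            rep.to_csv(out / f"mape_{name}.csv")
        for name, inc in increments.items():
            inc.to_csv(out / f"increments_{name}.csv")
        crit_cmp.to_csv(out / "criterion_comparison.csv", index=False, float_format="%.10g")
        log = {
            "config": cfg.to_dict(),
            "seed_used": int(seed),
            "incidence_years": list(inc_years),
            "mortality_years": list(mort_years),
            "drift": {k: asdict(v) for k, v in drift.items()},
            "death_inference": {k: float(v) if isinstance(v, float) else v for k, v in perf.items()},
        }
        (out / "study_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
    return StudyResult(
        panel=panel, deaths=deaths, incidence=incidence, mortality=mortality,
        reports=reports, increments=increments, drift=drift,
        criterion_comparison=crit_cmp, death_performance=perf, out_dir=out,
    )


def criterion_comparison(panel: ClaimsPanel, status_a, status_b, cfg: StudyConfig,
                         deaths: DeathTable | None = None) -> pd.DataFrame:
    """Age-group incidence rates under two disease criteria, pooled over all
    years with a full washout window (direction check: the stricter criterion
    yields lower rates)."""
    y0, y1 = cfg.panel.year_range
    rows = []
    for sex in ("M", "F"):
        surfs = {}
        for name, st in (("a", status_a), ("b", status_b)):
            s = rate_surfaces(
                panel, st, "incidence", sex=sex, ages=cfg.incidence_ages,
                years=(y0 + cfg.washout_years, y1), washout_years=cfg.washout_years,
                deaths=deaths,
            )
            surfs[name] = group_ages(s, "five_45_99")
        a, b = surfs["a"], surfs["b"]
        ev_a, ex_a = a.events.sum(1), a.exposure.sum(1)
        ev_b, ex_b = b.events.sum(1), b.exposure.sum(1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ra = np.where(ex_a > 0, ev_a / np.maximum(ex_a, 1), np.nan)
            rb = np.where(ex_b > 0, ev_b / np.maximum(ex_b, 1), np.nan)
            ratio = np.where(ra > 0, rb / np.where(ra > 0, ra, 1), np.nan)
        for i, lab in enumerate(a.age_labels):
            rows.append(
                {
                    "sex": sex,
                    "age_group": lab,
                    "criterion_a": f"{status_a.criterion.mode}>={status_a.criterion.threshold}",
                    "rate_a": ra[i],
                    "criterion_b": f"{status_b.criterion.mode}>={status_b.criterion.threshold}",
                    "rate_b": rb[i],
                    "ratio_b_over_a": ratio[i],
                }
            )
    return pd.DataFrame(rows)
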