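"""Person-year accounting: status/death tables -> age x year rate surfaces.

Annual grain throughout: every observed year contributes one full person-year
of exposure, including an inferred death year (the death year is the person's
last year with claims, so they remain in that year's exposure and deaths).

Denominators by rate kind:

* incidence — diabetes-free observed person-years that also satisfy the
  washout observability requirement (observed and unflagged in each of the
  preceding ``washout_years``); events are the incident cases;
* mortality — diabetic (criterion-satisfying, or ever-diabetic with
  ``denominator="ever"``) person-years at ages >= ``min_age`` among persons
  eligible for death inference; events are inferred deaths of diabetics;
* prevalence — all observed person-years; events are flagged person-years.

When a :class:`~incimort.cohort.DeathTable` is supplied, observation is
truncated at the inferred death year for every kind: the registry keeps a
dead person enrolled (their claims simply stop, which is what makes the
cessation rule work), so without truncation the silent years after death
would pollute incidence and prevalence denominators with person-years that
can never produce an event.
"""

from __future__ import annotations

import numpy as np

from .cohort import DeathTable, StatusTable, incident_cases
from .panel import ClaimsPanel
from .surfaces import RateSurface


def _age_year_counts(ages_of_rows, years_col, mask, age_index, out):
    """Accumulate mask counts into out[(age, year)] for one year column."""
    ages = ages_of_rows[mask]
    lo, hi = age_index[0], age_index[-1]
    sel = (ages >= lo) & (ages <= hi)
    if sel.any():
        np.add.at(out[:, years_col], (ages[sel] - lo).astype(int), 1)


def rate_surfaces(
    panel: ClaimsPanel,
    status: StatusTable,
    kind: str,
    sex: str = "both",
    ages: tuple[int, int] = (45, 99),
    years: tuple[int, int] | None = None,
    deaths: DeathTable | None = None,
    washout_years: int = 2,
    min_age: int = 65,
    denominator: str = "current",
) -> RateSurface:
    """Build the (events, exposure) surface of ``kind`` for one sex.

    ``years`` restricts the calendar window (e.g. mortality is only estimable
    where the cessation rule can call deaths). Returns a combined surface with
    both events and exposure filled.
    """
    if kind not in ("incidence", "mortality", "prevalence"):
        raise ValueError(f"unsupported rate kind {kind!r}")
    if kind == "mortality" and deaths is None:
        raise ValueError("mortality surfaces need a DeathTable")
    if denominator not in ("current", "ever"):
        raise ValueError(f"unknown denominator {denominator!r}")

    y0, y1 = int(status.years[0]), int(status.years[-1])
    if years is None:
        years = (y0 + washout_years, y1) if kind == "incidence" else (y0, y1)
    yfirst, ylast = years
    if yfirst < y0 or ylast > y1:
        raise ValueError(f"years {years} outside panel span {y0}-{y1}")
    year_index = np.arange(yfirst, ylast + 1)
    age_index = np.arange(ages[0], ages[1] + 1)

    if sex == "both":
        smask = np.ones(len(status.person_ids), dtype=bool)
    else:
        smask = panel.persons["sex"].to_numpy() == sex

    birth = status.birth_year
    flags = status.flags
    observed = status.observed
    A, Y = len(age_index), len(year_index)
    events = np.zeros((A, Y))
    exposure = np.zeros((A, Y))

    ever_flagged = np.zeros(len(status.person_ids), dtype=bool)
    dead_year = None
    if deaths is not None:
        dead_year = np.full(len(status.person_ids), np.iinfo(np.int64).max)
        pos = {p: i for i, p in enumerate(status.person_ids)}
        for p, yy in zip(deaths.table["person_id"].to_numpy(), deaths.table["year"].to_numpy()):
            dead_year[pos[p]] = yy

    # cumulative "ever flagged up to and including t" built in panel-year order
    for jpanel, t in enumerate(status.years):
        ever_flagged |= flags[:, jpanel]
        if t < yfirst or t > ylast:
            continue
        jc = t - yfirst
        age_t = t - birth
        pre_death = np.ones(len(status.person_ids), dtype=bool) if dead_year is None else (t <= dead_year)

        if kind == "prevalence":
            elig = observed[:, jpanel] & smask & pre_death
            _age_year_counts(age_t, jc, elig, age_index, exposure)
            _age_year_counts(age_t, jc, elig & flags[:, jpanel], age_index, events)
        elif kind == "incidence":
            if jpanel - washout_years < 0:
                raise ValueError(
                    f"incidence year {t} lacks a full {washout_years}-year washout window"
                )
            elig = observed[:, jpanel] & smask & pre_death
            for k in range(1, washout_years + 1):
                elig &= observed[:, jpanel - k] & ~flags[:, jpanel - k]
            _age_year_counts(age_t, jc, elig, age_index, exposure)
            _age_year_counts(age_t, jc, elig & flags[:, jpanel], age_index, events)
        else:  # mortality
            diab = flags[:, jpanel] if denominator == "current" else ever_flagged
            elig = diab & observed[:, jpanel] & smask & (age_t >= min_age) & pre_death
            _age_year_counts(age_t, jc, elig, age_index, exposure)
            died_now = dead_year == t
            _age_year_counts(age_t, jc, elig & died_now, age_index, events)

    return RateSurface(
        kind=kind,
        sex=sex,
        ages=age_index.astype(float),
        years=year_index,
        events=events,
        exposure=exposure,
    )


def compute_exposures(
    panel: ClaimsPanel, status: StatusTable, kind: str, **kwargs
) -> RateSurface:
    """Exposure-only view of :func:`rate_surfaces` (same accounting rules)."""
    s = rate_surfaces(panel, status, kind, **kwargs)
    return RateSurface(
        kind=s.kind, sex=s.sex, ages=s.ages, years=s.years,
        exposure=s.exposure, age_labels=s.age_labels,
    )


__all__ = ["rate_surfaces", "compute_exposures", "incident_cases"]
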