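"""Cohort construction from a claims panel.

Three steps turn raw claims into analyzable person-year tables:

* :func:`classify_diabetic` — per-calendar-year disease status under an
  explicit criterion (e.g. >=4 diabetes outpatient visits per year, or >=1
  refillable chronic prescription per year), with ICD-9 family 250 inclusion
  and type-1 subcode (250x1 / 250x3) exclusion;
* :func:`incident_cases` — new cases in a year, requiring a disease-free and
  fully observed two-year washout (observation) window beforehand;
* :func:`infer_deaths` — death ascertained from permanent claim cessation,
  applied only at ages >= 65 where near-universal utilization makes silence
  informative. The inferred death year is the last year with claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ClaimsPanel


@dataclass(frozen=True)
class DiseaseCriterion:
    """Per-calendar-year claim-count criterion for diabetes status."""

    mode: str = "rp_count"  # or "outpatient_visits"
    threshold: int = 1
    include_code_family: str = "250"
    exclude_subcode_digits: tuple[str, ...] = ("1", "3")  # 250x1 / 250x3 families

    def __post_init__(self):
        if self.mode not in ("outpatient_visits", "rp_count"):
            raise ValueError(f"unknown criterion mode {self.mode!r}")
        if self.threshold < 1:
            raise ValueError(f"threshold must be >= 1, got {self.threshold!r}")

    @property
    def claim_type(self) -> str:
        return "outpatient" if self.mode == "outpatient_visits" else "rp"

    def code_mask(self, codes: pd.Series) -> pd.Series:
        """True for codes in the included family and not in an excluded
        subcode family (exclusion is by subcode membership, not numeric range)."""
        codes = codes.astype(str)
        fam = codes.str.startswith(self.include_code_family)
        k = len(self.include_code_family) + 1  # position of the subcode digit
        sub = codes.str.len() >= (k + 1)
        excl = fam & sub & codes.str[k].isin(self.exclude_subcode_digits)
        return fam & ~excl


@dataclass
class StatusTable:
    """Dense (person x year) disease flags for one criterion.

    Rows are aligned with ``panel.persons``; ``observed`` marks each person's
    observation window, and flags are defined only for observed person-years.
    """

    person_ids: np.ndarray
    years: np.ndarray
    flags: np.ndarray  # bool (P, Y)
    observed: np.ndarray  # bool (P, Y)
    criterion: DiseaseCriterion
    birth_year: np.ndarray = field(default=None)  # type: ignore[assignment]

    def year_col(self, year: int) -> int:
        idx = np.searchsorted(self.years, year)
        if idx >= len(self.years) or self.years[idx] != year:
            raise ValueError(f"year {year} outside panel years {self.years[0]}-{self.years[-1]}")
        return int(idx)

    def to_frame(self) -> pd.DataFrame:
        """Long audit format: one row per flagged person-year."""
        p, y = np.nonzero(self.flags)
        return pd.DataFrame(
            {"person_id": self.person_ids[p], "year": self.years[y], "flag": 1}
        )


def _person_matrices(panel: ClaimsPanel):
    persons = panel.persons
    pids = persons["person_id"].to_numpy()
    y0, y1 = panel.year_range
    years = np.arange(y0, y1 + 1)
    fy = persons["first_year"].to_numpy()[:, None]
    ly = persons["last_year"].to_numpy()[:, None]
    observed = (years[None, :] >= fy) & (years[None, :] <= ly)
    return pids, years, observed


def _count_matrix(panel: ClaimsPanel, events: pd.DataFrame, pids, years) -> np.ndarray:
    pos = pd.Series(np.arange(len(pids)), index=pids)
    counts = np.zeros((len(pids), len(years)), dtype=np.int64)
    if len(events):
        rows = pos.loc[events["person_id"]].to_numpy()
        cols = events["year"].to_numpy() - years[0]
        np.add.at(counts, (rows, cols), events["n"].to_numpy())
    return counts


def classify_diabetic(panel: ClaimsPanel, criterion: DiseaseCriterion) -> StatusTable:
    """Flag (person, year) iff the year's count of criterion-mode claims with
    an included, non-excluded diabetes code reaches the threshold."""
    pids, years, observed = _person_matrices(panel)
    ev = panel.events
    if len(ev):
        mask = (ev["claim_type"] == criterion.claim_type) & criterion.code_mask(ev["icd_code"])
        ev = ev.loc[mask]
    counts = _count_matrix(panel, ev, pids, years)
    flags = (counts >= criterion.threshold) & observed
    return StatusTable(
        person_ids=pids,
        years=years,
        flags=flags,
        observed=observed,
        criterion=criterion,
        birth_year=panel.persons["birth_year"].to_numpy(),
    )


def incident_cases(status: StatusTable, year: int, washout_years: int = 2) -> np.ndarray:
    """Person ids newly flagged in ``year`` after a clean washout window.

    A person is incident iff flagged in ``year``, and observed *and* unflagged
    in each of the ``washout_years`` preceding years. Persons not observed
    through the full window are excluded (washout unverifiable).
    """
    j = status.year_col(year)
    if j - washout_years < 0:
        raise ValueError(
            f"year {year} has fewer than {washout_years} prior panel years; "
            "restrict the incidence year range to years with a full washout window"
        )
    ok = status.flags[:, j] & status.observed[:, j]
    for k in range(1, washout_years + 1):
        ok &= status.observed[:, j - k] & ~status.flags[:, j - k]
    return status.person_ids[ok]


@dataclass
class DeathTable:
    """Inferred deaths: person_id -> death year, plus the rule parameters."""

    table: pd.DataFrame  # person_id, year
    min_age: int
    min_prior_utilization_years: int
    silence_horizon: int

    def __len__(self):
        return len(self.table)

    def as_dict(self) -> dict:
        return dict(zip(self.table["person_id"], self.table["year"]))

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def infer_deaths(
    panel: ClaimsPanel,
    min_age: int = 65,
    min_prior_utilization_years: int = 2,
    silence_horizon: int = 2,
) -> DeathTable:
    """Infer deaths from permanent claim cessation.

    A person is inferred dead in year ``t`` (their last year with any claim)
    iff: age at ``t`` >= ``min_age``; they have >=1 claim in ``t`` and in each
    of the ``min_prior_utilization_years`` preceding (observed) years; and
    every observed year after ``t`` is claim-free with at least
    ``silence_horizon`` such silent years before the panel ends. Persons whose
    silence window is truncated by the end of the panel are censored, not
    dead — so the last ``silence_horizon`` panel years yield no death calls.
    """
    y0, y1 = panel.year_range
    if (y1 - y0 + 1) < min_prior_utilization_years + 1:
        raise ValueError("panel too short for the prior-utilization requirement")
    pids, years, observed = _person_matrices(panel)
    any_claim = _count_matrix(panel, panel.events, pids, years) > 0
    has = any_claim.any(axis=1)
    Y = len(years)
    # last column with a claim (valid only where has)
    last = Y - 1 - np.argmax(any_claim[:, ::-1], axis=1)
    ok = has.copy()
    # prior utilization: claims in each of the preceding years (inside the window)
    for k in range(1, min_prior_utilization_years + 1):
        idx = last - k
        valid = idx >= 0
        prior = np.zeros(len(pids), dtype=bool)
        prior[valid] = any_claim[np.nonzero(valid)[0], idx[valid]] & observed[np.nonzero(valid)[0], idx[valid]]
        ok &= prior
    # silence: every year after `last` is claim-free by construction of `last`;
    # require at least silence_horizon observed years after it (censoring)
    ly = panel.persons["last_year"].to_numpy()
    death_years = years[np.clip(last, 0, Y - 1)]
    ok &= (ly - death_years) >= silence_horizon
    for k in range(1, silence_horizon + 1):
        idx = last + k
        valid = idx <= Y - 1
        cur = np.zeros(len(pids), dtype=bool)
        cur[valid] = observed[np.nonzero(valid)[0], idx[valid]]
        ok &= cur
    # age criterion
    birth = panel.persons["birth_year"].to_numpy()
    ok &= (death_years - birth) >= min_age
    table = pd.DataFrame({"person_id": pids[ok], "year": death_years[ok]})
    return DeathTable(
        table=table,
        min_age=min_age,
        min_prior_utilization_years=min_prior_utilization_years,
        silence_horizon=silence_horizon,
    )


def death_inference_performance(panel: ClaimsPanel, deaths: DeathTable) -> dict:
    """Sensitivity/specificity of the cessation rule against synthetic truth.

    Sensitivity is computed over truth deaths inside the callable window
    [panel_start + min_prior_utilization_years, panel_end - silence_horizon]
    at ages >= min_age (the rule cannot, by construction, call deaths outside
    that window). Requires a panel with truth.
    """
    if panel.truth is None:
        raise ValueError("performance metrics need a panel with ground truth")
    y0, y1 = panel.year_range
    lo = y0 + deaths.min_prior_utilization_years
    hi = y1 - deaths.silence_horizon
    t = panel.truth.merge(panel.persons[["person_id", "birth_year"]], on="person_id")
    age_at_death = t["death_year"] - t["birth_year"]
    in_window = (
        t["death_year"].notna()
        & (t["death_year"] >= lo)
        & (t["death_year"] <= hi)
        & (age_at_death >= deaths.min_age)
    )
    truth_dead = t.loc[in_window, ["person_id", "death_year"]]
    inferred = deaths.as_dict()
    hit = sum(
        inferred.get(p, None) == y for p, y in zip(truth_dead["person_id"], truth_dead["death_year"])
    )
    n_dead = len(truth_dead)
    # specificity: persons alive through the panel that were never called dead
    alive = t.loc[t["death_year"].isna(), "person_id"]
    false_pos = sum(p in inferred for p in alive)
    return {
        "sensitivity": hit / n_dead if n_dead else float("nan"),
        "n_truth_deaths": int(n_dead),
        "specificity": 1.0 - false_pos / len(alive) if len(alive) else float("nan"),
        "n_false_positives": int(false_pos),
    }
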