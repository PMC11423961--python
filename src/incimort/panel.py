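"""Longitudinal claims panel: person registry plus year-stamped claim events.

The panel is the raw input of the whole pipeline. Events live at an annual
grain (no dates within a year) and are stored aggregated: one row per
(person_id, year, claim_type, icd_code) with a count column ``n``. A person's
age in year ``t`` is ``t - birth_year`` throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CLAIM_TYPES = ("outpatient", "inpatient", "rp")

PERSON_COLS = ["person_id", "sex", "birth_year", "first_year", "last_year"]
EVENT_COLS = ["person_id", "year", "claim_type", "icd_code", "n"]
TRUTH_COLS = ["person_id", "onset_year", "death_year", "adherent"]


@dataclass
class ClaimsPanel:
    """Person registry, claim events and (synthetic panels only) ground truth.

    Attributes
    ----------
    persons : DataFrame
        person_id, sex ('M'/'F'), birth_year, first_year, last_year
        (inclusive observation window).
    events : DataFrame
        person_id, year, claim_type, icd_code, n (count of identical claims).
    truth : DataFrame or None
        person_id, onset_year, death_year (NaN if none), adherent flag.
    """

    persons: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame | None = None

    @property
    def year_range(self) -> tuple[int, int]:
        return int(self.persons["first_year"].min()), int(self.persons["last_year"].max())

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    def validate(self) -> None:
        """Raise ValueError on any violated panel invariant."""
        p, e = self.persons, self.events
        if p["person_id"].duplicated().any():
            raise ValueError("duplicate person_id in registry")
        if not set(e["claim_type"].unique()) <= set(CLAIM_TYPES):
            raise ValueError("unknown claim_type in events")
        merged = e.merge(p[["person_id", "first_year", "last_year"]], on="person_id", how="left")
        if merged["first_year"].isna().any():
            raise ValueError("event person_id missing from registry")
        bad = (merged["year"] < merged["first_year"]) | (merged["year"] > merged["last_year"])
        if bad.any():
            raise ValueError("event year outside person's observation window")
        if (e["n"] < 1).any():
            raise ValueError("event count n must be >= 1")
        if self.truth is not None:
            t = self.truth
            me = e.merge(t[["person_id", "death_year"]], on="person_id", how="left")
            dead = me["death_year"].notna()
            if (me.loc[dead, "year"] > me.loc[dead, "death_year"]).any():
                raise ValueError("events after truth death_year")

    # ------------------------------------------------------------------- I/O
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.persons[PERSON_COLS].to_csv(d / "persons.csv", index=False)
        self.events[EVENT_COLS].to_csv(d / "events.csv", index=False)
        if self.truth is not None:
            self.truth[TRUTH_COLS].to_csv(d / "truth.csv", index=False, float_format="%g")

    @classmethod
    def load(cls, directory: str | Path) -> "ClaimsPanel":
        d = Path(directory)
        persons = pd.read_csv(d / "persons.csv")
        events = pd.read_csv(d / "events.csv", dtype={"icd_code": str})
        if "n" not in events.columns:
            events["n"] = 1
        truth = None
        tp = d / "truth.csv"
        if tp.exists():
            truth = pd.read_csv(tp)
        return cls(persons=persons, events=events, truth=truth)


def panel_from_records(persons: list[tuple], events: list[tuple], truth: list[tuple] | None = None) -> ClaimsPanel:
    """Build a small panel from plain tuples (test/doc convenience).

    ``persons``: (person_id, sex, birth_year, first_year, last_year);
    ``events``: (person_id, year, claim_type, icd_code[, n]).
    """
    pdf = pd.DataFrame(persons, columns=PERSON_COLS)
    rows = []
    for ev in events:
        if len(ev) == 4:
            ev = (*ev, 1)
        rows.append(ev)
    edf = pd.DataFrame(rows, columns=EVENT_COLS) if rows else pd.DataFrame(columns=EVENT_COLS)
    tdf = pd.DataFrame(truth, columns=TRUTH_COLS) if truth is not None else None
    panel = ClaimsPanel(persons=pdf, events=edf, truth=tdf)
    panel.validate()
    return panel
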