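"""Age x calendar-year rate surfaces.

A :class:`RateSurface` holds event counts and person-year exposures on an
age x year grid for one sex and one rate kind (incidence, mortality or
prevalence), plus the derived central rate ``m_xt = events / exposure``.
Fitted or graduated surfaces carry explicit rates instead of counts.

Events and exposures are additive under age grouping; rates are not and are
always recomputed from the grouped sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

RATE_KINDS = ("incidence", "mortality", "prevalence")

#: Age-layout presets used in the study designs: single ages exclude 90+
#: (tiny populations), mortality layouts start at 70.
LAYOUTS = {
    "single_45_89": ("single", 45, 89),
    "five_45_99": ("five", 45, 99),
    "five_70_99": ("five", 70, 99),
    "single_70_89": ("single", 70, 89),
}


def _default_labels(ages: np.ndarray) -> tuple[str, ...]:
    out = []
    for a in ages:
        if float(a).is_integer():
            out.append(str(int(a)))
        else:
            out.append(f"{float(a):g}")
    return tuple(out)


@dataclass
class RateSurface:
    """Counts, exposures and/or rates on an age x year grid.

    Parameters
    ----------
    kind : str
        One of ``incidence``, ``mortality``, ``prevalence`` (free-form for
        derived surfaces such as residuals).
    sex : str
        ``"M"``, ``"F"`` or ``"both"``.
    ages : array
        Numeric representative age per row (group midpoints for grouped ages).
    years : array
        Calendar years per column.
    events, exposure : array or None
        ``(A, Y)`` matrices; either may be absent (e.g. an exposure-only
        surface, or a fitted surface carrying only ``rates``).
    rates : array or None
        Explicit rates; when absent the rate is ``events / exposure`` with
        NaN marking zero-exposure cells.
    age_labels : tuple of str, optional
        Display labels, e.g. ``"45-49"`` for grouped ages.
    """

    kind: str
    sex: str
    ages: np.ndarray
    years: np.ndarray
    events: np.ndarray | None = None
    exposure: np.ndarray | None = None
    rates: np.ndarray | None = None
    age_labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        shape = (len(self.ages), len(self.years))
        for name in ("events", "exposure", "rates"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != shape:
                    raise ValueError(
                        f"{name} has shape {arr.shape}, expected {shape}"
                    )
                setattr(self, name, arr)
        if self.events is None and self.exposure is None and self.rates is None:
            raise ValueError("surface needs at least one of events/exposure/rates")
        if self.age_labels is None:
            self.age_labels = _default_labels(self.ages)
        elif len(self.age_labels) != len(self.ages):
            raise ValueError("age_labels length mismatch")

    # ------------------------------------------------------------------ rates
    @property
    def rate(self) -> np.ndarray:
        """Rate matrix; NaN where undefined (zero exposure)."""
        if self.rates is not None:
            return self.rates
        if self.events is None or self.exposure is None:
            raise ValueError("surface has neither explicit rates nor counts")
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(self.exposure > 0, self.events / np.where(self.exposure > 0, self.exposure, 1.0), np.nan)
        return r

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.ages), len(self.years))

    # --------------------------------------------------------------- slicing
    def subset_years(self, first: int, last: int) -> "RateSurface":
        """Inclusive calendar-year window."""
        mask = (self.years >= first) & (self.years <= last)
        if not mask.any():
            raise ValueError(f"no years in [{first}, {last}]")
        take = lambda a: None if a is None else a[:, mask]
        return replace(
            self,
            years=self.years[mask],
            events=take(self.events),
            exposure=take(self.exposure),
            rates=take(self.rates),
        )

    def subset_ages(self, first: float, last: float) -> "RateSurface":
        mask = (self.ages >= first) & (self.ages <= last)
        if not mask.any():
            raise ValueError(f"no ages in [{first}, {last}]")
        take = lambda a: None if a is None else a[mask, :]
        return replace(
            self,
            ages=self.ages[mask],
            age_labels=tuple(l for l, m in zip(self.age_labels, mask) if m),
            events=take(self.events),
            exposure=take(self.exposure),
            rates=take(self.rates),
        )

    # ------------------------------------------------------------------- I/O
    def to_frame(self) -> pd.DataFrame:
        """Long format: sex, kind, age_or_group, year, events, exposure, rate."""
        A, Y = self.shape
        with np.errstate(invalid="ignore", divide="ignore"):
            try:
                rate = self.rate
            except ValueError:
                rate = np.full((A, Y), np.nan)
        ev = self.events if self.events is not None else np.full((A, Y), np.nan)
        ex = self.exposure if self.exposure is not None else np.full((A, Y), np.nan)
        rows = {
            "sex": np.repeat(self.sex, A * Y),
            "kind": np.repeat(self.kind, A * Y),
            "age_or_group": np.repeat(self.age_labels, Y),
            "year": np.tile(self.years, A),
            "events": ev.ravel(),
            "exposure": ex.ravel(),
            "rate": rate.ravel(),
        }
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RateSurface":
        sexes = df["sex"].unique()
        kinds = df["kind"].unique()
        if len(sexes) != 1 or len(kinds) != 1:
            raise ValueError("frame must hold one (sex, kind) surface")
        df = df.assign(age_or_group=df["age_or_group"].astype(str))
        labels = list(dict.fromkeys(df["age_or_group"]))
        years = np.array(sorted(df["year"].unique()), dtype=int)
        ages = np.array([_label_to_age(l) for l in labels])
        order = np.argsort(ages)
        labels = [labels[i] for i in order]
        ages = ages[order]
        pivot = lambda col: (
            df.pivot_table(index="age_or_group", columns="year", values=col, aggfunc="first")
            .reindex(index=labels, columns=years)
            .to_numpy(dtype=float)
        )
        ev, ex, rt = pivot("events"), pivot("exposure"), pivot("rate")
        return cls(
            kind=str(kinds[0]),
            sex=str(sexes[0]),
            ages=ages,
            years=years,
            events=None if np.isnan(ev).all() else ev,
            exposure=None if np.isnan(ex).all() else ex,
            rates=None if np.isnan(rt).all() else rt,
            age_labels=tuple(labels),
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "RateSurface":
        return cls.from_frame(pd.read_csv(path))


def _label_to_age(label: str) -> float:
    label = str(label)
    if "-" in label:
        lo, hi = label.split("-")
        return (float(lo) + float(hi)) / 2.0
    return float(label)


def compute_rates(events: RateSurface, exposure: RateSurface) -> RateSurface:
    """Merge an events surface and an exposure surface into a rate surface.

    Cellwise ratio; zero-exposure cells carry NaN and are excluded (weight 0)
    by every downstream consumer (model fitting, MAPE).
    """
    if events.kind != exposure.kind or events.sex != exposure.sex:
        raise ValueError("kind/sex mismatch between events and exposure")
    if not np.array_equal(events.ages, exposure.ages) or not np.array_equal(
        events.years, exposure.years
    ):
        raise ValueError("age/year index mismatch between events and exposure")
    if events.events is None:
        raise ValueError("events surface has no event counts")
    if exposure.exposure is None:
        raise ValueError("exposure surface has no exposures")
    return RateSurface(
        kind=events.kind,
        sex=events.sex,
        ages=events.ages,
        years=events.years,
        events=events.events,
        exposure=exposure.exposure,
        age_labels=events.age_labels,
    )


def group_ages(surface: RateSurface, layout, weights: np.ndarray | None = None) -> RateSurface:
    """Regroup a single-age surface into one of the study layouts.

    ``layout`` is a preset name from :data:`LAYOUTS` or a tuple
    ``("single"|"five", first_age, last_age)``. Events and exposures are
    summed within groups (exact conservation); rates are recomputed. A
    rates-only surface (e.g. a reference schedule) can be grouped by passing
    ``weights`` — an (A, Y) exposure matrix on the same single-age grid —
    giving the exposure-weighted mean rate per group.
    """
    if isinstance(layout, str):
        try:
            spec = LAYOUTS[layout]
        except KeyError:
            raise ValueError(f"unknown layout {layout!r}; options: {sorted(LAYOUTS)}")
    else:
        spec = tuple(layout)
    mode, first, last = spec
    amin, amax = surface.ages.min(), surface.ages.max()
    if first < amin or last > amax:
        raise ValueError(
            f"layout span {first}-{last} exceeds surface span {amin:g}-{amax:g}"
        )
    if mode == "single":
        return surface.subset_ages(first, last)
    if mode != "five":
        raise ValueError(f"unknown layout mode {mode!r}")
    by_counts = surface.events is not None and surface.exposure is not None
    if not by_counts and weights is None:
        raise ValueError("grouping needs events and exposure (or rates plus weights)")
    if weights is not None and np.asarray(weights).shape != surface.shape:
        raise ValueError("weights must match the surface shape")
    starts = np.arange(first, last + 1, 5)
    A, Y = len(starts), len(surface.years)
    ev = np.zeros((A, Y))
    ex = np.zeros((A, Y))
    rt = np.zeros((A, Y))
    labels = []
    mids = []
    for i, s in enumerate(starts):
        e = s + 4
        m = (surface.ages >= s) & (surface.ages <= e)
        if not m.any():
            raise ValueError(f"no surface ages inside group {s}-{e}")
        if by_counts:
            ev[i] = surface.events[m].sum(axis=0)
            ex[i] = surface.exposure[m].sum(axis=0)
        else:
            w = np.asarray(weights, float)[m]
            wsum = w.sum(axis=0)
            rt[i] = (w * surface.rate[m]).sum(axis=0) / np.where(wsum > 0, wsum, np.nan)
        labels.append(f"{s}-{e}")
        mids.append(s + 2.0)
    return RateSurface(
        kind=surface.kind,
        sex=surface.sex,
        ages=np.array(mids),
        years=surface.years,
        events=ev if by_counts else None,
        exposure=ex if by_counts else None,
        rates=None if by_counts else rt,
        age_labels=tuple(labels),
    )
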