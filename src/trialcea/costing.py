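"""Resource-use costing from the UK NHS/PSS perspective (2021/22 prices).

Turns the trial's event streams into costed items:

* wound samples (tissue/swab/bone) at laboratory unit costs;
* hospital admissions costed per HRG-derived category as
  ``cost_per_episode + excess bed days x cost_per_excess_bed_day``,
  with a one-off post-amputation rehabilitation cost for amputations;
* antibiotic courses priced per unit form from the BNF-derived list;
* community/outpatient contacts from a 4-week-recall questionnaire,
  extrapolated to the whole interval since the previous visit.

All tables are plain YAML/CSV configuration so prices can be overridden;
the bundled defaults reproduce the published 2021/22 schedules.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml


@dataclass(frozen=True)
class UnitCostTable:
    """Sample and healthcare-contact unit costs (pounds)."""

    samples: dict[str, float]
    contacts: dict[str, float]
    price_year: str = "2021/22"

    def __post_init__(self) -> None:
        for name, cost in {**self.samples, **self.contacts}.items():
            if cost < 0:
                raise ValueError(f"negative unit cost for {name!r}")


@dataclass(frozen=True)
class AdmissionCategory:
    cost_per_episode: float
    average_length_of_stay: float  # days
    cost_per_excess_bed_day: float

    def __post_init__(self) -> None:
        if min(self.cost_per_episode, self.average_length_of_stay,
               self.cost_per_excess_bed_day) < 0:
            raise ValueError("admission cost parameters must be non-negative")


@dataclass(frozen=True)
class AdmissionCostTable:
    categories: dict[str, AdmissionCategory]
    post_amputation_cost: float = 529.0
    amputation_categories: tuple[str, ...] = ("major_amputation", "minor_amputation")
    price_year: str = "2021/22"


@dataclass(frozen=True)
class AntibioticPriceList:
    """Map (drug, form) -> cost per unit form in pounds."""

    prices: dict[tuple[str, str], float]
    default_duration_days: float = 7.0  # NICE-guideline fallback when unrecorded
    default_units_per_day: float = 1.0  # minimum-dosage fallback

    def lookup(self, drug: str, form: str) -> float:
        key = (drug.lower().strip(), form.lower().strip())
        try:
            return self.prices[key]
        except KeyError:
            raise KeyError(
                f"no price for {drug!r} / {form!r}; known drugs: "
                f"{sorted({d for d, _ in self.prices})}"
            ) from None


@dataclass(frozen=True)
class CostEvent:
    """One costed resource item for one patient at one week."""

    patient_id: object
    week: float
    category: str  # admission | antibiotic | contact | sample
    amount: float

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("cost amount must be non-negative")
        if self.week < 0:
            raise ValueError("week must be non-negative")


def _read_bundled(name: str) -> str:
    return resources.files("trialcea.data").joinpath(name).read_text()


def load_unit_costs(path: str | None = None) -> UnitCostTable:
    text = _read_bundled("unit_costs.yaml") if path is None else open(path).read()
    raw = yaml.safe_load(text)
    return UnitCostTable(
        samples={k: float(v) for k, v in raw["samples"].items()},
        contacts={k: float(v) for k, v in raw["contacts"].items()},
        price_year=str(raw.get("price_year", "2021/22")),
    )


def load_admission_costs(path: str | None = None) -> AdmissionCostTable:
    text = _read_bundled("admission_costs.yaml") if path is None else open(path).read()
    raw = yaml.safe_load(text)
    cats = {
        name: AdmissionCategory(
            cost_per_episode=float(v["cost_per_episode"]),
            average_length_of_stay=float(v["average_length_of_stay"]),
            cost_per_excess_bed_day=float(v["cost_per_excess_bed_day"]),
        )
        for name, v in raw["categories"].items()
    }
    return AdmissionCostTable(
        categories=cats,
        post_amputation_cost=float(raw.get("post_amputation_cost", 0.0)),
        amputation_categories=tuple(raw.get("amputation_categories", ())),
        price_year=str(raw.get("price_year", "2021/22")),
    )


def load_antibiotic_prices(path: str | None = None) -> AntibioticPriceList:
    text = _read_bundled("antibiotic_prices.csv") if path is None else open(path).read()
    df = pd.read_csv(io.StringIO(text))
    prices = {
        (str(r.drug).lower(), str(r.form).lower()): float(r.unit_cost)
        for r in df.itertuples()
    }
    if any(v <= 0 for v in prices.values()):
        raise ValueError("antibiotic unit costs must be positive")
    return AntibioticPriceList(prices=prices)


def cost_admission(
    category: str, observed_los_days: float, table: AdmissionCostTable
) -> float:
    """Cost of one admission episode.

    Episode cost plus excess bed days beyond the category's costed average
    stay; amputation admissions carry the post-amputation rehabilitation
    cost once per episode.
    """
    if category not in table.categories:
        raise KeyError(
            f"unknown admission category {category!r}; known: "
            f"{sorted(table.categories)}"
        )
    cat = table.categories[category]
    excess = max(0.0, observed_los_days - cat.average_length_of_stay)
    cost = cat.cost_per_episode + excess * cat.cost_per_excess_bed_day
    if category in table.amputation_categories:
        cost += table.post_amputation_cost
    return cost


def resolve_overlapping_admissions(
    events: pd.DataFrame, table: AdmissionCostTable
) -> pd.DataFrame:
    """Keep only the most expensive of admissions recorded for identical dates.

    Events sharing a patient and an identical (start_week, end_week) pair are
    treated as one episode recorded under several descriptions; the costliest
    survives. Ties break on category name so the result does not depend on
    input order. Requires columns patient_id, category, start_week, end_week,
    los_days.
    """
    ev = events.copy()
    if (ev["end_week"] < ev["start_week"]).any():
        raise ValueError("admission end_week before start_week")
    ev["_cost"] = [
        cost_admission(c, l, table) for c, l in zip(ev["category"], ev["los_days"])
    ]
    ev = ev.sort_values(
        ["patient_id", "start_week", "end_week", "_cost", "category"],
        ascending=[True, True, True, False, True],
        kind="mergesort",
    )
    keep = ~ev.duplicated(["patient_id", "start_week", "end_week"], keep="first")
    return (
        ev.loc[keep]
        .drop(columns="_cost")
        .sort_values(["patient_id", "start_week"], kind="mergesort")
        .reset_index(drop=True)
    )


def cost_antibiotic_course(
    drug: str,
    form: str,
    units_per_day: float | None,
    duration_days: float | None,
    prices: AntibioticPriceList,
) -> float:
    """Cost of one antibiotic course: units/day x days x unit price.

    Missing duration or frequency falls back to the configured defaults
    (guideline course length / minimum dosage).
    """
    unit = prices.lookup(drug, form)
    if duration_days is None or (isinstance(duration_days, float) and np.isnan(duration_days)):
        duration_days = prices.default_duration_days
    if units_per_day is None or (isinstance(units_per_day, float) and np.isnan(units_per_day)):
        units_per_day = prices.default_units_per_day
    if duration_days < 0 or units_per_day < 0:
        raise ValueError("dose frequency and duration must be non-negative")
    return units_per_day * duration_days * unit


def cost_contacts_window(contact_counts: dict[str, float], table: UnitCostTable) -> float:
    """Cost of the contacts reported for one 4-week recall window."""
    total = 0.0
    for kind, count in contact_counts.items():
        if kind not in table.contacts:
            raise KeyError(
                f"unknown contact type {kind!r}; known: {sorted(table.contacts)}"
            )
        if count < 0:
            raise ValueError(f"negative contact count for {kind!r}")
        total += count * table.contacts[kind]
    return total


def extrapolate_window(window_cost: float, weeks_since_last_visit: float) -> float:
    """Scale a 4-week recall window cost to the whole inter-visit interval.

    The questionnaire asks about the previous 4 weeks only; the window is
    assumed representative of the period since the last observation.
    """
    if weeks_since_last_visit <= 0:
        raise ValueError("weeks_since_last_visit must be positive")
    return window_cost * weeks_since_last_visit / 4.0


@dataclass
class CostTables:
    """Bundle of the three cost configurations used throughout the pipeline."""

    unit: UnitCostTable = field(default_factory=load_unit_costs)
    admission: AdmissionCostTable = field(default_factory=load_admission_costs)
    antibiotics: AntibioticPriceList = field(default_factory=load_antibiotic_prices)

    def expected_admission_cost(self, category: str) -> float:
        """Expected episode cost at the category's average stay (no excess days)."""
        return cost_admission(
            category,
            self.admission.categories[category].average_length_of_stay,
            self.admission,
        )
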