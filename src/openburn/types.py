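"""Core domain containers for the open-burning emission chain.

The estimation chain runs household survey -> per-capita burned mass
(``MassEstimate``) -> per-species emissions (``EmissionEstimate``) via
emission factors (``EmissionFactor``), aggregated over administrative
units (``RegionRecord``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

EDUCATION_LEVELS = ("none", "primary_incomplete", "primary_complete", "secondary")

ASSET_FLAGS = ("cellphone", "radio", "color_tv", "computer", "internet")

REGION_LEVELS = ("community", "city", "department", "national")

N_WEEKS = 4


@dataclass(frozen=True)
class HouseholdRecord:
    """One surveyed household.

    ``weekly_masses_kg`` always has exactly four entries (the four
    collection weeks); a missing week is ``None``/NaN, never silently
    zero-filled.
    """

    household_id: str
    persons: int
    weekly_masses_kg: tuple
    burn_primary: bool
    education: str = "none"
    cellphone: bool = False
    radio: bool = False
    color_tv: bool = False
    computer: bool = False
    internet: bool = False
    respondent_age_years: Optional[float] = None

    def __post_init__(self):
        if self.persons < 1:
            raise ValueError(
                f"household {self.household_id!r}: persons must be >= 1, got {self.persons}"
            )
        if len(self.weekly_masses_kg) != N_WEEKS:
            raise ValueError(
                f"household {self.household_id!r}: expected {N_WEEKS} weekly masses, "
                f"got {len(self.weekly_masses_kg)}"
            )
        for w, m in enumerate(self.weekly_masses_kg, start=1):
            if m is not None and not math.isnan(m) and m < 0:
                raise ValueError(
                    f"household {self.household_id!r}: week {w} mass {m} < 0"
                )
        if self.education not in EDUCATION_LEVELS:
            raise ValueError(
                f"household {self.household_id!r}: unknown education {self.education!r}"
            )

    def valid_weeks(self) -> list:
        """(week index, mass) pairs for weeks actually observed."""
        return [
            (w, m)
            for w, m in enumerate(self.weekly_masses_kg)
            if m is not None and not math.isnan(m)
        ]

    @property
    def total_mass_kg(self) -> float:
        """Sum of observed weekly masses (kg over the collection period)."""
        return float(sum(m for _, m in self.valid_weeks()))


@dataclass(frozen=True)
class MassEstimate:
    """A per-capita (or total) mass with 1-sigma uncertainty.

    ``sd == 0`` marks a point estimate, e.g. the national per-capita
    upper-bound generation value which is a single published figure
    rather than a distribution.
    """

    mean: float
    sd: float = 0.0
    label: str = ""
    units: str = "kg/capita/yr"

    def __post_init__(self):
        if self.mean < 0:
            raise ValueError(f"mass mean must be >= 0, got {self.mean}")
        if self.sd < 0:
            raise ValueError(f"mass sd must be >= 0, got {self.sd}")

    def scaled(self, factor: float, label: Optional[str] = None) -> "MassEstimate":
        """Scale mean and sd by a non-negative factor (linear operation)."""
        if factor < 0:
            raise ValueError(f"scale factor must be >= 0, got {factor}")
        return MassEstimate(
            self.mean * factor,
            self.sd * factor,
            label if label is not None else self.label,
            self.units,
        )


@dataclass
class RegionRecord:
    """An administrative unit carrying census quantities.

    ``burn_fraction`` is the proportion of households disposing of waste
    by open burning (for cities, the proportion of generated plastic
    assumed burned); ``rural_fraction`` the proportion of the population
    living rurally.
    """

    name: str
    level: str
    population: int
    households: int
    burn_fraction: float
    rural_fraction: float = 0.0
    generation_pc: Optional[MassEstimate] = None

    def __post_init__(self):
        if self.level not in REGION_LEVELS:
            raise ValueError(f"region {self.name!r}: unknown level {self.level!r}")
        if self.population < 1:
            raise ValueError(f"region {self.name!r}: population must be >= 1")
        if self.households < 1:
            raise ValueError(f"region {self.name!r}: households must be >= 1")
        if self.population < self.households:
            raise ValueError(
                f"region {self.name!r}: population {self.population} < households "
                f"{self.households}"
            )
        for attr in ("burn_fraction", "rural_fraction"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"region {self.name!r}: {attr}={v} outside [0, 1]")

    @property
    def burning_population(self) -> float:
        """Population weighted by the household burn fraction (persons)."""
        return self.population * self.burn_fraction


@dataclass(frozen=True)
class EmissionFactor:
    """Mass of a pollutant emitted per kg of plastic burned (g/kg)."""

    species: str
    ef_mean: float
    ef_sd: float
    source: str = ""

    def __post_init__(self):
        if self.ef_mean < 0:
            raise ValueError(f"{self.species}: ef_mean must be >= 0, got {self.ef_mean}")
        if self.ef_sd < 0:
            raise ValueError(f"{self.species}: ef_sd must be >= 0, got {self.ef_sd}")


@dataclass(frozen=True)
class EmissionEstimate:
    """Per-capita and total emission (mean, SD) for one species x region."""

    species: str
    region: str
    per_capita_mean: float  # kg/capita/yr
    per_capita_sd: float
    total_mean: float = 0.0  # kg/yr
    total_sd: float = 0.0
    negative_draw_fraction: float = 0.0
    quantiles: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.per_capita_sd < 0 or self.total_sd < 0:
            raise ValueError(f"{self.species}/{self.region}: SDs must be >= 0")


@dataclass(frozen=True)
class InventoryEntry:
    """A national inventory total for one species (kg/yr)."""

    species: str
    national_total_kg: float
    year: int
    source: str = ""

    def __post_init__(self):
        if self.national_total_kg <= 0:
            raise ValueError(
                f"{self.species}: inventory total must be > 0, got {self.national_total_kg}"
            )


@dataclass(frozen=True)
class PercentIncrease:
    """Percent increase over an inventory baseline for one species/bound."""

    species: str
    bound: str  # "lower" or "upper"
    mean_pct: float  # negative only for degenerate tiny-sample MC diagnostics
    sd_pct: float

    def __post_init__(self):
        if self.bound not in ("lower", "upper"):
            raise ValueError(f"bound must be 'lower' or 'upper', got {self.bound!r}")
        if self.sd_pct < 0:
            raise ValueError(f"{self.species}: percent SD must be >= 0")


def weekly_matrix(records: Sequence[HouseholdRecord]):
    """Households x weeks float array with NaN for missing weeks."""
    import numpy as np

    out = np.full((len(records), N_WEEKS), np.nan)
    for i, rec in enumerate(records):
        for w, m in rec.valid_weeks():
            out[i, w] = m
    return out
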