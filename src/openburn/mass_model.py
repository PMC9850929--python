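"""Burned-mass models: per-capita generation -> burned plastic at each level.

The chain is linear throughout: a daily per-capita rate is annualized,
scaled by the fraction of households that burn (a proxy for the fraction
of generated plastic that is burned), and aggregated over administrative
units by population. Uncertainty (1-sigma) propagates multiplicatively
through every scaling, so relative SD is preserved.

Two per-capita generation scenarios bracket the unknown national rate: a
"lower" bound from the field survey (carrying a between-household SD) and
an "upper" bound from a published national point value (SD 0).
"""

from __future__ import annotations

import csv
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .types import MassEstimate, RegionRecord

DAYS_PER_YEAR = 365

#: Field-survey lower-bound per-capita generation, kg/person/day (mean, SD).
SURVEY_DAILY_PC = (3.34e-2, 1.58e-2)
#: Same, restricted to households whose primary disposal is burning.
SURVEY_DAILY_PC_BURNERS = (2.66e-2, 1.32e-2)
#: National per-capita plastic generation point value, kg/capita/yr (upper bound).
WORLD_BANK_PC_KG_YR = 29.3

#: City-level plastic generation (kg/capita/yr) and the fraction of that
#: plastic assumed burned (one minus the waste-collection rate). The two
#: published passages disagree on which city carries which rate; this
#: mapping is the one consistent with the downstream burned-mass figures
#: (7.87 and 13.5 kg/capita/yr), and the alternative is kept alongside so
#: the conflict stays visible rather than silently reconciled.
CITY_BURN_FRACTIONS = {"Guatemala city": 0.280, "Jutiapa": 0.875}
CITY_BURN_FRACTIONS_ALTERNATE = {"Guatemala city": 0.875, "Jutiapa": 0.280}
CITY_GENERATION_PC = {"Guatemala city": 28.1, "Jutiapa": 15.4}


def annualize(daily_mean: float, daily_sd: float,
              days_per_year: int = DAYS_PER_YEAR, label: str = "") -> MassEstimate:
    """Convert a daily per-capita rate (kg/person/day) to kg/capita/yr."""
    if daily_mean < 0 or daily_sd < 0:
        raise ValueError("daily mean and sd must be >= 0")
    return MassEstimate(daily_mean * days_per_year, daily_sd * days_per_year, label)


def region_burned_mass(generation_pc: MassEstimate, burn_fraction: float,
                       label: str = "") -> MassEstimate:
    """Scale per-capita generation by the burn fraction -> per-capita burned mass."""
    if not 0.0 <= burn_fraction <= 1.0:
        raise ValueError(f"burn_fraction {burn_fraction} outside [0, 1]")
    return generation_pc.scaled(burn_fraction, label or generation_pc.label)


def bound_rescale(lower: MassEstimate, lower_pc: float,
                  upper_pc: float = WORLD_BANK_PC_KG_YR) -> MassEstimate:
    """Rescale a lower-bound burned mass to the upper-bound generation scenario.

    The upper-bound per-capita generation is a point value, so the result
    carries no SD.
    """
    if lower_pc <= 0:
        raise ValueError(f"lower_pc must be > 0, got {lower_pc}")
    return MassEstimate(lower.mean * upper_pc / lower_pc, 0.0, lower.label, lower.units)


def national_burn_coefficient(regions: Sequence[RegionRecord]) -> float:
    """Effective burning population C = sum_d population_d x burn_fraction_d.

    Multiplying C by a per-capita burned mass gives the national total;
    by construction this equals the sum of per-department totals.
    """
    if not regions:
        raise ValueError("empty region list")
    return float(sum(r.burning_population for r in regions))


def national_burned_mass(regions: Sequence[RegionRecord],
                         generation_pc: MassEstimate) -> MassEstimate:
    """National total burned mass (kg/yr): C x per-capita generation."""
    c = national_burn_coefficient(regions)
    est = generation_pc.scaled(c, label="national total")
    return MassEstimate(est.mean, est.sd, est.label, units="kg/yr")


def department_burned_masses(regions: Sequence[RegionRecord],
                             generation_pc: MassEstimate) -> dict:
    """Per-department per-capita burned mass under one generation scenario."""
    return {
        r.name: region_burned_mass(generation_pc, r.burn_fraction, label=r.name)
        for r in regions
    }


def rural_regression(regions: Sequence[RegionRecord],
                     generation_pc: Optional[MassEstimate] = None):
    """OLS of per-capita burned mass on rural population fraction.

    ``generation_pc`` supplies a shared per-capita generation value; if
    omitted, each region's own ``generation_pc`` is used. Returns
    ``(slope, intercept, r_squared)``.
    """
    if len(regions) < 3:
        raise ValueError(f"need at least 3 regions, got {len(regions)}")
    x = np.array([r.rural_fraction for r in regions], dtype=float)
    if x.std() == 0:
        raise ValueError("zero variance in rural_fraction")
    y = []
    for r in regions:
        pc = generation_pc if generation_pc is not None else r.generation_pc
        if pc is None:
            raise ValueError(f"region {r.name!r} has no per-capita generation value")
        y.append(pc.mean * r.burn_fraction)
    y = np.asarray(y)
    if np.ptp(y) == 0:
        # constant burned mass: nothing to explain, R^2 defined as 0
        return 0.0, float(y[0]), 0.0
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.params[1]), float(fit.params[0]), float(fit.rsquared)


def city_burned_masses(use_alternate_mapping: bool = False) -> dict:
    """Per-capita burned mass for the two reference cities (kg/capita/yr)."""
    fractions = CITY_BURN_FRACTIONS_ALTERNATE if use_alternate_mapping else CITY_BURN_FRACTIONS
    return {
        city: region_burned_mass(
            MassEstimate(CITY_GENERATION_PC[city], 0.0, label=city), fractions[city]
        )
        for city in CITY_GENERATION_PC
    }


# ---------------------------------------------------------------------------
# CSV I/O

def read_regions_csv(path) -> list:
    """Load regions. Accepts either burn_fraction or households_burning."""
    regions = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        fields = set(reader.fieldnames or ())
        required = {"name", "level", "population", "households", "rural_fraction"}
        missing = required - fields
        if missing:
            raise ValueError(f"regions CSV missing columns: {sorted(missing)}")
        if not ({"burn_fraction", "households_burning"} & fields):
            raise ValueError("regions CSV needs burn_fraction or households_burning")
        for i, row in enumerate(reader, start=2):
            try:
                households = int(row["households"])
                if row.get("burn_fraction", "").strip():
                    burn_fraction = float(row["burn_fraction"])
                else:
                    burn_fraction = float(row["households_burning"]) / households
                gen = None
                if row.get("generation_pc_mean", "").strip():
                    gen = MassEstimate(
                        float(row["generation_pc_mean"]),
                        float(row.get("generation_pc_sd", "") or 0.0),
                        label=row["name"],
                    )
                regions.append(RegionRecord(
                    name=row["name"], level=row["level"].strip(),
                    population=int(row["population"]), households=households,
                    burn_fraction=burn_fraction,
                    rural_fraction=float(row["rural_fraction"]),
                    generation_pc=gen,
                ))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"regions CSV row {i}: {exc}") from exc
    if not regions:
        raise ValueError("regions CSV contains no rows")
    return regions


def write_regions_csv(regions: Sequence[RegionRecord], path) -> None:
    cols = ["name", "level", "population", "households", "burn_fraction",
            "rural_fraction", "generation_pc_mean", "generation_pc_sd"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for r in regions:
            gen_mean = repr(r.generation_pc.mean) if r.generation_pc else ""
            gen_sd = repr(r.generation_pc.sd) if r.generation_pc else ""
            writer.writerow([r.name, r.level, r.population, r.households,
                             repr(r.burn_fraction), repr(r.rural_fraction),
                             gen_mean, gen_sd])
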