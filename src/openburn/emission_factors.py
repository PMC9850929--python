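"""Emission-factor (EF) tables and back-derivation from published per-capita rows.

An EF is the mass of a pollutant released per kilogram of plastic burned
(g/kg). The full 62-species table from field burn measurements is
user-supplied; the packaged default carries the five headline species
(PM2.5, BC, OC, CO, CO2) back-derived from a published city-level
per-capita emission row whose burned mass is a point value, so the
division E/M recovers the EF mean and SD exactly.
"""

from __future__ import annotations

import csv
from typing import Sequence

from .types import EmissionFactor

#: Guatemala-city per-capita emissions (kg/capita/yr): (mean, SD) per species.
#: The city burned mass carries no uncertainty, so EF = E / M is exact.
_CITY_PER_CAPITA_EMISSIONS = {
    "PM2.5": (0.659, 0.100),
    "BC": (8.12e-2, 8.17e-3),
    "OC": (0.393, 5.20e-2),
    "CO": (0.310, 0.254),
    "CO2": (20.3, 1.24),
}
#: Guatemala-city per-capita burned plastic, kg/capita/yr (28.1 x 0.280).
_CITY_BURNED_PC_KG_YR = 7.87

HEADLINE_SPECIES = tuple(_CITY_PER_CAPITA_EMISSIONS)


def derive_ef(per_capita_emission_mean: float, per_capita_emission_sd: float,
              per_capita_mass: float, species: str = "",
              source: str = "back-derived") -> EmissionFactor:
    """Invert E = M x EF for a point-mass M.

    Inputs are kg/capita/yr; the returned EF is in g per kg burned. Only
    valid when the burned mass has no uncertainty of its own (city rows
    and upper-bound department rows).
    """
    if per_capita_mass <= 0:
        raise ValueError(f"per_capita_mass must be > 0, got {per_capita_mass}")
    if per_capita_emission_mean < 0 or per_capita_emission_sd < 0:
        raise ValueError("emission mean and sd must be >= 0")
    return EmissionFactor(
        species=species,
        ef_mean=per_capita_emission_mean / per_capita_mass * 1000.0,
        ef_sd=per_capita_emission_sd / per_capita_mass * 1000.0,
        source=source,
    )


def default_ef_table() -> list:
    """The packaged five-species EF table (g/kg), back-derived at full precision."""
    return [
        derive_ef(mean, sd, _CITY_BURNED_PC_KG_YR, species=species,
                  source="back-derived from Guatemala-city per-capita row")
        for species, (mean, sd) in _CITY_PER_CAPITA_EMISSIONS.items()
    ]


def load_ef_table(path) -> list:
    """Load and validate an EF CSV (species, ef_mean_g_per_kg, ef_sd_g_per_kg, source)."""
    factors, seen = [], set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"species", "ef_mean_g_per_kg", "ef_sd_g_per_kg"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"EF CSV missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            species = row["species"].strip()
            if species in seen:
                raise ValueError(f"EF CSV row {i}: duplicate species {species!r}")
            seen.add(species)
            try:
                factors.append(EmissionFactor(
                    species=species,
                    ef_mean=float(row["ef_mean_g_per_kg"]),
                    ef_sd=float(row["ef_sd_g_per_kg"]),
                    source=row.get("source", "").strip(),
                ))
            except ValueError as exc:
                raise ValueError(f"EF CSV row {i}: {exc}") from exc
    if not factors:
        raise ValueError("EF CSV contains no rows")
    return factors


def write_ef_table(factors: Sequence[EmissionFactor], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species", "ef_mean_g_per_kg", "ef_sd_g_per_kg", "source"])
        for f in factors:
            writer.writerow([f.species, repr(f.ef_mean), repr(f.ef_sd), f.source])
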