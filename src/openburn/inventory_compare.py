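"""Percent-increase comparison of plastic-burning totals against a national inventory.

The baseline inventory (national totals per species, kg/yr) is treated
as exact and purely additive: it contains no open domestic burning, so
plastic-burning totals add on top without double counting. The percent
increase is therefore linear in the plastic total, and its SD is the
plastic total's SD divided by the inventory total.
"""

from __future__ import annotations

import csv
from typing import Sequence

from .types import InventoryEntry, PercentIncrease

#: National inventory totals for Guatemala (kg in 2015) for the headline species.
_DEFAULT_INVENTORY = {
    "PM2.5": 1.19e8,
    "BC": 1.45e7,
    "OC": 5.54e7,
    "CO": 2.05e9,
    "CO2": 3.68e10,
}


def default_inventory() -> list:
    """The packaged five-species national inventory baseline."""
    return [
        InventoryEntry(species=s, national_total_kg=v, year=2015,
                       source="EDGAR v5.0")
        for s, v in _DEFAULT_INVENTORY.items()
    ]


def percent_increase(total_mean: float, total_sd: float, inventory: InventoryEntry,
                     bound: str = "lower") -> PercentIncrease:
    """Express a plastic-burning national total as % of the inventory total."""
    if inventory.national_total_kg <= 0:
        raise ValueError("inventory total must be > 0")
    if total_sd < 0:
        raise ValueError("total sd must be >= 0")
    return PercentIncrease(
        species=inventory.species, bound=bound,
        mean_pct=100.0 * total_mean / inventory.national_total_kg,
        sd_pct=100.0 * total_sd / inventory.national_total_kg,
    )


def bound_gap(lower: PercentIncrease, upper: PercentIncrease):
    """Difference between upper- and lower-bound percent increases.

    Returns ``(difference of means, quadrature-combined sd)``; the
    combination rule for the SD is a package choice (the bounds share the
    EF uncertainty, so quadrature overstates the spread — reported for
    orientation only).
    """
    if lower.species != upper.species:
        raise ValueError(
            f"species mismatch: {lower.species!r} vs {upper.species!r}"
        )
    diff = upper.mean_pct - lower.mean_pct
    sd = (lower.sd_pct**2 + upper.sd_pct**2) ** 0.5
    return float(diff), float(sd)


def load_inventory(path) -> list:
    """Load inventory CSV (species, national_total_kg, year, source)."""
    entries, seen = [], set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"species", "national_total_kg", "year"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"inventory CSV missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            species = row["species"].strip()
            if species in seen:
                raise ValueError(f"inventory CSV row {i}: duplicate species {species!r}")
            seen.add(species)
            try:
                entries.append(InventoryEntry(
                    species=species,
                    national_total_kg=float(row["national_total_kg"]),
                    year=int(row["year"]),
                    source=row.get("source", "").strip(),
                ))
            except ValueError as exc:
                raise ValueError(f"inventory CSV row {i}: {exc}") from exc
    if not entries:
        raise ValueError("inventory CSV contains no rows")
    return entries


def write_inventory(entries: Sequence[InventoryEntry], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species", "national_total_kg", "year", "source"])
        for e in entries:
            writer.writerow([e.species, repr(e.national_total_kg), e.year, e.source])
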