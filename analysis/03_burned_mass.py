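#!/usr/bin/env python
"""Burned-mass models: community, city, department, and national estimates.

Annualizes the survey per-capita generation rates into the lower-bound
scenario (12.2 +/- 5.8 kg/capita/yr), scales city generation by the city
burn fractions (Guatemala city 28.0%, Jutiapa 87.5%), rescales each
department's lower bound to the 29.3 kg/capita/yr upper-bound scenario,
aggregates to national totals via the effective burning population, and
regresses departmental burned mass on rural population fraction.
"""

import argparse
import csv
from pathlib import Path

from openburn import mass_model as mm
from openburn.types import MassEstimate


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--census", type=Path,
                        default=Path("results/inputs/census.csv"))
    parser.add_argument("--out", type=Path, default=Path("results/tables"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    lower_pc = mm.annualize(*mm.SURVEY_DAILY_PC, label="lower bound")
    xalapan_pc = mm.annualize(*mm.SURVEY_DAILY_PC_BURNERS, label="Xalapan")
    upper_pc = MassEstimate(mm.WORLD_BANK_PC_KG_YR, 0.0, label="upper bound")
    cities = mm.city_burned_masses()
    regions = mm.read_regions_csv(args.census)

    rows = [("Xalapan", "community", "survey", xalapan_pc.mean, xalapan_pc.sd)]
    rows += [(name, "city", "world-bank", est.mean, est.sd)
             for name, est in cities.items()]
    for r in regions:
        lo = mm.region_burned_mass(lower_pc, r.burn_fraction)
        up = mm.bound_rescale(lo, lower_pc.mean, upper_pc.mean)
        rows.append((r.name, "department", "lower", lo.mean, lo.sd))
        rows.append((r.name, "department", "upper", up.mean, up.sd))
    national = {b: mm.national_burned_mass(regions, pc)
                for b, pc in (("lower", lower_pc), ("upper", upper_pc))}
    for b, est in national.items():
        rows.append(("National total (kg/yr)", "national", b, est.mean, est.sd))

    out = args.out / "burned_mass.csv"
    with open(out, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["region", "level", "bound", "mean", "sd"])
        w.writerows(rows)

    slope, intercept, r2 = mm.rural_regression(regions, lower_pc)

    print(f"lower-bound generation: {lower_pc.mean:.3g} +/- {lower_pc.sd:.2g} "
          "kg/capita/yr")
    print(f"community (Xalapan) burned: {xalapan_pc.mean:.3g} +/- "
          f"{xalapan_pc.sd:.3g} kg/capita/yr")
    for name, est in cities.items():
        print(f"{name} burned: {est.mean:.3g} kg/capita/yr")
    for b, est in national.items():
        print(f"national burned mass, {b} bound: {est.mean / 1e6:.3g} Gg/yr"
              + (f" (SD {est.sd / 1e6:.3g})" if est.sd else ""))
    print(f"burned mass vs rural fraction: slope {slope:.3g}, R^2 = {r2:.2f}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
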