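#!/usr/bin/env python
"""Monte Carlo emission estimates: E = M x EF per species and region.

Propagates the burned-mass distributions through the five-species EF
table (back-derived from the published city per-capita row) with one
million paired normal draws per cell. Community and city rows are
per-capita only; the national rows scale the shared per-capita draw
vector by the effective burning population so relative uncertainty is
preserved in the totals.
"""

import argparse
import csv
from pathlib import Path

from openburn import mass_model as mm
from openburn import mc_engine as mc
from openburn.emission_factors import default_ef_table
from openburn.types import MassEstimate


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--census", type=Path,
                        default=Path("results/inputs/census.csv"))
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n", type=int, default=1_000_000)
    parser.add_argument("--out", type=Path, default=Path("results/tables"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    regions = mm.read_regions_csv(args.census)
    c_eff = mm.national_burn_coefficient(regions)
    ef_table = default_ef_table()
    cfg = mc.MCConfig(n_samples=args.n, seed=args.seed)

    masses = {
        "Xalapan": mm.annualize(*mm.SURVEY_DAILY_PC_BURNERS, label="Xalapan"),
        **{name: est for name, est in mm.city_burned_masses().items()},
        "National (lower)": mm.annualize(*mm.SURVEY_DAILY_PC,
                                         label="National (lower)"),
        "National (upper)": MassEstimate(mm.WORLD_BANK_PC_KG_YR, 0.0,
                                         label="National (upper)"),
    }

    out = args.out / "emissions.csv"
    with open(out, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["region", "species", "per_capita_mean_kg", "per_capita_sd_kg",
                    "total_mean_kg", "total_sd_kg", "n_samples", "seed"])
        for label, mass in masses.items():
            national = label.startswith("National")
            for ef in ef_table:
                rng = mc.child_rng(cfg.seed, label, ef.species)
                draws = mc.mc_draws(mass, ef, cfg, rng=rng)
                s = mc.summarize_draws(draws)
                if national:
                    tm, ts = mc.total_from_per_capita(draws, c_eff)
                else:
                    tm = ts = ""
                w.writerow([label, ef.species, s.mean, s.sd, tm, ts,
                            cfg.n_samples, cfg.seed])
                if ef.species == "PM2.5":
                    line = (f"{label:<17} PM2.5: {s.mean:.3g} "
                            f"(SD {s.sd:.3g}) kg/capita/yr")
                    if national:
                        line += f"; total {tm:.3g} (SD {ts:.3g}) kg/yr"
                    print(line)

    print(f"effective burning population: {c_eff:,.0f}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
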