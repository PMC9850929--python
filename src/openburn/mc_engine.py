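"""Monte Carlo propagation of E = M x EF with a closed-form moments oracle.

Burned mass M (kg/capita/yr) and emission factor EF (g/kg) are modelled
as independent normals; emissions per species are the product of one
draw from each, converted to kg. Draws are deliberately NOT truncated at
zero by default: the published per-capita SDs match the untruncated
product-of-normals closed form, and truncation would bias both moments.
A ``truncate_negative`` switch exists purely as a diagnostic.

National totals scale the SAME per-capita draw vector by the effective
burning population (M and EF are global random variables shared across
departments), so the relative SD of a national total equals that of the
per-capita estimate exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import EmissionEstimate, EmissionFactor, MassEstimate, RegionRecord

DEFAULT_N_SAMPLES = 1_000_000
DEFAULT_QUANTILES = (0.025, 0.25, 0.5, 0.75, 0.975)


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo settings: draw count, root seed, diagnostic truncation."""

    n_samples: int = DEFAULT_N_SAMPLES
    seed: int = 0
    truncate_negative: bool = False

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")


@dataclass(frozen=True)
class MCSummary:
    """Empirical summary of a product-of-normals emission distribution (kg)."""

    mean: float
    sd: float
    quantiles: dict
    negative_draw_fraction: float
    histogram_counts: tuple
    histogram_edges: tuple
    n_samples: int


def child_rng(root_seed: int, *labels: str) -> np.random.Generator:
    """Deterministic per-(label...) stream derived from one root seed.

    Streams are independent of the order in which other labels are drawn,
    so adding a species or region does not perturb existing results.
    """
    entropy = [root_seed & 0x7FFFFFFF] + [
        zlib.crc32(lbl.encode("utf-8")) for lbl in labels
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def analytic_moments(mu_m: float, sd_m: float, mu_f: float, sd_f: float):
    """Exact mean and SD of the product of two independent normals.

    mean = mu_M mu_F;  var = mu_M^2 sd_F^2 + mu_F^2 sd_M^2 + sd_M^2 sd_F^2.
    Units multiply (kg/capita/yr x kg/kg -> kg/capita/yr).
    """
    mean = mu_m * mu_f
    var = mu_m**2 * sd_f**2 + mu_f**2 * sd_m**2 + sd_m**2 * sd_f**2
    return float(mean), float(np.sqrt(var))


def _freedman_diaconis_bins(draws: np.ndarray) -> int:
    q75, q25 = np.percentile(draws, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return 1
    width = 2 * iqr / len(draws) ** (1 / 3)
    span = draws.max() - draws.min()
    return max(1, int(np.ceil(span / width))) if span > 0 else 1


def mc_draws(mass: MassEstimate, ef: EmissionFactor, cfg: MCConfig,
             rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Raw per-capita emission draws in kg: (M draws) x (EF draws) / 1000."""
    if rng is None:
        rng = child_rng(cfg.seed, mass.label or "mass", ef.species)
    m = rng.normal(mass.mean, mass.sd, cfg.n_samples)
    f = rng.normal(ef.ef_mean, ef.ef_sd, cfg.n_samples)
    if cfg.truncate_negative:
        m = np.clip(m, 0.0, None)
        f = np.clip(f, 0.0, None)
    return m * f / 1000.0


def summarize_draws(draws: np.ndarray,
                    quantiles: Sequence[float] = DEFAULT_QUANTILES) -> MCSummary:
    """Empirical moments, quantiles and a histogram for one draw vector."""
    n = len(draws)
    sd = float(draws.std(ddof=1)) if n > 1 else 0.0
    counts, edges = np.histogram(draws, bins=_freedman_diaconis_bins(draws))
    return MCSummary(
        mean=float(draws.mean()),
        sd=sd,
        quantiles={q: float(np.quantile(draws, q)) for q in quantiles},
        negative_draw_fraction=float((draws < 0).mean()),
        histogram_counts=tuple(int(c) for c in counts),
        histogram_edges=tuple(float(e) for e in edges),
        n_samples=n,
    )


def mc_product(mass: MassEstimate, ef: EmissionFactor, cfg: MCConfig,
               rng: Optional[np.random.Generator] = None) -> MCSummary:
    """Monte Carlo distribution of the per-capita emission M x EF (kg/capita/yr)."""
    return summarize_draws(mc_draws(mass, ef, cfg, rng=rng))


def total_from_per_capita(per_capita_draws: np.ndarray, effective_population: float):
    """Scale per-capita draws by the effective burning population (kg/yr).

    The same draw vector is scaled, so the relative SD is preserved
    exactly — M and EF uncertainty is shared across the aggregation, not
    redrawn per department.
    """
    if effective_population < 0:
        raise ValueError("effective_population must be >= 0")
    totals = per_capita_draws * effective_population
    sd = float(totals.std(ddof=1)) if len(totals) > 1 else 0.0
    return float(totals.mean()), sd


def estimate_region(region: RegionRecord, burned_pc: MassEstimate,
                    ef_table: Sequence[EmissionFactor], cfg: MCConfig,
                    effective_population: Optional[float] = None) -> list:
    """Per-species emission estimates for one region.

    ``burned_pc`` is the region's per-capita burned plastic mass;
    ``effective_population`` (default: the region's burning population)
    converts per-capita draws into a regional total.
    """
    if not ef_table:
        raise ValueError("ef_table is empty")
    if effective_population is None:
        effective_population = region.burning_population
    out = []
    for ef in ef_table:
        rng = child_rng(cfg.seed, region.name, ef.species)
        draws = mc_draws(burned_pc, ef, cfg, rng=rng)
        summary = summarize_draws(draws)
        total_mean, total_sd = total_from_per_capita(draws, effective_population)
        out.append(EmissionEstimate(
            species=ef.species, region=region.name,
            per_capita_mean=summary.mean, per_capita_sd=summary.sd,
            total_mean=total_mean, total_sd=total_sd,
            negative_draw_fraction=summary.negative_draw_fraction,
            quantiles=summary.quantiles,
        ))
    return out
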