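"""Monte Carlo product-of-normals engine against its closed-form oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from openburn import mc_engine as mc
from openburn.emission_factors import default_ef_table
from openburn.types import EmissionFactor, MassEstimate, RegionRecord

import published_values as pub

finite = st.floats(0.0, 100.0)


class TestAnalyticMoments:
    def test_department_co_cell(self):
        mean, sd = mc.analytic_moments(6.04, 2.86, 0.0394, 0.0323)
        assert mean == pytest.approx(0.238, rel=5e-3)
        assert sd == pytest.approx(0.243, rel=5e-3)

    def test_department_co2_cell(self):
        mean, sd = mc.analytic_moments(7.44, 3.52, 2.586, 0.158)
        assert mean == pytest.approx(19.2, rel=5e-3)
        assert sd == pytest.approx(9.19, rel=5e-3)

    def test_point_masses_multiply(self):
        assert mc.analytic_moments(3.0, 0.0, 4.0, 0.0) == (12.0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(mu_m=finite, sd_m=finite, mu_f=finite, sd_f=finite, k=st.floats(0.01, 10))
    def test_homogeneous_of_degree_one(self, mu_m, sd_m, mu_f, sd_f, k):
        base_mean, base_sd = mc.analytic_moments(mu_m, sd_m, mu_f, sd_f)
        scaled_mean, scaled_sd = mc.analytic_moments(k * mu_m, k * sd_m, mu_f, sd_f)
        assert scaled_mean == pytest.approx(k * base_mean)
        assert scaled_sd == pytest.approx(k * base_sd)
        # symmetric in the two factors
        assert mc.analytic_moments(mu_f, sd_f, mu_m, sd_m) == pytest.approx(
            (base_mean, base_sd))


class TestMcProduct:
    def test_degenerate_inputs_give_point_mass(self):
        s = mc.mc_product(MassEstimate(2.0, 0.0), EmissionFactor("X", 500.0, 0.0),
                          mc.MCConfig(n_samples=100, seed=1))
        assert s.mean == pytest.approx(1.0)
        assert s.sd == 0.0

    def test_converges_to_analytic_moments(self):
        mass = MassEstimate(9.709, 4.818, label="Xalapan")
        ef = default_ef_table()[0]
        cfg = mc.MCConfig(n_samples=400_000, seed=3)
        s = mc.mc_product(mass, ef, cfg)
        a_mean, a_sd = mc.analytic_moments(mass.mean, mass.sd,
                                           ef.ef_mean / 1000, ef.ef_sd / 1000)
        assert abs(s.mean - a_mean) < 4 * a_sd / math.sqrt(cfg.n_samples)
        assert s.sd == pytest.approx(a_sd, rel=0.01)

    def test_seed_reproducibility(self):
        mass = MassEstimate(5.0, 2.0, label="R")
        ef = EmissionFactor("X", 40.0, 30.0)
        cfg = mc.MCConfig(n_samples=10_000, seed=42)
        assert mc.mc_product(mass, ef, cfg) == mc.mc_product(mass, ef, cfg)

    def test_negative_draw_fraction_matches_normal_cdf(self):
        """P(product < 0) = p_M (1 - p_F) + p_F (1 - p_M) with p = Phi(-mu/sd);
        sizeable for CO where sd/mean of the EF is ~0.82."""
        mass = MassEstimate(9.709, 4.818, label="Xalapan")
        ef = next(f for f in default_ef_table() if f.species == "CO")
        cfg = mc.MCConfig(n_samples=300_000, seed=5)
        s = mc.mc_product(mass, ef, cfg)
        p_m = norm.cdf(-mass.mean / mass.sd)
        p_f = norm.cdf(-ef.ef_mean / ef.ef_sd)
        p_neg = p_m * (1 - p_f) + p_f * (1 - p_m)
        se = math.sqrt(p_neg * (1 - p_neg) / cfg.n_samples)
        assert abs(s.negative_draw_fraction - p_neg) < 3 * se
        assert s.negative_draw_fraction > 0.1

    def test_truncation_is_diagnostic_only(self):
        """Truncating negatives shifts the mean upward, which is why it is off
        by default."""
        mass = MassEstimate(9.709, 4.818, label="X")
        ef = next(f for f in default_ef_table() if f.species == "CO")
        plain = mc.mc_product(mass, ef, mc.MCConfig(n_samples=100_000, seed=6))
        trunc = mc.mc_product(mass, ef,
                              mc.MCConfig(n_samples=100_000, seed=6,
                                          truncate_negative=True))
        assert trunc.negative_draw_fraction == 0.0
        assert trunc.mean > plain.mean

    def test_histogram_reconstructs_draw_count(self):
        s = mc.mc_product(MassEstimate(5.0, 1.0, label="R"),
                          EmissionFactor("X", 100.0, 10.0),
                          mc.MCConfig(n_samples=50_000, seed=7))
        assert sum(s.histogram_counts) == 50_000
        assert len(s.histogram_edges) == len(s.histogram_counts) + 1


class TestTotals:
    def test_relative_sd_preserved_exactly(self):
        rng = np.random.default_rng(8)
        draws = rng.normal(2.0, 0.5, 10_000)
        mean, sd = mc.total_from_per_capita(draws, 1.7e6)
        assert sd / mean == pytest.approx(draws.std(ddof=1) / draws.mean())

    def test_zero_population(self):
        assert mc.total_from_per_capita(np.ones(10), 0.0) == (0.0, 0.0)

    def test_national_lower_pm25_total(self):
        """80.2 Gg burned at the back-derived PM2.5 EF gives the published
        6.71e6 kg/yr national total within 1%."""
        ef = default_ef_table()[0]
        mean = pub.NATIONAL_BURNED["lower"] * ef.ef_mean / 1000
        assert mean == pytest.approx(pub.NATIONAL_TOTALS["lower"]["PM2.5"][0],
                                     rel=0.01)


class TestEstimateRegion:
    @staticmethod
    def _region(burn):
        return RegionRecord("R", "department", 100_000, 20_000, burn, 0.5)

    def test_empty_ef_table_rejected(self):
        with pytest.raises(ValueError):
            mc.estimate_region(self._region(0.5), MassEstimate(12.2, 5.8), [],
                               mc.MCConfig(n_samples=10, seed=0))

    def test_five_species_xalapan_row(self):
        mass = MassEstimate(9.709, 4.818, label="Xalapan")
        out = mc.estimate_region(self._region(0.84), mass, default_ef_table(),
                                 mc.MCConfig(n_samples=200_000, seed=1))
        assert [e.species for e in out] == list(pub.SPECIES)
        pm = out[0]
        assert pm.per_capita_mean == pytest.approx(0.813, rel=0.01)
        assert pm.per_capita_sd == pytest.approx(0.425, rel=0.02)
        # total = per-capita x effective population, draw-for-draw
        assert pm.total_mean / pm.per_capita_mean == pytest.approx(0.84 * 100_000)

    def test_linearity_in_burn_fraction(self):
        """Two regions identical apart from burn fraction k differ by exactly k
        in every per-capita mean (shared child streams per species)."""
        cfg = mc.MCConfig(n_samples=50_000, seed=2)
        pc = MassEstimate(12.2, 5.8)
        a = mc.estimate_region(self._region(0.3),
                               pc.scaled(0.3), default_ef_table(), cfg)
        b = mc.estimate_region(self._region(0.6),
                               pc.scaled(0.6), default_ef_table(), cfg)
        for ea, eb in zip(a, b):
            assert eb.per_capita_mean / ea.per_capita_mean == pytest.approx(2.0)
            assert eb.per_capita_sd / ea.per_capita_sd == pytest.approx(2.0)

    def test_adding_a_species_does_not_perturb_others(self):
        cfg = mc.MCConfig(n_samples=10_000, seed=3)
        mass = MassEstimate(12.2, 5.8)
        table = default_ef_table()
        full = mc.estimate_region(self._region(0.5), mass, table, cfg)
        partial = mc.estimate_region(self._region(0.5), mass, table[:3], cfg)
        assert full[:3] == partial


def test_mcconfig_validation():
    with pytest.raises(ValueError):
        mc.MCConfig(n_samples=0)
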