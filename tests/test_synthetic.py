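import numpy as np
import pandas as pd
import pytest

from seedtrend import (
    FecundityCoefficients,
    SimulationConfig,
    default_fecundity_coefficients,
    default_growth_coefficients,
    dispersal_kernel,
    gen_landscape,
    gen_tree_population,
    make_fixture,
    sim_growth,
    sim_observations,
    sim_reproduction,
    simulate_dataset,
)
from seedtrend.datamodel import CLIMATE_VARS, estimate_climate_trend
from seedtrend.growth import GrowthCoefficients
from seedtrend.synthetic import SimulationTruth
from seedtrend.io import read_tables

from conftest import make_site, make_tree


class TestLandscape:
    def test_site_count_and_coverage(self):
        sites = gen_landscape(3, (2000, 2010), seed=0)
        assert len(sites) == 3
        for s in sites:
            assert sorted(s.anomalies) == list(range(2000, 2011))

    def test_seed_determinism(self):
        a = gen_landscape(4, (2000, 2010), seed=5)
        b = gen_landscape(4, (2000, 2010), seed=5)
        for sa, sb in zip(a, b):
            assert sa.norms == sb.norms
            assert sa.anomalies == sb.anomalies
            assert sa.trends == sb.trends

    def test_noiseless_series_recovers_slope_exactly(self):
        sd = {v: 0.0 for v in CLIMATE_VARS}
        sites = gen_landscape(2, (2000, 2015), anomaly_sd=sd, seed=1)
        for s in sites:
            for v in CLIMATE_VARS:
                series = {y: s.norms[v] + s.anomalies[y][v] for y in s.anomalies}
                slope = estimate_climate_trend(series, s.window)
                # the stored trend is the OLS slope of the same linear series
                assert slope == pytest.approx(s.trends[v], abs=1e-12)
                fitted = [series[s.window[0]] + slope * (y - s.window[0])
                          for y in range(s.window[0], s.window[1] + 1)]
                actual = [series[y] for y in range(s.window[0], s.window[1] + 1)]
                assert np.allclose(fitted, actual, atol=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gen_landscape(0, (2000, 2010))
        with pytest.raises(ValueError):
            gen_landscape(2, (2010, 2000))


class TestPopulation:
    def test_counts(self):
        sites = gen_landscape(2, (2000, 2008), seed=0)
        trees = gen_tree_population(sites, 10, (5, 40), (0.2,) * 5, seed=1)
        assert len(trees) == 20

    def test_degenerate_shade(self):
        sites = gen_landscape(1, (2000, 2008), seed=0)
        trees = gen_tree_population(sites, 15, (5, 40), (1, 0, 0, 0, 0), seed=1)
        assert all(t.shade_class == 1 for t in trees)

    def test_determinism_and_errors(self):
        sites = gen_landscape(1, (2000, 2008), seed=0)
        a = gen_tree_population(sites, 5, (5, 40), (0.2,) * 5, seed=3)
        b = gen_tree_population(sites, 5, (5, 40), (0.2,) * 5, seed=3)
        assert [(t.tree_id, t.diameters, t.shade_class) for t in a] == [
            (t.tree_id, t.diameters, t.shade_class) for t in b
        ]
        with pytest.raises(ValueError):
            gen_tree_population([], 5, (5, 40), (0.2,) * 5)
        with pytest.raises(ValueError, match="shade_probs"):
            gen_tree_population(sites, 5, (5, 40), (0.5, 0.5, 0.5, 0, 0))


class TestGrowth:
    def _const_coef(self, intercept):
        beta = np.zeros(14)
        beta[0] = intercept
        return GrowthCoefficients(beta_g=beta, sigma_g=0.25)

    def test_noiseless_constant_increment(self):
        site = make_site()
        tree = make_tree(years=[2010])
        sim_growth([tree], self._const_coef(0.4), [site], seed=0, noise_sd=0.0)
        incs = np.diff([tree.diameters[y] for y in tree.years])
        assert np.allclose(incs, 0.4)

    def test_negative_mean_fully_censored(self):
        site = make_site()
        tree = make_tree(years=[2010])
        sim_growth([tree], self._const_coef(-1.0), [site], seed=0, noise_sd=0.0)
        incs = np.diff([tree.diameters[y] for y in tree.years])
        assert np.allclose(incs, 0.0)

    def test_trajectories_nondecreasing(self, small_sim):
        dataset, _ = small_sim
        for t in dataset.trees:
            d = [t.diameters[y] for y in t.years]
            assert all(b >= a for a, b in zip(d, d[1:]))


class TestReproduction:
    def test_deep_immature_limit(self):
        site = make_site()
        trees = [make_tree(tree_id=f"t{i}") for i in range(5)]
        coef = default_fecundity_coefficients()
        coef = FecundityCoefficients(
            alpha0=-50.0, alpha_g=0.0, beta=coef.beta,
            sigma2_resid=coef.sigma2_resid, sigma2_re=coef.sigma2_re,
        )
        truth = sim_reproduction(trees, coef, [site], seed=0)
        assert (truth.psi["z"] == 0).all()
        assert (truth.psi["psi"] == 0).all()

    def test_unit_fecundity_when_all_effects_zero(self):
        site = make_site()
        tree = make_tree()
        coef = FecundityCoefficients(
            alpha0=50.0, alpha_g=0.0, beta=np.zeros(14),
            sigma2_resid=0.0, sigma2_re=0.0,
        )
        truth = sim_reproduction([tree], coef, [site], seed=0)
        assert (truth.psi["z"] == 1).all()
        assert np.allclose(truth.psi["psi"], 1.0)

    def test_negative_alpha_g_rejected(self):
        with pytest.raises(ValueError, match="alpha_g"):
            FecundityCoefficients(alpha0=0.0, alpha_g=-0.1, beta=np.zeros(14))

    def test_maturation_frequency_matches_probit(self):
        # binomial simulation oracle: fraction mature at diameter G across
        # replicate trees approximates Phi(alpha0 + alphaG * G)
        from scipy import stats

        site = make_site(years=range(2009, 2012))
        n = 10_000
        g = 25.0
        trees = [
            make_tree(tree_id=f"r{i}", diameter=g, years=[2010, 2011])
            for i in range(n)
        ]
        for t in trees:  # freeze diameter so rho is constant
            t.diameters = {2010: g, 2011: g}
        coef = FecundityCoefficients(
            alpha0=-2.5, alpha_g=0.08, beta=np.zeros(14),
            sigma2_resid=0.0, sigma2_re=0.0,
        )
        truth = sim_reproduction(trees, coef, [site], seed=42)
        frac = truth.psi.groupby("year")["z"].mean()
        p = stats.norm.cdf(-2.5 + 0.08 * g)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(frac.loc[2010] - p) < 3 * se

    def test_maturation_monotone_in_time(self, small_sim):
        _, truth = small_sim
        for _, grp in truth.psi.sort_values("year").groupby("tree_id"):
            z = grp["z"].to_numpy()
            assert (np.diff(z) >= 0).all()


class TestObservations:
    def _one_tree_setup(self, n_years=10_000, psi=100.0, mature=True):
        years = list(range(1, n_years + 1))
        tree = make_tree(tree_id="solo", years=years)
        tree.diameters = {y: 30.0 for y in years}
        psi_df = pd.DataFrame(
            {"tree_id": "solo", "year": years,
             "z": int(mature), "psi": psi if mature else 0.0}
        )
        coef = default_fecundity_coefficients()
        truth = SimulationTruth(
            fecundity_coefficients=coef,
            growth_coefficients=default_growth_coefficients(),
            b={"solo": 0.0}, maturation_year={"solo": 1 if mature else None},
            psi=psi_df,
        )
        return tree, truth

    def test_immature_crop_counts_zero(self):
        tree, truth = self._one_tree_setup(n_years=300, mature=False)
        cfg = SimulationConfig(p_tree_observed=1.0, p_year_observed=1.0,
                               theta_range=(1.0, 1.0))
        cc, _, _ = sim_observations(truth, [tree], cfg, seed=0)
        assert (cc["count"] == 0).all()
        assert tree.first_seed_year is None

    def test_crop_count_mean_matches_theta_psi(self):
        tree, truth = self._one_tree_setup()
        cfg = SimulationConfig(p_tree_observed=1.0, p_year_observed=1.0,
                               theta_range=(0.7, 0.7), traps_per_plot=0)
        cc, _, _ = sim_observations(truth, [tree], cfg, seed=1)
        lam = 0.7 * 100.0
        se = np.sqrt(lam / len(cc))
        assert len(cc) == 10_000
        assert abs(cc["count"].mean() - lam) < 3 * se

    def test_trap_count_mean_matches_kernel_intensity(self):
        tree, truth = self._one_tree_setup()
        cfg = SimulationConfig(p_tree_observed=0.0, traps_per_plot=1,
                               trap_area_m2=1.0, kernel_u=100.0)
        _, traps, tc = sim_observations(truth, [tree], cfg, seed=2)
        r2 = (traps.iloc[0]["x"] - tree.x) ** 2 + (traps.iloc[0]["y"] - tree.y) ** 2
        lam = 1.0 * 100.0 * float(dispersal_kernel(r2, 100.0))
        se = np.sqrt(lam / len(tc))
        assert abs(tc["count"].mean() - lam) < 3 * se

    def test_kernel_closed_form_at_source(self):
        # tree exactly at the trap: lambda = a * psi * u / (pi u^2)
        assert float(dispersal_kernel(0.0, 100.0)) * 100.0 * 1.0 == pytest.approx(
            100.0 / (np.pi * 100.0)
        )

    def test_theta_outside_unit_interval_rejected(self):
        tree, truth = self._one_tree_setup(n_years=10)
        cfg = SimulationConfig(theta_range=(0.0, 1.2))
        with pytest.raises(ValueError, match="theta"):
            sim_observations(truth, [tree], cfg, seed=0)

    def test_first_seed_year_set_from_observations(self, small_sim):
        dataset, truth = small_sim
        seen = dataset.crop_counts[dataset.crop_counts["count"] > 0]
        for tid, grp in seen.groupby("tree_id"):
            tree = dataset.tree_map()[tid]
            assert tree.first_seed_year == grp["year"].min()


class TestFixture:
    def test_roundtrip_and_determinism(self, tmp_path, small_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        make_fixture(small_config, d1, seed=9)
        make_fixture(small_config, d2, seed=9)
        for name in ("trees", "climate", "cropcounts", "traps", "trapcounts"):
            assert (d1 / f"{name}.csv").read_bytes() == (d2 / f"{name}.csv").read_bytes()
        ds = read_tables(d1, window=small_config.window)
        direct, _ = simulate_dataset(small_config, seed=9)
        assert len(ds.trees) == len(direct.trees)
        for a, b in zip(sorted(ds.trees, key=lambda t: t.tree_id),
                        sorted(direct.trees, key=lambda t: t.tree_id)):
            assert a.tree_id == b.tree_id
            assert a.diameters == pytest.approx(b.diameters)
            assert a.first_seed_year == b.first_seed_year
        pd.testing.assert_frame_equal(ds.crop_counts, direct.crop_counts)

    def test_row_counts_match_config_arithmetic(self, tmp_path, small_config):
        make_fixture(small_config, tmp_path, seed=3)
        trees = pd.read_csv(tmp_path / "trees.csv")
        n_trees = (small_config.n_sites * small_config.plots_per_site
                   * small_config.trees_per_plot)
        n_years = small_config.years[1] - small_config.years[0]  # start+1..end
        assert len(trees) == n_trees * n_years
        tc = pd.read_csv(tmp_path / "trapcounts.csv")
        n_traps = small_config.n_sites * small_config.plots_per_site \
            * small_config.traps_per_plot
        assert len(tc) == n_traps * n_years
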