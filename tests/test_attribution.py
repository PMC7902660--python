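import math

import numpy as np
import pytest
from scipy import stats

from seedtrend import (
    FecundityCoefficients,
    FecundityModel,
    aggregate_plot,
    decompose_tree_year,
    default_fecundity_coefficients,
    default_growth_coefficients,
    genus_fallback,
    propagate_uncertainty,
    residual_gamma,
    response_partials,
    route_growth_to_climate,
    stand_absolute_change,
)
from seedtrend.datamodel import DESIGN_COLUMNS, build_design_vector
from seedtrend.growth import GrowthCoefficients

from conftest import make_site, make_tree

IDX = {n: i for i, n in enumerate(DESIGN_COLUMNS)}
TRENDS = {"tsp": 0.03, "tsum": 0.02, "deficit": 0.8}


def _design(g=30.0, tsp=5.0, tsum=20.0, d=50.0, shade=2.0,
            anoms=(0.1, -0.2, 0.3, -5.0, 4.0)):
    x = np.zeros(14)
    x[0] = 1.0
    x[IDX["diam"]], x[IDX["diam_sq"]] = g, g * g
    x[IDX["shade"]] = shade
    x[IDX["tsp_norm"]], x[IDX["tsp_anom"]] = tsp, anoms[0]
    x[IDX["tsum_norm"]], x[IDX["tsum_norm_sq"]] = tsum, tsum * tsum
    x[IDX["tsum_anom"]], x[IDX["tsum_anom_lag"]] = anoms[1], anoms[2]
    x[IDX["d_norm"]], x[IDX["d_anom"]], x[IDX["d_anom_lag"]] = d, anoms[3], anoms[4]
    x[IDX["d_norm_x_diam"]] = d * g
    return x


def _log_rho_psi(coef, g, tsp, tsum, d, shade):
    x = _design(g, tsp, tsum, d, shade)
    mu = coef.alpha0 + coef.alpha_g * g
    return float(stats.norm.logcdf(mu)) + float(x @ coef.beta)


class TestResponsePartials:
    def test_moisture_partial_arithmetic(self):
        beta = np.zeros(14)
        beta[IDX["d_norm"]] = -0.02
        beta[IDX["d_norm_x_diam"]] = 0.001
        coef = FecundityCoefficients(alpha0=-50, alpha_g=0.0, beta=beta)
        p = response_partials(coef, _design(g=30.0))
        assert p["deficit"] == pytest.approx(-0.02 + 0.001 * 30)

    def test_inverse_mills_at_zero(self):
        beta = np.zeros(14)
        coef = FecundityCoefficients(alpha0=0.0, alpha_g=0.05, beta=beta)
        x = _design(g=0.0)
        p = response_partials(coef, x)
        assert p["diam"] == pytest.approx(0.05 * stats.norm.pdf(0) / 0.5, rel=1e-6)
        assert p["diam"] == pytest.approx(0.03989, abs=1e-4)

    def test_deep_immature_no_nan(self):
        coef = default_fecundity_coefficients()
        x = _design(g=1e-3)
        coef2 = FecundityCoefficients(alpha0=-40.0, alpha_g=coef.alpha_g,
                                      beta=coef.beta)
        p = response_partials(coef2, x)
        assert np.isfinite(p["diam"])

    def test_matches_finite_differences_of_log_rho_psi(self):
        rng = np.random.default_rng(0)
        h = 1e-5
        for _ in range(40):
            coef = FecundityCoefficients(
                alpha0=rng.uniform(-4, 0), alpha_g=rng.uniform(0.0, 0.15),
                beta=rng.normal(0, 0.05, 14),
            )
            g, tsp, tsum, d, s = (rng.uniform(5, 80), rng.uniform(-5, 10),
                                  rng.uniform(12, 26), rng.uniform(0, 120),
                                  float(rng.integers(1, 6)))
            p = response_partials(coef, _design(g, tsp, tsum, d, s))
            fd = {
                "diam": (_log_rho_psi(coef, g + h, tsp, tsum, d, s)
                         - _log_rho_psi(coef, g - h, tsp, tsum, d, s)) / (2 * h),
                "tsp": (_log_rho_psi(coef, g, tsp + h, tsum, d, s)
                        - _log_rho_psi(coef, g, tsp - h, tsum, d, s)) / (2 * h),
                "tsum": (_log_rho_psi(coef, g, tsp, tsum + h, d, s)
                         - _log_rho_psi(coef, g, tsp, tsum - h, d, s)) / (2 * h),
                "deficit": (_log_rho_psi(coef, g, tsp, tsum, d + h, s)
                            - _log_rho_psi(coef, g, tsp, tsum, d - h, s)) / (2 * h),
            }
            for k, v in fd.items():
                assert p[k] == pytest.approx(v, abs=1e-6)


class TestDecomposition:
    def test_all_zero_trends(self):
        coef = default_fecundity_coefficients()
        t = decompose_tree_year(coef, _design(), {k: 0.0 for k in TRENDS}, dG=0.0,
                                gamma=0.123)
        assert t.direct_tsp == t.direct_tsum == t.direct_d == t.growth_term == 0.0
        assert t.total == 0.123

    def test_single_trend_arithmetic(self):
        beta = np.zeros(14)
        beta[IDX["tsp_norm"]] = 0.1
        coef = FecundityCoefficients(alpha0=-50, alpha_g=0.0, beta=beta)
        t = decompose_tree_year(coef, _design(),
                                {"tsp": 0.5, "tsum": 0.0, "deficit": 0.0},
                                dG=0.0, gamma=0.01)
        assert t.direct_tsp == pytest.approx(0.05)
        assert t.total == pytest.approx(0.06)

    def test_missing_trend_named(self):
        coef = default_fecundity_coefficients()
        with pytest.raises(KeyError, match="tsum"):
            decompose_tree_year(coef, _design(), {"tsp": 0.1, "deficit": 0.0}, dG=0.0)

    def test_additivity_exact(self):
        coef = default_fecundity_coefficients()
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = _design(g=rng.uniform(5, 80), d=rng.uniform(0, 120))
            t = decompose_tree_year(
                coef, x,
                {k: rng.normal(0, 0.1) for k in TRENDS},
                dG=rng.normal(0, 0.5), gamma=rng.normal(),
            )
            parts = (t.direct_tsp + t.direct_tsum + t.direct_d
                     + t.growth_term + t.gamma)
            assert abs(t.total - parts) <= 1e-12

    def test_first_order_error_quadratic_in_perturbation(self):
        coef = default_fecundity_coefficients()
        rng = np.random.default_rng(2)
        g, tsp, tsum, d, s = 30.0, 5.0, 20.0, 50.0, 2.0
        x = _design(g, tsp, tsum, d, s)
        hs = np.logspace(-3, -1, 7)
        errs = []
        for h in hs:
            e = []
            for _ in range(60):
                dt = {k: rng.normal() * h for k in TRENDS}
                dg = rng.normal() * h * 10
                t = decompose_tree_year(coef, x, dt, dG=dg)
                exact = (_log_rho_psi(coef, g + dg, tsp + dt["tsp"],
                                      tsum + dt["tsum"], d + dt["deficit"], s)
                         - _log_rho_psi(coef, g, tsp, tsum, d, s))
                e.append(abs(exact - t.total))
            errs.append(np.mean(e))
        slope = np.polyfit(np.log(hs), np.log(errs), 1)[0]
        assert 1.8 <= slope <= 2.2

    def test_sign_propagation(self):
        # response and trend sharing sign yields a positive direct term
        beta = np.zeros(14)
        beta[IDX["tsp_norm"]] = 0.2
        coef = FecundityCoefficients(alpha0=-50, alpha_g=0.0, beta=beta)
        pos = decompose_tree_year(coef, _design(),
                                  {"tsp": 0.4, "tsum": 0.0, "deficit": 0.0}, 0.0)
        neg = decompose_tree_year(coef, _design(),
                                  {"tsp": -0.4, "tsum": 0.0, "deficit": 0.0}, 0.0)
        assert pos.direct_tsp > 0 > neg.direct_tsp

    def test_maturation_component_sign_follows_growth(self):
        coef = default_fecundity_coefficients()
        up = decompose_tree_year(coef, _design(), TRENDS, dG=0.5)
        down = decompose_tree_year(coef, _design(), TRENDS, dG=-0.5)
        assert up.maturation_component > 0 > down.maturation_component

    def test_nu_var_is_twice_residual_variance(self):
        coef = default_fecundity_coefficients()
        t = decompose_tree_year(coef, _design(), TRENDS, dG=0.1)
        assert t.nu_var == pytest.approx(2 * coef.sigma2_resid)


class TestGamma:
    def test_year_effect_trend_plus_anomaly_carryover(self):
        coef = default_fecundity_coefficients()
        coef.kappa = {"ecoA": {2010 + i: 0.02 * i for i in range(10)}}
        g = residual_gamma(coef, "ecoA", TRENDS)
        b = coef.beta
        expected = (0.02
                    + b[IDX["tsp_anom"]] * TRENDS["tsp"]
                    + (b[IDX["tsum_anom"]] + b[IDX["tsum_anom_lag"]]) * TRENDS["tsum"]
                    + (b[IDX["d_anom"]] + b[IDX["d_anom_lag"]]) * TRENDS["deficit"])
        assert g == pytest.approx(expected, abs=1e-12)


class TestRouting:
    def test_growth_depends_only_on_deficit(self):
        fec = default_fecundity_coefficients()
        bg = np.zeros(14)
        bg[IDX["d_norm"]] = -0.002
        gro = GrowthCoefficients(beta_g=bg, sigma_g=0.2)
        x = _design()
        routed, unexp, dG = route_growth_to_climate(fec, gro, x, TRENDS)
        dfdg = response_partials(fec, x)["diam"]
        assert routed["tsp"] == routed["tsum"] == 0.0
        assert routed["deficit"] == pytest.approx(dfdg * -0.002 * TRENDS["deficit"])

    def test_zero_trends_all_unexplained(self):
        fec = default_fecundity_coefficients()
        gro = default_growth_coefficients()
        x = _design()
        routed, unexp, dG = route_growth_to_climate(
            fec, gro, x, {k: 0.0 for k in TRENDS}
        )
        assert all(v == 0.0 for v in routed.values())
        dfdg = response_partials(fec, x)["diam"]
        assert unexp == pytest.approx(dfdg * dG)

    def test_conservation_identity(self):
        fec = default_fecundity_coefficients()
        gro = default_growth_coefficients()
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = _design(g=rng.uniform(5, 80), d=rng.uniform(0, 120),
                        tsum=rng.uniform(12, 26))
            trends = {k: rng.normal(0, 0.2) for k in TRENDS}
            routed, unexp, dG = route_growth_to_climate(fec, gro, x, trends)
            t = decompose_tree_year(fec, x, trends, dG=dG)
            assert abs(sum(routed.values()) + unexp - t.growth_term) <= 1e-12


class TestAggregation:
    def _terms(self, totals, plot="p1"):
        out = []
        trees = []
        for i, tot in enumerate(totals):
            coef = FecundityCoefficients(alpha0=-50, alpha_g=0.0, beta=np.zeros(14))
            t = decompose_tree_year(coef, _design(), {k: 0.0 for k in TRENDS},
                                    dG=0.0, gamma=tot, tree_id=f"t{i}", year=2015)
            out.append(t)
            trees.append(make_tree(tree_id=f"t{i}", plot_id=plot,
                                   species="Quercus alba" if i % 2 else "Pinus taeda"))
        return out, trees

    def test_mean_of_totals(self):
        terms, trees = self._terms([0.02, -0.01])
        s = aggregate_plot(terms, trees)
        assert s.mean_df == pytest.approx(0.005)
        assert s.n_trees == 2

    def test_single_tree(self):
        terms, trees = self._terms([0.042])
        s = aggregate_plot(terms, trees)
        assert s.mean_df == pytest.approx(terms[0].total)

    def test_component_means_linear(self):
        terms, trees = self._terms([0.01, 0.03, -0.02])
        s = aggregate_plot(terms, trees)
        total_from_components = (
            s.mean_components["direct_tsp"] + s.mean_components["direct_tsum"]
            + s.mean_components["direct_d"] + s.mean_components["growth_term"]
            + s.mean_components["gamma"]
        )
        assert total_from_components == pytest.approx(s.mean_df, abs=1e-15)

    def test_empty_plot_raises(self):
        with pytest.raises(ValueError):
            aggregate_plot([], [])

    def test_stand_change_through_aggregate(self):
        terms, trees = self._terms([0.1, -0.2])
        s = aggregate_plot(terms, trees, fecundity={"t0": 100.0, "t1": 50.0})
        assert s.dF_stand == pytest.approx(100 * 0.1 - 50 * 0.2)


class TestStandChange:
    def test_examples(self):
        assert stand_absolute_change([100, 50], [0.1, -0.2]) == pytest.approx(0.0)
        assert stand_absolute_change([0.0, 70.0], [5.0, 0.01]) == pytest.approx(0.7)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            stand_absolute_change([1.0], [0.1, 0.2])

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        F = rng.uniform(0, 500, 30)
        df = rng.normal(0, 0.05, 30)
        brute = sum(f * d for f, d in zip(F, df))
        assert stand_absolute_change(F, df) == pytest.approx(brute, rel=1e-12)


class TestGenusFallback:
    def _coef(self, scale):
        return FecundityCoefficients(
            alpha0=-2.0 * scale, alpha_g=0.05 * scale,
            beta=np.full(14, scale), kappa={"e": {2010: scale}},
            sigma2_resid=scale, sigma2_re=scale,
        )

    def test_fitted_species_identity(self):
        fitted = {"Quercus alba": self._coef(1.0)}
        got = genus_fallback(fitted, "Quercus alba", "Quercus",
                             {"Quercus alba": "Quercus"})
        assert got is fitted["Quercus alba"]

    def test_two_congeners_mean(self):
        fitted = {"Quercus alba": self._coef(1.0), "Quercus rubra": self._coef(3.0)}
        gmap = {"Quercus alba": "Quercus", "Quercus rubra": "Quercus"}
        got = genus_fallback(fitted, "Quercus velutina", "Quercus", gmap)
        assert np.allclose(got.beta, 2.0)
        assert got.alpha0 == pytest.approx(-4.0)
        assert got.kappa["e"][2010] == pytest.approx(2.0)

    def test_three_congeners_match_column_means(self):
        scales = [0.5, 1.0, 2.5]
        fitted = {f"Pinus sp{i}": self._coef(s) for i, s in enumerate(scales)}
        gmap = {k: "Pinus" for k in fitted}
        got = genus_fallback(fitted, "Pinus nova", "Pinus", gmap)
        brute = np.mean([fitted[k].beta for k in fitted], axis=0)
        assert np.allclose(got.beta, brute)

    def test_no_congener_raises(self):
        with pytest.raises(KeyError, match="Abies"):
            genus_fallback({"Quercus alba": self._coef(1.0)}, "Abies concolor",
                           "Abies", {"Quercus alba": "Quercus"})


class TestPropagateUncertainty:
    def test_interval_endpoints_are_empirical_quantiles(self, small_fit):
        s = small_fit.samples_
        x = _design()
        df = propagate_uncertainty(s, x, TRENDS, dG=0.3, ecoregion=s.ecoregions[0])
        totals = np.empty(s.n_draws)
        from seedtrend.attribution import decompose_tree_year as dec
        for i in range(s.n_draws):
            coef = s.coefficients_at(i)
            g = residual_gamma(coef, s.ecoregions[0], TRENDS)
            totals[i] = dec(coef, x, TRENDS, dG=0.3, gamma=g).total
        assert df.loc["total", "q05"] == pytest.approx(np.quantile(totals, 0.05))
        assert df.loc["total", "q95"] == pytest.approx(np.quantile(totals, 0.95))
        assert df.loc["total", "q50"] == pytest.approx(np.median(totals))

    def test_requires_enough_draws(self, small_fit):
        import dataclasses

        s = small_fit.samples_
        short = dataclasses.replace(
            s, beta=s.beta[:50], alpha0=s.alpha0[:50], alpha_g=s.alpha_g[:50],
            kappa=s.kappa[:50], sigma2=s.sigma2[:50], sigma2_re=s.sigma2_re[:50],
            tau2=s.tau2[:50], kernel_u=s.kernel_u[:50],
            changepoint=s.changepoint[:50], deviance=s.deviance[:50],
        )
        with pytest.raises(ValueError, match="100"):
            propagate_uncertainty(short, _design(), TRENDS, dG=0.1)
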