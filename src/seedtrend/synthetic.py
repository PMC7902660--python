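"""Synthetic landscapes, tree populations, and observation layers.

The generator emulates the statistical structure the analysis assumes:
sites with climate norms, linear decadal trends, and interannual anomalies;
plots of trees with initial sizes and shade classes; Tobit-censored annual
diameter growth on the shared covariate structure; absorbing maturation
(probit in diameter, one uniform per tree so the state probability matches
Phi(alpha0 + alphaG G) while maturation is monotone); lognormal conditional
fecundity with year effects and individual random effects; and Poisson
crop-count and seed-trap observation layers.

Ground truth (coefficients, random effects, latent states) is retained in
:class:`SimulationTruth` so that recovery experiments can score the fitted
model against the generating process.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    CLIMATE_VARS,
    DESIGN_COLUMNS,
    Dataset,
    SiteClimate,
    TreeRecord,
    build_design_vector,
    site_climate_from_series,
)
from .fecundity import FecundityCoefficients, dispersal_kernel
from .growth import GrowthCoefficients

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "default_fecundity_coefficients",
    "default_growth_coefficients",
    "gen_landscape",
    "gen_tree_population",
    "gen_year_effects",
    "sim_growth",
    "sim_reproduction",
    "sim_observations",
    "simulate_dataset",
    "make_fixture",
]

_SPECIES_POOL = (
    ("Quercus alba", "Quercus"),
    ("Quercus rubra", "Quercus"),
    ("Pinus taeda", "Pinus"),
    ("Acer rubrum", "Acer"),
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic network.

    Defaults describe a desk-scale network: 10 sites in 4 ecoregions,
    4 plots per site (40 plots) of 25 trees each, a 16-year climate series
    whose last 15 years form the analysis window, temperate climate norms,
    decadal trends of realistic magnitude, and both observation layers
    (binocular crop counts with partial-crop fractions, and 0.5-m^2 seed
    traps under a Student-t seed shadow).
    """

    n_sites: int = 10
    n_ecoregions: int = 4
    plots_per_site: int = 4
    trees_per_plot: int = 25
    years: Tuple[int, int] = (2004, 2019)       # climate series span
    window: Tuple[int, int] = (2005, 2019)      # norm/trend/analysis window
    norm_ranges: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"tsp": (-4.0, 8.0), "tsum": (14.0, 24.0),
                                 "deficit": (0.0, 120.0)}
    )
    trend_ranges: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"tsp": (-0.02, 0.06), "tsum": (0.0, 0.05),
                                 "deficit": (-0.5, 1.5)}
    )
    anomaly_sd: Dict[str, float] = field(
        default_factory=lambda: {"tsp": 1.0, "tsum": 0.7, "deficit": 12.0}
    )
    ar1_rho: float = 0.0                        # optional anomaly autocorrelation
    diameter_init_range: Tuple[float, float] = (5.0, 45.0)
    shade_probs: Tuple[float, ...] = (0.15, 0.30, 0.30, 0.15, 0.10)
    plot_size: float = 50.0                     # m, square plots
    traps_per_plot: int = 2
    trap_area_m2: float = 0.5
    kernel_u: float = 80.0                      # m^2
    p_tree_observed: float = 0.6                # crop-count coverage over trees
    p_year_observed: float = 0.75               # ... and over years
    theta_range: Tuple[float, float] = (0.4, 1.0)  # fraction of crop observed
    sd_year_effect: float = 0.4
    sd_ecoregion_effect: float = 0.15
    species_pool: Tuple[Tuple[str, str], ...] = _SPECIES_POOL


def default_fecundity_coefficients(kernel_u: float = 80.0) -> FecundityCoefficients:
    """Generating fecundity parameters for the default study conditions.

    Maturation reaches 50% near 31 cm; conditional fecundity peaks at
    ~50 cm diameter (beta_G and beta_G^2) and near 17.5 degC summer T;
    shading suppresses; moisture deficit suppresses, more so for large trees.
    """
    beta = np.array([
        1.0,        # intercept
        0.09,       # G (cm)
        -9e-4,      # G^2
        -0.25,      # shade class
        0.06,       # Tsp norm (degC)
        0.05,       # Tsp anomaly
        0.35,       # Tsum norm
        -0.010,     # Tsum norm^2
        0.08,       # Tsum anomaly
        0.05,       # Tsum anomaly, lag 1
        -0.004,     # D norm (mm-month)
        -0.003,     # D anomaly
        -0.002,     # D anomaly, lag 1
        -5e-5,      # D norm x G
    ])
    return FecundityCoefficients(
        alpha0=-2.5, alpha_g=0.08, beta=beta,
        sigma2_resid=0.64, sigma2_re=0.16, kernel_u=kernel_u,
    )


def default_growth_coefficients() -> GrowthCoefficients:
    """Generating Tobit growth parameters (mean increment ~0.3-0.5 cm/yr)."""
    beta_g = np.array([
        0.35,       # intercept
        4e-3,       # G
        -8e-5,      # G^2
        -0.06,      # shade
        0.010,      # Tsp norm
        0.008,      # Tsp anomaly
        0.030,      # Tsum norm
        -1e-3,      # Tsum norm^2
        0.010,      # Tsum anomaly
        0.005,      # Tsum anomaly lag
        -1.5e-3,    # D norm
        -1e-3,      # D anomaly
        -5e-4,      # D anomaly lag
        -1e-5,      # D norm x G
    ])
    return GrowthCoefficients(beta_g=beta_g, sigma_g=0.25)


@dataclass
class SimulationTruth:
    """Everything the generator knew: coefficients, latents, and the seed."""

    fecundity_coefficients: FecundityCoefficients
    growth_coefficients: GrowthCoefficients
    b: Dict[str, float]                       # per-tree random effects
    maturation_year: Dict[str, Optional[int]]
    psi: pd.DataFrame                         # tree_id, year, z, psi
    seed: Optional[int] = None


def gen_landscape(
    n_sites: int,
    years: Tuple[int, int],
    trend_ranges: Optional[Dict[str, Tuple[float, float]]] = None,
    anomaly_sd: Optional[Dict[str, float]] = None,
    seed: Optional[int] = None,
    norm_ranges: Optional[Dict[str, Tuple[float, float]]] = None,
    window: Optional[Tuple[int, int]] = None,
    n_ecoregions: int = 4,
    ar1_rho: float = 0.0,
) -> List[SiteClimate]:
    """Draw site climates: norm + trend x (year - window midpoint) + anomaly."""
    cfg = SimulationConfig()
    trend_ranges = trend_ranges or cfg.trend_ranges
    anomaly_sd = anomaly_sd or cfg.anomaly_sd
    norm_ranges = norm_ranges or cfg.norm_ranges
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    y0, y1 = years
    if y0 >= y1:
        raise ValueError("years start must precede end")
    window = window or (y0 + 1, y1)
    for v in CLIMATE_VARS:
        lo, hi = trend_ranges[v]
        if lo > hi:
            raise ValueError(f"invalid trend range for {v!r}")
        lo, hi = norm_ranges[v]
        if lo > hi:
            raise ValueError(f"invalid norm range for {v!r}")
    rng = np.random.default_rng(seed)
    mid = 0.5 * (window[0] + window[1])
    yrs = np.arange(y0, y1 + 1)
    sites: List[SiteClimate] = []
    for s in range(n_sites):
        eco = f"eco{s * n_ecoregions // n_sites + 1}"
        series: Dict[str, Dict[int, float]] = {}
        for v in CLIMATE_VARS:
            norm = rng.uniform(*norm_ranges[v])
            trend = rng.uniform(*trend_ranges[v])
            eps = rng.standard_normal(len(yrs)) * anomaly_sd[v]
            if ar1_rho:
                for t in range(1, len(eps)):
                    eps[t] = ar1_rho * eps[t - 1] + math.sqrt(1 - ar1_rho ** 2) * eps[t]
            vals = norm + trend * (yrs - mid) + eps
            series[v] = {int(y): float(val) for y, val in zip(yrs, vals)}
        sites.append(site_climate_from_series(f"site{s + 1:02d}", eco, series, window))
    return sites


def gen_tree_population(
    sites: Sequence[SiteClimate],
    n_trees_per_plot: int,
    diameter_init_range: Tuple[float, float],
    shade_probs: Sequence[float],
    seed: Optional[int] = None,
    plots_per_site: int = 1,
    plot_size: float = 50.0,
    species_pool: Sequence[Tuple[str, str]] = _SPECIES_POOL,
) -> List[TreeRecord]:
    """Trees with initial diameters, shade classes, and plot coordinates."""
    if not sites:
        raise ValueError("no sites supplied")
    probs = np.asarray(shade_probs, dtype=float)
    if probs.shape != (5,) or abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
        raise ValueError("shade_probs must be 5 non-negative probabilities summing to 1")
    rng = np.random.default_rng(seed)
    trees: List[TreeRecord] = []
    for site in sites:
        y_start = min(site.anomalies) + 1  # lagged anomalies exist from here on
        for p in range(plots_per_site):
            plot_id = f"{site.site_id}_p{p + 1}"
            for t in range(n_trees_per_plot):
                sp, genus = species_pool[rng.integers(len(species_pool))]
                d0 = rng.uniform(*diameter_init_range)
                shade = int(rng.choice(5, p=probs)) + 1
                trees.append(
                    TreeRecord(
                        tree_id=f"{plot_id}_t{t + 1:03d}",
                        species=sp, genus=genus,
                        site_id=site.site_id, plot_id=plot_id,
                        x=float(rng.uniform(0, plot_size)),
                        y=float(rng.uniform(0, plot_size)),
                        shade_class=shade,
                        diameters={y_start: float(d0)},
                    )
                )
    return trees


def sim_growth(
    trees: Sequence[TreeRecord],
    growth_coefficients: GrowthCoefficients,
    sites: Sequence[SiteClimate],
    seed: Optional[int] = None,
    noise_sd: Optional[float] = None,
) -> List[TreeRecord]:
    """Fill diameter trajectories with Tobit-censored annual increments.

    increment(y -> y+1) = max(0, x'beta_g + N(0, sigma_g^2)); diameters are
    therefore nondecreasing.  Trees are modified in place and returned.
    """
    site_map = {s.site_id: s for s in sites}
    sd = growth_coefficients.sigma_g if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    for tree in trees:
        site = site_map[tree.site_id]
        y = min(tree.diameters)
        last = max(site.anomalies)
        while y < last:
            x = build_design_vector(tree, site, y)
            m = float(x @ growth_coefficients.beta_g)
            inc = max(0.0, m + sd * rng.standard_normal())
            tree.diameters[y + 1] = tree.diameters[y] + inc
            y += 1
    return list(trees)


def gen_year_effects(
    ecoregions: Sequence[str],
    years: Sequence[int],
    sd_year: float,
    sd_ecoregion: float,
    seed: Optional[int] = None,
) -> Dict[str, Dict[int, float]]:
    """Year effects: shared yearly mean + ecoregion deviations, grand mean 0.

    Centering to zero grand mean puts the generating values on the same
    identified scale the fitted model reports (intercept absorbs the mean).
    """
    rng = np.random.default_rng(seed)
    kbar = rng.standard_normal(len(years)) * sd_year
    kap = kbar[None, :] + rng.standard_normal((len(ecoregions), len(years))) * sd_ecoregion
    kap -= kap.mean()
    return {
        eco: {int(y): float(kap[e, t]) for t, y in enumerate(years)}
        for e, eco in enumerate(ecoregions)
    }


def sim_reproduction(
    trees: Sequence[TreeRecord],
    fecundity_coefficients: FecundityCoefficients,
    sites: Sequence[SiteClimate],
    seed: Optional[int] = None,
) -> SimulationTruth:
    """Draw maturation states and conditional fecundities for every tree-year.

    One uniform per tree couples the maturation path monotonically:
    z_t = 1 iff Phi(alpha0 + alphaG G_t) >= u_i, so P(z_t = 1) matches the
    probit while the state is absorbing.  Mature tree-years get
    log psi = x'beta + kappa_[eco, t] + b_i + eps.
    """
    coef = fecundity_coefficients
    site_map = {s.site_id: s for s in sites}
    rng = np.random.default_rng(seed)
    b: Dict[str, float] = {}
    mat_year: Dict[str, Optional[int]] = {}
    rows = []
    sd_re = math.sqrt(coef.sigma2_re)
    sd_e = math.sqrt(coef.sigma2_resid)
    for tree in trees:
        site = site_map[tree.site_id]
        u_i = rng.random()
        b_i = sd_re * rng.standard_normal()
        b[tree.tree_id] = float(b_i)
        first_mature: Optional[int] = None
        gmax = 0.0
        for y in tree.years:
            if y not in site.anomalies or (y - 1) not in site.anomalies:
                continue
            gmax = max(gmax, tree.diameters[y])
            rho = float(stats.norm.cdf(coef.alpha0 + coef.alpha_g * gmax))
            z = 1 if rho >= u_i else 0
            if z and first_mature is None:
                first_mature = y
            if z:
                x = build_design_vector(tree, site, y)
                kap = coef.kappa_at(site.ecoregion, y, warn=False)
                lp = float(x @ coef.beta) + kap + b_i + sd_e * rng.standard_normal()
                psi = math.exp(lp)
            else:
                psi = 0.0
            rows.append((tree.tree_id, y, z, psi))
        mat_year[tree.tree_id] = first_mature
    psi_df = pd.DataFrame(rows, columns=["tree_id", "year", "z", "psi"])
    return SimulationTruth(
        fecundity_coefficients=coef,
        growth_coefficients=default_growth_coefficients(),
        b=b, maturation_year=mat_year, psi=psi_df, seed=seed,
    )


def sim_observations(
    truth: SimulationTruth,
    trees: Sequence[TreeRecord],
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Poisson crop counts and seed-trap counts from the latent states.

    Crop counts ~ Poisson(theta * psi) for a random subset of tree-years,
    with theta (fraction of crop observed) stored per observation; trap
    counts ~ Poisson(area * sum_i z_i psi_i K(r_i; u)).  Trees observed with
    seed get ``first_seed_year`` set (they are known mature from then on).
    """
    lo, hi = config.theta_range
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError("theta_range must lie within (0, 1]")
    rng = np.random.default_rng(seed)
    psi_lut = {
        (r.tree_id, int(r.year)): (int(r.z), float(r.psi))
        for r in truth.psi.itertuples(index=False)
    }

    cc_rows = []
    for tree in trees:
        if rng.random() >= config.p_tree_observed:
            continue
        theta = float(rng.uniform(lo, hi))
        first_seed: Optional[int] = None
        for y in tree.years:
            if (tree.tree_id, y) not in psi_lut:
                continue
            if rng.random() >= config.p_year_observed:
                continue
            z, psi = psi_lut[(tree.tree_id, y)]
            count = int(rng.poisson(theta * psi)) if z else 0
            cc_rows.append((tree.tree_id, y, count, theta))
            if count > 0 and (first_seed is None or y < first_seed):
                first_seed = y
        if first_seed is not None:
            tree.first_seed_year = first_seed
    crop_counts = pd.DataFrame(cc_rows, columns=["tree_id", "year", "count", "fraction"])

    plots: Dict[str, List[TreeRecord]] = {}
    for t in trees:
        plots.setdefault(t.plot_id, []).append(t)
    trap_rows = []
    tc_rows = []
    for plot_id in sorted(plots):
        members = plots[plot_id]
        years = sorted({y for t in members for y in t.years if (t.tree_id, y) in psi_lut})
        for q in range(config.traps_per_plot):
            trap_id = f"{plot_id}_trap{q + 1}"
            tx = float(rng.uniform(0, config.plot_size))
            ty = float(rng.uniform(0, config.plot_size))
            trap_rows.append((trap_id, plot_id, tx, ty, config.trap_area_m2))
            for y in years:
                lam = 0.0
                for t in members:
                    st = psi_lut.get((t.tree_id, y))
                    if st is None or st[0] == 0:
                        continue
                    r2 = (t.x - tx) ** 2 + (t.y - ty) ** 2
                    lam += st[1] * float(dispersal_kernel(r2, config.kernel_u))
                lam *= config.trap_area_m2
                tc_rows.append((trap_id, y, int(rng.poisson(lam))))
    traps = pd.DataFrame(trap_rows, columns=["trap_id", "plot_id", "x", "y", "area_m2"])
    trap_counts = pd.DataFrame(tc_rows, columns=["trap_id", "year", "count"])
    return crop_counts, traps, trap_counts


def simulate_dataset(
    config: Optional[SimulationConfig] = None,
    seed: Optional[int] = None,
    fecundity_coefficients: Optional[FecundityCoefficients] = None,
    growth_coefficients: Optional[GrowthCoefficients] = None,
) -> Tuple[Dataset, SimulationTruth]:
    """End-to-end simulation: landscape -> trees -> growth -> seed -> data."""
    cfg = config or SimulationConfig()
    seed = 0 if seed is None else int(seed)
    fec = fecundity_coefficients or default_fecundity_coefficients(cfg.kernel_u)
    gro = growth_coefficients or default_growth_coefficients()
    sites = gen_landscape(
        cfg.n_sites, cfg.years, cfg.trend_ranges, cfg.anomaly_sd,
        seed=seed, norm_ranges=cfg.norm_ranges, window=cfg.window,
        n_ecoregions=cfg.n_ecoregions, ar1_rho=cfg.ar1_rho,
    )
    trees = gen_tree_population(
        sites, cfg.trees_per_plot, cfg.diameter_init_range, cfg.shade_probs,
        seed=seed + 1, plots_per_site=cfg.plots_per_site,
        plot_size=cfg.plot_size, species_pool=cfg.species_pool,
    )
    sim_growth(trees, gro, sites, seed=seed + 2)
    if not fec.kappa:
        ecoregions = sorted({s.ecoregion for s in sites})
        years = list(range(cfg.window[0], cfg.window[1] + 1))
        fec = replace(
            fec,
            kappa=gen_year_effects(
                ecoregions, years, cfg.sd_year_effect, cfg.sd_ecoregion_effect,
                seed=seed + 3,
            ),
        )
    truth = sim_reproduction(trees, fec, sites, seed=seed + 4)
    truth.growth_coefficients = gro
    truth.seed = seed
    crop_counts, traps, trap_counts = sim_observations(truth, trees, cfg, seed=seed + 5)
    dataset = Dataset(
        trees=trees, sites=sites, crop_counts=crop_counts,
        traps=traps, trap_counts=trap_counts,
    )
    return dataset, truth


def make_fixture(
    config: Optional[SimulationConfig],
    out_dir,
    seed: Optional[int] = None,
) -> Dict[str, str]:
    """Write a complete fixture (CSV tables + truth.json) to ``out_dir``."""
    from . import io as io_mod  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, truth = simulate_dataset(config, seed=seed)
    paths = io_mod.write_tables(dataset, out)
    truth_path = out / "truth.json"
    coef = truth.fecundity_coefficients
    payload = {
        "seed": truth.seed,
        "fecundity": {
            "alpha0": coef.alpha0,
            "alpha_g": coef.alpha_g,
            "beta": {name: float(v) for name, v in zip(DESIGN_COLUMNS, coef.beta)},
            "kappa": {e: {str(y): v for y, v in d.items()} for e, d in coef.kappa.items()},
            "sigma2_resid": coef.sigma2_resid,
            "sigma2_re": coef.sigma2_re,
            "kernel_u": coef.kernel_u,
        },
        "growth": {
            "beta_g": {
                name: float(v)
                for name, v in zip(DESIGN_COLUMNS, truth.growth_coefficients.beta_g)
            },
            "sigma_g": truth.growth_coefficients.sigma_g,
        },
        "random_effects": truth.b,
        "maturation_year": truth.maturation_year,
    }
    truth_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    paths["truth"] = str(truth_path)
    return paths
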