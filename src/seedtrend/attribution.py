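"""Trend attribution: decompose proportionate fecundity change per tree-year.

Proportionate change df/dt = d log F / dt is split, to first order, into
direct climate terms (response partial x climate trend), a growth term
(including its maturation component through the inverse Mills ratio of the
maturation probit), and a residual gamma that houses trends entering through
year effects and climate anomalies:

    df/dt =   beta_Tsp * dTsp
            + (beta_T + 2 beta_T2 T) * dT
            + (beta_D + beta_GD G) * dD
            + (alphaG phi(mu)/Phi(mu) + beta_G + 2 beta_G2 G + beta_GD D) * dG
            + gamma

The growth term can be routed back to climate variables by expanding
dG/dt on the same covariates (the growth model's partials times the climate
trends), which exposes the two climate-condition-interaction pathways:
size-dependent effects of climate change and climate-dependent effects of
growth.  All terms are exact arithmetic so additivity holds to machine
precision, and the decomposition is the exact first-order Taylor expansion
of log(rho * psi), so its error against an exact recomputation shrinks as
the squared perturbation norm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import (
    DESIGN_COLUMNS,
    I_D,
    I_D_A,
    I_D_A1,
    I_DG,
    I_G,
    I_G2,
    I_S,
    I_TSP,
    I_TSP_A,
    I_TSUM,
    I_TSUM2,
    I_TSUM_A,
    I_TSUM_A1,
    TreeRecord,
)
from .fecundity import FecundityCoefficients, PosteriorSamples, inverse_mills
from .growth import GrowthCoefficients, growth_partials

__all__ = [
    "TATerms",
    "PlotSummary",
    "response_partials",
    "residual_gamma",
    "decompose_tree_year",
    "route_growth_to_climate",
    "aggregate_plot",
    "stand_absolute_change",
    "genus_fallback",
    "propagate_uncertainty",
]

CLIMATE_KEYS = ("tsp", "tsum", "deficit")


@dataclass
class TATerms:
    """Per tree-year decomposition terms (all in proportionate change / yr)."""

    tree_id: str
    year: int
    direct_tsp: float
    direct_tsum: float
    direct_d: float
    growth_term: float
    maturation_component: float
    gamma: float
    nu_var: float                         # Var of the stochastic residual, 2 sigma^2
    routed: Dict[str, float] = field(default_factory=dict)
    routed_unexplained: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.direct_tsp + self.direct_tsum + self.direct_d
            + self.growth_term + self.gamma
        )


@dataclass
class PlotSummary:
    """Plot-level aggregation: unweighted means over member trees."""

    plot_id: str
    n_trees: int
    mean_df: float                        # mean proportionate change, 1/yr
    mean_components: Dict[str, float]
    dF_stand: Optional[float]             # absolute stand change, seeds/yr
    by_species: Dict[str, float]          # species -> mean total


def response_partials(
    coefficients: FecundityCoefficients, design: np.ndarray
) -> Dict[str, float]:
    """Partial derivatives of log F = log(rho * psi) per underlying variable.

    Main effects are fitted coefficients; interaction and quadratic columns
    contribute combinations of coefficients and state variables; diameter
    additionally carries the maturation component alphaG * phi(mu)/Phi(mu)
    (the derivative of log Phi), computed in log space so deep-immature
    trees cannot produce NaN.
    """
    x = np.asarray(design, dtype=float)
    b = coefficients.beta
    g = x[I_G]
    tsum = x[I_TSUM]
    d = x[I_D]
    mu = coefficients.alpha0 + coefficients.alpha_g * g
    mills = float(inverse_mills(mu))
    return {
        "tsp": float(b[I_TSP]),
        "tsum": float(b[I_TSUM] + 2.0 * b[I_TSUM2] * tsum),
        "deficit": float(b[I_D] + b[I_DG] * g),
        "diam": float(
            coefficients.alpha_g * mills + b[I_G] + 2.0 * b[I_G2] * g + b[I_DG] * d
        ),
        "shade": float(b[I_S]),
        "maturation": float(coefficients.alpha_g * mills),
    }


def residual_gamma(
    coefficients: FecundityCoefficients,
    ecoregion: str,
    climate_trends: Mapping[str, float],
) -> float:
    """Trend contributions that are neither geographic climate nor growth.

    Year effects and climate anomalies both drift over the window; their
    trends enter the decomposition through this residual: the OLS slope of
    the ecoregion's year effects plus the anomaly coefficients (current and
    lagged) times the corresponding climate trends.
    """
    from .datamodel import estimate_climate_trend

    b = coefficients.beta
    gamma = 0.0
    kap = coefficients.kappa.get(ecoregion, {})
    if len(kap) >= 3:
        years = sorted(kap)
        gamma += estimate_climate_trend(
            {y: kap[y] for y in years}, (years[0], years[-1])
        )
    gamma += float(b[I_TSP_A]) * climate_trends["tsp"]
    gamma += float(b[I_TSUM_A] + b[I_TSUM_A1]) * climate_trends["tsum"]
    gamma += float(b[I_D_A] + b[I_D_A1]) * climate_trends["deficit"]
    return gamma


def decompose_tree_year(
    coefficients: FecundityCoefficients,
    design: np.ndarray,
    climate_trends: Mapping[str, float],
    dG: float,
    tree_id: str = "",
    year: int = 0,
    gamma: float = 0.0,
    dt: float = 1.0,
) -> TATerms:
    """First-order decomposition of d log F for one tree-year.

    ``climate_trends`` must provide 'tsp', 'tsum', 'deficit' (units/yr);
    ``dG`` is the diameter growth rate (cm/yr) from the growth model or
    observed remeasurements; ``gamma`` is the residual trend term (see
    :func:`residual_gamma`).  The total is the exact sum of the terms.
    """
    for v in CLIMATE_KEYS:
        if v not in climate_trends:
            raise KeyError(f"missing climate trend for {v!r}")
    p = response_partials(coefficients, design)
    mat = p["maturation"] * dG * dt
    return TATerms(
        tree_id=tree_id,
        year=year,
        direct_tsp=p["tsp"] * climate_trends["tsp"] * dt,
        direct_tsum=p["tsum"] * climate_trends["tsum"] * dt,
        direct_d=p["deficit"] * climate_trends["deficit"] * dt,
        growth_term=p["diam"] * dG * dt,
        maturation_component=mat,
        gamma=gamma,
        nu_var=2.0 * coefficients.sigma2_resid,
    )


def route_growth_to_climate(
    fec_coefficients: FecundityCoefficients,
    growth_coefficients: GrowthCoefficients,
    design: np.ndarray,
    climate_trends: Mapping[str, float],
    dG: Optional[float] = None,
) -> Tuple[Dict[str, float], float, float]:
    """Split the growth term into climate-mediated and unexplained shares.

    dG/dt (by default the growth model's latent predictor x'beta_g) is
    decomposed into per-variable components d g/d c x dc/dt; each, times the
    fecundity response to diameter, is that climate variable's
    growth-mediated contribution.  Returns (routed, unexplained, dG), with
    sum(routed) + unexplained == growth term exactly.
    """
    x = np.asarray(design, dtype=float)
    if x.shape != (len(DESIGN_COLUMNS),):
        raise ValueError("design vector not aligned to the canonical ordering")
    if dG is None:
        dG = float(x @ growth_coefficients.beta_g)
    gp = growth_partials(growth_coefficients, x)
    dfdg = response_partials(fec_coefficients, x)["diam"]
    routed: Dict[str, float] = {}
    dg_explained = 0.0
    for v in CLIMATE_KEYS:
        if v not in climate_trends:
            raise KeyError(f"missing climate trend for {v!r}")
        part = gp[v] * climate_trends[v]
        dg_explained += part
        routed[v] = dfdg * part
    unexplained = dfdg * (dG - dg_explained)
    return routed, unexplained, float(dG)


def aggregate_plot(
    terms: Sequence[TATerms],
    trees: Sequence[TreeRecord],
    fecundity: Optional[Mapping[str, float]] = None,
) -> PlotSummary:
    """Average proportionate changes over the trees of one plot.

    ``fecundity`` (tree_id -> expected seeds/yr) enables the absolute
    stand-level change sum(F_i * df_i); omitted, ``dF_stand`` is None.
    """
    if not terms:
        raise ValueError("cannot aggregate an empty plot")
    tree_map = {t.tree_id: t for t in trees}
    plot_ids = {tree_map[tt.tree_id].plot_id for tt in terms if tt.tree_id in tree_map}
    if len(plot_ids) > 1:
        raise ValueError(f"terms span multiple plots: {sorted(plot_ids)}")
    plot_id = plot_ids.pop() if plot_ids else ""
    totals = np.array([t.total for t in terms])
    comp = {
        "direct_tsp": float(np.mean([t.direct_tsp for t in terms])),
        "direct_tsum": float(np.mean([t.direct_tsum for t in terms])),
        "direct_d": float(np.mean([t.direct_d for t in terms])),
        "growth_term": float(np.mean([t.growth_term for t in terms])),
        "maturation_component": float(np.mean([t.maturation_component for t in terms])),
        "gamma": float(np.mean([t.gamma for t in terms])),
    }
    by_species: Dict[str, List[float]] = {}
    for t in terms:
        sp = tree_map[t.tree_id].species if t.tree_id in tree_map else "unknown"
        by_species.setdefault(sp, []).append(t.total)
    dF = None
    if fecundity is not None:
        dF = stand_absolute_change(
            [fecundity[t.tree_id] for t in terms], [t.total for t in terms]
        )
    return PlotSummary(
        plot_id=plot_id,
        n_trees=len(terms),
        mean_df=float(totals.mean()),
        mean_components=comp,
        dF_stand=dF,
        by_species={sp: float(np.mean(v)) for sp, v in by_species.items()},
    )


def stand_absolute_change(F_values, df_values) -> float:
    """Absolute stand-level fecundity change: sum_i F_i * df_i (seeds/yr)."""
    F = np.asarray(F_values, dtype=float)
    df = np.asarray(df_values, dtype=float)
    if F.shape != df.shape:
        raise ValueError(f"length mismatch: {F.shape} vs {df.shape}")
    return float(F @ df)


def genus_fallback(
    fitted: Mapping[str, FecundityCoefficients],
    species: str,
    genus: str,
    genus_map: Mapping[str, str],
) -> FecundityCoefficients:
    """Coefficients for a species, averaging fitted congeners when unfitted."""
    if species in fitted:
        return fitted[species]
    congeners = [sp for sp in sorted(fitted) if genus_map.get(sp) == genus]
    if not congeners:
        raise KeyError(f"no fitted species in genus {genus!r} to fall back on")
    members = [fitted[sp] for sp in congeners]
    kappa: Dict[str, Dict[int, float]] = {}
    keys = {(e, y) for m in members for e, d in m.kappa.items() for y in d}
    for e, y in keys:
        vals = [m.kappa[e][y] for m in members if e in m.kappa and y in m.kappa[e]]
        kappa.setdefault(e, {})[y] = float(np.mean(vals))
    return FecundityCoefficients(
        alpha0=float(np.mean([m.alpha0 for m in members])),
        alpha_g=float(np.mean([m.alpha_g for m in members])),
        beta=np.mean([m.beta for m in members], axis=0),
        kappa=kappa,
        sigma2_resid=float(np.mean([m.sigma2_resid for m in members])),
        sigma2_re=float(np.mean([m.sigma2_re for m in members])),
        kernel_u=float(np.mean([m.kernel_u for m in members])),
    )


def propagate_uncertainty(
    samples: PosteriorSamples,
    design: np.ndarray,
    climate_trends: Mapping[str, float],
    dG: float,
    ecoregion: Optional[str] = None,
    include_pred_noise: bool = False,
    quantiles: Sequence[float] = (0.05, 0.50, 0.95),
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Per-term posterior quantiles by re-decomposing at every retained draw.

    With ``include_pred_noise`` the per-draw totals also receive the
    stochastic residual nu ~ N(0, 2 sigma^2), yielding predictive rather than
    credible intervals.  Requires at least 100 retained draws.
    """
    if samples.n_draws < 100:
        raise ValueError("uncertainty propagation needs at least 100 retained draws")
    rng = np.random.default_rng(seed)
    names = ["direct_tsp", "direct_tsum", "direct_d", "growth_term",
             "maturation_component", "gamma", "total"]
    draws = {n: np.empty(samples.n_draws) for n in names}
    for s in range(samples.n_draws):
        coef = samples.coefficients_at(s)
        gamma = (
            residual_gamma(coef, ecoregion, climate_trends) if ecoregion else 0.0
        )
        t = decompose_tree_year(coef, design, climate_trends, dG, gamma=gamma)
        total = t.total
        if include_pred_noise:
            total += math.sqrt(t.nu_var) * rng.standard_normal()
        for n in names[:-1]:
            draws[n][s] = getattr(t, n)
        draws["total"][s] = total
    out = {
        n: np.quantile(v, quantiles) for n, v in draws.items()
    }
    return pd.DataFrame(out, index=[f"q{int(100 * q):02d}" for q in quantiles]).T
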