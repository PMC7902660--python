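"""Hierarchical maturation + conditional-fecundity model, fit by MCMC.

The model per tree i, site j, year t:

    z_ij,t ~ absorbing maturation state, P(mature) = Phi(alpha0 + alphaG * G)
    log psi_ij,t = x'beta + kappa_[eco(j), t] + b_i + eps,  eps ~ N(0, sigma^2/w)
    crop count  ~ Poisson(theta * z * psi)        (theta = fraction observed)
    trap count  ~ Poisson(area * sum_i z psi K(r; u))

with a 2-D Student-t dispersal kernel K(r; u) = u / (pi (u + r^2)^2), year
effects kappa fixed within an ecoregion and hierarchically shrunk toward an
across-ecoregion yearly mean, and per-tree random effects b_i ~ N(0,
sigma_re^2).  Coefficient sampling is a weighted regression: w are
size-class weights (inverse occupancy of 5-cm diameter bins, winsorized
and normalized to mean 1) so rare and abundant sizes contribute comparably
to the size-fecundity curve; the weights enter every conjugate update
coherently, as inverse relative variances.

Posterior simulation composes conjugate Gaussian updates (beta, kappa, b,
variances) with Metropolis updates for the latent log psi (adaptive log-scale
random walk), a prior-proposal Metropolis-Hastings move for each tree's
maturation changepoint (absorbing by construction; trees observed bearing
seed are constrained mature from that year on), and a random-walk Metropolis
update for the maturation probit (alpha0, alphaG).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

from . import _sampler
from .datamodel import (
    DESIGN_COLUMNS,
    Dataset,
    SiteClimate,
    TreeRecord,
    build_design_vector,
)

__all__ = [
    "FecundityCoefficients",
    "PosteriorSamples",
    "FecundityModel",
    "fit_fecundity",
    "maturation_prob",
    "inverse_mills",
    "dispersal_kernel",
    "crop_count_loglik",
    "seed_trap_loglik",
    "size_class_weights",
    "predict_fecundity",
    "compute_dic",
    "dic_from_deviances",
]

_DEFAULT_PRIORS = {
    "beta_sd": 10.0,       # beta, kappa-mean ~ N(0, 10^2)
    "alpha0_mean": -3.0,
    "alpha0_sd": 2.0,
    "alphag_mean": 0.05,
    "alphag_sd": 0.05,     # truncated at 0
    "var_shape": 2.0,      # inverse-gamma(2, 1) for variances
    "var_rate": 1.0,
    "log_u_sd": 0.5,       # lognormal prior around the configured kernel u
}


@dataclass
class FecundityCoefficients:
    """Point (or single-draw) values of all model coefficients.

    ``beta`` is aligned to :data:`seedtrend.datamodel.DESIGN_COLUMNS`;
    ``kappa`` maps ecoregion -> {year: year effect}.
    """

    alpha0: float
    alpha_g: float
    beta: np.ndarray
    kappa: Dict[str, Dict[int, float]] = field(default_factory=dict)
    sigma2_resid: float = 0.25
    sigma2_re: float = 0.04
    kernel_u: float = 80.0
    theta_default: float = 1.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(DESIGN_COLUMNS),):
            raise ValueError(
                f"beta must have length {len(DESIGN_COLUMNS)} (canonical design order)"
            )
        if self.alpha_g < 0:
            raise ValueError("alpha_g must be >= 0: maturation increases with size")
        if self.sigma2_resid < 0 or self.sigma2_re < 0:
            raise ValueError("variances must be non-negative")

    def kappa_at(self, ecoregion: str, year: int, warn: bool = True) -> float:
        """Year effect, falling back to the ecoregion mean for unknown years."""
        eco = self.kappa.get(ecoregion, {})
        if year in eco:
            return eco[year]
        if eco:
            if warn:
                warnings.warn(
                    f"no year effect for {ecoregion}/{year}; using ecoregion mean",
                    stacklevel=2,
                )
            return float(np.mean(list(eco.values())))
        return 0.0


def maturation_prob(alpha0: float, alpha_g: float, diameter) -> np.ndarray:
    """Probability a tree of the given diameter (cm) is mature: Phi(a0 + aG*G)."""
    return stats.norm.cdf(alpha0 + alpha_g * np.asarray(diameter, dtype=float))


def inverse_mills(mu) -> np.ndarray:
    """phi(mu) / Phi(mu), computed in log space so deep-negative mu cannot NaN."""
    mu = np.asarray(mu, dtype=float)
    return np.exp(stats.norm.logpdf(mu) - special.log_ndtr(mu))


def dispersal_kernel(r2, u: float) -> np.ndarray:
    """Isotropic 2-D Student-t seed shadow, unit integral over the plane.

    ``r2`` is squared distance (m^2); ``u`` (m^2) controls spread.
    """
    if u <= 0:
        raise ValueError("kernel parameter u must be positive")
    r2 = np.asarray(r2, dtype=float)
    return u / (np.pi * (u + r2) ** 2)


def crop_count_loglik(count: int, fraction: float, psi: float) -> float:
    """Poisson log-likelihood of one crop count at rate fraction * psi."""
    if count < 0:
        raise ValueError("crop count must be non-negative")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction observed must lie in (0, 1]")
    if psi < 0:
        raise ValueError("psi must be >= 0")
    rate = fraction * psi
    if rate == 0.0:
        return 0.0 if count == 0 else -np.inf
    return float(count * np.log(rate) - rate - special.gammaln(count + 1.0))


def seed_trap_loglik(
    trap_counts,
    trap_xy: Tuple[float, float],
    trap_area: float,
    tree_xy: np.ndarray,
    z: np.ndarray,
    psi: np.ndarray,
    kernel_u: float,
) -> float:
    """Poisson log-likelihood of a trap's yearly counts.

    ``z`` and ``psi`` are (n_years, n_trees) maturation states and conditional
    fecundities of candidate source trees at ``tree_xy`` (n_trees, 2); the
    intensity per year is ``area * sum_i z_i psi_i K(r_i; u)``.
    """
    counts = np.atleast_1d(np.asarray(trap_counts, dtype=float))
    z = np.atleast_2d(np.asarray(z, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    tree_xy = np.atleast_2d(np.asarray(tree_xy, dtype=float))
    r2 = (tree_xy[:, 0] - trap_xy[0]) ** 2 + (tree_xy[:, 1] - trap_xy[1]) ** 2
    k = dispersal_kernel(r2, kernel_u)
    lam = trap_area * (z * psi) @ k
    out = 0.0
    for c, l in zip(counts, lam):
        if l == 0.0:
            if c != 0:
                return -np.inf
            continue
        out += c * np.log(l) - l - float(special.gammaln(c + 1.0))
    return float(out)


def size_class_weights(diameters, bin_cm: float = 5.0,
                       max_ratio: float = 10.0) -> np.ndarray:
    """Inverse size-class-occupancy weights, normalized to mean 1.

    Each observation is weighted by 1 / (count of observations in its
    ``bin_cm``-wide diameter bin), balancing abundant and rare size classes.
    Raw weights are winsorized at ``max_ratio`` times the median raw weight
    before normalization -- the usual guard against a nearly-empty bin
    dominating the regression with an extreme weight.
    """
    if bin_cm <= 0:
        raise ValueError("bin_cm must be positive")
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("no diameters supplied")
    bins = np.floor(d / bin_cm).astype(np.int64)
    _, inv, counts = np.unique(bins, return_inverse=True, return_counts=True)
    w = 1.0 / counts[inv]
    if max_ratio is not None and np.isfinite(max_ratio):
        w = np.minimum(w, max_ratio * float(np.median(w)))
    return w / w.mean()


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in MCMC draws plus latent-state summaries."""

    beta: np.ndarray               # (S, P)
    alpha0: np.ndarray             # (S,)
    alpha_g: np.ndarray            # (S,)
    kappa: np.ndarray              # (S, E, T)
    sigma2: np.ndarray             # (S,)
    sigma2_re: np.ndarray          # (S,)
    tau2: np.ndarray               # (S,)
    kernel_u: np.ndarray           # (S,)
    changepoint: np.ndarray        # (S, n_trees) int16 positions
    deviance: np.ndarray           # (S,)
    z_mean: np.ndarray             # (n_ty,)
    psi_mean: np.ndarray           # (n_ty,) conditional on mature (0 if never)
    deviance_at_mean: float
    tree_ids: List[str]
    tree_ptr: np.ndarray
    ty_tree: np.ndarray
    ty_year: np.ndarray
    ecoregions: List[str]
    years: List[int]
    meta: Dict[str, object] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def z_draws(self) -> np.ndarray:
        """(S, n_ty) maturation indicators reconstructed from changepoints."""
        n_ty = self.ty_tree.shape[0]
        pos = np.arange(n_ty) - self.tree_ptr[self.ty_tree]
        return (pos[None, :] >= self.changepoint[:, self.ty_tree]).astype(np.int8)

    def coefficients_at(self, s: int) -> FecundityCoefficients:
        kappa = {
            eco: {y: float(self.kappa[s, e, t]) for t, y in enumerate(self.years)}
            for e, eco in enumerate(self.ecoregions)
        }
        return FecundityCoefficients(
            alpha0=float(self.alpha0[s]),
            alpha_g=float(self.alpha_g[s]),
            beta=self.beta[s].copy(),
            kappa=kappa,
            sigma2_resid=float(self.sigma2[s]),
            sigma2_re=float(self.sigma2_re[s]),
            kernel_u=float(self.kernel_u[s]),
        )

    def mean_coefficients(self) -> FecundityCoefficients:
        km = self.kappa.mean(axis=0)
        kappa = {
            eco: {y: float(km[e, t]) for t, y in enumerate(self.years)}
            for e, eco in enumerate(self.ecoregions)
        }
        return FecundityCoefficients(
            alpha0=float(self.alpha0.mean()),
            alpha_g=float(max(self.alpha_g.mean(), 0.0)),
            beta=self.beta.mean(axis=0),
            kappa=kappa,
            sigma2_resid=float(self.sigma2.mean()),
            sigma2_re=float(self.sigma2_re.mean()),
            kernel_u=float(self.kernel_u.mean()),
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (iteration, parameter, value) table of scalar draws."""
        rows = []
        S = self.n_draws
        for j, name in enumerate(DESIGN_COLUMNS):
            rows.append(
                pd.DataFrame(
                    {"iteration": np.arange(S), "parameter": f"beta_{name}",
                     "value": self.beta[:, j]}
                )
            )
        for name, arr in (
            ("alpha0", self.alpha0), ("alpha_g", self.alpha_g),
            ("sigma2", self.sigma2), ("sigma2_re", self.sigma2_re),
            ("tau2", self.tau2), ("kernel_u", self.kernel_u),
            ("deviance", self.deviance),
        ):
            rows.append(
                pd.DataFrame({"iteration": np.arange(S), "parameter": name, "value": arr})
            )
        for e, eco in enumerate(self.ecoregions):
            for t, y in enumerate(self.years):
                rows.append(
                    pd.DataFrame(
                        {"iteration": np.arange(S),
                         "parameter": f"kappa_{eco}_{y}",
                         "value": self.kappa[:, e, t]}
                    )
                )
        return pd.concat(rows, ignore_index=True)


def split_rhat(chain: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one scalar chain."""
    x = np.asarray(chain, dtype=float)
    n = x.size // 2
    if n < 2:
        return float("nan")
    halves = np.stack([x[:n], x[-n:]])
    w = halves.var(axis=1, ddof=1).mean()
    b = n * halves.mean(axis=1).var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


# ---------------------------------------------------------------------------
# data packing


@dataclass
class _Packed:
    n_ty: int
    n_trees: int
    tree_ids: List[str]
    tree_ptr: np.ndarray
    ty_tree: np.ndarray
    ty_year: np.ndarray
    X: np.ndarray
    w: np.ndarray
    cell_idx: np.ndarray
    eco_of_tree: np.ndarray
    rho_g: np.ndarray          # running-max diameter per tree-year
    cc_ptr: np.ndarray
    cc_count: np.ndarray
    cc_frac: np.ndarray
    cc_k: np.ndarray           # tree-year index of each crop-count row
    pair_ptr: np.ndarray
    pair_tw: np.ndarray
    pair_r2: np.ndarray
    pair_area: np.ndarray
    pair_k: np.ndarray
    tw_count: np.ndarray
    limit: np.ndarray
    ecoregions: List[str]
    years: List[int]


def _pack(dataset: Dataset, bin_cm: float, window: Optional[Tuple[int, int]],
          spring_disperser: bool) -> _Packed:
    sites = dataset.site_map()
    trees = sorted(dataset.trees, key=lambda t: t.tree_id)
    if not trees:
        raise ValueError("dataset has no trees")

    ty_tree: List[int] = []
    ty_year: List[int] = []
    X_rows: List[np.ndarray] = []
    tree_ptr = [0]
    tree_ids = []
    for i, t in enumerate(trees):
        if t.site_id not in sites:
            raise ValueError(f"tree {t.tree_id} references unknown site {t.site_id}")
        site = sites[t.site_id]
        for y in t.years:
            if window is not None and not (window[0] <= y <= window[1]):
                continue
            if y not in site.anomalies or (y - 1) not in site.anomalies:
                continue
            ty_tree.append(i)
            ty_year.append(y)
            X_rows.append(build_design_vector(t, site, y, spring_disperser))
        tree_ptr.append(len(ty_tree))
        tree_ids.append(t.tree_id)
    if not ty_tree:
        raise ValueError("no usable tree-years (check window and anomaly coverage)")

    ty_tree_a = np.asarray(ty_tree, dtype=np.int64)
    ty_year_a = np.asarray(ty_year, dtype=np.int64)
    tree_ptr_a = np.asarray(tree_ptr, dtype=np.int64)
    X = np.vstack(X_rows)
    n_ty = len(ty_tree_a)

    years = sorted(set(ty_year))
    y0 = years[0]
    full_years = list(range(y0, years[-1] + 1))
    T = len(full_years)
    ecoregions = sorted({sites[t.site_id].ecoregion for t in trees})
    eco_index = {e: k for k, e in enumerate(ecoregions)}
    eco_of_tree = np.array(
        [eco_index[sites[t.site_id].ecoregion] for t in trees], dtype=np.int64
    )
    cell_idx = eco_of_tree[ty_tree_a] * T + (ty_year_a - y0)

    # running-max diameter drives the monotone maturation prior
    rho_g = np.empty(n_ty)
    for i, t in enumerate(trees):
        ys = t.years
        gmax: Dict[int, float] = {}
        m = 0.0
        for y in ys:
            m = max(m, t.diameters[y])
            gmax[y] = m
        for k in range(tree_ptr_a[i], tree_ptr_a[i + 1]):
            rho_g[k] = gmax[int(ty_year_a[k])]

    w = size_class_weights(X[:, 1], bin_cm)

    # crop counts -> CSR over tree-years
    ty_index = {(int(ty_tree_a[k]), int(ty_year_a[k])): k for k in range(n_ty)}
    tree_index = {t.tree_id: i for i, t in enumerate(trees)}
    cc_lists: List[List[Tuple[int, float]]] = [[] for _ in range(n_ty)]
    cc = dataset.crop_counts
    if len(cc):
        for tid, yr, count, frac in cc[["tree_id", "year", "count", "fraction"]].itertuples(
            index=False
        ):
            if tid not in tree_index:
                raise ValueError(f"crop count references unknown tree {tid}")
            if not (0.0 < frac <= 1.0):
                raise ValueError(f"crop-count fraction {frac} outside (0, 1]")
            if count < 0:
                raise ValueError("crop counts must be non-negative")
            key = (tree_index[tid], int(yr))
            if key in ty_index:
                cc_lists[ty_index[key]].append((int(count), float(frac)))
    cc_ptr = np.zeros(n_ty + 1, dtype=np.int64)
    cc_count_l: List[int] = []
    cc_frac_l: List[float] = []
    cc_k_l: List[int] = []
    for k in range(n_ty):
        for cnt, frac in cc_lists[k]:
            cc_count_l.append(cnt)
            cc_frac_l.append(frac)
            cc_k_l.append(k)
        cc_ptr[k + 1] = len(cc_count_l)
    cc_count_a = np.asarray(cc_count_l, dtype=np.int64)
    cc_frac_a = np.asarray(cc_frac_l, dtype=np.float64)
    cc_k_a = np.asarray(cc_k_l, dtype=np.int64)

    # seed traps -> trap-years coupled to tree-years
    plot_trees: Dict[str, List[int]] = {}
    for i, t in enumerate(trees):
        plot_trees.setdefault(t.plot_id, []).append(i)
    trap_info: Dict[str, Tuple[str, float, float, float]] = {}
    if len(dataset.traps):
        for tid, pid, tx, ty_, area in dataset.traps[
            ["trap_id", "plot_id", "x", "y", "area_m2"]
        ].itertuples(index=False):
            if pid not in plot_trees:
                raise ValueError(f"trap {tid} references unknown plot {pid}")
            trap_info[tid] = (pid, float(tx), float(ty_), float(area))

    pair_lists: List[List[Tuple[int, float, float]]] = [[] for _ in range(n_ty)]
    tw_count_l: List[int] = []
    tc = dataset.trap_counts
    if len(tc):
        for trap_id, yr, count in tc[["trap_id", "year", "count"]].itertuples(index=False):
            if trap_id not in trap_info:
                raise ValueError(f"trap count references unknown trap {trap_id}")
            pid, tx, ty_c, area = trap_info[trap_id]
            pairs = []
            for i in plot_trees[pid]:
                key = (i, int(yr))
                if key in ty_index:
                    pairs.append((ty_index[key], i))
            if not pairs:
                if count > 0:
                    raise ValueError(
                        f"trap {trap_id} year {yr}: positive count but no candidate "
                        f"source trees in the dataset"
                    )
                continue
            j = len(tw_count_l)
            tw_count_l.append(int(count))
            for k, i in pairs:
                tr = trees[i]
                r2 = (tr.x - tx) ** 2 + (tr.y - ty_c) ** 2
                pair_lists[k].append((j, r2, area))
    pair_ptr = np.zeros(n_ty + 1, dtype=np.int64)
    pair_tw_l: List[int] = []
    pair_r2_l: List[float] = []
    pair_area_l: List[float] = []
    for k in range(n_ty):
        for j, r2, area in pair_lists[k]:
            pair_tw_l.append(j)
            pair_r2_l.append(r2)
            pair_area_l.append(area)
        pair_ptr[k + 1] = len(pair_tw_l)
    pair_tw_a = np.asarray(pair_tw_l, dtype=np.int64)
    pair_r2_a = np.asarray(pair_r2_l, dtype=np.float64)
    pair_area_a = np.asarray(pair_area_l, dtype=np.float64)
    pair_k_a = np.repeat(np.arange(n_ty, dtype=np.int64), np.diff(pair_ptr))
    tw_count_a = np.asarray(tw_count_l, dtype=np.int64)

    # maturation upper limits: a tree observed bearing seed is mature from
    # that year on (first_seed_year and positive crop counts)
    limit = np.empty(len(trees), dtype=np.int64)
    for i, t in enumerate(trees):
        b0, b1 = tree_ptr_a[i], tree_ptr_a[i + 1]
        n = b1 - b0
        L = n
        if t.first_seed_year is not None and n > 0:
            yrs = ty_year_a[b0:b1]
            if t.first_seed_year <= yrs[-1]:
                L = min(L, int(np.searchsorted(yrs, t.first_seed_year)))
        for k in range(b0, b1):
            for c in range(cc_ptr[k], cc_ptr[k + 1]):
                if cc_count_a[c] > 0:
                    L = min(L, k - b0)
                    break
        limit[i] = L

    return _Packed(
        n_ty=n_ty, n_trees=len(trees), tree_ids=tree_ids, tree_ptr=tree_ptr_a,
        ty_tree=ty_tree_a, ty_year=ty_year_a, X=X, w=w, cell_idx=cell_idx,
        eco_of_tree=eco_of_tree, rho_g=rho_g,
        cc_ptr=cc_ptr, cc_count=cc_count_a, cc_frac=cc_frac_a, cc_k=cc_k_a,
        pair_ptr=pair_ptr, pair_tw=pair_tw_a, pair_r2=pair_r2_a,
        pair_area=pair_area_a, pair_k=pair_k_a, tw_count=tw_count_a,
        limit=limit, ecoregions=ecoregions, years=full_years,
    )


# ---------------------------------------------------------------------------
# the estimator


class FecundityModel(BaseEstimator):
    """MCMC estimator of the maturation + conditional-fecundity model.

    Parameters mirror the run configuration: chain length, burn-in, thinning,
    the size-class bin width (cm) for inverse-occupancy weighting, the
    dispersal-kernel parameter ``kernel_u`` (m^2, optionally sampled under a
    lognormal prior), and an optional subset of design columns (the intercept
    is always retained; excluded coefficients are fixed at zero).

    After ``fit``: ``samples_`` (:class:`PosteriorSamples`), ``coefficients_``
    (posterior means), ``diagnostics_`` (acceptance rates, split-chain R-hat).
    """

    def __init__(
        self,
        n_iter: int = 4000,
        n_burn: int = 2000,
        thin: int = 2,
        bin_cm: float = 5.0,
        kernel_u: float = 80.0,
        sample_kernel_u: bool = False,
        design_columns: Optional[Sequence[str]] = None,
        spring_disperser: bool = False,
        window: Optional[Tuple[int, int]] = None,
        priors: Optional[Dict[str, float]] = None,
        random_state: Optional[int] = None,
    ):
        self.n_iter = n_iter
        self.n_burn = n_burn
        self.thin = thin
        self.bin_cm = bin_cm
        self.kernel_u = kernel_u
        self.sample_kernel_u = sample_kernel_u
        self.design_columns = design_columns
        self.spring_disperser = spring_disperser
        self.window = window
        self.priors = priors
        self.random_state = random_state

    # -- internal helpers -------------------------------------------------

    def _design_subset(self) -> np.ndarray:
        if self.design_columns is None:
            return np.arange(len(DESIGN_COLUMNS))
        idx = []
        for name in self.design_columns:
            if name not in DESIGN_COLUMNS:
                raise ValueError(f"unknown design column {name!r}")
            idx.append(DESIGN_COLUMNS.index(name))
        if 0 not in idx:
            idx = [0] + idx
        return np.asarray(sorted(set(idx)), dtype=np.int64)

    # -- fit ---------------------------------------------------------------

    def fit(self, dataset: Dataset, y=None) -> "FecundityModel":
        if self.n_burn >= self.n_iter:
            raise ValueError("n_burn must be smaller than n_iter")
        pri = dict(_DEFAULT_PRIORS)
        if self.priors:
            pri.update(self.priors)
        rng = np.random.default_rng(self.random_state)
        pk = _pack(dataset, self.bin_cm, self.window, self.spring_disperser)
        cols = self._design_subset()
        Xs = np.ascontiguousarray(pk.X[:, cols])
        P = len(cols)
        E, T = len(pk.ecoregions), len(pk.years)
        n_ty, n_trees = pk.n_ty, pk.n_trees

        # state
        alpha0 = pri["alpha0_mean"]
        alpha_g = max(pri["alphag_mean"], 1e-6)
        beta = np.zeros(P)
        kappa = np.zeros((E, T))
        kbar = np.zeros(T)
        b = np.zeros(n_trees)
        sigma2, sigma2_re, tau2 = 1.0, 0.1, 0.04
        u_kernel = float(self.kernel_u)

        rho = stats.norm.cdf(alpha0 + alpha_g * pk.rho_g)

        # init changepoints from the constrained prior
        cp = np.zeros(n_trees, dtype=np.int64)
        for i in range(n_trees):
            b0, b1 = pk.tree_ptr[i], pk.tree_ptr[i + 1]
            n = b1 - b0
            if n == 0:
                continue
            maxp = min(pk.limit[i], n)
            wv = np.empty(maxp + 1)
            for p in range(maxp + 1):
                wv[p] = _sampler._prior_w(rho, b0, n, p)
            s = wv.sum()
            if s <= 0:
                cp[i] = maxp
            else:
                cp[i] = rng.choice(maxp + 1, p=wv / s)
        pos = np.arange(n_ty) - pk.tree_ptr[pk.ty_tree]
        mature = (pos >= cp[pk.ty_tree]).astype(np.uint8)

        # init latent log psi: from counts where available, prior noise elsewhere
        log_psi = 0.5 * rng.standard_normal(n_ty)
        for c in range(len(pk.cc_count)):
            k = pk.cc_k[c]
            log_psi[k] = math.log((pk.cc_count[c] + 0.5) / pk.cc_frac[c])

        pair_ak = pk.pair_area * dispersal_kernel(pk.pair_r2, u_kernel)
        n_tw = len(pk.tw_count)

        def recompute_lam() -> np.ndarray:
            lam = np.zeros(n_tw)
            if len(pk.pair_k):
                np.add.at(
                    lam, pk.pair_tw,
                    pair_ak * np.exp(log_psi[pk.pair_k]) * mature[pk.pair_k],
                )
            return lam

        lam = recompute_lam()

        prior_prec_beta = 1.0 / pri["beta_sd"] ** 2
        a_v, b_v = pri["var_shape"], pri["var_rate"]
        log_u0 = math.log(u_kernel) if u_kernel > 0 else 0.0

        psi_step = 0.5
        alpha_scale = np.array([0.1, 0.005])
        u_step = 0.2
        acc_psi = acc_cp = acc_alpha = acc_u = 0
        tot_psi = tot_cp = tot_alpha = tot_u = 0
        win_acc_psi = win_tot_psi = 0
        win_acc_alpha = win_tot_alpha = 0

        n_save = max((self.n_iter - self.n_burn) // self.thin, 0)
        S_beta = np.empty((n_save, len(DESIGN_COLUMNS)))
        S_a0 = np.empty(n_save)
        S_ag = np.empty(n_save)
        S_kappa = np.empty((n_save, E, T))
        S_s2 = np.empty(n_save)
        S_s2re = np.empty(n_save)
        S_tau2 = np.empty(n_save)
        S_u = np.empty(n_save)
        S_cp = np.empty((n_save, n_trees), dtype=np.int16)
        S_dev = np.empty(n_save)
        z_count = np.zeros(n_ty)
        lp_sum = np.zeros(n_ty)
        psi_sum = np.zeros(n_ty)
        b_sum = np.zeros(n_trees)
        s_out = 0

        cc_gammaln = special.gammaln(pk.cc_count + 1.0) if len(pk.cc_count) else np.zeros(0)
        tw_gammaln = special.gammaln(pk.tw_count + 1.0) if n_tw else np.zeros(0)

        def _joint_loglik(lp_vec, mat_mask, lam_vec, mu_vec, s2_now) -> float:
            # "complete" deviance: observations given latents, plus the latent
            # conditional-fecundity density given the regression -- the focus
            # where covariate choice matters (maturation states conditioned on)
            ll = 0.0
            if len(pk.cc_count):
                m = mat_mask[pk.cc_k]
                rate = pk.cc_frac[m] * np.exp(np.minimum(lp_vec[pk.cc_k[m]], 600.0))
                rate = np.maximum(rate, 1e-300)
                ll += float(
                    np.sum(pk.cc_count[m] * np.log(rate) - rate - cc_gammaln[m])
                )
                # immature tree-years with observed counts are impossible states;
                # counts there are zero by the maturation constraint
            if n_tw:
                lam_c = np.maximum(lam_vec, 1e-300)
                pos_c = pk.tw_count > 0
                ll += float(np.sum(pk.tw_count[pos_c] * np.log(lam_c[pos_c])))
                ll -= float(np.sum(lam_vec)) + float(np.sum(tw_gammaln))
            if np.any(mat_mask):
                r = lp_vec[mat_mask] - mu_vec[mat_mask]
                s2k = s2_now / pk.w[mat_mask]
                ll += float(
                    np.sum(-0.5 * r * r / s2k - 0.5 * np.log(2 * np.pi * s2k))
                )
            return ll

        def deviance_now() -> float:
            mu_now = Xs @ beta + kappa.reshape(-1)[pk.cell_idx] + b[pk.ty_tree]
            return -2.0 * _joint_loglik(log_psi, mature.astype(bool), lam, mu_now, sigma2)

        for it in range(self.n_iter):
            sig2k = sigma2 / pk.w
            mu = Xs @ beta + kappa.reshape(-1)[pk.cell_idx] + b[pk.ty_tree]

            # latent fecundity Metropolis sweep
            zn = rng.standard_normal(n_ty)
            un = rng.random(n_ty)
            a, t_ = _sampler.psi_sweep(
                log_psi, mature, mu, sig2k,
                pk.cc_ptr, pk.cc_count, pk.cc_frac,
                pk.pair_ptr, pk.pair_tw, pair_ak, lam, pk.tw_count,
                psi_step, zn, un,
            )
            acc_psi += a; tot_psi += t_
            win_acc_psi += a; win_tot_psi += t_

            # maturation changepoints
            u1 = rng.random(n_trees)
            u2 = rng.random(n_trees)
            zn2 = rng.standard_normal(n_ty)
            a, t_ = _sampler.cp_sweep(
                cp, pk.tree_ptr, pk.limit, rho,
                log_psi, mature, mu, sig2k,
                pk.cc_ptr, pk.cc_count, pk.cc_frac,
                pk.pair_ptr, pk.pair_tw, pair_ak, lam, pk.tw_count,
                u1, u2, zn2,
            )
            acc_cp += a; tot_cp += t_

            # maturation probit (alpha0, alphaG) Metropolis
            cur_lp = (
                _sampler.changepoint_logprior(cp, pk.tree_ptr, rho)
                + stats.norm.logpdf(alpha0, pri["alpha0_mean"], pri["alpha0_sd"])
                + stats.norm.logpdf(alpha_g, pri["alphag_mean"], pri["alphag_sd"])
            )
            step = alpha_scale * rng.standard_normal(2)
            a0_p, ag_p = alpha0 + step[0], alpha_g + step[1]
            tot_alpha += 1; win_tot_alpha += 1
            if ag_p >= 0:
                rho_p = stats.norm.cdf(a0_p + ag_p * pk.rho_g)
                new_lp = (
                    _sampler.changepoint_logprior(cp, pk.tree_ptr, rho_p)
                    + stats.norm.logpdf(a0_p, pri["alpha0_mean"], pri["alpha0_sd"])
                    + stats.norm.logpdf(ag_p, pri["alphag_mean"], pri["alphag_sd"])
                )
                if math.log(rng.random()) < new_lp - cur_lp:
                    alpha0, alpha_g, rho = a0_p, ag_p, rho_p
                    acc_alpha += 1; win_acc_alpha += 1

            # dispersal kernel u (optional)
            if self.sample_kernel_u and n_tw:
                tot_u += 1
                lu_new = math.log(u_kernel) + u_step * rng.standard_normal()
                u_new = math.exp(lu_new)
                ak_new = pk.pair_area * dispersal_kernel(pk.pair_r2, u_new)
                lam_new = np.zeros(n_tw)
                np.add.at(
                    lam_new, pk.pair_tw,
                    ak_new * np.exp(log_psi[pk.pair_k]) * mature[pk.pair_k],
                )
                lam_c = np.maximum(lam, 1e-300)
                lam_nc = np.maximum(lam_new, 1e-300)
                pos_c = pk.tw_count > 0
                dll = float(
                    np.sum(pk.tw_count[pos_c] * (np.log(lam_nc[pos_c]) - np.log(lam_c[pos_c])))
                ) - float(np.sum(lam_new) - np.sum(lam))
                dll += stats.norm.logpdf(lu_new, log_u0, pri["log_u_sd"]) - stats.norm.logpdf(
                    math.log(u_kernel), log_u0, pri["log_u_sd"]
                )
                if math.log(rng.random()) < dll:
                    u_kernel = u_new
                    pair_ak = ak_new
                    lam = lam_new
                    acc_u += 1

            # conjugate block: beta, kappa (hierarchical), b, variances
            m = mature.astype(bool)
            n_m = int(m.sum())
            if n_m:
                Xm = Xs[m]
                wm = pk.w[m]
                lpm = log_psi[m]
                cell_m = pk.cell_idx[m]
                tree_m = pk.ty_tree[m]

                y1 = lpm - kappa.reshape(-1)[cell_m] - b[tree_m]
                A = (Xm * wm[:, None]).T @ Xm / sigma2 + prior_prec_beta * np.eye(P)
                rhs = Xm.T @ (wm * y1) / sigma2
                cf = np.linalg.cholesky(A)
                mean_b = np.linalg.solve(cf.T, np.linalg.solve(cf, rhs))
                beta = mean_b + np.linalg.solve(cf.T, rng.standard_normal(P))

                y2 = lpm - Xm @ beta
                r = y2 - b[tree_m]
                sw = np.bincount(cell_m, weights=wm * r, minlength=E * T)
                nw = np.bincount(cell_m, weights=wm, minlength=E * T)
            else:
                beta = (
                    rng.standard_normal(P) * pri["beta_sd"]
                )
                sw = np.zeros(E * T)
                nw = np.zeros(E * T)

            prec_cell = nw / sigma2 + 1.0 / tau2
            mean_cell = (sw / sigma2 + np.tile(kbar, E) / tau2) / prec_cell
            kappa = (mean_cell + rng.standard_normal(E * T) / np.sqrt(prec_cell)).reshape(E, T)

            prec_kb = E / tau2 + prior_prec_beta
            mean_kb = kappa.sum(axis=0) / tau2 / prec_kb
            kbar = mean_kb + rng.standard_normal(T) / math.sqrt(prec_kb)

            tau2 = 1.0 / rng.gamma(
                a_v + 0.5 * E * T, 1.0 / (b_v + 0.5 * float(((kappa - kbar) ** 2).sum()))
            )

            if n_m:
                r = y2 - kappa.reshape(-1)[cell_m]
                swb = np.bincount(tree_m, weights=wm * r, minlength=n_trees)
                nwb = np.bincount(tree_m, weights=wm, minlength=n_trees)
            else:
                swb = np.zeros(n_trees)
                nwb = np.zeros(n_trees)
            prec_b = nwb / sigma2 + 1.0 / sigma2_re
            mean_bb = (swb / sigma2) / prec_b
            b = mean_bb + rng.standard_normal(n_trees) / np.sqrt(prec_b)

            if n_m:
                resid = y2 - kappa.reshape(-1)[cell_m] - b[tree_m]
                sigma2 = 1.0 / rng.gamma(
                    a_v + 0.5 * n_m, 1.0 / (b_v + 0.5 * float(np.sum(wm * resid ** 2)))
                )
            else:
                sigma2 = 1.0 / rng.gamma(a_v, 1.0 / b_v)
            sigma2_re = 1.0 / rng.gamma(
                a_v + 0.5 * n_trees, 1.0 / (b_v + 0.5 * float(np.sum(b ** 2)))
            )

            # adapt proposal scales during burn-in
            if it < self.n_burn and (it + 1) % 50 == 0:
                if win_tot_psi:
                    rate = win_acc_psi / win_tot_psi
                    psi_step *= math.exp(np.clip(rate - 0.3, -0.5, 0.5))
                    psi_step = float(np.clip(psi_step, 1e-3, 10.0))
                if win_tot_alpha:
                    rate = win_acc_alpha / win_tot_alpha
                    alpha_scale *= math.exp(np.clip(rate - 0.3, -0.5, 0.5))
                win_acc_psi = win_tot_psi = 0
                win_acc_alpha = win_tot_alpha = 0

            # record (identified scale: kappa centered, grand mean in intercept)
            if it >= self.n_burn and (it - self.n_burn) % self.thin == 0 and s_out < n_save:
                km = float(kappa.mean())
                beta_full = np.zeros(len(DESIGN_COLUMNS))
                beta_full[cols] = beta
                beta_full[0] += km
                S_beta[s_out] = beta_full
                S_a0[s_out] = alpha0
                S_ag[s_out] = alpha_g
                S_kappa[s_out] = kappa - km
                S_s2[s_out] = sigma2
                S_s2re[s_out] = sigma2_re
                S_tau2[s_out] = tau2
                S_u[s_out] = u_kernel
                S_cp[s_out] = cp.astype(np.int16)
                S_dev[s_out] = deviance_now()
                z_count += mature
                lp_sum += np.where(mature.astype(bool), log_psi, 0.0)
                psi_sum += np.where(
                    mature.astype(bool), np.exp(np.minimum(log_psi, 600.0)), 0.0
                )
                b_sum += b
                s_out += 1

        if s_out == 0:
            raise RuntimeError("no posterior draws retained; check n_iter/n_burn/thin")

        z_mean = z_count / s_out
        with np.errstate(divide="ignore", invalid="ignore"):
            lp_bar = np.where(z_count > 0, lp_sum / np.maximum(z_count, 1), 0.0)
            psi_mean = np.where(z_count > 0, psi_sum / np.maximum(z_count, 1), 0.0)

        # plug-in deviance at posterior means (latents and regression)
        z_hat = (z_mean > 0.5)
        psi_hat = np.where(z_hat, np.exp(np.minimum(lp_bar, 600.0)), 0.0)
        lam_hat = np.zeros(n_tw)
        if n_tw:
            u_hat = float(np.mean(S_u[:s_out]))
            ak_hat = pk.pair_area * dispersal_kernel(pk.pair_r2, u_hat)
            np.add.at(lam_hat, pk.pair_tw, ak_hat * psi_hat[pk.pair_k])
        beta_hat_full = S_beta[:s_out].mean(axis=0)
        kappa_hat = S_kappa[:s_out].mean(axis=0)
        mu_hat = (
            pk.X @ beta_hat_full
            + kappa_hat.reshape(-1)[pk.cell_idx]
            + (b_sum / s_out)[pk.ty_tree]
        )
        deviance_at_mean = -2.0 * _joint_loglik(
            lp_bar, z_hat, lam_hat, mu_hat, float(np.mean(S_s2[:s_out]))
        )

        meta = {
            "n_iter": self.n_iter,
            "n_burn": self.n_burn,
            "thin": self.thin,
            "seed": self.random_state,
            "acceptance": {
                "psi": acc_psi / max(tot_psi, 1),
                "changepoint": acc_cp / max(tot_cp, 1),
                "alpha": acc_alpha / max(tot_alpha, 1),
                "kernel_u": acc_u / max(tot_u, 1) if tot_u else None,
            },
            "psi_step_final": psi_step,
            "design_columns": [DESIGN_COLUMNS[j] for j in cols],
        }
        samples = PosteriorSamples(
            beta=S_beta[:s_out], alpha0=S_a0[:s_out], alpha_g=S_ag[:s_out],
            kappa=S_kappa[:s_out], sigma2=S_s2[:s_out], sigma2_re=S_s2re[:s_out],
            tau2=S_tau2[:s_out], kernel_u=S_u[:s_out], changepoint=S_cp[:s_out],
            deviance=S_dev[:s_out], z_mean=z_mean, psi_mean=psi_mean,
            deviance_at_mean=deviance_at_mean,
            tree_ids=pk.tree_ids, tree_ptr=pk.tree_ptr, ty_tree=pk.ty_tree,
            ty_year=pk.ty_year, ecoregions=pk.ecoregions, years=pk.years, meta=meta,
        )
        rhat = {
            f"beta_{DESIGN_COLUMNS[j]}": split_rhat(samples.beta[:, j]) for j in cols
        }
        rhat["alpha0"] = split_rhat(samples.alpha0)
        rhat["sigma2"] = split_rhat(samples.sigma2)
        self.samples_ = samples
        self.coefficients_ = samples.mean_coefficients()
        self.diagnostics_ = {"rhat": rhat, **meta}
        return self

    def predict(self, tree: TreeRecord, site: SiteClimate, year: int) -> float:
        """Posterior-mean expected seeds per year for one tree-year."""
        if not hasattr(self, "coefficients_"):
            raise RuntimeError("model is not fitted")
        return predict_fecundity(
            self.coefficients_, tree, site, year, spring_disperser=self.spring_disperser
        )


def fit_fecundity(dataset: Dataset, seed: Optional[int] = None, **params) -> PosteriorSamples:
    """Fit the fecundity model and return posterior samples (thin wrapper)."""
    model = FecundityModel(random_state=seed, **params).fit(dataset)
    return model.samples_


def predict_fecundity(
    coefficients: FecundityCoefficients,
    tree: TreeRecord,
    site: SiteClimate,
    year: int,
    spring_disperser: bool = False,
    use_mean: bool = True,
) -> float:
    """Expected seeds per year: E[F] = Phi(mu) * exp(x'beta + kappa + s2/2).

    Random individual effects are marginalized, so the lognormal correction
    uses sigma^2_pred = sigma^2_resid + sigma^2_re.  With ``use_mean=False``
    the lognormal median (no correction) is returned instead.
    """
    x = build_design_vector(tree, site, year, spring_disperser)
    rho = float(maturation_prob(coefficients.alpha0, coefficients.alpha_g,
                                tree.diameters[year]))
    kap = coefficients.kappa_at(site.ecoregion, year)
    s2 = coefficients.sigma2_resid + coefficients.sigma2_re
    corr = 0.5 * s2 if use_mean else 0.0
    return rho * float(np.exp(x @ coefficients.beta + kap + corr))


def dic_from_deviances(deviances, deviance_at_mean: float) -> Dict[str, float]:
    """DIC = mean deviance + p_D, with p_D = mean deviance - deviance at mean."""
    dev = np.asarray(deviances, dtype=float)
    if dev.size < 10:
        raise ValueError("DIC needs at least 10 retained iterations")
    dbar = float(dev.mean())
    pd_ = dbar - float(deviance_at_mean)
    return {"dic": dbar + pd_, "p_d": pd_, "mean_deviance": dbar}


def compute_dic(samples: PosteriorSamples) -> Dict[str, float]:
    """Deviance information criterion of a fitted model."""
    return dic_from_deviances(samples.deviance, samples.deviance_at_mean)
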