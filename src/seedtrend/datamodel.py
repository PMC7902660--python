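"""Domain types and design-vector assembly for tree fecundity analysis.

The model works at the tree-year scale.  Each tree carries a yearly
diameter series (cm) and an ordinal shade class; each site carries climate
norms (window means), yearly anomalies, and linear trends for three
variables: spring minimum temperature (degC), summer mean temperature
(degC), and moisture deficit D = PET - P accumulated over months 1-8
(mm-month, positive = drier).

Every regression in the package (fecundity and growth) shares one canonical
design vector whose ordering is fixed by :data:`DESIGN_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DESIGN_COLUMNS",
    "CLIMATE_VARS",
    "TreeRecord",
    "SiteClimate",
    "Dataset",
    "Violation",
    "MissingDataError",
    "build_design_vector",
    "split_norm_anomaly",
    "estimate_climate_trend",
    "site_climate_from_series",
    "validate_dataset",
]

#: Canonical ordering of the shared design vector.  All coefficient vectors
#: (fecundity beta, growth beta_g) are aligned to this ordering.
DESIGN_COLUMNS: Tuple[str, ...] = (
    "intercept",      # 1
    "diam",           # G, cm
    "diam_sq",        # G^2, cm^2
    "shade",          # ordinal 1-5 (exposed -> understory)
    "tsp_norm",       # spring minimum T site norm, degC
    "tsp_anom",       # spring minimum T anomaly, year t
    "tsum_norm",      # summer mean T site norm, degC
    "tsum_norm_sq",   # (summer mean T norm)^2
    "tsum_anom",      # summer T anomaly, year t
    "tsum_anom_lag",  # summer T anomaly, year t-1
    "d_norm",         # moisture deficit site norm, mm-month
    "d_anom",         # moisture deficit anomaly, year t
    "d_anom_lag",     # moisture deficit anomaly, year t-1
    "d_norm_x_diam",  # D norm x G interaction
)

N_DESIGN = len(DESIGN_COLUMNS)

# Column indices, used throughout the package.
I_INT = 0
I_G = 1
I_G2 = 2
I_S = 3
I_TSP = 4
I_TSP_A = 5
I_TSUM = 6
I_TSUM2 = 7
I_TSUM_A = 8
I_TSUM_A1 = 9
I_D = 10
I_D_A = 11
I_D_A1 = 12
I_DG = 13

#: Climate variables carried by :class:`SiteClimate`.
CLIMATE_VARS: Tuple[str, ...] = ("tsp", "tsum", "deficit")


class MissingDataError(KeyError):
    """A tree-year requested from the design assembly is not available."""


@dataclass
class TreeRecord:
    """One tree: identity, location, and its yearly state variables.

    ``diameters`` maps calendar year -> stem diameter (cm) and must be
    defined on consecutive years.  ``first_seed_year``, when present, is the
    earliest year the tree was observed bearing seed; the tree is then known
    to be mature from that year on.
    """

    tree_id: str
    species: str
    genus: str
    site_id: str
    plot_id: str
    x: float
    y: float
    shade_class: int
    diameters: Dict[int, float] = field(default_factory=dict)
    first_seed_year: Optional[int] = None

    def __post_init__(self) -> None:
        if self.shade_class not in (1, 2, 3, 4, 5):
            raise ValueError(
                f"tree {self.tree_id}: shade_class must be in 1..5, got {self.shade_class}"
            )
        if self.diameters:
            years = sorted(self.diameters)
            if years != list(range(years[0], years[-1] + 1)):
                raise ValueError(
                    f"tree {self.tree_id}: diameter series must cover consecutive years"
                )
            for y, d in self.diameters.items():
                if not np.isfinite(d) or d <= 0:
                    raise ValueError(
                        f"tree {self.tree_id}: non-positive diameter {d} in year {y}"
                    )
            if self.first_seed_year is not None and not (
                years[0] <= self.first_seed_year <= years[-1]
            ):
                raise ValueError(
                    f"tree {self.tree_id}: first_seed_year {self.first_seed_year} "
                    f"outside diameter span {years[0]}..{years[-1]}"
                )

    @property
    def years(self) -> List[int]:
        return sorted(self.diameters)


@dataclass
class SiteClimate:
    """Per-site climate norms, yearly anomalies, and linear trends.

    ``norms`` and ``trends`` are keyed by :data:`CLIMATE_VARS`;
    ``anomalies`` maps year -> {var: anomaly}.  Trends are OLS slopes in
    units per year over ``window``.
    """

    site_id: str
    ecoregion: str
    norms: Dict[str, float]
    anomalies: Dict[int, Dict[str, float]]
    trends: Dict[str, float]
    window: Tuple[int, int]

    def __post_init__(self) -> None:
        if self.window[0] >= self.window[1]:
            raise ValueError(f"site {self.site_id}: window start must precede end")
        for v in CLIMATE_VARS:
            if v not in self.norms:
                raise ValueError(f"site {self.site_id}: missing norm for {v!r}")
            if v not in self.trends or not np.isfinite(self.trends[v]):
                raise ValueError(f"site {self.site_id}: missing/non-finite trend for {v!r}")
        # anomalies over the window average to ~0 by construction
        for v in CLIMATE_VARS:
            win = [
                self.anomalies[y][v]
                for y in range(self.window[0], self.window[1] + 1)
                if y in self.anomalies
            ]
            if win:
                scale = max(1.0, max(abs(a) for a in win))
                if abs(float(np.mean(win))) > 1e-6 * scale:
                    raise ValueError(
                        f"site {self.site_id}: anomalies for {v!r} do not average to zero"
                    )


@dataclass
class Dataset:
    """A validated bundle of trees, site climate, and observations.

    Observation tables are plain DataFrames with documented schemas:

    - ``crop_counts``: tree_id, year, count, fraction (of crop observed)
    - ``traps``: trap_id, plot_id, x, y, area_m2
    - ``trap_counts``: trap_id, year, count
    """

    trees: List[TreeRecord]
    sites: List[SiteClimate]
    crop_counts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["tree_id", "year", "count", "fraction"])
    )
    traps: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["trap_id", "plot_id", "x", "y", "area_m2"])
    )
    trap_counts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["trap_id", "year", "count"])
    )

    def site_map(self) -> Dict[str, SiteClimate]:
        return {s.site_id: s for s in self.sites}

    def tree_map(self) -> Dict[str, TreeRecord]:
        return {t.tree_id: t for t in self.trees}


def build_design_vector(
    tree: TreeRecord,
    site: SiteClimate,
    year: int,
    spring_disperser: bool = False,
) -> np.ndarray:
    """Assemble the canonical design vector for one tree-year.

    Requires the tree's diameter at ``year`` and site anomalies at ``year``
    and ``year - 1`` (summer temperature and moisture deficit enter with
    current and previous-year anomalies).  For spring-dispersing species
    (``spring_disperser=True``) only previous-year anomalies are used: the
    current-year anomaly slots carry the ``year - 1`` values and the lag
    slots are zero.
    """
    if year not in tree.diameters:
        raise MissingDataError(
            f"tree {tree.tree_id}: no diameter for year {year}"
        )
    for y in (year, year - 1):
        if y not in site.anomalies:
            raise MissingDataError(
                f"tree {tree.tree_id}: site {site.site_id} has no anomalies for year {y}"
            )
    g = float(tree.diameters[year])
    a_t = site.anomalies[year]
    a_l = site.anomalies[year - 1]
    if spring_disperser:
        tsp_a = a_l["tsp"]
        tsum_a, tsum_a1 = a_l["tsum"], 0.0
        d_a, d_a1 = a_l["deficit"], 0.0
    else:
        tsp_a = a_t["tsp"]
        tsum_a, tsum_a1 = a_t["tsum"], a_l["tsum"]
        d_a, d_a1 = a_t["deficit"], a_l["deficit"]
    x = np.array(
        [
            1.0,
            g,
            g * g,
            float(tree.shade_class),
            site.norms["tsp"],
            tsp_a,
            site.norms["tsum"],
            site.norms["tsum"] ** 2,
            tsum_a,
            tsum_a1,
            site.norms["deficit"],
            d_a,
            d_a1,
            site.norms["deficit"] * g,
        ],
        dtype=float,
    )
    if not np.all(np.isfinite(x)):
        raise ValueError(
            f"tree {tree.tree_id}, year {year}: non-finite design entries"
        )
    return x


def split_norm_anomaly(
    series: Mapping[int, float], window: Tuple[int, int]
) -> Tuple[float, Dict[int, float]]:
    """Split a yearly series into its window mean (norm) and anomalies.

    The norm is the mean over ``window`` (inclusive); anomalies are
    deviations from it for *every* year in the series, so that
    ``norm + anomaly`` reconstructs the input exactly.
    """
    y0, y1 = window
    if y0 >= y1:
        raise ValueError("window start must precede end")
    win_years = [y for y in range(y0, y1 + 1)]
    missing = [y for y in win_years if y not in series]
    if missing:
        raise ValueError(f"series does not cover window years {missing}")
    norm = float(np.mean([series[y] for y in win_years]))
    anomalies = {y: float(series[y]) - norm for y in series}
    return norm, anomalies


def estimate_climate_trend(
    series: Mapping[int, float], window: Tuple[int, int]
) -> float:
    """OLS slope (units per year) of a yearly series over ``window``."""
    y0, y1 = window
    years = np.array([y for y in sorted(series) if y0 <= y <= y1], dtype=float)
    if years.size < 3:
        raise ValueError("trend estimation needs at least 3 years in the window")
    vals = np.array([series[int(y)] for y in years], dtype=float)
    yc = years - years.mean()
    return float(yc @ (vals - vals.mean()) / (yc @ yc))


def site_climate_from_series(
    site_id: str,
    ecoregion: str,
    series: Mapping[str, Mapping[int, float]],
    window: Tuple[int, int],
) -> SiteClimate:
    """Build a :class:`SiteClimate` from raw yearly series.

    ``series`` maps each of :data:`CLIMATE_VARS` to {year: value}; norms,
    anomalies and OLS trends are computed over ``window``.
    """
    norms: Dict[str, float] = {}
    trends: Dict[str, float] = {}
    anomalies: Dict[int, Dict[str, float]] = {}
    for v in CLIMATE_VARS:
        norm, anom = split_norm_anomaly(series[v], window)
        norms[v] = norm
        trends[v] = estimate_climate_trend(series[v], window)
        for y, a in anom.items():
            anomalies.setdefault(y, {})[v] = a
    return SiteClimate(site_id, ecoregion, norms, anomalies, trends, window)


@dataclass
class Violation:
    """One validation finding; ``severity`` is 'error' or 'info'."""

    kind: str
    message: str
    severity: str = "error"


def validate_dataset(
    trees: Sequence[TreeRecord],
    sites: Sequence[SiteClimate],
    crop_counts: Optional[pd.DataFrame] = None,
    traps: Optional[pd.DataFrame] = None,
    trap_counts: Optional[pd.DataFrame] = None,
) -> List[Violation]:
    """Structural validation; returns an empty list iff the dataset is clean.

    Shrinking diameter series are reported at 'info' severity only (real
    remeasurements can shrink); everything else is an error.
    """
    out: List[Violation] = []
    site_ids = {s.site_id for s in sites}
    tree_ids = set()
    plot_ids = set()
    for t in trees:
        if t.tree_id in tree_ids:
            out.append(Violation("duplicate_tree", f"duplicate tree_id {t.tree_id}"))
        tree_ids.add(t.tree_id)
        plot_ids.add(t.plot_id)
        if t.site_id not in site_ids:
            out.append(
                Violation("unknown_site", f"tree {t.tree_id} references unknown site {t.site_id}")
            )
        for y, d in t.diameters.items():
            if d <= 0:
                out.append(
                    Violation("bad_diameter", f"tree {t.tree_id} year {y}: diameter {d} <= 0")
                )
        ys = t.years
        for a, b in zip(ys, ys[1:]):
            if t.diameters[b] < t.diameters[a]:
                out.append(
                    Violation(
                        "shrinking_diameter",
                        f"tree {t.tree_id}: diameter shrinks {a}->{b}",
                        severity="info",
                    )
                )
    if crop_counts is not None and len(crop_counts):
        for tid in crop_counts["tree_id"].unique():
            if tid not in tree_ids:
                out.append(
                    Violation("unknown_tree", f"crop count references unknown tree_id {tid}")
                )
        bad = crop_counts[(crop_counts["fraction"] <= 0) | (crop_counts["fraction"] > 1)]
        for _, r in bad.iterrows():
            out.append(
                Violation(
                    "bad_fraction",
                    f"crop count for tree {r['tree_id']} year {r['year']}: "
                    f"fraction {r['fraction']} outside (0, 1]",
                )
            )
        neg = crop_counts[crop_counts["count"] < 0]
        for _, r in neg.iterrows():
            out.append(
                Violation("negative_count", f"crop count for tree {r['tree_id']} is negative")
            )
    if traps is not None and len(traps):
        for pid in traps["plot_id"].unique():
            if pid not in plot_ids:
                out.append(
                    Violation("unknown_plot", f"trap references unknown plot_id {pid}")
                )
        trap_ids = set(traps["trap_id"])
        if trap_counts is not None and len(trap_counts):
            for tid in trap_counts["trap_id"].unique():
                if tid not in trap_ids:
                    out.append(
                        Violation("unknown_trap", f"trap count references unknown trap_id {tid}")
                    )
    elif trap_counts is not None and len(trap_counts):
        out.append(Violation("unknown_trap", "trap counts present but no traps defined"))
    return out
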