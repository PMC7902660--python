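"""Table readers/writers, run configuration, and the end-to-end pipeline.

All tables are UTF-8 CSV with a header row:

- ``trees.csv``: tree_id, species, genus, site_id, plot_id, x, y,
  shade_class, year, diameter_cm[, first_seed_year] (one row per tree-year)
- ``climate.csv``: site_id, ecoregion, year, tsp_min, tsum_mean, deficit
  (raw yearly values; norms/anomalies/trends are derived on read)
- ``cropcounts.csv``: tree_id, year, count, fraction
- ``traps.csv``: trap_id, plot_id, x, y, area_m2
- ``trapcounts.csv``: trap_id, year, count

The pipeline chains simulate (optional) -> fecundity MCMC -> Tobit growth ->
trend attribution -> plot aggregation -> report, writing its artifacts into
one output directory.  Every stochastic stage consumes a seed derived from
the run seed, so a rerun with the same configuration and seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import attribution as ta
from .datamodel import (
    CLIMATE_VARS,
    DESIGN_COLUMNS,
    Dataset,
    SiteClimate,
    TreeRecord,
    build_design_vector,
    site_climate_from_series,
    validate_dataset,
)
from .fecundity import (
    FecundityCoefficients,
    FecundityModel,
    predict_fecundity,
)
from .growth import GrowthCoefficients, TobitRegressor
from .synthetic import SimulationConfig, make_fixture

logger = logging.getLogger("seedtrend")

__all__ = [
    "read_tables",
    "write_tables",
    "RunConfig",
    "run_pipeline",
    "report",
]

_TREE_COLS = ["tree_id", "species", "genus", "site_id", "plot_id", "x", "y",
              "shade_class", "year", "diameter_cm"]
_CLIMATE_COLS = ["site_id", "ecoregion", "year", "tsp_min", "tsum_mean", "deficit"]
_CLIMATE_VAR_COL = {"tsp": "tsp_min", "tsum": "tsum_mean", "deficit": "deficit"}


def _require_columns(df: pd.DataFrame, cols, fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{fname}: missing required column(s) {missing}")


def write_tables(dataset: Dataset, out_dir) -> Dict[str, str]:
    """Write the dataset's five tables; returns {name: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in sorted(dataset.trees, key=lambda t: t.tree_id):
        for y in t.years:
            rows.append(
                (t.tree_id, t.species, t.genus, t.site_id, t.plot_id, t.x, t.y,
                 t.shade_class, y, t.diameters[y],
                 t.first_seed_year if t.first_seed_year is not None else "")
            )
    trees_df = pd.DataFrame(rows, columns=_TREE_COLS + ["first_seed_year"])
    crows = []
    for s in sorted(dataset.sites, key=lambda s: s.site_id):
        for y in sorted(s.anomalies):
            crows.append(
                (s.site_id, s.ecoregion, y,
                 s.norms["tsp"] + s.anomalies[y]["tsp"],
                 s.norms["tsum"] + s.anomalies[y]["tsum"],
                 s.norms["deficit"] + s.anomalies[y]["deficit"])
            )
    climate_df = pd.DataFrame(crows, columns=_CLIMATE_COLS)
    paths = {}
    for name, df in (
        ("trees", trees_df), ("climate", climate_df),
        ("cropcounts", dataset.crop_counts), ("traps", dataset.traps),
        ("trapcounts", dataset.trap_counts),
    ):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    return paths


def read_tables(data_dir, window: Optional[Tuple[int, int]] = None) -> Dataset:
    """Read and validate a dataset directory; fails fast on violations.

    ``window`` sets the climate norm/trend window; default is the climate
    series' full span.
    """
    d = Path(data_dir)
    trees_p = d / "trees.csv"
    climate_p = d / "climate.csv"
    for p in (trees_p, climate_p):
        if not p.exists():
            raise FileNotFoundError(f"required table missing: {p}")
    trees_df = pd.read_csv(trees_p)
    _require_columns(trees_df, _TREE_COLS, "trees.csv")
    climate_df = pd.read_csv(climate_p)
    _require_columns(climate_df, _CLIMATE_COLS, "climate.csv")

    sites: List[SiteClimate] = []
    for site_id, grp in climate_df.groupby("site_id", sort=True):
        eco = str(grp["ecoregion"].iloc[0])
        series = {
            v: {int(r.year): float(getattr(r, _CLIMATE_VAR_COL[v]))
                for r in grp.itertuples(index=False)}
            for v in CLIMATE_VARS
        }
        years = sorted(series["tsp"])
        win = window or (years[0], years[-1])
        sites.append(site_climate_from_series(str(site_id), eco, series, win))

    trees: List[TreeRecord] = []
    has_fsy = "first_seed_year" in trees_df.columns
    for tree_id, grp in trees_df.groupby("tree_id", sort=True):
        r0 = grp.iloc[0]
        fsy = None
        if has_fsy and pd.notna(r0["first_seed_year"]) and r0["first_seed_year"] != "":
            fsy = int(float(r0["first_seed_year"]))
        trees.append(
            TreeRecord(
                tree_id=str(tree_id), species=str(r0["species"]), genus=str(r0["genus"]),
                site_id=str(r0["site_id"]), plot_id=str(r0["plot_id"]),
                x=float(r0["x"]), y=float(r0["y"]), shade_class=int(r0["shade_class"]),
                diameters={int(r["year"]): float(r["diameter_cm"])
                           for _, r in grp.iterrows()},
                first_seed_year=fsy,
            )
        )

    def _read_optional(name: str, cols) -> pd.DataFrame:
        p = d / f"{name}.csv"
        if not p.exists():
            return pd.DataFrame(columns=cols)
        df = pd.read_csv(p)
        _require_columns(df, cols, f"{name}.csv")
        return df

    cc = _read_optional("cropcounts", ["tree_id", "year", "count", "fraction"])
    traps = _read_optional("traps", ["trap_id", "plot_id", "x", "y", "area_m2"])
    tc = _read_optional("trapcounts", ["trap_id", "year", "count"])

    violations = validate_dataset(trees, sites, cc, traps, tc)
    errors = [v for v in violations if v.severity == "error"]
    if errors:
        msgs = "; ".join(v.message for v in errors[:10])
        raise ValueError(f"dataset validation failed ({len(errors)} errors): {msgs}")
    return Dataset(trees=trees, sites=sites, crop_counts=cc, traps=traps, trap_counts=tc)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """One text file drives the whole pipeline; CLI flags override fields."""

    out_dir: str = "artifacts"
    seed: int = 0
    data_dir: Optional[str] = None
    window: Optional[Tuple[int, int]] = None
    simulate: Optional[Dict] = None        # SimulationConfig overrides, or None
    fit: Dict = field(default_factory=dict)
    growth: Dict = field(default_factory=dict)
    attribution: Dict = field(default_factory=lambda: {"routing": True})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.window is not None:
            cfg.window = (int(cfg.window[0]), int(cfg.window[1]))
        return cfg

    def validate(self) -> None:
        if self.simulate is None and self.data_dir is None:
            raise ValueError("config must set either a simulate block or data_dir")
        if self.simulate is None and not Path(self.data_dir).exists():
            raise FileNotFoundError(f"data_dir does not exist: {self.data_dir}")
        if self.window is not None and self.window[0] >= self.window[1]:
            raise ValueError("window start must precede end")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    def content_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _coef_to_json(coef: FecundityCoefficients) -> Dict:
    return {
        "alpha0": coef.alpha0,
        "alpha_g": coef.alpha_g,
        "beta": {n: float(v) for n, v in zip(DESIGN_COLUMNS, coef.beta)},
        "kappa": {e: {str(y): v for y, v in d.items()} for e, d in coef.kappa.items()},
        "sigma2_resid": coef.sigma2_resid,
        "sigma2_re": coef.sigma2_re,
        "kernel_u": coef.kernel_u,
    }


def _coef_from_json(d: Dict) -> FecundityCoefficients:
    return FecundityCoefficients(
        alpha0=d["alpha0"], alpha_g=d["alpha_g"],
        beta=np.array([d["beta"][n] for n in DESIGN_COLUMNS]),
        kappa={e: {int(y): v for y, v in kk.items()} for e, kk in d["kappa"].items()},
        sigma2_resid=d["sigma2_resid"], sigma2_re=d["sigma2_re"],
        kernel_u=d["kernel_u"],
    )


# ---------------------------------------------------------------------------
# pipeline stages


def _stage_fit(dataset: Dataset, config: RunConfig, out: Path) -> FecundityModel:
    model = FecundityModel(
        random_state=int(config.seed) + 10, window=config.window, **config.fit
    ).fit(dataset)
    samples = model.samples_
    samples.to_long_frame().to_csv(out / "samples.csv", index=False)
    latent = pd.DataFrame(
        {
            "tree_id": [samples.tree_ids[i] for i in samples.ty_tree],
            "year": samples.ty_year,
            "z_mean": samples.z_mean,
            "psi_mean": samples.psi_mean,
        }
    )
    latent.to_csv(out / "latent_summary.csv", index=False)
    (out / "diagnostics.json").write_text(
        json.dumps(model.diagnostics_, indent=1, default=str)
    )
    (out / "fecundity_coefficients.json").write_text(
        json.dumps(_coef_to_json(model.coefficients_), indent=1)
    )
    return model


def _growth_training(dataset: Dataset, window) -> Tuple[np.ndarray, np.ndarray]:
    sites = dataset.site_map()
    X_rows, y_rows = [], []
    for t in dataset.trees:
        site = sites[t.site_id]
        ys = t.years
        for y in ys[:-1]:
            if window is not None and not (window[0] <= y <= window[1]):
                continue
            if y not in site.anomalies or (y - 1) not in site.anomalies:
                continue
            X_rows.append(build_design_vector(t, site, y))
            y_rows.append(max(0.0, t.diameters[y + 1] - t.diameters[y]))
    if not X_rows:
        raise ValueError("no growth increments available (check diameter series)")
    return np.vstack(X_rows), np.asarray(y_rows)


def _stage_growth(dataset: Dataset, config: RunConfig, out: Path) -> GrowthCoefficients:
    X, y = _growth_training(dataset, config.window)
    est = TobitRegressor(**config.growth).fit(X, y)
    coef = est.coefficients()
    (out / "growth_fit.json").write_text(
        json.dumps(
            {
                "beta_g": {n: float(v) for n, v in zip(DESIGN_COLUMNS, coef.beta_g)},
                "sigma_g": coef.sigma_g,
                "se": {n: float(v) for n, v in zip(DESIGN_COLUMNS, coef.se)},
                "converged": bool(coef.converged),
                "n_censored": est.n_censored_,
                "loglik": est.loglik_,
            },
            indent=1,
        )
    )
    return coef


def _stage_attribution(
    dataset: Dataset,
    fec: FecundityCoefficients,
    gro: GrowthCoefficients,
    config: RunConfig,
    out: Path,
) -> pd.DataFrame:
    sites = dataset.site_map()
    routing = bool(config.attribution.get("routing", True))
    rows = []
    for t in sorted(dataset.trees, key=lambda t: t.tree_id):
        site = sites[t.site_id]
        trends = site.trends
        gamma = ta.residual_gamma(fec, site.ecoregion, trends)
        for y in t.years:
            if config.window is not None and not (config.window[0] <= y <= config.window[1]):
                continue
            if y not in site.anomalies or (y - 1) not in site.anomalies:
                continue
            x = build_design_vector(t, site, y)
            dG = float(x @ gro.beta_g)
            terms = ta.decompose_tree_year(
                fec, x, trends, dG, tree_id=t.tree_id, year=y, gamma=gamma
            )
            if routing:
                routed, unexpl, _ = ta.route_growth_to_climate(fec, gro, x, trends, dG=dG)
            else:
                routed, unexpl = {v: np.nan for v in ta.CLIMATE_KEYS}, np.nan
            F = predict_fecundity(fec, t, site, y)
            rows.append(
                {
                    "tree_id": t.tree_id, "year": y, "plot_id": t.plot_id,
                    "species": t.species,
                    "direct_tsp": terms.direct_tsp, "direct_tsum": terms.direct_tsum,
                    "direct_d": terms.direct_d, "growth_term": terms.growth_term,
                    "maturation_component": terms.maturation_component,
                    "routed_tsp": routed["tsp"], "routed_tsum": routed["tsum"],
                    "routed_d": routed["deficit"], "routed_unexplained": unexpl,
                    "gamma": terms.gamma, "nu_var": terms.nu_var,
                    "total": terms.total, "expected_seeds": F,
                }
            )
    att = pd.DataFrame(rows)
    att.to_csv(out / "attribution.csv", index=False)
    return att


def _stage_plot_summary(att: pd.DataFrame, out: Path) -> pd.DataFrame:
    # one row per tree (its latest decomposed year), averaged within plots
    latest = att.sort_values("year").groupby("tree_id", sort=True).tail(1)
    rows = []
    comp_cols = ["direct_tsp", "direct_tsum", "direct_d", "growth_term",
                 "maturation_component", "gamma", "total"]
    for plot_id, grp in latest.groupby("plot_id", sort=True):
        row = {"plot_id": plot_id, "species": "(all)", "n_trees": len(grp)}
        for c in comp_cols:
            row[f"mean_{c}"] = float(grp[c].mean())
        row["dF_stand"] = float((grp["expected_seeds"] * grp["total"]).sum())
        rows.append(row)
        for sp, sgrp in grp.groupby("species", sort=True):
            srow = {"plot_id": plot_id, "species": sp, "n_trees": len(sgrp)}
            for c in comp_cols:
                srow[f"mean_{c}"] = float(sgrp[c].mean())
            srow["dF_stand"] = float((sgrp["expected_seeds"] * sgrp["total"]).sum())
            rows.append(srow)
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "plot_summary.csv", index=False)
    return summary


def run_pipeline(config: RunConfig, seed: Optional[int] = None) -> Path:
    """Execute the full pipeline; returns the artifact directory."""
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    # console output only when the application configured verbose logging
    logger.propagate = logging.getLogger().getEffectiveLevel() <= logging.INFO
    try:
        logger.info("seed=%s config_hash=%s", config.seed, config.content_hash())
        stage = "simulate"
        if config.simulate is not None:
            sim_cfg = SimulationConfig(**config.simulate)
            data_dir = out / "data"
            make_fixture(sim_cfg, data_dir, seed=int(config.seed))
            window = config.window or sim_cfg.window
            config = dataclasses.replace(
                config, data_dir=str(data_dir), window=window
            )
            logger.info("simulated fixture written to %s", data_dir)
        stage = "read"
        dataset = read_tables(config.data_dir, window=config.window)
        logger.info(
            "dataset: %d trees, %d sites, %d crop counts, %d trap counts",
            len(dataset.trees), len(dataset.sites),
            len(dataset.crop_counts), len(dataset.trap_counts),
        )
        stage = "fit_fecundity"
        model = _stage_fit(dataset, config, out)
        logger.info("fecundity fit done; acceptance=%s",
                    model.diagnostics_["acceptance"])
        stage = "fit_growth"
        gro = _stage_growth(dataset, config, out)
        stage = "attribute"
        att = _stage_attribution(dataset, model.coefficients_, gro, config, out)
        stage = "aggregate"
        _stage_plot_summary(att, out)
        stage = "report"
        report(out)
        logger.info("pipeline complete")
    except Exception as e:
        logger.error("stage %s failed: %s", stage, e)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def report(artifact_dir) -> str:
    """Human-readable markdown summary of a pipeline run; writes report.md."""
    out = Path(artifact_dir)
    samples_p = out / "samples.csv"
    att_p = out / "attribution.csv"
    for p in (samples_p, att_p):
        if not p.exists():
            raise FileNotFoundError(f"missing pipeline output: {p}")
    samples = pd.read_csv(samples_p)
    att = pd.read_csv(att_p)

    lines = ["# seedtrend run report", ""]
    lines.append("## Fecundity coefficients (posterior mean [5%, 95%])")
    lines.append("")
    lines.append("| parameter | mean | q05 | q95 |")
    lines.append("|---|---|---|---|")
    coef_rows = samples[samples["parameter"].str.startswith(("beta_", "alpha", "sigma2"))]
    for name, grp in coef_rows.groupby("parameter", sort=True):
        v = grp["value"].to_numpy()
        lines.append(
            f"| {name} | {v.mean():.4g} | {np.quantile(v, 0.05):.4g} "
            f"| {np.quantile(v, 0.95):.4g} |"
        )
    lines.append("")
    lines.append("## Mean proportionate fecundity change by component (per yr)")
    lines.append("")
    comp_cols = ["direct_tsp", "direct_tsum", "direct_d", "growth_term",
                 "maturation_component", "gamma", "total"]
    lines.append("| component | mean over tree-years |")
    lines.append("|---|---|")
    for c in comp_cols:
        lines.append(f"| {c} | {att[c].mean():.5g} |")
    lines.append("")

    truth_p = out / "data" / "truth.json"
    if truth_p.exists():
        truth = json.loads(truth_p.read_text())
        lines.append("## Recovery vs generating truth")
        lines.append("")
        lines.append("| parameter | truth | posterior mean | q05 | q95 | covered |")
        lines.append("|---|---|---|---|---|---|")
        entries = [("alpha0", truth["fecundity"]["alpha0"]),
                   ("alpha_g", truth["fecundity"]["alpha_g"])]
        entries += [(f"beta_{n}", truth["fecundity"]["beta"][n]) for n in DESIGN_COLUMNS]
        for name, tv in entries:
            grp = samples[samples["parameter"] == name]["value"].to_numpy()
            if grp.size == 0:
                continue
            lo, hi = np.quantile(grp, [0.05, 0.95])
            cov = "yes" if lo <= tv <= hi else "no"
            lines.append(
                f"| {name} | {tv:.4g} | {grp.mean():.4g} | {lo:.4g} | {hi:.4g} | {cov} |"
            )
        lines.append("")
    text = "\n".join(lines)
    (out / "report.md").write_text(text)
    return text
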