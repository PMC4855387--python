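"""End-to-end orchestration: ingest/generate -> filters -> AR -> composite ->
congruence -> seascape models -> ordination -> report.

A run is driven by a YAML/dict config with one master seed; per-stage
randomness derives from it, and every exclusion decision (sample, species,
island) is logged into the :class:`RunManifest` with a machine-readable
reason. Stages write plain CSV/JSON so any stage can be rerun from the
previous stage's files alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .composite import composite_ar
from .congruence import congruence_ttest, driver_correlations, species_congruence
from .io_formats import (SEASCAPE_PREDICTORS, TRAIT_COLUMNS, AlleleCountTable,
                         read_long_genotypes, read_seascape, read_traits)
from .ordination import RDA, morans_i
from .rarefaction import apply_inclusion_filters, species_island_ar
from .seascape_models import (MixedModelSelection, ModelSelection,
                              colinearity_screen, quadratic_fit, trait_models)
from .synthetic import generate_scenario, scenario_presets, ScenarioConfig

logger = logging.getLogger(__name__)

_version = "0.1.0"

DEFAULT_CONFIG = {
    "scenario": "habitat_driver",     # or paths: {genetic, seascape, traits}
    "seed": 0,
    "g_haploid": 6,
    "g_diploid": 12,
    "min_specimens": 6,
    "min_islands": 2,
    "strict_min": None,
    "k_species": 12,
    "n_resamples": 500,
    "congruence_min_islands": 6,
    "driver_min_islands": 5,
    "leave_one_out": False,
    "predictors": ["habitat_area_t", "lgm_loss", "coral_cover", "cca_cover",
                   "thermal_stress"],
    "max_terms": 3,
    "colinearity_threshold": 0.7,
    "regions": ["ARCH", "NWHI", "MHI"],
    "rda_permutations": 199,
    "moran_permutations": 199,
}


class ConfigError(ValueError):
    """Config violates the schema; message lists every violation."""


def _validate_config(cfg: dict) -> dict:
    merged = dict(DEFAULT_CONFIG)
    merged.update(cfg or {})
    problems = []
    if merged["k_species"] < 2:
        problems.append("k_species must be >= 2")
    if merged["min_specimens"] < 1:
        problems.append("min_specimens must be >= 1")
    if merged["max_terms"] < 1:
        problems.append("max_terms must be >= 1")
    if not (0 < merged["colinearity_threshold"] <= 1):
        problems.append("colinearity_threshold must lie in (0, 1]")
    has_paths = isinstance(merged.get("inputs"), dict)
    if not has_paths and "scenario" not in merged:
        problems.append("config needs either 'inputs' paths or a 'scenario' name")
    if problems:
        raise ConfigError("; ".join(problems))
    return merged


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    config_hash: str
    seed: int
    version: str = _version
    input_digests: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def log_stage(self, name: str, seconds: float, **counts) -> None:
        self.stages[name] = {"wall_seconds": round(seconds, 3), **counts}

    def log_exclusion(self, level: str, item: str, reason: str) -> None:
        self.exclusions.append({"level": level, "item": item, "reason": reason})

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {k: getattr(self, k) for k in
             ("config", "config_hash", "seed", "version", "input_digests",
              "stages", "exclusions", "outputs")},
            indent=2, default=str))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> RunManifest:
    """Run every stage in order and write outputs + manifest to ``out_dir``.

    ``config`` is a dict or a YAML path. Any stage failure halts the run
    with the manifest written up to that point.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg = _validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
    manifest = RunManifest(config=cfg, config_hash=cfg_hash, seed=int(cfg["seed"]))
    manifest_path = out / "manifest.json"
    try:
        _run_stages(cfg, out, manifest)
    finally:
        manifest.write(manifest_path)
    return manifest


def _run_stages(cfg: dict, out: Path, manifest: RunManifest) -> None:
    seed = int(cfg["seed"])

    # -- ingest / generate -------------------------------------------------
    t0 = time.perf_counter()
    if isinstance(cfg.get("inputs"), dict):
        paths = {k: Path(v) for k, v in cfg["inputs"].items()}
        table = read_long_genotypes(paths["genetic"])
        seascape = read_seascape(paths["seascape"])
        traits = read_traits(paths["traits"])
        manifest.input_digests = {k: _digest(p) for k, p in paths.items()}
        truth = None
    else:
        scen = cfg["scenario"]
        scen_cfg = scenario_presets(scen) if isinstance(scen, str) else ScenarioConfig(**scen)
        seascape, table, traits, truth = generate_scenario(scen_cfg, seed=seed)
        (out / "truth.json").write_text(json.dumps(truth, indent=2, default=str))
    table.to_csv(out / "genetic.csv")
    seascape.to_csv(out / "seascape.csv")
    traits.to_csv(out / "traits.csv")
    manifest.log_stage("ingest", time.perf_counter() - t0,
                       n_rows=len(table), n_islands=len(seascape.islands),
                       n_species=len(traits.species))

    # -- inclusion filters + rarefaction ----------------------------------
    t0 = time.perf_counter()
    filtered, report = apply_inclusion_filters(
        table, min_specimens=cfg["min_specimens"], min_islands=cfg["min_islands"],
        strict_min=cfg["strict_min"])
    for rec in report.records:
        manifest.log_exclusion(rec["level"],
                               f"{rec['species']}@{rec.get('island')}", rec["reason"])
    ar = species_island_ar(filtered, g_haploid=cfg["g_haploid"],
                           g_diploid=cfg["g_diploid"])
    ar.wide.to_csv(out / "ar_wide.csv")
    ar.per_locus.to_csv(out / "ar_per_locus.csv", index=False)
    manifest.log_stage("rarefaction", time.perf_counter() - t0,
                       n_cells=int(ar.wide.notna().sum().sum()),
                       n_excluded_samples=len(report.records))

    # -- composite ---------------------------------------------------------
    t0 = time.perf_counter()
    comp = composite_ar(ar, k_species=cfg["k_species"],
                        n_resamples=cfg["n_resamples"], seed=seed)
    for _, row in comp.data[~comp.data["included"]].iterrows():
        manifest.log_exclusion(
            "island", row["island"],
            f"only {row['n_species_available']} species with AR "
            f"(< {cfg['k_species']} required for the composite)")
    comp.to_csv(out / "composite.csv")
    manifest.log_stage("composite", time.perf_counter() - t0,
                       n_islands_included=len(comp.included_islands))

    # -- congruence + driver correlations ----------------------------------
    t0 = time.perf_counter()
    prof = species_congruence(ar, comp, min_islands=cfg["congruence_min_islands"],
                              leave_one_out=cfg["leave_one_out"])
    ttest = congruence_ttest(prof)
    drivers = driver_correlations(ar, seascape,
                                  min_islands=cfg["driver_min_islands"])
    profile = prof.data.join(drivers.data, how="outer")
    profile.to_csv(out / "correlation_profile.csv")
    (out / "congruence_test.json").write_text(json.dumps(
        {"t": ttest.t, "df": ttest.df, "p": ttest.p, "mean_r": ttest.mean_r,
         "n_species": ttest.n_species}, indent=2))
    manifest.log_stage("congruence", time.perf_counter() - t0,
                       n_species_tested=ttest.n_species, t=ttest.t, p=ttest.p)

    # -- seascape model selection ------------------------------------------
    t0 = time.perf_counter()
    retained, corr = colinearity_screen(seascape, cfg["predictors"],
                                        threshold=cfg["colinearity_threshold"])
    corr.to_csv(out / "predictor_correlations.csv")
    comp_series = comp.series()
    env = seascape.data
    model_tables = []
    for region in cfg["regions"]:
        islands = comp_series.index
        if region != "ARCH":
            islands = [i for i in islands if env.loc[i, "region"] == region]
        sub_env = env.loc[list(islands), retained].dropna()
        y = comp_series[sub_env.index]
        try:
            res = ModelSelection(y, sub_env, max_terms=cfg["max_terms"],
                                 region=region).fit()
        except Exception as e:  # small regional subsets can be infeasible
            logger.warning("model selection for region %s skipped: %s", region, e)
            continue
        tbl = res.table.copy()
        tbl["region"] = region
        tbl["coefficients"] = tbl["terms"].map(
            lambda t: json.dumps(res.fits[t].coefficients))
        tbl["islands_used"] = json.dumps(list(sub_env.index))
        model_tables.append(tbl.drop(columns=["terms"]))
    ols_table = pd.concat(model_tables, ignore_index=True)
    ols_table.to_csv(out / "models_composite.csv", index=False)

    # mixed models on the long species-by-marker records
    long = ar.per_locus[ar.per_locus["included"]].copy()
    long["group"] = long["species"] + "|" + long["marker_type"]
    long = (long.groupby(["group", "island"], as_index=False)["ar"].mean()
            .join(env[retained], on="island"))
    mixed_tbl = None
    try:
        mres = MixedModelSelection(long, retained, max_terms=cfg["max_terms"]).fit()
        mixed_tbl = mres.table.copy()
        mixed_tbl["coefficients"] = mixed_tbl["terms"].map(
            lambda t: json.dumps(mres.fits[t].coefficients))
        mixed_tbl.drop(columns=["terms"]).to_csv(out / "models_mixed.csv", index=False)
    except Exception as e:
        logger.warning("mixed model selection skipped: %s", e)

    # quadratic margins fit + trait models
    quad = quadratic_fit(comp_series.to_numpy(),
                         env.loc[comp_series.index, "latitude"].to_numpy())
    (out / "quadratic_latitude.json").write_text(json.dumps(
        {"r2": quad.r2, "p": quad.p, "coefficients": quad.coefficients}, indent=2))
    tm = trait_models(drivers, traits,
                      trait_columns=[c for c in TRAIT_COLUMNS
                                     if c in traits.data.columns],
                      max_terms=min(cfg["max_terms"], 2))
    trait_rows = []
    for drv, res in tm.items():
        top = res.top_set.copy()
        top["driver"] = drv
        trait_rows.append(top.drop(columns=["terms"]))
    if trait_rows:
        pd.concat(trait_rows, ignore_index=True).to_csv(
            out / "models_traits.csv", index=False)
    manifest.log_stage("models", time.perf_counter() - t0,
                       retained_predictors=retained,
                       n_candidates=int((ols_table["region"] == "ARCH").sum()))

    # -- ordination + spatial screen ---------------------------------------
    t0 = time.perf_counter()
    Y = drivers.driver_matrix().dropna()
    trait_cols = [c for c in TRAIT_COLUMNS if c in traits.data.columns]
    X = traits.data.set_index("species")[trait_cols].loc[
        Y.index.intersection(traits.data["species"])]
    Y = Y.loc[X.index]
    rda_res = None
    if len(Y) > len(trait_cols) + 1:
        rda_res = RDA(Y, X).fit(n_perm=cfg["rda_permutations"], seed=seed + 1)
        rda_res.species_scores.to_csv(out / "rda_species_scores.csv")
        rda_res.trait_scores.to_csv(out / "rda_trait_scores.csv")
        (out / "rda.json").write_text(json.dumps(
            {"constrained_proportion": rda_res.constrained_proportion,
             "p_perm": rda_res.p_perm,
             "eigenvalues": list(rda_res.eigenvalues)}, indent=2))
    coords = env.loc[comp_series.index, ["latitude", "longitude"]].to_numpy()
    moran = morans_i(comp_series.to_numpy(), coords=coords,
                     n_perm=cfg["moran_permutations"], seed=seed + 2)
    (out / "moran.json").write_text(json.dumps(
        {"morans_i": moran.morans_i, "expected": moran.expected,
         "p_perm": moran.p_perm, "weights": moran.weight_spec}, indent=2))
    manifest.log_stage("ordination", time.perf_counter() - t0,
                       rda_proportion=(rda_res.constrained_proportion
                                       if rda_res else None),
                       morans_i=moran.morans_i)
    manifest.outputs = {p.name: str(p) for p in sorted(out.glob("*.csv"))}


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

REPORT_REQUIRES = ["composite.csv", "models_composite.csv",
                   "correlation_profile.csv", "seascape.csv"]


def make_report(run_dir: str | Path) -> dict:
    """Assemble tables and figures from a completed run; recomputes nothing."""
    run = Path(run_dir)
    missing = [f for f in REPORT_REQUIRES if not (run / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"run at {run} is incomplete; missing stage outputs: {missing}")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comp = pd.read_csv(run / "composite.csv")
    env = pd.read_csv(run / "seascape.csv").set_index("island")
    models = pd.read_csv(run / "models_composite.csv")
    figures = {}

    merged = comp[comp["included"]].join(env, on="island")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(merged["fish_richness"], merged["composite"],
                yerr=merged["mc_sd"], fmt="o", capsize=2)
    ax.set_xlabel("fish species richness")
    ax.set_ylabel("composite AR (alleles / sample)")
    fig.tight_layout()
    p = run / "fig_composite_vs_richness.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    figures["composite_vs_richness"] = str(p)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(merged["latitude"], merged["composite"])
    xs = np.linspace(merged["latitude"].min(), merged["latitude"].max(), 100)
    try:
        quad = json.loads((run / "quadratic_latitude.json").read_text())
        c = quad["coefficients"]
        ax.plot(xs, c["intercept"] + c["x"] * xs + c["x2"] * xs ** 2, "r-",
                label=f"quadratic r$^2$={quad['r2']:.2f}")
        ax.legend()
    except FileNotFoundError:
        pass
    ax.set_xlabel("latitude (deg N)")
    ax.set_ylabel("composite AR")
    fig.tight_layout()
    p = run / "fig_composite_vs_latitude.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    figures["composite_vs_latitude"] = str(p)

    if (run / "rda_species_scores.csv").exists():
        sp = pd.read_csv(run / "rda_species_scores.csv", index_col=0)
        tr = pd.read_csv(run / "rda_trait_scores.csv", index_col=0)
        if sp.shape[1] >= 2:
            fig, ax = plt.subplots(figsize=(5.5, 5))
            ax.scatter(sp.iloc[:, 0], sp.iloc[:, 1], s=12, alpha=0.7)
            scale = np.abs(sp.iloc[:, :2].to_numpy()).max()
            for name, row in tr.iterrows():
                ax.annotate(name, (row.iloc[0] * scale, row.iloc[1] * scale),
                            color="firebrick", fontsize=8)
            ax.set_xlabel(sp.columns[0])
            ax.set_ylabel(sp.columns[1])
            fig.tight_layout()
            p = run / "fig_rda_biplot.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            figures["rda_biplot"] = str(p)

    top = models[models["delta_aicc"] < 2.0][
        ["region", "model", "K", "aicc", "delta_aicc", "w", "adj_r2",
         "coefficients"]]
    top_path = run / "report_top_models.csv"
    top.to_csv(top_path, index=False)
    return {"figures": figures, "top_models": str(top_path)}
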