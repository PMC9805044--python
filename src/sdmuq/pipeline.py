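"""End-to-end orchestration of the simulation experiment.

Stages: forcing -> truth -> samples -> models (fit/project/score/aggregate)
-> novelty -> shares.  Each stage writes its artifacts under the output
directory and records the configuration hash in a manifest; re-running with
an unchanged configuration loads the artifacts instead of recomputing.
Raw per-cell predictions are reduced to per-member annual metrics and
regional aggregates immediately and never persisted in full.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score

from ._rng import child_seed
from .config import ExperimentConfig
from .evaluation import auc_by_year, running_mean, spearman_by_year
from .extrapolation import percent_novel, reference_from_env
from .forcing import generate_forcing, write_forcing
from .operating_model import draw_truth
from .sampling import SDM_COVARIATES, attach_proxy_covariates, sample_cells
from .sdm import EnsembleMember, SdmConfig, enumerate_ensemble, fit_hurdle, project
from .uncertainty import aggregate_predictions, shares_by_year

__all__ = ["ExperimentResult", "run_experiment", "summarize"]

log = logging.getLogger(__name__)

STAGES = ("forcing", "truth", "samples", "models", "novelty", "shares")


@dataclass
class ExperimentResult:
    """Tables produced by one full experiment run."""

    config: ExperimentConfig
    performance: pd.DataFrame   # per member-year rho/auc (train and test roles)
    train_stats: pd.DataFrame   # per member pooled training-period fit metrics
    novelty: pd.DataFrame       # per (archetype, esm, year) percent-novel
    aggregates: pd.DataFrame    # per (member, year, region) biomass aggregate
    shares: pd.DataFrame        # per (experiment, archetype, region, year) shares
    stages_run: list[str] = field(default_factory=list)
    out_dir: Path | None = None


class _Manifest:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "manifest.json"
        self.data = {}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def fresh(self, stage: str, config_hash: str, files: list[Path]) -> bool:
        rec = self.data.get(stage)
        return (rec is not None and rec.get("config_hash") == config_hash
                and all(f.exists() for f in files))

    def record(self, stage: str, config_hash: str, seconds: float) -> None:
        self.data[stage] = {"config_hash": config_hash,
                            "wall_seconds": round(seconds, 2)}
        self.path.write_text(json.dumps(self.data, indent=1))


def _temp_roster(roster) -> list[tuple[str, str]]:
    fams = sorted({fam for fam, _ in roster},
                  key=[f for f, _ in roster].index)
    return [(fam, "Temp") for fam in fams]


def _retained_members(cfg: ExperimentConfig) -> list[EnsembleMember]:
    return enumerate_ensemble(cfg.archetype_names, cfg.esm_ids, cfg.roster,
                              cfg.exclusions, cfg.master_seed)


def _temp_members(cfg: ExperimentConfig) -> list[EnsembleMember]:
    return enumerate_ensemble(cfg.archetype_names, cfg.esm_ids,
                              _temp_roster(cfg.roster), frozenset(),
                              cfg.master_seed)


def run_experiment(config: ExperimentConfig, out_dir, force: bool = False
                   ) -> ExperimentResult:
    """Run (or resume) the full experiment; returns the result tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out_dir)
    chash = config.content_hash()
    stages_run: list[str] = []

    def stage(name, files, compute, load):
        files = [out_dir / f for f in files]
        if not force and manifest.fresh(name, chash, files):
            log.info("stage %s: up to date, skipping", name)
            return load(files)
        t0 = time.perf_counter()
        out = compute(files)
        manifest.record(name, chash, time.perf_counter() - t0)
        stages_run.append(name)
        log.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
        return out

    # -- forcing ------------------------------------------------------------
    def compute_forcing(files):
        envs = {}
        for style, f in zip(config.styles, files):
            env = generate_forcing(config.grid, style,
                                   seed=child_seed(config.master_seed, "forcing"))
            write_forcing(env, f)
            envs[style.esm_id] = env
        return envs

    def load_forcing(files):
        envs = {}
        for style, f in zip(config.styles, files):
            with xr.open_dataset(f, engine="scipy") as ds:
                envs[style.esm_id] = ds.load()
            envs[style.esm_id].attrs["esm_id"] = style.esm_id
        return envs

    envs = stage("forcing", [f"forcing_{s.esm_id}.nc" for s in config.styles],
                 compute_forcing, load_forcing)

    # -- truth --------------------------------------------------------------
    combos = [(a, e) for a in config.archetype_names for e in config.esm_ids]

    def compute_truth(files):
        truths = {}
        for (arch, esm), f in zip(combos, files):
            spec = config.archetype(arch)
            truths[(arch, esm)] = draw_truth(
                envs[esm], spec,
                seed=child_seed(config.master_seed, "truth", arch, esm))
            truths[(arch, esm)].to_netcdf(f, engine="scipy")
        return truths

    def load_truth(files):
        truths = {}
        for (arch, esm), f in zip(combos, files):
            with xr.open_dataset(f, engine="scipy") as ds:
                truths[(arch, esm)] = ds.load()
            truths[(arch, esm)].attrs.update(archetype=arch, esm_id=esm)
        return truths

    truths = stage("truth", [f"truth_{a}_{e}.nc" for a, e in combos],
                   compute_truth, load_truth)

    # -- samples ------------------------------------------------------------
    roles = [("train", config.train_years), ("test", config.test_years)]
    sample_files = [f"samples_{a}_{e}_{r}.csv"
                    for a, e in combos for r, _ in roles]

    def compute_samples(files):
        samples = {}
        it = iter(files)
        for arch, esm in combos:
            for role, (y0, y1) in roles:
                df = sample_cells(
                    truths[(arch, esm)], envs[esm], np.arange(y0, y1 + 1),
                    n_per_year=config.n_per_year,
                    seed=child_seed(config.master_seed, "samples", arch, role),
                    role=role)
                df = attach_proxy_covariates(df, arch)
                df.to_csv(next(it), index=False)
                samples[(arch, esm, role)] = df
        return samples

    def load_samples(files):
        samples = {}
        it = iter(files)
        for arch, esm in combos:
            for role, _ in roles:
                df = pd.read_csv(next(it))
                df = attach_proxy_covariates(df, arch)
                df.attrs["role"] = role
                samples[(arch, esm, role)] = df
        return samples

    samples = stage("samples", sample_files, compute_samples, load_samples)

    # -- models: fit, project, score, aggregate -----------------------------
    members = _retained_members(config)
    if config.include_temperature_only:
        members = members + _temp_members(config)

    def compute_models(files):
        perf_f, stats_f, agg_f = files
        perf_rows, stat_rows, agg_frames = [], [], []
        for m in members:
            train = samples[(m.archetype, m.esm_id, "train")]
            test = samples[(m.archetype, m.esm_id, "test")]
            fitted = fit_hurdle(train, m.config)
            pred_in = project(fitted, train)
            pred_out = project(fitted, test)

            key = dict(archetype=m.archetype, esm=m.esm_id,
                       family=m.config.family,
                       parameterization=m.config.parameterization,
                       sdm_id=m.config.sdm_id)

            rho_pool = float(spearmanr(train["biomass"].values,
                                       pred_in["biomass_pred"].values).statistic)
            y = train["presence"].values
            auc_pool = float(roc_auc_score(y, pred_in["p_occ"].values)) \
                if y.min() != y.max() else np.nan
            stat_rows.append({**key, "rho_train": rho_pool,
                              "auc_train": auc_pool,
                              "n_train": fitted.n_train,
                              "n_positive": fitted.n_positive})

            for role, tr, pr in (("train", train, pred_in),
                                 ("test", test, pred_out)):
                rho = spearman_by_year(tr, pr)
                auc = auc_by_year(tr, pr)
                perf_rows.append(pd.DataFrame({
                    **key, "role": role, "year": rho.index,
                    "rho": rho.values, "auc": auc.reindex(rho.index).values,
                }))

            pred_out = pred_out.merge(
                test[["year", "cell", "lat"]], on=["year", "cell"])
            pred_out = pred_out.assign(**key)
            agg_frames.append(pd.concat([
                aggregate_predictions(pred_out, by_region=True),
                aggregate_predictions(pred_out, by_region=False),
            ], ignore_index=True))

        perf = pd.concat(perf_rows, ignore_index=True)
        stats = pd.DataFrame(stat_rows)
        agg = pd.concat(agg_frames, ignore_index=True)
        perf.to_csv(perf_f, index=False)
        stats.to_csv(stats_f, index=False)
        agg.to_csv(agg_f, index=False)
        return perf, stats, agg

    def load_models(files):
        return tuple(pd.read_csv(f) for f in files)

    perf, stats, agg = stage(
        "models", ["performance.csv", "train_stats.csv", "aggregates.csv"],
        compute_models, load_models)

    # -- novelty ------------------------------------------------------------
    def compute_novelty(files):
        rows = []
        y0, y1 = config.train_years
        for arch, esm in combos:
            spec = config.archetype(arch)
            mask = spec.domain_mask(envs[esm])
            covs = SDM_COVARIATES[arch]
            ref = reference_from_env(envs[esm], covs, np.arange(y0, y1 + 1), mask)
            pn = percent_novel(envs[esm], ref, covs, mask=mask)
            rows.append(pd.DataFrame({
                "archetype": arch, "esm": esm,
                "year": pn.index, "percent_novel": pn.values}))
        nov = pd.concat(rows, ignore_index=True)
        nov.to_csv(files[0], index=False)
        return nov

    novelty = stage("novelty", ["novelty.csv"], compute_novelty,
                    lambda files: pd.read_csv(files[0]))

    # -- uncertainty shares -------------------------------------------------
    def compute_shares(files):
        frames = []
        experiments = {"full": {m.member_id for m in _retained_members(config)}}
        if config.include_temperature_only:
            temp_ids = set()
            for m in _retained_members(config):
                cfgm = m.config
                if cfgm.parameterization == "E":
                    cfgm = replace(cfgm, parameterization="Temp")
                temp_ids.add(f"{m.archetype}:{m.esm_id}:{cfgm.sdm_id}")
            experiments["temp-only"] = temp_ids
        agg_ids = (agg["archetype"] + ":" + agg["esm"] + ":"
                   + agg["family"] + "_" + agg["parameterization"])
        for name, ids in experiments.items():
            sub = agg[agg_ids.isin(ids)]
            sh = shares_by_year(sub, smooth_window=config.smooth_window)
            sh.insert(0, "experiment", name)
            frames.append(sh)
        shares = pd.concat(frames, ignore_index=True)
        shares.to_csv(files[0], index=False)
        return shares

    shares = stage("shares", ["shares.csv"], compute_shares,
                   lambda files: pd.read_csv(files[0]))

    return ExperimentResult(
        config=config, performance=perf, train_stats=stats, novelty=novelty,
        aggregates=agg, shares=shares, stages_run=stages_run, out_dir=out_dir)


def _ensemble_mean_rho(result: ExperimentResult, archetype: str) -> pd.Series:
    """Annual test-period rho averaged over the retained members and ESMs."""
    cfg = result.config
    retained_ids = {f"{m.config.sdm_id}" for m in _retained_members(cfg)
                    if m.archetype == archetype}
    perf = result.performance
    sel = perf[(perf["archetype"] == archetype) & (perf["role"] == "test")
               & perf["sdm_id"].isin(retained_ids)]
    return sel.groupby("year")["rho"].mean()


def summarize(result: ExperimentResult, path=None) -> dict:
    """Headline report of the experiment (JSON-serializable).

    Collects: training-fit floor, in-sample occurrence AUC, early- vs
    late-century ensemble skill, end-of-century novelty, the novelty-skill
    correlation, and early/late uncertainty shares.
    """
    cfg = result.config
    retained = _retained_members(cfg)
    retained_ids = sorted({m.config.sdm_id for m in retained})
    stats = result.train_stats
    ret = stats[stats["parameterization"] != "Temp"
                ].loc[lambda d: d["sdm_id"].isin(retained_ids)]

    report: dict = {
        "ensemble_size": len(retained_ids),
        "min_train_rho": float(ret["rho_train"].min()),
        "min_train_auc": float(ret["auc_train"].min()),
        "archetypes": {},
        "shares": {},
    }

    e0, e1 = cfg.test_years[0], cfg.test_years[0] + 29
    l0, l1 = cfg.test_years[1] - 29, cfg.test_years[1]
    for arch in cfg.archetype_names:
        rho = _ensemble_mean_rho(result, arch)
        nov = (result.novelty[result.novelty["archetype"] == arch]
               .groupby("year")["percent_novel"].mean())
        smooth = cfg.smooth_window
        corr = running_mean(rho, smooth).corr(
            running_mean(nov.reindex(rho.index), smooth), method="spearman")
        report["archetypes"][arch] = {
            "rho_early": float(rho.loc[e0:e1].mean()),
            "rho_late": float(rho.loc[l0:l1].mean()),
            "final_year": int(nov.index.max()),
            "percent_novel_final": float(nov.loc[nov.index.max()]),
            "novelty_rho_correlation": float(corr),
        }

    sh = result.shares
    for exp in sh["experiment"].unique():
        sub = sh[(sh["experiment"] == exp) & (sh["region"] == "all")]
        rec = {}
        for arch, grp in sub.groupby("archetype"):
            early = grp[(grp["year"] >= e0) & (grp["year"] <= e1)]
            late = grp[(grp["year"] >= l0) & (grp["year"] <= l1)]
            rec[arch] = {
                "share_esm_early": float(early["share_esm"].mean()),
                "share_esm_late": float(late["share_esm"].mean()),
                "share_sdm_early": float(
                    (early["share_family"] + early["share_parameterization"]).mean()),
                "share_sdm_late": float(
                    (late["share_family"] + late["share_parameterization"]).mean()),
            }
        report["shares"][exp] = rec

    if path is not None:
        Path(path).write_text(json.dumps(report, indent=1))
    return report
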