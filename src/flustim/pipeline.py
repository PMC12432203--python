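"""End-to-end orchestration: simulate (optional) -> preprocess -> thresholds
-> switch table -> condition-effect models -> FDR contrasts -> e-field
associations, with every intermediate written as delimited text so any
downstream stage can resume from disk.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import efield as ef
from . import preprocessing as prep
from . import stats as st
from . import switching as sw
from .embeddings import load_embeddings
from .synthetic_data import SimulationConfig, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and cause."""


@dataclass
class RunConfig:
    """Pipeline run configuration.

    Exactly one of ``simulate`` (a :class:`SimulationConfig` or dict of its
    fields) and ``inputs`` (paths to trials/embeddings/efields/covariates
    tables) must be set.
    """

    outdir: Path
    seed: int = 0
    simulate: Optional[SimulationConfig] = None
    inputs: Optional[dict[str, str]] = None
    oov_policy: str = "skip"
    stages: tuple = ("simulate", "preprocess", "thresholds", "switches", "fit", "efield", "report")

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if (self.simulate is None) == (self.inputs is None):
            raise PipelineError("exactly one of 'simulate' and 'inputs' must be configured")
        if isinstance(self.simulate, dict):
            self.simulate = SimulationConfig(**self.simulate)
        if self.simulate is not None:
            self.simulate.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def input_path(self, key: str) -> Path:
        if self.inputs is not None:
            return Path(self.inputs[key])
        names = {
            "trials": "trials.tsv", "embeddings": "embeddings.vec",
            "efields": "efields.tsv", "covariates": "covariates.tsv",
            "category_members": "category_members.tsv",
        }
        return self.outdir / "data" / names[key]


def _read_members(path: Path) -> Optional[dict[str, list[str]]]:
    if not path.exists():
        return None
    df = pd.read_csv(path, sep="\t")
    return {str(c): g["word"].astype(str).tolist() for c, g in df.groupby("category")}


def infer_difficulty(item: pd.Series) -> pd.Series:
    """Category difficulty from the category label suffix
    (``..._easy`` / ``..._difficult``)."""
    s = item.astype(str)
    out = pd.Series("easy", index=item.index)
    out[s.str.contains("difficult")] = "difficult"
    return out


# ----------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig) -> None:
    if cfg.simulate is None:
        return
    ds = simulate_dataset(cfg.simulate)
    write_dataset(ds, cfg.outdir / "data")


def stage_preprocess(cfg: RunConfig) -> None:
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    trials_path = cfg.input_path("trials")
    if not trials_path.exists():
        raise PipelineError(f"preprocess: trials table not found: {trials_path}")
    trials = prep.read_trials(trials_path)
    members = _read_members(cfg.input_path("category_members"))
    trials = prep.code_fluency_accuracy(trials, category_members=members)
    fig = trials["task"] == "figural_fluency"
    if fig.any():
        trials.loc[fig, "correct"] = prep.code_figural_accuracy(trials[fig])
    trials.to_csv(out / "trials_coded.tsv", sep="\t", index=False)

    removal_rows = []
    for task in prep.TASKS:
        if not (trials["task"] == task).any():
            continue
        rts, flagged = prep.compute_rts(trials, task)
        kept, report = prep.outlier_filter(rts)
        kept.to_csv(out / f"rts_{task}.tsv", sep="\t", index=False)
        removal_rows.append({
            "task": task, "n_rts": report.n_total, "n_outliers": report.n_removed,
            "outlier_fraction": report.removed_fraction, "n_flagged": len(flagged),
        })
    pd.DataFrame(removal_rows).to_csv(out / "removal_report.tsv", sep="\t", index=False)

    cov_path = cfg.input_path("covariates")
    if cov_path.exists():
        cov = pd.read_csv(cov_path, sep="\t", dtype={"participant": str})
        prep.executive_composite(cov).to_csv(out / "covariates_z.tsv", sep="\t", index=False)


def stage_thresholds(cfg: RunConfig) -> None:
    out = cfg.outdir
    store = load_embeddings(cfg.input_path("embeddings"))
    trials = pd.read_csv(out / "trials_coded.tsv", sep="\t", dtype={"participant": str})
    members = _read_members(cfg.input_path("category_members"))
    thresholds = sw.compute_thresholds(trials, store, policy=cfg.oov_policy,
                                       word_pools=members)
    sw.write_thresholds(thresholds, out / "thresholds.tsv")


def stage_switches(cfg: RunConfig) -> None:
    out = cfg.outdir
    store = load_embeddings(cfg.input_path("embeddings"))
    trials = pd.read_csv(out / "trials_coded.tsv", sep="\t", dtype={"participant": str})
    thr = pd.read_csv(out / "thresholds.tsv", sep="\t")
    thresholds = {
        r.category: sw.CategoryThreshold(r.category, r.threshold, int(r.pool_size),
                                         int(r.pair_count))
        for r in thr.itertuples()
    }
    table = sw.switch_table(trials, store, thresholds, policy=cfg.oov_policy)
    table["difficulty"] = infer_difficulty(table["category"])
    table.to_csv(out / "switch_table.tsv", sep="\t", index=False)


def _merge_covariates(df: pd.DataFrame, out: Path) -> tuple[pd.DataFrame, list[str]]:
    cov_path = out / "covariates_z.tsv"
    if not cov_path.exists():
        return df, []
    cov = pd.read_csv(cov_path, sep="\t", dtype={"participant": str})
    return df.merge(cov[["participant", "executive_z", "stw_z"]], on="participant"), \
        ["executive_z", "stw_z"]


def stage_fit(cfg: RunConfig) -> None:
    out = cfg.outdir
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)

    def _write(name: str, fit: st.FitResult):
        frame = fit.summary_frame()
        cond = frame["term"].str.startswith("condition[") & np.isfinite(frame["p"])
        frame["p_adj"] = np.nan
        if cond.any():
            frame.loc[cond, "p_adj"] = st.fdr_bh(frame.loc[cond, "p"].to_numpy())
        frame.to_csv(models_dir / f"{name}_coefficients.tsv", sep="\t", index=False)
        st.condition_contrasts(fit).to_csv(
            models_dir / f"{name}_contrasts.tsv", sep="\t", index=False)

    # RT models per task
    for task, extra in (
        ("semantic_fluency", ["difficulty"]),
        ("figural_fluency", []),
        ("picture_naming", []),
    ):
        path = out / f"rts_{task}.tsv"
        if not path.exists():
            continue
        rts = pd.read_csv(path, sep="\t", dtype={"participant": str})
        if "difficulty" in extra:
            rts["difficulty"] = infer_difficulty(rts["item"])
        rts, covs = _merge_covariates(rts, out)
        spec = st.ModelSpec(outcome="log_rt", family="gaussian_on_log",
                            fixed_terms=["condition", "session"] + extra + covs)
        _write(f"rt_{task}", st.fit_rt_model(rts, spec))

    # accuracy models
    trials = pd.read_csv(out / "trials_coded.tsv", sep="\t", dtype={"participant": str})
    fig = trials[trials["task"] == "figural_fluency"].copy()
    if not fig.empty:
        fig["n_bars"] = fig["response"].astype(str).str.count(";") + 1.0
        fig, covs = _merge_covariates(fig, out)
        spec = st.ModelSpec(outcome="binary_correct", family="binomial_logit",
                            fixed_terms=["condition", "session", "n_bars"]
                            + [c for c in covs if c == "executive_z"])
        _write("accuracy_figural_fluency", st.fit_accuracy_model(fig, spec))
    nam = trials[trials["task"] == "picture_naming"].copy()
    if not nam.empty and nam["correct"].astype("boolean").nunique() > 1:
        nam, covs = _merge_covariates(nam, out)
        spec = st.ModelSpec(outcome="binary_correct", family="binomial_logit",
                            fixed_terms=["condition", "session"]
                            + [c for c in covs if c == "stw_z"])
        _write("accuracy_picture_naming", st.fit_accuracy_model(nam, spec))

    # correct-item counts for semantic fluency (NB)
    sem = trials[trials["task"] == "semantic_fluency"]
    if not sem.empty:
        counts = (
            sem.assign(correct=sem["correct"].astype("boolean").fillna(False).astype(int))
            .groupby(["participant", "session", "condition", "item"], as_index=False)
            ["correct"].sum().rename(columns={"correct": "n_correct"})
        )
        counts["difficulty"] = infer_difficulty(counts["item"])
        counts, covs = _merge_covariates(counts, out)
        spec = st.ModelSpec(outcome="count", family="negative_binomial_log",
                            fixed_terms=["condition", "session", "difficulty"] + covs)
        _write("ncorrect_semantic_fluency",
               st.fit_switch_count_model(counts, spec, count_col="n_correct"))

    # switch counts (NB)
    sw_path = out / "switch_table.tsv"
    if sw_path.exists():
        table = pd.read_csv(sw_path, sep="\t", dtype={"participant": str})
        spec = st.ModelSpec(outcome="count", family="negative_binomial_log",
                            fixed_terms=["condition", "session", "difficulty"])
        _write("switches_semantic_fluency", st.fit_switch_count_model(table, spec))


def stage_efield(cfg: RunConfig) -> None:
    out = cfg.outdir
    ef_path = cfg.input_path("efields")
    if not ef_path.exists():
        logger.info("no e-field table; skipping association stage")
        return
    efields = ef.read_efields(ef_path)

    rows = []
    for task in prep.TASKS:
        path = out / f"rts_{task}.tsv"
        if path.exists():
            rts = pd.read_csv(path, sep="\t", dtype={"participant": str})
            agg = rts.groupby(["participant", "condition"], as_index=False)["rt"].mean()
            for r in agg.itertuples():
                rows.append({"participant": r.participant, "condition": r.condition,
                             "task": task, "measure": "mean_rt", "value": r.rt})
    trials = pd.read_csv(out / "trials_coded.tsv", sep="\t", dtype={"participant": str})
    acc = (
        trials.assign(correct=trials["correct"].astype("boolean"))
        .dropna(subset=["correct"])
        .groupby(["participant", "condition", "task"], as_index=False)["correct"].mean()
    )
    for r in acc.itertuples():
        rows.append({"participant": r.participant, "condition": r.condition,
                     "task": r.task, "measure": "accuracy", "value": float(r.correct)})
    behavior = pd.DataFrame(rows)
    behavior.to_csv(out / "behavior_summaries.tsv", sep="\t", index=False)

    assoc = ef.correlate_efield_behavior(efields, behavior)
    assoc.to_csv(out / "efield_associations.tsv", sep="\t", index=False)

    # dual-site regressions: both targets' fields vs dual-session behavior
    dual_rows = []
    edual = efields[efields["condition"] == "dual"].pivot(
        index="participant", columns="target", values="e95_Vpm")
    if {"IFG", "preSMA"} <= set(edual.columns):
        beh_dual = behavior[behavior["condition"] == "dual"]
        for (task, measure), grp in beh_dual.groupby(["task", "measure"]):
            merged = edual.join(grp.set_index("participant")["value"]).dropna()
            if len(merged) < 4:
                continue
            try:
                res = ef.dual_site_regression(
                    merged["IFG"], merged["preSMA"], merged["value"])
            except ef.EFieldError as exc:
                logger.warning("dual-site (%s, %s): %s", task, measure, exc)
                continue
            for term in ("e_IFG", "e_preSMA"):
                dual_rows.append({
                    "task": task, "measure": measure, "term": term, "n": res.n,
                    "coefficient": res.coefficients[term],
                    "se": res.std_errors[term], "p": res.p_values[term],
                    "standardized_beta": res.standardized_betas[term],
                    "r_squared": res.r_squared,
                })
    pd.DataFrame(dual_rows).to_csv(out / "dual_site_regressions.tsv", sep="\t", index=False)


def stage_report(cfg: RunConfig) -> None:
    out = cfg.outdir
    lines = ["# Fluency pipeline run report", ""]

    def _table(path: Path, title: str, n: int = 12):
        if not path.exists():
            return
        df = pd.read_csv(path, sep="\t")
        lines.append(f"## {title}")
        lines.append("")
        lines.append(df.head(n).to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        if len(df) > n:
            lines.append(f"... ({len(df)} rows total)")
        lines.append("")

    _table(out / "removal_report.tsv", "RT extraction and outlier removal")
    _table(out / "thresholds.tsv", "Category switch thresholds")
    _table(out / "switch_table.tsv", "Switch table (head)")
    for f in sorted((out / "models").glob("*_contrasts.tsv")) if (out / "models").exists() else []:
        _table(f, f"Condition contrasts: {f.stem.replace('_contrasts', '')}")
    _table(out / "efield_associations.tsv", "E-field / behavior correlations")
    _table(out / "dual_site_regressions.tsv", "Dual-site regressions")
    (out / "report.md").write_text("\n".join(lines))


_STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "thresholds": stage_thresholds,
    "switches": stage_switches,
    "fit": stage_fit,
    "efield": stage_efield,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages in order; returns the report path.

    Identical config + seed produce byte-identical outputs.  A stage error
    aborts the run with the stage name and cause.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    for name in cfg.stages:
        if name == "simulate" and cfg.simulate is None:
            continue
        stage = _STAGES[name]
        logger.info("stage: %s", name)
        try:
            stage(cfg)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    return cfg.outdir / "report.md"
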