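"""End-to-end pipeline: cohort -> descriptives -> labels -> reduction ->
evaluation -> association -> report.

One YAML config drives the whole analysis.  Every stage writes plain CSV or
JSON files into the output directory before the next stage starts, so any
stage can be re-run or inspected in isolation; the final report collects
the table analogues (descriptives, frequencies, CV AUC comparison, final
ROC with optimal thresholds, pooled association) plus a reproducibility
manifest (seeds, config hash, package version).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import MICEConfig, run_association
from .cohort import (BIOMARKERS, CohortTable, correlation_structure,
                     descriptive_by_age, read_cohort, reproductive_frequency,
                     write_cohort)
from .evaluation import (compare_methods, cv_auc, final_roc, make_folds,
                         orient_scores)
from .exceptions import ConfigError, GCCScreenError
from .labels import CONDITIONS, CutoffSet, derive_labels, prevalence
from .reduction import (DEFAULT_ARCH, TrainConfig, fit_autoencoder, fit_pca,
                        pca_score, save_model)
from .synthetic import (SyntheticConfig, default_config,
                        default_frequency_bins, generate_cohort,
                        inject_missing)

REPORT_SECTIONS = ("descriptives", "frequencies", "correlation", "prevalence",
                   "cv_auc", "roc", "association", "manifest")


@dataclass
class PipelineConfig:
    """Validated pipeline settings (see ``validate_config``)."""

    outdir: str = "gcc_run"
    cohort_csv: str | None = None
    synthetic: dict[str, Any] | None = None
    cutoffs: dict[str, Any] = field(default_factory=dict)
    cutoff_quantile: float | None = None
    methods: tuple[str, ...] = ("autoencoder", "pca")
    arch: tuple[int, ...] = DEFAULT_ARCH
    train: dict[str, Any] = field(default_factory=dict)
    folds: int = 10
    seed: int | None = 0
    mice_m: int = 5
    mice_iterations: int = 10
    formats: tuple[str, ...] = ("json",)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("methods", "arch", "formats"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        # hash only semantically meaningful fields: where outputs land
        # (outdir) and which renderings are written (formats) do not
        # change any computed number
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k not in ("outdir", "formats")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def validate_config(cfg: PipelineConfig) -> list[str]:
    """Collect (not fail-fast) every configuration error; empty list means
    the config is runnable."""
    errors: list[str] = []
    if cfg.cohort_csv is not None and cfg.synthetic is not None:
        errors.append("ambiguous input: both cohort_csv and synthetic supplied")
    if cfg.cohort_csv is None and cfg.synthetic is None:
        errors.append("no input: supply cohort_csv or synthetic")
    if cfg.cohort_csv is not None and not Path(cfg.cohort_csv).exists():
        errors.append(f"cohort_csv not found: {cfg.cohort_csv}")
    if cfg.seed is None:
        errors.append("stage 'pipeline' has no seed")
    if cfg.folds < 2:
        errors.append("folds must be >= 2")
    if cfg.mice_m < 1:
        errors.append("mice_m must be >= 1")
    for m in cfg.methods:
        if m not in ("autoencoder", "pca"):
            errors.append(f"unknown reduction method {m!r}")
    for f in cfg.formats:
        if f not in ("json", "markdown"):
            errors.append(f"unknown report format {f!r}")
    if cfg.cutoff_quantile is not None and not (0 < cfg.cutoff_quantile < 1):
        errors.append("cutoff_quantile must lie in (0, 1)")
    return errors


@dataclass
class RunReport:
    """All result surfaces of one pipeline run, keyed by section."""

    sections: dict[str, Any]

    def require_complete(self) -> None:
        missing = [s for s in REPORT_SECTIONS if s not in self.sections]
        if missing:
            raise ConfigError(f"report missing section(s): {missing}")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def run_all(cfg: PipelineConfig, log=print) -> RunReport:
    """Execute every stage in order, writing stage outputs as it goes.

    Deterministic given the config: all stage seeds derive from
    ``cfg.seed``.  On stage failure the exception propagates with partial
    outputs preserved on disk.
    """
    errors = validate_config(cfg)
    if errors:
        raise ConfigError("invalid config: " + "; ".join(errors))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    sections: dict[str, Any] = {}

    # --- stage 1: cohort -------------------------------------------------
    if cfg.synthetic is not None:
        syn = default_config(**cfg.synthetic) if cfg.synthetic else default_config()
        if "seed" not in (cfg.synthetic or {}):
            syn = dataclasses.replace(syn, seed=cfg.seed)
        cohort, truth = generate_cohort(syn)
        cohort = inject_missing(cohort, syn)
        truth.to_csv(outdir / "truth.csv", index=False)
    else:
        cohort = read_cohort(cfg.cohort_csv)
    write_cohort(cohort, outdir / "cohort.csv")
    log(f"[cohort] n={len(cohort)} seed={cfg.seed} t={time.time()-t0:.1f}s")

    # --- stage 2: descriptives -------------------------------------------
    desc = descriptive_by_age(cohort)
    desc.group_stats.to_csv(outdir / "descriptives.csv")
    freq = reproductive_frequency(cohort, default_frequency_bins())
    corr = correlation_structure(cohort)
    corr.corr.to_csv(outdir / "correlation.csv")
    sections["descriptives"] = {"group_stats": desc.group_stats,
                                "tests": desc.tests, "n_total": desc.n_total}
    sections["frequencies"] = {"n_total": freq.n_total,
                               "factor_n": freq.factor_n,
                               "tables": freq.tables}
    sections["correlation"] = {"labels": corr.labels, "matrix": corr.corr,
                               "linkage": corr.linkage_matrix}
    log(f"[descriptives] biomarkers={len(BIOMARKERS)} t={time.time()-t0:.1f}s")

    # --- stage 3: labels --------------------------------------------------
    if cfg.cutoff_quantile is not None:
        cutoffs = CutoffSet.from_quantiles(cohort, q=cfg.cutoff_quantile)
    else:
        cutoffs = CutoffSet(**cfg.cutoffs)
    labels = derive_labels(cohort, cutoffs)
    labels.to_csv(outdir / "labels.csv", index=False)
    sections["prevalence"] = prevalence(labels)
    log(f"[labels] prevalence={sections['prevalence']} t={time.time()-t0:.1f}s")

    # --- stage 4+5: reduction and evaluation (complete biomarker rows) ----
    complete = cohort.biomarkers().notna().all(axis=1)
    sub = CohortTable(cohort.data.loc[complete].reset_index(drop=True))
    sub_labels = labels.loc[complete.to_numpy()].reset_index(drop=True)
    train_cfg = TrainConfig(**{"seed": cfg.seed, **cfg.train})
    folds = make_folds(len(sub), cfg.folds, seed=cfg.seed)
    estimates = {}
    for method in cfg.methods:
        estimates[method], _ = cv_auc(sub, sub_labels, method, folds,
                                      widths=cfg.arch, train_cfg=train_cfg)
    comparison = (compare_methods(estimates["autoencoder"], estimates["pca"])
                  if set(("autoencoder", "pca")) <= set(cfg.methods) else None)
    sections["cv_auc"] = {"estimates": estimates, "comparison": comparison,
                          "folds": cfg.folds}
    log(f"[evaluate] methods={cfg.methods} t={time.time()-t0:.1f}s")

    # final scores: refit on all complete rows with the better method
    X = sub.biomarkers().to_numpy(dtype=float)
    model = fit_autoencoder(X, cfg.arch, train_cfg, feature_names=list(BIOMARKERS))
    save_model(model, outdir / "model.json")
    scores, flipped = orient_scores(model.encode(X), sub.data["fpg"])
    pd.DataFrame({"subject_id": sub.data["subject_id"], "gcc": scores}
                 ).to_csv(outdir / "gcc.csv", index=False)
    roc = final_roc(sub, sub_labels, scores)
    sections["roc"] = {
        cond: {"auc": rc.auc, "optimal_threshold": rc.optimal_threshold,
               "optimal_tpr": rc.optimal_tpr, "optimal_fpr": rc.optimal_fpr}
        for cond, rc in roc.items()}
    pd.concat([
        pd.DataFrame({"condition": cond, "fpr": rc.fpr, "tpr": rc.tpr,
                      "threshold": rc.thresholds})
        for cond, rc in roc.items()]).to_csv(outdir / "roc_points.csv", index=False)
    log(f"[reduce] refit-all flipped={flipped} t={time.time()-t0:.1f}s")

    # --- stage 6: association --------------------------------------------
    assoc_df = sub.data.loc[:, ["age", "menarche_age", "menopause_age",
                                "repro_lifespan", "live_births", "abortions"]].copy()
    assoc_df["gcc"] = scores
    assoc = run_association(assoc_df, cfg=MICEConfig(
        m=cfg.mice_m, iterations=cfg.mice_iterations, seed=cfg.seed))
    sections["association"] = {"or_table": assoc.or_table, "note": assoc.note}
    assoc.or_table.to_csv(outdir / "association.csv", index=False)
    log(f"[associate] m={cfg.mice_m} t={time.time()-t0:.1f}s")

    sections["manifest"] = {
        "seed": cfg.seed, "config_hash": cfg.config_hash(),
        "version": __version__, "n_input": len(cohort),
        "n_complete_biomarkers": int(complete.sum()),
    }
    report = RunReport(sections)
    render_report(report, outdir, cfg.formats)
    return report


def render_report(report: RunReport, outdir, formats=("json",)) -> list[Path]:
    """Write the report; JSON always carries every number, markdown is a
    human-readable rendering of the same values."""
    report.require_complete()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for fmt in formats:
        if fmt == "json":
            path = outdir / "report.json"
            payload = _jsonable(report.sections)
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(payload, fh, indent=1)
        elif fmt == "markdown":
            path = outdir / "report.md"
            path.write_text(_render_markdown(report), encoding="utf-8")
        else:
            raise ConfigError(f"unknown report format {fmt!r}")
        written.append(path)
    return written


def _render_markdown(report: RunReport) -> str:
    s = report.sections
    lines = ["# GCC pipeline report", ""]
    man = s["manifest"]
    lines += [f"- seed: {man['seed']}", f"- config hash: {man['config_hash']}",
              f"- version: {man['version']}", ""]
    lines += ["## Condition prevalence", ""]
    for cond, p in s["prevalence"].items():
        lines.append(f"- {cond}: {p:.4f}")
    lines += ["", "## Cross-validated AUC", ""]
    for method, est in s["cv_auc"]["estimates"].items():
        for cond, e in est.items():
            lines.append(f"- {method} / {cond}: {e.mean:.3f} "
                         f"({e.ci_low:.3f}-{e.ci_high:.3f})")
    if s["cv_auc"]["comparison"]:
        lines += ["", "### Paired t-test (autoencoder - pca)", ""]
        for cond, cmpres in s["cv_auc"]["comparison"].items():
            lines.append(f"- {cond}: diff={cmpres.mean_difference:+.3f} "
                         f"p={cmpres.p_value:.2e}")
    lines += ["", "## Final ROC (refit on all rows)", ""]
    for cond, rc in s["roc"].items():
        lines.append(f"- {cond}: AUC={rc['auc']:.3f} "
                     f"optimal threshold={rc['optimal_threshold']:.4f}")
    lines += ["", "## Association (exponentiated linear coefficients)", ""]
    lines.append(s["association"]["or_table"].to_string(index=False))
    lines += ["", f"note: {s['association']['note']}", ""]
    return "\n".join(lines)
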