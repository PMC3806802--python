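"""End-to-end orchestration: simulate → quantify → metagene → wavefront →
features, with a reproducible run directory and a two-run comparison mode
(e.g. normal vs repair-deficient fibroblasts).

A run is driven by a YAML config naming the annotation, one read file per
condition (a ``control`` label is required; recovery conditions carry a
``t_effective`` in minutes), optional enhancer intervals, analysis
parameter overrides, an output directory and a seed.  Every run writes
its fully-resolved config back out, logs to console and file, and its
summary numbers are recomputable from the stage output tables alone.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .annotation import (read_enhancer_bed, read_gene_bed, read_gene_gtf,
                         read_reads_bed)
from .features import (erna_signal, feature_table, prompt_index,
                       readthrough_index)
from .metagene import build_profile, select_cohort
from .quantify import (AnalysisParams, classify_fold_changes,
                       quantify_condition, size_stratified_summary)
from .simulate import SimConfig, simulate_condition, synthesize_genes
from .wavefront import RecoveryWaveModel

logger = logging.getLogger("bruwave")

FLOAT_FMT = "%.6g"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class ConditionSpec:
    reads: str
    role: str = ""            # '', 'control', 'treated', 'recovery'
    t_effective: float | None = None


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    annotation: str
    conditions: dict[str, ConditionSpec]
    outdir: str
    enhancers: str | None = None
    params: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if "control" not in self.conditions:
            raise ValueError("control condition required")
        if len(self.conditions) < 2:
            raise ValueError("need a control and at least one other condition")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        conds = {}
        for label, spec in raw["conditions"].items():
            if isinstance(spec, str):
                spec = {"reads": spec}
            conds[label] = ConditionSpec(
                reads=spec["reads"], role=spec.get("role", ""),
                t_effective=spec.get("t_effective"))
        params = AnalysisParams(**(raw.get("params") or {}))
        return cls(annotation=raw["annotation"], conditions=conds,
                   outdir=raw.get("outdir", "bruwave_run"),
                   enhancers=raw.get("enhancers"), params=params,
                   seed=int(raw.get("seed", 0)))

    def resolved(self) -> dict:
        d = {"annotation": self.annotation,
             "conditions": {k: {kk: vv for kk, vv in asdict(v).items()
                                if vv not in ("", None)}
                            for k, v in self.conditions.items()},
             "enhancers": self.enhancers,
             "params": asdict(self.params),
             "outdir": str(self.outdir), "seed": self.seed}
        return d


def _treated_label(config: RunConfig) -> str | None:
    for label, spec in config.conditions.items():
        if spec.role == "treated":
            return label
    if "cpt0" in config.conditions:
        return "cpt0"
    for label, spec in config.conditions.items():
        if label != "control" and spec.t_effective is None:
            return label
    return None


def _file_md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _round6(x):
    if isinstance(x, dict):
        return {k: _round6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round6(v) for v in x]
    if isinstance(x, (float, np.floating)):
        return float(f"{float(x):.6g}")
    if isinstance(x, (int, np.integer)):
        return int(x)
    return x


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write the report bundle, return it as a dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    warn_counter = _WarningCounter()
    logger.addFilter(warn_counter)
    params = config.params
    params.validate()
    summary: dict = {"seed": config.seed, "params": asdict(params)}
    bundle: dict = {"summary": summary, "outdir": outdir}
    try:
        # --- load -----------------------------------------------------
        stage = "load"
        summary["annotation_md5"] = _file_md5(config.annotation)
        ann = Path(config.annotation)
        genes = read_gene_gtf(ann) if ann.suffix.lower() == ".gtf" \
            else read_gene_bed(ann)
        reads = {label: read_reads_bed(spec.reads)
                 for label, spec in config.conditions.items()}

        # --- quantify -------------------------------------------------
        stage = "quantify"
        expr = {label: quantify_condition(genes, r, label)
                for label, r in reads.items()}
        for label, df in expr.items():
            df.to_csv(outdir / f"expression_{label}.tsv", sep="\t",
                      index=False, float_format=FLOAT_FMT)
        treated = _treated_label(config)
        if treated is not None:
            fc, fc_summary = classify_fold_changes(expr["control"],
                                                   expr[treated], params)
            fc.to_csv(outdir / "fold_changes.tsv", sep="\t", index=False,
                      float_format=FLOAT_FMT)
            strata, rho, pval = size_stratified_summary(fc)
            strata.to_csv(outdir / "size_strata.tsv", sep="\t", index=False,
                          float_format=FLOAT_FMT)
            summary["fold_change"] = dict(fc_summary, treated_label=treated,
                                          spearman_rho=rho,
                                          spearman_p=pval)

        # --- metagene -------------------------------------------------
        stage = "metagene"
        cohort = select_cohort(expr["control"], genes, params)
        summary["metagene"] = {"n_cohort_genes": len(cohort)}
        for label, r in reads.items():
            prof = build_profile(cohort, r, len(r), params, condition=label)
            prof.to_frame().to_csv(outdir / f"metagene_{label}.tsv", sep="\t",
                                   index=False, float_format=FLOAT_FMT)
            bundle.setdefault("profiles", {})[label] = prof

        # --- wavefront ------------------------------------------------
        stage = "wavefront"
        recovery = {float(spec.t_effective): reads[label]
                    for label, spec in config.conditions.items()
                    if spec.t_effective is not None}
        if recovery:
            model = RecoveryWaveModel(genes, reads["control"], recovery,
                                      params=params, cohort=cohort)
            res = model.fit(seed=config.seed)
            res.fronts_frame().to_csv(outdir / "fronts.tsv", sep="\t",
                                      index=False, float_format=FLOAT_FMT)
            res.per_gene_fronts().to_csv(outdir / "per_gene_fronts.tsv",
                                         sep="\t", index=False,
                                         float_format=FLOAT_FMT)
            summary["rate"] = {
                "rate_kb_per_min": res.rate_kb_per_min,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "per_timepoint": {f"{t:g}": v for t, v in
                                  res.per_timepoint_rates.items()},
                "n_bootstrap": res.rate.n_bootstrap,
            }
            bundle["wave_results"] = res

        # --- features -------------------------------------------------
        stage = "features"
        if treated is not None:
            from .features import ReadIndex
            lib_c, lib_t = len(reads["control"]), len(reads[treated])
            idx_c = ReadIndex(reads["control"], lib_c)
            idx_t = ReadIndex(reads[treated], lib_t)
            recs = []
            for g in genes:
                recs.append(readthrough_index(g, idx_c, idx_t, lib_c, lib_t,
                                              params, other_genes=genes))
                recs.append(prompt_index(g, idx_c, idx_t, lib_c, lib_t,
                                         params))
            if config.enhancers:
                enh = read_enhancer_bed(config.enhancers)
                recs.extend(erna_signal(enh, idx_c, idx_t, lib_c, lib_t,
                                        params, genes=genes))
            ft = feature_table(recs)
            ft.to_csv(outdir / "features.tsv", sep="\t", index=False,
                      float_format=FLOAT_FMT)
            summary["features"] = {
                f"median_delta_{kind}": float(sub["delta"].median())
                for kind, sub in ft.groupby("kind")}

        stage = "report"
        summary["n_warnings"] = warn_counter.count
        summary_r = _round6(summary)
        with open(outdir / "summary.yaml", "w") as fh:
            yaml.safe_dump(summary_r, fh, sort_keys=True)
        with open(outdir / "resolved_config.yaml", "w") as fh:
            yaml.safe_dump(config.resolved(), fh, sort_keys=True)
        bundle["summary"] = summary_r
        return bundle
    except Exception as exc:  # propagate with the failing stage's name
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
    finally:
        logger.removeHandler(handler)
        logger.removeFilter(warn_counter)
        handler.close()


class _WarningCounter(logging.Filter):
    def __init__(self):
        super().__init__()
        self.count = 0

    def filter(self, record):
        if record.levelno >= logging.WARNING:
            self.count += 1
        return True


def _load_summary(run) -> dict:
    if isinstance(run, dict):
        return run["summary"]
    with open(Path(run) / "summary.yaml") as fh:
        return yaml.safe_load(fh)


def compare_runs(run_a, run_b) -> dict:
    """Side-by-side comparison of two completed runs.

    Both runs must have used the same annotation and parameters.  Rates
    are flagged 'similar' when the bootstrap CIs overlap; genes whose
    regulation class differs between the runs are listed.
    """
    sa, sb = _load_summary(run_a), _load_summary(run_b)
    if sa["annotation_md5"] != sb["annotation_md5"]:
        raise ValueError("annotation mismatch between runs")
    if sa["params"] != sb["params"]:
        raise ValueError("param mismatch between runs")
    out: dict = {}
    if "rate" in sa and "rate" in sb:
        ra, rb = sa["rate"], sb["rate"]
        overlap = (ra["ci_low"] <= rb["ci_high"]
                   and rb["ci_low"] <= ra["ci_high"])
        out["rate_a"] = ra
        out["rate_b"] = rb
        out["rates_flag"] = "similar" if overlap else "different"
    if "fold_change" in sa and "fold_change" in sb:
        out["classes_a"] = {k: sa["fold_change"][k]
                            for k in ("n_up", "n_down", "n_unchanged")}
        out["classes_b"] = {k: sb["fold_change"][k]
                            for k in ("n_up", "n_down", "n_unchanged")}

    def _fc_table(run):
        path = (run["outdir"] if isinstance(run, dict) else Path(run))
        p = Path(path) / "fold_changes.tsv"
        return pd.read_csv(p, sep="\t") if p.exists() else None

    fa, fb = _fc_table(run_a), _fc_table(run_b)
    if fa is not None and fb is not None:
        m = fa.merge(fb, on="gene_id", suffixes=("_a", "_b"))
        disc = m[m["cls_a"] != m["cls_b"]]
        out["n_discordant"] = int(len(disc))
        out["discordant_genes"] = disc["gene_id"].tolist()
    return out


# ---------------------------------------------------------------------------
# simulation studies
# ---------------------------------------------------------------------------

def rate_recovery_study(v_recovery: float = 1200.0, seed: int = 1,
                        n_genes: int = 100,
                        length_range: tuple[float, float] = (150_000, 300_000),
                        depth: int = 1_000_000, n_bootstrap: int = 100,
                        params: AnalysisParams | None = None,
                        sim_config: SimConfig | None = None):
    """Parameter-recovery experiment for the wave-front rate estimator.

    Simulates control plus two recovery labelings over a long-gene
    cohort at the given post-washout elongation rate, then estimates the
    rate back from the reads via the metagene + wavefront stages.
    Returns the fitted :class:`~bruwave.wavefront.RecoveryWaveResults`.
    """
    from dataclasses import replace
    rng = np.random.default_rng(seed)
    genes = synthesize_genes(
        n_genes, {"kind": "log_uniform", "low": length_range[0],
                  "high": length_range[1]}, rng)
    base = sim_config or SimConfig()
    cfg = replace(base, genes=genes, v_recovery=v_recovery, depth=depth,
                  seed=seed)
    reads = {}
    for cond in ("control", "rec15", "rec30"):
        reads[cond], _ = simulate_condition(cfg, cond)
    model = RecoveryWaveModel(
        genes, reads["control"],
        {cfg.t_label: reads["rec15"], 2 * cfg.t_label: reads["rec30"]},
        params=params)
    return model.fit(n_bootstrap=n_bootstrap, seed=seed)
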