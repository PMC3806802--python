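"""Gene-level nascent-RNA quantification: counts, RPKM, fold-change classes.

Relative synthesis rates are read densities: reads assigned to a gene
(by read midpoint, same strand) divided by the intron-inclusive gene
length in kb and by the library size in millions — "reads per thousand
base pairs per million reads" (RPKM).  Fold changes between a treated
and a control condition use a pseudocount-stabilized RPKM ratio and a
symmetric 2-fold cut-off, and are summarized against gene size, where
elongation inhibitors produce a characteristic dichotomy: long genes
lose signal, short genes gain it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel

logger = logging.getLogger("bruwave")


@dataclass
class AnalysisParams:
    """Tunable thresholds shared across the analysis stages.

    ``expr_min_rpkm`` and ``metagene_min_length`` implement the long-gene
    cohort rule (control RPKM > 1, length >= 100 kb); ``fc_threshold`` the
    2-fold regulation classes.  ``epsilon`` stabilizes RPKM-scale ratios;
    ``epsilon_index`` stabilizes the dimensionless feature indices, which
    live on a much smaller scale.  ``front_alpha`` is the
    recovery/control ratio below which a metagene bin counts as
    unrecovered when detecting the wave front.
    """

    epsilon: float = 0.25            # RPKM pseudocount
    fc_threshold: float = 2.0        # regulation class cut-off (fold)
    expr_min_rpkm: float = 1.0       # expression floor for cohort selection
    metagene_min_length: int = 100_000   # bp
    bin_width: int = 1000            # bp
    max_extent: int = 100_000        # bp of TSS-aligned profile
    front_alpha: float = 0.5         # ratio threshold for front detection
    rt_window: int = 10_000          # bp downstream of TES
    prompt_window: int = 5_000       # bp upstream of TSS
    epsilon_index: float = 0.01      # pseudocount on dimensionless indices
    n_bootstrap: int = 1000

    def validate(self) -> None:
        for name in ("epsilon", "fc_threshold", "expr_min_rpkm",
                     "metagene_min_length", "bin_width", "max_extent",
                     "rt_window", "prompt_window", "epsilon_index",
                     "n_bootstrap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"AnalysisParams.{name} must be > 0")
        if not 0.0 < self.front_alpha < 1.0:
            raise ValueError("front_alpha must lie in (0, 1)")


def _sorted_midpoints(reads: pd.DataFrame) -> dict[tuple[str, str], np.ndarray]:
    """Sorted read-midpoint arrays keyed by (chrom, strand)."""
    out: dict[tuple[str, str], np.ndarray] = {}
    if reads.empty:
        return out
    mids = (reads["start"].to_numpy() + reads["end"].to_numpy()) / 2.0
    key = pd.MultiIndex.from_arrays([reads["chrom"], reads["strand"]])
    frame = pd.DataFrame({"mid": mids}, index=key)
    for k, grp in frame.groupby(level=[0, 1], sort=False):
        out[k] = np.sort(grp["mid"].to_numpy())
    return out


def count_reads(genes: Sequence[GeneModel], reads: pd.DataFrame
                ) -> tuple[pd.Series, int]:
    """Count reads per gene (same strand, read midpoint inside the span).

    Returns (counts indexed by gene_id, library size).  The library size
    is the total number of input reads, assigned or not — densities are
    "per million reads", not per million assigned reads.  Overlapping
    same-strand genes each count a shared read independently.
    """
    if len(genes) == 0:
        raise ValueError("empty gene list")
    grouped = _sorted_midpoints(reads)
    counts = np.zeros(len(genes), dtype=np.int64)
    for i, g in enumerate(genes):
        mids = grouped.get((g.chrom, g.strand))
        if mids is None:
            continue
        counts[i] = (np.searchsorted(mids, g.end, "left")
                     - np.searchsorted(mids, g.start, "left"))
    return pd.Series(counts, index=[g.gene_id for g in genes]), int(len(reads))


def rpkm(count, length_bp, library_size):
    """Reads per kb of (genomic) gene length per million library reads."""
    length_bp = np.asarray(length_bp, dtype=float)
    if np.any(length_bp < 1):
        raise ValueError("length_bp must be >= 1")
    if library_size < 1:
        raise ValueError("library_size must be >= 1 (zero library)")
    return np.asarray(count, dtype=float) / (length_bp / 1000.0) \
        / (library_size / 1e6)


def quantify_condition(genes: Sequence[GeneModel], reads: pd.DataFrame,
                       condition: str) -> pd.DataFrame:
    """Per-gene expression table for one condition (one row per gene)."""
    counts, lib = count_reads(genes, reads)
    lengths = np.array([g.length for g in genes], dtype=np.int64)
    dens = rpkm(counts.to_numpy(), lengths, max(lib, 1)) if lib >= 1 else \
        np.zeros(len(genes))
    return pd.DataFrame({
        "gene_id": counts.index,
        "condition": condition,
        "read_count": counts.to_numpy(),
        "rpkm": dens,
        "length_bp": lengths,
        "library_size": lib,
    })


def classify_fold_changes(control: pd.DataFrame, treated: pd.DataFrame,
                          params: AnalysisParams | None = None
                          ) -> tuple[pd.DataFrame, dict]:
    """Classify genes up/down/unchanged by pseudocount-stabilized RPKM ratio.

    fold = (rpkm_treated + eps) / (rpkm_control + eps); up iff
    fold >= threshold, down iff fold <= 1/threshold.  Genes present in
    only one condition are excluded and logged.  The summary reports the
    class sizes and median gene lengths per class.
    """
    params = params or AnalysisParams()
    eps, thr = params.epsilon, params.fc_threshold
    c = control.set_index("gene_id")
    t = treated.set_index("gene_id")
    shared = c.index.intersection(t.index)
    dropped = len(c.index.union(t.index)) - len(shared)
    if dropped:
        logger.warning("classify_fold_changes: %d genes present in only one "
                       "condition were excluded", dropped)
    rc = c.loc[shared, "rpkm"].to_numpy()
    rt = t.loc[shared, "rpkm"].to_numpy()
    fold = (rt + eps) / (rc + eps)
    cls = np.where(fold >= thr, "up", np.where(fold <= 1.0 / thr,
                                               "down", "unchanged"))
    out = pd.DataFrame({
        "gene_id": shared,
        "rpkm_control": rc,
        "rpkm_treated": rt,
        "fold": fold,
        "log2_fc": np.log2(fold),
        "cls": cls,
        "length_bp": c.loc[shared, "length_bp"].to_numpy(),
        "expressed": rc >= params.expr_min_rpkm,
    })
    summary = {"n_excluded": dropped}
    for name in ("up", "down", "unchanged"):
        sub = out[out["cls"] == name]
        summary[f"n_{name}"] = int(len(sub))
        summary[f"median_length_{name}"] = (
            float(sub["length_bp"].median()) if len(sub) else float("nan"))
    return out, summary


def size_stratified_summary(fold_changes: pd.DataFrame, n_bins: int = 10
                            ) -> tuple[pd.DataFrame, float, float]:
    """Median log2 fold change per gene-length quantile bin, plus trend.

    Restricted to expressed genes (control RPKM above the floor): ratios
    of near-zero densities are unstable.  Returns (table, Spearman rho of
    log2_fc vs log10 length, p-value); rho < 0 is the signature of
    preferential long-gene inhibition.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    fc = fold_changes[fold_changes["expressed"]] \
        if "expressed" in fold_changes else fold_changes
    if len(fc) < n_bins:
        raise ValueError(f"need at least {n_bins} (expressed) genes")
    lengths = fc["length_bp"].to_numpy(dtype=float)
    if np.unique(lengths).size == 1:
        logger.warning("size_stratified_summary: all gene lengths equal; "
                       "falling back to a single bin")
        labels = pd.Series(np.zeros(len(fc), dtype=int), index=fc.index)
    else:
        labels = pd.qcut(lengths, q=n_bins, labels=False, duplicates="drop")
        labels = pd.Series(labels, index=fc.index)
    table = fc.assign(size_bin=labels.to_numpy()).groupby("size_bin").agg(
        n_genes=("gene_id", "size"),
        median_length_bp=("length_bp", "median"),
        median_log2_fc=("log2_fc", "median"),
    ).reset_index()
    if np.unique(lengths).size == 1:
        rho, pval = float("nan"), float("nan")
    else:
        rho, pval = stats.spearmanr(fc["log2_fc"], np.log10(lengths))
    return table, float(rho), float(pval)
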