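"""Readthrough, divergent-upstream (PROMPT) and enhancer-RNA indices.

Each index is a dimensionless window-over-body density ratio computed
per condition, with the treated/control change reported as ``delta``:

* readthrough — sense-strand density in ``[TES, TES + rt_window)``
  relative to the gene-body sense density; elevated when termination
  fails and polymerases continue past the poly(A) site.
* PROMPT — antisense density in ``[TSS - prompt_window, TSS)`` relative
  to the gene-body sense density; divergent upstream transcription.
* eRNA — both-strand per-kb-per-million density inside an enhancer
  interval; enhancers have no body, so the raw density is the index.

Densities are per-kb-per-million, so all indices are invariant (in
expectation) under uniform read subsampling.  The body density in an
index denominator is floored at the RPKM pseudocount; the treated /
control delta uses a separate, much smaller pseudocount sized for
dimensionless indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import EnhancerInterval, GeneModel
from .quantify import AnalysisParams

logger = logging.getLogger("bruwave")


@dataclass
class FeatureIndexRecord:
    """Window signal for one gene/enhancer, per condition pair."""

    feature_id: str
    kind: str            # 'readthrough' | 'prompt' | 'erna'
    signal_control: float
    signal_treated: float
    index_control: float
    index_treated: float
    delta: float
    flag: str = ""

    def __post_init__(self) -> None:
        if min(self.signal_control, self.signal_treated) < 0:
            raise ValueError("signals must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")


class ReadIndex:
    """Sorted read-midpoint index for fast repeated window queries.

    All feature operations accept either a raw reads frame or a
    pre-built index; build one index per condition when scoring many
    features.
    """

    def __init__(self, reads: pd.DataFrame, library_size: int | None = None):
        from .quantify import _sorted_midpoints
        self.library_size = int(library_size if library_size is not None
                                else len(reads))
        self._by_strand = _sorted_midpoints(reads)
        pooled: dict[str, list[np.ndarray]] = {}
        for (chrom, _), mids in self._by_strand.items():
            pooled.setdefault(chrom, []).append(mids)
        self._pooled = {c: np.sort(np.concatenate(a))
                        for c, a in pooled.items()}

    def count(self, chrom: str, start: int, end: int,
              strand: str | None = None) -> int:
        mids = self._pooled.get(chrom) if strand is None \
            else self._by_strand.get((chrom, strand))
        if mids is None:
            return 0
        return int(np.searchsorted(mids, end, "left")
                   - np.searchsorted(mids, start, "left"))

    def density(self, chrom: str, start: int, end: int,
                strand: str | None = None) -> float:
        if end <= start:
            raise ValueError("empty window")
        return self.count(chrom, start, end, strand) \
            / ((end - start) / 1000.0) / (max(self.library_size, 1) / 1e6)


def as_read_index(reads, library_size: int | None = None) -> ReadIndex:
    if isinstance(reads, ReadIndex):
        return reads
    return ReadIndex(reads, library_size)


def window_density(reads, chrom: str, start: int, end: int,
                   library_size: int, strand: str | None = None) -> float:
    """Per-kb-per-million midpoint density in [start, end); both strands
    when ``strand`` is None."""
    return as_read_index(reads, library_size).density(chrom, start, end,
                                                      strand)


def _delta(idx_t: float, idx_c: float, eps_idx: float) -> float:
    return (idx_t + eps_idx) / (idx_c + eps_idx)


def _body_index(win_dens: float, body_dens: float, eps: float) -> float:
    # floor the body density at the pseudocount; keep the window density raw
    return win_dens / max(body_dens, eps)


def readthrough_index(gene: GeneModel,
                      control: pd.DataFrame, treated: pd.DataFrame,
                      lib_control: int, lib_treated: int,
                      params: AnalysisParams | None = None,
                      other_genes: Sequence[GeneModel] = ()
                      ) -> FeatureIndexRecord:
    """Sense-strand density past the TES relative to the gene body."""
    params = params or AnalysisParams()
    rt = params.rt_window
    if gene.strand == "+":
        w0, w1 = gene.tes, gene.tes + rt
    else:
        w0, w1 = gene.tes - rt, gene.tes
    if w0 < 0:
        raise ValueError(f"readthrough window extends past contig start "
                         f"for {gene.gene_id}")
    flag = ""
    for og in other_genes:
        if (og.gene_id != gene.gene_id and og.chrom == gene.chrom
                and og.strand == gene.strand
                and og.start < w1 and og.end > w0):
            flag = f"window_overlaps:{og.gene_id}"
            logger.warning("readthrough window of %s overlaps %s",
                           gene.gene_id, og.gene_id)
            break
    vals = {}
    for name, reads, lib in (("control", control, lib_control),
                             ("treated", treated, lib_treated)):
        idx = as_read_index(reads, lib)
        win = idx.density(gene.chrom, w0, w1, gene.strand)
        body = idx.density(gene.chrom, gene.start, gene.end, gene.strand)
        vals[name] = (win, _body_index(win, body, params.epsilon))
    return FeatureIndexRecord(
        gene.gene_id, "readthrough",
        vals["control"][0], vals["treated"][0],
        vals["control"][1], vals["treated"][1],
        _delta(vals["treated"][1], vals["control"][1], params.epsilon_index),
        flag=flag)


def prompt_index(gene: GeneModel,
                 control: pd.DataFrame, treated: pd.DataFrame,
                 lib_control: int, lib_treated: int,
                 params: AnalysisParams | None = None) -> FeatureIndexRecord:
    """Antisense density upstream of the TSS relative to the sense body."""
    params = params or AnalysisParams()
    pw = params.prompt_window
    anti = "-" if gene.strand == "+" else "+"
    if gene.strand == "+":
        w0, w1 = gene.tss - pw, gene.tss
    else:
        w0, w1 = gene.tss, gene.tss + pw
    if w0 < 0:
        raise ValueError(f"prompt window extends past contig start "
                         f"for {gene.gene_id}")
    vals = {}
    for name, reads, lib in (("control", control, lib_control),
                             ("treated", treated, lib_treated)):
        idx = as_read_index(reads, lib)
        win = idx.density(gene.chrom, w0, w1, anti)
        body = idx.density(gene.chrom, gene.start, gene.end, gene.strand)
        vals[name] = (win, _body_index(win, body, params.epsilon))
    return FeatureIndexRecord(
        gene.gene_id, "prompt",
        vals["control"][0], vals["treated"][0],
        vals["control"][1], vals["treated"][1],
        _delta(vals["treated"][1], vals["control"][1], params.epsilon_index),
    )


def erna_signal(enhancers: Sequence[EnhancerInterval],
                control: pd.DataFrame, treated: pd.DataFrame,
                lib_control: int, lib_treated: int,
                params: AnalysisParams | None = None,
                genes: Sequence[GeneModel] = ()) -> list[FeatureIndexRecord]:
    """Both-strand density inside each enhancer interval, per condition.

    Enhancer RNA is bidirectional, so both strands pool; there is no
    body denominator — the per-kb-per-million density itself is the
    index, and delta is its pseudocount-stabilized treated/control
    ratio (the RPKM-scale pseudocount, since densities are RPKM-like).
    """
    params = params or AnalysisParams()
    idx_c = as_read_index(control, lib_control)
    idx_t = as_read_index(treated, lib_treated)
    out = []
    for enh in enhancers:
        flag = ""
        for g in genes:
            if g.chrom == enh.chrom and g.start < enh.end and g.end > enh.start:
                flag = f"overlaps_gene:{g.gene_id}"
                logger.warning("enhancer %s overlaps gene %s", enh.id,
                               g.gene_id)
                break
        d_c = idx_c.density(enh.chrom, enh.start, enh.end, strand=None)
        d_t = idx_t.density(enh.chrom, enh.start, enh.end, strand=None)
        out.append(FeatureIndexRecord(
            enh.id, "erna", d_c, d_t, d_c, d_t,
            (d_t + params.epsilon) / (d_c + params.epsilon), flag=flag))
    return out


def feature_table(records: Sequence[FeatureIndexRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "feature_id": r.feature_id, "kind": r.kind,
        "signal_control": r.signal_control, "signal_treated": r.signal_treated,
        "index_control": r.index_control, "index_treated": r.index_treated,
        "delta": r.delta, "flag": r.flag} for r in records])
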