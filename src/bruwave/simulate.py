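"""Mechanistic simulator of nascent transcription under Top1 trapping.

The generator emulates a bromouridine pulse-labeling (Bru-Seq) experiment
around a 45-min camptothecin exposure.  Four conditions are produced:

``control``
    Steady-state transcription; polymerases initiate at ``k_init`` per
    minute, elongate at ``v_elong`` and terminate at the TES.  Labeling
    lasts 30 min (twice the drug-arm label window).
``cpt0``
    Drug present for the full 45 min.  Camptothecin traps topoisomerase I
    covalently on DNA; trap sites are a homogeneous spatial Poisson
    process (rate ``trap_density`` per bp) fixed per gene — lesions sit on
    the DNA and are shared by every polymerase of that gene.  A polymerase
    elongates until the first trap downstream of the promoter (or its
    terminator) and then stalls permanently.  Labeling covers the final
    ``t_label`` minutes of treatment.  Divergent upstream (PROMPT)
    initiation is multiplied by ``prompt_rate_fold``; short genes that
    escape internal blockage may read through the TES.
``rec15`` / ``rec30``
    Drug washed out at time zero; traps are cleared for *new*
    polymerases, but no polymerase engaged before washout ever labels
    again — blocked complexes are discarded, not recycled.  Fresh
    initiations elongate at the reduced rate ``v_recovery``.  ``rec15``
    labels minutes [0, t_label]; ``rec30`` labels [t_label, 2·t_label].

Reads are sampled by Poisson thinning uniformly along the labeled spans
to an expected per-condition depth, emitted in genomic coordinates on
the transcript's strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import GeneModel, write_gene_bed, write_reads_bed

CONDITIONS = ("control", "cpt0", "rec15", "rec30")

TRUTH_COLUMNS = (
    "gene_id", "condition", "kind", "init_time", "stall_pos",
    "span_start", "span_end",
)


@dataclass
class SimConfig:
    """Parameters of the elongation/trapping simulator.

    Rates are per minute, positions in bp on the gene axis (0 = TSS,
    increasing 5'→3').  Defaults are the study conditions: 45 min drug
    exposure with the final 15 min labeled, ~2 kb/min baseline elongation
    and ~1.2 kb/min after washout, and a trap density of 0.25/kb so a
    100-kb gene is almost surely blocked internally while a 5-kb gene
    escapes with probability exp(-1.25) ≈ 0.29.
    """

    genes: list[GeneModel] = field(default_factory=list)
    k_init: float = 1.0            # initiations / min / gene
    v_elong: float = 2000.0        # bp / min
    v_recovery: float = 1200.0     # bp / min after washout
    trap_density: float = 2.5e-4   # traps / bp under drug (0.25 / kb)
    t_treat: float = 45.0          # min of drug before labeling ends
    t_label: float = 15.0          # min labeling window
    readthrough_prob: float = 0.5  # P(continue past TES | short unblocked gene)
    readthrough_extent: float = 5000.0  # bp past TES (cap; mean of truncated draw)
    short_gene_max: float = 20000.0     # genes up to this length may read through
    prompt_rate_fold: float = 5.0  # drug fold-increase of divergent initiation
    prompt_basal_frac: float = 0.1  # basal PROMPT initiation as fraction of k_init
    prompt_extent: float = 1000.0  # bp of antisense PROMPT transcript
    init_boost: float = 1.0        # optional initiation enhancement under drug
    read_length: int = 50          # bp
    depth: int = 200_000           # expected reads per condition
    seed: int = 0

    @property
    def t_label_control(self) -> float:
        """Control labeling window (min): twice the drug-arm window."""
        return 2.0 * self.t_label

    def validate(self) -> None:
        for name in ("k_init", "v_elong", "v_recovery", "t_treat", "t_label"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimConfig.{name} must be > 0")
        if not 0.0 <= self.readthrough_prob <= 1.0:
            raise ValueError("readthrough_prob must lie in [0, 1]")
        if self.trap_density < 0:
            raise ValueError("trap_density must be >= 0")
        if self.v_recovery > self.v_elong:
            raise ValueError("v_recovery must not exceed v_elong")


@dataclass(frozen=True)
class PolymeraseTruth:
    """Ground truth for one (labeled or arrested) polymerase.

    ``labeled_span`` is a half-open [a, b) interval on the gene axis;
    PROMPT transcripts occupy the negative side of that axis.  Arrested
    polymerases in recovery conditions carry an empty span — blocked
    complexes never synthesize again.
    """

    gene_id: str
    condition: str
    kind: str                # 'sense' | 'prompt'
    init_time: float         # min, on the condition clock
    stall_pos: float | None  # bp from TSS, or None
    labeled_span: tuple[float, float] | None


def place_traps(gene: GeneModel, lam: float, rng: np.random.Generator,
                extent: float = 0.0) -> np.ndarray:
    """Place Top1 trap sites on one gene: homogeneous Poisson process.

    Positions are bp from the TSS on ``[0, length + extent)``, sorted.
    Traps are fixed per gene per condition — they live on the DNA and are
    shared by all polymerases of that gene.
    """
    if lam < 0:
        raise ValueError("trap density must be >= 0")
    span = gene.length + extent
    n = rng.poisson(lam * span)
    if n == 0:
        return np.empty(0)
    return np.sort(rng.uniform(0.0, span, size=n))


def _condition_rng(config: SimConfig, condition: str) -> np.random.Generator:
    # one stream per condition: seed + condition index (spec'd layout)
    return np.random.default_rng(config.seed + CONDITIONS.index(condition))


def _gene_truth_control(cfg: SimConfig, gene: GeneModel, rng, t_win: float):
    """Steady-state sense spans for one gene over a label window [0, t_win]."""
    L = float(gene.length)
    v = cfg.v_elong
    lookback = L / v  # a polymerase covering the TES at t=0 initiated at -L/v
    n = rng.poisson(cfg.k_init * (lookback + t_win))
    tau = rng.uniform(-lookback, t_win, size=n)
    s0 = np.clip(v * np.maximum(0.0, -tau), 0.0, L)
    s1 = np.clip(v * (t_win - tau), 0.0, L)
    keep = s1 > s0
    return tau[keep], s0[keep], s1[keep]


def _simulate_gene(cfg: SimConfig, gene: GeneModel, condition: str,
                   rng: np.random.Generator) -> list[PolymeraseTruth]:
    rows: list[PolymeraseTruth] = []
    L = float(gene.length)
    gid = gene.gene_id
    tl = cfg.t_label

    if condition == "control":
        tau, s0, s1 = _gene_truth_control(cfg, gene, rng, cfg.t_label_control)
        for t, a, b in zip(tau, s0, s1):
            rows.append(PolymeraseTruth(gid, condition, "sense", float(t),
                                        None, (float(a), float(b))))
        prompt_rate = cfg.k_init * cfg.prompt_basal_frac
        n_p = rng.poisson(prompt_rate * cfg.t_label_control)
        for _ in range(n_p):
            rows.append(PolymeraseTruth(gid, condition, "prompt", 0.0, None,
                                        (-cfg.prompt_extent, 0.0)))
        return rows

    if condition == "cpt0":
        T = cfg.t_treat
        traps = place_traps(gene, cfg.trap_density, rng, cfg.readthrough_extent)
        x1 = traps[0] if traps.size else math.inf
        n = rng.poisson(cfg.k_init * cfg.init_boost * T)
        tau = rng.uniform(0.0, T, size=n)
        short = L <= cfg.short_gene_max
        for t in tau:
            term = L
            if short and rng.random() < cfg.readthrough_prob:
                ext = min(rng.exponential(cfg.readthrough_extent),
                          cfg.readthrough_extent)
                term = L + ext
            x_stop = min(x1, term)
            stall = float(x1) if x1 < term else None

            def pos(tt: float) -> float:
                return min(cfg.v_elong * max(0.0, tt - t), x_stop)

            a, b = pos(T - tl), pos(T)
            span = (a, b) if b > a else None
            rows.append(PolymeraseTruth(gid, condition, "sense", float(t),
                                        stall, span))
        prompt_rate = cfg.k_init * cfg.prompt_basal_frac * cfg.prompt_rate_fold
        n_p = rng.poisson(prompt_rate * tl)
        for _ in range(n_p):
            rows.append(PolymeraseTruth(gid, condition, "prompt", T - tl, None,
                                        (-cfg.prompt_extent, 0.0)))
        return rows

    if condition in ("rec15", "rec30"):
        # clock: 0 = washout.  Treatment-phase polymerases (negative init
        # times) are permanently arrested and never label.
        T = cfg.t_treat
        traps = place_traps(gene, cfg.trap_density, rng, cfg.readthrough_extent)
        x1 = traps[0] if traps.size else math.inf
        n_pre = rng.poisson(cfg.k_init * cfg.init_boost * T)
        tau_pre = rng.uniform(-T, 0.0, size=n_pre)
        for t in tau_pre:
            reach = cfg.v_elong * (-t)
            x_stop = min(x1, reach, L)
            stall = float(x_stop) if x_stop < L else None  # None: completed
            rows.append(PolymeraseTruth(gid, condition, "sense", float(t),
                                        stall, None))
        vr = cfg.v_recovery
        if condition == "rec15":
            w0, w1 = 0.0, tl
            n_new = rng.poisson(cfg.k_init * tl)
            tau = rng.uniform(0.0, tl, size=n_new)
        else:
            w0, w1 = tl, 2.0 * tl
            n_new = rng.poisson(cfg.k_init * 2.0 * tl)
            tau = rng.uniform(0.0, 2.0 * tl, size=n_new)
        for t in tau:
            a = min(vr * max(0.0, w0 - t), L)
            b = min(vr * max(0.0, w1 - t), L)
            span = (float(a), float(b)) if b > a else None
            rows.append(PolymeraseTruth(gid, condition, "sense", float(t),
                                        None, span))
        prompt_rate = cfg.k_init * cfg.prompt_basal_frac
        n_p = rng.poisson(prompt_rate * tl)
        for _ in range(n_p):
            rows.append(PolymeraseTruth(gid, condition, "prompt", w0, None,
                                        (-cfg.prompt_extent, 0.0)))
        return rows

    raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")


def truth_to_frame(rows: list[PolymeraseTruth]) -> pd.DataFrame:
    """Tabulate truth rows (documented column order, empty spans as NaN)."""
    rec = {
        "gene_id": [r.gene_id for r in rows],
        "condition": [r.condition for r in rows],
        "kind": [r.kind for r in rows],
        "init_time": [r.init_time for r in rows],
        "stall_pos": [np.nan if r.stall_pos is None else r.stall_pos for r in rows],
        "span_start": [np.nan if r.labeled_span is None else r.labeled_span[0]
                       for r in rows],
        "span_end": [np.nan if r.labeled_span is None else r.labeled_span[1]
                     for r in rows],
    }
    return pd.DataFrame(rec, columns=list(TRUTH_COLUMNS))


def _spans_to_genomic(truth: pd.DataFrame, genes: dict[str, GeneModel]
                      ) -> pd.DataFrame:
    """Map gene-axis labeled spans to genomic intervals with read strand."""
    t = truth.dropna(subset=["span_start", "span_end"])
    if t.empty:
        return pd.DataFrame(columns=["chrom", "gstart", "gend", "strand"])
    chroms, gstarts, gends, strands = [], [], [], []
    for gid, kind, a, b in zip(t["gene_id"], t["kind"],
                               t["span_start"], t["span_end"]):
        g = genes[gid]
        sense = kind == "sense"
        strand = g.strand if sense else ("-" if g.strand == "+" else "+")
        if g.strand == "+":
            gs, ge = g.start + a, g.start + b
        else:
            gs, ge = g.end - b, g.end - a
        chroms.append(g.chrom)
        gstarts.append(gs)
        gends.append(ge)
        strands.append(strand)
    return pd.DataFrame(
        {"chrom": chroms, "gstart": np.asarray(gstarts),
         "gend": np.asarray(gends), "strand": strands}
    )


def _sample_reads(spans: pd.DataFrame, depth: int, read_length: int,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Poisson-thin reads uniformly along labeled spans to expected depth.

    Reads lie fully inside their span (length is clipped for spans
    shorter than ``read_length``), so every read respects the span
    bounds the truth table declares.
    """
    if spans.empty:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64),
                             "strand": pd.Series(dtype=str)})
    lens = (spans["gend"] - spans["gstart"]).to_numpy(dtype=float)
    total = lens.sum()
    counts = rng.poisson(depth * lens / total)
    idx = np.repeat(np.arange(len(spans)), counts)
    gs = spans["gstart"].to_numpy(dtype=float)[idx]
    ln = lens[idx]
    rl = np.minimum(float(read_length), ln)
    offset = rng.uniform(0.0, 1.0, size=len(idx)) * (ln - rl)
    start = np.floor(gs + offset).astype(np.int64)
    end = start + np.maximum(1, np.round(rl).astype(np.int64))
    out = pd.DataFrame({
        "chrom": spans["chrom"].to_numpy()[idx],
        "start": start,
        "end": end,
        "strand": spans["strand"].to_numpy()[idx],
    })
    out.sort_values(["chrom", "start", "end", "strand"], inplace=True,
                    kind="mergesort")
    out.reset_index(drop=True, inplace=True)
    return out


def simulate_condition(config: SimConfig, condition: str,
                       rng: np.random.Generator | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one condition: (reads frame, polymerase truth table).

    Reads are in genomic coordinates (``chrom,start,end,strand``); truth
    rows record per-polymerase init times, stall positions and labeled
    spans on the gene axis (PROMPTs on the negative side).
    """
    config.validate()
    if condition not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if not config.genes:
        raise ValueError("SimConfig.genes is empty")
    if rng is None:
        rng = _condition_rng(config, condition)
    rows: list[PolymeraseTruth] = []
    for gene in config.genes:
        rows.extend(_simulate_gene(config, gene, condition, rng))
    truth = truth_to_frame(rows)
    gene_map = {g.gene_id: g for g in config.genes}
    spans = _spans_to_genomic(truth, gene_map)
    reads = _sample_reads(spans, config.depth, config.read_length, rng)
    return reads, truth


# ---------------------------------------------------------------------------
# fixture construction
# ---------------------------------------------------------------------------

def synthesize_genes(n_genes: int, length_distribution: dict | None,
                     rng: np.random.Generator, chrom: str = "chrS",
                     gap: int = 50_000, offset: int = 100_000
                     ) -> list[GeneModel]:
    """Lay out ``n_genes`` non-overlapping genes on one contig.

    ``length_distribution``: ``{"kind": "log_uniform", "low": .., "high": ..}``
    (default 2 kb–500 kb, spanning both size classes) or
    ``{"kind": "fixed", "length": ..}``.  Genes are separated by ``gap``
    bp so upstream/downstream feature windows never collide.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    spec = length_distribution or {"kind": "log_uniform",
                                   "low": 2000, "high": 500_000}
    kind = spec.get("kind", "log_uniform")
    if kind == "log_uniform":
        lo, hi = float(spec["low"]), float(spec["high"])
        lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    elif kind == "fixed":
        lengths = np.full(n_genes, float(spec["length"]))
    else:
        raise ValueError(f"unknown length distribution kind {kind!r}")
    lengths = np.maximum(1, np.round(lengths)).astype(np.int64)
    genes: list[GeneModel] = []
    cursor = offset
    width = len(str(n_genes))
    for i, L in enumerate(lengths):
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i + 1:0{width}d}", chrom, cursor,
                               cursor + int(L), strand))
        cursor += int(L) + gap
    return genes


def make_fixture(n_genes: int, length_distribution: dict | None = None,
                 seed: int = 0, outdir=None,
                 config: SimConfig | None = None,
                 conditions: tuple[str, ...] = CONDITIONS) -> dict:
    """Build a complete synthetic dataset: annotation, reads, truth, config.

    Deterministic for a fixed seed (byte-identical files on re-run).
    Returns a dict with the in-memory objects; when ``outdir`` is given,
    also writes ``genes.bed``, ``reads_<condition>.bed``,
    ``truth_<condition>.tsv`` and a ``config.yaml`` echo.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    layout_rng = np.random.default_rng(seed)
    genes = synthesize_genes(n_genes, length_distribution, layout_rng)
    cfg = replace(config, genes=genes, seed=seed) if config is not None \
        else SimConfig(genes=genes, seed=seed)
    result: dict = {"genes": genes, "config": cfg, "reads": {}, "truth": {}}
    for cond in conditions:
        reads, truth = simulate_condition(cfg, cond)
        result["reads"][cond] = reads
        result["truth"][cond] = truth
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_bed(genes, outdir / "genes.bed")
        for cond in conditions:
            write_reads_bed(result["reads"][cond], outdir / f"reads_{cond}.bed")
            result["truth"][cond].to_csv(outdir / f"truth_{cond}.tsv",
                                         sep="\t", index=False,
                                         float_format="%.6g")
        echo = asdict(cfg)
        echo["genes"] = f"{len(genes)} genes in genes.bed"
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(echo, fh, sort_keys=True)
        result["outdir"] = outdir
    return result
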