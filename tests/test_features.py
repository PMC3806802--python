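import numpy as np
import pandas as pd
import pytest

import bruwave as bw
from bruwave.features import ReadIndex


def reads_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


def uniform_reads(rng, n, lo, hi, strand=None, chrom="c"):
    pos = rng.integers(lo, hi - 50, n)
    strands = (np.where(rng.random(n) < 0.5, "+", "-")
               if strand is None else np.full(n, strand))
    return reads_frame([(chrom, int(p), int(p) + 50, s)
                        for p, s in zip(pos, strands)])


class TestReadthrough:
    def test_index_is_window_over_body(self):
        """Body density 10x the downstream window -> index 0.1."""
        gene = bw.GeneModel("g", "c", 100_000, 110_000, "+")
        rng = np.random.default_rng(0)
        body = uniform_reads(rng, 1000, 100_000, 110_000, "+")
        down = uniform_reads(rng, 100, 110_000, 120_000, "+")
        reads = pd.concat([body, down], ignore_index=True)
        rec = bw.readthrough_index(gene, reads, reads, len(reads), len(reads))
        assert rec.index_control == pytest.approx(0.1, rel=0.15)
        assert rec.delta == pytest.approx(1.0)

    def test_zero_downstream_both_conditions_delta_one(self):
        gene = bw.GeneModel("g", "c", 100_000, 110_000, "+")
        rng = np.random.default_rng(1)
        body = uniform_reads(rng, 500, 100_000, 110_000, "+")
        rec = bw.readthrough_index(gene, body, body, len(body), len(body))
        assert rec.index_control == 0.0
        assert rec.delta == 1.0

    def test_drug_induces_readthrough_on_short_genes(self):
        """Short genes that escape internal blockage read through the TES
        under drug: median treated/control delta over the cohort > 2."""
        cfg = bw.SimConfig(depth=500_000)
        fx = bw.make_fixture(300, {"kind": "fixed", "length": 2000}, seed=5,
                             config=cfg, conditions=("control", "cpt0"))
        rc = ReadIndex(fx["reads"]["control"])
        rt = ReadIndex(fx["reads"]["cpt0"])
        deltas = [bw.readthrough_index(g, rc, rt, rc.library_size,
                                       rt.library_size).delta
                  for g in fx["genes"]]
        assert np.median(deltas) > 2.0

    def test_strand_reflection_invariance(self):
        """Mirroring the locus and flipping strands leaves the index
        unchanged."""
        P = 1_000_000
        rng = np.random.default_rng(2)
        gene = bw.GeneModel("g", "c", 100_000, 110_000, "+")
        reads = pd.concat([uniform_reads(rng, 800, 100_000, 110_000, "+"),
                           uniform_reads(rng, 80, 110_000, 120_000, "+")],
                          ignore_index=True)
        fwd = bw.readthrough_index(gene, reads, reads, len(reads), len(reads))
        gene_r = bw.GeneModel("g", "c", P - 110_000, P - 100_000, "-")
        refl = reads.assign(start=P - reads["end"], end=P - reads["start"],
                            strand="-")
        rev = bw.readthrough_index(gene_r, refl, refl, len(refl), len(refl))
        assert rev.index_control == pytest.approx(fwd.index_control)
        assert rev.delta == pytest.approx(fwd.delta)

    def test_downstream_same_strand_gene_flagged(self):
        gene = bw.GeneModel("g", "c", 100_000, 110_000, "+")
        other = bw.GeneModel("h", "c", 112_000, 130_000, "+")
        empty = reads_frame([("c", 100_000, 100_050, "+")])
        rec = bw.readthrough_index(gene, empty, empty, 1, 1,
                                   other_genes=[gene, other])
        assert rec.flag.startswith("window_overlaps")


class TestPrompt:
    def test_only_antisense_upstream_reads_count(self):
        gene = bw.GeneModel("g", "c", 100_000, 110_000, "+")
        up_anti = reads_frame([("c", 98_000, 98_050, "-")] * 10)
        up_sense = reads_frame([("c", 98_000, 98_050, "+")] * 10)
        body = reads_frame([("c", 105_000, 105_050, "+")] * 10)
        with_anti = pd.concat([up_anti, body], ignore_index=True)
        with_sense = pd.concat([up_sense, body], ignore_index=True)
        rec_a = bw.prompt_index(gene, with_anti, with_anti, 20, 20)
        rec_s = bw.prompt_index(gene, with_sense, with_sense, 20, 20)
        assert rec_a.signal_control > 0
        assert rec_s.signal_control == 0.0

    @pytest.mark.parametrize("fold,lo,hi", [(5.0, 3.0, 7.0),
                                            (1.0, 0.7, 1.3)])
    def test_divergent_initiation_fold_recovered(self, fold, lo, hi):
        """The drug multiplies divergent upstream initiation; the median
        per-gene delta recovers the programmed fold."""
        cfg = bw.SimConfig(trap_density=0.0, readthrough_prob=0.0,
                           k_init=5.0, depth=500_000, prompt_rate_fold=fold)
        fx = bw.make_fixture(100, {"kind": "fixed", "length": 5000}, seed=3,
                             config=cfg, conditions=("control", "cpt0"))
        params = bw.AnalysisParams(prompt_window=1000)
        rc = ReadIndex(fx["reads"]["control"])
        rt = ReadIndex(fx["reads"]["cpt0"])
        deltas = [bw.prompt_index(g, rc, rt, rc.library_size,
                                  rt.library_size, params).delta
                  for g in fx["genes"]]
        assert lo <= np.median(deltas) <= hi


class TestErna:
    def test_zero_control_large_finite_delta(self):
        enh = bw.EnhancerInterval("e", "c", 10_000, 12_000)
        empty = reads_frame([("c", 500_000, 500_050, "+")])
        treated = pd.concat(
            [empty, reads_frame([("c", 10_500, 10_550, "+")] * 50)],
            ignore_index=True)
        (rec,) = bw.erna_signal([enh], empty, treated, len(empty),
                                len(treated))
        assert np.isfinite(rec.delta) and rec.delta > 50

    def test_both_strands_pool(self):
        enh = bw.EnhancerInterval("e", "c", 10_000, 12_000)
        mixed = pd.concat([reads_frame([("c", 10_500, 10_550, "+")] * 10),
                           reads_frame([("c", 11_000, 11_050, "-")] * 10)],
                          ignore_index=True)
        plus_only = reads_frame([("c", 10_500, 10_550, "+")] * 20)
        (a,) = bw.erna_signal([enh], mixed, mixed, 20, 20)
        (b,) = bw.erna_signal([enh], plus_only, plus_only, 20, 20)
        assert a.signal_control == b.signal_control

    def test_uniform_background_null_delta(self):
        """With identical uniform backgrounds, delta ~ 1 across random
        intervals."""
        rng = np.random.default_rng(6)
        control = uniform_reads(rng, 50_000, 0, 1_000_000)
        treated = uniform_reads(rng, 50_000, 0, 1_000_000)
        enh = [bw.EnhancerInterval(f"e{i}", "c", int(s), int(s) + 2000)
               for i, s in enumerate(rng.integers(0, 990_000, 100))]
        recs = bw.erna_signal(enh, control, treated, len(control),
                              len(treated))
        med = np.median([r.delta for r in recs])
        assert abs(med - 1.0) < 0.1

    def test_genic_enhancer_flagged(self):
        enh = bw.EnhancerInterval("e", "c", 10_000, 12_000)
        gene = bw.GeneModel("g", "c", 11_000, 30_000, "+")
        empty = reads_frame([("c", 500_000, 500_050, "+")])
        (rec,) = bw.erna_signal([enh], empty, empty, 1, 1, genes=[gene])
        assert rec.flag == "overlaps_gene:g"


class TestSubsamplingInvariance:
    def test_indices_stable_under_half_subsampling(self):
        """Per-million normalization makes all three indices invariant in
        expectation under uniform read subsampling; at dense coverage the
        median per-feature shift of a 50% subsample stays below 5%."""
        rng = np.random.default_rng(7)
        genes, enhancers, chunks = [], [], []
        for i in range(30):
            base = 400_000 * i
            g = bw.GeneModel(f"g{i}", "c", base + 100_000, base + 200_000,
                             "+")
            genes.append(g)
            enhancers.append(bw.EnhancerInterval(f"e{i}", "c", base + 20_000,
                                                 base + 40_000))
            chunks += [
                uniform_reads(rng, 10_000, g.start, g.end, "+"),          # body
                uniform_reads(rng, 1000, g.end, g.end + 10_000, "+"),     # RT
                uniform_reads(rng, 800, g.start - 5000, g.start, "-"),    # PROMPT
                uniform_reads(rng, 2000, base + 20_000, base + 40_000),   # eRNA
            ]
        reads = pd.concat(chunks, ignore_index=True)
        half = reads.sample(frac=0.5, random_state=1).reset_index(drop=True)
        full_ix, half_ix = ReadIndex(reads), ReadIndex(half)
        shifts = []
        for g, e in zip(genes, enhancers):
            rt_f = bw.readthrough_index(g, full_ix, full_ix,
                                        len(reads), len(reads))
            rt_h = bw.readthrough_index(g, half_ix, half_ix,
                                        len(half), len(half))
            pr_f = bw.prompt_index(g, full_ix, full_ix, len(reads),
                                   len(reads))
            pr_h = bw.prompt_index(g, half_ix, half_ix, len(half), len(half))
            (er_f,) = bw.erna_signal([e], full_ix, full_ix, len(reads),
                                     len(reads))
            (er_h,) = bw.erna_signal([e], half_ix, half_ix, len(half),
                                     len(half))
            shifts += [abs(rt_h.index_control / rt_f.index_control - 1),
                       abs(pr_h.index_control / pr_f.index_control - 1),
                       abs(er_h.index_control / er_f.index_control - 1)]
        assert np.median(shifts) < 0.05
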