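import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bruwave as bw


def _gene(length=100_000, start=100_000, strand="+", gid="g"):
    return bw.GeneModel(gid, "chrS", start, start + length, strand)


class TestPlaceTraps:
    def test_zero_rate_always_empty(self):
        rng = np.random.default_rng(0)
        for L in (2000, 100_000):
            assert bw.place_traps(_gene(L), 0.0, rng).size == 0

    def test_counts_are_poisson(self):
        """Trap counts over many genes follow Poisson(lambda * span)."""
        rng = np.random.default_rng(1)
        lam, L = 2.5e-4, 100_000
        n = 2000
        counts = np.array([bw.place_traps(_gene(L), lam, rng).size
                           for _ in range(n)])
        mu = lam * L
        lo = int(stats.poisson.ppf(0.01, mu))
        hi = int(stats.poisson.ppf(0.99, mu))
        inner = np.arange(lo + 1, hi)
        obs = np.r_[(counts <= lo).sum(),
                    [(counts == c).sum() for c in inner],
                    (counts >= hi).sum()]
        exp = n * np.r_[stats.poisson.cdf(lo, mu),
                        stats.poisson.pmf(inner, mu),
                        stats.poisson.sf(hi - 1, mu)]
        _, p = stats.chisquare(obs, exp)
        assert p > 0.01

    def test_first_trap_distance_is_exponential(self):
        """Distance TSS -> first trap has mean 1/lambda = 4 kb."""
        rng = np.random.default_rng(2)
        lam = 2.5e-4
        firsts = []
        while len(firsts) < 10_000:
            tr = bw.place_traps(_gene(1_000_000), lam, rng)
            if tr.size:
                firsts.append(tr[0])
        mean = np.mean(firsts)
        assert abs(mean - 4000.0) / 4000.0 < 0.05


class TestConditions:
    def test_unknown_condition_rejected(self):
        cfg = bw.SimConfig(genes=[_gene()])
        with pytest.raises(ValueError, match="unknown condition"):
            bw.simulate_condition(cfg, "washout45")

    def test_control_coverage_flat(self):
        """Steady state: binned control coverage is flat over the 5' body."""
        cfg = bw.SimConfig(genes=[_gene(100_000)], depth=1_000_000, seed=0)
        reads, _ = bw.simulate_condition(cfg, "control")
        mids = (reads["start"] + reads["end"]) / 2.0 - 100_000
        hist, _ = np.histogram(mids, bins=np.arange(0, 31_000, 1000))
        cv = hist.std() / hist.mean()
        assert cv < 0.1

    def test_cpt0_stall_distribution(self):
        """P(stall beyond 10 kb) = exp(-lambda*10kb) = 0.082 +- 0.01."""
        genes = [_gene(100_000, start=100_000 + i * 150_000, gid=f"g{i}")
                 for i in range(25)]
        cfg = bw.SimConfig(genes=genes, k_init=10.0, depth=1000, seed=3)
        _, truth = bw.simulate_condition(cfg, "cpt0")
        stalls = truth.loc[truth["kind"] == "sense", "stall_pos"].dropna()
        assert len(stalls) >= 10_000
        frac = (stalls > 10_000).mean()
        assert abs(frac - np.exp(-2.5)) < 0.01

    @pytest.mark.parametrize("condition,bound_min", [("rec15", 15.0),
                                                     ("rec30", 30.0)])
    def test_recovery_kinematic_bound(self, condition, bound_min):
        """No labeled base beyond v_recovery * minutes-since-washout."""
        cfg = bw.SimConfig(genes=[_gene(200_000)], k_init=20.0,
                           depth=10_000, seed=4)
        _, truth = bw.simulate_condition(cfg, condition)
        sense = truth[(truth["kind"] == "sense")
                      & (truth["init_time"] >= 0)].dropna(subset=["span_end"])
        bound = cfg.v_recovery * bound_min
        assert sense["span_end"].max() <= bound + 1e-9
        assert sense["span_end"].max() > bound - 1500  # nearly attained

    def test_prewashout_polymerases_never_label(self):
        """Blocked complexes are discarded: treatment-phase rows carry no
        labeled span in either recovery condition."""
        genes = [_gene(150_000, start=100_000 + i * 200_000, gid=f"g{i}")
                 for i in range(10)]
        cfg = bw.SimConfig(genes=genes, depth=5000, seed=5)
        for cond in ("rec15", "rec30"):
            _, truth = bw.simulate_condition(cfg, cond)
            pre = truth[truth["init_time"] < 0]
            assert len(pre) > 0
            assert pre["span_start"].isna().all()
            assert pre["span_end"].isna().all()

    def test_labeled_output_scales_with_k_init(self):
        """Total labeled bases in control scale linearly with k_init."""
        totals = {}
        for k in (1.0, 4.0):
            cfg = bw.SimConfig(genes=[_gene(100_000)], k_init=k,
                               depth=1000, seed=6)
            _, truth = bw.simulate_condition(cfg, "control")
            s = truth[truth["kind"] == "sense"]
            totals[k] = float((s["span_end"] - s["span_start"]).sum())
        assert abs(totals[4.0] / totals[1.0] - 4.0) < 4.0 * 0.05

    def test_reads_confined_to_extended_gene_span(self):
        """Reads stay within [span - prompt window, span + readthrough]."""
        fx = bw.make_fixture(30, {"kind": "log_uniform", "low": 2000,
                                  "high": 50_000}, seed=8,
                             config=bw.SimConfig(depth=50_000))
        cfg = fx["config"]
        pad = max(cfg.prompt_extent, cfg.readthrough_extent)
        lo = np.array([g.start - pad for g in fx["genes"]])
        hi = np.array([g.end + pad for g in fx["genes"]])
        for cond, reads in fx["reads"].items():
            idx = np.searchsorted(lo, reads["start"].to_numpy(), "right") - 1
            assert (idx >= 0).all()
            assert (reads["end"].to_numpy() <= hi[idx]).all()

    def test_drug_occupancy_decays_exponentially(self):
        """Averaged over genes, drug-arm coverage ~ exp(-lambda x); the
        log-coverage slope matches -lambda within 10%."""
        genes = [_gene(60_000, start=100_000 + i * 100_000, gid=f"g{i}")
                 for i in range(400)]
        cfg = bw.SimConfig(genes=genes, depth=2_000_000, seed=9)
        reads, truth = bw.simulate_condition(cfg, "cpt0")
        n_poly = (truth["kind"] == "sense").sum()
        assert n_poly >= 5000
        starts = np.array([g.start for g in genes])
        sense = reads[reads["strand"] == "+"]
        d = (sense["start"].to_numpy() + sense["end"].to_numpy()) / 2.0
        # map to distance from own TSS ('+' genes only, uniform spacing)
        idx = np.searchsorted(starts, d, "right") - 1
        ok = (idx >= 0)
        dist = d[ok] - starts[idx[ok]]
        dist = dist[(dist >= 0) & (dist < 16_000)]
        hist, edges = np.histogram(dist, bins=np.arange(0, 17_000, 1000))
        x = (edges[:-1] + edges[1:]) / 2.0
        slope = np.polyfit(x, np.log(hist), 1)[0]
        assert abs(-slope - cfg.trap_density) / cfg.trap_density < 0.10


class TestFixture:
    def test_deterministic_bytes(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        for d in (a, b):
            bw.make_fixture(20, seed=1, outdir=d,
                            config=bw.SimConfig(depth=5000))
        for f in sorted(p.name for p in a.iterdir()):
            assert (a / f).read_bytes() == (b / f).read_bytes(), f

    def test_rejects_nonpositive_n_genes(self):
        with pytest.raises(ValueError, match="n_genes"):
            bw.make_fixture(0)

    def test_all_short_genes_empty_cohort(self):
        fx = bw.make_fixture(20, {"kind": "fixed", "length": 5000}, seed=2,
                             config=bw.SimConfig(depth=20_000),
                             conditions=("control",))
        expr = bw.quantify_condition(fx["genes"], fx["reads"]["control"],
                                     "control")
        with pytest.raises(ValueError, match="0 genes selected"):
            bw.select_cohort(expr, fx["genes"], bw.AnalysisParams())

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            bw.SimConfig(genes=[_gene()], readthrough_prob=1.5).validate()
        with pytest.raises(ValueError):
            bw.SimConfig(genes=[_gene()], v_recovery=3000.0).validate()
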