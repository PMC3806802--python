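"""Recovery wave-front detection and elongation-rate estimation.

After washout of an elongation-blocking drug, newly initiated
polymerases repopulate long genes from the 5' end; the farthest labeled
position (the wave front) advances at the post-washout elongation rate.
The front is read off the recovery/control metagene ratio: scanning from
the TSS, it is the right edge of the last bin before the smoothed ratio
first stays below ``front_alpha`` for three consecutive bins (a
persistence rule against single-bin noise dips).

With fronts at one or more effective times t (washout to end of
labeling), the rate is the least-squares slope through the origin,

    v = sum(front_i * t_i) / sum(t_i^2)   [kb/min],

since front(0) = 0 by construction.  Uncertainty is bootstrapped over
cohort genes — gene-to-gene variation dominates the aggregate noise —
re-running detection and the fit on each resample.

:class:`RecoveryWaveModel` packages the whole estimation (cohort
profiles → fronts → rate with CI) behind a statsmodels-style
``fit()``/Results interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .metagene import (MetageneProfile, build_profile, gene_profile_matrix,
                       profile_from_matrix, select_cohort)
from .quantify import AnalysisParams, quantify_condition

logger = logging.getLogger("bruwave")


@dataclass
class FrontEstimate:
    """Detected wave-front position for one recovery time point."""

    condition: str
    t_effective: float       # min from washout to end of labeling
    front_bp: float
    alpha: float
    n_genes: int
    flag: str | None = None  # None | 'beyond_extent' | 'no_signal'

    def __post_init__(self) -> None:
        if self.front_bp < 0:
            raise ValueError("front_bp must be >= 0")
        if self.t_effective <= 0:
            raise ValueError("t_effective must be > 0")


def smooth3(values: np.ndarray) -> np.ndarray:
    """Centered 3-bin moving average; shrunk windows at the edges."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        return v.copy()
    out = np.empty_like(v)
    out[1:-1] = (v[:-2] + v[1:-1] + v[2:]) / 3.0
    out[0] = v[:2].mean()
    out[-1] = v[-2:].mean()
    return out


def detect_front(recovery_profile: MetageneProfile,
                 control_profile: MetageneProfile,
                 params: AnalysisParams | None = None,
                 t_effective: float = 15.0,
                 condition: str | None = None) -> FrontEstimate:
    """Locate the recovery wave front on the recovery/control ratio."""
    params = params or AnalysisParams()
    cond = condition if condition is not None else recovery_profile.condition
    if (recovery_profile.bin_width != control_profile.bin_width
            or len(recovery_profile.values) != len(control_profile.values)):
        raise ValueError("profiles do not share binning")
    bw = recovery_profile.bin_width
    n = len(recovery_profile.values)
    if not np.any(recovery_profile.values > 0):
        return FrontEstimate(cond, t_effective, 0.0, params.front_alpha,
                             recovery_profile.n_genes, flag="no_signal")
    ratio = (recovery_profile.values + params.epsilon) \
        / (control_profile.values + params.epsilon)
    sm = smooth3(ratio)
    below = sm < params.front_alpha
    run = below[:-2] & below[1:-1] & below[2:] if n >= 3 else \
        np.zeros(0, dtype=bool)
    hits = np.flatnonzero(run)
    if hits.size == 0:
        return FrontEstimate(cond, t_effective, float(n * bw),
                             params.front_alpha, recovery_profile.n_genes,
                             flag="beyond_extent")
    front = float(hits[0] * bw)  # right edge of the bin before the drop
    return FrontEstimate(cond, t_effective, front, params.front_alpha,
                         recovery_profile.n_genes)


def fit_rate_through_origin(fronts_bp: np.ndarray, times_min: np.ndarray
                            ) -> float:
    """Least-squares slope through the origin, in kb/min."""
    f = np.asarray(fronts_bp, dtype=float) / 1000.0
    t = np.asarray(times_min, dtype=float)
    denom = float((t * t).sum())
    if denom == 0:
        raise ValueError("need at least one time point with t_effective > 0")
    return float((f * t).sum() / denom)


@dataclass
class RateEstimate:
    """Fitted post-washout elongation rate with bootstrap CI."""

    rate_kb_per_min: float
    per_timepoint_rates: dict[float, float]
    ci_low: float
    ci_high: float
    method: str = "origin_slope"
    n_bootstrap: int = 0
    fronts: list[FrontEstimate] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (np.isnan(self.ci_low)
                or self.ci_low <= self.rate_kb_per_min <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def estimate_rate(fronts: Sequence[FrontEstimate],
                  params: AnalysisParams | None = None,
                  bootstrap_rates: np.ndarray | None = None) -> RateEstimate:
    """Pool front estimates into one rate; CI from supplied bootstrap draws.

    Fronts flagged 'beyond_extent' are censored (the true front lies past
    the profiled extent) and may not be used; if every front is flagged,
    estimation fails.
    """
    params = params or AnalysisParams()
    valid = [f for f in fronts if f.flag != "beyond_extent"]
    if not valid:
        raise ValueError("all fronts flagged beyond_extent; extend max_extent")
    f_bp = np.array([f.front_bp for f in valid])
    t = np.array([f.t_effective for f in valid])
    rate = fit_rate_through_origin(f_bp, t)
    per_tp = {float(fe.t_effective): fe.front_bp / 1000.0 / fe.t_effective
              for fe in valid}
    if bootstrap_rates is not None and len(bootstrap_rates):
        lo, hi = np.percentile(bootstrap_rates, [2.5, 97.5])
        lo, hi = min(float(lo), rate), max(float(hi), rate)
        nb = len(bootstrap_rates)
    elif rate == 0.0 and np.all(f_bp == 0):
        lo = hi = 0.0
        nb = 0
    else:
        lo = hi = float("nan")
        nb = 0
    return RateEstimate(rate, per_tp, lo, hi, n_bootstrap=nb,
                        fronts=list(valid))


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------

class RecoveryWaveModel:
    """Post-washout elongation-rate model for a long-gene cohort.

    Parameters
    ----------
    genes
        Annotation (all genes); the cohort is selected from it by the
        control RPKM/length rule unless ``cohort`` is given explicitly.
    control_reads, recovery_reads
        Control read frame and a mapping ``t_effective (min) -> reads``
        for each recovery labeling.
    params
        Analysis thresholds; defaults are the package defaults.
    """

    def __init__(self, genes: Sequence[GeneModel],
                 control_reads: pd.DataFrame,
                 recovery_reads: Mapping[float, pd.DataFrame],
                 params: AnalysisParams | None = None,
                 max_extent: int | None = None,
                 cohort: Sequence[GeneModel] | None = None):
        self.params = params or AnalysisParams()
        self.max_extent = max_extent if max_extent is not None \
            else self.params.max_extent
        self.genes = list(genes)
        self.control_reads = control_reads
        self.recovery_reads = dict(recovery_reads)
        if not self.recovery_reads:
            raise ValueError("need at least one recovery time point")
        if cohort is None:
            expr = quantify_condition(self.genes, control_reads, "control")
            cohort = select_cohort(expr, self.genes, self.params)
        self.cohort = list(cohort)

    @classmethod
    def from_files(cls, genes_bed, control_bed, recovery_beds: Mapping[float, str],
                   params: AnalysisParams | None = None, **kw):
        from .annotation import read_gene_bed, read_reads_bed
        genes = read_gene_bed(genes_bed)
        control = read_reads_bed(control_bed)
        recovery = {float(t): read_reads_bed(p)
                    for t, p in recovery_beds.items()}
        return cls(genes, control, recovery, params=params, **kw)

    def _matrices(self):
        p = self.params
        ctrl = gene_profile_matrix(self.cohort, self.control_reads,
                                   len(self.control_reads), p, self.max_extent)
        recs = {}
        for t, reads in sorted(self.recovery_reads.items()):
            recs[t] = gene_profile_matrix(self.cohort, reads, len(reads),
                                          p, self.max_extent)
        return ctrl, recs

    def fit(self, n_bootstrap: int | None = None,
            seed: int | None = 0) -> "RecoveryWaveResults":
        """Detect fronts, fit the through-origin rate, bootstrap the CI."""
        p = self.params
        nb = p.n_bootstrap if n_bootstrap is None else n_bootstrap
        (c_mat, c_mask, dist), recs = self._matrices()
        bw = p.bin_width
        gene_ids = [g.gene_id for g in self.cohort]
        ctrl_prof = profile_from_matrix(c_mat, c_mask, dist, bw,
                                        condition="control",
                                        gene_ids=gene_ids)
        profiles = {"control": ctrl_prof}
        fronts = []
        for t, (m, mask, _) in recs.items():
            prof = profile_from_matrix(m, mask, dist, bw,
                                       condition=f"recovery@{t:g}min",
                                       gene_ids=gene_ids)
            profiles[f"recovery@{t:g}min"] = prof
            fronts.append(detect_front(prof, ctrl_prof, p, t_effective=t))
        for fe in fronts:
            if fe.flag:
                logger.warning("front at t=%g min flagged %s", fe.t_effective,
                               fe.flag)

        boot_rates = None
        if nb > 0:
            rng = np.random.default_rng(seed)
            G = len(self.cohort)
            rates = []
            for _ in range(nb):
                idx = rng.integers(0, G, G)
                b_ctrl = profile_from_matrix(c_mat[idx], c_mask[idx], dist, bw,
                                             condition="control")
                b_fronts = []
                for t, (m, mask, _) in recs.items():
                    b_prof = profile_from_matrix(m[idx], mask[idx], dist, bw)
                    b_fronts.append(detect_front(b_prof, b_ctrl, p,
                                                 t_effective=t))
                b_valid = [f for f in b_fronts if f.flag != "beyond_extent"]
                if not b_valid:
                    continue
                rates.append(fit_rate_through_origin(
                    np.array([f.front_bp for f in b_valid]),
                    np.array([f.t_effective for f in b_valid])))
            boot_rates = np.asarray(rates)
        rate = estimate_rate(fronts, p, bootstrap_rates=boot_rates)
        return RecoveryWaveResults(self, rate, fronts, profiles, boot_rates)


class RecoveryWaveResults:
    """Results of :meth:`RecoveryWaveModel.fit`.

    Attributes
    ----------
    rate_kb_per_min, ci_low, ci_high
        Pooled through-origin slope and its bootstrap 95% CI.
    per_timepoint_rates
        ``{t_effective: front/t}`` in kb/min.
    fronts
        :class:`FrontEstimate` per recovery time point.
    profiles
        The cohort metagene profiles the fronts were read from.
    """

    def __init__(self, model: RecoveryWaveModel, rate: RateEstimate,
                 fronts: list[FrontEstimate],
                 profiles: dict[str, MetageneProfile],
                 bootstrap_rates: np.ndarray | None):
        self.model = model
        self.rate = rate
        self.fronts = fronts
        self.profiles = profiles
        self.bootstrap_rates = bootstrap_rates

    @property
    def rate_kb_per_min(self) -> float:
        return self.rate.rate_kb_per_min

    @property
    def ci_low(self) -> float:
        return self.rate.ci_low

    @property
    def ci_high(self) -> float:
        return self.rate.ci_high

    @property
    def per_timepoint_rates(self) -> dict[float, float]:
        return self.rate.per_timepoint_rates

    def fronts_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "condition": f.condition, "t_effective_min": f.t_effective,
            "front_bp": f.front_bp, "alpha": f.alpha,
            "n_genes": f.n_genes, "flag": f.flag or ""} for f in self.fronts])

    def per_gene_fronts(self) -> pd.DataFrame:
        return per_gene_fronts(self.model.cohort, self.model.control_reads,
                               self.model.recovery_reads, self.model.params,
                               max_extent=self.model.max_extent)

    def summary(self) -> str:
        lines = ["Recovery wave-front elongation rate",
                 "=" * 48,
                 f"cohort genes:        {len(self.model.cohort)}",
                 f"bin width:           {self.model.params.bin_width} bp",
                 f"front alpha:         {self.model.params.front_alpha}",
                 ""]
        for f in self.fronts:
            tag = f"  [{f.flag}]" if f.flag else ""
            lines.append(f"front @ {f.t_effective:5.1f} min: "
                         f"{f.front_bp / 1000:6.1f} kb  "
                         f"({f.front_bp / 1000 / f.t_effective:.2f} kb/min)"
                         f"{tag}")
        lines += ["",
                  f"pooled rate (through-origin slope): "
                  f"{self.rate_kb_per_min:.3f} kb/min",
                  f"bootstrap 95% CI ({self.rate.n_bootstrap} reps):   "
                  f"[{self.ci_low:.3f}, {self.ci_high:.3f}] kb/min"]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the cohort profiles with detected fronts marked."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for name, prof in self.profiles.items():
            ax.plot(prof.distances / 1000.0, prof.values, label=name)
        for f in self.fronts:
            ax.axvline(f.front_bp / 1000.0, linestyle="--", alpha=0.5)
        ax.set_xlabel("distance from TSS (kb)")
        ax.set_ylabel("mean density (per kb per million)")
        ax.legend(fontsize="small")
        return ax


def per_gene_fronts(cohort: Sequence[GeneModel],
                    control_reads: pd.DataFrame,
                    recovery_reads: Mapping[float, pd.DataFrame],
                    params: AnalysisParams | None = None,
                    max_extent: int | None = None) -> pd.DataFrame:
    """Front detection on each gene's own binned recovery/control ratio.

    Genes with insufficient control signal (body RPKM below the
    expression floor) are skipped with a reason; genes whose drop never
    occurs within their profiled extent are flagged 'beyond_extent'.
    """
    params = params or AnalysisParams()
    max_extent = max_extent if max_extent is not None else params.max_extent
    ctrl_expr = quantify_condition(list(cohort), control_reads, "control")
    ctrl_rpkm = ctrl_expr.set_index("gene_id")["rpkm"]
    c_mat, c_mask, dist = gene_profile_matrix(
        cohort, control_reads, len(control_reads), params, max_extent)
    rec_mats = {t: gene_profile_matrix(cohort, reads, len(reads), params,
                                       max_extent)[0]
                for t, reads in recovery_reads.items()}
    bw = params.bin_width
    rows = []
    for i, g in enumerate(cohort):
        n_bins_g = int(c_mask[i].sum())
        if float(ctrl_rpkm[g.gene_id]) < params.expr_min_rpkm:
            for t in sorted(rec_mats):
                rows.append({"gene_id": g.gene_id, "t_effective_min": t,
                             "front_bp": np.nan, "flag": "skipped",
                             "reason": "control body RPKM below floor"})
            logger.info("per_gene_fronts: %s skipped (low control signal)",
                        g.gene_id)
            continue
        ctrl_prof = MetageneProfile("control", bw, dist[:n_bins_g],
                                    c_mat[i, :n_bins_g], 1)
        for t in sorted(rec_mats):
            rec_prof = MetageneProfile(f"recovery@{t:g}min", bw,
                                       dist[:n_bins_g],
                                       rec_mats[t][i, :n_bins_g], 1)
            fe = detect_front(rec_prof, ctrl_prof, params, t_effective=t)
            rows.append({"gene_id": g.gene_id, "t_effective_min": t,
                         "front_bp": fe.front_bp, "flag": fe.flag or "",
                         "reason": ""})
    return pd.DataFrame(rows)
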