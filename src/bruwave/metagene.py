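"""TSS-aligned aggregate (metagene) profiles for long, expressed genes.

Genes are aligned at their transcription start sites on a common 5'→3'
axis; read midpoints are binned by distance from the TSS and converted
to per-kb-per-million densities per gene, then averaged across the
cohort.  Bins beyond a gene's own length are masked out of that gene's
contribution, so short cohort members never dilute the far bins.

Only a global per-million normalization is applied — no per-gene
rescaling — which keeps cross-condition bin ratios meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .quantify import AnalysisParams


@dataclass
class MetageneProfile:
    """Binned mean normalized signal vs distance from TSS for a gene cohort.

    ``distances`` are bin start offsets (bp); ``values`` the cohort-mean
    density per bin (per-kb-per-million units); ``n_contributing`` how
    many genes reach each bin.  ``gene_matrix``/``mask`` retain the
    per-gene contributions for bootstrap resampling.
    """

    condition: str
    bin_width: int
    distances: np.ndarray
    values: np.ndarray
    n_genes: int
    n_contributing: np.ndarray | None = None
    gene_ids: list[str] | None = None
    gene_matrix: np.ndarray | None = field(default=None, repr=False)
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.distances) != len(self.values):
            raise ValueError("distances and values must have equal length")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if np.any(self.values < 0):
            raise ValueError("profile values must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        n_c = self.n_contributing if self.n_contributing is not None \
            else np.full(len(self.values), self.n_genes)
        return pd.DataFrame({"distance_bp": self.distances,
                             "value": self.values,
                             "n_contributing": n_c})


def select_cohort(expression: pd.DataFrame, genes: Sequence[GeneModel],
                  params: AnalysisParams | None = None) -> list[GeneModel]:
    """Long, expressed genes: control RPKM above the floor and length
    at least ``metagene_min_length`` (the >100 kb, RPKM>1 rule)."""
    params = params or AnalysisParams()
    expr = expression.set_index("gene_id")["rpkm"]
    cohort = [
        g for g in genes
        if g.length >= params.metagene_min_length
        and g.gene_id in expr.index
        and float(expr[g.gene_id]) > params.expr_min_rpkm
    ]
    if not cohort:
        raise ValueError(
            "0 genes selected for the metagene cohort; lower "
            "expr_min_rpkm/metagene_min_length or provide longer, more "
            "expressed genes")
    return cohort


def gene_profile_matrix(cohort: Sequence[GeneModel], reads: pd.DataFrame,
                        library_size: int, params: AnalysisParams,
                        max_extent: int | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene binned densities: (matrix [G,B], mask [G,B], distances [B]).

    matrix[g, b] is gene g's read-midpoint count in distance bin b scaled
    to per-kb-per-million; mask[g, b] marks bins fully inside gene g.
    """
    max_extent = max_extent if max_extent is not None else params.max_extent
    bw = params.bin_width
    if max_extent < bw:
        raise ValueError("max_extent must be >= bin_width")
    n_bins = max_extent // bw
    distances = np.arange(n_bins) * bw
    G = len(cohort)
    matrix = np.zeros((G, n_bins))
    mask = np.zeros((G, n_bins), dtype=bool)
    scale = 1.0 / (bw / 1000.0) / (max(library_size, 1) / 1e6)

    from .quantify import _sorted_midpoints
    grouped = _sorted_midpoints(reads)
    for i, g in enumerate(cohort):
        mask[i] = (distances + bw) <= g.length
        mids = grouped.get((g.chrom, g.strand))
        if mids is None:
            continue
        if g.strand == "+":
            lo, hi = g.tss, g.tss + n_bins * bw
            sel = mids[np.searchsorted(mids, lo, "left"):
                       np.searchsorted(mids, hi, "left")]
            d = sel - g.tss
        else:
            lo, hi = g.tss - n_bins * bw, g.tss
            sel = mids[np.searchsorted(mids, lo, "right"):
                       np.searchsorted(mids, hi, "right")]
            d = g.tss - sel
        d = d[(d >= 0) & (d < n_bins * bw)]
        if d.size:
            matrix[i] = np.bincount((d // bw).astype(int),
                                    minlength=n_bins) * scale
    return matrix, mask, distances


def profile_from_matrix(matrix: np.ndarray, mask: np.ndarray,
                        distances: np.ndarray, bin_width: int,
                        condition: str = "",
                        gene_ids: list[str] | None = None) -> MetageneProfile:
    """Masked cohort mean of per-gene binned densities."""
    n_contrib = mask.sum(axis=0)
    with np.errstate(invalid="ignore"):
        values = np.where(n_contrib > 0,
                          (matrix * mask).sum(axis=0) / np.maximum(n_contrib, 1),
                          0.0)
    return MetageneProfile(condition=condition, bin_width=bin_width,
                           distances=distances, values=values,
                           n_genes=matrix.shape[0],
                           n_contributing=n_contrib, gene_ids=gene_ids,
                           gene_matrix=matrix, mask=mask)


def build_profile(cohort: Sequence[GeneModel], reads: pd.DataFrame,
                  library_size: int, params: AnalysisParams | None = None,
                  max_extent: int | None = None,
                  condition: str = "") -> MetageneProfile:
    """TSS-aligned cohort-mean profile of strand-matched read density."""
    params = params or AnalysisParams()
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    matrix, mask, distances = gene_profile_matrix(
        cohort, reads, library_size, params, max_extent)
    return profile_from_matrix(matrix, mask, distances, params.bin_width,
                               condition=condition,
                               gene_ids=[g.gene_id for g in cohort])


def ratio_profile(profile_a: MetageneProfile, profile_b: MetageneProfile,
                  epsilon: float) -> MetageneProfile:
    """Bin-wise pseudocount-stabilized ratio (a + eps) / (b + eps)."""
    if (profile_a.bin_width != profile_b.bin_width
            or len(profile_a.values) != len(profile_b.values)
            or not np.array_equal(profile_a.distances, profile_b.distances)):
        raise ValueError("binning mismatch between profiles")
    values = (profile_a.values + epsilon) / (profile_b.values + epsilon)
    return MetageneProfile(
        condition=f"{profile_a.condition}/{profile_b.condition}",
        bin_width=profile_a.bin_width,
        distances=profile_a.distances.copy(),
        values=values,
        n_genes=profile_a.n_genes,
        n_contributing=profile_a.n_contributing,
    )
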