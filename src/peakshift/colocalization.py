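"""Colocalization of TF peak sets: Venn overlap counts, conditional loss,
pairwise overlap correlation with Ward clustering, and genomic feature
distribution of binding sites.

The correlation matrix vectorizes each peak set as binary occupancy over
the merged union-region universe — the standard representation for TF
co-binding heatmaps — and clusters 1 - r with Ward linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .io_genomics import GeneModel, GenomicInterval, Peak, PeakSet
from .peak_dynamics import _merge_union_regions

__all__ = [
    "VennResult",
    "ColocalizationMatrix",
    "FeatureDistribution",
    "overlap_venn",
    "subset_overlapping",
    "conditional_loss_fraction",
    "pairwise_overlap_correlation",
    "feature_distribution",
    "promoter_enrichment_ratio",
]


@dataclass(frozen=True)
class VennResult:
    """Peak-based two-set overlap counts, reported in each direction.

    Because counting is per peak (not per merged region), the number of
    "shared" peaks differs by direction: ``both_a`` counts A peaks that
    overlap at least one B peak, ``both_b`` the converse. ``both`` aliases
    ``both_a``.
    """

    a_label: str
    b_label: str
    a_total: int
    b_total: int
    a_only: int
    b_only: int
    both_a: int
    both_b: int

    @property
    def both(self) -> int:
        return self.both_a

    @property
    def fraction_a_in_b(self) -> float:
        return self.both_a / self.a_total if self.a_total else 0.0

    @property
    def fraction_b_in_a(self) -> float:
        return self.both_b / self.b_total if self.b_total else 0.0


@dataclass
class ColocalizationMatrix:
    """TF x TF Pearson correlations over union-region binary occupancy."""

    labels: tuple[str, ...]
    r: np.ndarray
    linkage_order: tuple[int, ...]

    @property
    def ordered_labels(self) -> tuple[str, ...]:
        return tuple(self.labels[i] for i in self.linkage_order)


@dataclass(frozen=True)
class FeatureDistribution:
    """Counts and fractions of peaks in promoter / gene body / intergenic."""

    counts: dict[str, int]
    total: int

    @property
    def fractions(self) -> dict[str, float]:
        if self.total == 0:
            return {k: 0.0 for k in self.counts}
        return {k: v / self.total for k, v in self.counts.items()}


def _chrom_trees(peak_set: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peak_set:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    return trees


def _overlaps(trees: dict[str, IntervalTree], peak: Peak, min_bp: int) -> bool:
    tree = trees.get(peak.chrom)
    if tree is None:
        return False
    for iv in tree.overlap(peak.start, peak.end):
        if min(iv.end, peak.end) - max(iv.begin, peak.start) >= min_bp:
            return True
    return False


def overlap_venn(a: PeakSet, b: PeakSet, min_overlap_bp: int = 1) -> VennResult:
    """Two-set Venn overlap: a peak counts as shared iff it overlaps >= 1
    peak of the other set by at least ``min_overlap_bp``."""
    trees_b = _chrom_trees(b)
    trees_a = _chrom_trees(a)
    both_a = sum(1 for p in a if _overlaps(trees_b, p, min_overlap_bp))
    both_b = sum(1 for p in b if _overlaps(trees_a, p, min_overlap_bp))
    return VennResult(
        a_label=a.label, b_label=b.label,
        a_total=len(a), b_total=len(b),
        a_only=len(a) - both_a, b_only=len(b) - both_b,
        both_a=both_a, both_b=both_b,
    )


def subset_overlapping(a: PeakSet, b: PeakSet, min_overlap_bp: int = 1) -> PeakSet:
    """The peaks of A that overlap at least one peak of B (the A∩B peaks)."""
    trees_b = _chrom_trees(b)
    shared = [p for p in a if _overlaps(trees_b, p, min_overlap_bp)]
    return PeakSet(label=f"{a.label}_in_{b.label}", peaks=shared,
                   genome_id=a.genome_id)


def conditional_loss_fraction(
    shared: PeakSet, lost_in: PeakSet, min_overlap_bp: int = 1
) -> float:
    """Fraction of ``shared`` peaks with no overlap in ``lost_in``.

    Used to ask how many peaks of a colocalized subset disappear in a later
    condition (e.g. how many CTCF-colocalized unstimulated peaks vanish
    after stimulation).
    """
    if len(shared) == 0:
        raise ValueError("shared peak set is empty")
    trees = _chrom_trees(lost_in)
    lost = sum(1 for p in shared if not _overlaps(trees, p, min_overlap_bp))
    return lost / len(shared)


def occupancy_vectors(
    peak_sets: Sequence[PeakSet], min_overlap_bp: int = 1
) -> tuple[np.ndarray, int]:
    """Binary occupancy matrix (n_sets x n_union_regions) over merged regions."""
    groups = _merge_union_regions(peak_sets)
    trees = {ps.label: _chrom_trees(ps) for ps in peak_sets}
    mat = np.zeros((len(peak_sets), len(groups)), dtype=int)
    for j, group in enumerate(groups):
        chrom = group[0].chrom
        start = min(p.start for p in group)
        end = max(p.end for p in group)
        probe = Peak(GenomicInterval(chrom, start, end), start, 0.0)
        for i, ps in enumerate(peak_sets):
            if _overlaps(trees[ps.label], probe, min_overlap_bp):
                mat[i, j] = 1
    return mat, len(groups)


def pairwise_overlap_correlation(
    peak_sets: Sequence[PeakSet], min_overlap_bp: int = 1
) -> ColocalizationMatrix:
    """Pearson correlation of binary union-region occupancy between all
    pairs of peak sets, with Ward-linkage leaf ordering on distance 1 - r.

    A set occupying every union region or none has zero variance; its
    correlations are undefined and reported as NaN (with a warning), and it
    is appended after the clustered leaves in the ordering.
    """
    if len(peak_sets) < 2:
        raise ValueError("need >= 2 peak sets")
    labels = tuple(ps.label for ps in peak_sets)
    mat, _ = occupancy_vectors(peak_sets, min_overlap_bp)
    n = len(peak_sets)
    variances = mat.var(axis=1)
    degenerate = np.where(variances == 0)[0]
    if degenerate.size:
        warnings.warn(
            "sets with constant occupancy (all or no union regions), "
            f"correlations undefined: {[labels[i] for i in degenerate]}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(mat.astype(float))
    r = np.asarray(r)
    np.fill_diagonal(r, 1.0)
    for i in degenerate:
        r[i, :] = np.nan
        r[:, i] = np.nan
        r[i, i] = 1.0

    valid = [i for i in range(n) if i not in set(degenerate.tolist())]
    if len(valid) >= 2:
        sub = r[np.ix_(valid, valid)]
        dist = 1.0 - sub
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        z = linkage(squareform(dist, checks=False), method="ward")
        order = [valid[i] for i in leaves_list(z)]
    else:
        order = list(valid)
    order += [int(i) for i in degenerate]
    return ColocalizationMatrix(labels=labels, r=r, linkage_order=tuple(order))


def promoter_interval(
    gene: GeneModel, promoter_up: int = 2000, promoter_down: int = 500
) -> tuple[int, int]:
    """Half-open strand-aware promoter window around the TSS.

    Positions p with strand-aware offset d in [-promoter_up, promoter_down),
    where d = p - tss on the + strand and tss - p on the - strand.
    """
    if gene.strand == "+":
        return gene.tss - promoter_up, gene.tss + promoter_down
    return gene.tss - promoter_down + 1, gene.tss + promoter_up + 1


def feature_distribution(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    promoter_up: int = 2000,
    promoter_down: int = 500,
) -> FeatureDistribution:
    """Assign each peak summit to promoter > gene body > intergenic.

    A summit in any gene's strand-aware promoter window
    [tss - promoter_up, tss + promoter_down) counts as promoter regardless
    of gene-body overlap (precedence); otherwise a summit inside a gene
    body is genic; everything else is intergenic. Each peak is counted
    exactly once.
    """
    prom_trees: dict[str, IntervalTree] = {}
    body_trees: dict[str, IntervalTree] = {}
    for g in genes:
        ps, pe = promoter_interval(g, promoter_up, promoter_down)
        if ps < pe:
            prom_trees.setdefault(g.body.chrom, IntervalTree()).addi(max(0, ps), pe)
        body_trees.setdefault(g.body.chrom, IntervalTree()).addi(
            g.body.start, g.body.end
        )
    counts = {"promoter": 0, "gene_body": 0, "intergenic": 0}
    for p in peaks:
        s = p.summit
        if p.chrom in prom_trees and prom_trees[p.chrom].overlaps_point(s):
            counts["promoter"] += 1
        elif p.chrom in body_trees and body_trees[p.chrom].overlaps_point(s):
            counts["gene_body"] += 1
        else:
            counts["intergenic"] += 1
    return FeatureDistribution(counts=counts, total=len(peaks))


def promoter_enrichment_ratio(
    dist_a: FeatureDistribution, dist_b: FeatureDistribution
) -> float:
    """Ratio of promoter fractions between two feature distributions (a/b)."""
    fa = dist_a.fractions.get("promoter", 0.0)
    fb = dist_b.fractions.get("promoter", 0.0)
    if fb == 0.0:
        raise ValueError("promoter fraction in denominator distribution is zero")
    return fa / fb
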