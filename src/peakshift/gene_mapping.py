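"""Tiered assignment of peaks to genes.

Tiers are evaluated in precedence order; the first non-empty tier wins:

1. ``promoter``   — genes whose promoter window overlaps the peak;
2. ``gene_body``  — genes whose body overlaps the peak;
3. flank          — the nearest gene within ``flank_bp`` on each side of
                    the peak; a gene on both sides gives ``flank_both``
                    (two genes reported), otherwise ``flank_5`` /
                    ``flank_3`` by side;
4. ``unassigned`` — nothing within the flank window.

Distances are measured between the peak edge and the nearest gene edge
(0 for any overlap). If more than two genes tie within a direct-overlap
tier, the gene with the TSS nearest the peak summit is kept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .io_genomics import GeneModel, Peak, PeakSet
from .colocalization import promoter_interval

__all__ = ["GeneAssignment", "assign_peaks_to_genes"]

TIERS = ("promoter", "gene_body", "flank_both", "flank_5", "flank_3", "unassigned")


@dataclass(frozen=True)
class GeneAssignment:
    """A peak's gene assignment: 0-2 gene ids, a tier, and distances (bp)."""

    peak_name: str
    gene_ids: tuple[str, ...]
    tier: str
    distances: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.tier == "flank_both" and len(self.gene_ids) != 2:
            raise ValueError("flank_both requires exactly 2 genes")
        if self.tier == "unassigned" and self.gene_ids:
            raise ValueError("unassigned peaks carry no genes")


def _edge_distance(peak: Peak, gene: GeneModel) -> int:
    """bp between peak edge and nearest gene edge; 0 for overlaps."""
    if gene.body.chrom != peak.chrom:
        raise ValueError("distance across chromosomes is undefined")
    if gene.body.start < peak.end and peak.start < gene.body.end:
        return 0
    if gene.body.end <= peak.start:
        return peak.start - gene.body.end
    return gene.body.start - peak.end


def _reduce_overlap_tier(
    genes: list[GeneModel], peak: Peak
) -> list[GeneModel]:
    """Keep all genes if <= 2; otherwise keep the one with nearest TSS."""
    if len(genes) <= 2:
        return sorted(genes, key=lambda g: g.gene_id)
    return [min(genes, key=lambda g: (abs(g.tss - peak.summit), g.gene_id))]


def assign_peaks_to_genes(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    promoter_up: int = 2000,
    promoter_down: int = 500,
    flank_bp: int = 50000,
) -> list[GeneAssignment]:
    """Assign every peak to genes by the tiered precedence rule.

    Every peak appears exactly once in the output. The promoter window is
    the strand-aware [tss - promoter_up, tss + promoter_down) shared with
    the feature-distribution annotator.
    """
    prom_trees: dict[str, IntervalTree] = {}
    body_trees: dict[str, IntervalTree] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        ps, pe = promoter_interval(g, promoter_up, promoter_down)
        if ps < pe:
            prom_trees.setdefault(g.body.chrom, IntervalTree()).addi(
                max(0, ps), pe, g
            )
        body_trees.setdefault(g.body.chrom, IntervalTree()).addi(
            g.body.start, g.body.end, g
        )
        by_chrom.setdefault(g.body.chrom, []).append(g)

    out: list[GeneAssignment] = []
    for p in peaks:
        # tier 1: promoter overlap
        hits = [
            iv.data for iv in prom_trees.get(p.chrom, IntervalTree()).overlap(
                p.start, p.end
            )
        ]
        if hits:
            chosen = _reduce_overlap_tier(hits, p)
            out.append(GeneAssignment(
                p.name, tuple(g.gene_id for g in chosen), "promoter",
                tuple(0 for _ in chosen),
            ))
            continue
        # tier 2: gene-body overlap
        hits = [
            iv.data for iv in body_trees.get(p.chrom, IntervalTree()).overlap(
                p.start, p.end
            )
        ]
        if hits:
            chosen = _reduce_overlap_tier(hits, p)
            out.append(GeneAssignment(
                p.name, tuple(g.gene_id for g in chosen), "gene_body",
                tuple(0 for _ in chosen),
            ))
            continue
        # tier 3: nearest gene within flank_bp on each side
        left_best: tuple[int, str, GeneModel] | None = None
        right_best: tuple[int, str, GeneModel] | None = None
        for g in by_chrom.get(p.chrom, []):
            d = _edge_distance(p, g)
            if d == 0 or d > flank_bp:
                continue
            key = (d, g.gene_id, g)
            if g.body.end <= p.start:
                if left_best is None or key[:2] < left_best[:2]:
                    left_best = key
            else:
                if right_best is None or key[:2] < right_best[:2]:
                    right_best = key
        if left_best and right_best:
            out.append(GeneAssignment(
                p.name,
                (left_best[2].gene_id, right_best[2].gene_id),
                "flank_both",
                (left_best[0], right_best[0]),
            ))
        elif left_best:
            out.append(GeneAssignment(
                p.name, (left_best[2].gene_id,), "flank_5", (left_best[0],)
            ))
        elif right_best:
            out.append(GeneAssignment(
                p.name, (right_best[2].gene_id,), "flank_3", (right_best[0],)
            ))
        else:
            out.append(GeneAssignment(p.name, (), "unassigned", ()))
    return out
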