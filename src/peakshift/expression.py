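"""Differential-expression integration.

DE statistics (e.g. from DESeq) are consumed as a table, not computed;
this module applies the FDR / fold-change selection thresholds, computes
RPKM from raw counts, and intersects DE gene lists with peak-assigned
genes to estimate the fraction of DE genes that are direct binding targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .gene_mapping import GeneAssignment

__all__ = [
    "TargetOverlapResult",
    "compute_rpkm",
    "select_de_genes",
    "classify_de_direction",
    "direct_target_fraction",
]


@dataclass(frozen=True)
class TargetOverlapResult:
    """Overlap of a DE gene list with peak-assigned (direct target) genes."""

    n_de: int
    n_direct: int
    genes: tuple[str, ...]

    @property
    def fraction(self) -> float:
        return round(self.n_direct / self.n_de, 3)

    @property
    def percent(self) -> int:
        """Nearest-percent report (e.g. 117/367 -> 32)."""
        return round(100 * self.n_direct / self.n_de)


def compute_rpkm(
    counts: Mapping[str, float],
    gene_lengths_bp: Mapping[str, float],
    library_size: float,
) -> dict[str, float]:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM = count / (length/1000) / (library_size/1e6).
    """
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    out: dict[str, float] = {}
    for gene, c in counts.items():
        length = gene_lengths_bp[gene]
        if length <= 0:
            raise ValueError(f"gene {gene}: non-positive length {length}")
        out[gene] = c / (length / 1000.0) / (library_size / 1e6)
    return out


def classify_de_direction(
    log2fc: float, fdr: float, fdr_max: float = 0.001, fc_min: float = 1.5
) -> str:
    """'up', 'down' or 'ns' under strict FDR < fdr_max and |FC| > fc_min."""
    if fdr < fdr_max and abs(log2fc) > math.log2(fc_min):
        return "up" if log2fc > 0 else "down"
    return "ns"


def select_de_genes(
    table: pd.DataFrame, fdr_max: float = 0.001, fc_min: float = 1.5
) -> tuple[list[str], list[str]]:
    """Split a DE table into (up, down) gene lists.

    Thresholds follow the strict convention FDR < fdr_max (a gene at
    exactly the cutoff is excluded) and fold change > fc_min, compared
    symmetrically in log2 space.
    """
    missing = {"gene", "log2fc", "fdr"} - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    up, down = [], []
    for row in table.itertuples():
        direction = classify_de_direction(row.log2fc, row.fdr, fdr_max, fc_min)
        if direction == "up":
            up.append(row.gene)
        elif direction == "down":
            down.append(row.gene)
    return up, down


def direct_target_fraction(
    de_genes: Sequence[str], assignments: Sequence[GeneAssignment]
) -> TargetOverlapResult:
    """Fraction of DE genes annotated to any peak (direct targets).

    A DE gene counts as direct if it appears as any gene id in any
    assignment; duplicate assignments of a gene to several peaks count
    once.
    """
    if len(de_genes) == 0:
        raise ValueError("empty DE gene list")
    assigned = {g for a in assignments for g in a.gene_ids}
    direct = sorted(set(de_genes) & assigned)
    return TargetOverlapResult(
        n_de=len(set(de_genes)), n_direct=len(direct), genes=tuple(direct)
    )
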