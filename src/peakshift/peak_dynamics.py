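"""Peak standardization, repeat filtering, and condition-occupancy classification.

The central operation here is :func:`classify_occupancy`: peaks from all
conditions are merged into a non-redundant universe of occupied regions,
and each region receives a presence/absence pattern across conditions
(e.g. bound only before stimulation, only after, or in both). This is the
clustering that separates condition-specific from constitutive binding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from pyfaidx import Fasta

from .io_genomics import GenomicInterval, Peak, PeakSet, read_bedgraph

__all__ = [
    "OccupancyClassification",
    "OccupancyMatrix",
    "standardize_peaks",
    "filter_repeat_peaks",
    "classify_occupancy",
    "pattern_counts",
    "occupancy_heatmap_matrix",
]


@dataclass(frozen=True)
class OccupancyClassification:
    """One merged occupied region with its cross-condition occupancy pattern."""

    region: Peak
    conditions: tuple[str, ...]
    pattern: tuple[int, ...]
    cluster_label: str

    def __post_init__(self) -> None:
        if sum(self.pattern) < 1:
            raise ValueError("occupancy pattern must have >= 1 set bit")


@dataclass
class OccupancyMatrix:
    """Per-region, per-condition binned coverage over a fixed window.

    ``values[c]`` has shape (n_regions, window_bp // bin_bp); rows follow
    ``rows`` ordering (grouped by cluster label, then by first-condition
    signal descending).
    """

    rows: list[OccupancyClassification]
    conditions: tuple[str, ...]
    values: dict[str, np.ndarray]
    window_bp: int
    bin_bp: int


def cluster_label_for(pattern: Sequence[int], conditions: Sequence[str]) -> str:
    """Human-readable label for an occupancy pattern.

    One condition only -> "<cond>_only"; all conditions -> "shared";
    anything in between -> "+"-joined member list.
    """
    members = [c for c, bit in zip(conditions, pattern) if bit]
    if len(members) == 1:
        return f"{members[0]}_only"
    if len(members) == len(conditions):
        return "shared"
    return "+".join(members)


def standardize_peaks(
    peak_set: PeakSet,
    width: int = 400,
    chrom_sizes: Mapping[str, int] | None = None,
) -> PeakSet:
    """Re-center every peak on its summit at a fixed width.

    Each peak becomes [summit - width/2, summit + width/2), clamped at
    chromosome bounds when lengths are known; the summit itself is
    unchanged. Fixed-width peaks make overlap and motif statistics
    comparable across datasets with different peak-caller geometries.
    """
    if width % 2 != 0 or width < 2:
        raise ValueError(f"width must be even and >= 2, got {width}")
    half = width // 2
    out: list[Peak] = []
    for p in peak_set:
        start = p.summit - half
        end = p.summit + half
        if chrom_sizes is not None and p.chrom in chrom_sizes:
            start = max(0, start)
            end = min(chrom_sizes[p.chrom], end)
        else:
            start = max(0, start)
        out.append(
            Peak(GenomicInterval(p.chrom, start, end, p.interval.strand),
                 p.summit, p.score, p.name)
        )
    return PeakSet(label=peak_set.label, peaks=out, genome_id=peak_set.genome_id)


def _repeat_fraction_from_fasta(fasta: Fasta, peak: Peak) -> float:
    seq = str(fasta[peak.chrom][peak.start:peak.end])
    if not seq:
        return 0.0
    return sum(1 for b in seq if b.islower()) / len(seq)


def _repeat_fraction_from_bed(trees: dict[str, IntervalTree], peak: Peak) -> float:
    tree = trees.get(peak.chrom)
    if tree is None:
        return 0.0
    covered = 0
    for iv in tree.overlap(peak.start, peak.end):
        covered += min(iv.end, peak.end) - max(iv.begin, peak.start)
    return covered / (peak.end - peak.start)


def filter_repeat_peaks(
    peak_set: PeakSet,
    genome_fasta: str | Path | Fasta | None = None,
    repeat_bed: str | Path | Sequence[GenomicInterval] | None = None,
    max_repeat_fraction: float = 0.40,
) -> tuple[PeakSet, PeakSet]:
    """Split peaks into (kept, removed) by repetitive-sequence content.

    A peak is removed iff strictly more than ``max_repeat_fraction`` of its
    bases are repetitive ("more than 40%" by default, so exactly 40% is
    kept). Repeats come from soft-masked lowercase bases in the genome
    FASTA, or from an explicit repeat interval BED, which takes precedence.
    """
    if genome_fasta is None and repeat_bed is None:
        raise ValueError("need a repeat source: soft-masked FASTA or repeat BED")
    trees: dict[str, IntervalTree] | None = None
    fasta: Fasta | None = None
    if repeat_bed is not None:
        if isinstance(repeat_bed, (str, Path)):
            df = pd.read_csv(
                repeat_bed, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
                names=["chrom", "start", "end"], dtype={"chrom": str},
            )
            intervals = [
                GenomicInterval(r.chrom, int(r.start), int(r.end))
                for r in df.itertuples()
            ]
        else:
            intervals = list(repeat_bed)
        trees = {}
        for iv in intervals:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
        for t in trees.values():
            t.merge_overlaps()
    else:
        fasta = genome_fasta if isinstance(genome_fasta, Fasta) else Fasta(
            str(genome_fasta), as_raw=True, sequence_always_upper=False
        )
    kept: list[Peak] = []
    removed: list[Peak] = []
    for p in peak_set:
        if trees is not None:
            frac = _repeat_fraction_from_bed(trees, p)
        else:
            assert fasta is not None
            if p.chrom not in fasta:
                raise KeyError(f"chromosome {p.chrom!r} absent from repeat source")
            frac = _repeat_fraction_from_fasta(fasta, p)
        (removed if frac > max_repeat_fraction else kept).append(p)
    return (
        PeakSet(label=peak_set.label, peaks=kept, genome_id=peak_set.genome_id),
        PeakSet(label=f"{peak_set.label}_repeat_filtered", peaks=removed,
                genome_id=peak_set.genome_id),
    )


def _merge_union_regions(peak_sets: Sequence[PeakSet]) -> list[list[Peak]]:
    """Merge all peaks of all sets into groups of mutually overlapping peaks."""
    all_peaks = [p for ps in peak_sets for p in ps]
    all_peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    groups: list[list[Peak]] = []
    cur: list[Peak] = []
    cur_chrom, cur_end = None, -1
    for p in all_peaks:
        if cur and p.chrom == cur_chrom and p.start < cur_end:
            cur.append(p)
            cur_end = max(cur_end, p.end)
        else:
            if cur:
                groups.append(cur)
            cur = [p]
            cur_chrom, cur_end = p.chrom, p.end
    if cur:
        groups.append(cur)
    return groups


def classify_occupancy(
    peak_sets: Sequence[PeakSet],
    min_overlap_bp: int = 1,
) -> list[OccupancyClassification]:
    """Classify merged binding regions by their occupancy across conditions.

    The union of all standardized peaks is merged into non-redundant
    regions; a region's bit for condition ``c`` is set iff at least one peak
    of ``c`` overlaps the region by ``min_overlap_bp`` or more. The region
    summit and score are taken from the highest-score contributing peak.
    """
    if len(peak_sets) < 2:
        raise ValueError("need >= 2 condition peak sets")
    conditions = tuple(ps.label for ps in peak_sets)
    for ps in peak_sets:
        if len(ps) == 0:
            warnings.warn(
                f"condition {ps.label!r} has no peaks; its pattern bit is always 0",
                stacklevel=2,
            )
    trees: dict[str, dict[str, IntervalTree]] = {}
    for ps in peak_sets:
        per_chrom: dict[str, IntervalTree] = {}
        for p in ps:
            per_chrom.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
        trees[ps.label] = per_chrom

    out: list[OccupancyClassification] = []
    for idx, group in enumerate(_merge_union_regions(peak_sets)):
        chrom = group[0].chrom
        start = min(p.start for p in group)
        end = max(p.end for p in group)
        best = max(group, key=lambda p: p.score)
        pattern = []
        for cond in conditions:
            tree = trees[cond].get(chrom)
            hit = 0
            if tree is not None:
                for iv in tree.overlap(start, end):
                    if min(iv.end, end) - max(iv.begin, start) >= min_overlap_bp:
                        hit = 1
                        break
            pattern.append(hit)
        region = Peak(
            GenomicInterval(chrom, start, end), best.summit, best.score,
            name=f"region_{idx}",
        )
        out.append(
            OccupancyClassification(
                region=region,
                conditions=conditions,
                pattern=tuple(pattern),
                cluster_label=cluster_label_for(pattern, conditions),
            )
        )
    return out


def pattern_counts(classified: Sequence[OccupancyClassification]) -> dict[str, int]:
    """Region counts per cluster label."""
    counts: dict[str, int] = {}
    for c in classified:
        counts[c.cluster_label] = counts.get(c.cluster_label, 0) + 1
    return counts


def _binned_coverage(
    track: pd.DataFrame, chrom: str, wstart: int, wend: int, bin_bp: int
) -> np.ndarray:
    """Mean coverage per bin over [wstart, wend) from a sorted bedGraph."""
    nbins = (wend - wstart) // bin_bp
    out = np.zeros(nbins)
    sub = track[track["chrom"] == chrom]
    if sub.empty:
        return out
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    vals = sub["value"].to_numpy()
    lo = np.searchsorted(ends, wstart, side="right")
    hi = np.searchsorted(starts, wend, side="left")
    for s, e, v in zip(starts[lo:hi], ends[lo:hi], vals[lo:hi]):
        if v == 0:
            continue
        a, b = max(s, wstart), min(e, wend)
        if a >= b:
            continue
        first = (a - wstart) // bin_bp
        last = (b - 1 - wstart) // bin_bp
        for bi in range(first, last + 1):
            ba = wstart + bi * bin_bp
            bb = ba + bin_bp
            out[bi] += v * (min(b, bb) - max(a, ba))
    return out / bin_bp


def occupancy_heatmap_matrix(
    classified: Sequence[OccupancyClassification],
    coverage_tracks: Mapping[str, pd.DataFrame | str | Path],
    window_bp: int = 5000,
    bin_bp: int = 50,
) -> OccupancyMatrix:
    """Build the per-condition signal matrix behind an occupancy heatmap.

    For each classified region, mean coverage per ``bin_bp`` bin is computed
    in a ``window_bp`` window centered on the region summit, scaled
    per-million (track values multiplied by 1e6 / total track signal).
    Rows are grouped by cluster label and ordered by descending
    first-condition signal within each group.
    """
    if window_bp % bin_bp != 0:
        raise ValueError(f"window_bp {window_bp} not divisible by bin_bp {bin_bp}")
    if not classified:
        raise ValueError("no classified regions supplied")
    conditions = classified[0].conditions
    tracks: dict[str, pd.DataFrame] = {}
    for cond in conditions:
        t = coverage_tracks[cond]
        df = t if isinstance(t, pd.DataFrame) else read_bedgraph(t)
        tracks[cond] = df.sort_values(["chrom", "start"]).reset_index(drop=True)

    scales = {}
    for cond, df in tracks.items():
        total = float(((df["end"] - df["start"]) * df["value"]).sum())
        scales[cond] = 1e6 / total if total > 0 else 0.0

    half = window_bp // 2
    raw: dict[str, list[np.ndarray]] = {c: [] for c in conditions}
    for region in classified:
        center = region.region.summit
        for cond in conditions:
            vec = _binned_coverage(
                tracks[cond], region.region.chrom, center - half, center + half,
                bin_bp,
            )
            raw[cond].append(vec * scales[cond])

    first = conditions[0]
    order = sorted(
        range(len(classified)),
        key=lambda i: (classified[i].cluster_label, -float(raw[first][i].sum())),
    )
    values = {c: np.vstack([raw[c][i] for i in order]) for c in conditions}
    rows = [classified[i] for i in order]
    return OccupancyMatrix(
        rows=rows, conditions=conditions, values=values,
        window_bp=window_bp, bin_bp=bin_bp,
    )
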