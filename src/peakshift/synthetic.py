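"""Seeded synthetic-data generator with machine-readable ground truth.

Emulates the structure of a two-condition differential-occupancy ChIP-seq
study: a toy genome with soft-masked "repeat" blocks, planted binding
regions with known condition membership, planted motif instances (an
architectural-factor motif with an ETS partner at fixed spacing in
condition-A-specific regions; a central GAS site in condition-B-specific
regions), per-condition peak sets with controllable noise, coverage
tracks, gene models near regions, and a differential-expression table
correlated with peak proximity.

All generators are pure functions of (parameters, seed); consensus
sequences are planted verbatim (not sampled from the PWM) so recovery
tests are deterministic. A ``sample_motifs=True`` switch samples planted
sites from the PWM instead, for stochastic tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_genomics import (
    BASES,
    GeneModel,
    GenomicInterval,
    PWM,
    Peak,
    PeakSet,
    pwm_from_consensus,
)

__all__ = [
    "SyntheticGenome",
    "PlantedMotif",
    "RegionTruth",
    "SyntheticTruth",
    "MotifPlan",
    "builtin_motifs",
    "DEFAULT_MOTIF_PLAN",
    "generate_genome",
    "plant_regions",
    "generate_peak_sets",
    "generate_coverage_tracks",
    "generate_gene_models",
    "generate_de_table",
]

# Consensus strings for the bundled synthetic motifs. The architectural
# motif is long and information-rich (CTCF-like), the ETS motif carries the
# GGAA core, and the GAS motif is the STAT consensus TTCnnnGAA with a fixed
# spacer so planting is deterministic.
CONSENSUS = {
    "CTCF": "CCACCAGGGGGCGCTA",
    "ETS": "ACAGGAAGTG",
    "GAS": "TTCCAGGAA",
}


def builtin_motifs(pseudocount: float = 0.1, match_prob: float = 0.91) -> dict[str, PWM]:
    """The bundled CTCF / ETS / GAS position weight matrices."""
    return {
        mid: pwm_from_consensus(mid, cons, match_prob=match_prob,
                                pseudocount=pseudocount)
        for mid, cons in CONSENSUS.items()
    }


@dataclass
class SyntheticGenome:
    """A toy genome: chromosome name -> sequence (mutable list planting)."""

    sequences: dict[str, str]
    gc: float
    mask_fraction: float
    seed: int

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def write_fasta(self, path: str | Path, width: int = 80) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
        return path


@dataclass(frozen=True)
class PlantedMotif:
    motif_id: str
    chrom: str
    start: int  # absolute, 0-based
    strand: str
    partner_gap: int | None = None  # gap to the next planted partner, if any


@dataclass(frozen=True)
class RegionTruth:
    name: str
    chrom: str
    center: int
    pattern: str  # condition membership, e.g. "A", "B", "AB"
    motifs: tuple[PlantedMotif, ...] = ()


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic dataset."""

    regions: list[RegionTruth]
    conditions: tuple[str, ...]
    params: dict = field(default_factory=dict)
    de_targets: list[str] = field(default_factory=list)
    gene_region: dict[str, str] = field(default_factory=dict)  # gene -> region

    def to_json(self, path: str | Path) -> None:
        payload = {
            "conditions": list(self.conditions),
            "params": self.params,
            "de_targets": self.de_targets,
            "gene_region": self.gene_region,
            "regions": [asdict(r) for r in self.regions],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        regions = [
            RegionTruth(
                name=r["name"], chrom=r["chrom"], center=r["center"],
                pattern=r["pattern"],
                motifs=tuple(PlantedMotif(**m) for m in r["motifs"]),
            )
            for r in payload["regions"]
        ]
        return cls(
            regions=regions,
            conditions=tuple(payload["conditions"]),
            params=payload["params"],
            de_targets=payload["de_targets"],
            gene_region=payload["gene_region"],
        )


@dataclass(frozen=True)
class MotifPlan:
    """What to plant in regions of one occupancy pattern.

    ``secondary`` + ``spacing_bp`` plants primary and secondary consensus
    on the same strand separated by exactly ``spacing_bp``; a lone
    ``primary`` is planted at the region center.
    """

    primary: str
    secondary: str | None = None
    spacing_bp: int | None = None


DEFAULT_MOTIF_PLAN: dict[str, MotifPlan] = {
    "A": MotifPlan("CTCF", "ETS", 7),
    "B": MotifPlan("GAS"),
}


def generate_genome(
    n_chrom: int = 2,
    chrom_len: int = 500_000,
    gc: float = 0.5,
    mask_fraction: float = 0.0,
    seed: int = 0,
    mask_block_bp: int = 500,
) -> SyntheticGenome:
    """I.i.d. random genome at a given GC content, with ``mask_fraction``
    of bases lowercased in contiguous blocks as synthetic repeats."""
    if not 0 < gc < 1:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    if chrom_len < 10_000:
        raise ValueError("chrom_len must be >= 10000")
    if not 0 <= mask_fraction < 1:
        raise ValueError("mask_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sequences: dict[str, str] = {}
    for c in range(n_chrom):
        codes = rng.choice(4, size=chrom_len, p=probs)
        seq = np.frombuffer(BASES.encode(), dtype=np.uint8)[codes]
        if mask_fraction > 0:
            n_blocks = int(round(mask_fraction * chrom_len / mask_block_bp))
            lower = seq.copy()
            mask = np.zeros(chrom_len, dtype=bool)
            for _ in range(n_blocks):
                s = int(rng.integers(0, chrom_len - mask_block_bp))
                mask[s : s + mask_block_bp] = True
            lower[mask] += 32  # ASCII lowercase
            seq = lower
        sequences[f"chr{c + 1}"] = seq.tobytes().decode()
    return SyntheticGenome(
        sequences=sequences, gc=gc, mask_fraction=mask_fraction, seed=seed
    )


def _sample_site(pwm: PWM, rng: np.random.Generator) -> str:
    return "".join(
        BASES[rng.choice(4, p=row / row.sum())] for row in pwm.matrix
    )


def plant_regions(
    genome: SyntheticGenome,
    n_per_pattern: Mapping[str, int],
    motif_plan: Mapping[str, MotifPlan] | None = None,
    seed: int = 0,
    min_separation_bp: int = 1000,
    region_width: int = 400,
    sample_motifs: bool = False,
) -> SyntheticTruth:
    """Choose non-overlapping region centers and plant motif instances.

    Regions are laid out left to right with random gaps of at least
    ``min_separation_bp`` between region edges, shuffled across patterns so
    patterns are not spatially ordered. Planted consensus (or PWM-sampled)
    sequences overwrite the genome in place; every planted coordinate is
    recorded in the returned truth object.
    """
    if motif_plan is None:
        motif_plan = DEFAULT_MOTIF_PLAN
    rng = np.random.default_rng(seed)
    motifs = builtin_motifs()
    conditions = tuple(sorted({c for pat in n_per_pattern for c in pat}))

    labels = [pat for pat, n in sorted(n_per_pattern.items()) for _ in range(n)]
    rng.shuffle(labels)
    n_regions = len(labels)
    if n_regions == 0:
        return SyntheticTruth(regions=[], conditions=conditions,
                              params={"seed": seed})

    chroms = list(genome.sequences)
    sizes = genome.chrom_sizes
    usable = sum(sizes.values())
    need = n_regions * (region_width + min_separation_bp) + 2 * min_separation_bp
    if need > usable:
        raise ValueError(
            f"insufficient genome space: need ~{need} bp, have {usable} bp"
        )

    # spread regions across chromosomes proportionally to length
    per_chrom: dict[str, int] = {}
    remaining = n_regions
    for i, c in enumerate(chroms):
        if i == len(chroms) - 1:
            per_chrom[c] = remaining
        else:
            k = int(round(n_regions * sizes[c] / usable))
            k = min(k, remaining)
            per_chrom[c] = k
            remaining -= k

    seqs = {c: np.frombuffer(s.encode(), dtype=np.uint8).copy()
            for c, s in genome.sequences.items()}

    regions: list[RegionTruth] = []
    idx = 0
    for chrom in chroms:
        k = per_chrom[chrom]
        if k == 0:
            continue
        stride = region_width + min_separation_bp
        span = sizes[chrom] - 2 * min_separation_bp
        if k * stride > span:
            raise ValueError(f"insufficient space on {chrom} for {k} regions")
        slack = span - k * stride
        # random extra gaps summing to <= slack
        extras = np.sort(rng.integers(0, slack + 1, size=k)) if slack > 0 else np.zeros(k, dtype=int)
        pos = min_separation_bp
        starts = []
        prev_extra = 0
        for j in range(k):
            pos += int(extras[j]) - prev_extra
            prev_extra = int(extras[j])
            starts.append(pos)
            pos += stride
        for s in starts:
            pattern = labels[idx]
            center = s + region_width // 2
            planted: list[PlantedMotif] = []
            plan = motif_plan.get(pattern)
            if plan is not None:
                ppwm = motifs[plan.primary]
                psite = (_sample_site(ppwm, rng) if sample_motifs
                         else ppwm.consensus)
                if plan.secondary is not None:
                    spwm = motifs[plan.secondary]
                    gap = plan.spacing_bp or 0
                    pair_len = len(psite) + gap + len(spwm)
                    pstart = center - pair_len // 2
                    ssite = (_sample_site(spwm, rng) if sample_motifs
                             else spwm.consensus)
                    sstart = pstart + len(psite) + gap
                    _write(seqs[chrom], pstart, psite)
                    _write(seqs[chrom], sstart, ssite)
                    planted.append(PlantedMotif(plan.primary, chrom, pstart, "+", gap))
                    planted.append(PlantedMotif(plan.secondary, chrom, sstart, "+"))
                else:
                    pstart = center - len(psite) // 2
                    _write(seqs[chrom], pstart, psite)
                    planted.append(PlantedMotif(plan.primary, chrom, pstart, "+"))
            regions.append(RegionTruth(
                name=f"true_{idx}", chrom=chrom, center=center,
                pattern=pattern, motifs=tuple(planted),
            ))
            idx += 1

    genome.sequences = {c: a.tobytes().decode() for c, a in seqs.items()}
    return SyntheticTruth(
        regions=regions,
        conditions=conditions,
        params={
            "seed": seed,
            "n_per_pattern": dict(n_per_pattern),
            "region_width": region_width,
            "min_separation_bp": min_separation_bp,
            "spacing_bp": {p: mp.spacing_bp for p, mp in motif_plan.items()},
        },
    )


def _write(arr: np.ndarray, start: int, site: str) -> None:
    arr[start : start + len(site)] = np.frombuffer(site.encode(), dtype=np.uint8)


def generate_peak_sets(
    truth: SyntheticTruth,
    genome: SyntheticGenome | None = None,
    width_jitter_bp: int = 100,
    summit_noise_bp: float = 0.0,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    seed: int = 0,
    base_width: int = 400,
) -> dict[str, PeakSet]:
    """Emit one raw peak set per condition from the region truth.

    Each truth region produces a peak in every condition of its pattern
    (dropped with probability ``fn_rate`` per condition); the peak summit
    is the planted center plus rounded Normal(0, summit_noise_bp) noise and
    the raw width is ``base_width`` plus a symmetric jitter, so that
    downstream summit standardization is exercised. False-positive peaks
    (``fp_rate`` x number of true peaks, per condition) are placed
    uniformly at least ``min_separation_bp`` away from any truth region.
    """
    for r, nm in ((fp_rate, "fp_rate"), (fn_rate, "fn_rate")):
        if not 0 <= r <= 1:
            raise ValueError(f"{nm} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sizes = genome.chrom_sizes if genome is not None else {}
    sep = int(truth.params.get("min_separation_bp", 1000))
    out: dict[str, list[Peak]] = {c: [] for c in truth.conditions}
    for region in truth.regions:
        for cond in truth.conditions:
            if cond not in region.pattern:
                continue
            if fn_rate > 0 and rng.random() < fn_rate:
                continue
            summit = region.center
            if summit_noise_bp > 0:
                summit += int(round(rng.normal(0, summit_noise_bp)))
            half = base_width // 2 + int(rng.integers(0, width_jitter_bp + 1))
            start = max(0, summit - half)
            end = summit + half
            if region.chrom in sizes:
                end = min(end, sizes[region.chrom])
                summit = min(max(summit, start), end - 1)
            score = float(rng.uniform(5, 100))
            out[cond].append(Peak(
                GenomicInterval(region.chrom, start, end), summit, score,
                name=f"{cond}_{region.name}",
            ))
    # false positives, uniform in unplanted space
    if fp_rate > 0 and genome is not None:
        centers = {}
        for r in truth.regions:
            centers.setdefault(r.chrom, []).append(r.center)
        for cond in truth.conditions:
            n_fp = int(round(fp_rate * len(out[cond])))
            placed = 0
            attempts = 0
            while placed < n_fp and attempts < 100 * n_fp + 100:
                attempts += 1
                chrom = list(sizes)[int(rng.integers(0, len(sizes)))]
                summit = int(rng.integers(sep, sizes[chrom] - sep))
                if any(abs(summit - c) < sep for c in centers.get(chrom, [])):
                    continue
                half = base_width // 2 + int(rng.integers(0, width_jitter_bp + 1))
                out[cond].append(Peak(
                    GenomicInterval(chrom, max(0, summit - half),
                                    min(sizes[chrom], summit + half)),
                    summit, float(rng.uniform(5, 100)),
                    name=f"{cond}_fp_{placed}",
                ))
                placed += 1
    return {
        c: PeakSet(label=c, peaks=sorted(
            peaks, key=lambda p: (p.chrom, p.start)
        ))
        for c, peaks in out.items()
    }


def generate_coverage_tracks(
    truth: SyntheticTruth,
    peak_height: float = 20.0,
    profile_halfwidth: int = 400,
    bin_bp: int = 50,
    background: float = 0.0,
) -> dict[str, pd.DataFrame]:
    """Piecewise-constant bedGraph tracks: a triangular signal profile
    centered on every region occupied in each condition."""
    tracks: dict[str, list[tuple[str, int, int, float]]] = {
        c: [] for c in truth.conditions
    }
    for region in truth.regions:
        for cond in truth.conditions:
            if cond not in region.pattern:
                continue
            for b0 in range(-profile_halfwidth, profile_halfwidth, bin_bp):
                mid = abs(b0 + bin_bp / 2)
                v = background + peak_height * max(0.0, 1 - mid / profile_halfwidth)
                if v > 0:
                    tracks[cond].append(
                        (region.chrom, region.center + b0,
                         region.center + b0 + bin_bp, v)
                    )
    out = {}
    for cond, rows in tracks.items():
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        out[cond] = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return out


def generate_gene_models(
    truth: SyntheticTruth,
    genome: SyntheticGenome,
    target_pattern: str = "A",
    gene_length_bp: int = 5000,
    tss_offset_bp: int = 1000,
    n_background: int = 50,
    seed: int = 0,
) -> tuple[list[GeneModel], SyntheticTruth]:
    """Place one gene per ``target_pattern`` region, plus background genes
    far from any region.

    Each target gene's TSS sits ``tss_offset_bp`` downstream of its region
    center on the + strand, so the gene's promoter window overlaps the
    region's peak and tiered mapping links every region to its own gene
    deterministically (promoter tier). Near a chromosome end the gene is
    placed upstream on the - strand instead, preserving the promoter
    overlap. The truth object records the gene -> region map.
    """
    rng = np.random.default_rng(seed)
    sizes = genome.chrom_sizes
    genes: list[GeneModel] = []
    # zones a background gene must stay 60 kb clear of (regions + target genes)
    zones: dict[str, list[tuple[int, int]]] = {c: [] for c in sizes}
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in sizes}
    for region in truth.regions:
        zones[region.chrom].append(
            (region.center - 500, region.center + 500)
        )
    gi = 0
    for region in truth.regions:
        if region.pattern != target_pattern:
            continue
        start = region.center + tss_offset_bp
        end = start + gene_length_bp
        strand = "+"
        if end > sizes[region.chrom]:
            strand = "-"
            end = region.center - tss_offset_bp + 1
            start = end - gene_length_bp
        gid = f"gene_t{gi}"
        genes.append(GeneModel(gid, GenomicInterval(region.chrom, start, end, strand), strand))
        truth.gene_region[gid] = region.name
        zones[region.chrom].append((start, end))
        placed[region.chrom].append((start, end))
        gi += 1
    # background genes: non-overlapping, outside the flank window of any zone
    for b in range(n_background):
        for _ in range(200):
            chrom = list(sizes)[int(rng.integers(0, len(sizes)))]
            start = int(rng.integers(0, sizes[chrom] - gene_length_bp))
            end = start + gene_length_bp
            near_zone = any(
                start - 60_000 < e and s < end + 60_000
                for s, e in zones[chrom]
            )
            overlaps = any(
                start < e and s < end for s, e in placed[chrom]
            )
            if not near_zone and not overlaps:
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(GeneModel(
                    f"gene_bg{b}", GenomicInterval(chrom, start, end, strand),
                    strand,
                ))
                placed[chrom].append((start, end))
                break
    return genes, truth


def generate_de_table(
    genes: Sequence[GeneModel],
    target_gene_ids: Sequence[str],
    effect_log2fc: float = 1.5,
    effect_sd: float = 0.2,
    null_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """A DE table where target genes are truly differential.

    Targets draw log2FC ~ Normal(effect_log2fc, effect_sd) and FDR
    ~ Uniform(0, 1e-6) (far below the 1e-3 selection cutoff); non-targets
    draw log2FC ~ Normal(0, null_sd) and FDR ~ Uniform(0, 1).
    """
    targets = set(target_gene_ids)
    unknown = targets - {g.gene_id for g in genes}
    if unknown:
        raise ValueError(f"target genes not in gene set: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    for g in genes:
        if g.gene_id in targets:
            lfc = rng.normal(effect_log2fc, effect_sd)
            fdr = rng.uniform(0, 1e-6)
        else:
            lfc = rng.normal(0, null_sd)
            fdr = rng.uniform(0, 1)
        rows.append((g.gene_id, float(lfc), float(fdr)))
    return pd.DataFrame(rows, columns=["gene", "log2fc", "fdr"])
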