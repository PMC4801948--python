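"""End-to-end orchestration of the differential-occupancy workflow.

``run_pipeline`` executes: standardize -> repeat-filter -> occupancy
classification -> two-set Venn / colocalization matrix -> feature
distribution -> motif centrality and spacing -> tiered gene mapping ->
DE integration, writing one tab-delimited output per stage plus a summary
table. Every output carries its parameters in '#'-prefixed metadata
header lines so results are self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from . import colocalization as coloc
from . import expression as expr
from . import gene_mapping as gm
from . import motif_analysis as ma
from . import peak_dynamics as pd_mod
from .io_genomics import (
    PeakSet,
    extract_sequences,
    read_de_table,
    read_gene_table,
    read_meme_pwm,
    read_peaks,
    write_peaks,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and cause."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs and parameters for one pipeline run.

    ``condition_peaks`` maps condition label -> peak file (order defines
    the occupancy pattern bit order); ``extra_tf_peaks`` adds further TF
    peak sets to the colocalization correlation matrix.
    """

    condition_peaks: dict[str, str] = field(default_factory=dict)
    peak_format: str = "narrowPeak"
    genome_fasta: str | None = None
    repeat_bed: str | None = None
    gene_table: str | None = None
    motif_file: str | None = None
    de_table: str | None = None
    extra_tf_peaks: dict[str, str] = field(default_factory=dict)
    coverage_tracks: dict[str, str] = field(default_factory=dict)
    outdir: str = "peakshift_out"
    genome_build: str = ""

    width: int = 400
    max_repeat_fraction: float = 0.40
    min_overlap_bp: int = 1
    promoter_up: int = 2000
    promoter_down: int = 500
    flank_bp: int = 50000
    fdr_max: float = 0.001
    fc_min: float = 1.5
    max_gap: int = 150
    summit_window: int = 100
    primary_motif: str = "CTCF"
    secondary_motif: str = "ETS"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if len(self.condition_peaks) < 2:
            raise ValueError("need >= 2 condition peak files")
        for label, p in {**self.condition_peaks, **self.extra_tf_peaks}.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"peak file for {label!r} not found: {p}")
        for name in ("genome_fasta", "repeat_bed", "gene_table", "motif_file",
                     "de_table"):
            val = getattr(self, name)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"{name} not found: {val}")

    def params(self) -> dict[str, Any]:
        d = asdict(self)
        for k in ("condition_peaks", "extra_tf_peaks", "coverage_tracks"):
            d.pop(k)
        return d


def _header(config: RunConfig) -> str:
    return "".join(
        f"# {k}={v}\n" for k, v in sorted(config.params().items())
    )


def _write_tsv(path: Path, config: RunConfig, columns: list[str],
               rows: list[tuple]) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run all applicable stages; returns the summary dict written to
    ``summary.tsv``. Stages whose inputs are not configured are skipped."""
    try:
        config.validate()
    except Exception as exc:
        raise PipelineError("config", str(exc)) from exc
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {}

    # --- load + standardize -------------------------------------------------
    try:
        chrom_sizes = None
        fasta = None
        if config.genome_fasta:
            from pyfaidx import Fasta

            fasta = Fasta(config.genome_fasta, as_raw=True,
                          sequence_always_upper=False)
            chrom_sizes = {name: len(fasta[name]) for name in fasta.keys()}
        conditions: dict[str, PeakSet] = {}
        for label, path in config.condition_peaks.items():
            raw = read_peaks(path, format=config.peak_format, label=label,
                             genome_id=config.genome_build)
            conditions[label] = pd_mod.standardize_peaks(
                raw, width=config.width, chrom_sizes=chrom_sizes
            )
            summary[f"n_peaks_raw.{label}"] = len(raw)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("standardize", str(exc)) from exc

    # --- repeat filtering ---------------------------------------------------
    try:
        if config.repeat_bed or config.genome_fasta:
            for label in list(conditions):
                kept, removed = pd_mod.filter_repeat_peaks(
                    conditions[label],
                    genome_fasta=fasta,
                    repeat_bed=config.repeat_bed,
                    max_repeat_fraction=config.max_repeat_fraction,
                )
                conditions[label] = kept
                summary[f"n_peaks_repeat_removed.{label}"] = len(removed)
        for label, ps in conditions.items():
            summary[f"n_peaks.{label}"] = len(ps)
            write_peaks(ps, outdir / f"peaks_{label}.narrowPeak")
    except Exception as exc:
        raise PipelineError("repeat_filter", str(exc)) from exc

    # --- occupancy classification -------------------------------------------
    try:
        classified = pd_mod.classify_occupancy(
            list(conditions.values()), min_overlap_bp=config.min_overlap_bp
        )
        counts = pd_mod.pattern_counts(classified)
        for label, n in sorted(counts.items()):
            summary[f"n_regions.{label}"] = n
        summary["n_regions.total"] = len(classified)
        _write_tsv(
            outdir / "classified_regions.tsv", config,
            ["region", "chrom", "start", "end", "summit", "pattern",
             "cluster_label"],
            [(c.region.name, c.region.chrom, c.region.start, c.region.end,
              c.region.summit, "".join(map(str, c.pattern)), c.cluster_label)
             for c in classified],
        )
    except Exception as exc:
        raise PipelineError("classify", str(exc)) from exc

    cond_labels = list(conditions)
    first, second = cond_labels[0], cond_labels[1]

    # --- venn + colocalization matrix ---------------------------------------
    try:
        venn = coloc.overlap_venn(conditions[first], conditions[second],
                                  min_overlap_bp=config.min_overlap_bp)
        summary[f"venn.{first}_only"] = venn.a_only
        summary[f"venn.{second}_only"] = venn.b_only
        summary[f"venn.both.{first}"] = venn.both_a
        summary[f"venn.both.{second}"] = venn.both_b
        summary[f"venn.fraction_{first}_in_{second}"] = round(
            venn.fraction_a_in_b, 4)
        summary[f"venn.fraction_{second}_in_{first}"] = round(
            venn.fraction_b_in_a, 4)
        all_sets = list(conditions.values()) + [
            pd_mod.standardize_peaks(
                read_peaks(p, format=config.peak_format, label=label),
                width=config.width, chrom_sizes=chrom_sizes,
            )
            for label, p in config.extra_tf_peaks.items()
        ]
        if len(all_sets) >= 2:
            cm = coloc.pairwise_overlap_correlation(
                all_sets, min_overlap_bp=config.min_overlap_bp
            )
            with open(outdir / "coloc_matrix.tsv", "w") as fh:
                fh.write(_header(config))
                fh.write("tf\t" + "\t".join(cm.labels) + "\n")
                for i, lab in enumerate(cm.labels):
                    fh.write(lab + "\t" + "\t".join(
                        f"{v:.4f}" for v in cm.r[i]) + "\n")
                fh.write("# leaf_order=" + ",".join(cm.ordered_labels) + "\n")
    except Exception as exc:
        raise PipelineError("colocalization", str(exc)) from exc

    # --- feature distribution ------------------------------------------------
    genes = None
    try:
        if config.gene_table:
            genes = read_gene_table(config.gene_table)
            rows = []
            dists = {}
            for label, ps in conditions.items():
                dist = coloc.feature_distribution(
                    ps, genes, promoter_up=config.promoter_up,
                    promoter_down=config.promoter_down,
                )
                dists[label] = dist
                for cat, n in dist.counts.items():
                    rows.append((label, cat, n, round(dist.fractions[cat], 4)))
                    summary[f"feature.{label}.{cat}"] = n
            _write_tsv(outdir / "feature_distribution.tsv", config,
                       ["condition", "category", "count", "fraction"], rows)
            try:
                summary["promoter_enrichment_ratio"] = round(
                    coloc.promoter_enrichment_ratio(dists[first], dists[second]),
                    4,
                )
            except ValueError:
                summary["promoter_enrichment_ratio"] = "NA"
    except Exception as exc:
        raise PipelineError("features", str(exc)) from exc

    # --- motif centrality + spacing ------------------------------------------
    try:
        if config.motif_file and config.genome_fasta:
            pwms = {p.id: p for p in read_meme_pwm(config.motif_file)}
            focus = [c for c in classified
                     if c.cluster_label == f"{first}_only"] or classified
            seqs = extract_sequences(
                fasta, [c.region for c in focus], mode="summit_window",
                window=config.width,
            )
            seqs = [s.upper() for s in seqs if len(s) == config.width]
            if config.primary_motif in pwms and seqs:
                cres = ma.central_enrichment(seqs, pwms[config.primary_motif])
                summary["centrality.motif"] = config.primary_motif
                summary["centrality.best_halfwidth"] = cres.best_halfwidth
                summary["centrality.hits_in_window"] = cres.hits_in_window
                summary["centrality.n"] = cres.n_sequences
                summary["centrality.p"] = f"{cres.p_value:.3e}"
            if (config.primary_motif in pwms and config.secondary_motif in pwms
                    and seqs):
                sres = ma.spacing_analysis(
                    seqs, pwms[config.primary_motif],
                    pwms[config.secondary_motif], max_gap=config.max_gap,
                )
                summary["spacing.best_gap"] = sres.best_gap
                summary["spacing.best_quadrant"] = sres.best_quadrant
                summary["spacing.count"] = sres.best_count
                summary["spacing.n_anchored"] = sres.n_anchored
                summary["spacing.p"] = f"{sres.p_value:.3e}"
                rows = [
                    (q, g, int(sres.gap_histogram[q][g]))
                    for q in ma.QUADRANTS
                    for g in range(sres.max_gap + 1)
                    if sres.gap_histogram[q][g] > 0
                ]
                _write_tsv(outdir / "spacing_histogram.tsv", config,
                           ["quadrant", "gap_bp", "count"], rows)
    except Exception as exc:
        raise PipelineError("motifs", str(exc)) from exc

    # --- gene mapping + DE integration ---------------------------------------
    assignments = None
    try:
        if genes is not None:
            focus = [c for c in classified
                     if c.cluster_label == f"{first}_only"]
            focus_set = PeakSet(
                label=f"{first}_only_regions",
                peaks=[c.region for c in focus],
            )
            assignments = gm.assign_peaks_to_genes(
                focus_set, genes, promoter_up=config.promoter_up,
                promoter_down=config.promoter_down, flank_bp=config.flank_bp,
            )
            tiers: dict[str, int] = {}
            for a in assignments:
                tiers[a.tier] = tiers.get(a.tier, 0) + 1
            for tier, n in sorted(tiers.items()):
                summary[f"gene_mapping.{tier}"] = n
            _write_tsv(
                outdir / "gene_assignments.tsv", config,
                ["peak", "tier", "genes", "distances_bp"],
                [(a.peak_name, a.tier, ",".join(a.gene_ids) or ".",
                  ",".join(map(str, a.distances)) or ".")
                 for a in assignments],
            )
    except Exception as exc:
        raise PipelineError("gene_mapping", str(exc)) from exc

    try:
        if config.de_table and assignments is not None:
            table = read_de_table(config.de_table)
            up, down = expr.select_de_genes(
                table, fdr_max=config.fdr_max, fc_min=config.fc_min
            )
            summary["de.n_up"] = len(up)
            summary["de.n_down"] = len(down)
            for name, lst in (("up", up), ("down", down)):
                if lst:
                    res = expr.direct_target_fraction(lst, assignments)
                    summary[f"de.direct_{name}"] = res.n_direct
                    summary[f"de.direct_{name}_fraction"] = res.fraction
                    summary[f"de.direct_{name}_percent"] = res.percent
    except Exception as exc:
        raise PipelineError("expression", str(exc)) from exc

    _write_tsv(outdir / "summary.tsv", config, ["key", "value"],
               sorted(summary.items()))
    return summary
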