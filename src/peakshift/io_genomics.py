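"""Readers/writers for genomic formats and the shared coordinate model.

All coordinates are 0-based half-open (BED convention) throughout the
package; conversion to 1-based happens only in human-readable reports.

Formats handled here: BED6 and ENCODE narrowPeak for peaks, indexed FASTA
for genome sequence (via pyfaidx), a tab-delimited gene table, MEME minimal
format for position weight matrices, and tab-delimited differential
expression tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "GeneModel",
    "PWM",
    "read_peaks",
    "write_peaks",
    "read_gene_table",
    "write_gene_table",
    "read_meme_pwm",
    "write_meme_pwm",
    "pwm_from_consensus",
    "extract_sequences",
    "read_de_table",
    "read_bedgraph",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak: an interval plus its summit (bp of maximal signal)."""

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside peak "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class PeakSet:
    """An ordered, named collection of peaks (one TF/condition)."""

    label: str
    peaks: list[Peak] = field(default_factory=list)
    genome_id: str = ""

    def __post_init__(self) -> None:
        names = [p.name for p in self.peaks if p.name != "."]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate peak names in set {self.label!r}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)


@dataclass(frozen=True)
class GeneModel:
    """A gene body with its transcription start site.

    The TSS is the strand-aware 5' end: ``body.start`` for + strand genes
    and ``body.end - 1`` for - strand genes.
    """

    gene_id: str
    body: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.body.start if self.strand == "+" else self.body.end - 1


@dataclass
class PWM:
    """A position weight matrix: L x 4 probabilities over A, C, G, T.

    ``matrix`` rows are renormalized after adding ``pseudocount * background``
    so that log-odds are finite everywhere.
    """

    id: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")
        rowsums = self.matrix.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 0.1):
            raise FormatError(
                f"PWM {self.id}: probability row sums deviate from 1 by > 0.1"
            )
        # pseudocount regularization, then renormalize each row
        reg = self.matrix + self.pseudocount * self.background
        self.matrix = reg / reg.sum(axis=1, keepdims=True)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """L x 4 natural-log odds ln(p / background); -inf where p = 0."""
        with np.errstate(divide="ignore"):
            return np.log(self.matrix / self.background)

    @property
    def max_score(self) -> float:
        """Best attainable log-odds score (consensus score)."""
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


# ---------------------------------------------------------------------------
# peaks


def read_peaks(
    path: str | Path,
    format: Literal["bed6", "narrowPeak"] = "narrowPeak",
    label: str | None = None,
    genome_id: str = "",
) -> PeakSet:
    """Read a peak file into a :class:`PeakSet`.

    narrowPeak column 10 is the summit offset from ``start``; an offset of
    -1 (summit not called) falls back to the interval midpoint, as does the
    BED6 dialect, which carries no summit at all.
    """
    path = Path(path)
    want = 10 if format == "narrowPeak" else 6
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < want:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {want} columns for "
                    f"{format}, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3] if fields[3] else "."
                score = float(fields[4]) if fields[4] not in (".", "") else 0.0
                strand = fields[5] if fields[5] in ("+", "-", ".") else "."
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed line ({exc})") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            if format == "narrowPeak":
                try:
                    offset = int(fields[9])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: malformed summit offset {fields[9]!r}"
                    ) from exc
                summit = start + offset if offset >= 0 else (start + end) // 2
            else:
                summit = (start + end) // 2
            try:
                peaks.append(
                    Peak(GenomicInterval(chrom, start, end, strand), summit, score, name)
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(label=label or path.stem, peaks=peaks, genome_id=genome_id)


def write_peaks(
    peak_set: PeakSet,
    path: str | Path,
    format: Literal["bed6", "narrowPeak"] = "narrowPeak",
) -> None:
    """Write peaks as BED6 or 10-column narrowPeak.

    narrowPeak preserves the summit exactly (column 10 offset); BED6 drops
    it, so a BED6 round trip recovers the summit only for peaks whose summit
    is the floor midpoint (e.g. after width standardization).
    """
    with open(path, "w") as fh:
        for i, p in enumerate(peak_set.peaks):
            name = p.name if p.name != "." else f"{peak_set.label}_{i}"
            base = [p.chrom, str(p.start), str(p.end), name, repr(p.score),
                    p.interval.strand]
            if format == "narrowPeak":
                base += ["0", "-1", "-1", str(p.summit - p.start)]
            fh.write("\t".join(base) + "\n")


# ---------------------------------------------------------------------------
# genes


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a tab-delimited gene table: gene_id, chrom, start, end, strand.

    Coordinates are 0-based half-open. Duplicate gene ids are an error.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            gene_id, chrom = fields[0], fields[1]
            try:
                start, end = int(fields[2]), int(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed coordinates") from exc
            strand = fields[4]
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            try:
                genes.append(GeneModel(gene_id, GenomicInterval(chrom, start, end, strand if strand in ("+", "-") else "."), strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.body.chrom}\t{g.body.start}\t{g.body.end}\t{g.strand}\n"
            )


# ---------------------------------------------------------------------------
# MEME minimal motif format


def read_meme_pwm(path: str | Path, pseudocount: float = 0.1) -> list[PWM]:
    """Parse MEME minimal format into a list of :class:`PWM`.

    Requires the "MEME version" header. An optional background-frequencies
    block is honoured; otherwise a uniform background is used. Rows are
    renormalized after pseudocount regularization (see :class:`PWM`).
    """
    path = Path(path)
    text = Path(path).read_text()
    if "MEME version" not in text:
        raise FormatError(f"{path}: missing 'MEME version' header")
    background = np.full(4, 0.25)
    bg_match = re.search(
        r"Background letter frequencies.*?\n\s*A\s+([\d.eE+-]+)\s+C\s+([\d.eE+-]+)"
        r"\s+G\s+([\d.eE+-]+)\s+T\s+([\d.eE+-]+)",
        text,
        re.S,
    )
    if bg_match:
        background = np.array([float(x) for x in bg_match.groups()])
        background = background / background.sum()
    pwms: list[PWM] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1] if len(parts) > 1 else f"motif_{len(pwms)}"
            # advance to the letter-probability header
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[j].strip().startswith("MOTIF"):
                    break
                j += 1
            if j >= len(lines) or not lines[j].strip().startswith(
                "letter-probability matrix"
            ):
                raise FormatError(f"{path}: motif {motif_id} has no probability matrix")
            rows = []
            j += 1
            while j < len(lines):
                vals = lines[j].split()
                if len(vals) == 4:
                    try:
                        rows.append([float(v) for v in vals])
                    except ValueError:
                        break
                    j += 1
                else:
                    break
            if not rows:
                raise FormatError(f"{path}: motif {motif_id} has an empty matrix")
            pwms.append(
                PWM(motif_id, np.array(rows), background=background,
                    pseudocount=pseudocount)
            )
            i = j
        else:
            i += 1
    return pwms


def write_meme_pwm(pwms: Sequence[PWM], path: str | Path) -> None:
    """Write PWMs in MEME minimal format (post-regularization probabilities)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write(
            "Background letter frequencies\n"
            f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def pwm_from_consensus(
    motif_id: str,
    consensus: str,
    match_prob: float = 0.91,
    background: np.ndarray | None = None,
    pseudocount: float = 0.1,
) -> PWM:
    """Build a PWM from a consensus string (IUPAC N allowed, uniform row)."""
    if background is None:
        background = np.full(4, 0.25)
    rows = []
    other = (1.0 - match_prob) / 3.0
    for base in consensus.upper():
        if base == "N":
            rows.append([0.25] * 4)
        elif base in _BASE_INDEX:
            row = [other] * 4
            row[_BASE_INDEX[base]] = match_prob
            rows.append(row)
        else:
            raise ValueError(f"unsupported consensus base {base!r}")
    return PWM(motif_id, np.array(rows), background=np.asarray(background),
               pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# sequence extraction


def extract_sequences(
    genome_fasta: str | Path | Fasta,
    intervals: Iterable[GenomicInterval | Peak],
    mode: str = "full",
    window: int = 100,
) -> list[str]:
    """Extract sequences for intervals from an indexed FASTA.

    ``mode="full"`` returns the interval sequence; ``mode="summit_window"``
    returns the half-open window [summit - w//2, summit + w//2), clamped at
    chromosome edges (so edge sequences may be shorter). Soft-masked
    lowercase bases are preserved.
    """
    fasta = genome_fasta if isinstance(genome_fasta, Fasta) else Fasta(
        str(genome_fasta), as_raw=True, sequence_always_upper=False
    )
    seqs: list[str] = []
    for item in intervals:
        if isinstance(item, Peak):
            chrom, start, end, summit = item.chrom, item.start, item.end, item.summit
        else:
            chrom, start, end = item.chrom, item.start, item.end
            summit = (start + end) // 2
        if chrom not in fasta:
            raise KeyError(f"chromosome {chrom!r} absent from FASTA")
        clen = len(fasta[chrom])
        if mode == "summit_window":
            start = summit - window // 2
            end = summit + window // 2
        start = max(0, start)
        end = min(clen, end)
        seqs.append(str(fasta[chrom][start:end]))
    return seqs


# ---------------------------------------------------------------------------
# tables


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited differential-expression table.

    Requires columns ``gene``, ``log2fc`` and ``fdr`` (case-insensitive;
    ``gene_id`` accepted for ``gene``).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    df = df.rename(columns={"gene_id": "gene"})
    missing = {"gene", "log2fc", "fdr"} - set(df.columns)
    if missing:
        raise FormatError(f"DE table missing columns: {sorted(missing)}")
    return df


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph coverage track (chrom, start, end, value)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )
    return df
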