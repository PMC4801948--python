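from __future__ import annotations

import numpy as np
import pytest

from peakshift.io_genomics import GeneModel, GenomicInterval, Peak, PeakSet
from peakshift.synthetic import builtin_motifs


@pytest.fixture(scope="session")
def motifs():
    return builtin_motifs()


@pytest.fixture
def write_fasta(tmp_path):
    """Write a dict of chrom -> sequence to an indexed FASTA file."""

    def _write(sequences: dict[str, str], name: str = "genome.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for chrom, seq in sequences.items():
                fh.write(f">{chrom}\n{seq}\n")
        return path

    return _write


def make_peak(chrom: str, start: int, end: int, summit: int | None = None,
              score: float = 1.0, name: str = ".") -> Peak:
    if summit is None:
        summit = (start + end) // 2
    return Peak(GenomicInterval(chrom, start, end), summit, score, name)


def make_set(label: str, triples, score: float = 1.0) -> PeakSet:
    peaks = [
        make_peak(t[0], t[1], t[2], score=score, name=f"{label}_{i}")
        for i, t in enumerate(triples)
    ]
    return PeakSet(label=label, peaks=peaks)


def make_gene(gene_id: str, chrom: str, start: int, end: int,
              strand: str = "+") -> GeneModel:
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand), strand)


def random_background(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
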