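"""Quality filtering and identity-thresholded read mapping to panel genes.

Reads are end-trimmed at a Phred threshold, dropped when short or
low-mean-quality, then aligned semiglobally (both orientations) against
every panel gene.  Only the single best-scoring hit per read is kept, and
only when its identity (matches / aligned columns, gap columns included)
reaches the stringency threshold — 0.90 by default, with 0.70 as the
permissive alternative for sensitivity analyses.  Equal-best ties across
genes are dropped by default rather than split, so co-occurrence counts are
never inflated by ambiguous reads.

An optional exact k-mer seed prefilter (default on) skips gene candidates
sharing no 11-mer with the read; it exists purely to avoid needless dynamic
programming and must not change the emitted alignments.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._align import encode, glocal_align, revcomp_encoded
from .errors import FormatError, ParameterError
from .panel import GenePanel
from .screen import canonical_kmers

logger = logging.getLogger(__name__)

FastqRead = tuple[str, str, str]  # (name, sequence, quality)


@dataclass
class MapperConfig:
    min_identity: float = 0.90
    trim_quality: int = 20
    min_mean_quality: float = 10.0
    min_read_length_after_trim: int = 50
    tie_rule: str = "drop"  # or "first_by_gene_id"
    use_seed_prefilter: bool = True
    seed_k: int = 11

    def __post_init__(self):
        if not 0 < self.min_identity <= 1:
            raise ParameterError(f"min_identity must be in (0, 1], got {self.min_identity}")
        if self.trim_quality < 0 or self.min_mean_quality < 0:
            raise ParameterError("quality thresholds must be >= 0")
        if self.tie_rule not in {"drop", "first_by_gene_id"}:
            raise ParameterError(f"unknown tie_rule {self.tie_rule!r}")


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    gene_id: str
    ref_start: int  # 0-based inclusive
    ref_end: int    # 0-based exclusive
    matches: int
    aligned_columns: int
    strand: str
    score: int

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_columns


def _phred(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int32) - 33


def quality_trim(read: FastqRead, trim_quality: int) -> FastqRead:
    """Remove maximal low-quality runs (Phred < threshold) from both ends."""
    name, seq, qual = read
    if len(seq) != len(qual):
        raise FormatError(f"read {name!r}: sequence/quality length mismatch")
    q = _phred(qual)
    good = np.flatnonzero(q >= trim_quality)
    if good.size == 0:
        return (name, "", "")
    lo, hi = int(good[0]), int(good[-1]) + 1
    return (name, seq[lo:hi], qual[lo:hi])


def filter_reads(reads: Iterable[FastqRead], cfg: MapperConfig,
                 ) -> tuple[list[FastqRead], Counter]:
    """Trim then drop short / low-mean-quality reads; counts per drop reason."""
    counts: Counter = Counter()
    kept = []
    for read in reads:
        counts["input"] += 1
        trimmed = quality_trim(read, cfg.trim_quality)
        if len(trimmed[1]) < cfg.min_read_length_after_trim:
            counts["dropped_short"] += 1
            continue
        if _phred(trimmed[2]).mean() < cfg.min_mean_quality:
            counts["dropped_low_mean_quality"] += 1
            continue
        counts["kept"] += 1
        kept.append(trimmed)
    return kept, counts


def align_semiglobal(read_seq: str, gene_seq: str) -> ReadAlignment:
    """Best full-read alignment against any window of the gene, both strands."""
    read_f = encode(read_seq)
    gene = encode(gene_seq)
    read_r = revcomp_encoded(read_f)
    fwd = glocal_align(read_f, gene)
    rev = glocal_align(read_r, gene)
    if rev[0] > fwd[0]:
        score, matches, cols, start, end = rev
        strand = "-"
    else:
        score, matches, cols, start, end = fwd
        strand = "+"
    return ReadAlignment("", "", start, end, matches, cols, strand, score)


class _PanelIndex:
    """Encoded panel genes plus an exact k-mer seed index for candidate pruning."""

    def __init__(self, panel: GenePanel, seed_k: int):
        self.gene_ids: list[str] = []
        self.encoded: list[np.ndarray] = []
        self.lengths: dict[str, int] = {}
        self.seed_k = seed_k
        self.kmer_to_genes: dict[str, list[int]] = {}
        for idx, (gene_id, seq) in enumerate(panel.genes()):
            self.gene_ids.append(gene_id)
            self.encoded.append(encode(seq))
            self.lengths[gene_id] = len(seq)
            for kmer in set(canonical_kmers(seq, seed_k)):
                self.kmer_to_genes.setdefault(kmer, []).append(idx)

    def candidates(self, read_seq: str) -> list[int]:
        hit: set[int] = set()
        for kmer in set(canonical_kmers(read_seq, self.seed_k)):
            hit.update(self.kmer_to_genes.get(kmer, ()))
        return sorted(hit)


def _iter_fastq(source: str | Path | Iterable[FastqRead]) -> Iterator[FastqRead]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from FastqGeneralIterator(fh)
    else:
        yield from source


def map_sample(reads: str | Path | Iterable[FastqRead], panel: GenePanel,
               cfg: MapperConfig | None = None,
               ) -> tuple[list[ReadAlignment], dict]:
    """Map a sample's reads to the panel; best hit per read, identity-gated.

    Returns emitted alignments plus a summary of filter and mapping counts.
    """
    cfg = cfg or MapperConfig()
    index = _PanelIndex(panel, cfg.seed_k)
    filtered, counts = filter_reads(_iter_fastq(reads), cfg)
    alignments: list[ReadAlignment] = []
    n_mapped = n_unmapped = n_tied = n_below_identity = 0
    for name, seq, _ in filtered:
        if cfg.use_seed_prefilter:
            cand = index.candidates(seq)
        else:
            cand = list(range(len(index.gene_ids)))
        if not cand:
            n_unmapped += 1
            continue
        read_f = encode(seq)
        read_r = revcomp_encoded(read_f)
        best: list[tuple[int, ReadAlignment]] = []
        best_score = None
        for gi in cand:
            gene = index.encoded[gi]
            fwd = glocal_align(read_f, gene)
            rev = glocal_align(read_r, gene)
            res, strand = (rev, "-") if rev[0] > fwd[0] else (fwd, "+")
            score, matches, cols, start, end = res
            aln = ReadAlignment(name.split()[0], index.gene_ids[gi], start, end,
                                matches, cols, strand, score)
            if best_score is None or score > best_score:
                best_score = score
                best = [(gi, aln)]
            elif score == best_score:
                best.append((gi, aln))
        if len(best) > 1:
            if cfg.tie_rule == "drop":
                n_tied += 1
                continue
            best.sort(key=lambda t: index.gene_ids[t[0]])
        winner = best[0][1]
        if winner.aligned_columns > 0 and winner.identity >= cfg.min_identity:
            alignments.append(winner)
            n_mapped += 1
        else:
            n_below_identity += 1
    summary = dict(counts)
    summary.update(
        mapped=n_mapped, unmapped_no_seed=n_unmapped,
        below_identity=n_below_identity, ties_dropped=n_tied,
        min_identity=cfg.min_identity,
    )
    return alignments, summary


def alignments_to_frame(alignments: Iterable[ReadAlignment]) -> pd.DataFrame:
    rows = [
        {
            "read_id": a.read_id, "gene_id": a.gene_id, "ref_start": a.ref_start,
            "ref_end": a.ref_end, "matches": a.matches,
            "aligned_columns": a.aligned_columns,
            "identity": round(a.identity, 6), "strand": a.strand, "score": a.score,
        }
        for a in alignments
    ]
    return pd.DataFrame(
        rows,
        columns=["read_id", "gene_id", "ref_start", "ref_end", "matches",
                 "aligned_columns", "identity", "strand", "score"],
    )
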