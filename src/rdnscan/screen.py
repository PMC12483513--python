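"""Scaled-MinHash (FracMinHash) sketching and containment prescreening.

A sketch keeps the canonical k-mer hashes falling below ``H_MAX / scale`` of
a 64-bit hash space, giving an unbiased estimate of set containment between
sequence collections at 1/scale the memory.  Samples are retained when the
best panel query's containment in the sample sketch exceeds a threshold
(default 0.2, strict inequality) — the same gate used to pull candidate
metagenomes out of a large sequence archive before the expensive mapping
stage.

Hashing is stdlib blake2b truncated to 64 bits, keyed by an explicit seed;
k, scale and the hash seed are recorded in every serialized sketch so scores
are reproducible.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from hashlib import blake2b
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ParameterError
from .panel import GenePanel

logger = logging.getLogger(__name__)

H_MAX = 2 ** 64
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class ScreenConfig:
    k: int = 21
    scale: int = 100
    hash_seed: int = 42
    containment_threshold: float = 0.2
    query_mode: str = "pair"  # "pair": one query per EI pair; "gene": per gene

    def __post_init__(self):
        if self.k < 11:
            raise ParameterError(f"k must be >= 11, got {self.k}")
        if self.scale < 1:
            raise ParameterError("scale must be >= 1")
        if not 0 < self.containment_threshold <= 1:
            raise ParameterError("containment_threshold must be in (0, 1]")
        if self.query_mode not in {"pair", "gene"}:
            raise ParameterError(f"unknown query_mode {self.query_mode!r}")


@dataclass
class Sketch:
    k: int
    scale: int
    hash_seed: int
    hashes: frozenset[int]
    source_id: str = ""

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"k": self.k, "scale": self.scale, "seed": self.hash_seed,
                 "source_id": self.source_id, "hashes": sorted(self.hashes)},
                fh,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "Sketch":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["k"], d["scale"], d["seed"], frozenset(d["hashes"]), d.get("source_id", ""))


def canonical_kmers(seq: str, k: int) -> list[str]:
    """All canonical k-mers of ``seq`` (multiset, in order of occurrence).

    A k-mer is reported as the lexicographic min of itself and its reverse
    complement; windows containing non-ACGT characters are skipped.
    """
    import numpy as np

    seq = seq.upper()
    n = len(seq)
    if k > n:
        return []
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    valid = np.isin(raw, np.frombuffer(b"ACGT", dtype=np.uint8)).astype(np.int32)
    csum = np.concatenate(([0], np.cumsum(valid)))
    starts = np.flatnonzero(csum[k:] - csum[:-k] == k)
    out = []
    for i in starts:
        window = seq[i : i + k]
        rc = window.translate(_COMPLEMENT)[::-1]
        out.append(min(window, rc))
    return out


def hash_kmer(kmer: str, seed: int) -> int:
    """Fixed 64-bit hash of a k-mer string (blake2b, keyed by seed)."""
    h = blake2b(kmer.encode(), digest_size=8, key=seed.to_bytes(8, "little"))
    return int.from_bytes(h.digest(), "little")


def build_sketch(seqs: Iterable[str], cfg: ScreenConfig, source_id: str = "") -> Sketch:
    threshold = H_MAX // cfg.scale
    hashes = set()
    for seq in seqs:
        for kmer in set(canonical_kmers(seq, cfg.k)):
            h = hash_kmer(kmer, cfg.hash_seed)
            if h < threshold:
                hashes.add(h)
    return Sketch(cfg.k, cfg.scale, cfg.hash_seed, frozenset(hashes), source_id)


def sketch_fastq(path: str | Path, cfg: ScreenConfig, source_id: str = "") -> Sketch:
    with open(path) as fh:
        return build_sketch(
            (seq for _, seq, _ in FastqGeneralIterator(fh)), cfg,
            source_id or Path(path).stem,
        )


def containment(query: Sketch, subject: Sketch) -> float:
    """|query ∩ subject| / |query| over retained hashes."""
    if query.k != subject.k or query.scale != subject.scale:
        raise ParameterError(
            f"sketch parameters differ: k {query.k}/{subject.k}, "
            f"scale {query.scale}/{subject.scale}"
        )
    if query.hash_seed != subject.hash_seed:
        raise ParameterError("sketch hash seeds differ")
    if not query.hashes:
        raise ParameterError(f"containment undefined: query {query.source_id!r} sketch is empty")
    return len(query.hashes & subject.hashes) / len(query.hashes)


def panel_queries(panel: GenePanel, cfg: ScreenConfig) -> list[Sketch]:
    """Query sketches: one per EI pair (both genes) or one per gene."""
    queries = []
    if cfg.query_mode == "pair":
        for p in panel:
            queries.append(
                build_sketch([p.rdnE_seq, p.rdnI_seq], cfg, source_id=p.taxon_label)
            )
    else:
        for gene_id, seq in panel.genes():
            queries.append(build_sketch([seq], cfg, source_id=gene_id))
    return [q for q in queries if q.hashes]


def prescreen(corpus_index: pd.DataFrame, panel: GenePanel, cfg: ScreenConfig,
              ) -> tuple[list[str], pd.DataFrame, list[str]]:
    """Score every sample against every panel query.

    Returns (retained sample ids, per-(sample, query) containment table,
    unreadable-sample ids).  A sample is retained iff its best query
    containment is strictly greater than the threshold.
    """
    queries = panel_queries(panel, cfg)
    if not queries:
        raise ParameterError("no non-empty panel query sketches (k too large for genes?)")
    rows, retained, failures = [], [], []
    for _, sample in corpus_index.iterrows():
        sid = sample["sample_id"]
        try:
            sk = sketch_fastq(sample["fastq_path"], cfg, source_id=sid)
        except (OSError, ValueError) as exc:
            logger.warning("prescreen: skipping unreadable sample %s (%s)", sid, exc)
            failures.append(sid)
            continue
        best = 0.0
        for q in queries:
            c = containment(q, sk)
            rows.append({"sample_id": sid, "query_id": q.source_id, "containment": c})
            best = max(best, c)
        if best > cfg.containment_threshold:
            retained.append(sid)
    table = pd.DataFrame(rows, columns=["sample_id", "query_id", "containment"])
    if not table.empty:
        table["retained"] = table["sample_id"].isin(set(retained))
    else:
        table["retained"] = pd.Series(dtype=bool)
    return retained, table, failures
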