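"""Synthetic metagenome generator with known ground truth.

Emulates the statistical structure the coverage-ratio analysis assumes:
communities carrying subsets of panel taxa at controlled per-gene sequencing
depths (including an "orphan immunity" regime where rdnI depth exceeds rdnE
depth), per-base substitution sequencing error with Phred qualities,
background non-panel DNA, and panel-gene variants at controlled divergence.

The model is deliberately simple — substitution-only errors, uniform
non-circular read starts, single-end reads, constant per-sample Phred — so
that alignment identity stays exactly interpretable and every sample ships
with a machine-readable truth manifest.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, RdnscanError
from .panel import GenePanel

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for i, b in enumerate(b"ACGT"):
    _BASE_INDEX[b] = i


@dataclass
class CommunitySpec:
    """Recipe for one synthetic sample.

    per_taxon_depth maps taxon_label -> (rdnE mean depth, rdnI mean depth);
    gene_divergence maps taxon_label -> substitution fraction applied to both
    genes before reads are drawn (0 = reads come from the panel sequence).
    """

    panel: GenePanel
    per_taxon_depth: dict[str, tuple[float, float]]
    sample_id: str
    gene_divergence: dict[str, float] = field(default_factory=dict)
    read_length: int = 150
    substitution_error_rate: float = 0.005
    background_fraction: float = 0.1
    background_genome_length: int = 20_000
    environment: str = "unlabeled"
    bad_tail_length: int = 0
    bad_tail_quality: int = 2
    seed: int = 0

    def validate(self) -> None:
        panel_taxa = set(self.panel.taxa())
        for taxon, (de, di) in self.per_taxon_depth.items():
            if taxon not in panel_taxa:
                raise ParameterError(f"{self.sample_id}: taxon {taxon!r} not in panel")
            if de < 0 or di < 0:
                raise ParameterError(f"{self.sample_id}: negative depth for {taxon!r}")
        for taxon, div in self.gene_divergence.items():
            if not 0 <= div <= 0.3:
                raise ParameterError(f"{self.sample_id}: divergence {div} outside [0, 0.3]")
        if self.read_length < 50:
            raise ParameterError("read_length must be >= 50")
        if not 0 <= self.substitution_error_rate < 1:
            raise ParameterError("substitution_error_rate must be in [0, 1)")
        if not 0 <= self.background_fraction < 1:
            raise ParameterError("background_fraction must be in [0, 1)")


@dataclass
class TruthManifest:
    """Ground truth written next to each synthetic FASTQ."""

    sample_id: str
    environment: str
    seed: int
    true_depth: dict[str, float]          # "taxon:rdnE" / "taxon:rdnI" -> x
    true_log10_ratio: dict[str, float]    # taxon -> log10(I/E), both depths > 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _seq_to_array(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    if (_BASE_INDEX[arr] < 0).any():
        raise ParameterError("sequence contains non-ACGT characters")
    return arr


def mutate_sequence(seq: str, divergence: float, seed: int | np.random.Generator) -> str:
    """Substitute Binomial(L, divergence) positions, each to a different base."""
    if not 0 <= divergence <= 0.3:
        raise ParameterError(f"divergence {divergence} outside [0, 0.3]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = _seq_to_array(seq).copy()
    hit = rng.random(arr.size) < divergence
    idx = np.flatnonzero(hit)
    if idx.size:
        cur = _BASE_INDEX[arr[idx]].astype(np.int64)
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASES[(cur + shift) % 4]
    return arr.tobytes().decode()


def _phred_char(error_rate: float) -> str:
    q = 40 if error_rate <= 0 else min(40, int(round(-10 * math.log10(error_rate))))
    return chr(33 + q)


def simulate_reads(template: str, template_id: str, mean_depth: float, read_length: int,
                   error_rate: float, rng: np.random.Generator,
                   bad_tail_length: int = 0, bad_tail_quality: int = 2,
                   ) -> list[tuple[str, str, str]]:
    """Draw uniform-start single-end reads from a linear template.

    N = round(mean_depth * L / read_length); starts uniform on
    [0, L - read_length].  Per-base substitution errors at ``error_rate``;
    the quality string is the constant Phred matching the error model
    (optionally with a degraded tail to exercise quality trimming).
    Returns (name, sequence, quality) tuples; names carry the template id
    and 0-based coordinates for truth tracking.
    """
    arr = _seq_to_array(template)
    L = arr.size
    if L < read_length:
        raise ParameterError(
            f"template {template_id!r} length {L} < read_length {read_length}"
        )
    if mean_depth < 0:
        raise ParameterError("mean_depth must be >= 0")
    n_reads = int(round(mean_depth * L / read_length))
    if n_reads == 0:
        return []
    starts = rng.integers(0, L - read_length + 1, size=n_reads)
    qual_good = _phred_char(error_rate) * read_length
    if bad_tail_length > 0:
        tail = min(bad_tail_length, read_length)
        qual = qual_good[: read_length - tail] + chr(33 + bad_tail_quality) * tail
    else:
        qual = qual_good
    reads = []
    for i, s in enumerate(starts):
        sub = arr[s : s + read_length].copy()
        if error_rate > 0:
            hit = np.flatnonzero(rng.random(read_length) < error_rate)
            if hit.size:
                cur = _BASE_INDEX[sub[hit]].astype(np.int64)
                shift = rng.integers(1, 4, size=hit.size)
                sub[hit] = _BASES[(cur + shift) % 4]
        name = f"{template_id}|{s}-{s + read_length}|{i}"
        reads.append((name, sub.tobytes().decode(), qual))
    return reads


def generate_sample(spec: CommunitySpec, out_dir: str | Path) -> tuple[Path, TruthManifest]:
    """Write one FASTQ + truth manifest for a community spec.

    Reads from each taxon's (possibly diverged) rdnE/rdnI templates are
    concatenated with background reads from a random genome, then shuffled
    deterministically by the spec seed.
    """
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5EED]))

    pairs = {p.taxon_label: p for p in spec.panel}
    reads: list[tuple[str, str, str]] = []
    true_depth: dict[str, float] = {}
    true_ratio: dict[str, float] = {}
    for taxon in sorted(spec.per_taxon_depth):
        depth_e, depth_i = spec.per_taxon_depth[taxon]
        div = spec.gene_divergence.get(taxon, 0.0)
        pair = pairs[taxon]
        for gene, seq, depth in (
            ("rdnE", pair.rdnE_seq, depth_e),
            ("rdnI", pair.rdnI_seq, depth_i),
        ):
            template = mutate_sequence(seq, div, rng) if div > 0 else seq.upper()
            reads.extend(
                simulate_reads(
                    template, f"{taxon}:{gene}", depth, spec.read_length,
                    spec.substitution_error_rate, rng,
                    spec.bad_tail_length, spec.bad_tail_quality,
                )
            )
            true_depth[f"{taxon}:{gene}"] = depth
        if depth_e > 0 and depth_i > 0:
            true_ratio[taxon] = math.log10(depth_i / depth_e)

    if spec.background_fraction > 0:
        bg = _BASES[rng.integers(0, 4, size=spec.background_genome_length)].tobytes().decode()
        n_panel = len(reads)
        f = spec.background_fraction
        if n_panel > 0:
            n_bg = int(round(n_panel * f / (1 - f)))
        else:
            # pure-background sample: fill to ~1x of the background genome
            n_bg = int(round(spec.background_genome_length / spec.read_length))
        bg_depth = n_bg * spec.read_length / spec.background_genome_length
        reads.extend(
            simulate_reads(bg, "background", bg_depth, spec.read_length,
                           spec.substitution_error_rate, rng)
        )

    order = rng.permutation(len(reads))
    fastq_path = out_dir / f"{spec.sample_id}.fastq"
    try:
        with open(fastq_path, "w") as fh:
            for i in order:
                name, seq, qual = reads[i]
                fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    except OSError as exc:
        raise RdnscanError(f"cannot write {fastq_path}: {exc}") from exc

    manifest = TruthManifest(
        sample_id=spec.sample_id, environment=spec.environment, seed=spec.seed,
        true_depth=true_depth, true_log10_ratio=true_ratio,
    )
    manifest.to_json(out_dir / f"{spec.sample_id}.truth.json")
    return fastq_path, manifest


def generate_corpus(specs: Sequence[CommunitySpec], out_dir: str | Path) -> Path:
    """Generate one FASTQ + manifest per spec; returns the corpus index TSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = [s.sample_id for s in specs]
    dup = sorted({i for i in ids if ids.count(i) > 1})
    if dup:
        raise ParameterError(f"duplicate sample_id in corpus: {dup}")
    rows = []
    for spec in specs:
        fastq, manifest = generate_sample(spec, out_dir)
        rows.append(
            {
                "sample_id": spec.sample_id,
                "fastq": fastq.name,
                "manifest": f"{spec.sample_id}.truth.json",
                "environment": spec.environment,
                "seed": spec.seed,
            }
        )
    index = pd.DataFrame(rows, columns=["sample_id", "fastq", "manifest", "environment", "seed"])
    index_path = out_dir / "corpus_index.tsv"
    index.to_csv(index_path, sep="\t", index=False)
    return index_path


def read_corpus_index(index_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(index_path, sep="\t", dtype={"sample_id": str, "environment": str})
    base = Path(index_path).parent
    df["fastq_path"] = [str(base / f) for f in df["fastq"]]
    if "manifest" in df.columns:
        df["manifest_path"] = [str(base / m) for m in df["manifest"]]
    return df
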