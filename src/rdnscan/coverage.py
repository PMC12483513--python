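"""Per-base coverage pileup and the coverage-based retention/detection rules.

A (sample, taxon) observation is *retained* when the concatenated
effector+immunity profile has mean depth > 2x, at least one base > 5x, and
more than half its bases covered — all strict inequalities.  A single gene
is *detected* when its own mean depth exceeds 1x; detection feeds the ratio
and co-occurrence stages, retention is the sample-level inclusion gate.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError
from .mapper import ReadAlignment


@dataclass
class CoverageProfile:
    gene_id: str
    depth: np.ndarray  # int per-base coverage, length = gene length

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if self.depth.size else 0.0

    @property
    def max_depth(self) -> int:
        return int(self.depth.max()) if self.depth.size else 0

    @property
    def breadth(self) -> float:
        return float((self.depth >= 1).mean()) if self.depth.size else 0.0


@dataclass
class DetectionConfig:
    min_mean_depth: float = 2.0          # criterion 1, strict >
    min_single_base_depth: float = 5.0   # criterion 2, strict >
    min_pair_breadth: float = 0.5        # criterion 3, strict >
    per_gene_detection_min_mean: float = 1.0  # per-gene rule, strict >


def pileup(alignments: Iterable[ReadAlignment], gene_length: int,
           gene_id: str | None = None) -> CoverageProfile:
    """depth[i] = number of alignments whose reference span covers i."""
    delta = np.zeros(gene_length + 1, dtype=np.int64)
    gid = gene_id
    for aln in alignments:
        if gid is None:
            gid = aln.gene_id
        elif aln.gene_id != gid:
            raise FormatError(
                f"pileup mixes genes {gid!r} and {aln.gene_id!r}"
            )
        if not (0 <= aln.ref_start < aln.ref_end <= gene_length):
            raise FormatError(
                f"alignment span [{aln.ref_start},{aln.ref_end}) outside "
                f"gene {gid!r} of length {gene_length}"
            )
        delta[aln.ref_start] += 1
        delta[aln.ref_end] -= 1
    depth = np.cumsum(delta[:-1])
    return CoverageProfile(gid or "", depth)


def retention_filter(profE: CoverageProfile, profI: CoverageProfile,
                     cfg: DetectionConfig | None = None) -> tuple[bool, dict[str, bool]]:
    """Three-criterion retention over the concatenated E+I profile."""
    cfg = cfg or DetectionConfig()
    combined = np.concatenate([profE.depth, profI.depth])
    flags = {
        "mean_depth": bool(combined.mean() > cfg.min_mean_depth),
        "single_base_depth": bool(combined.max(initial=0) > cfg.min_single_base_depth),
        "breadth": bool((combined >= 1).mean() > cfg.min_pair_breadth),
    }
    return all(flags.values()), flags


@dataclass(frozen=True)
class DetectionRecord:
    sample_id: str
    taxon_label: str
    retained: bool
    rdnE_mean: float
    rdnI_mean: float
    rdnE_detected: bool
    rdnI_detected: bool
    criteria_flags: tuple[tuple[str, bool], ...]


def detect_genes(profiles: Mapping[str, tuple[CoverageProfile, CoverageProfile]],
                 sample_id: str, cfg: DetectionConfig | None = None,
                 ) -> list[DetectionRecord]:
    """Per-taxon retention and per-gene detection for one sample.

    ``profiles`` maps taxon_label -> (rdnE profile, rdnI profile); callers
    include only taxa with at least one mapped read.
    """
    cfg = cfg or DetectionConfig()
    records = []
    for taxon in sorted(profiles):
        profE, profI = profiles[taxon]
        retained, flags = retention_filter(profE, profI, cfg)
        records.append(
            DetectionRecord(
                sample_id=sample_id,
                taxon_label=taxon,
                retained=retained,
                rdnE_mean=profE.mean_depth,
                rdnI_mean=profI.mean_depth,
                rdnE_detected=profE.mean_depth > cfg.per_gene_detection_min_mean,
                rdnI_detected=profI.mean_depth > cfg.per_gene_detection_min_mean,
                criteria_flags=tuple(flags.items()),
            )
        )
    return records


def profiles_from_alignments(alignments: Iterable[ReadAlignment],
                             gene_lengths: Mapping[str, int],
                             ) -> dict[str, tuple[CoverageProfile, CoverageProfile]]:
    """Group alignments by taxon and pile up both genes of each touched taxon.

    gene ids follow the panel convention ``taxon:rdnE`` / ``taxon:rdnI``.
    """
    by_gene: dict[str, list[ReadAlignment]] = {}
    for aln in alignments:
        by_gene.setdefault(aln.gene_id, []).append(aln)
    taxa = {gid.rsplit(":", 1)[0] for gid in by_gene}
    out = {}
    for taxon in taxa:
        ge, gi = f"{taxon}:rdnE", f"{taxon}:rdnI"
        out[taxon] = (
            pileup(by_gene.get(ge, []), gene_lengths[ge], ge),
            pileup(by_gene.get(gi, []), gene_lengths[gi], gi),
        )
    return out


def detection_to_frame(records: Iterable[DetectionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id, "taxon_label": r.taxon_label,
            "retained": r.retained,
            "rdnE_mean": round(r.rdnE_mean, 6), "rdnI_mean": round(r.rdnI_mean, 6),
            "rdnE_detected": r.rdnE_detected, "rdnI_detected": r.rdnI_detected,
        }
        row.update({f"criterion_{k}": v for k, v in r.criteria_flags})
        rows.append(row)
    cols = ["sample_id", "taxon_label", "retained", "rdnE_mean", "rdnI_mean",
            "rdnE_detected", "rdnI_detected", "criterion_mean_depth",
            "criterion_single_base_depth", "criterion_breadth"]
    return pd.DataFrame(rows, columns=cols)
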