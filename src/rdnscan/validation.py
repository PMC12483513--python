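"""Parameter-recovery experiments on synthetic corpora.

Each experiment plants known ground truth with the generator, runs the
mapping -> coverage -> detection -> ratio stages, and reports how well the
pipeline recovers it.  These drivers back both the test suite and the
reproduction script; sizes default to desk-scale corpora (tens of samples,
~10^2 reads per sample).
"""
from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .coverage import DetectionConfig, detect_genes, profiles_from_alignments
from .mapper import MapperConfig, map_sample
from .panel import GenePanel, load_reference_panel
from .ratios import build_cooccurrence, ratio_records
from .simulate import CommunitySpec, generate_sample

PROTEUS = "Proteus mirabilis BB2000"
FOCAL_TAXA = (
    "Prevotella jejuni CD3:33",
    PROTEUS,
    "Pseudomonas ogarae F113",
    "Rothia dentocariosa C6B",
)


def _sample_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2**31, size=n)]


def _detections_for_spec(spec: CommunitySpec, panel: GenePanel, mapper_cfg: MapperConfig,
                         det_cfg: DetectionConfig, work_dir: Path):
    fastq, manifest = generate_sample(spec, work_dir)
    alignments, _ = map_sample(fastq, panel, mapper_cfg)
    gene_lengths = {gid: len(seq) for gid, seq in panel.genes()}
    profiles = profiles_from_alignments(alignments, gene_lengths)
    return detect_genes(profiles, spec.sample_id, det_cfg), manifest


@dataclass
class RatioRecovery:
    true_ratio: float
    median_recovered: float
    n_samples: int


def ratio_recovery_experiment(seed: int, n_samples: int = 20,
                              panel: GenePanel | None = None,
                              ) -> dict[str, RatioRecovery]:
    """Recover planted log10(I/E) of -1, 0 and +1 from synthetic corpora.

    One taxon per sample at (rdnE, rdnI) target depths of (50,5), (20,20)
    and (5,50); 150-nt reads at 0.5% substitution error (generator
    defaults).  Returns the per-regime median recovered ratio.
    """
    panel = panel or load_reference_panel().focal_subset()
    regimes = {"minus1": (50.0, 5.0), "zero": (20.0, 20.0), "plus1": (5.0, 50.0)}
    mapper_cfg, det_cfg = MapperConfig(), DetectionConfig()
    out: dict[str, RatioRecovery] = {}
    with tempfile.TemporaryDirectory() as tmp:
        work = Path(tmp)
        for ri, (name, (de, di)) in enumerate(regimes.items()):
            seeds = _sample_seeds(seed + ri, n_samples)
            ratios = []
            for i, s in enumerate(seeds):
                spec = CommunitySpec(panel, {PROTEUS: (de, di)},
                                     sample_id=f"{name}_{i}", seed=s)
                detections, _ = _detections_for_spec(spec, panel, mapper_cfg,
                                                     det_cfg, work)
                recs, _ = ratio_records(detections)
                ratios.extend(r.ratio for r in recs)
            out[name] = RatioRecovery(
                true_ratio=float(np.log10(di / de)),
                median_recovered=float(np.median(ratios)),
                n_samples=n_samples,
            )
    return out


def stringency_experiment(seed: int, panel: GenePanel | None = None,
                          depth: float = 10.0) -> dict[tuple[float, float], bool]:
    """Detectability of planted genes at 5% vs 20% divergence under the
    strict (0.90) and permissive (0.70) identity thresholds.

    Returns {(divergence, min_identity): both genes detected}.
    """
    panel = panel or load_reference_panel().focal_subset()
    det_cfg = DetectionConfig()
    results: dict[tuple[float, float], bool] = {}
    with tempfile.TemporaryDirectory() as tmp:
        work = Path(tmp)
        seeds = _sample_seeds(seed, 2)
        for divergence, s in zip((0.05, 0.20), seeds):
            spec = CommunitySpec(
                panel, {PROTEUS: (depth, depth)},
                gene_divergence={PROTEUS: divergence},
                sample_id=f"div{int(divergence * 100)}", seed=s,
            )
            fastq, _ = generate_sample(spec, work)
            for min_identity in (0.90, 0.70):
                alignments, _ = map_sample(fastq, panel,
                                           MapperConfig(min_identity=min_identity))
                gene_lengths = {gid: len(sq) for gid, sq in panel.genes()}
                profiles = profiles_from_alignments(alignments, gene_lengths)
                detections = detect_genes(profiles, spec.sample_id, det_cfg)
                rec = next((d for d in detections if d.taxon_label == PROTEUS), None)
                detected = bool(rec and rec.rdnE_detected and rec.rdnI_detected)
                results[(divergence, min_identity)] = detected
    return results


@dataclass
class CooccurrenceRecovery:
    planted_sets: dict[frozenset, int]
    recovered_sets: dict[frozenset, int]
    n_samples: int

    @property
    def n_mismatches(self) -> int:
        keys = set(self.planted_sets) | set(self.recovered_sets)
        return sum(self.planted_sets.get(k, 0) != self.recovered_sets.get(k, 0)
                   for k in keys)


def cooccurrence_experiment(seed: int, n_samples: int = 30,
                            panel: GenePanel | None = None,
                            depth: float = 8.0) -> CooccurrenceRecovery:
    """Plant random focal-taxon subsets and recover the exact Euler sets."""
    panel = panel or load_reference_panel().focal_subset()
    rng = np.random.default_rng(seed)
    mapper_cfg, det_cfg = MapperConfig(), DetectionConfig()
    planted: dict[frozenset, int] = {}
    detections = []
    with tempfile.TemporaryDirectory() as tmp:
        work = Path(tmp)
        seeds = _sample_seeds(seed + 7, n_samples)
        for i, s in enumerate(seeds):
            members = frozenset(t for t in FOCAL_TAXA if rng.random() < 0.45)
            if members:
                planted[members] = planted.get(members, 0) + 1
            spec = CommunitySpec(
                panel, {t: (depth, depth) for t in members},
                sample_id=f"cs{i}", seed=s,
            )
            dets, _ = _detections_for_spec(spec, panel, mapper_cfg, det_cfg, work)
            detections.extend(dets)
    table = build_cooccurrence(detections)
    return CooccurrenceRecovery(planted, dict(table.set_counts), n_samples)
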