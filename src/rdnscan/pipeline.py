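"""Pipeline orchestration: screen -> map -> detect -> ratios/co-occurrence.

Each stage reads and writes fixed-header TSVs so stages can be run
individually or via :func:`run_pipeline` with bit-identical outputs.  Every
TSV starts with a ``# rdnscan seed=<seed>`` comment line; nested run
metadata (config, per-stage counts) goes to ``run.json``.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coverage import (DetectionConfig, detection_to_frame, detect_genes,
                       profiles_from_alignments)
from .errors import RdnscanError, StageError
from .mapper import MapperConfig, ReadAlignment, alignments_to_frame, map_sample
from .panel import GenePanel, load_panel, load_reference_panel
from .ratios import (DEFAULT_BANDWIDTH, build_cooccurrence, cooccurrence_to_frame,
                     plot_kde, ratio_records, ratios_to_frame, summarize_by_environment)
from .screen import ScreenConfig, prescreen
from .simulate import read_corpus_index

logger = logging.getLogger(__name__)

FAILED_MARKER = "FAILED"


@dataclass
class PipelineConfig:
    panel_fasta_E: str | None = None
    panel_fasta_I: str | None = None
    panel_metadata: str | None = None
    focal_only: bool = True
    screen: ScreenConfig = field(default_factory=lambda: ScreenConfig(scale=1))
    mapper: MapperConfig = field(default_factory=MapperConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    bandwidth: float = DEFAULT_BANDWIDTH
    require_retained: bool = True
    cooccur_require_both: bool = False
    run_screen: bool = True
    seed: int = 0
    out_dir: str = "rdnscan_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, sub_cls in (("screen", ScreenConfig), ("mapper", MapperConfig),
                             ("detection", DetectionConfig)):
            if key in raw:
                kwargs[key] = sub_cls(**raw.pop(key))
        kwargs.update(raw)
        return cls(**kwargs)

    def load_panel(self) -> GenePanel:
        if self.panel_metadata:
            panel = load_panel(self.panel_fasta_E, self.panel_fasta_I, self.panel_metadata)
        else:
            panel = load_reference_panel()
        return panel.focal_subset() if self.focal_only else panel

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _write_tsv(frame: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# rdnscan seed={seed}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_stage_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def stage_screen(corpus: pd.DataFrame, panel: GenePanel, cfg: PipelineConfig,
                 out_dir: Path) -> tuple[list[str], dict]:
    retained, table, failures = prescreen(corpus, panel, cfg.screen)
    _write_tsv(table, out_dir / "screen.tsv", cfg.seed)
    counts = {"samples_screened": int(len(corpus)), "samples_retained": len(retained),
              "samples_unreadable": len(failures)}
    return retained, counts


def stage_map(corpus: pd.DataFrame, panel: GenePanel, cfg: PipelineConfig,
              out_dir: Path, sample_ids: list[str] | None = None) -> tuple[pd.DataFrame, dict]:
    if sample_ids is not None:
        corpus = corpus[corpus["sample_id"].isin(set(sample_ids))]
    frames, summaries = [], []
    for _, sample in corpus.iterrows():
        alignments, summary = map_sample(sample["fastq_path"], panel, cfg.mapper)
        frame = alignments_to_frame(alignments)
        frame.insert(0, "sample_id", sample["sample_id"])
        frames.append(frame)
        summary_row = {"sample_id": sample["sample_id"]}
        summary_row.update(summary)
        summaries.append(summary_row)
    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = alignments_to_frame([])
        table.insert(0, "sample_id", pd.Series(dtype=str))
    _write_tsv(table, out_dir / "alignments.tsv", cfg.seed)
    _write_tsv(pd.DataFrame(summaries), out_dir / "map_summary.tsv", cfg.seed)
    counts = {
        "samples_mapped": int(len(corpus)),
        "reads_in": int(sum(s.get("input", 0) for s in summaries)),
        "reads_kept": int(sum(s.get("kept", 0) for s in summaries)),
        "reads_mapped": int(sum(s.get("mapped", 0) for s in summaries)),
    }
    return table, counts


def stage_detect(alignment_table: pd.DataFrame, panel: GenePanel, cfg: PipelineConfig,
                 out_dir: Path) -> tuple[pd.DataFrame, dict]:
    gene_lengths = {gid: len(seq) for gid, seq in panel.genes()}
    detection_rows, coverage_rows = [], []
    for sample_id, group in alignment_table.groupby("sample_id", sort=True):
        alignments = [
            ReadAlignment(
                read_id=row.read_id, gene_id=row.gene_id, ref_start=int(row.ref_start),
                ref_end=int(row.ref_end), matches=int(row.matches),
                aligned_columns=int(row.aligned_columns), strand=row.strand,
                score=int(row.score),
            )
            for row in group.itertuples(index=False)
        ]
        profiles = profiles_from_alignments(alignments, gene_lengths)
        for taxon in sorted(profiles):
            for prof in profiles[taxon]:
                coverage_rows.append(
                    {"sample_id": sample_id, "gene_id": prof.gene_id,
                     "mean_depth": round(prof.mean_depth, 6),
                     "max_depth": prof.max_depth, "breadth": round(prof.breadth, 6)}
                )
        detection_rows.extend(detect_genes(profiles, sample_id, cfg.detection))
    det_frame = detection_to_frame(detection_rows)
    _write_tsv(det_frame, out_dir / "detection.tsv", cfg.seed)
    _write_tsv(
        pd.DataFrame(coverage_rows,
                     columns=["sample_id", "gene_id", "mean_depth", "max_depth", "breadth"]),
        out_dir / "coverage.tsv", cfg.seed,
    )
    counts = {"detection_records": int(len(det_frame)),
              "samples_retained_by_coverage": int(det_frame["retained"].sum())
              if len(det_frame) else 0}
    return det_frame, counts


def _records_from_frame(det_frame: pd.DataFrame):
    from .coverage import DetectionRecord

    records = []
    for row in det_frame.itertuples(index=False):
        records.append(
            DetectionRecord(
                sample_id=row.sample_id, taxon_label=row.taxon_label,
                retained=bool(row.retained), rdnE_mean=float(row.rdnE_mean),
                rdnI_mean=float(row.rdnI_mean), rdnE_detected=bool(row.rdnE_detected),
                rdnI_detected=bool(row.rdnI_detected),
                criteria_flags=(
                    ("mean_depth", bool(row.criterion_mean_depth)),
                    ("single_base_depth", bool(row.criterion_single_base_depth)),
                    ("breadth", bool(row.criterion_breadth)),
                ),
            )
        )
    return records


def stage_ratios(det_frame: pd.DataFrame, corpus: pd.DataFrame, cfg: PipelineConfig,
                 out_dir: Path, plot: bool = False) -> tuple[pd.DataFrame, dict]:
    detections = _records_from_frame(det_frame)
    environments = dict(zip(corpus["sample_id"], corpus.get("environment", "unlabeled")))
    records, n_orphan = ratio_records(detections, environments,
                                      require_retained=cfg.require_retained)
    ratio_frame = ratios_to_frame(records)
    _write_tsv(ratio_frame, out_dir / "ratios.tsv", cfg.seed)
    env_frame, kdes = summarize_by_environment(
        records, detections, environments, bandwidth=cfg.bandwidth,
        require_retained=cfg.require_retained,
    )
    _write_tsv(env_frame, out_dir / "environment_summary.tsv", cfg.seed)
    kde_rows = []
    for (env, taxon), summ in sorted(kdes.items()):
        for g, d in zip(summ.grid, summ.density):
            kde_rows.append({"environment": env, "taxon_label": taxon,
                             "grid": round(float(g), 6), "density": round(float(d), 8)})
    _write_tsv(
        pd.DataFrame(kde_rows, columns=["environment", "taxon_label", "grid", "density"]),
        out_dir / "kde.tsv", cfg.seed,
    )
    if plot and kdes:
        plot_kde(kdes, str(out_dir / "kde.png"))
    counts = {"ratio_records": int(len(ratio_frame)), "orphan_candidates": n_orphan}
    return ratio_frame, counts


def stage_cooccur(det_frame: pd.DataFrame, cfg: PipelineConfig, out_dir: Path,
                  ) -> tuple[pd.DataFrame, dict]:
    detections = _records_from_frame(det_frame)
    table = build_cooccurrence(detections, require_both_genes=cfg.cooccur_require_both)
    frame = cooccurrence_to_frame(table)
    _write_tsv(frame, out_dir / "cooccurrence.tsv", cfg.seed)
    pair_rows = [
        {"taxon_a": a, "taxon_b": b, "n_samples": n}
        for (a, b), n in sorted(table.pairwise_counts.items()) if a < b
    ]
    _write_tsv(pd.DataFrame(pair_rows, columns=["taxon_a", "taxon_b", "n_samples"]),
               out_dir / "cooccurrence_pairs.tsv", cfg.seed)
    counts = {"cooccurrence_sets": int(len(frame))}
    return frame, counts


def run_pipeline(cfg: PipelineConfig, corpus_index: str | Path, plot: bool = False) -> dict:
    """Run all stages in order; returns (and writes) the run report."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker = out_dir / FAILED_MARKER
    report: dict = {"version": __version__, "seed": cfg.seed, "stages": {},
                    "config": cfg.to_dict()}
    stage = "setup"
    try:
        corpus = read_corpus_index(corpus_index)
        panel = cfg.load_panel()
        report["panel"] = {"name": panel.name, "n_pairs": len(panel)}
        if cfg.run_screen:
            stage = "screen"
            retained, counts = stage_screen(corpus, panel, cfg, out_dir)
            report["stages"]["screen"] = counts
        else:
            retained = corpus["sample_id"].tolist()
        stage = "map"
        aln_table, counts = stage_map(corpus, panel, cfg, out_dir, sample_ids=retained)
        report["stages"]["map"] = counts
        stage = "detect"
        det_frame, counts = stage_detect(aln_table, panel, cfg, out_dir)
        report["stages"]["detect"] = counts
        stage = "ratios"
        _, counts = stage_ratios(det_frame, corpus, cfg, out_dir, plot=plot)
        report["stages"]["ratios"] = counts
        stage = "cooccur"
        _, counts = stage_cooccur(det_frame, cfg, out_dir)
        report["stages"]["cooccur"] = counts
    except RdnscanError as exc:
        marker.write_text(f"stage={stage}\nerror={exc}\n")
        raise StageError(stage, str(exc)) from exc
    except Exception as exc:  # pragma: no cover - defensive
        marker.write_text(f"stage={stage}\nerror={exc}\n")
        raise StageError(stage, f"unexpected failure: {exc}") from exc
    if marker.exists():
        marker.unlink()
    with open(out_dir / "run.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return report
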