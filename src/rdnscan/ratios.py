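"""log10(I/E) coverage-ratio statistic, KDE summaries and co-occurrence sets.

For each (sample, taxon) passing detection, the ratio of immunity to
effector abundance is log10(mean rdnI depth / mean rdnE depth): 0 means
balanced copy number, positive values an immunity-gene excess (candidate
orphan immunity genes).  Distributions are summarized per taxon and
environment with a Gaussian KDE (kernel standard deviation 0.4 by default)
and the raw-ratio median; cross-taxon co-occurrence is tallied from
effector detections as exact-set (Euler) and pairwise counts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import DetectionRecord
from .errors import ParameterError, UndefinedRatioError

DEFAULT_BANDWIDTH = 0.4


def log_ratio(I: float, E: float) -> float:
    """log10(I/E); defined only for strictly positive mean depths."""
    if I <= 0 or E <= 0:
        raise UndefinedRatioError(f"log10(I/E) undefined for I={I}, E={E}")
    return math.log10(I / E)


@dataclass(frozen=True)
class RatioRecord:
    sample_id: str
    taxon_label: str
    environment: str
    I: float
    E: float
    ratio: float


def ratio_records(detections: Iterable[DetectionRecord],
                  environments: Mapping[str, str] | None = None,
                  require_retained: bool = True,
                  ) -> tuple[list[RatioRecord], int]:
    """Finite ratios for records with both genes detected.

    Records with exactly one detected gene are candidate orphan
    observations; they are excluded from the ratio set and tallied in the
    returned count rather than assigned infinite ratios.
    """
    environments = environments or {}
    records, n_orphan = [], 0
    for det in detections:
        if require_retained and not det.retained:
            continue
        if det.rdnE_detected != det.rdnI_detected:
            n_orphan += 1
            continue
        if not (det.rdnE_detected and det.rdnI_detected):
            continue
        records.append(
            RatioRecord(
                sample_id=det.sample_id,
                taxon_label=det.taxon_label,
                environment=environments.get(det.sample_id, "unlabeled"),
                I=det.rdnI_mean,
                E=det.rdnE_mean,
                ratio=log_ratio(det.rdnI_mean, det.rdnE_mean),
            )
        )
    return records, n_orphan


@dataclass
class KDESummary:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    median: float
    n: int


def kde_density(ratios: Sequence[float], bandwidth: float = DEFAULT_BANDWIDTH,
                grid: np.ndarray | None = None, grid_points: int = 512) -> KDESummary:
    """Gaussian KDE with kernel standard deviation = ``bandwidth``.

    The grid spans [min - 4*bw, max + 4*bw] unless supplied; the median is
    computed on the raw ratios, not on the density.
    """
    x = np.asarray(list(ratios), dtype=float)
    if x.size == 0:
        raise ParameterError("kde_density requires at least one ratio")
    if bandwidth <= 0:
        raise ParameterError("bandwidth must be > 0")
    if grid is None:
        grid = np.linspace(x.min() - 4 * bandwidth, x.max() + 4 * bandwidth,
                           max(grid_points, 512))
    z = (grid[:, None] - x[None, :]) / bandwidth
    density = np.exp(-0.5 * z ** 2).sum(axis=1) / (
        x.size * bandwidth * math.sqrt(2 * math.pi)
    )
    return KDESummary(grid=grid, density=density, bandwidth=bandwidth,
                      median=float(np.median(x)), n=int(x.size))


@dataclass
class CooccurrenceTable:
    presence: pd.DataFrame            # sample x taxon booleans (effector detections)
    set_counts: dict[frozenset, int]  # exact detected-taxon set -> samples
    pairwise_counts: dict[tuple[str, str], int]


def build_cooccurrence(detections: Iterable[DetectionRecord],
                       require_both_genes: bool = False) -> CooccurrenceTable:
    """Euler-style co-occurrence of effector detections across taxa.

    Presence marks taxa whose effector gene is detected in a sample
    (optionally requiring the immunity gene too); set_counts partitions
    samples by their exact detected-taxon set.
    """
    cells: dict[tuple[str, str], bool] = {}
    for det in detections:
        present = det.rdnE_detected and (det.rdnI_detected or not require_both_genes)
        key = (det.sample_id, det.taxon_label)
        cells[key] = cells.get(key, False) or present
    if not cells:
        empty = pd.DataFrame(dtype=bool)
        return CooccurrenceTable(empty, {}, {})
    samples = sorted({s for s, _ in cells})
    taxa = sorted({t for _, t in cells})
    presence = pd.DataFrame(False, index=samples, columns=taxa)
    for (s, t), v in cells.items():
        presence.loc[s, t] = v
    set_counts: dict[frozenset, int] = {}
    for s in samples:
        detected = frozenset(presence.columns[presence.loc[s]])
        if detected:
            set_counts[detected] = set_counts.get(detected, 0) + 1
    pairwise: dict[tuple[str, str], int] = {}
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            n = int((presence[t1] & presence[t2]).sum())
            pairwise[(t1, t2)] = n
            pairwise[(t2, t1)] = n
    return CooccurrenceTable(presence, set_counts, pairwise)


def summarize_by_environment(ratios: Iterable[RatioRecord],
                             detections: Iterable[DetectionRecord],
                             environments: Mapping[str, str] | None = None,
                             bandwidth: float = DEFAULT_BANDWIDTH,
                             require_retained: bool = True,
                             ) -> tuple[pd.DataFrame, dict[tuple[str, str], KDESummary]]:
    """Per-(environment, taxon) ratio medians, KDE summaries and detection counts.

    The n reported per panel is the number of samples above the per-gene
    detection limit for *both* genes of that taxon.
    """
    environments = environments or {}
    ratios = list(ratios)
    detections = list(detections)
    n_both: dict[tuple[str, str], int] = {}
    for det in detections:
        if require_retained and not det.retained:
            continue
        if det.rdnE_detected and det.rdnI_detected:
            env = environments.get(det.sample_id, "unlabeled")
            key = (env, det.taxon_label)
            n_both[key] = n_both.get(key, 0) + 1
    grouped: dict[tuple[str, str], list[float]] = {}
    for rec in ratios:
        grouped.setdefault((rec.environment, rec.taxon_label), []).append(rec.ratio)
    rows, kdes = [], {}
    for key in sorted(set(n_both) | set(grouped)):
        env, taxon = key
        vals = grouped.get(key, [])
        row = {
            "environment": env, "taxon_label": taxon,
            "n_detected_both": n_both.get(key, 0),
            "n_ratios": len(vals),
            "median_ratio": float(np.median(vals)) if vals else float("nan"),
        }
        if vals:
            kdes[key] = kde_density(vals, bandwidth=bandwidth)
        rows.append(row)
    frame = pd.DataFrame(
        rows, columns=["environment", "taxon_label", "n_detected_both",
                       "n_ratios", "median_ratio"],
    )
    return frame, kdes


def ratios_to_frame(records: Iterable[RatioRecord]) -> pd.DataFrame:
    rows = [
        {"sample_id": r.sample_id, "taxon_label": r.taxon_label,
         "environment": r.environment, "I": round(r.I, 6), "E": round(r.E, 6),
         "ratio": round(r.ratio, 6)}
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["sample_id", "taxon_label", "environment", "I", "E", "ratio"]
    )


def cooccurrence_to_frame(table: CooccurrenceTable) -> pd.DataFrame:
    rows = [
        {"taxon_set": "|".join(sorted(s)), "n_samples": n}
        for s, n in sorted(table.set_counts.items(), key=lambda kv: sorted(kv[0]))
    ]
    return pd.DataFrame(rows, columns=["taxon_set", "n_samples"])


def plot_kde(kdes: Mapping[tuple[str, str], KDESummary], out_path: str) -> None:
    """Optional density plot, one subpanel per environment."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    envs = sorted({env for env, _ in kdes})
    fig, axes = plt.subplots(1, max(len(envs), 1), figsize=(4 * max(len(envs), 1), 3),
                             squeeze=False)
    for ax, env in zip(axes[0], envs):
        for (e, taxon), summ in sorted(kdes.items()):
            if e != env:
                continue
            ax.plot(summ.grid, summ.density, label=f"{taxon} (n={summ.n})")
            ax.axvline(summ.median, linestyle="--", alpha=0.5)
        ax.set_title(env)
        ax.set_xlabel("log10(I/E)")
        ax.legend(fontsize=6)
    axes[0][0].set_ylabel("density")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
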