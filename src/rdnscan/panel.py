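"""Effector-immunity (EI) gene panel: loading, validation and curation.

The panel is the reference database for every downstream stage: one row per
taxon carrying the nucleotide sequences of an effector nuclease gene (rdnE)
and the immunity gene encoded directly downstream of it (rdnI).  Curation
implements two biological filters used when assembling such panels from
genome annotations:

* adjacency — a candidate immunity gene must be the next annotated gene
  downstream of the effector on the same strand, with no intervening gene
  and a bounded intergenic gap (EI pairs are co-transcribed in known
  systems);
* catalytic-motif integrity — the effector must retain the PD-(D/E)XK
  nuclease triad (D, D/E, K; positions 39/53/55 on the Proteus reference
  protein), read off a global alignment of the translated candidate against
  the reference.  Candidates with a disrupted triad are presumed inactive
  and removed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq

from .errors import FormatError, PanelIntegrityError

logger = logging.getLogger(__name__)

IUPAC_NT = set("ACGTRYSWKMBDHVN")
MIN_GENE_LENGTH = 150

METADATA_COLUMNS = ["taxon_label", "phylum", "isolation_source", "rdnE_id", "rdnI_id", "focal"]


@dataclass(frozen=True)
class EIGenePair:
    """One taxon's effector + immunity nucleotide sequences with metadata."""

    taxon_label: str
    phylum: str
    isolation_source: str
    rdnE_id: str
    rdnI_id: str
    rdnE_seq: str
    rdnI_seq: str
    focal: bool = False

    def __post_init__(self):
        for name, seq in (("rdnE", self.rdnE_seq), ("rdnI", self.rdnI_seq)):
            bad = set(seq.upper()) - IUPAC_NT
            if bad:
                raise PanelIntegrityError(
                    f"{self.taxon_label} {name}: non-IUPAC characters {sorted(bad)}"
                )
            if len(seq) < MIN_GENE_LENGTH:
                raise PanelIntegrityError(
                    f"{self.taxon_label} {name}: length {len(seq)} < {MIN_GENE_LENGTH} nt"
                )
        if self.rdnE_id == self.rdnI_id:
            raise PanelIntegrityError(
                f"{self.taxon_label}: rdnE_id equals rdnI_id ({self.rdnE_id})"
            )

    @property
    def gene_id_E(self) -> str:
        return f"{self.taxon_label}:rdnE"

    @property
    def gene_id_I(self) -> str:
        return f"{self.taxon_label}:rdnI"


@dataclass
class GenePanel:
    """Ordered, validated collection of EI pairs."""

    pairs: list[EIGenePair]
    name: str = "panel"

    def __post_init__(self):
        if not self.pairs:
            raise PanelIntegrityError("panel is empty")
        seen = set()
        for p in self.pairs:
            if p.taxon_label in seen:
                raise PanelIntegrityError(f"duplicate taxon_label {p.taxon_label!r}")
            seen.add(p.taxon_label)

    def __iter__(self) -> Iterator[EIGenePair]:
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def taxa(self) -> list[str]:
        return [p.taxon_label for p in self.pairs]

    def genes(self) -> list[tuple[str, str]]:
        """All (gene_id, sequence) in panel order, effector before immunity."""
        out = []
        for p in self.pairs:
            out.append((p.gene_id_E, p.rdnE_seq.upper()))
            out.append((p.gene_id_I, p.rdnI_seq.upper()))
        return out

    def subset(self, taxa: Iterable[str], name: str | None = None) -> "GenePanel":
        wanted = list(taxa)
        by_label = {p.taxon_label: p for p in self.pairs}
        missing = [t for t in wanted if t not in by_label]
        if missing:
            raise PanelIntegrityError(f"taxa not in panel: {missing}")
        return GenePanel([by_label[t] for t in wanted], name=name or self.name)

    def focal_subset(self, name: str | None = None) -> "GenePanel":
        return GenePanel(
            [p for p in self.pairs if p.focal], name=name or f"{self.name}-focal"
        )


def load_panel(pair_fasta_E: str | Path, pair_fasta_I: str | Path, metadata: str | Path,
               name: str | None = None) -> GenePanel:
    """Load a panel from two FASTA files plus a tab-separated metadata table.

    FASTA record IDs must match the ``rdnE_id`` / ``rdnI_id`` metadata columns
    one-to-one; pair order follows metadata row order.
    """
    meta = pd.read_csv(metadata, sep="\t", dtype=str)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise FormatError(f"metadata missing columns {missing_cols}")

    def read_fasta(path) -> dict[str, str]:
        records = {}
        try:
            parsed = list(SeqIO.parse(str(path), "fasta"))
        except (ValueError, OSError) as exc:
            raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
        if not parsed:
            raise FormatError(f"no FASTA records in {path}")
        for rec in parsed:
            if rec.id in records:
                raise PanelIntegrityError(f"duplicate FASTA record ID {rec.id!r} in {path}")
            records[rec.id] = str(rec.seq).upper()
        return records

    seqs_E = read_fasta(pair_fasta_E)
    seqs_I = read_fasta(pair_fasta_I)

    for col, seqs, path in (("rdnE_id", seqs_E, pair_fasta_E), ("rdnI_id", seqs_I, pair_fasta_I)):
        ids = meta[col].tolist()
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelIntegrityError(f"duplicate {col} in metadata: {dup}")
        absent = [i for i in ids if i not in seqs]
        if absent:
            raise PanelIntegrityError(f"{col} {absent[0]!r} has no record in {path}")
        extra = [i for i in seqs if i not in set(ids)]
        if extra:
            raise PanelIntegrityError(f"FASTA record {extra[0]!r} in {path} absent from metadata")

    pairs = []
    for _, row in meta.iterrows():
        pairs.append(
            EIGenePair(
                taxon_label=row["taxon_label"],
                phylum=row["phylum"],
                isolation_source=row["isolation_source"],
                rdnE_id=row["rdnE_id"],
                rdnI_id=row["rdnI_id"],
                rdnE_seq=seqs_E[row["rdnE_id"]],
                rdnI_seq=seqs_I[row["rdnI_id"]],
                focal=str(row["focal"]).strip().lower() in {"true", "1", "yes"},
            )
        )
    return GenePanel(pairs, name=name or Path(metadata).stem)


def load_reference_panel() -> GenePanel:
    """The packaged 21-pair panel: real metadata, synthetic stand-in sequences."""
    data = resources.files("rdnscan.data")
    return load_panel(
        data / "panel_rdnE.synthetic.fna",
        data / "panel_rdnI.synthetic.fna",
        data / "table1_metadata.tsv",
        name="reference-21",
    )


def load_reference_effector_protein() -> str:
    data = resources.files("rdnscan.data")
    rec = next(SeqIO.parse(str(data / "rdnE_reference.synthetic.faa"), "fasta"))
    return str(rec.seq)


# ---------------------------------------------------------------------------
# Adjacency pairing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """A gene on a contig; coordinates 0-based half-open."""

    contig_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    product_label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(f"{self.gene_id}: invalid interval [{self.start},{self.end})")
        if self.strand not in {"+", "-"}:
            raise FormatError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")


def find_adjacent_pairs(annotations: Sequence[GeneAnnotation], effector_ids: set[str],
                        immunity_ids: set[str], max_gap_nt: int = 500) -> list[tuple[str, str]]:
    """Pair each effector with the immunity gene encoded directly downstream.

    Downstream is strand-relative; the immunity gene must be the *next*
    annotated gene on the contig (no intervening annotation, any strand), on
    the same strand as the effector, with intergenic gap <= ``max_gap_nt``.
    Output order follows (contig, start) of the effector, so it is invariant
    under permutation of the input.
    """
    by_contig: dict[str, list[GeneAnnotation]] = {}
    for ann in annotations:
        by_contig.setdefault(ann.contig_id, []).append(ann)
    pairs = []
    for contig in sorted(by_contig):
        anns = sorted(by_contig[contig], key=lambda a: (a.start, a.end, a.gene_id))
        for i, eff in enumerate(anns):
            if eff.gene_id not in effector_ids:
                continue
            if eff.strand == "+":
                if i + 1 >= len(anns):
                    continue
                cand = anns[i + 1]
                gap = cand.start - eff.end
            else:
                if i == 0:
                    continue
                cand = anns[i - 1]
                gap = eff.start - cand.end
            if cand.gene_id not in immunity_ids:
                continue
            if cand.strand != eff.strand:
                continue
            if gap > max_gap_nt:
                continue
            pairs.append((eff.gene_id, cand.gene_id))
    return pairs


# ---------------------------------------------------------------------------
# Catalytic-triad integrity
# ---------------------------------------------------------------------------

def _default_reference() -> str:
    return load_reference_effector_protein()


@dataclass
class MotifSpec:
    """PD-(D/E)XK triad positions on a reference effector protein.

    ``triad_positions`` are 1-based positions on ``reference_protein``;
    ``allowed_residues`` the residue set permitted at each (D / D,E / K by
    default, the canonical triad of the nuclease superfamily).
    """

    reference_protein: str = field(default_factory=_default_reference)
    triad_positions: tuple[int, int, int] = (39, 53, 55)
    allowed_residues: tuple[frozenset, frozenset, frozenset] = (
        frozenset("D"), frozenset("DE"), frozenset("K"),
    )

    def __post_init__(self):
        p = self.triad_positions
        if not (0 < p[0] < p[1] < p[2] <= len(self.reference_protein)):
            raise FormatError(
                f"triad positions {p} not strictly increasing within reference "
                f"length {len(self.reference_protein)}"
            )


@dataclass(frozen=True)
class TriadResult:
    intact: bool
    mapped_positions: tuple[int | None, int | None, int | None]  # 1-based on candidate
    residues: tuple[str, str, str]
    no_coverage: bool = False


# Alignment parameters for mapping the triad onto a diverged candidate:
# global with affine gaps so terminal extensions are penalized and the
# catalytic core stays in register.
_TRIAD_ALIGN = dict(match=2.0, mismatch=-1.0, open_gap=-10.0, extend_gap=-0.5)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = _TRIAD_ALIGN["match"]
    aligner.mismatch_score = _TRIAD_ALIGN["mismatch"]
    aligner.open_gap_score = _TRIAD_ALIGN["open_gap"]
    aligner.extend_gap_score = _TRIAD_ALIGN["extend_gap"]
    return aligner


def check_triad_integrity(candidate_protein: str, spec: MotifSpec | None = None) -> TriadResult:
    """Check whether the candidate retains the catalytic triad.

    Globally aligns the candidate to the reference protein and reads the
    candidate residues in the columns of the three triad positions.  Intact
    iff every triad column holds an allowed residue (no gaps).
    """
    spec = spec or MotifSpec()
    candidate = candidate_protein.upper().rstrip("*")
    if len(candidate) < 50:
        raise FormatError(f"candidate protein too short ({len(candidate)} aa < 50)")
    aligner = _make_aligner()
    aln = aligner.align(spec.reference_protein, candidate)[0]
    ref_idx = aln.indices[0]   # reference position per column, -1 in gaps
    cand_idx = aln.indices[1]
    col_of_ref = {int(r): c for c, r in enumerate(ref_idx) if r >= 0}

    mapped: list[int | None] = []
    residues: list[str] = []
    for pos in spec.triad_positions:
        col = col_of_ref.get(pos - 1)
        ci = int(cand_idx[col]) if col is not None else -1
        if col is None or ci < 0:
            mapped.append(None)
            residues.append("-")
        else:
            mapped.append(ci + 1)
            residues.append(candidate[ci])
    no_coverage = all(m is None for m in mapped)
    intact = not no_coverage and all(
        m is not None and res in allowed
        for m, res, allowed in zip(mapped, residues, spec.allowed_residues)
    )
    return TriadResult(intact, tuple(mapped), tuple(residues), no_coverage)


def translate_effector(nt_seq: str) -> str:
    """Translate a panel effector CDS (frame 0, standard code, stop stripped)."""
    seq = nt_seq.upper()
    if len(seq) % 3 != 0:
        raise FormatError(f"effector CDS length {len(seq)} not divisible by 3")
    return str(Seq(seq).translate()).rstrip("*")


@dataclass(frozen=True)
class RemovalRecord:
    taxon_label: str
    reason: str


def curate_panel(candidates: GenePanel, spec: MotifSpec | None = None,
                 ) -> tuple[GenePanel | None, list[RemovalRecord]]:
    """Retain pairs whose translated effector passes the triad check.

    Returns (curated panel or None if nothing survives, removal records).
    Untranslatable effectors are dropped with a warning rather than raising.
    """
    spec = spec or MotifSpec()
    kept, removed = [], []
    for pair in candidates:
        try:
            protein = translate_effector(pair.rdnE_seq)
            result = check_triad_integrity(protein, spec)
        except FormatError as exc:
            logger.warning("curation: dropping %s (%s)", pair.taxon_label, exc)
            removed.append(RemovalRecord(pair.taxon_label, f"untranslatable: {exc}"))
            continue
        if result.intact:
            kept.append(pair)
        else:
            reason = ("triad not covered by alignment" if result.no_coverage
                      else f"disrupted triad {'/'.join(result.residues)}")
            logger.info("curation: removing %s (%s)", pair.taxon_label, reason)
            removed.append(RemovalRecord(pair.taxon_label, reason))
    if not kept:
        logger.warning("curation removed every candidate pair")
        return None, removed
    return GenePanel(kept, name=f"{candidates.name}-curated"), removed


def protein_identity(a: str, b: str) -> float:
    """Pairwise global identity = identical columns / aligned columns."""
    aligner = _make_aligner()
    aln = aligner.align(a.upper(), b.upper())[0]
    ia, ib = aln.indices
    cols = len(ia)
    matches = sum(
        1 for x, y in zip(ia, ib) if x >= 0 and y >= 0 and a[int(x)].upper() == b[int(y)].upper()
    )
    return matches / cols
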