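"""Quality filtering and the semiglobal aligner, checked against DP oracles."""
import numpy as np
import pytest

from oracles import glocal_score, glocal_score_bothstrands, random_dna
from rdnscan.errors import FormatError, ParameterError
from rdnscan.mapper import (MapperConfig, align_semiglobal, filter_reads,
                            map_sample, quality_trim)
from rdnscan.simulate import mutate_sequence, simulate_reads

Q = lambda phred, n: chr(33 + phred) * n  # noqa: E731


# ---------------------------------------------------------------------------
# Quality trimming and filtering
# ---------------------------------------------------------------------------

def test_trim_keeps_high_quality_read():
    read = ("r", "A" * 50, Q(30, 50))
    assert quality_trim(read, 20) == read


def test_trim_removes_low_quality_tail():
    read = ("r", "A" * 50, Q(30, 45) + Q(2, 5))
    _, seq, qual = quality_trim(read, 20)
    assert len(seq) == 45 and len(qual) == 45


def test_trim_everything_below_threshold():
    assert quality_trim(("r", "ACGT", Q(2, 4)), 20)[1] == ""


def test_trim_interior_bases_untouched():
    qual = Q(2, 3) + Q(30, 10) + Q(2, 2) + Q(30, 10) + Q(2, 4)
    _, seq, q = quality_trim(("r", "A" * len(qual), qual), 20)
    assert len(seq) == 22  # interior Q2 run stays
    assert q == Q(30, 10) + Q(2, 2) + Q(30, 10)


def test_trim_length_mismatch():
    with pytest.raises(FormatError):
        quality_trim(("r", "ACGT", "II"), 20)


def test_filter_reads_reasons():
    cfg = MapperConfig()
    reads = [
        # high ends survive trimming but the interior drags the mean below 10
        ("low_mean", "A" * 70, Q(30, 5) + Q(2, 60) + Q(30, 5)),
        ("good", "A" * 60, Q(30, 60)),
        ("short_after_trim", "A" * 60, Q(30, 30) + Q(2, 30)),
        ("all_low", "A" * 60, Q(8, 60)),  # trims to empty -> dropped as short
    ]
    kept, counts = filter_reads(reads, cfg)
    assert [r[0] for r in kept] == ["good"]
    assert counts["input"] == 4
    assert counts["dropped_low_mean_quality"] == 1
    assert counts["dropped_short"] == 2


# ---------------------------------------------------------------------------
# Semiglobal alignment
# ---------------------------------------------------------------------------

def test_exact_substring_alignment(rng):
    gene = random_dna(rng, 600)
    read = gene[200:350]
    aln = align_semiglobal(read, gene)
    assert aln.identity == 1.0 and aln.aligned_columns == 150
    assert (aln.ref_start, aln.ref_end, aln.strand) == (200, 350, "+")


def test_reverse_complement_alignment(rng):
    gene = random_dna(rng, 600)
    read = gene[200:350].translate(str.maketrans("ACGT", "TGCA"))[::-1]
    aln = align_semiglobal(read, gene)
    assert aln.identity == 1.0 and aln.strand == "-"
    assert (aln.ref_start, aln.ref_end) == (200, 350)


def test_ten_substitutions_give_90_percent_identity(rng):
    """100-nt read with exactly 10 substitutions vs its source window."""
    gene = random_dna(rng, 400)
    window = gene[100:200]
    positions = rng.choice(100, size=10, replace=False)
    read = list(window)
    for p in positions:
        read[int(p)] = next(b for b in "ACGT" if b != window[int(p)])
    read = "".join(read)
    aln = align_semiglobal(read, gene)
    # substitution-only: gapless alignment dominates (gap -2 < mismatch -1)
    assert aln.aligned_columns == 100 and aln.matches == 90
    assert aln.identity == pytest.approx(0.90)
    assert aln.score == glocal_score(read, gene)


def test_random_reads_stay_below_70_percent_identity(focal_panel, rng):
    """Null distribution: uniform-random reads never reach the permissive
    identity threshold against a panel gene."""
    gene = focal_panel.pairs[0].rdnE_seq
    for _ in range(1000):
        read = random_dna(rng, 100)
        aln = align_semiglobal(read, gene)
        assert aln.identity < 0.70


def test_aligner_score_matches_dp_oracle(rng):
    """Bit-exact score agreement with the prefix-scan DP oracle."""
    for _ in range(200):
        read_len = int(rng.integers(20, 200))
        gene_len = int(rng.integers(read_len, 200))
        # mix of related and unrelated pairs
        gene = random_dna(rng, gene_len)
        if rng.random() < 0.5:
            start = int(rng.integers(0, gene_len - read_len + 1))
            read = mutate_sequence(gene[start : start + read_len], 0.15,
                                   np.random.default_rng(int(rng.integers(2**31))))
        else:
            read = random_dna(rng, read_len)
        aln = align_semiglobal(read, gene)
        assert aln.score == glocal_score_bothstrands(read, gene)


def test_alignment_bounds_and_identity_definition(rng):
    gene = random_dna(rng, 300)
    read = mutate_sequence(gene[50:170], 0.05, 3)
    aln = align_semiglobal(read, gene)
    assert 0 <= aln.ref_start < aln.ref_end <= len(gene)
    assert aln.identity == aln.matches / aln.aligned_columns


# ---------------------------------------------------------------------------
# map_sample
# ---------------------------------------------------------------------------

def _reads_from_gene(gene, n, rng, divergence=0.0, error=0.0):
    template = mutate_sequence(gene, divergence, rng) if divergence else gene
    return simulate_reads(template, "t", n * 150 / len(template), 150, error, rng)


def test_reads_map_to_their_source_gene(focal_panel, rng):
    proteus = next(p for p in focal_panel if "Proteus" in p.taxon_label)
    reads = _reads_from_gene(proteus.rdnE_seq, 60, rng)
    alignments, summary = map_sample(reads, focal_panel, MapperConfig())
    assert summary["kept"] == len(reads)
    frac = sum(a.gene_id == proteus.gene_id_E for a in alignments) / len(reads)
    assert frac >= 0.99


@pytest.mark.parametrize("min_identity, expect_high", [(0.9, False), (0.7, True)])
def test_stringency_on_diverged_gene(focal_panel, rng, min_identity, expect_high):
    """Reads from a 20%-diverged gene map at 70% but not 90% stringency."""
    proteus = next(p for p in focal_panel if "Proteus" in p.taxon_label)
    reads = _reads_from_gene(proteus.rdnE_seq, 50, rng, divergence=0.20)
    cfg = MapperConfig(min_identity=min_identity)
    alignments, _ = map_sample(reads, focal_panel, cfg)
    frac = len(alignments) / len(reads)
    if expect_high:
        assert frac > 0.9
    else:
        assert frac < 0.05


def test_identity_calibration(focal_panel, rng):
    """Mean mapped identity within 0.01 of 1 - per-read substitution rate."""
    proteus = next(p for p in focal_panel if "Proteus" in p.taxon_label)
    for p_sub in (0.02, 0.05, 0.10):
        reads = _reads_from_gene(proteus.rdnE_seq, 80, rng, error=p_sub)
        # quality gating off: high error rates encode Phred below the trim
        # threshold and this check targets the aligner's identity, not the filter
        cfg = MapperConfig(min_identity=0.7, trim_quality=0, min_mean_quality=0)
        alignments, _ = map_sample(reads, focal_panel, cfg)
        mean_id = np.mean([a.identity for a in alignments])
        assert abs(mean_id - (1 - p_sub)) < 0.01


def test_strand_symmetry(focal_panel, rng):
    """Mapping the reverse complement of every read gives identical spans."""
    proteus = next(p for p in focal_panel if "Proteus" in p.taxon_label)
    reads = _reads_from_gene(proteus.rdnE_seq, 40, rng, error=0.005)
    rc = str.maketrans("ACGT", "TGCA")
    flipped = [(n, s.translate(rc)[::-1], q[::-1]) for n, s, q in reads]
    a1, _ = map_sample(reads, focal_panel, MapperConfig())
    a2, _ = map_sample(flipped, focal_panel, MapperConfig())
    spans1 = sorted((a.read_id, a.gene_id, a.ref_start, a.ref_end) for a in a1)
    spans2 = sorted((a.read_id, a.gene_id, a.ref_start, a.ref_end) for a in a2)
    assert spans1 == spans2


def test_seed_prefilter_does_not_change_alignments(focal_panel, rng):
    proteus = next(p for p in focal_panel if "Proteus" in p.taxon_label)
    reads = _reads_from_gene(proteus.rdnE_seq, 30, rng, divergence=0.05, error=0.005)
    reads += [(f"bg{i}", random_dna(rng, 150), "I" * 150) for i in range(10)]
    on, _ = map_sample(reads, focal_panel, MapperConfig(use_seed_prefilter=True))
    off, _ = map_sample(reads, focal_panel, MapperConfig(use_seed_prefilter=False))
    assert sorted(map(repr, on)) == sorted(map(repr, off))


def test_tie_rule(ref_panel):
    """Two panel genes with identical sequence force an equal-best tie."""
    from rdnscan.panel import EIGenePair, GenePanel

    seq = ref_panel.pairs[0].rdnE_seq
    other = ref_panel.pairs[0].rdnI_seq
    twins = GenePanel([
        EIGenePair("A taxon", "P", "lab", "E1", "I1", seq, other),
        EIGenePair("B taxon", "P", "lab", "E2", "I2", seq, other[::-1]),
    ])
    reads = [("r0", seq[10:130], "I" * 120)]
    dropped, summary = map_sample(reads, twins, MapperConfig(tie_rule="drop"))
    assert dropped == [] and summary["ties_dropped"] == 1
    kept, _ = map_sample(reads, twins, MapperConfig(tie_rule="first_by_gene_id"))
    assert len(kept) == 1 and kept[0].gene_id == "A taxon:rdnE"


def test_mapper_config_validation():
    with pytest.raises(ParameterError):
        MapperConfig(min_identity=0.0)
    with pytest.raises(ParameterError):
        MapperConfig(tie_rule="random")
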