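"""Panel loading, adjacency pairing and catalytic-triad curation."""
import numpy as np
import pytest

from oracles import gapless_score, gotoh_global_score, random_dna
from rdnscan.errors import FormatError, PanelIntegrityError
from rdnscan.panel import (EIGenePair, GeneAnnotation, GenePanel, MotifSpec,
                           check_triad_integrity, curate_panel, find_adjacent_pairs,
                           load_panel, load_reference_effector_protein,
                           protein_identity, translate_effector)

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Loading and validation
# ---------------------------------------------------------------------------

def _write_panel_files(tmp_path, rows, seqs_e=None, seqs_i=None):
    """rows: list of (taxon, eid, iid); default sequences are valid CDS-ish."""
    meta = tmp_path / "meta.tsv"
    lines = ["taxon_label\tphylum\tisolation_source\trdnE_id\trdnI_id\tfocal"]
    for taxon, eid, iid in rows:
        lines.append(f"{taxon}\tTestphylum\tlab\t{eid}\t{iid}\tfalse")
    meta.write_text("\n".join(lines) + "\n")
    rng = np.random.default_rng(5)
    seqs_e = seqs_e or {eid: random_dna(rng, 300) for _, eid, _ in rows}
    seqs_i = seqs_i or {iid: random_dna(rng, 300) for _, _, iid in rows}
    fe, fi = tmp_path / "e.fna", tmp_path / "i.fna"
    fe.write_text("".join(f">{k}\n{v}\n" for k, v in seqs_e.items()))
    fi.write_text("".join(f">{k}\n{v}\n" for k, v in seqs_i.items()))
    return fe, fi, meta


def test_single_row_roundtrip(tmp_path):
    fe, fi, meta = _write_panel_files(tmp_path, [("Taxon one", "E1", "I1")])
    panel = load_panel(fe, fi, meta)
    assert len(panel) == 1
    assert panel.pairs[0].gene_id_E == "Taxon one:rdnE"


def test_fasta_record_absent_from_metadata_errors(tmp_path):
    rng = np.random.default_rng(6)
    fe, fi, meta = _write_panel_files(
        tmp_path, [("Taxon one", "E1", "I1")],
        seqs_e={"E1": random_dna(rng, 300), "EXTRA": random_dna(rng, 300)},
    )
    with pytest.raises(PanelIntegrityError, match="EXTRA"):
        load_panel(fe, fi, meta)


def test_metadata_id_missing_from_fasta_errors(tmp_path):
    fe, fi, meta = _write_panel_files(
        tmp_path, [("Taxon one", "E1", "I1")],
        seqs_e={"WRONG": random_dna(np.random.default_rng(7), 300)},
    )
    with pytest.raises(PanelIntegrityError, match="E1"):
        load_panel(fe, fi, meta)


@pytest.mark.parametrize(
    "kwargs, match",
    [
        (dict(rdnE_seq="ACGT" * 10), "length"),          # < 150 nt
        (dict(rdnE_seq="ACGJ" * 50), "non-IUPAC"),
        (dict(rdnI_id="E1"), "rdnE_id equals rdnI_id"),
    ],
)
def test_pair_invariants(kwargs, match):
    base = dict(
        taxon_label="T", phylum="P", isolation_source="lab",
        rdnE_id="E1", rdnI_id="I1",
        rdnE_seq="ACGT" * 50, rdnI_seq="ACGT" * 50,
    )
    base.update(kwargs)
    with pytest.raises(PanelIntegrityError, match=match):
        EIGenePair(**base)


def test_duplicate_taxon_rejected():
    p = EIGenePair("T", "P", "lab", "E1", "I1", "ACGT" * 50, "ACGT" * 50)
    q = EIGenePair("T", "P", "lab", "E2", "I2", "ACGT" * 50, "ACGT" * 50)
    with pytest.raises(PanelIntegrityError, match="duplicate"):
        GenePanel([p, q])


# ---------------------------------------------------------------------------
# Adjacency pairing
# ---------------------------------------------------------------------------

def _ann(contig, gid, start, end, strand):
    return GeneAnnotation(contig, gid, start, end, strand)


ADJ_CASE = [
    _ann("c1", "rdnE", 100, 500, "+"),
    _ann("c1", "rdnI", 520, 900, "+"),
]


def test_adjacent_pair_found():
    pairs = find_adjacent_pairs(ADJ_CASE, {"rdnE"}, {"rdnI"}, max_gap_nt=500)
    assert pairs == [("rdnE", "rdnI")]


def test_intervening_gene_blocks_pair():
    anns = ADJ_CASE + [_ann("c1", "other", 505, 515, "+")]
    assert find_adjacent_pairs(anns, {"rdnE"}, {"rdnI"}, 500) == []


def test_opposite_strand_blocks_pair():
    anns = [ADJ_CASE[0], _ann("c1", "rdnI", 520, 900, "-")]
    assert find_adjacent_pairs(anns, {"rdnE"}, {"rdnI"}, 500) == []


def test_gap_ceiling_and_minus_strand_downstream():
    far = [ADJ_CASE[0], _ann("c1", "rdnI", 1100, 1400, "+")]
    assert find_adjacent_pairs(far, {"rdnE"}, {"rdnI"}, 500) == []
    # on the minus strand, downstream means decreasing coordinate
    minus = [_ann("c1", "rdnI", 100, 400, "-"), _ann("c1", "rdnE", 420, 800, "-")]
    assert find_adjacent_pairs(minus, {"rdnE"}, {"rdnI"}, 500) == [("rdnE", "rdnI")]


def test_adjacency_invariant_under_input_permutation(rng):
    anns = [
        _ann("c1", "e1", 0, 300, "+"), _ann("c1", "i1", 310, 600, "+"),
        _ann("c1", "x", 700, 800, "+"),
        _ann("c2", "e2", 50, 350, "-"), _ann("c2", "i2", 400, 700, "-"),
        _ann("c2", "i3", 0, 40, "-"),
    ]
    expected = find_adjacent_pairs(anns, {"e1", "e2"}, {"i1", "i2", "i3"}, 500)
    assert ("e1", "i1") in expected
    for _ in range(10):
        perm = [anns[i] for i in rng.permutation(len(anns))]
        assert find_adjacent_pairs(perm, {"e1", "e2"}, {"i1", "i2", "i3"}, 500) == expected


# ---------------------------------------------------------------------------
# Triad integrity
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def ref_protein():
    return load_reference_effector_protein()


def test_reference_is_intact(ref_protein):
    res = check_triad_integrity(ref_protein)
    assert res.intact and res.mapped_positions == (39, 53, 55)
    assert res.residues == ("D", "E", "K")


def test_d39a_mutant_is_disrupted(ref_protein):
    mutant = ref_protein[:38] + "A" + ref_protein[39:]
    res = check_triad_integrity(mutant)
    assert not res.intact
    assert res.residues[0] == "A"


@pytest.mark.parametrize("triad_index, pos", [(0, 39), (1, 53), (2, 55)])
def test_single_triad_flip_flips_result(ref_protein, triad_index, pos):
    mutant = ref_protein[: pos - 1] + "A" + ref_protein[pos:]
    assert check_triad_integrity(ref_protein).intact
    assert not check_triad_integrity(mutant).intact


def test_divergent_candidate_with_conserved_triad(ref_protein, rng):
    """40% divergence outside the motif keeps the triad mapped and intact.

    The affine-global Gotoh oracle confirms the optimal alignment is the
    gapless one, so triad columns map position-to-position.
    """
    protected = {38, 52, 54}
    sites = [i for i in range(len(ref_protein)) if i not in protected]
    n_mut = int(round(0.4 * len(sites)))
    cand = list(ref_protein)
    for i in rng.choice(len(sites), size=n_mut, replace=False):
        pos = sites[int(i)]
        cand[pos] = next(a for a in AA if a != ref_protein[pos])
    cand = "".join(cand)
    assert gotoh_global_score(ref_protein, cand) == pytest.approx(
        gapless_score(ref_protein, cand)
    )
    res = check_triad_integrity(cand)
    assert res.intact and res.mapped_positions == (39, 53, 55)


def test_triad_positions_must_fit_reference(ref_protein):
    with pytest.raises(FormatError):
        MotifSpec(reference_protein=ref_protein, triad_positions=(39, 53, 500))


def test_short_candidate_rejected():
    with pytest.raises(FormatError, match="too short"):
        check_triad_integrity("MKV" * 10)


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def _back_translate_simple(protein):
    table = {a: c for c, a in [
        ("GCT", "A"), ("TGT", "C"), ("GAT", "D"), ("GAA", "E"), ("TTT", "F"),
        ("GGT", "G"), ("CAT", "H"), ("ATT", "I"), ("AAA", "K"), ("CTT", "L"),
        ("ATG", "M"), ("AAT", "N"), ("CCT", "P"), ("CAA", "Q"), ("CGT", "R"),
        ("TCT", "S"), ("ACT", "T"), ("GTT", "V"), ("TGG", "W"), ("TAT", "Y"),
    ]}
    return "".join(table[a] for a in protein)


def _pair(taxon, protein, iid_suffix=""):
    nt = _back_translate_simple(protein)
    return EIGenePair(taxon, "P", "lab", f"E-{taxon}", f"I-{taxon}",
                      nt, "ACGT" * 60)


def test_curation_removes_disrupted_triad(ref_protein):
    k_to_a = ref_protein[:54] + "A" + ref_protein[55:]
    panel = GenePanel([
        _pair("good1", ref_protein),
        _pair("bad", k_to_a),
        _pair("good2", ref_protein),
    ])
    curated, removed = curate_panel(panel)
    assert curated.taxa() == ["good1", "good2"]
    assert [r.taxon_label for r in removed] == ["bad"]
    assert "disrupted" in removed[0].reason


def test_curation_is_idempotent_and_identity_on_intact(ref_panel):
    once, removed = curate_panel(ref_panel)
    assert removed == [] and once.taxa() == ref_panel.taxa()
    twice, _ = curate_panel(once)
    assert twice.taxa() == once.taxa()


def test_curation_all_disrupted_gives_empty(ref_protein, caplog):
    d_to_a = ref_protein[:38] + "A" + ref_protein[39:]
    panel = GenePanel([_pair("bad1", d_to_a), _pair("bad2", d_to_a)])
    curated, removed = curate_panel(panel)
    assert curated is None and len(removed) == 2


def test_untranslatable_sequence_dropped_with_warning(ref_protein):
    good = _pair("good", ref_protein)
    bad_nt = EIGenePair("badlen", "P", "lab", "Eb", "Ib", "ACGT" * 50, "ACGT" * 50)
    curated, removed = curate_panel(GenePanel([good, bad_nt]))  # 200 nt: not /3
    assert curated.taxa() == ["good"]
    assert "untranslatable" in removed[0].reason


def test_translate_effector_strips_stop(ref_protein):
    nt = _back_translate_simple(ref_protein) + "TAA"
    assert translate_effector(nt) == ref_protein


# ---------------------------------------------------------------------------
# Pairwise identity
# ---------------------------------------------------------------------------

def test_protein_identity_matches_planted_divergence(ref_protein, rng):
    """Mutating a known fraction of positions yields exactly that identity
    (substitution-only, so the optimal global alignment is gapless)."""
    n_mut = 62  # 45% of 138
    cand = list(ref_protein)
    for i in rng.choice(len(ref_protein), size=n_mut, replace=False):
        cand[int(i)] = next(a for a in AA if a != ref_protein[int(i)])
    cand = "".join(cand)
    expected = (len(ref_protein) - n_mut) / len(ref_protein)
    assert protein_identity(ref_protein, cand) == pytest.approx(expected)
    assert protein_identity(cand, ref_protein) == pytest.approx(expected)
    assert protein_identity(ref_protein, ref_protein) == 1.0
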