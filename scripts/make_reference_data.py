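"""One-off generator for the packaged synthetic reference sequences.

The real rdnE/rdnI nucleotide sequences live behind JGI gene IDs and an OSF
archive; the packaged fixture ships synthetic stand-ins with the same shape:
a 138-aa effector reference with the catalytic triad at positions 39/53/55,
per-taxon effector proteins derived from it at controlled divergence
(back-translated with random synonymous codons), and random-CDS immunity
genes.  Regenerating with the same seed is byte-identical.
"""
from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

AA = "ACDEFGHIKLMNPQRSTVWY"
TRIAD = {38: "D", 52: "E", 54: "K"}  # 0-based: D39, E53, K55
PD_P = 37  # the P of the P-D dinucleotide motif, 0-based

CODONS = {}
for codon, aa in standard_dna_table.forward_table.items():
    CODONS.setdefault(aa, []).append(codon)
for aa in CODONS:
    CODONS[aa].sort()

# aa divergence of each taxon's effector from the reference (non-triad sites)
FOCAL_DIV = {
    "Proteus mirabilis BB2000": 0.0,
    "Rothia dentocariosa C6B": 0.45,
    "Prevotella jejuni CD3:33": 0.55,
    "Pseudomonas ogarae F113": 0.55,
}


def make_reference_protein(rng: np.random.Generator) -> str:
    aa = [AA[i] for i in rng.integers(0, len(AA), size=138)]
    aa[PD_P] = "P"
    for pos, res in TRIAD.items():
        aa[pos] = res
    return "".join(aa)


def mutate_protein(ref: str, divergence: float, rng: np.random.Generator) -> str:
    out = list(ref)
    protected = set(TRIAD) | {PD_P}
    sites = [i for i in range(len(ref)) if i not in protected]
    n_mut = int(round(divergence * len(sites)))
    for i in rng.choice(len(sites), size=n_mut, replace=False):
        pos = sites[i]
        choices = [a for a in AA if a != ref[pos]]
        out[pos] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [CODONS[a][rng.integers(0, len(CODONS[a]))] for a in protein]
    return "".join(codons) + "TAA"


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    aas = [AA[i] for i in rng.integers(0, len(AA), size=n_codons - 2)]
    return "ATG" + back_translate(aas, rng)


def main() -> None:
    import pandas as pd

    meta = pd.read_csv("src/rdnscan/data/table1_metadata.tsv", sep="\t", dtype=str)
    rng = np.random.default_rng(20240901)
    ref_protein = make_reference_protein(rng)

    e_records, i_records = [], []
    for _, row in meta.iterrows():
        taxon = row["taxon_label"]
        div = FOCAL_DIV.get(taxon, float(rng.uniform(0.35, 0.60)))
        protein = mutate_protein(ref_protein, div, rng)
        e_seq = back_translate(protein, rng)
        n_codons = int(rng.integers(160, 300))
        i_seq = random_cds(n_codons, rng)
        e_records.append((row["rdnE_id"], taxon, e_seq))
        i_records.append((row["rdnI_id"], taxon, i_seq))

    def write_fasta(path, records, gene):
        with open(path, "w") as fh:
            for gid, taxon, seq in records:
                fh.write(f">{gid} {gene} {taxon} [synthetic stand-in]\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    write_fasta("src/rdnscan/data/panel_rdnE.synthetic.fna", e_records, "rdnE")
    write_fasta("src/rdnscan/data/panel_rdnI.synthetic.fna", i_records, "rdnI")
    with open("src/rdnscan/data/rdnE_reference.synthetic.faa", "w") as fh:
        fh.write(">rdnE_reference_synthetic 138aa triad D39/E53/K55 [synthetic stand-in]\n")
        for i in range(0, len(ref_protein), 70):
            fh.write(ref_protein[i : i + 70] + "\n")
    print("reference protein:", ref_protein)


if __name__ == "__main__":
    main()
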