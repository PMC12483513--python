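# Methods

`rdnscan` quantifies paired effector (rdnE) / immunity (rdnI) genes in
shotgun metagenomes. rdnE-family proteins are PD-(D/E)XK DNA nucleases
delivered between bacterial cells (e.g. via the type VI secretion system);
the rdnI gene encoded directly downstream neutralizes the effector in
recipient cells. Communities in which rdnI reads outnumber rdnE reads are
candidates for "orphan" immunity genes — immunity without the cognate
effector. The pipeline: containment prescreen → identity-thresholded
mapping → coverage-based detection → log10(I/E) ratio and co-occurrence
summaries, with a synthetic-community generator providing ground truth for
every stage.

## Panel and curation

The reference database is a panel of EI pairs: per taxon, the rdnE and rdnI
nucleotide sequences plus metadata (phylum, isolation source, gene IDs).
The packaged fixture carries 21 pairs across four phyla; its metadata table
is real, but the sequences are **synthetic stand-ins** (`*.synthetic.fna`):
seeded constructions with the same shape (a 138-aa effector with the
catalytic triad at positions 39/53/55, back-translated with random
synonymous codons; random-CDS immunity genes of 480–900 nt). Four taxa
(*Proteus mirabilis* BB2000, *Rothia dentocariosa* C6B, *Prevotella jejuni*
CD3:33, *Pseudomonas ogarae* F113) are flagged focal and form the default
working panel.

Two curation filters reflect how such panels are assembled from genome
annotations:

* **Adjacency.** A candidate immunity gene must be the next annotated gene
  downstream of the effector (downstream is strand-relative), on the same
  strand, with no intervening annotation and an intergenic gap ≤ 500 nt by
  default. The strand-concordance and gap ceiling operationalize "directly
  downstream"; known EI pairs are co-transcribed, so discordant-strand or
  distant candidates are rejected.
* **Triad integrity.** The translated effector (frame 0, standard code —
  panel sequences are CDS) is globally aligned to the reference effector
  protein with affine gaps (match +2, mismatch −1, gap open −10, extend
  −0.5; Biopython `PairwiseAligner`). The candidate residues in the columns
  of reference positions 39/53/55 must be D, D/E and K respectively; a gap
  in any triad column, or all three falling in terminal gaps ("no
  coverage"), marks the pair disrupted and it is removed. The heavy gap
  penalties keep the catalytic core in register even at ~40–60% sequence
  divergence. Curation is idempotent by construction.

## Containment prescreen

Samples are screened with scaled-MinHash (FracMinHash) sketches: canonical
k-mers (k = 21; lexicographic min of k-mer and reverse complement; windows
with non-ACGT characters skipped) are hashed to 64 bits and kept when the
hash falls below 2^64/scale. Containment of a panel query sketch in a
sample sketch estimates |Q ∩ S| / |Q| without bias; at scale = 1 it is the
exact set containment. A sample is retained when its best query containment
is **strictly greater than 0.2**. One query per EI pair (both genes
sketched together) is the default; per-gene queries are available
(`query_mode="gene"`), since it is genuinely ambiguous whether a screen of
this kind should use genomes or gene pairs as queries.

Numerical choices: hashing is stdlib `blake2b` truncated to 64 bits with a
keyed, recorded seed — sketches therefore serialize to plain JSON with
`{k, scale, seed, hashes}` and any two runs are comparable. The `scale`
default is 100 for realistically sized inputs, but the pipeline default is
scale = 1: the panel queries here are single genes (417–900 nt, i.e. a few
hundred k-mers), for which fractional sketches would retain too few hashes
to score stably. Sketches are unweighted (read abundance is ignored).

## Quality filtering and mapping

Reads are end-trimmed at Phred < 20 (maximal low-quality runs removed from
both ends; interior bases untouched), then dropped if mean Phred < 10 or
trimmed length < 50 nt. Surviving reads are aligned semiglobally against
every panel gene: global in the read, free end-gaps on the gene, scoring
match +1 / mismatch −1 / gap −2, both orientations. The implementation is a
numba-compiled dynamic program with full traceback; ties are broken
deterministically (leftmost best end column; diagonal over read-gap over
gene-gap during traceback; forward strand preferred on equal scores).
Exhaustive read × gene alignment is affordable because the reference is at
most a few dozen genes; an exact 11-mer seed prefilter (default on) skips
genes sharing no k-mer with the read and is verified in the tests to leave
emitted alignments unchanged.

Identity = matches / aligned columns, gap columns included. A read is
emitted only for its single best-scoring gene and only when identity ≥ the
stringency threshold: 0.90 by default, 0.70 as the permissive alternative
for sensitivity analysis. Equal-best ties across genes are dropped by
default (`tie_rule="drop"`) rather than split or assigned arbitrarily —
panel genes from different phyla are strongly diverged, so ties are rare
and ambiguous, and dropping them avoids inflating co-occurrence.

## Coverage, retention and detection

Per-base depth is piled up from accepted alignment spans. A (sample, taxon)
observation is **retained** when the concatenated rdnE+rdnI profile has
(1) mean depth > 2×, (2) at least one base > 5×, and (3) more than half of
its bases covered. All three are strict inequalities. A single gene is
**detected** when its own mean depth > 1×. The retention rule is the
sample-level inclusion gate; the per-gene rule decides ratio eligibility
and co-occurrence membership. The two-rule split resolves the tension
between a pair-level inclusion filter and a per-gene plotting/detection
cutoff; both are computed and reported side by side in the detection table.

Retention means are over the full gene (no interior restriction); the
generator's read-count rule conserves full-gene mean depth exactly, while
interior coverage runs slightly higher because read starts cannot overhang
the template (see below).

## Ratio and co-occurrence statistics

For each retained (sample, taxon) with both genes detected, the statistic
is log10(I/E), I and E the mean per-base depths of rdnI and rdnE. Records
with exactly one detected gene are tallied as candidate orphan
observations, never given infinite ratios. Ratio distributions are
summarized per (environment, taxon) by the raw-ratio median and a Gaussian
KDE whose kernel standard deviation is the bandwidth (default 0.4), on a
grid spanning the data ± 4 bandwidths at ≥ 512 points; the trapezoidal
integral of the density is within 1% of 1 by construction. The median is
always computed on raw ratios, not on the density curve.

Co-occurrence counts effector detections: a presence matrix (sample ×
taxon), exact-set (Euler) counts partitioning samples by their detected
taxon set, and symmetric pairwise counts. Requiring joint E+I detection for
membership is available as a flag (`require_both_genes`) but off by
default, since effector presence is the quantity of interest.

## Synthetic community generator

The generator emulates the statistical structure the analysis assumes:
per-taxon target depths for rdnE and rdnI (including orphan-immunity
regimes where rdnI depth ≫ rdnE depth), per-gene divergence from the panel
sequence (substitutions only, uniform over positions, each to a different
base), per-base substitution sequencing error with the matching constant
Phred score (optionally a degraded tail to exercise trimming), and
background reads from a random genome at a configurable fraction (default
10%). Reads are single-end, 150 nt, with uniform starts on
[0, L − read_length]; N = round(depth · L / read_length) per gene. Each
sample ships a JSON truth manifest (true depths, true log10 ratios, seed),
and identical spec + seed reproduce byte-identical FASTQ.

Deliberate simplifications, and what they imply for test evidence: no
indels (alignment identity is exactly interpretable, but indel-rich real
data will map slightly worse), no GC or abundance bias, no paired ends, one
Phred value per sample. Because N is deterministic and substitution-only
reads always align over their full length, recovered mean depths are exact
functions of the design; recovered ratio medians therefore deviate from
the planted truth only through read-count rounding (≲0.005 at the default
gene lengths). Passing recovery tests consequently demonstrates correctness
of the pipeline arithmetic under the stated error model, not robustness to
real-data artifacts.

## Validation problem sizes

The packaged experiments (also used by `scripts/acceptance.py`) run at
desk scale: ratio recovery uses three regimes of 20 single-taxon samples at
(rdnE, rdnI) depths (50,5), (20,20), (5,50) — about 12,000 reads total;
stringency sensitivity uses one sample each at 5% and 20% gene divergence
(depth 10×) mapped at both 0.90 and 0.70 identity; co-occurrence recovery
plants random focal-taxon subsets in 30 samples at 8× depth. Oracle
comparisons use 100 random sequence pairs (containment, bit-exact at
scale 1) and 200 random read/gene pairs (alignment score vs an independent
prefix-scan DP).

## Known limitations

* The mapper is not claimed concordant with any external aligner's identity
  definition or ambiguous-read defaults; only the stringency *thresholds*
  (0.90/0.70) carry over.
* Headline archive-scale counts (thousands of retained metagenomes) are
  functions of a ~500k-sample public corpus and are out of scope; the
  package reproduces the decision rules, not the archive.
* The packaged panel sequences are synthetic; analyses of real data must
  load the real gene sequences via `load_panel`.
* KDE conventions (grid, normalization) are fixed here; only the bandwidth
  is externally specified.
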