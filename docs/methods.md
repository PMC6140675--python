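# Methods

This note documents the models, conventions and parameter choices behind
each stage, what the synthetic-data generators do and do not emulate, and
the limitations a user should know before applying the pipeline to real
data.

## ORF prediction

ORF calling is purely structural. Both strands and all three frames are
scanned; within a frame, stop codons partition the codon string into
segments, and:

- a segment ending in a stop whose first ATG exists yields a **complete**
  ORF from that ATG to the stop (the "maximal" start→stop span);
- the leading segment of a frame, when it ends in a stop but contains no
  ATG, is reported **five_prime_partial** (the start may lie upstream of
  the assembled fragment);
- the trailing open segment yields a **three_prime_partial** ORF from its
  first ATG, or an **internal** ORF when it has no ATG;
- interior stop-to-stop segments with no ATG are not reported.

Start codons are ATG only; alternative starts and coding-likelihood
(Markov) scoring are deliberately out of scope — the only retention
criterion is the 5-aa minimum peptide length, chosen low because short
luciferin-precursor peptides are themselves of interest. Codons containing
N translate to X, and X never scores positively in alignment, so ambiguous
sequence cannot create spurious homology. Coordinates are 0-based half-open
on the reported strand; the stop codon lies inside the span but not in the
peptide. The "mature transcript" criterion used by the motif screen is
completeness: a start and a stop codon.

## Local alignment and search statistics

The aligner computes the exact optimal local alignment under affine gap
costs (a gap of length L costs `gap_open + L·gap_extend`) with the Gotoh
three-matrix recurrence; the inner loop is JIT-compiled. The traceback
prefers diagonal over up over left on ties, and the alignment ending
cell is the first maximum in row-major order, making results fully
deterministic. The default scheme is BLOSUM62 with gap open 11 / extend 1
and the corresponding gapped Karlin–Altschul parameters λ = 0.267,
K = 0.041.

Raw scores convert to bits as S′ = (λS − ln K)/ln 2 and E-values as
E = m·n·2^(−S′) with m the query length and n the total residue count of
the searched database. Two BLAST refinements are intentionally omitted:
effective-length (edge) corrections and composition-based score
adjustment. Bitscores therefore track blastp closely, while E-values are
systematically conservative by a modest factor on short sequences;
published E-values should be treated as consistency references, not
bit-exact targets. The homology decision itself is made on bitscores,
which do not depend on database size.

## Reciprocal screen

For each ORF × local database, the single best hit with E ≤ 10⁻⁵ is kept
(ties by lower E-value, then lexicographic accession). The best hit against
the curated reference database is computed **without** an E-value cutoff —
a weak reference hit must still be allowed to outscore a weak local hit —
and the candidate is retained iff the local bitscore is greater than or
equal to the reference bitscore. The comparison uses the single best
reference hit, the standard reading of a reciprocal best-hit screen.
Rejected candidates are first-class output (a photoprotein candidate that
"better matches calmodulin" is a result), reported with the winning
reference accession.

## Isotope-label mass analysis

Monoisotopic masses: C 12 (exact), H 1.00782503, N 14.0030740,
O 15.9949146, S 31.9720707, P 30.9737615 Da; ¹³C 13.0033548 Da, so each
label shifts the ion by 1.0033548 Da regardless of position. Adduct mass is
the **proton** (1.00727646 Da), not the hydrogen atom: the electron mass
(~0.00055 Da) matters at the fourth decimal place of m/z. The compound
table carries coelenteramine as C₁₇H₁₅N₃O and coelenterazine as
C₂₆H₂₁N₃O₃, their standard structures.

EIC extraction sums, per scan, the intensities of peaks within a **closed**
±tol ppm window (default 10 ppm); a 10⁻⁹ relative slack keeps
floating-point rounding from excluding a peak placed exactly on the
boundary (the boundary convention distinguishes 0.01 ppm differences, six
orders of magnitude above the slack). Detection reports the EIC apex
(earliest scan on intensity ties), the trapezoidal area over the whole
EIC, the ppm error between the intensity-weighted mean observed m/z at the
apex scan and the theoretical value (reported to 1 decimal place), and
whether the apex retention time falls within ±rt_tol (default 0.2 min) of
a reference standard's. An all-zero EIC yields an explicit "not detected"
report — absence (e.g. of intact coelenterazine in aged specimens) is a
reportable outcome. Exact integration bounds for peak areas are a free
convention; areas here are whole-EIC trapezoids and should not be compared
across tools.

## COI distances, delimitation, and NJ

p-distance is the uncorrected proportion of differing sites among
comparable sites, a site being comparable iff both sequences have A/C/G/T
there (pairwise deletion). Complete deletion of every column containing
any gap/ambiguity is available as a flag, since published ranges do not
always state which convention was used; on typical barcode alignments the
two differ by well under half a percentage point. A pair with zero
comparable sites has undefined distance and raises an error rather than
returning 0.

Species delimitation is single-linkage clustering at a cutoff (default
0.03, the conventional ~3% crustacean COI species boundary): connected
components of the graph joining pairs at or below the cutoff. The
misidentification flag reports a sequence whose nearest cluster (by mean
distance to the cluster's other members) is dominated by a different
species label than its own; it fires only when the foreign label strictly
outvotes the sequence's own label, so mixed clusters are not over-flagged.

The neighbor-joining tree is a desk-scale auxiliary view of the distance
matrix: standard Q-minimisation with Saitou–Nei branch lengths, negative
branch lengths clamped to zero, and ties in Q broken on the
lexicographically smallest pair of cluster representatives so output is
deterministic. NJ recovers additive metrics exactly (property-tested), but
it is not a substitute for model-based phylogenetics: no substitution
model, no bootstrap support.

## Synthetic data: what it emulates, and what it does not

The generators produce the *inputs* the pipeline consumes, with planted
ground truth:

- **Transcriptomes**: each planted homolog is a mutated copy of a source
  protein at a controlled identity (substituted positions chosen without
  replacement; replacements uniform over the 19 alternatives, so realised
  identity is the closest achievable to the target and no stops appear),
  back-translated with uniformly chosen synonymous codons, embedded behind
  an in-frame TAA guard so the ORF caller recovers exactly the planted
  peptide. Mature plants get a start and stop codon; non-mature plants
  omit the stop. Decoys are i.i.d. uniform nucleotides — at the database
  sizes used in testing the probability of a chance hit at E ≤ 10⁻⁵ is
  negligible, which the screen tests confirm empirically.
- **Peak lists**: Gaussian chromatographic profiles (0.2 min s.d. by
  default — a plausible UPLC peak width; real peak shape is irrelevant to
  apex/area logic), one centroid per scan within ±4 s.d., m/z jittered
  uniformly within ±ppm_jitter. Noise peaks are uniform over the run and
  the 100–1000 m/z range with a guard band of max(3×jitter, 12) ppm around
  planted ions, so that a 10 ppm extraction window can never pick up
  noise; the 12 ppm floor exists because 3×jitter alone would be narrower
  than the extraction window at small jitter.
- **COI alignments**: a star-within-species / split-between-species
  genealogy with uniform (Jukes–Cantor-like) substitutions. Per-branch
  change probabilities are solved through the substitution process
  (per-site identity coefficients 1 − (4/3)q multiply along a path, and
  p = (3/4)(1 − s_path)), then applied as *exact* mutation counts at
  positions sampled without replacement, so realised within/between
  p-distances concentrate tightly on their targets even at barcode length
  (600 nt); a per-site Bernoulli scheme would scatter a sizeable fraction
  of replicates outside a ±10% relative band.

Not emulated: read-level error and assembly artefacts (transcripts appear
fully assembled), paralog families and repeat structure, isotope
fine-structure envelopes and detector saturation, chromatographic drift
between runs, alignment error in COI matrices, and rate variation across
sites. Passing the fixture-based tests therefore demonstrates the
correctness of the *computations* on well-formed inputs, not robustness to
assembly or alignment artefacts, which the user's upstream tools must
handle.

All generators take an explicit seed and produce byte-identical output for
identical parameters.

## Problem sizes used in the test suite

The oracle-equivalence and recovery tests run at sizes chosen to exercise
every code path while keeping the default suite fast: 500 random peptide
pairs (length ≤ 30) against a brute-force affine-gap DP for the aligner;
200 random transcripts (≤ 800 nt) against exhaustive ORF enumeration; 20
independently seeded screen fixtures (plants at 60–90% identity among
random decoys); 50 random additive trees (4–10 leaves) for NJ; and
multi-species COI fixtures at barcode length 600 nt with within-species
divergence ≤ 2% and between-species divergence ≥ 10%, bracketing the
~3% delimitation cutoff from both sides with published-scale divergences.

## Known limitations

- E-values lack BLAST's edge and composition corrections (see above).
- The aligner is exhaustive (no heuristic seeding); it is meant for ORFs
  against curated databases of tens-to-thousands of proteins, not for
  all-vs-all searches of millions of sequences.
- Only the [M+H]⁺ singly charged adduct is implemented; other adducts and
  charge states would need additional arithmetic.
- The genetic code is the standard table; mitochondrially encoded ORFs
  are outside the intended use of the ORF caller (COI sequences are
  handled purely as nucleotides).
- The misidentification flag operationalises a qualitative judgment; its
  output is a pointer for curation, not an authority.
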