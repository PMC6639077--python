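# Methods

## The question and the quantities

For each reference protein carrying an N/Q-rich prion(-like) domain the
pipeline produces, at each of three nested taxonomic levels (genus ⊆ WGD
group ⊆ class):

* a **domain mean conservation** — the mean of normalized per-column
  conservation scores over the alignment columns carrying the domain;
* a **whole-sequence mean conservation** over all unmasked columns;
* the reference's own prion score (**SCPS**) and the **EWPS**, a
  divergence-weighted mean of its orthologs' prion scores.

The comparison layer then contrasts the known-prion (KP), prion-former (PFP)
and prion-like (PLP) sets on these quantities.

## Pairwise alignment and statistics

BLAST-style searching is replaced by exact Smith–Waterman under BLOSUM62
with affine gaps. The gap convention is BLAST's: a gap of length *g* costs
`open + g·extend` with open = 11, extend = 1 (so the first gap residue
costs 12). Scores convert to bits and E-values with the BLASTP gapped-default
Karlin–Altschul parameters for this matrix and penalty pair, λ = 0.267,
K = 0.041:

    bits = (λ·S − ln K) / ln 2        E = K·m·n·exp(−λ·S)

with m, n the two sequence lengths. Using the per-pair product m·n rather
than a database-effective search space makes E-values a few hundred-fold
more permissive than a whole-proteome BLAST would report at desk scale; this
does not disturb best-hit orthology for the candidate proteins (their true
orthologs score far above threshold) but it is the reason ortholog searches
are run *from the candidate reference proteins* (see below). An
outfmt-6-like tabular reader allows substituting externally computed hits
when exact BLAST statistics are wanted.

Percent identity is counted over aligned (non-gap) columns, matching
BLAST's identities/alignment-length; whether identity should instead be
normalized by full sequence length is a known ambiguity, and this choice is
kept consistent everywhere (weights, guide trees).

Two independent implementations back these numbers: a numba-compiled Gotoh
score kernel (used for batch best-hit scans) and Biopython's
`PairwiseAligner` (used for alignment paths and identity). They agree
exactly and are both checked against a brute-force DP oracle in the tests.

## Orthology

A reference protein's ortholog in another proteome is its bidirectional
best hit (BDBH): the subject with maximal bitscore among hits with
E ≤ 0.001 such that, searched back against the *full* reference proteome,
its best hit is the reference protein again. Ties in bitscore break by
higher percent identity, then lexicographic id. The reference proteome is
never searched against itself (no self-orthologs), and each species
contributes at most one ortholog per family.

Forward searches run from the candidate reference proteins rather than from
every protein of every proteome. This matches how the analysis is consumed
(families are only ever built for the examined proteins) and has a
statistical consequence worth stating: with unrelated decoy proteins in the
proteomes, all-vs-all BDBH at E ≤ 0.001 under the per-pair E convention
would admit roughly `0.001 × (number of decoy pairs)` chance reciprocal
hits — about 20 spurious pairs per species pair at the synthetic study's
scale — whereas candidate-query BDBH admits essentially none, because a
chance hit would additionally have to outscore a true ortholog in both
directions.

## Multiple alignment

Families are aligned with a deterministic progressive aligner: UPGMA
(average linkage) on distances d = 1 − %identity/100, then profile–profile
global Gotoh merges using occupancy-weighted column frequency vectors
(counts/rows; gap positions contribute nothing, so sparse columns carry
proportionally less substitution score) and the same gap convention as
above. No iterative refinement. Disorder-aware aligners handle N/Q-rich
low-complexity regions better; because the downstream statistics depend
only on column composition, the pipeline accepts precomputed alignments
(plain gapped FASTA, `<ref_id>.<level>.afa`) in place of the built-in
aligner, and each family is aligned per level rather than once and
subset. Every output row ungaps exactly to its input sequence; this is a
tested invariant.

## Conservation

For column *i* with residue frequencies p estimated by unweighted counts
over non-gap symbols (X carries no compositional information and is
excluded, as are gaps — no 21st symbol):

    S(i) = Σₐ p·ln p

so a perfectly conserved column scores 0 and diversity drives the score
negative. Columns with gap fraction > 0.5 are masked. Scores over the
unmasked columns are normalized to zero mean and unit SD, so a positive
value is "more conserved than this alignment's average column". Means over
whole sequences exclude masked columns (the alternative — including them —
is a sensitivity worth checking when comparing against other tools).
Domain means use the columns onto which the 1-based reference-coordinate
domain interval maps; a domain whose columns are all masked is flagged
undefined and excluded from downstream statistics. If every column has the
same raw score the normalized scores are all zero (with a warning) rather
than undefined.

## Prion scoring

A two-state hidden Markov model: a background state emitting the proteome
residue composition and a prion-like state emitting the composition of
N/Q-rich prion-forming domains. Working in log-odds units (the background
emission cancels), residue *c* contributes ln(prion(c)/background(c));
X contributes exactly 0. Decoding uses Viterbi over an expanded chain —
background, then P₁…P_core with forced advancement below the core length —
so any decoded prion run is at least `core_length` residues (default 60).
The enter and exit probabilities are a single pair, both 1/core, making the
expected prion-state dwell time equal the core length; they shape the
decoding only and do not enter the score.

* **PRD score** = Σ log-odds over all decoded prion-state residues, clamped
  at 0; sequences where the model finds nothing score exactly 0 (never
  negative, never missing), and zeros are retained in all downstream
  summations.
* **domain interval** = the decoded run (the highest-scoring one if
  several); absent whenever the unclamped total is ≤ 0.
* **LLR** = the maximum log-odds sum over any window of core length
  (ties to the smallest start; sequences shorter than the window use the
  single full-length window).

The shipped frequency tables are an N/Q-rich composition modelled on
experimentally characterized yeast prion-forming domains (N ≈ 0.20,
Q ≈ 0.18, enriched S/G/Y/P, depleted charged and hydrophobic residues) over
a standard S. cerevisiae proteome background. They are approximate,
versioned in `src/prioncons/data/`, and swappable via two-column TSVs; all
conclusions the tests establish are about planted-composition recovery,
which is robust to the exact values. One background table is applied to
every species scored (a per-species background is a config-level extension,
not implemented).

## EWPS

    EWPS = Σᵢ wᵢPᵢ / Σᵢ wᵢ

over the orthologs of a family (the reference is excluded: its PC weight
would be 0 and its BS weight 1 would dominate). Pᵢ is the ortholog's
clamped PRD score; zeros stay in the summation. Two weightings:

* PC: wᵢ = 1 − %identityᵢ/100
* BS: wᵢ = bitscoreᵢ / self-bitscore (clamped into [0, 1])

Note the two published formulas pull in opposite directions — PC gives
*divergent* orthologs more weight, BS gives *similar* ones more weight.
Both are implemented exactly as defined rather than harmonized; empirically
they rank families almost identically (Spearman ρ ≈ 0.94 on the synthetic
study), which is why the discrepancy has little practical consequence.
Families with no orthologs or zero total weight (every ortholog 100%
identical under PC) are flagged undefined: they appear with EWPS 0 in
ranking tables but are excluded from correlations.

## Statistics

* Welch's two-sided t-test (unequal variances) for set-vs-set mean
  conservation; KP is compared against PFP-*minus*-KP so groups are
  disjoint.
* Mann–Whitney U, two-sided, for EWPS/SCPS set comparisons: exact
  enumeration when both n < 20 and the data are tie-free, otherwise the
  tie-corrected normal approximation with continuity correction.
* Pearson r with the t-transform p-value for EWPS↔SCPS and
  EWPS↔conservation correlations; undefined entries removed pairwise.
* Thirds consistency: per level, proteins are ranked by domain mean
  conservation (descending, ties by id) and split top/middle/bottom; when n
  is not divisible by 3 the top third takes the first extra member and the
  bottom the second. Reported: the fraction keeping their third at every
  level and the proteins traversing all three thirds. The construction is
  invariant under monotone transformations of the values.
* No multiple-testing correction; raw p-values are reported.

## The synthetic study

The generator is the package's study design, not a test fixture. Defaults:
8 species in nested tiers of 2 (genus), 4 (WGD) and 8 (class), at depths
1.0 / 2.5 / 4.5 expected flank substitutions per site × rate 0.10 — i.e.
roughly 90% / 78% / 64% flank identity to the reference, spanning the
divergence range BDBH must handle. The ancestor is 60 flank + 60 domain +
60 flank residues (proteome-composition flanks; domain 80% N/Q, 55:45 N:Q,
remainder background-distributed). The reference species sits at the
star's centre (zero branch), so reference-coordinate ground truth is exact.
Substitutions draw replacements from the segment's stationary composition;
indels are geometric (mean 2) at 0.005 events/site/depth and stay within
their segment, keeping the true domain interval exact in every descendant.
Category analogs plant the rate structure KP : PFP : PLP = 3 : 2 : 1 on the
domain only. Unrelated decoys are fresh draws from the flank composition at
5× the family count per species.

What this emulates: rate heterogeneity between a low-complexity domain and
its flanks, nested divergence tiers, ortholog presence/absence, and
composition-preserving drift. What it does not: paralogy from genome
duplication, gene loss beyond random dropout, realistic rate matrices or
site-rate variation, and real low-complexity repeat expansion. Passing
recovery tests therefore demonstrate the pipeline's correctness and
sensitivity under the planted model, not performance on any particular real
proteome snapshot; quantities computed on real data will depend on the
database snapshot used.

Problem sizes used by the test suite and the acceptance script — 20 seeds ×
30 families × 5× decoys for ortholog recovery, 100 replicates per rate
multiplier for conservation recovery, 20 families per category for the
set-comparison twin, 100 constructions for domain recovery — were chosen as
the smallest scales at which the binomial/rank statistics involved are
stable, and are stated alongside each result (`"n"`).

## Numerical conventions and edge cases

* Gap character `-` only; `.` converted on read; B/Z/U/O/J map to X with a
  warning (or are rejected per config).
* Domain intervals are 1-based inclusive in ungapped reference coordinates
  (UniProt feature convention); alignment columns are likewise reported
  1-based.
* Local alignments with no positive-scoring cell follow the
  empty-alignment convention: raw score 0, identity 0, E = K·m·n.
* All randomness flows from a single integer seed; pipeline re-runs are
  byte-identical, and completed stages are skipped (outputs untouched)
  unless forced.

## Known limitations

* The built-in aligner is a generic progressive aligner; for publication
  use on real N/Q-rich proteins, ingest alignments from a disorder-aware
  tool.
* E-values use per-pair m·n (see above); BDBH membership is insensitive to
  this for candidate queries, but reported E-values are not comparable to
  whole-database BLAST E-values.
* The prion-state frequency tables are approximate reconstructions;
  absolute PRD-score values are therefore not directly comparable to other
  tools' outputs, though orderings and recovery behaviour are robust.
* Sequence-weighted frequency estimation and sum-of-pairs/matrix-based
  conservation measures are out of scope (entropy measure only).
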