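# Methods

## Scope and model

`cnsfoot` detects short conserved noncoding blocks between two long,
mostly unalignable loci and interprets them as candidate regulatory
elements.  The underlying model of sequence evolution is the one the
detection strategy assumes: neutral noncoding background diverging at
close to one substitution per site plus frequent indels, against which
short functional islands (binding-site clusters) evolve under strong
constraint, remain co-linear, occasionally flip orientation, and are
diluted — on one lineage — by transposable-element expansion.

## Coordinates and formats

Internally every interval is 0-based half-open with a strand flag;
minus-strand features are stored coordinate-sorted, never with swapped
endpoints.  The printed-table dialect (`TSV1`) is 1-based inclusive with
minus-strand query coordinates printed descending; conversion happens only
at the I/O boundary and round-trips exactly for intervals of at least
2 bp (a 1-bp descending pair is indistinguishable from ascending, so its
strand prints as '+').  FASTA I/O goes through Biopython; non-ACGTN
residues are replaced by N with a logged warning.

## Local alignment statistics

The scoring scheme is match/mismatch with affine gaps (defaults
+1/−2, gap open −5, gap extend −2, uniform background).  λ is obtained by
bracketed root-finding (`scipy.optimize.brentq`) on
f(λ) = p_match·e^{λ·match} + (1−p_match)·e^{λ·mismatch} − 1, after
rescaling scores by their gcd; the residual of the defining equation is
below 1e−9.  K uses the partial-sum series of the associated random walk

σ = Σ_k (1/k)·[P(S_k ≥ 0) + E(e^{λS_k}; S_k < 0)],
K = e^{−2σ} / (av·(1 − e^{−λδ})),

with `av` the mean step of the tilted walk and δ the lattice span of the
(rescaled) score support.  The series is evaluated by repeated
convolution of the step distribution until the k-th term falls below
1e−12 (at most 500 terms).  For +1/−1, +1/−2 and +2/−3 on uniform
backgrounds this reproduces the ungapped (λ, K) printed by NCBI blastn
2.17 to the displayed precision (0.333, 0.621, 0.408); the test suite
pins those values as an independent reference.  Gapped hits reuse the
ungapped parameters — the standard approximation — and e-values use the
plain m·n search space with no edge-effect correction, which only affects
marginal hits near the cutoff.  No bit-for-bit equality with any
particular BLAST build is claimed.

## Seed-and-extend detector

Exact 7-mers seed both strands (the conserved unit being one or two
adjacent ~6–8-bp binding sites; an 11-mer seed would miss short islands
at 85% identity).  Each seed is extended ungapped in both directions with
an X-drop rule (default drop 20), skipping seeds already covered on the
same diagonal.  Cores whose ungapped score is more than 50-fold in
e-value above the cutoff are discarded — gapped refinement can only raise
a score, so this prunes safely — and overlapping cores that the same
window would refine are collapsed best-score-first.  Survivors are
re-aligned by an affine-gap Smith–Waterman (Gotoh) pass on a window
padded by 25 bp, with full traceback for per-column statistics (percent
identity rounded half-up to 2 decimals; gap opens count maximal gap runs,
not gap columns).  Hits at e ≤ 0.1 are reported; a hit wholly contained
in a higher-scoring hit within 16 diagonals is dropped, and remaining
ties order by leftmost reference then query start.  Minus-strand hits are
computed on the reverse-complemented query and mirrored back, which makes
the hit set exactly symmetric under reverse-complementing either
sequence.

The windowed-identity caller defines a conserved segment as the union of
all windows of ≥ `min_width` columns whose identity (gap columns counting
as non-identities) is ≥ `min_identity`; maximal merged runs are reported
with their overall identity.  The union is computed exactly (per-start
vectorised scan, O(L²) worst case), matching a window-enumeration oracle
bit for bit; parameter presets follow the conventional (100 bp, 70%) and
(25 bp, 85%) settings.

## Filtering and cross-validation

A hit is discarded when more than `max_overlap_frac` (default 0.5 — "most
of the hit") of its span in either species is covered by coding sequence
(reason `coding`, taking precedence) or repeats (reason `repeat`);
coverage uses merged feature overlap, so nested annotations do not double
count.  The filter is idempotent and the report accounts for every input
hit.  Cross-validation flags a block as recovered when any block from the
second-reference comparison overlaps it on the shared query axis by
≥ `min_overlap_bp` (default 1 bp: recovery is block identity, and any
overlap of tens-of-bp blocks identifies them).

## Clone-contig projection

Clone offsets come from anchor pairs — the same block observed in two
overlapping clones.  Each anchor implies offset(B) = offset(A) + posA −
posB; multiple anchors for a pair are averaged (exact least squares for a
single offset parameter), and a spread beyond `tolerance` raises an error
naming the pair.  The default tolerance is 10 bp (sequencing-scale
agreement).  The packaged clone map is built with a 2 000 bp tolerance
instead: its overlapping clones carry *different alleles* of the same
region, and the three anchors joining one clone pair disagree by up to
1.6 kb of allelic indels.  Pairs with no anchor are assumed to abut and
are flagged.  The nonredundant span is Σ clone lengths − identical
overlap − allelic overlap.

## Colinearity

Blocks are sorted by reference start; their query positions are clone
coordinates projected to the contig.  Midpoints are the default ordering
statistic so minus-strand blocks need no special casing (start/end are
available and give the same fixture result).  The maximal colinear chain
is the longest strictly increasing subsequence (patience sorting,
O(n log n); among equal-length chains the lexicographically earliest by
reference order).  Chaining is unweighted — blocks are near-uniform tens
of bp.  Blocks outside the chain are order breaks, classified by **rank
displacement** (|query-order rank − reference-order rank|): displacement
below 5 is a local shuffle, the signature of microrearrangement among
immediate neighbours; displacement ≥ 5 is a clear long-range break.  On
the packaged 28-block table the strict chain has 22 members and 6 breaks
— five local shuffles (displacement ≤ 3, forced by within-clone coordinate
flips that no strictly increasing projection can undo) and exactly one
clear break (displacement 15): the last reference block, which maps back
into the middle of the query contig.  Orientation flips never affect
chain membership; they are counted separately as microinversions.

## Motif scanning and architectures

IUPAC consensi are matched positionally on both strands; a window
matching on both strands (self-reverse-complementary) is reported once,
unstranded.  The shipped dictionary carries only consensi anchored in the
proneural-enhancer literature (E-box `CANNTG`, N-box `CACNAG`, En/Antp
`TTAATTAA`, Ara/Caup `ACA`, TATA `TATAWAW`); α-box and β-box consensi are
not published and ship as empty placeholders that must come from user
configuration — the package never invents binding-site definitions.  The
3-bp Ara/Caup site is meaningless genome-wide and should be counted only
inside user-chosen windows such as a conserved block.  Architectures are
ordered site lists over a window; two architectures conserve order iff
one ordered motif-name string is a subsequence of the other (LCS equals
the shorter length), and count tables are reported per motif.

## Locus-size estimates and reporting

Two estimators are implemented exactly as stated proportionalities:
locus·(query genome/reference genome), and sequenced span/covered
fraction.  On the published inputs (104 kb locus, 176 Mb vs 750 Mb
genomes; 530 kb sequenced at 78% coverage) these give 443.2 kb and
679.5 kb; the published analysis rounds the same calculations to 452 and
660 kb, and the report documents the deviation rather than matching the
rounded claims.  Clone summaries round percentages half-up to 2 decimals.
Of the 28 packaged blocks, 18 carry enhancer footnotes (7 wing disc,
2 UTR, 9 embryonic nervous system); the published prose total of 22
(13 embryonic) cannot be reconstructed from the printed rows, so only the
footnote-derived counts are computed.  Enhancer coordinates are not
printed either; the packaged enhancer track reuses the footnoted blocks'
own reference intervals (labelled synthetic), which is exact for overlap
counting by construction.

## Synthetic data

The simulator emulates the assumed evolutionary scenario on the fixed
topology ((ref1:t1, ref2:t2):t3, query:t4), defaults (0.1, 0.1, 0.3,
0.4): 0.8 substitutions/site between query and references, 0.2 between
the references.  Substitutions are Jukes–Cantor per branch (a site
differs with probability (3/4)(1 − e^{−(4/3)rt})); islands and coding
sequence use a reduced rate scale (default 0.15, i.e. ~0.12 subs/site on
the query–reference path, within the ≤15% island-divergence regime the
detector targets).  Indels occur only in unconstrained background
(Poisson events, geometric lengths of mean 3, insertion/deletion
equiprobable), so every planted island and gene survives in every taxon
exactly once and the cross-taxon identity map is a bijection by
construction.  TEs are inserted on the query branch only, as slices of a
4-element internal library with 5% per-copy divergence; the default rate
of 0.37 events/kb with 300–1500 bp copies is calibrated so the expected
query repeat content is ~25% (0.37·0.9 kb ≈ 1/3 of the ancestral length,
i.e. a quarter of the expanded locus).  Each island flips orientation on
the query branch with probability 0.1.  The default ancestral locus is
12 kb with 3 intronless co-oriented genes (600–1000 bp) and 10 islands
(20–60 bp) — a scaled-down emulation chosen so that a 20-locus benchmark
is cheap while the statistical regime (island length, divergence, repeat
fraction, background unalignability) matches the target scenario; locus
length itself does not enter the detector beyond the m·n term.

What the simulator does **not** model: realistic codon evolution,
selection beyond the two-rate scheme, indels inside constrained features,
TE activity on the reference lineages (so repeat-vs-repeat artifact hits
between query and reference do not arise in simulation and the repeat
filter is exercised through the truth track), allelic variation between
overlapping clones, and large-scale rearrangement beyond island flips.
Passing benchmarks therefore demonstrate detector calibration and
recovery in the assumed regime, not performance on real TE-rich genomes.

## Numerical and testing choices

Percentages round half-up (decimal arithmetic) to 2 decimals.  Identity
thresholds compare as 100·matches ≥ threshold·width in floating point,
the same arithmetic the enumeration oracle uses, so implementation and
oracle agree exactly.  Smith–Waterman tie-breaks prefer diagonal moves
and the smallest end coordinates; scores were cross-checked against
Biopython's local `PairwiseAligner` as an independent implementation.
The LIS oracle suite enumerates all permutations up to n = 6 and 100–200
random permutations at n = 7, 8 against the exhaustive-subsequence
oracle, keeping the suite fast while still covering every small case
exhaustively.  The planted-island benchmark (20 loci at defaults)
recovers ≈90% of islands with ≈0.5–1.0 spurious non-island, non-repeat
hits per locus at e ≤ 0.1 — consistent with the e-value calibration,
which predicts ~0.1 background hits per comparison plus occasional
boundary effects.

## Known limitations

The aligner is a surrogate for early blastn-era tools, not a
reimplementation: printed e-values/bit scores of historical runs are
reference shapes, not regression targets.  K is ungapped theory applied
to gapped scores.  The windowed caller is O(L²) worst case and meant for
alignments up to a few kb.  The clear-break displacement threshold (5) is
a reporting convention; the strict LIS partition is always available
alongside it.
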