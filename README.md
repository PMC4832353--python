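# cnsfoot

Phylogenetic footprinting of fast-turnover noncoding DNA: detection and
interpretation of conserved noncoding sequences (CNS) between diverged
insect loci, built around the comparative analysis of the *achaete-scute*
complex (AS-C) between the blowfly *Calliphora vicina* and *Drosophila*
references.

## The problem

Insect cis-regulatory DNA turns over fast: enhancers keep their function
while their sequence becomes unalignable over ~150 Myr.  What survives are
short islands — a few tens of bp, often one or two adjacent transcription
factor binding sites — embedded in a large nonconserved background.  In a
species whose genome has expanded several-fold (TE-driven, ~25% repeat
content), these islands are the only sequence-level trace of conserved
regulatory elements.  `cnsfoot` provides the complete analysis chain for
finding and interpreting them:

1. **Detection** — a seed-and-extend local aligner (exact word seeds,
   ungapped X-drop extension, gapped Smith–Waterman refinement) scored
   with Karlin–Altschul statistics: for a hit of raw score *S* against
   sequences of lengths *m, n*,

   E = K·m·n·e^(−λS),  with λ the positive root of Σᵢⱼ pᵢpⱼ e^(λsᵢⱼ) = 1

   and *K* computed by the classical partial-sum series of the score
   random walk (validated against NCBI blastn's ungapped parameters).
   A VISTA-style windowed percent-identity caller over fixed alignments
   (e.g. minimum width 25 bp at 85% identity) complements it.
2. **Filtering** — hits mostly covered by coding sequence or repeats are
   discarded; blocks are cross-validated against a second reference
   species on the shared query coordinate axis.
3. **Clone-contig projection** — BAC-clone coordinates are placed on one
   contig axis from overlap anchors (least-squares offsets), with
   identical- and allelic-overlap accounting.
4. **Colinearity** — the maximal colinear chain is the longest strictly
   increasing subsequence of projected query positions; blocks outside the
   chain are classified by rank displacement into local shuffles
   (microinversion scale) and clear long-range breaks.
5. **Motif architecture** — IUPAC consensus scanning on both strands
   (E-box `CANNTG`, N-box `CACNAG`, En/Antp `TTAATTAA`, ...), adjacent
   site-pair detection, and cross-species comparison of enhancer
   architectures (site counts plus subsequence order conservation).
6. **Reporting** — enhancer-category overlap counts, per-clone gene and
   repeat accounting, and locus-size estimates by genome-size scaling and
   by conserved-span coverage.

A three-taxon locus-evolution simulator (`((ref1,ref2),query)` tree,
two-rate island/background substitution model, geometric indels, TE
insertion on the query branch, island microinversions) provides planted
truth sets for benchmarking the detector.

## Worked example

Reference-locus analysis from the packaged tables (six sequenced BAC
clones, 28 cross-validated conserved blocks):

```bash
cnsfoot report --out report_out
```

prints (abridged):

```json
{
  "n_blocks": 28,
  "n_recovered": 28,
  "n_chain": 22,
  "n_breaks": 6,
  "n_clear_breaks": 1,
  "clear_break_ref_starts": [109968],
  "n_inversions": 14,
  "total_bp": 651394,
  "repeat_bp": 165646,
  "repeat_pct": 25.43,
  "nonredundant_span_bp": 529566,
  "nonredundant_gene_bp": 2634,
  "wing_disc_blocks": 7,
  "utr_blocks": 2,
  "embryonic_ns_blocks": 9,
  "ref_coverage_fraction": 0.8048,
  "locus_size_genome_scaled_kb": 443.2,
  "locus_size_coverage_kb": 679.5
}
```

Reading: all 28 conserved blocks found against the first reference are
recovered against the second; their order along the two genomes is
colinear up to five local shuffles, with a single clear long-range break
(the block at reference position 109 968, which maps back into the middle
of the query contig).  Fourteen blocks are orientation-flipped
(microinversions).  The six clones total 651 394 bp of which 25.43% is
repeat; removing 38 828 bp of identical and 83 000 bp of allelic clone
overlap leaves a 529 566 bp nonredundant span carrying one copy of each
of the three genes (2 634 coding bp).  The conserved blocks span ~80% of
the 120-kb reference window, and the two size estimators put the full
query locus at 443.2 kb (genome-size proportionality) or 679.5 kb
(coverage extrapolation).

An end-to-end run on a simulated locus:

```bash
cnsfoot run --out run_out        # uses default config, seed 0
```

simulates a 12-kb ancestral locus with 10 planted islands, ~25% query TE
expansion and 0.8 substitutions/site background divergence, detects
blocks against both references, filters, cross-validates, chains and
scans motifs; `run_out/summary.json` reports, per stage, hit counts plus
the truth-based island recovery and spurious-hit rate.

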