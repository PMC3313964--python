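# Methods

## Distance model

Pairwise divergence uses the Kimura two-parameter substitution model,
which distinguishes transitions (A↔G, C↔T) from transversions. For a pair
of aligned sequences, columns where either member carries a gap (`-`), a
missing-locus symbol (`?`) or an IUPAC ambiguity code are excluded
(pairwise deletion). Over the remaining *n* comparable columns with
transition proportion *P* and transversion proportion *Q*, the per-site
rate is

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

An entry is undefined when *n* < `min_overlap` (default 50 — low-overlap
pairs arise naturally from concatenations with missing loci, and their
distances would be noise-dominated) or when either logarithm argument is
non-positive (saturation). Distances are stored per site and rendered per
100 sites in all reports, with table percentages rounded half-up to one
decimal. Treating ambiguity codes as missing rather than as partial
information is the conservative standard for distance barcoding; `-` and
`?` are deliberately both non-comparable but kept distinct in storage so
alignment gaps and absent loci can be reported separately.

## Tree construction

Neighbor-joining follows the classic agglomeration: join the pair
minimising Q(i,j) = (m−2)·d(i,j) − r(i) − r(j), branch lengths from the
standard two-point formulas, distances to the merged node by the reduction
d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2. Two numerical choices matter:

- **Tie-breaking.** The active node list is kept in creation order (input
  leaf order, merged nodes appended); among equal Q values the lowest
  (row, col) pair wins. This makes the topology a pure function of the
  input matrix.
- **Negative branch lengths.** Clamped to zero with the deficit moved to
  the sister edge so the joined pair's path length is preserved (standard
  practice); raw values are retained in a log on the tree object.

Undefined matrix entries entering NJ are imputed with the maximum finite
distance and counted; this keeps partially sequenced samples in the tree
rather than dropping them, and the count is surfaced in the report. On
additive (tree-metric) inputs the implementation reconstructs the
generating topology and path lengths exactly; the test suite verifies this
against exhaustive least-squares search over all unrooted topologies for
up to seven leaves.

Bootstrap support resamples alignment columns with replacement, rebuilds
the distance matrix and NJ tree per replicate, and counts each internal
bipartition of the *original* tree across replicates (support is mapped
onto the single NJ tree, not a consensus — matching how barcoding studies
annotate one tree). Replicates whose resampled matrix has no defined entry
are discarded and the effective replicate count reported. Default 1000
replicates; a single integer seed drives all resampling. Rooting places
the root on the outgroup's pendant edge (midpoint rooting as a flagged
fallback); supports are re-attached by bipartition identity after
rerooting, so annotations never migrate to a different split.

## Species discrimination

A species is discriminated when more than τ (default 0.5, strict — "more
than half") of its individuals form one clade containing no other species'
individuals, on the rooted tree. Flagged samples are ignored on both sides
of the purity test. Singleton species are trivially "monophyletic" as
single leaves, so they are reported separately and excluded from the
headline count and its denominator (the number of multi-sample species).
Misidentification flags are advisory and require both (i) the smallest
clade joining the sample to any conspecific to contain ≥2 other species,
and (ii) the nearest neighbor by K2P to belong to a different section.
Samples without conspecifics are never flagged.

## Leave-one-out identification

The aligner is a small BLAST-style heuristic: exact word seeding (default
word size 11), seed diagonals clustered, then a banded affine-gap
Smith–Waterman extension (default half-band 24) around each cluster. The
spec-level ungapped X-drop stage is folded into the banded DP: within the
band the score is the exact local optimum for the scoring scheme, so on
pairs whose optimal alignment stays within the band the heuristic equals
full Smith–Waterman (verified in tests); pairs sharing no seed word score
zero. Scoring defaults +1/−2 with gap open −5 (first gapped position) and
extend −2 are a conventional nucleotide-BLAST-like configuration; all
parameters are exposed in `AlignerConfig` and echoed into reports.

Each sequence is queried against all others (gaps stripped first), the
self-hit excluded, and hits ranked by score with ties broken by smaller
K2P distance, then lexicographic subject id. The tie-break distance is the
K2P over the dataset's aligned columns rather than over the local
alignment span only — the two coincide in rank on the shallow-divergence
data this targets, and the aligned-columns value is already computed for
the distance matrix. "Top-3" means the three best-scoring distinct
records, not distinct species. Queries with no scoring hit are recorded
as unidentifiable and excluded from accuracy denominators, and per-species
accuracy is summarised over species with at least two sequences (a
leave-one-out query cannot match a conspecific it does not have);
singleton species are counted separately. Section-assignment rates are
given per section with both the unweighted mean over sections and the
sample-weighted mean.

## Alignment cleaning and indel accounting

In coding loci, a run of columns where exactly one sample carries residues
and all others are gapped (a private insertion) is treated as a processing
error and deleted; a gap run private to one sample (private deletion) is
logged but left in place, since nothing can be restored — whether such
runs should instead be column-deleted is genuinely open, and logging
without modification is the least destructive choice. Non-coding loci are
never modified.

The indel catalogue groups maximal gap runs by exact span: runs that
overlap but differ in endpoints are distinct events (span-exact grouping
is reproducible, and real datasets do contain near-identical spans that
were counted separately). Events are classified autapomorphic (one
carrier), clade-diagnostic (carriers exactly the union of whole sampled
species, or one whole section), otherwise shared. Runs touching the first
or last column are treated as terminal missing tails from incomplete
reads and excluded. Coordinates are 0-based half-open internally, 1-based
inclusive in logs.

## Synthetic data generator

The generator emulates the regime the pipeline is designed to expose:

- **Species tree.** Ultrametric, depth T (expected substitutions/site),
  sections monophyletic; within-section split ages uniform in a
  configurable window of T, section joins near the root (root pinned at
  exactly T), optional outgroup attached at 2.2 T. Expected divergence
  between random species ≈ 2 T.
- **Gene trees.** Within-species Kingman coalescence with mean pairwise
  time θ/2 (so mean intraspecific divergence ≈ θ), truncated at each
  population boundary; lineages escape their species' tip population with
  probability `ils` and only coalesce in ancestral populations. This
  phenomenological treatment of incomplete lineage sorting produces
  species non-monophyly and cross-species haplotype sharing without full
  multispecies-coalescent machinery, which is all the downstream
  statistics are sensitive to.
- **Sequences.** K2P substitution process (transition/transversion ratio
  κ, default 2) along the gene tree via the closed-form transition
  probabilities; per-locus relative rates scale branch lengths.
- **Indels.** Non-coding loci receive Poisson-many gap-block events
  (branch chosen proportional to length, geometric lengths, deletions gap
  the subtree / insertions gap its complement); coding loci are indel-free
  except optional planted single-sample insertions used to exercise the
  cleaning step. The alignment emitted is the truth — no realignment.
- **Labels.** A configurable fraction of samples from multi-sample
  species is relabelled as a species from a different section (planted
  misidentifications). Metadata shows the assigned species; the ledger
  records the truth.

Every event is written to a truth ledger (true species/gene trees,
planted indel spans and carriers, label swaps), which the tests compare
pipeline output against.

Two presets define the study conditions. `fraxinus-like`: 56 species in 6
sections, 253 samples (7 singletons, 2–28 samples/species), two spacer
loci of 698 and 1023 columns with indels and per-locus missingness of
0.11/0.20, T = 0.011, θ = 0.005, ils = 0.5, very recent within-section
splits (2–42% of T). These values were calibrated once so that realized
mean intra-/interspecific K2P per 100 sites sit near 1.0 and 2.0 with
heavy overlap and low NJ discrimination — the documented negative-result
regime; the recent splits, not just lineage escape, are what break species
monophyly, since with longer stems the within-species coalescent completes
and species remain discriminable. `gapped`: 12 species in 4 sections,
T = 0.08, θ = 0.002 (T/θ = 40), no ILS — a strict barcode gap under which
overlap is zero and discrimination and top-1 identification are complete.

What the simulator does *not* emulate: reticulation/hybridization
networks, chloroplast linkage between loci (each locus draws an
independent gene tree), alignment error (true alignments are emitted),
intraspecific spacer inversions, and sequencing-quality artifacts beyond
whole-locus missingness. Passing tests therefore demonstrate correctness
of the statistics and the qualitative regimes, not robustness to
misalignment or reticulate evolution in real data.

## Problem sizes and runtime choices

The test suite and acceptance script run the `gapped` preset (~48
samples) and the full-scale `fraxinus-like` preset (253 samples); the
acceptance script averages each preset over three seeds, a size chosen to
keep a complete from-scratch run around ten seconds while still averaging
over simulation noise (the test suite covers ten seeds per preset).
Bootstrap-heavy runs (B = 1000) are a user-facing setting, not part of
the default suite, which uses B ≤ 30 on small alignments.

## Known limitations

- The misidentification flag is a heuristic; its recall is validated on
  planted cross-section swaps under the gapped preset (≥0.8), but swaps
  within a section are undetectable by design (condition ii).
- Distance imputation by maximum finite distance biases flagged pairs
  outward; the alternative (dropping samples) is available by subsetting
  the alignment before tree building.
- The aligner's band makes scores conservative for alignments with large
  offsets between seeds; widen `band` (or lower `word_size`) for
  indel-rich data.
- `?` and `-` are treated identically in comparisons, although they are
  distinguishable in principle.
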