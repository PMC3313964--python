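# barcodegap

Evaluation toolkit for distance-based DNA barcoding in low-divergence
groups — built for the situation faced in recently diverged tree genera
(ashes, oaks, spruces), where chloroplast barcode loci vary so little that
within-species and between-species distances overlap and standard
identification protocols break down.

Given per-locus aligned FASTA files and a sample table (specimen id,
species, taxonomic section, provenance), the package quantifies how well a
locus — or a concatenation of loci tolerant of missing data — separates
species:

- **K2P distances.** Pairwise Kimura two-parameter substitution rates with
  pairwise deletion of gaps/ambiguities. With transition proportion *P* and
  transversion proportion *Q* over the comparable columns of a pair,

  *d* = −½ ln((1 − 2*P* − *Q*) · √(1 − 2*Q*))

  per site, reported per 100 sites. Saturated or low-overlap pairs are
  flagged undefined.
- **Barcode gap.** Intra- vs interspecific distance histograms, a global
  overlap fraction (share of interspecific pairs at or below the maximum
  intraspecific distance) and per-species local gaps.
- **NJ trees with bootstrap.** Classic neighbor-joining with deterministic
  tie-breaking, nonparametric column-resampling bootstrap mapped onto the
  original tree, outgroup (or midpoint) rooting, newick output.
- **Species discrimination.** A species counts as discriminated when more
  than 50% of its individuals (threshold τ configurable, strict) fall in
  one monophyletic group containing no other species; probable
  misidentifications are flagged (topology + out-of-section nearest
  neighbor) and excluded.
- **Leave-one-out identification.** A seed-and-extend local aligner
  (word seeding, banded affine-gap Smith–Waterman extension) ranks every
  other sequence for each query; top-1/top-3 species accuracy and
  section-assignment rates are tallied with the self-hit removed.
- **Site statistics.** Variable and parsimony-informative ("diagnostic")
  site counts, and an indel catalogue with span-exact grouping classified
  as autapomorphic / shared / clade-diagnostic.
- **Synthetic data.** A generator producing labeled multi-locus datasets
  under a sectioned species tree with within-species coalescence,
  incomplete-lineage-sorting escapes, K2P sequence evolution and spacer
  indels — with a truth ledger (true trees, planted indels and label
  swaps) so every pipeline stage can be validated end to end.

## Worked example

Simulate a dataset with a strict barcode gap, then evaluate it:

```bash
barcodegap simulate --preset gapped --seed 1 -o demo
barcodegap evaluate --config demo/evaluate_config.json -o demo_out
```

prints

```
wrote 48 samples x 1 loci to demo
locusA: 47 samples, NJ-discriminated species: 12
report written to demo_out/report.json
```

and `demo_out/report.tsv` contains the per-dataset summary row:

```
dataset  n_species  n_samples  n_sites  variable_sites  variable_pct  diagnostic_sites  diagnostic_pct  min_pairwise_rate_per100  max_pairwise_rate_per100  mean_intra_per100  intra_range_per100  mean_inter_per100  inter_range_per100  n_species_identified_nj
locusA   12         47         800      349             43.6          339               42.4            0.0                       18.5                      0.2                0.0-1.0             12.8               3.2-18.5            12
```

Read: 12 species, 47 ingroup samples, 800 aligned columns of which 349
vary; mean intraspecific distance 0.2 vs mean interspecific 12.8 per 100
sites — a clean barcode gap (`overlap_fraction` 0.0 in `report.json`), so
all 12 multi-sample species are discriminated by the monophyly criterion.
The `fraxinus-like` preset produces the opposite regime (overlap fraction
≈ 0.8–1.0, under a third of species discriminated), mirroring what
shallow, ILS-affected chloroplast data look like in practice.

The same `evaluate` entry point runs on real data: point the config's
`loci` at your aligned FASTA files, `metadata` at your sample table, and
define datasets (e.g. multi-locus concatenations with missing-locus
tolerance) in the `datasets` list. For published GenBank datasets, fetch
the accessions, align each locus (e.g. with MAFFT/ClustalW), and list the
resulting files in the config; `report.compare_to_reference` then produces
a per-column deviation table against any published summary row.

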