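# isocross

Quantitative analysis of interspecific reproductive barriers from diallel
crossing experiments and SNP genotypes.

The package covers the full pipeline:

- **`isocross.crossdata`** — cross-record tables (one row per pollination
  with pollen-tube score, fruit/seed/germination outcomes), per-pair
  aggregation, and classification on an ordinal 1–8 crossability index
  (1 = fully fertile selfing, 8 = pollen arrested atop the stigma).
- **`isocross.isolation`** — stage-wise reproductive-isolation (RI)
  indices for four sequential stages (pollen–pistil, fruit set, fruit
  weight, seed production). Per direction, RI = max(0, 1 − interspecific
  success / selfing success); reciprocal crosses are averaged. Sequential
  absolute contributions AC₁ = RI₁, ACₙ = RIₙ·(1 − ΣACᵢ), total
  T = ΣACₙ and relative contributions RCₙ = ACₙ/T.
- **`isocross.geneaction`** — degree of dominance d/|a| for traits on
  P1/P2/F1 with a midparent-contrast F test.
- **`isocross.popgen`** — genotype matrices from VCF (pseudodiploid
  scoring for polyploids), the site-filtering cascade (genotype depth
  ≥ 10, no missing calls, no monomorphic sites, per-site heterozygous
  fraction ≤ 0.80, ≥ 20 bp thinning), per-sample heterozygosity, Nei's
  (1972) standard genetic distance, neighbor-joining trees and
  locus-resampling bootstrap supports.
- **`isocross.matstats`** — Pearson and Mantel matrix correlation tests
  and the clustered-heatmap computation (unit-variance column scaling,
  correlation distance, average linkage).
- **`isocross.synthdata`** — synthetic species trees, genotype matrices
  and diallel datasets with known ground truth, for testing every stage
  without external data.

## Command line

```sh
# synthetic dataset with known truth
isocross simulate --out data/ --seed 7

# full pipeline: summaries, CI matrix, RI matrices, contribution table,
# filtered VCF, Nei distances, bootstrapped NJ tree, RI-vs-distance
# correlations, heatmap tables, JSON manifest
isocross run data/ --out results/ --seed 7

# individual steps
isocross crosses data/crosses.tsv --out results/
isocross ri data/crosses.tsv --out results/
isocross contributions data/crosses.tsv --out results/contributions.tsv
isocross filter data/genotypes.vcf --out results/
isocross distance data/genotypes.vcf --out results/nei.tsv
isocross tree data/genotypes.vcf --out results/nj.nwk --bootstrap 1000 --seed 7
isocross mantel results/nei.tsv results/nei.tsv --seed 7
isocross heatmap table.tsv --out results/
isocross geneaction traits.tsv --out results/gene_action.tsv
```

All tables are TSV, trees are Newick, and every stochastic step requires
an explicit seed. Exit codes: 0 success, 2 validation error, 3 stage
failure.

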