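# devoglass

Cross-species profiling of developmental transcriptome conservation
through complete metamorphosis: does pupal development follow the
classical **hourglass** (conservation peaking mid-course) or an inverted
**spindle** (conservation dipping mid-course)?

The package is aimed at comparative developmental transcriptomics: two
species sampled over an ordered developmental time course (embryo E,
larva L, pupal stages P1–P5, intermediate and late pupae, adult A) with
biological replicates, linked by one-to-one orthologs and, optionally, by
gene-age (phylostratum) assignments.

## What it computes

Given gene-level count matrices for two species, the pipeline

1. normalizes counts with median-of-ratios size factors
   (s_j = median_g [ c_gj / (∏_k c_gk)^(1/m) ]) and transforms to
   log2(c/s + 1);
2. checks replicate concordance (Spearman ρ) and screens for outlier
   replicates along the first principal component of each stage's
   replicate sub-matrix;
3. removes weakly expressed / invariant genes using density-inflection
   thresholds estimated from the data;
4. builds stage × stage similarity surfaces (Spearman ρ, Euclidean
   distance) over ortholog pairs, extracts the **diagonal conservation
   profile** ρ(s) with a replicate-pair ±SD band, the per-stage replicate
   STD metric with its 1000×50% gene-downsampling band, and stage-level
   PCA, then classifies the profile shape (hourglass / spindle /
   monotone / flat);
5. calls **stage-specific genes**: upregulated at a stage (BH-adjusted
   p < 0.05, positive log2 effect, stage replicates vs. all other stages
   pooled) and at no non-adjacent stage;
6. clusters pupal-stage trajectories (average-linkage hierarchical
   clustering with distance 1 − ρ_Spearman, k = 8 per species), pairs
   clusters across species by maximizing shared orthologs (optimal
   assignment), and reports overlap fractions;
7. resolves expression and conservation by phylostratum: per-stratum
   trajectories, per-stratum conservation profiles, per-gene
   cross-species ρ with one-sided Mann–Whitney contrasts, χ² comparisons
   of stratum distributions, and the cluster × stratum enrichment

   ρ_ij = (observed_ij − expected_ij)² / expected_ij,
   expected_ij = |cluster_i| · |stratum_j| / N.

A negative-binomial simulator (`devoglass.simulate`) generates paired
two-species time courses with planted conservation shape, trajectory
archetypes, stratum timing and outlier replicates, so every step above
has a recoverable ground truth.

## Worked example

```python
import devoglass as dg

cfg = dg.SimulationConfig(n_genes=2000, seed=7)   # spindle-shaped divergence
a, b, orth, strata, truth = dg.generate_dataset(cfg)
res = dg.ConservationStudy(a, b, orth, strata).fit()
print(res.summary())
```

prints (abridged):

```
Two-species developmental conservation study
====================================================
genes (species A / B):        2000 / 2000
retained ortholog pairs:      839 (41.9% of table)
mean replicate Spearman rho:  A 0.952, B 0.955
PC1 explained variance:       A 50.5%, B 43.8%
conservation pattern:         spindle

diagonal conservation profile (mean rho +/- sd over replicate pairs):
       E: 0.9200  [0.9148, 0.9252]
       L: 0.9356  [0.9318, 0.9394]
      ...
      P4: 0.8414  [0.8373, 0.8456]
      ...
       A: 0.9526  [0.9498, 0.9555]

cluster pairing (common-label id, shared orthologs, overlap):
  pair 1: A1 <-> B1  shared=176  overlap=0.96
  ...
```

The diagonal profile is high at the endpoints (E, A) and dips through
mid-metamorphosis with its pupal minimum near P4 — the planted spindle —
and the classifier reports `spindle` accordingly. `res.save(outdir)`
writes the full TSV/JSON artifact bundle; two runs with the same inputs
and seeds are byte-identical.

The same pipeline runs from the shell:

```bash
devoglass simulate --n-genes 2000 --seed 7 --outdir sim
devoglass run-all --config run.yaml        # paths + options in YAML
```

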