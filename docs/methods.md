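# Methods

This note documents the models, estimators and numerical choices behind
`devoglass`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Study design and data model

The pipeline compares two species across an ordered developmental chain
E – L – P1 – P2 – P3 – P4 – P5 – Pmid – Plate – A (ten stages spanning
embryo, larva, prepupal/pupal stages and adult; P4 is the buoyant stage,
head-sac eversion). Adjacency is along this chain and non-circular (A is
not adjacent to E). All larval samples are treated as replicates of a
single larval stage. Inputs are gene-level integer count matrices
(transcript-level counts are first summed to genes via a
transcript→gene map), a one-to-one ortholog table, and optionally a
gene→phylostratum table, per-gene dN/dS values and boolean gene
annotations. Phylostratum inference, dN/dS estimation and functional
annotation are upstream of this package and consumed as inputs.

## Normalization and transformation

Counts are normalized by DESeq-style median-of-ratios size factors: the
reference for gene g is its geometric mean across samples (genes with any
zero count are excluded from the reference set), and the size factor of
sample j is the median of c_gj / ref_g. Expression is then
log2(c/s + 1). This transform is deterministic, dependency-free and
variance-stabilizing in the large-count regime, which is where the
downstream rank statistics operate; it is not a full variance-stabilizing
transform for low counts, and the filtering step below removes the
low-count stratum before any inference. Size factors are reported
without rescaling, so each species carries its own geometric reference —
cross-species comparisons are rank-based (Spearman) and insensitive to
the resulting constant log offset.

## Replicate QC and outlier screening

Within-stage replicate agreement is summarized by Spearman ρ per
unordered replicate pair, plus the grand mean. Outlier replicates are
screened on the first principal component of each stage's gene-centred
replicate sub-matrix, computed over the better-expressed half of the
genes (counting noise in barely expressed genes otherwise dominates PC1
of clean replicate groups). Each replicate's deviation is taken from
its stage's **median** PC1 score and standardized by the pooled
root-mean-square of deviations across all stages of the matrix; samples
exceeding `threshold_sd` (default 1.5) pooled units are flagged. A
stage-local scale would be useless at three replicates — with n points
no deviation can exceed (n−1)/√n ≈ 1.15 sample SDs, so a per-stage rule
at 1.5 SD can never fire — whereas the pooled scale is dominated by a
genuine outlier when one exists, making the screen both sensitive and
specific in that case. On data with **no** strong outlier the flagged
list is simply the upper tail of ordinary replicate variation;
flagging is therefore a screen, and exclusion is opt-in
(`exclude_outliers=True` or an explicit `exclude_samples` list).

## Expression and variance filters

Stage-level expression is the arithmetic mean of retained replicates.
Genes enter the comparative analysis only if, in **both** species, their
mean expression and their across-stage variance (ddof = 1) clear
data-driven thresholds:

- **Expression threshold** — the left inflection point of the per-gene
  mean-expression density, separating the bell of expressed genes from
  the low-expression tail. The density is a Gaussian KDE; curvature is
  estimated at the wider bandwidth h₂ = 2·s_robust·n^(−1/9) (the optimal
  rate for second-derivative estimation; s_robust = min(SD, IQR/1.349)),
  the first non-negative second-derivative crossing below the main mode
  is located on a 512-point grid with linear interpolation, and the known
  kernel inflation of the mode-to-inflection distance d is removed by
  Gaussian deconvolution (threshold = mode − √(d² − h₂²)). For Gaussian
  means this lands within a few hundredths of a SD of μ − σ at n = 10⁴.
- **Variance threshold** — the first inflection point of the smoothed
  cumulative distribution of per-gene variance. Since the CDF's
  inflections are the density's modes, this is the first local maximum of
  the Silverman-bandwidth variance KDE, scanning upward.

Degenerate inputs (constant values, no sign change) raise an error
instructing a manual threshold; thresholds can be overridden in the
study configuration.

## Conservation surfaces and profiles

All cross-species statistics are computed over ortholog-paired,
row-aligned matrices. The stage × stage surface holds Spearman ρ (ties:
average ranks) or Euclidean distance between stage expression vectors.
The diagonal conservation profile averages ρ over **all** replicate-pair
combinations per stage (3×3 = 9 with full replication); the band is ±1
sample SD over those pairs. Averaging pairs, rather than correlating
replicate-averaged profiles, is what yields a replicate-derived
uncertainty band. The per-stage stability metric is the per-gene
replicate STD (sample SD, n−1 denominator, so three replicates at values
1, 2, 3 give exactly 1.0); its per-stage median gets a stability band
from 1000 recomputations on random 50% gene subsets (2.5th–97.5th
percentile of the subset medians, robust to the skew of median
distributions). Stage-level PCA treats stages as observations and
gene-centred expression as variables; explained-variance fractions sum
to 1.

### Profile-shape classification

With the metric oriented so that higher = more conserved, and an interior
window that excludes the first and last stage, precedence flat >
monotone > hourglass > spindle:

- **flat** if max − min < ε (default ε = 0.02);
- **monotone** if non-increasing or non-decreasing throughout;
- **hourglass** if the interior maximum exceeds both endpoint values by
  ≥ ε;
- **spindle** if the interior minimum lies below both endpoint values by
  ≥ ε.

Non-monotone profiles whose interior extrema stay within ε of the
endpoints match neither bulge and are reported as flat (amplitude below
the contrast floor). ε and the interior window are configurable; the
defaults are conventions of this package, chosen to make the qualitative
hourglass/spindle reading operational.

## Stage-specific genes

Upregulation at stage s is tested per gene with Welch's t on the
transformed scale, the stage's replicates against all other stages'
samples pooled; p-values are Benjamini–Hochberg adjusted per stage
across genes (one family per contrast), and an up-call requires adjusted
p < α (default 0.05) and a positive log2 effect. Genes with zero
variance in both groups get p = 1 when the means are equal and p = 0
otherwise. A negative-binomial count-level test would be the choice at
production scale; Welch's t on transformed values is self-contained and
adequate here, and the bespoke part — the specificity rule — is
independent of the test behind the calls. A gene is **stage-specific**
at s iff it is called up at s and every other stage where it is called up
is an immediate chain neighbour of s; a gene up at two adjacent stages is
specific to both, a gene up at two non-adjacent stages to neither.

## Pupal trajectory clustering and cross-species pairing

Genes are clustered on their seven pupal-stage values
(P1…P5, Pmid, Plate) with average-linkage agglomeration under the
distance 1 − ρ_Spearman between gene trajectories, the tree cut to
exactly k = 8 clusters per species (average linkage is the standard
companion to correlation distances and resists chaining; k is a
convention of the emulated design, overridable). Zero-variance genes are
excluded before the distance step. Median trajectories are reported over
**all** stages. Clusters are matched across species by the number of
shared one-to-one orthologs: the optimal assignment (Hungarian method)
maximizes the total shared count, pairs are sorted by descending shared
count (ties by the smaller species-A id) and renamed 1..k. Overlap
fractions use shared / min(cluster sizes) by default (interpretable when
sizes differ); Jaccard is available.

## Phylostratum analyses

Strata are ordered oldest → youngest (default labels Oldest, Bilateria,
Arthropoda, Pancrustacea, Insecta, Holometabola ≈ 340 My, Diptera,
Drosophila; the user's table overrides). Genes without stratum
annotation are excluded from stratum analyses and from the enrichment
total, so the formula's margins are over annotated genes. Per stratum the
package reports median ± SD expression trajectories, a per-stratum
conservation profile (same all-replicate-pairs convention as the global
diagonal), and per-gene cross-species Spearman ρ across the stage axis
(zero-variance profiles excluded with a count). Group contrasts use the
Mann–Whitney U test: exact when min(n, m) ≤ 8 with no ties, otherwise
the normal approximation with tie and continuity correction. Stratum
distributions of two gene sets are compared with Pearson's χ² on the
2 × S contingency table (zero-total strata pooled away; df = S′ − 1).
The cluster × stratum enrichment ρ = (obs − exp)²/exp with
exp = |cluster|·|stratum|/N is reported descriptively, without a
significance calibration; the χ² machinery is available when a test is
wanted.

## Synthetic-data generator

`generate_dataset` emulates the study design: two species × 10 stages ×
3 replicates, a complete one-to-one ortholog bijection, planted
per-stage divergence, eight trajectory archetypes and eight phylostrata.
Species A carries each gene's reference log2 trajectory

μ_A(g, s) = baseline_g + amplitude_g · T_{a(g)}(s) + bump_{strat(g)}(s),

with baseline ~ N(5, 1.5²) log2 units (counts centred near 2⁵ ≈ 32,
a realistic bulk depth at desk scale), amplitude ~ U(2, 4) log2 units
(developmental genes swing several fold), archetype templates T on
[0, 1], and an optional stratum timing bump (peak_bias log2 units at the
stratum's peak stage, 0.4× at its neighbours). Species B deviates by
independent per-stage draws d(g, s) ~ N(0, σ_d(s)²); the σ_d profile
encodes the planted shape (spindle: peaked at P4; hourglass: lowest
mid-course; flat; monotone). Divergence magnitudes between real species
are not constrained by the emulated design, so σ_d defaults are free
parameters chosen to give clearly resolvable but not degenerate
profiles. Counts are NB with Var = μ + α μ², mean 2^μ · size factor,
per-gene dispersion α log-normal around 0.05 (typical bulk RNA-seq
biological dispersion), size factors U(0.7, 1.4); dispersion 0 yields the
deterministic rounded mean (noise-free limit). One `numpy` Generator
seeded from the config drives every draw, so identical configs are
bit-identical. Outlier replicates are injected by multiplicative
log-normal noise of scale = inflation on a single sample.

The eight archetype templates (monotone rise, early-pupal peak,
embryo+pupal peak, P4 burst, early-pupal plateau, mid-pupal+adult,
late-pupal+larval, larval+adult) are fixed piecewise-linear profiles
whose pupal sub-vectors carry distinct rank orderings with no flat
segments — a deliberate property, since the downstream clustering
distance is rank-based and rank-degenerate templates would be
unrecoverable by construction.

What the generator does **not** emulate: tissue composition and
whole-body averaging artefacts, developmental-clock offsets between
species (real stages are matched by monitoring, not perfectly aligned),
correlated gene–gene noise, batch effects, sex differences, and
lineage-specific duplications (the ortholog map is a perfect bijection).
Passing recovery tests therefore demonstrates the estimators' correctness
and power under the stated noise model, not robustness to those real-data
complications.

## Problem sizes and numerical conventions

Tests and the acceptance script run at desk scale: 400–4000 genes,
10–50 simulation seeds, 100–1000 downsampling iterations — sizes chosen
so the planted effects are resolvable with comfortable margins while the
suite stays quick. Ranks use average ties throughout. Sample (n−1)
standard deviations are used everywhere an SD is reported. Floating-point
degeneracy in the outlier screen (identical replicates) is handled with a
relative floor on the pooled scale. All TSV/JSON writers are
deterministic (sorted keys, fixed column orders), which is what makes
end-to-end reruns byte-identical.

## Limitations

- The hourglass/spindle classifier is a coarse rule on a 10-point
  profile; it does not model uncertainty in the profile and can be
  sensitive near ε for weakly-shaped data.
- Welch's t on transformed values loses power versus count-level NB
  tests for low-count genes; the expression filter mitigates but does not
  remove this.
- The per-species geometric reference leaves a constant cross-species
  log offset; only rank-based cross-species statistics are offered, and
  absolute cross-species expression differences are out of scope.
- With three replicates the outlier screen cannot distinguish a mild
  outlier from ordinary tail variation; flagged lists on clean data are
  expected and exclusion is deliberately opt-in.
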