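"""Count-matrix preprocessing: aggregation, normalization, QC and filtering.

The pipeline starts from gene- or transcript-level integer counts.
Transcript counts are summed to genes, counts are normalized with
median-of-ratios size factors and moved to a log2 scale, replicate
concordance is checked (Spearman), outlier replicates are detected along
the first principal component of the per-stage replicate sub-matrices,
replicates are averaged per stage, and genes with low mean expression or
low across-stage variance are removed using density/CDF inflection-point
thresholds computed from the data themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    CountMatrix,
    ReplicateExpressionMatrix,
    validate_orthologs,
)

__all__ = [
    "aggregate_transcripts",
    "normalize_transform",
    "size_factors",
    "replicate_concordance",
    "ConcordanceResult",
    "detect_outlier_replicates",
    "average_replicates",
    "filter_thresholds",
    "FilterThresholds",
    "apply_filters",
]


def aggregate_transcripts(transcript_counts: CountMatrix,
                          tx2gene: pd.Series | dict) -> CountMatrix:
    """Sum transcript-level counts to gene level.

    ``tx2gene`` maps transcript id -> gene id and must cover every row of
    the matrix.  Column (per-sample) sums are preserved exactly.
    """
    mapping = pd.Series(tx2gene)
    missing = transcript_counts.values.index.difference(mapping.index)
    if len(missing) > 0:
        raise KeyError(f"transcripts missing from tx2gene map: {sorted(missing)[:10]}")
    genes = mapping.reindex(transcript_counts.values.index)
    summed = transcript_counts.values.groupby(genes).sum()
    summed.index.name = "gene_id"
    return CountMatrix(summed, transcript_counts.stage_order)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios (DESeq-style) per-sample size factors.

    The reference is the per-gene geometric mean across samples; genes with
    a zero reference (any zero count) are excluded from the medians.
    """
    arr = counts.to_numpy(dtype=float)
    zero_samples = counts.columns[(arr.sum(axis=0) == 0)]
    if len(zero_samples) > 0:
        raise ValueError(f"sample(s) with all-zero counts: {list(zero_samples)}")
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has nonzero counts in every sample; "
                         "cannot build a geometric reference")
    ref = np.exp(np.log(arr[positive]).mean(axis=1))
    sf = np.median(arr[positive] / ref[:, None], axis=0)
    if np.any(sf <= 0):
        bad = counts.columns[sf <= 0]
        raise ValueError(f"non-positive size factor for sample(s): {list(bad)}")
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_transform(counts: CountMatrix) -> ReplicateExpressionMatrix:
    """Normalize counts by size factors and move to log2(x/sf + 1)."""
    sf = size_factors(counts.values)
    values = np.log2(counts.values.to_numpy(dtype=float) / sf.to_numpy()[None, :] + 1.0)
    df = pd.DataFrame(values, index=counts.values.index, columns=counts.values.columns)
    return ReplicateExpressionMatrix(df, counts.stage_order)


@dataclass
class ConcordanceResult:
    """Within-stage replicate agreement (Spearman), one row per pair."""

    table: pd.DataFrame  # species, stage, rep_a, rep_b, rho
    mean_rho: float
    skipped: list  # (species, stage) groups with a single replicate


def replicate_concordance(expr: ReplicateExpressionMatrix) -> ConcordanceResult:
    rows, skipped = [], []
    for species in expr.species:
        for stage in expr.stages_present():
            cols = expr.replicates_of(stage, species)
            if len(cols) == 0:
                continue
            if len(cols) < 2:
                skipped.append((species, stage))
                continue
            for a, b in combinations(cols, 2):
                rho = stats.spearmanr(expr.values[a], expr.values[b]).statistic
                rows.append((species, stage, a, b, float(rho)))
    table = pd.DataFrame(rows, columns=["species", "stage", "rep_a", "rep_b", "rho"])
    mean_rho = float(table["rho"].mean()) if len(table) else float("nan")
    return ConcordanceResult(table, mean_rho, skipped)


def detect_outlier_replicates(expr: ReplicateExpressionMatrix,
                              threshold_sd: float = 1.5) -> list[str]:
    """Flag replicates that diverge along their stage's first PC.

    For every (species, stage) group with >= 3 replicates, replicates are
    projected on the first principal component of the gene-centred
    replicate sub-matrix.  A replicate's deviation is measured from the
    group's *median* score; deviations are standardised by their pooled
    root-mean-square across all groups (a stage-local scale is useless at
    n = 3, where no point can sit far from its own group's spread).
    Samples with |deviation| > threshold_sd * pooled scale are flagged.

    Only the better-expressed half of the genes enters the projection:
    counting noise in barely-expressed genes otherwise dominates PC1 for
    clean replicate groups.
    """
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    means = expr.values.mean(axis=1)
    expr = ReplicateExpressionMatrix(
        expr.values[means >= means.quantile(0.5)], expr.stage_order)
    deviations: dict[str, float] = {}
    for species in expr.species:
        for stage in expr.stages_present():
            cols = expr.replicates_of(stage, species)
            if len(cols) < 3:
                continue
            sub = expr.values[cols].to_numpy(dtype=float).T  # reps x genes
            centred = sub - sub.mean(axis=0, keepdims=True)
            # first left-singular direction = PC1 scores of the replicates
            u, s, _ = np.linalg.svd(centred, full_matrices=False)
            scores = u[:, 0] * s[0]
            devs = scores - np.median(scores)
            for c, d in zip(cols, devs):
                deviations[c] = float(d)
    if not deviations:
        return []
    devs = np.array(list(deviations.values()))
    scale = float(np.sqrt(np.mean(devs**2)))
    # numerically-degenerate groups (e.g. identical replicates) only carry
    # float residue; treat their spread as zero
    floor = 1e-9 * max(1.0, float(np.abs(expr.values.to_numpy()).max()))
    if scale <= floor:
        return []
    return [c for c, d in deviations.items() if abs(d) > threshold_sd * scale]


def average_replicates(expr: ReplicateExpressionMatrix,
                       exclude: list[str] | tuple[str, ...] = ()) -> pd.DataFrame:
    """Arithmetic mean of retained replicates per stage (one species).

    Returns a genes x ordered-stages DataFrame.  Excluded sample names are
    dropped first; a stage losing all its replicates is an error.
    """
    species = expr.species
    if len(species) != 1:
        raise ValueError("average_replicates expects a single-species matrix")
    unknown = set(exclude) - set(expr.values.columns)
    if unknown:
        raise KeyError(f"exclude names unknown samples: {sorted(unknown)}")
    out = {}
    for stage in expr.stages_present():
        cols = [c for c in expr.stage_columns(stage) if c not in exclude]
        if not cols:
            raise ValueError(f"stage {stage!r} has no retained replicates")
        out[stage] = expr.values[cols].mean(axis=1)
    return pd.DataFrame(out)


@dataclass
class FilterThresholds:
    expression: float
    variance: float


def _kde_grid(x: np.ndarray, n_grid: int = 512):
    kde = stats.gaussian_kde(x, bw_method="silverman")
    h = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, n_grid)
    return grid, kde(grid)


def expression_threshold(means: np.ndarray, n_grid: int = 512) -> float:
    """Left inflection point of the per-gene mean-expression density.

    Scanning down from the main mode of a Gaussian KDE, the threshold is
    the point where the second derivative turns non-negative — the
    inflection separating the bell of expressed genes from the
    low-expression tail.  Curvature is estimated at a wider bandwidth than
    the density itself, ``h2 = 2 * s_robust * n**(-1/9)`` (the optimal
    rate for second-derivative estimation; a robust scale guards against
    heavy low-expression tails), and the known kernel inflation of the
    mode-to-inflection distance is removed by Gaussian deconvolution:
    for a bell of width sigma the smoothed inflection sits at
    ``sqrt(sigma^2 + h2^2)`` below the mode, so the reported threshold is
    ``mode - sqrt(d^2 - h2^2)`` for a detected distance ``d``.
    """
    means = np.asarray(means, dtype=float)
    sd = float(np.std(means))
    if sd == 0:
        raise ValueError("degenerate expression values: no inflection point; "
                         "set the expression threshold manually")
    iqr_scale = float(np.subtract(*np.percentile(means, [75, 25]))) / 1.349
    s_robust = min(sd, iqr_scale) if iqr_scale > 0 else sd
    h2 = 2.0 * s_robust * len(means) ** (-1.0 / 9.0)
    kde = stats.gaussian_kde(means, bw_method=h2 / sd)
    grid = np.linspace(means.min() - 3 * h2, means.max() + 3 * h2, n_grid)
    step = grid[1] - grid[0]
    dens = kde(grid)
    d2 = np.gradient(np.gradient(dens, step), step)
    mode_i = int(np.argmax(dens))
    for i in range(mode_i - 1, 0, -1):
        if d2[i] >= 0.0:  # crossing between grid[i] and grid[i+1]
            frac = d2[i] / (d2[i] - d2[i + 1]) if d2[i] != d2[i + 1] else 0.0
            thr = float(grid[i] + frac * step)
            d = grid[mode_i] - thr
            if d > 1.1 * h2:
                thr = float(grid[mode_i] - np.sqrt(d * d - h2 * h2))
            return thr
    raise ValueError("no inflection point found in the expression density; "
                     "set the expression threshold manually")


def variance_threshold(variances: np.ndarray, n_grid: int = 512) -> float:
    """First inflection point of the smoothed cumulative variance distribution.

    The smoothed CDF's inflections are the modes of the smoothed density,
    so the threshold is the first (scanning upward) local maximum of the
    variance KDE.
    """
    variances = np.asarray(variances, dtype=float)
    if np.std(variances) == 0:
        raise ValueError("degenerate variance values: no inflection point; "
                         "set the variance threshold manually")
    vgrid, vdens = _kde_grid(variances, n_grid)
    vstep = vgrid[1] - vgrid[0]
    d1 = np.gradient(vdens, vstep)
    for i in range(len(d1) - 1):
        if d1[i] > 0.0 and d1[i + 1] <= 0.0:  # first +/- crossing of the slope
            frac = d1[i] / (d1[i] - d1[i + 1])
            return float(vgrid[i] + frac * vstep)
    raise ValueError("no inflection point found in the variance CDF; "
                     "set the variance threshold manually")


def filter_thresholds(stage_expr: pd.DataFrame, n_grid: int = 512) -> FilterThresholds:
    """Data-driven expression and variance thresholds from inflection points.

    See :func:`expression_threshold` (per-gene mean expression) and
    :func:`variance_threshold` (per-gene across-stage variance).
    """
    if stage_expr.shape[0] < 100:
        raise ValueError("need >= 100 genes for density-based thresholds")
    means = stage_expr.mean(axis=1).to_numpy(dtype=float)
    variances = stage_expr.var(axis=1, ddof=1).to_numpy(dtype=float)
    return FilterThresholds(expression=expression_threshold(means, n_grid),
                            variance=variance_threshold(variances, n_grid))


def apply_filters(stage_a: pd.DataFrame, stage_b: pd.DataFrame,
                  orthologs: pd.DataFrame,
                  thresholds_a: FilterThresholds,
                  thresholds_b: FilterThresholds) -> tuple[
                      pd.DataFrame, pd.DataFrame, dict]:
    """Keep ortholog pairs passing expression AND variance filters in both species.

    Returns the two matrices restricted to retained pairs, row-aligned in
    ortholog order, plus a report of retained fractions.
    """
    validate_orthologs(orthologs)

    def passes(mat: pd.DataFrame, thr: FilterThresholds) -> pd.Series:
        return (mat.mean(axis=1) >= thr.expression) & (mat.var(axis=1, ddof=1) >= thr.variance)

    pass_a = passes(stage_a, thresholds_a)
    pass_b = passes(stage_b, thresholds_b)
    pairs = orthologs[
        orthologs["gene_a"].isin(pass_a.index[pass_a])
        & orthologs["gene_b"].isin(pass_b.index[pass_b])
    ]
    if len(pairs) == 0:
        raise ValueError("no ortholog pair passes the filters; thresholds too strict")
    report = {
        "retained_fraction_a": float(pass_a.mean()),
        "retained_fraction_b": float(pass_b.mean()),
        "retained_pairs": int(len(pairs)),
        "retained_fraction_joint": float(len(pairs) / len(orthologs)),
    }
    out_a = stage_a.loc[pairs["gene_a"]]
    out_b = stage_b.loc[pairs["gene_b"]]
    return out_a, out_b, report
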