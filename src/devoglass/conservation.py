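"""Stage-similarity surfaces and conservation profiles.

Cross-species conservation of a developmental programme is read off the
stage x stage similarity surface of ortholog expression (Spearman rho or
Euclidean distance).  Its diagonal — same stage vs. same stage — is the
conservation profile along development; an "hourglass" profile peaks
mid-course, a "spindle" dips there instead.  Replicate-pair scatter and
gene-downsampling give uncertainty bands, and a small rule set classifies
the profile shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .containers import ReplicateExpressionMatrix

__all__ = [
    "SimilaritySurface",
    "ConservationProfile",
    "similarity_surface",
    "diagonal_profile",
    "std_profile",
    "StdProfile",
    "downsampling_band",
    "stage_pca",
    "classify_conservation_pattern",
]


@dataclass
class SimilaritySurface:
    """Stage x stage similarity values under a named metric."""

    values: pd.DataFrame  # rows: species-A stages, cols: species-B stages
    metric: str

    def diagonal(self) -> pd.Series:
        shared = [s for s in self.values.index if s in self.values.columns]
        return pd.Series([self.values.at[s, s] for s in shared], index=shared)


@dataclass
class ConservationProfile:
    """Per-stage central value with a lower/upper uncertainty band."""

    stages: list[str]
    central: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    provenance: str  # "replicates" | "downsampling"
    skipped: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.central = np.asarray(self.central, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not (len(self.stages) == len(self.central) == len(self.lower) == len(self.upper)):
            raise ValueError("profile components must have equal length")
        if np.any(self.lower > self.central + 1e-12) or np.any(self.central > self.upper + 1e-12):
            raise ValueError("band must bracket the central value")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"stage": self.stages, "central": self.central,
                             "lower": self.lower, "upper": self.upper})


def _spearman_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman rho between every column of ``a`` and every column of ``b``."""
    ra = np.apply_along_axis(rankdata, 0, a)
    rb = np.apply_along_axis(rankdata, 0, b)
    za = (ra - ra.mean(axis=0)) / ra.std(axis=0)
    zb = (rb - rb.mean(axis=0)) / rb.std(axis=0)
    return (za.T @ zb) / a.shape[0]


def similarity_surface(mat_a: pd.DataFrame, mat_b: pd.DataFrame,
                       metric: str = "spearman") -> SimilaritySurface:
    """All-vs-all stage similarity between two stage-expression matrices.

    The matrices must be row-aligned over the same (ortholog-paired) gene
    set; rows are compared positionally, so the two indexes may carry each
    species' own gene ids.
    """
    if mat_a.shape[0] != mat_b.shape[0]:
        raise ValueError("matrices must be row-aligned over the same gene pairs")
    if mat_a.shape[0] < 3:
        raise ValueError("need at least 3 shared genes")
    a, b = mat_a.to_numpy(dtype=float), mat_b.to_numpy(dtype=float)
    if metric == "spearman":
        vals = _spearman_matrix(a, b)
    elif metric == "euclidean":
        vals = cdist(a.T, b.T, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return SimilaritySurface(
        pd.DataFrame(vals, index=mat_a.columns, columns=mat_b.columns), metric)


def diagonal_profile(expr_a: ReplicateExpressionMatrix,
                     expr_b: ReplicateExpressionMatrix,
                     gene_pairs: pd.DataFrame) -> ConservationProfile:
    """Per-stage cross-species Spearman rho over all replicate pairs.

    For each stage shared by both species, rho is computed for every
    (species-A replicate, species-B replicate) combination over the paired
    genes; the profile's central value is the mean and the band is +/- one
    (sample) standard deviation over those pairs.  Stages missing in one
    species are omitted and listed in ``skipped``.
    """
    a_vals = expr_a.values.loc[gene_pairs["gene_a"]].to_numpy(dtype=float)
    b_vals = expr_b.values.loc[gene_pairs["gene_b"]].to_numpy(dtype=float)
    a_cols = list(expr_a.values.columns)
    b_cols = list(expr_b.values.columns)

    stages, central, lower, upper, skipped = [], [], [], [], []
    for stage in expr_a.stage_order:
        ca = [a_cols.index(c) for c in expr_a.replicates_of(stage)]
        cb = [b_cols.index(c) for c in expr_b.replicates_of(stage)]
        if not ca or not cb:
            if stage in set(expr_a.samples["stage"]) | set(expr_b.samples["stage"]):
                skipped.append(stage)
            continue
        rhos = _spearman_matrix(a_vals[:, ca], b_vals[:, cb]).ravel()
        m = float(np.mean(rhos))
        s = float(np.std(rhos, ddof=1)) if len(rhos) > 1 else 0.0
        stages.append(stage)
        central.append(m)
        lower.append(m - s)
        upper.append(m + s)
    return ConservationProfile(stages, np.array(central), np.array(lower),
                               np.array(upper), "replicates", skipped)


@dataclass
class StdProfile:
    """Per-gene replicate STD by stage, plus per-stage medians."""

    per_gene: pd.DataFrame  # genes x stages
    medians: pd.Series
    skipped: list


def std_profile(expr: ReplicateExpressionMatrix) -> StdProfile:
    """Replicate standard deviation (ddof=1) of each gene at each stage.

    The per-stage median STD is the stability metric: stages where
    expression is under tighter control have lower replicate STD.
    Single-replicate stages are omitted.
    """
    if len(expr.species) != 1:
        raise ValueError("std_profile expects a single-species matrix")
    cols, skipped = {}, []
    for stage in expr.stages_present():
        reps = expr.stage_columns(stage)
        if len(reps) < 2:
            skipped.append(stage)
            continue
        cols[stage] = expr.values[reps].std(axis=1, ddof=1)
    per_gene = pd.DataFrame(cols)
    return StdProfile(per_gene, per_gene.median(axis=0), skipped)


def downsampling_band(per_gene_values: pd.DataFrame, fraction: float = 0.5,
                      n_iter: int = 1000, seed: int = 0) -> ConservationProfile:
    """Stability band for per-stage medians under gene downsampling.

    The per-stage median of ``per_gene_values`` (genes x stages) is
    recomputed ``n_iter`` times on random subsets of ``floor(fraction*G)``
    genes; the band is the 2.5th-97.5th percentile of those medians.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    g = per_gene_values.shape[0]
    if g < 10:
        raise ValueError("need at least 10 genes")
    rng = np.random.default_rng(seed)
    k = int(np.floor(fraction * g))
    arr = per_gene_values.to_numpy(dtype=float)
    medians = np.empty((n_iter, arr.shape[1]))
    for i in range(n_iter):
        idx = rng.choice(g, size=k, replace=False)
        medians[i] = np.median(arr[idx], axis=0)
    central = np.median(arr, axis=0)
    lo = np.minimum(np.percentile(medians, 2.5, axis=0), central)
    hi = np.maximum(np.percentile(medians, 97.5, axis=0), central)
    return ConservationProfile(list(per_gene_values.columns), central, lo, hi,
                               "downsampling")


def stage_pca(stage_expr: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA with stages as observations and genes as (centred) variables.

    Returns the stage coordinates on the principal components and the
    explained-variance fractions (which sum to 1), components ordered by
    decreasing variance.
    """
    if stage_expr.shape[1] < 3:
        raise ValueError("need at least 3 stages")
    if stage_expr.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    x = stage_expr.to_numpy(dtype=float).T  # stages x genes
    x = x - x.mean(axis=0, keepdims=True)
    if not np.any(x):
        raise ValueError("zero total variance; PCA undefined")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    frac = s**2 / np.sum(s**2)
    coords = pd.DataFrame(
        u * s, index=stage_expr.columns,
        columns=[f"PC{i+1}" for i in range(len(s))])
    return coords, frac


def classify_conservation_pattern(profile, interior_stages,
                                  eps: float = 0.02) -> str:
    """Classify a conservation profile as hourglass/spindle/monotone/flat.

    The metric is oriented so that higher means more conserved.  Precedence
    is flat > monotone > hourglass > spindle:

    - flat: total range below ``eps``;
    - monotone: non-increasing or non-decreasing throughout;
    - hourglass: the maximum over the interior stages exceeds both endpoint
      values by at least ``eps``;
    - spindle: the minimum over the interior stages lies below both
      endpoint values by at least ``eps``.

    Non-monotone profiles whose interior extrema stay within ``eps`` of the
    endpoints match neither bulge; they are reported as flat.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if isinstance(profile, ConservationProfile):
        stages, values = list(profile.stages), np.asarray(profile.central, float)
    else:
        values = np.asarray(profile, dtype=float)
        stages = list(range(len(values)))
        if interior_stages and isinstance(interior_stages[0], str):
            raise TypeError("stage-labelled interior requires a ConservationProfile")
    if len(stages) < 5:
        raise ValueError("need at least 5 stages to classify a profile")
    interior_idx = [stages.index(s) for s in interior_stages]
    if not interior_idx:
        raise ValueError("interior_stages must be non-empty")
    if interior_idx != list(range(interior_idx[0], interior_idx[-1] + 1)):
        raise ValueError("interior_stages must be a contiguous sub-chain")
    if 0 in interior_idx or len(stages) - 1 in interior_idx:
        raise ValueError("interior_stages must exclude the first and last stage")

    if values.max() - values.min() < eps:
        return "flat"
    diffs = np.diff(values)
    if np.all(diffs >= 0) or np.all(diffs <= 0):
        return "monotone"
    first, last = values[0], values[-1]
    inner = values[interior_idx]
    if inner.max() >= first + eps and inner.max() >= last + eps:
        return "hourglass"
    if inner.min() <= first - eps and inner.min() <= last - eps:
        return "spindle"
    return "flat"
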