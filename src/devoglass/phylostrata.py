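"""Gene-age (phylostratum) resolved expression and conservation analyses.

A phylostratum is the most recent clade containing all detectable homologs
of a gene — a proxy for its evolutionary age.  Given an externally
computed gene -> stratum table, this module computes per-stratum
expression trajectories, per-stratum cross-species conservation profiles,
per-gene cross-species correlations, the cluster x stratum enrichment
statistic rho = (observed - expected)^2 / expected with
expected = |cluster| * |stratum| / total, and the generic rank (Mann-
Whitney U) and chi-square distribution comparisons used for dN/dS and
annotation-class contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ReplicateExpressionMatrix
from .conservation import ConservationProfile, diagonal_profile

__all__ = [
    "DEFAULT_STRATUM_ORDER",
    "EnrichmentMatrix",
    "rho_enrichment",
    "stratum_trajectories",
    "stratum_stage_correlation",
    "per_gene_cross_species_correlation",
    "rank_compare",
    "chisq_distribution_test",
]

#: Oldest -> youngest; override with the user's own ordered table.
DEFAULT_STRATUM_ORDER: tuple[str, ...] = (
    "Oldest", "Bilateria", "Arthropoda", "Pancrustacea",
    "Insecta", "Holometabola", "Diptera", "Drosophila",
)


@dataclass
class EnrichmentMatrix:
    """Observed/expected intersection counts and rho per (cluster, stratum)."""

    observed: pd.DataFrame
    expected: pd.DataFrame
    rho: pd.DataFrame  # NaN where expected == 0 (undefined)
    total: int

    def argmax(self) -> tuple:
        """(cluster, stratum) cell with the largest defined rho."""
        flat = self.rho.stack()
        return flat.idxmax()


def rho_enrichment(cluster_sets: dict, stratum_sets: dict,
                   total_gene_count: int) -> EnrichmentMatrix:
    """Cluster x stratum enrichment: rho = (obs - exp)^2 / exp.

    ``expected = |cluster| * |stratum| / total_gene_count``; cells with
    zero expected count are reported as NaN (undefined).  rho highlights
    strong intersections in either direction while adjusting for group
    sizes; it is reported descriptively, without a significance
    calibration.
    """
    if total_gene_count <= 0:
        raise ValueError("total_gene_count must be positive")
    clusters = list(cluster_sets)
    strata = list(stratum_sets)
    c_sets = {c: set(cluster_sets[c]) for c in clusters}
    s_sets = {s: set(stratum_sets[s]) for s in strata}
    for name, members in {**c_sets, **s_sets}.items():
        if len(members) > total_gene_count:
            raise ValueError(f"set {name!r} larger than total_gene_count")
    obs = pd.DataFrame(
        [[len(c_sets[c] & s_sets[s]) for s in strata] for c in clusters],
        index=pd.Index(clusters, name="cluster"),
        columns=pd.Index(strata, name="stratum"), dtype=float)
    exp = pd.DataFrame(
        [[len(c_sets[c]) * len(s_sets[s]) / total_gene_count for s in strata]
         for c in clusters], index=obs.index, columns=obs.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (obs - exp) ** 2 / exp
    rho = rho.where(exp > 0)
    return EnrichmentMatrix(obs, exp, rho, total_gene_count)


def stratum_trajectories(stage_expr: pd.DataFrame, strata: pd.Series,
                         stratum_order=None) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Per-stratum, per-stage median and STD of transformed expression.

    Returns ``(medians, stds, skipped)`` with strata as rows and stages as
    columns; strata with fewer than two annotated genes are omitted.
    """
    order = list(stratum_order) if stratum_order is not None else \
        [s for s in dict.fromkeys(strata)]
    medians, stds, skipped = {}, {}, []
    for stratum in order:
        genes = strata.index[strata == stratum].intersection(stage_expr.index)
        if len(genes) < 2:
            skipped.append(stratum)
            continue
        sub = stage_expr.loc[genes]
        medians[stratum] = sub.median(axis=0)
        stds[stratum] = sub.std(axis=0, ddof=1)
    return (pd.DataFrame(medians).T, pd.DataFrame(stds).T, skipped)


def stratum_stage_correlation(expr_a: ReplicateExpressionMatrix,
                              expr_b: ReplicateExpressionMatrix,
                              gene_pairs: pd.DataFrame,
                              strata: pd.Series,
                              stratum_order=None) -> dict[str, ConservationProfile]:
    """Per-stratum cross-species conservation profile (replicate-pair band).

    The strata annotation is keyed by species-A gene ids; each stratum's
    ortholog pairs get their own diagonal profile.  Strata with fewer than
    3 pairs are omitted.
    """
    order = list(stratum_order) if stratum_order is not None else \
        [s for s in dict.fromkeys(strata)]
    out: dict[str, ConservationProfile] = {}
    for stratum in order:
        genes = set(strata.index[strata == stratum])
        pairs = gene_pairs[gene_pairs["gene_a"].isin(genes)]
        if len(pairs) < 3:
            continue
        out[stratum] = diagonal_profile(expr_a, expr_b, pairs)
    return out


def per_gene_cross_species_correlation(stage_a: pd.DataFrame,
                                       stage_b: pd.DataFrame,
                                       gene_pairs: pd.DataFrame) -> pd.Series:
    """Spearman rho of each ortholog pair's stage profiles across development.

    Pairs where either profile has zero variance (rho undefined) are
    excluded; the number excluded is recorded in ``result.attrs['n_undefined']``.
    """
    if stage_a.shape[1] < 3:
        raise ValueError("need at least 3 stages")
    a = stage_a.loc[gene_pairs["gene_a"]].to_numpy(dtype=float)
    b = stage_b.loc[gene_pairs["gene_b"]].to_numpy(dtype=float)
    ra = np.apply_along_axis(stats.rankdata, 1, a)
    rb = np.apply_along_axis(stats.rankdata, 1, b)
    sa, sb = ra.std(axis=1), rb.std(axis=1)
    defined = (sa > 0) & (sb > 0)
    za = ra - ra.mean(axis=1, keepdims=True)
    zb = rb - rb.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (za * zb).mean(axis=1) / (sa * sb)
    out = pd.Series(rho[defined], index=gene_pairs["gene_a"].to_numpy()[defined],
                    name="rho")
    out.attrs["n_undefined"] = int((~defined).sum())
    return out


def rank_compare(group_values, background_values,
                 alternative: str = "greater") -> tuple[float, float]:
    """Mann-Whitney U test of a gene group against a background.

    Exact p-value when min(n, m) <= 8 and there are no ties; otherwise the
    normal approximation with tie correction and continuity correction.
    Used for per-stratum correlation vs. the rest and for gene-set dN/dS
    vs. all genes.
    """
    x = np.asarray(group_values, dtype=float)
    y = np.asarray(background_values, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def chisq_distribution_test(counts_a: pd.Series, counts_b: pd.Series
                            ) -> tuple[float, int, float]:
    """Pearson chi-square comparing two count distributions over strata.

    The two series share the same ordered stratum index (e.g. counts of
    all genes vs. counts of signal-peptide genes per stratum).  Strata
    whose column total is zero carry no information and are pooled away
    (merging a zero column into a neighbour leaves the table unchanged),
    keeping every expected cell positive; df = S' - 1 after pooling.
    """
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("the two count series must share the same stratum index")
    a = counts_a.to_numpy(dtype=float)
    b = counts_b.to_numpy(dtype=float)
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("a distribution with zero total cannot be compared")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    totals = a + b
    # pool zero-total strata leftwards so expected counts stay positive
    keep_a, keep_b = [], []
    for i in range(len(totals)):
        if totals[i] == 0:
            continue
        keep_a.append(a[i])
        keep_b.append(b[i])
    if len(keep_a) < 2:
        raise ValueError("fewer than 2 informative strata")
    table = np.array([keep_a, keep_b])
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
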