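"""Stage-specific gene identification with an adjacency-tolerant rule.

A gene is called upregulated at a stage when its transformed expression in
that stage's replicates exceeds the pooled remaining samples (Welch's
t-test, one BH family per stage across genes, adjusted p < alpha and a
positive effect).  It is *stage-specific* when it is upregulated at the
stage and at no other stage except immediate chain neighbours — the
tolerance reflecting that temporally adjacent stages share transcriptional
programmes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ReplicateExpressionMatrix
from .stages import StageOrder

__all__ = ["upregulation_calls", "all_stage_calls", "stage_specific_genes"]


def upregulation_calls(expr: ReplicateExpressionMatrix, stage: str,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene upregulation calls for one stage vs. all other stages.

    Welch's two-sample t-test on the transformed scale, the stage's
    replicates against all other stages' samples pooled.  Effect size is
    the log2 mean difference (stage minus rest).  Degenerate genes with
    zero variance in both groups get p = 1 when the means are equal and
    p = 0 otherwise.  Returns a DataFrame with columns
    ``effect, p, padj, up``.
    """
    if len(expr.species) != 1:
        raise ValueError("upregulation_calls expects a single-species matrix")
    in_cols = expr.stage_columns(stage)
    out_cols = [c for c in expr.values.columns if c not in in_cols]
    if len(in_cols) < 2:
        raise ValueError(f"stage {stage!r} needs >= 2 replicates")
    if len(out_cols) < 2:
        raise ValueError("pooled remaining stages need >= 2 samples")
    x = expr.values[in_cols].to_numpy(dtype=float)
    y = expr.values[out_cols].to_numpy(dtype=float)
    effect = x.mean(axis=1) - y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(x, y, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (x.var(axis=1) == 0) & (y.var(axis=1) == 0)
    p[degenerate & (effect == 0)] = 1.0
    p[degenerate & (effect != 0)] = 0.0
    p = np.nan_to_num(p, nan=1.0)
    padj = multipletests(p, method="fdr_bh")[1]
    up = (padj < alpha) & (effect > 0)
    return pd.DataFrame(
        {"effect": effect, "p": p, "padj": padj, "up": up},
        index=expr.values.index)


def all_stage_calls(expr: ReplicateExpressionMatrix,
                    alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Upregulation calls for every stage present in the matrix."""
    return {s: upregulation_calls(expr, s, alpha) for s in expr.stages_present()}


def stage_specific_genes(calls: dict[str, pd.DataFrame],
                         order: StageOrder) -> dict[str, list[str]]:
    """Apply the adjacency-tolerant specificity rule to per-stage calls.

    Gene g is specific to stage s iff it is called up at s and every other
    stage where it is called up is an immediate neighbour of s in the
    (non-circular) stage chain.  A gene may be specific to two adjacent
    stages at once; a gene up at two non-adjacent stages is specific to
    neither.
    """
    missing = [s for s in order if s not in calls]
    if missing:
        raise KeyError(f"calls missing for stage(s): {missing}")
    stages = list(order)
    up = pd.DataFrame({s: calls[s]["up"] for s in stages})
    result: dict[str, list[str]] = {s: [] for s in stages}
    up_arr = up.to_numpy(dtype=bool)
    genes = up.index
    for j, s in enumerate(stages):
        allowed = {j}
        if j > 0:
            allowed.add(j - 1)
        if j < len(stages) - 1:
            allowed.add(j + 1)
        forbidden = [k for k in range(len(stages)) if k not in allowed]
        ok = up_arr[:, j] & ~up_arr[:, forbidden].any(axis=1)
        result[s] = list(genes[ok])
    return result
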