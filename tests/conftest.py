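import numpy as np
import pandas as pd
import pytest

from devoglass import DEFAULT_STAGES, CountMatrix, ReplicateExpressionMatrix, StageOrder
from devoglass.containers import sample_name


def make_counts(values: np.ndarray, species: str = "A",
                stages=DEFAULT_STAGES, n_reps: int = 3,
                gene_ids=None) -> CountMatrix:
    """Wrap an array (genes x stages*reps) as a CountMatrix."""
    cols = [sample_name(species, s, r)
            for s in stages for r in range(1, n_reps + 1)]
    genes = gene_ids or [f"g{species}{i:04d}" for i in range(values.shape[0])]
    df = pd.DataFrame(np.asarray(values), index=pd.Index(genes, name="gene_id"),
                      columns=cols)
    return CountMatrix(df, StageOrder(tuple(stages)))


def make_expr(values: np.ndarray, species: str = "A",
              stages=DEFAULT_STAGES, n_reps: int = 3,
              gene_ids=None) -> ReplicateExpressionMatrix:
    cols = [sample_name(species, s, r)
            for s in stages for r in range(1, n_reps + 1)]
    genes = gene_ids or [f"g{species}{i:04d}" for i in range(values.shape[0])]
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      index=pd.Index(genes, name="gene_id"), columns=cols)
    return ReplicateExpressionMatrix(df, StageOrder(tuple(stages)))


def spearman_oracle(x, y) -> float:
    """Independent rank-and-correlate oracle (average ranks, Pearson on ranks)."""
    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        r[order] = np.arange(1, len(v) + 1)
        # average ties
        for val in np.unique(v):
            mask = v == val
            r[mask] = r[mask].mean()
        return r

    rx, ry = ranks(x), ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted spindle dataset shared across read-only tests."""
    from devoglass import SimulationConfig, generate_dataset

    cfg = SimulationConfig(n_genes=600, seed=42)
    return generate_dataset(cfg)
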