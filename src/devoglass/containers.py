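"""In-memory containers for count and expression matrices.

Matrices are genes x samples :class:`pandas.DataFrame` objects wrapped with
a sample annotation table.  Sample columns follow the naming convention
``<species>_<stage>_r<replicate>`` (e.g. ``Dmel_P4_r2``); species and stage
tags therefore must not contain underscores.

Stage-averaged matrices (genes x ordered stages) are plain DataFrames whose
columns are the stage labels in developmental order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stages import StageOrder

_SAMPLE_RE = re.compile(r"^(?P<species>[^_]+)_(?P<stage>[^_]+)_r(?P<rep>\d+)$")


def sample_name(species: str, stage: str, replicate: int) -> str:
    if "_" in species or "_" in stage:
        raise ValueError("species and stage tags must not contain '_'")
    return f"{species}_{stage}_r{replicate}"


def parse_sample_name(name: str) -> tuple[str, str, int]:
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise ValueError(
            f"sample name {name!r} does not match '<species>_<stage>_r<rep>'"
        )
    return m.group("species"), m.group("stage"), int(m.group("rep"))


def _sample_table(columns) -> pd.DataFrame:
    rows = [parse_sample_name(c) for c in columns]
    return pd.DataFrame(rows, columns=["species", "stage", "replicate"],
                        index=pd.Index(columns, name="sample"))


@dataclass
class SampleMatrix:
    """Genes x samples matrix with parsed sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene ids; columns are sample names in
        the ``<species>_<stage>_r<rep>`` convention.
    stage_order
        Declared developmental stage order; every sample's stage must be a
        member.
    """

    values: pd.DataFrame
    stage_order: StageOrder

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        self.samples = _sample_table(self.values.columns)
        bad = set(self.samples["stage"]) - set(self.stage_order.labels)
        if bad:
            raise ValueError(f"sample stages not in declared stage order: {sorted(bad)}")

    # -- accessors ---------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.samples["species"]))

    def stage_columns(self, stage: str, species: str | None = None) -> list[str]:
        sel = self.samples["stage"] == stage
        if species is not None:
            sel &= self.samples["species"] == species
        return list(self.samples.index[sel])

    def replicates_of(self, stage: str, species: str | None = None) -> list[str]:
        cols = self.stage_columns(stage, species)
        return sorted(cols, key=lambda c: parse_sample_name(c)[2])

    def stages_present(self) -> list[str]:
        present = set(self.samples["stage"])
        return [s for s in self.stage_order if s in present]

    # -- IO ----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def read_tsv(cls, path, stage_order: StageOrder):
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(df, stage_order)


class CountMatrix(SampleMatrix):
    """Raw integer read counts, genes x samples."""

    def __post_init__(self) -> None:
        super().__post_init__()
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.values = self.values.round().astype(np.int64)
            arr = self.values.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")


class ReplicateExpressionMatrix(SampleMatrix):
    """Transformed (log2-scale) expression, genes x samples."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")


def read_two_column_tsv(path, columns: tuple[str, str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != list(columns):
        df = pd.read_csv(path, sep="\t", header=None, names=list(columns))
    return df[list(columns)]


def read_ortholog_table(path) -> pd.DataFrame:
    """Two-column TSV of one-to-one ortholog gene-id pairs (A, B)."""
    df = read_two_column_tsv(path, ("gene_a", "gene_b"))
    validate_orthologs(df)
    return df


def validate_orthologs(orthologs: pd.DataFrame) -> None:
    if orthologs["gene_a"].duplicated().any() or orthologs["gene_b"].duplicated().any():
        raise ValueError("ortholog table is not one-to-one")


def read_phylostratum_table(path) -> pd.Series:
    """TSV of gene id -> stratum label, returned as a Series."""
    df = read_two_column_tsv(path, ("gene_id", "stratum"))
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in phylostratum table")
    return df.set_index("gene_id")["stratum"]
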