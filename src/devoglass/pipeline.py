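"""End-to-end pipeline execution from a single run configuration.

A :class:`RunConfig` (typically loaded from YAML) names the input tables
and analysis options; :func:`run_pipeline` builds the
:class:`~devoglass.model.ConservationStudy`, fits it, writes the full
TSV/JSON artifact bundle to the output directory and returns the run
report.  Identical configs (and seeds) produce byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .model import ConservationStudy, StudyConfig
from .stages import DEFAULT_STAGES, PUPAL_STAGES

__all__ = ["RunConfig", "run_pipeline", "PipelineConfigError", "PipelineDataError"]


class PipelineConfigError(ValueError):
    """The run configuration itself is invalid (CLI exit code 2)."""


class PipelineDataError(ValueError):
    """A pipeline stage failed on the data (CLI exit code 3)."""


@dataclass
class RunConfig:
    counts_a: str = ""
    counts_b: str = ""
    orthologs: str = ""
    outdir: str = "devoglass_run"
    tx2gene_a: str | None = None
    tx2gene_b: str | None = None
    strata: str | None = None
    dnds: str | None = None
    annotations: str | None = None
    stage_order: tuple[str, ...] = DEFAULT_STAGES
    pupal_stages: tuple[str, ...] = PUPAL_STAGES
    exclude_samples: tuple[str, ...] = ()
    exclude_outliers: bool = False
    alpha: float = 0.05
    k: int = 8
    eps: float = 0.02
    downsample_fraction: float = 0.5
    downsample_iters: int = 1000
    outlier_threshold_sd: float = 1.5
    overlap_denominator: str = "min"
    thresholds_override: dict | None = None
    stratum_order: tuple[str, ...] | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for key in ("counts_a", "counts_b", "orthologs"):
            path = getattr(self, key)
            if not path:
                raise PipelineConfigError(f"config key {key!r} is required")
            if not Path(path).exists():
                raise PipelineConfigError(f"{key}: file not found: {path}")
        for key in ("tx2gene_a", "tx2gene_b", "strata", "dnds", "annotations"):
            path = getattr(self, key)
            if path and not Path(path).exists():
                raise PipelineConfigError(f"{key}: file not found: {path}")
        if not isinstance(self.seed, int):
            raise PipelineConfigError("seed must be an integer")

    def study_config(self) -> StudyConfig:
        return StudyConfig(
            stage_order=tuple(self.stage_order),
            pupal_stages=tuple(self.pupal_stages),
            alpha=self.alpha, k=self.k, eps=self.eps,
            overlap_denominator=self.overlap_denominator,
            downsample_fraction=self.downsample_fraction,
            downsample_iters=self.downsample_iters,
            outlier_threshold_sd=self.outlier_threshold_sd,
            exclude_outliers=self.exclude_outliers,
            exclude_samples=tuple(self.exclude_samples),
            thresholds_override=self.thresholds_override,
            stratum_order=(tuple(self.stratum_order)
                           if self.stratum_order else None),
            seed=self.seed)


def run_pipeline(config: RunConfig) -> dict:
    """Run preprocess -> conservation -> stage specificity -> clustering ->
    phylostrata, write the artifact bundle, and return the run report."""
    config.validate()
    try:
        study = ConservationStudy.from_tsv(
            config.counts_a, config.counts_b, config.orthologs,
            strata_path=config.strata, dnds_path=config.dnds,
            annotations_path=config.annotations,
            tx2gene_a_path=config.tx2gene_a, tx2gene_b_path=config.tx2gene_b,
            config=config.study_config())
        results = study.fit()
        results.save(config.outdir)
    except PipelineConfigError:
        raise
    except (ValueError, KeyError) as exc:
        raise PipelineDataError(str(exc)) from exc
    return results.report()
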