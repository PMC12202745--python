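"""Model/Results interface for the full two-species conservation study.

:class:`ConservationStudy` is built from the raw inputs (two count
matrices, an ortholog table, optionally phylostrata, dN/dS values and
boolean gene annotations); :meth:`ConservationStudy.fit` runs the whole
pipeline — normalization, replicate QC, filtering, conservation surfaces
and profiles, pattern classification, stage-specific genes, pupal
clustering with cross-species pairing, and stratum-resolved analyses —
and returns a :class:`StudyResults` carrying every artifact, a
``summary()`` table and a deterministic ``save()`` writer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import clustering as _clustering
from . import conservation as _conservation
from . import phylostrata as _phylo
from . import preprocess as _pre
from . import stagespec as _stagespec
from .containers import (
    CountMatrix,
    ReplicateExpressionMatrix,
    read_ortholog_table,
    read_phylostratum_table,
    validate_orthologs,
)
from .stages import DEFAULT_STAGES, PUPAL_STAGES, StageOrder

__all__ = ["StudyConfig", "ConservationStudy", "StudyResults"]


@dataclass(frozen=True)
class StudyConfig:
    """Analysis options of a conservation study.

    ``interior_stages`` is the contiguous sub-chain (excluding the first
    and last stage) scanned for the hourglass bulge / spindle waist;
    ``eps`` is the minimal profile contrast treated as signal.
    """

    stage_order: tuple[str, ...] = DEFAULT_STAGES
    pupal_stages: tuple[str, ...] = PUPAL_STAGES
    interior_stages: tuple[str, ...] | None = None  # default: all interior
    alpha: float = 0.05
    k: int = 8
    eps: float = 0.02
    linkage: str = "average"
    overlap_denominator: str = "min"
    downsample_fraction: float = 0.5
    downsample_iters: int = 1000
    outlier_threshold_sd: float = 1.5
    exclude_outliers: bool = False
    exclude_samples: tuple[str, ...] = ()
    thresholds_override: dict | None = None  # {"a": {...}, "b": {...}}
    stratum_order: tuple[str, ...] | None = None
    seed: int = 0


class ConservationStudy:
    """The comparative developmental-conservation model for two species."""

    def __init__(self, counts_a: CountMatrix, counts_b: CountMatrix,
                 orthologs: pd.DataFrame, strata: pd.Series | None = None,
                 dnds: pd.Series | None = None,
                 annotations: pd.DataFrame | None = None,
                 config: StudyConfig | None = None):
        self.config = config or StudyConfig()
        self.stage_order = StageOrder(self.config.stage_order)
        self.counts_a = counts_a
        self.counts_b = counts_b
        validate_orthologs(orthologs)
        self.orthologs = orthologs.reset_index(drop=True)
        self.strata = strata
        self.dnds = dnds
        self.annotations = annotations

    # ------------------------------------------------------------------
    @classmethod
    def from_tsv(cls, counts_a_path, counts_b_path, orthologs_path,
                 strata_path=None, dnds_path=None, annotations_path=None,
                 tx2gene_a_path=None, tx2gene_b_path=None,
                 config: StudyConfig | None = None) -> "ConservationStudy":
        cfg = config or StudyConfig()
        order = StageOrder(cfg.stage_order)
        counts_a = CountMatrix.read_tsv(counts_a_path, order)
        counts_b = CountMatrix.read_tsv(counts_b_path, order)
        if tx2gene_a_path is not None:
            tx2gene = pd.read_csv(tx2gene_a_path, sep="\t", index_col=0).iloc[:, 0]
            counts_a = _pre.aggregate_transcripts(counts_a, tx2gene)
        if tx2gene_b_path is not None:
            tx2gene = pd.read_csv(tx2gene_b_path, sep="\t", index_col=0).iloc[:, 0]
            counts_b = _pre.aggregate_transcripts(counts_b, tx2gene)
        orthologs = read_ortholog_table(orthologs_path)
        strata = read_phylostratum_table(strata_path) if strata_path else None
        dnds = None
        if dnds_path:
            dnds = pd.read_csv(dnds_path, sep="\t", index_col=0).iloc[:, 0]
        annotations = None
        if annotations_path:
            annotations = pd.read_csv(annotations_path, sep="\t", index_col=0)
        return cls(counts_a, counts_b, orthologs, strata, dnds, annotations, cfg)

    # ------------------------------------------------------------------
    def fit(self) -> "StudyResults":
        cfg = self.config
        order = self.stage_order

        # --- preprocessing ------------------------------------------------
        expr_a = _pre.normalize_transform(self.counts_a)
        expr_b = _pre.normalize_transform(self.counts_b)
        concordance_a = _pre.replicate_concordance(expr_a)
        concordance_b = _pre.replicate_concordance(expr_b)
        flagged = (_pre.detect_outlier_replicates(expr_a, cfg.outlier_threshold_sd)
                   + _pre.detect_outlier_replicates(expr_b, cfg.outlier_threshold_sd))
        exclude = list(cfg.exclude_samples)
        if cfg.exclude_outliers:
            exclude += [s for s in flagged if s not in exclude]
        excl_a = [s for s in exclude if s in expr_a.values.columns]
        excl_b = [s for s in exclude if s in expr_b.values.columns]
        expr_a_used = _drop_samples(expr_a, excl_a)
        expr_b_used = _drop_samples(expr_b, excl_b)
        stage_a = _pre.average_replicates(expr_a_used)
        stage_b = _pre.average_replicates(expr_b_used)

        if cfg.thresholds_override is not None:
            thr_a = _pre.FilterThresholds(**cfg.thresholds_override["a"])
            thr_b = _pre.FilterThresholds(**cfg.thresholds_override["b"])
        else:
            thr_a = _pre.filter_thresholds(stage_a)
            thr_b = _pre.filter_thresholds(stage_b)
        f_a, f_b, filter_report = _pre.apply_filters(
            stage_a, stage_b, self.orthologs, thr_a, thr_b)
        pairs = self.orthologs[
            self.orthologs["gene_a"].isin(f_a.index)].reset_index(drop=True)

        # --- conservation -------------------------------------------------
        surfaces = {
            "inter_spearman": _conservation.similarity_surface(f_a, f_b, "spearman"),
            "inter_euclidean": _conservation.similarity_surface(f_a, f_b, "euclidean"),
            "intra_a_spearman": _conservation.similarity_surface(f_a, f_a, "spearman"),
            "intra_b_spearman": _conservation.similarity_surface(f_b, f_b, "spearman"),
        }
        diag = _conservation.diagonal_profile(expr_a_used, expr_b_used, pairs)
        std_a = _conservation.std_profile(
            _subset_genes(expr_a_used, f_a.index))
        std_b = _conservation.std_profile(
            _subset_genes(expr_b_used, f_b.index))
        band_a = _conservation.downsampling_band(
            std_a.per_gene, cfg.downsample_fraction, cfg.downsample_iters,
            seed=cfg.seed)
        band_b = _conservation.downsampling_band(
            std_b.per_gene, cfg.downsample_fraction, cfg.downsample_iters,
            seed=cfg.seed + 1)
        pca_a = _conservation.stage_pca(f_a)
        pca_b = _conservation.stage_pca(f_b)
        interior = (tuple(cfg.interior_stages) if cfg.interior_stages
                    else order.interior())
        pattern = _conservation.classify_conservation_pattern(
            diag, [s for s in interior if s in diag.stages], cfg.eps)

        # --- stage-specific genes ----------------------------------------
        calls_a = _stagespec.all_stage_calls(
            _subset_genes(expr_a_used, f_a.index), cfg.alpha)
        calls_b = _stagespec.all_stage_calls(
            _subset_genes(expr_b_used, f_b.index), cfg.alpha)
        specific_a = _stagespec.stage_specific_genes(calls_a, order)
        specific_b = _stagespec.stage_specific_genes(calls_b, order)

        # --- clustering ---------------------------------------------------
        pupal = [s for s in cfg.pupal_stages if s in f_a.columns]
        ca = f_a[f_a[pupal].std(axis=1, ddof=0) > 0]
        cb = f_b[f_b[pupal].std(axis=1, ddof=0) > 0]
        sol_a = _clustering.cluster_genes(ca, pupal, cfg.k, "A", cfg.linkage)
        sol_b = _clustering.cluster_genes(cb, pupal, cfg.k, "B", cfg.linkage)
        pairing = _clustering.pair_clusters(sol_a, sol_b, pairs)
        overlap = _clustering.cluster_overlap_matrix(
            sol_a, sol_b, pairs, cfg.overlap_denominator)

        # --- phylostrata --------------------------------------------------
        phylo: dict = {}
        if self.strata is not None:
            strat_order = (list(cfg.stratum_order) if cfg.stratum_order
                           else [s for s in _phylo.DEFAULT_STRATUM_ORDER
                                 if s in set(self.strata)]
                           or list(dict.fromkeys(self.strata)))
            med, std, skipped = _phylo.stratum_trajectories(
                f_a, self.strata, strat_order)
            phylo["trajectory_medians"] = med
            phylo["trajectory_stds"] = std
            phylo["trajectory_skipped"] = skipped
            phylo["stage_correlation"] = _phylo.stratum_stage_correlation(
                expr_a_used, expr_b_used, pairs, self.strata, strat_order)
            per_gene_rho = _phylo.per_gene_cross_species_correlation(
                f_a, f_b, pairs)
            phylo["per_gene_rho"] = per_gene_rho
            annotated = self.strata.reindex(per_gene_rho.index)
            medians, tests = {}, {}
            for stratum in strat_order:
                vals = per_gene_rho[annotated == stratum]
                rest = per_gene_rho[(annotated != stratum) & annotated.notna()]
                if len(vals) < 3 or len(rest) < 3:
                    continue
                medians[stratum] = float(vals.median())
                ug, pg = _phylo.rank_compare(vals, rest, "greater")
                ul, pl = _phylo.rank_compare(vals, rest, "less")
                tests[stratum] = {"U": ug, "p_greater": pg, "p_less": pl,
                                  "n": int(len(vals))}
            phylo["stratum_rho_medians"] = medians
            phylo["stratum_rho_tests"] = tests

            # cluster x stratum enrichment over annotated clustered genes
            annotated_genes = set(self.strata.index)
            cluster_sets = {
                int(pairing.renaming_a[c]): set(sol_a.members(c)) & annotated_genes
                for c in range(1, cfg.k + 1)}
            universe = set(sol_a.labels.index) & annotated_genes
            stratum_sets = {
                s: set(self.strata.index[self.strata == s]) & universe
                for s in strat_order}
            phylo["enrichment"] = _phylo.rho_enrichment(
                dict(sorted(cluster_sets.items())), stratum_sets, len(universe))

            if self.dnds is not None:
                dn = self.dnds.dropna()
                dnds_tests = {}
                for stratum in strat_order:
                    vals = dn[self.strata.reindex(dn.index) == stratum]
                    if len(vals) < 3:
                        continue
                    u, p = _phylo.rank_compare(vals, dn, "greater")
                    dnds_tests[stratum] = {"U": u, "p_greater": p,
                                           "n": int(len(vals))}
                phylo["dnds_tests"] = dnds_tests
            if self.annotations is not None:
                all_counts = self.strata.value_counts().reindex(
                    strat_order, fill_value=0)
                chi = {}
                for col in self.annotations.columns:
                    genes = self.annotations.index[
                        self.annotations[col].astype(bool)]
                    sub = self.strata.reindex(genes).dropna()
                    sub_counts = sub.value_counts().reindex(
                        strat_order, fill_value=0)
                    chi[col] = _phylo.chisq_distribution_test(
                        all_counts, sub_counts)
                phylo["annotation_chisq"] = chi

        return StudyResults(
            model=self, config=cfg,
            expr_a=expr_a, expr_b=expr_b,
            concordance_a=concordance_a, concordance_b=concordance_b,
            flagged_outliers=flagged, excluded_samples=exclude,
            stage_a=stage_a, stage_b=stage_b,
            thresholds_a=thr_a, thresholds_b=thr_b,
            filter_report=filter_report,
            filtered_a=f_a, filtered_b=f_b, pairs=pairs,
            surfaces=surfaces, diagonal=diag,
            std_a=std_a, std_b=std_b, band_a=band_a, band_b=band_b,
            pca_a=pca_a, pca_b=pca_b, pattern=pattern,
            calls_a=calls_a, calls_b=calls_b,
            specific_a=specific_a, specific_b=specific_b,
            clusters_a=sol_a, clusters_b=sol_b,
            pairing=pairing, overlap=overlap, phylo=phylo)


def _drop_samples(expr: ReplicateExpressionMatrix, drop: list[str]
                  ) -> ReplicateExpressionMatrix:
    if not drop:
        return expr
    kept = [c for c in expr.values.columns if c not in drop]
    return ReplicateExpressionMatrix(expr.values[kept], expr.stage_order)


def _subset_genes(expr: ReplicateExpressionMatrix, genes) -> ReplicateExpressionMatrix:
    return ReplicateExpressionMatrix(expr.values.loc[genes], expr.stage_order)


@dataclass
class StudyResults:
    """Fitted artifacts of a :class:`ConservationStudy`."""

    model: ConservationStudy
    config: StudyConfig
    expr_a: ReplicateExpressionMatrix
    expr_b: ReplicateExpressionMatrix
    concordance_a: _pre.ConcordanceResult
    concordance_b: _pre.ConcordanceResult
    flagged_outliers: list
    excluded_samples: list
    stage_a: pd.DataFrame
    stage_b: pd.DataFrame
    thresholds_a: _pre.FilterThresholds
    thresholds_b: _pre.FilterThresholds
    filter_report: dict
    filtered_a: pd.DataFrame
    filtered_b: pd.DataFrame
    pairs: pd.DataFrame
    surfaces: dict
    diagonal: _conservation.ConservationProfile
    std_a: _conservation.StdProfile
    std_b: _conservation.StdProfile
    band_a: _conservation.ConservationProfile
    band_b: _conservation.ConservationProfile
    pca_a: tuple
    pca_b: tuple
    pattern: str
    calls_a: dict
    calls_b: dict
    specific_a: dict
    specific_b: dict
    clusters_a: _clustering.ClusterSolution
    clusters_b: _clustering.ClusterSolution
    pairing: _clustering.ClusterPairing
    overlap: pd.DataFrame
    phylo: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    def report(self) -> dict:
        """JSON-serialisable run report."""
        rep = {
            "version": __version__,
            "config": _jsonable(asdict(self.config)),
            "n_genes_a": int(self.model.counts_a.values.shape[0]),
            "n_genes_b": int(self.model.counts_b.values.shape[0]),
            "mean_replicate_rho_a": self.concordance_a.mean_rho,
            "mean_replicate_rho_b": self.concordance_b.mean_rho,
            "flagged_outliers": list(self.flagged_outliers),
            "excluded_samples": list(self.excluded_samples),
            "thresholds": {
                "a": asdict(self.thresholds_a), "b": asdict(self.thresholds_b)},
            "filters": self.filter_report,
            "pattern": self.pattern,
            "pc1_variance_a": float(self.pca_a[1][0]),
            "pc1_variance_b": float(self.pca_b[1][0]),
            "diagonal_profile": {
                s: float(v) for s, v in zip(self.diagonal.stages,
                                            self.diagonal.central)},
            "cluster_pairing": self.pairing.pairs.to_dict(orient="records"),
            "n_stage_specific_a": {s: len(g) for s, g in self.specific_a.items()},
            "n_stage_specific_b": {s: len(g) for s, g in self.specific_b.items()},
        }
        if self.phylo:
            rep["stratum_rho_medians"] = self.phylo.get("stratum_rho_medians", {})
            rep["stratum_rho_tests"] = _jsonable(
                self.phylo.get("stratum_rho_tests", {}))
            if "enrichment" in self.phylo:
                enr = self.phylo["enrichment"]
                cell = enr.argmax()
                rep["enrichment_argmax"] = {
                    "cluster": int(cell[0]), "stratum": str(cell[1]),
                    "rho": float(enr.rho.loc[cell])}
            if "dnds_tests" in self.phylo:
                rep["dnds_tests"] = _jsonable(self.phylo["dnds_tests"])
            if "annotation_chisq" in self.phylo:
                rep["annotation_chisq"] = {
                    k: {"chi2": v[0], "df": v[1], "p": v[2]}
                    for k, v in self.phylo["annotation_chisq"].items()}
        return rep

    def summary(self) -> str:
        """Human-readable summary table of the fitted study."""
        rep = self.report()
        lines = [
            "Two-species developmental conservation study",
            "=" * 52,
            f"genes (species A / B):        {rep['n_genes_a']} / {rep['n_genes_b']}",
            f"retained ortholog pairs:      {rep['filters']['retained_pairs']} "
            f"({rep['filters']['retained_fraction_joint']:.1%} of table)",
            f"mean replicate Spearman rho:  A {rep['mean_replicate_rho_a']:.3f}, "
            f"B {rep['mean_replicate_rho_b']:.3f}",
            f"flagged outlier replicates:   {rep['flagged_outliers'] or 'none'}",
            f"expression/variance thresholds: "
            f"A ({self.thresholds_a.expression:.3f}, {self.thresholds_a.variance:.3f}) "
            f"B ({self.thresholds_b.expression:.3f}, {self.thresholds_b.variance:.3f})",
            f"PC1 explained variance:       A {rep['pc1_variance_a']:.1%}, "
            f"B {rep['pc1_variance_b']:.1%}",
            f"conservation pattern:         {self.pattern}",
            "",
            "diagonal conservation profile (mean rho +/- sd over replicate pairs):",
        ]
        for s, c, lo, hi in zip(self.diagonal.stages, self.diagonal.central,
                                self.diagonal.lower, self.diagonal.upper):
            lines.append(f"  {s:>6}: {c:.4f}  [{lo:.4f}, {hi:.4f}]")
        lines.append("")
        lines.append("cluster pairing (common-label id, shared orthologs, overlap):")
        for r in self.pairing.pairs.itertuples():
            lines.append(f"  pair {r.new_id}: A{r.cluster_a} <-> B{r.cluster_b}  "
                         f"shared={r.shared}  overlap={r.overlap:.2f}")
        if "enrichment_argmax" in rep:
            c = rep["enrichment_argmax"]
            lines.append("")
            lines.append(f"strongest cluster-stratum enrichment: cluster "
                         f"{c['cluster']} x {c['stratum']} (rho={c['rho']:.1f})")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def save(self, outdir) -> None:
        """Write the full TSV/JSON artifact bundle with stable file names."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.stage_a.to_csv(out / "stage_expression_a.tsv", sep="\t",
                            index_label="gene_id")
        self.stage_b.to_csv(out / "stage_expression_b.tsv", sep="\t",
                            index_label="gene_id")
        self.filtered_a.to_csv(out / "filtered_a.tsv", sep="\t",
                               index_label="gene_id")
        self.filtered_b.to_csv(out / "filtered_b.tsv", sep="\t",
                               index_label="gene_id")
        self.concordance_a.table.to_csv(out / "concordance_a.tsv", sep="\t",
                                        index=False)
        self.concordance_b.table.to_csv(out / "concordance_b.tsv", sep="\t",
                                        index=False)
        for name, surf in self.surfaces.items():
            surf.values.to_csv(out / f"surface_{name}.tsv", sep="\t")
        self.diagonal.as_frame().to_csv(out / "diagonal_profile.tsv", sep="\t",
                                        index=False)
        self.std_a.medians.to_frame("median_std").to_csv(
            out / "std_medians_a.tsv", sep="\t", index_label="stage")
        self.std_b.medians.to_frame("median_std").to_csv(
            out / "std_medians_b.tsv", sep="\t", index_label="stage")
        self.band_a.as_frame().to_csv(out / "std_downsampling_band_a.tsv",
                                      sep="\t", index=False)
        self.band_b.as_frame().to_csv(out / "std_downsampling_band_b.tsv",
                                      sep="\t", index=False)
        self.pca_a[0].to_csv(out / "stage_pca_a.tsv", sep="\t",
                             index_label="stage")
        self.pca_b[0].to_csv(out / "stage_pca_b.tsv", sep="\t",
                             index_label="stage")
        for sp, calls in (("a", self.calls_a), ("b", self.calls_b)):
            frames = []
            for stage, df in calls.items():
                d = df.copy()
                d.insert(0, "stage", stage)
                frames.append(d)
            pd.concat(frames).to_csv(out / f"upregulation_calls_{sp}.tsv",
                                     sep="\t", index_label="gene_id")
        with open(out / "stage_specific_genes.json", "w") as fh:
            json.dump({"a": self.specific_a, "b": self.specific_b}, fh,
                      indent=1, sort_keys=True)
        self.clusters_a.labels.to_frame().to_csv(
            out / "clusters_a.tsv", sep="\t", index_label="gene_id")
        self.clusters_b.labels.to_frame().to_csv(
            out / "clusters_b.tsv", sep="\t", index_label="gene_id")
        self.clusters_a.median_trajectories.to_csv(
            out / "cluster_trajectories_a.tsv", sep="\t")
        self.clusters_b.median_trajectories.to_csv(
            out / "cluster_trajectories_b.tsv", sep="\t")
        self.pairing.pairs.to_csv(out / "cluster_pairing.tsv", sep="\t",
                                  index=False)
        self.overlap.to_csv(out / "cluster_overlap.tsv", sep="\t")
        if "enrichment" in self.phylo:
            enr = self.phylo["enrichment"]
            enr.observed.to_csv(out / "enrichment_observed.tsv", sep="\t")
            enr.expected.to_csv(out / "enrichment_expected.tsv", sep="\t")
            enr.rho.to_csv(out / "enrichment_rho.tsv", sep="\t")
        if "trajectory_medians" in self.phylo:
            self.phylo["trajectory_medians"].to_csv(
                out / "stratum_trajectory_medians.tsv", sep="\t",
                index_label="stratum")
            self.phylo["trajectory_stds"].to_csv(
                out / "stratum_trajectory_stds.tsv", sep="\t",
                index_label="stratum")
        if "per_gene_rho" in self.phylo:
            self.phylo["per_gene_rho"].to_frame().to_csv(
                out / "per_gene_rho.tsv", sep="\t", index_label="gene_id")
        if "stage_correlation" in self.phylo:
            frames = []
            for stratum, prof in self.phylo["stage_correlation"].items():
                d = prof.as_frame()
                d.insert(0, "stratum", stratum)
                frames.append(d)
            if frames:
                pd.concat(frames).to_csv(out / "stratum_stage_correlation.tsv",
                                         sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(self.report(), fh, indent=1, sort_keys=True)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
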