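"""End-to-end orchestration of the variant-selection + subtyping flow.

Stage order: impute missing genotypes, logistic/positive-effect filter,
optional rare filter, optional deleterious filter, optional F-statistic
rank-and-cut intersected with the surviving set, feature-matrix
construction over the hypertensive patients (with optional gene burden
aggregation), consensus-NMF rank selection and cluster assignment, and
Kruskal–Wallis evaluation of the outcome variables.  Every stage logs its
input and output counts so selection sizes are auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, evaluation, franking, nmf
from .aggregation import FeatureMatrix, build_feature_matrix
from .config import PipelineConfig
from .evaluation import KWReport
from .nmf import ConsensusResult, SubtypeAssignment

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "impute_genotypes"]


@dataclass
class StageLog:
    stage: str
    n_in: int
    n_out: int


@dataclass
class PipelineResult:
    config: PipelineConfig
    selected_variants: list[str]
    association_results: list[association.AssociationResult]
    feature_matrix: FeatureMatrix
    rank_results: dict[int, ConsensusResult]
    best_k: int
    assignment: SubtypeAssignment
    kw_reports: list[KWReport]
    n_significant: int
    stage_log: list[StageLog] = field(default_factory=list)

    @property
    def cluster_sizes(self) -> dict[int, int]:
        labels = list(self.assignment.labels.values())
        return {k: labels.count(k) for k in sorted(set(labels))}

    def save(self, directory) -> dict[str, Path]:
        """Write the standard output file set (TSVs + run log)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        sel = pd.DataFrame({"variant_id": self.selected_variants})
        paths["selected_variants"] = directory / "selected_variants.tsv"
        sel.to_csv(paths["selected_variants"], sep="\t", index=False)

        paths["feature_matrix"] = directory / "feature_matrix.tsv"
        self.feature_matrix.to_frame().to_csv(paths["feature_matrix"], sep="\t")

        ccc = pd.DataFrame(
            {"K": list(self.rank_results), "ccc": [r.ccc for r in self.rank_results.values()]}
        )
        paths["ccc_by_rank"] = directory / "ccc_by_rank.tsv"
        ccc.to_csv(paths["ccc_by_rank"], sep="\t", index=False)

        for k, res in self.rank_results.items():
            p = directory / f"consensus_K{k}.tsv"
            pd.DataFrame(res.consensus, index=res.sample_ids, columns=res.sample_ids).to_csv(p, sep="\t")
            paths[f"consensus_K{k}"] = p

        assign = pd.DataFrame(
            {
                "patient": list(self.assignment.labels),
                "cluster": list(self.assignment.labels.values()),
                "margin": [self.assignment.margins[i] for i in self.assignment.labels],
            }
        )
        paths["assignments"] = directory / "assignments.tsv"
        assign.to_csv(paths["assignments"], sep="\t", index=False)

        kw = pd.DataFrame(
            {
                "variable": [r.variable for r in self.kw_reports],
                "h_statistic": [r.h_statistic for r in self.kw_reports],
                "p_value": [r.p_value for r in self.kw_reports],
                "significant": [r.significant for r in self.kw_reports],
                "testable": [r.testable for r in self.kw_reports],
            }
        )
        paths["kw_report"] = directory / "kw_report.tsv"
        kw.to_csv(paths["kw_report"], sep="\t", index=False)

        paths["run_log"] = directory / "run_log.txt"
        with open(paths["run_log"], "w") as fh:
            for entry in self.stage_log:
                fh.write(f"{entry.stage}\t{entry.n_in}\t{entry.n_out}\n")
            fh.write(f"best_K\t{self.best_k}\n")
            fh.write(f"n_significant\t{self.n_significant}\n")
        return paths


def impute_genotypes(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Fill missing calls with the per-variant rounded mean genotype.

    Rounding keeps entries integral (0/1/2), which the downstream
    count-matrix factorization assumes.  Variants that are entirely
    missing impute to 0.
    """
    values = genotypes.to_numpy(dtype=float).copy()
    col_means = np.nanmean(np.where(np.isnan(values), np.nan, values), axis=0)
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    fill = np.clip(np.rint(col_means), 0, 2)
    idx = np.where(np.isnan(values))
    values[idx] = fill[idx[1]]
    return pd.DataFrame(values, index=genotypes.index, columns=genotypes.columns)


def run_pipeline(
    genotypes: pd.DataFrame,
    subjects: pd.DataFrame,
    phenotypes: pd.DataFrame,
    annotation: pd.DataFrame,
    config: PipelineConfig,
) -> PipelineResult:
    """Run the full filter + subtype + evaluate flow on one cohort.

    ``subjects`` must carry status/age/sex/bmi indexed by subject id;
    filtering uses the full cohort, clustering and evaluation only the
    hypertensive patients.
    """
    config.validate()
    log: list[StageLog] = []

    def _stage(name: str, n_in: int, n_out: int) -> None:
        log.append(StageLog(name, n_in, n_out))
        logger.info("stage %-14s %6d -> %d", name, n_in, n_out)
        if n_out == 0:
            raise ValueError(f"empty selection after stage '{name}' ({n_in} -> 0)")

    subjects = subjects.loc[genotypes.index]
    status = subjects["status"].to_numpy(dtype=int)
    covariates = subjects[["age", "sex", "bmi"]]

    imputed = impute_genotypes(genotypes)
    _stage("impute", genotypes.shape[1], imputed.shape[1])

    assoc = association.fit_variant_logistic(imputed, status, covariates)
    selected = association.select_by_association(
        assoc, config.logistic_p_cutoff, positive_only=config.positive_only
    )
    _stage("logistic", len(assoc), len(selected))

    ann = annotation.set_index("variant_id", drop=False)
    if config.use_rare_filter:
        rare = association.select_rare(annotation, config.rare_threshold)
        selected &= rare
        _stage("rare", log[-1].n_out, len(selected))

    if config.use_deleterious_filter:
        deleterious = association.select_deleterious(annotation)
        selected &= deleterious
        _stage("deleterious", log[-1].n_out, len(selected))

    if config.use_f_ranking:
        # F ranking is computed on the whole candidate pool (rare variants
        # when the rare filter is on, otherwise all variants), cut at the
        # configured top fraction, then intersected with the surviving
        # positive-effect set.
        if config.use_rare_filter:
            pool = [v for v in imputed.columns if v in rare]
        else:
            pool = list(imputed.columns)
        scores = franking.score_variants(imputed[pool], status)
        top = set(franking.rank_and_cut(scores, config.f_top_fraction))
        selected &= top
        _stage("f_ranking", log[-1].n_out, len(selected))

    selected_ordered = [str(v) for v in imputed.columns if str(v) in selected]
    cases = [str(s) for s in subjects.index[subjects["status"] == 1]]
    if not cases:
        raise ValueError("cohort contains no hypertensive patients")

    gene_map = dict(zip(ann["variant_id"].astype(str), ann["gene_region"].astype(str)))
    feature = build_feature_matrix(
        imputed, selected_ordered, cases,
        aggregate=config.aggregate_genes, gene_map=gene_map,
    )
    _stage("feature_matrix", len(selected_ordered), feature.shape[0])

    max_rank = min(feature.shape) - 1
    ranks = [k for k in config.ranks if 2 <= k <= max_rank]
    if not ranks:
        raise ValueError(
            f"no valid ranks: requested {config.ranks} but the feature matrix is {feature.shape}"
        )
    best_k, rank_results = nmf.select_rank(
        feature, ranks, n_runs=config.nmf_runs, base_seed=config.nmf_seed
    )
    best = rank_results[best_k].best_run
    assignment = nmf.assign_clusters(best.H, col_ids=feature.col_ids)
    _stage("nmf", feature.shape[1], len(assignment.labels))

    pheno_cases = phenotypes.loc[[i for i in assignment.labels]]
    kw_reports, n_significant = evaluation.evaluate_subtypes(
        pheno_cases, assignment, alpha=config.kw_alpha
    )
    _stage("kruskal_wallis", len(kw_reports), len(kw_reports))

    return PipelineResult(
        config=config,
        selected_variants=selected_ordered,
        association_results=assoc,
        feature_matrix=feature,
        rank_results=rank_results,
        best_k=best_k,
        assignment=assignment,
        kw_reports=kw_reports,
        n_significant=n_significant,
        stage_log=log,
    )
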