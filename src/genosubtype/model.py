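"""Model/Results façade over the subtyping pipeline.

``SubtypeModel`` holds the data (genotypes, subject table, phenotypes,
variant annotation); ``fit`` runs the configured filter + NMF-consensus
flow and returns a ``SubtypeResults`` carrying the selected variants, the
rank scan, the patient assignment with ambiguity margins, and the
Kruskal–Wallis evaluation, with a ``summary()`` table.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .config import PIPELINE_PRESETS, PipelineConfig
from .pipeline import PipelineResult, run_pipeline
from .synthetic import Cohort

__all__ = ["SubtypeModel", "SubtypeResults"]


class SubtypeModel:
    """Genetic subtype-discovery model for a case/control cohort."""

    def __init__(
        self,
        genotypes: pd.DataFrame,
        subjects: pd.DataFrame,
        phenotypes: pd.DataFrame,
        annotation: pd.DataFrame,
    ):
        missing = set(genotypes.index) - set(subjects.index)
        if missing:
            raise ValueError(f"subjects table missing ids: {sorted(missing)[:10]}")
        known = set(annotation["variant_id"].astype(str))
        unknown = [v for v in map(str, genotypes.columns) if v not in known]
        if unknown:
            raise ValueError(f"annotation missing variants: {unknown[:10]}")
        self.genotypes = genotypes
        self.subjects = subjects
        self.phenotypes = phenotypes
        self.annotation = annotation

    @classmethod
    def from_files(cls, genotypes, subjects, phenotypes, annotation,
                   genotype_format: str | None = None) -> "SubtypeModel":
        from . import io as gio

        return cls(
            gio.read_genotypes(genotypes, format=genotype_format),
            gio.read_subjects(subjects),
            gio.read_phenotypes(phenotypes),
            gio.read_annotation(annotation),
        )

    @classmethod
    def from_cohort(cls, cohort: Cohort, annotation: pd.DataFrame) -> "SubtypeModel":
        return cls(cohort.genotypes, cohort.subjects_frame(), cohort.phenotypes, annotation)

    def fit(self, config: PipelineConfig | None = None, preset: str | None = None,
            **overrides) -> "SubtypeResults":
        """Run the pipeline; ``preset`` names one of the filter combinations."""
        if config is not None and preset is not None:
            raise ValueError("pass either config or preset, not both")
        if preset is not None:
            if preset not in PIPELINE_PRESETS:
                raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PIPELINE_PRESETS)}")
            config = PIPELINE_PRESETS[preset]
        if config is None:
            config = PipelineConfig()
        if overrides:
            config = config.replace(**overrides)
        result = run_pipeline(self.genotypes, self.subjects, self.phenotypes,
                              self.annotation, config)
        return SubtypeResults(self, result)


class SubtypeResults:
    """Fitted subtype structure: selection audit, rank scan, assignment, evaluation."""

    def __init__(self, model: SubtypeModel, result: PipelineResult):
        self.model = model
        self._result = result

    # Pass-through accessors -------------------------------------------------
    @property
    def config(self) -> PipelineConfig:
        return self._result.config

    @property
    def selected_variants(self) -> list[str]:
        return self._result.selected_variants

    @property
    def feature_matrix(self):
        return self._result.feature_matrix

    @property
    def best_k(self) -> int:
        return self._result.best_k

    @property
    def ccc_by_rank(self) -> pd.Series:
        return pd.Series({k: r.ccc for k, r in self._result.rank_results.items()}, name="ccc")

    @property
    def assignment(self):
        return self._result.assignment

    @property
    def cluster_sizes(self) -> dict[int, int]:
        return self._result.cluster_sizes

    @property
    def kw_reports(self):
        return self._result.kw_reports

    @property
    def n_significant(self) -> int:
        return self._result.n_significant

    @property
    def stage_log(self):
        return self._result.stage_log

    def kw_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "h_statistic": [r.h_statistic for r in self.kw_reports],
                "p_value": [r.p_value for r in self.kw_reports],
                "significant": [r.significant for r in self.kw_reports],
            },
            index=pd.Index([r.variable for r in self.kw_reports], name="variable"),
        )

    def save(self, directory) -> dict[str, Path]:
        return self._result.save(directory)

    def summary(self) -> str:
        """Human-readable report of the fitted subtype structure."""
        lines = ["Genetic subtype model", "=" * 52]
        lines.append(f"{'Stage':<16}{'in':>8}{'out':>8}")
        for entry in self.stage_log:
            lines.append(f"{entry.stage:<16}{entry.n_in:>8}{entry.n_out:>8}")
        lines.append("-" * 52)
        fm = self.feature_matrix
        lines.append(f"Feature matrix: {fm.shape[0]} features x {fm.shape[1]} patients")
        ccc = "  ".join(f"K={k}: {v:.3f}" for k, v in self.ccc_by_rank.items())
        lines.append(f"Cophenetic correlation by rank:  {ccc}")
        lines.append(f"Selected rank K = {self.best_k}")
        sizes = ", ".join(f"cluster {k}: {n}" for k, n in self.cluster_sizes.items())
        lines.append(f"Cluster sizes: {sizes}")
        lines.append("-" * 52)
        lines.append(f"{'Variable':<12}{'H':>8}{'p':>10}  significant (alpha={self.config.kw_alpha})")
        for r in self.kw_reports:
            if not r.testable:
                lines.append(f"{r.variable:<12}{'--':>8}{'--':>10}  untestable")
            else:
                flag = "*" if r.significant else ""
                lines.append(f"{r.variable:<12}{r.h_statistic:>8.3f}{r.p_value:>10.4f}  {flag}")
        lines.append(f"Significant variables: {self.n_significant} / "
                     f"{sum(r.testable for r in self.kw_reports)}")
        return "\n".join(lines)
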