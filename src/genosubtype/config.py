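"""Configuration objects for the synthetic cohort generator and the pipeline.

Both configs are plain dataclasses with explicit ``validate`` methods that
raise :class:`ConfigError` naming the offending field, so that a bad YAML
file fails loudly before any computation starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

__all__ = [
    "ConfigError",
    "CohortConfig",
    "PipelineConfig",
    "PIPELINE_PRESETS",
    "load_config",
]


class ConfigError(ValueError):
    """A configuration field violates its invariant."""


# Outcome variables measured by speckle-tracking echocardiography: tissue
# velocities (e' / s'), global strains, and strain rates of the left ventricle.
PHENOTYPE_VARIABLES = (
    "elateral",
    "eseptal",
    "gcs",
    "gls",
    "grs",
    "sr_a",
    "sr_e",
    "sr_s",
    "sseptal",
)

# Variables whose distribution is shifted between planted subtypes.
SHIFTED_PHENOTYPES = ("elateral", "eseptal", "gcs", "gls", "grs", "sr_a")


@dataclass
class CohortConfig:
    """Parameters of the synthetic case/control cohort.

    The generator plants ``n_subtypes`` latent subgroups among the cases:
    each subtype has its own block of ``n_subtype_variants`` variants whose
    alternate-allele frequency is raised by ``subtype_freq_shift`` within
    that subtype only.  Disease status is driven by a logistic model on
    covariates (age, sex, BMI) plus ``risk_beta`` log-odds per alternate
    allele over ``n_risk_variants`` dedicated risk variants.
    """

    n_cases: int = 200
    n_controls: int = 200
    n_variants: int = 300
    n_subtypes: int = 2
    n_risk_variants: int = 30
    n_subtype_variants: int = 30
    base_maf_range: tuple[float, float] = (0.05, 0.4)
    rare_fraction: float = 0.1
    subtype_freq_shift: float = 0.25
    risk_beta: float = 0.5
    covariate_effects: tuple[float, float, float] = (0.02, 0.3, 0.03)
    phenotype_shift: float = 1.0
    missing_rate: float = 0.0
    seed: int = 1

    def validate(self) -> None:
        for name in ("n_cases", "n_controls", "n_variants", "n_subtypes",
                     "n_risk_variants", "n_subtype_variants"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or value <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        lo, hi = self.base_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"base_maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.base_maf_range!r}")
        if not (0.0 <= self.rare_fraction < 1.0):
            raise ConfigError(f"rare_fraction must be in [0,1), got {self.rare_fraction!r}")
        if not (0.0 <= self.subtype_freq_shift < 1.0):
            raise ConfigError(f"subtype_freq_shift must be in [0,1), got {self.subtype_freq_shift!r}")
        if hi + self.subtype_freq_shift >= 1.0:
            raise ConfigError(
                "subtype_freq_shift pushes shifted frequencies outside (0,1): "
                f"max base frequency {hi} + shift {self.subtype_freq_shift} >= 1"
            )
        if self.n_risk_variants + self.n_subtype_variants * self.n_subtypes > self.n_variants:
            raise ConfigError(
                "n_risk_variants + n_subtype_variants * n_subtypes exceeds n_variants "
                f"({self.n_risk_variants} + {self.n_subtype_variants}*{self.n_subtypes} "
                f"> {self.n_variants})"
            )
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError(f"missing_rate must be in [0,1), got {self.missing_rate!r}")
        if len(self.covariate_effects) != 3:
            raise ConfigError("covariate_effects must be a (age, sex, bmi) triple")
        if self.phenotype_shift < 0:
            raise ConfigError(f"phenotype_shift must be >= 0, got {self.phenotype_shift!r}")

    def replace(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


@dataclass
class PipelineConfig:
    """Which filters to apply and how, mirroring the named filter combinations."""

    logistic_p_cutoff: float = 0.05
    positive_only: bool = True
    use_rare_filter: bool = False
    rare_threshold: float = 0.01
    use_deleterious_filter: bool = True
    use_f_ranking: bool = False
    f_top_fraction: float = 0.02
    aggregate_genes: bool = False
    ranks: tuple[int, ...] = (2, 3, 4, 5)
    nmf_runs: int = 30
    nmf_seed: int = 0
    nmf_max_iter: int = 2000
    kw_alpha: float = 0.1

    def validate(self) -> None:
        for name in ("logistic_p_cutoff", "rare_threshold", "kw_alpha"):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise ConfigError(f"{name} must be in (0,1), got {value!r}")
        if not (0.0 < self.f_top_fraction <= 1.0):
            raise ConfigError(f"f_top_fraction must be in (0,1], got {self.f_top_fraction!r}")
        if self.nmf_runs < 2:
            raise ConfigError(f"nmf_runs must be >= 2, got {self.nmf_runs!r}")
        if not self.ranks or any(k < 2 for k in self.ranks):
            raise ConfigError(f"ranks must be a non-empty set of integers >= 2, got {self.ranks!r}")
        if self.nmf_max_iter < 1:
            raise ConfigError("nmf_max_iter must be positive")

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


# Named presets for the six filter combinations reported in the study:
# rare- and all-variant F-ranked runs with gene aggregation, and the
# deleterious-variant runs at the two logistic p cutoffs with/without
# aggregation.
PIPELINE_PRESETS: dict[str, PipelineConfig] = {
    "rare_f_aggr": PipelineConfig(
        logistic_p_cutoff=0.05, use_rare_filter=True, use_deleterious_filter=False,
        use_f_ranking=True, f_top_fraction=0.02, aggregate_genes=True,
    ),
    "all_f_aggr": PipelineConfig(
        logistic_p_cutoff=0.05, use_rare_filter=False, use_deleterious_filter=False,
        use_f_ranking=True, f_top_fraction=0.02, aggregate_genes=True,
    ),
    "del_aggr_05": PipelineConfig(
        logistic_p_cutoff=0.05, use_deleterious_filter=True, aggregate_genes=True,
    ),
    "del_05": PipelineConfig(
        logistic_p_cutoff=0.05, use_deleterious_filter=True, aggregate_genes=False,
    ),
    "del_aggr_10": PipelineConfig(
        logistic_p_cutoff=0.1, use_deleterious_filter=True, aggregate_genes=True,
    ),
    "del_10": PipelineConfig(
        logistic_p_cutoff=0.1, use_deleterious_filter=True, aggregate_genes=False,
    ),
}


def load_config(path, kind: str = "pipeline"):
    """Load a flat key-value YAML file into a config dataclass.

    Unknown keys raise :class:`ConfigError`; tuples may be given as lists.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a flat mapping")
    cls = PipelineConfig if kind == "pipeline" else CohortConfig
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key, value in raw.items():
        if isinstance(value, list):
            raw[key] = tuple(value)
    config = cls(**raw)
    config.validate()
    return config
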