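"""Synthetic case/control cohorts with planted hypertensive subtypes.

The generator emulates the statistical structure the subtyping pipeline
assumes: Hardy–Weinberg genotypes, a logistic disease model on age/sex/BMI
plus positive-effect risk alleles, latent subtypes among cases marked by
allele-frequency shifts, and echocardiographic outcome variables whose
distributions differ between subtypes.  It exists so every downstream stage
is testable without access to any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    PHENOTYPE_VARIABLES,
    SHIFTED_PHENOTYPES,
    CohortConfig,
    ConfigError,
)

__all__ = ["Cohort", "generate_cohort", "generate_annotation", "write_fixture"]

DELETERIOUS_CLASSES = ("nonsynonymous", "stopgain", "stoploss")
ANNOTATION_CLASSES = DELETERIOUS_CLASSES + ("synonymous", "unknown")


@dataclass
class Cohort:
    """A subjects-by-variants cohort with disease status and outcomes.

    genotypes
        DataFrame (subjects x variants) of alternate-allele counts in
        {0, 1, 2}, NaN marking missing calls.
    status
        Per-subject hypertension status (1 = hypertensive).
    covariates
        Per-subject age (years), sex (0/1) and BMI (kg/m^2).
    phenotypes
        Per-subject echocardiographic outcome variables.
    truth_subtype
        Hidden planted subtype label (1..K) per case, -1 for controls.
        Only meaningful for synthetic cohorts.
    """

    genotypes: pd.DataFrame
    status: pd.Series
    covariates: pd.DataFrame
    phenotypes: pd.DataFrame
    truth_subtype: pd.Series

    @property
    def subject_ids(self) -> pd.Index:
        return self.genotypes.index

    @property
    def variant_ids(self) -> pd.Index:
        return self.genotypes.columns

    @property
    def case_ids(self) -> pd.Index:
        return self.status.index[self.status == 1]

    def subjects_frame(self) -> pd.DataFrame:
        """Subject table in the on-disk schema (status + covariates)."""
        out = self.covariates.copy()
        out.insert(0, "status", self.status)
        return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Bisect alpha0 so that mean sigmoid(alpha0 + eta) == target."""
    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _sigmoid(mid + eta).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _variant_roles(config: CohortConfig) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Partition variant indices into risk, per-subtype, and background blocks."""
    p = config.n_variants
    risk = np.arange(config.n_risk_variants)
    subtype_blocks = []
    start = config.n_risk_variants
    for _ in range(config.n_subtypes):
        subtype_blocks.append(np.arange(start, start + config.n_subtype_variants))
        start += config.n_subtype_variants
    background = np.arange(start, p)
    return risk, subtype_blocks, background


def _base_frequencies(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.base_maf_range
    freq = rng.uniform(lo, hi, size=config.n_variants)
    # Rare variants are drawn only among background variants: risk and
    # subtype-informative variants must stay common enough that the planted
    # frequency shift keeps frequencies inside (0,1).
    _, _, background = _variant_roles(config)
    n_rare = int(round(config.rare_fraction * config.n_variants))
    n_rare = min(n_rare, background.size)
    if n_rare > 0:
        rare_idx = rng.choice(background, size=n_rare, replace=False)
        freq[rare_idx] = rng.uniform(0.0005, 0.0095, size=n_rare)
    return freq


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a case/control cohort with planted subtypes among the cases.

    Genotypes are Binomial(2, f) per variant under Hardy–Weinberg
    equilibrium.  Disease status follows a logistic model whose intercept is
    calibrated by bisection so the expected case fraction matches
    n_cases / (n_cases + n_controls); subjects are then resampled to the
    exact requested counts.  Subtype-informative variants are re-drawn at
    frequency f + subtype_freq_shift for cases of the matching planted
    subtype only, so subtype structure exists among cases and not controls.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_target = config.n_cases + config.n_controls
    target_fraction = config.n_cases / n_target
    freq = _base_frequencies(config, rng)
    risk_idx, subtype_blocks, _ = _variant_roles(config)

    pool = 4 * n_target
    for attempt in range(5):
        age = rng.normal(55.0, 10.0, size=pool)
        sex = rng.binomial(1, 0.5, size=pool).astype(float)
        bmi = rng.normal(30.0, 5.0, size=pool)
        genotypes = rng.binomial(2, freq[None, :], size=(pool, config.n_variants)).astype(float)

        b_age, b_sex, b_bmi = config.covariate_effects
        # Age and BMI enter centred at their generative means so that the
        # calibrated intercept stays in a numerically benign range.
        eta = (
            b_age * (age - 55.0)
            + b_sex * (sex - 0.5)
            + b_bmi * (bmi - 30.0)
            + config.risk_beta * genotypes[:, risk_idx].sum(axis=1)
        )
        alpha0 = _calibrate_intercept(eta, target_fraction)
        prob = _sigmoid(alpha0 + eta)
        status = rng.binomial(1, prob)
        realized = status.mean()
        enough = status.sum() >= config.n_cases and (pool - status.sum()) >= config.n_controls
        within = abs(realized - target_fraction) <= 0.1 * target_fraction + 0.05
        if enough and within:
            break
        pool *= 2
    else:  # pragma: no cover - calibration makes this unreachable in practice
        raise RuntimeError("could not realize the requested case/control counts")

    case_pool = np.flatnonzero(status == 1)
    control_pool = np.flatnonzero(status == 0)
    cases = rng.choice(case_pool, size=config.n_cases, replace=False)
    controls = rng.choice(control_pool, size=config.n_controls, replace=False)
    keep = np.concatenate([cases, controls])

    genotypes = genotypes[keep]
    age, sex, bmi = age[keep], sex[keep], bmi[keep]
    status = status[keep]

    # Balanced planted subtype labels over the cases, shuffled.
    labels = np.tile(np.arange(1, config.n_subtypes + 1),
                     config.n_cases // config.n_subtypes + 1)[: config.n_cases]
    rng.shuffle(labels)
    truth = np.full(n_target, -1, dtype=int)
    truth[: config.n_cases] = labels

    # Re-draw subtype-informative variants at shifted frequency for cases of
    # the matching subtype.  These variants are disjoint from the risk
    # variants, so the disease model above is untouched.
    for s, block in enumerate(subtype_blocks, start=1):
        members = np.flatnonzero(truth == s)
        if members.size == 0:
            continue
        shifted = np.clip(freq[block] + config.subtype_freq_shift, 1e-6, 1 - 1e-6)
        genotypes[np.ix_(members, block)] = rng.binomial(
            2, shifted[None, :], size=(members.size, block.size)
        ).astype(float)

    # Outcome variables: standard normal noise; shifted variables get a
    # subtype-dependent mean offset, symmetric around 0, whose between-
    # subtype difference equals phenotype_shift (in SD units).
    phen = rng.standard_normal((n_target, len(PHENOTYPE_VARIABLES)))
    offsets = (np.arange(1, config.n_subtypes + 1) - (config.n_subtypes + 1) / 2.0)
    offsets = offsets / max(offsets[-1] - offsets[0], 1.0) * config.phenotype_shift * (config.n_subtypes - 1)
    for s in range(1, config.n_subtypes + 1):
        members = truth == s
        for j, var in enumerate(PHENOTYPE_VARIABLES):
            if var in SHIFTED_PHENOTYPES:
                phen[members, j] += offsets[s - 1]

    if config.missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes[mask] = np.nan

    subject_ids = pd.Index([f"S{i:05d}" for i in range(n_target)], name="subject_id")
    variant_ids = pd.Index([f"v{j:05d}" for j in range(config.n_variants)], name="variant_id")
    return Cohort(
        genotypes=pd.DataFrame(genotypes, index=subject_ids, columns=variant_ids),
        status=pd.Series(status, index=subject_ids, name="status"),
        covariates=pd.DataFrame(
            {"age": age, "sex": sex.astype(int), "bmi": bmi}, index=subject_ids
        ),
        phenotypes=pd.DataFrame(phen, index=subject_ids, columns=list(PHENOTYPE_VARIABLES)),
        truth_subtype=pd.Series(truth, index=subject_ids, name="truth_subtype"),
    )


def generate_annotation(
    config: CohortConfig,
    genes_per_cohort: int = 50,
    deleterious_fraction: float = 0.3,
) -> pd.DataFrame:
    """Build a variant annotation table matching a generated cohort.

    Each variant is assigned one gene region and three functional-class
    columns playing the role of independent gene-model annotation sources.
    A ``deleterious_fraction`` share of variants is deleterious
    (nonsynonymous / stopgain / stoploss) in at least one source; the rest
    are synonymous or unknown everywhere.  ``reference_freq`` is the
    generating population frequency under small multiplicative noise,
    standing in for an external reference-panel frequency.
    """
    config.validate()
    if genes_per_cohort <= 0:
        raise ConfigError(f"genes_per_cohort must be positive, got {genes_per_cohort!r}")
    if not (0.0 <= deleterious_fraction <= 1.0):
        raise ConfigError(f"deleterious_fraction must be in [0,1], got {deleterious_fraction!r}")

    # Separate stream: the annotation must not perturb cohort generation.
    rng = np.random.default_rng(config.seed + 1_000_003)
    p = config.n_variants
    freq = _base_frequencies(config, np.random.default_rng(config.seed))

    genes = np.array([f"GENE{g:04d}" for g in range(genes_per_cohort)])
    gene_of = genes[rng.integers(0, genes_per_cohort, size=p)]

    n_del = int(round(deleterious_fraction * p))
    del_variants = rng.choice(p, size=n_del, replace=False)
    is_del = np.zeros(p, dtype=bool)
    is_del[del_variants] = True

    classes = np.empty((p, 3), dtype=object)
    for j in range(p):
        if is_del[j]:
            n_sources = rng.integers(1, 4)
            sources = rng.choice(3, size=n_sources, replace=False)
            for k in range(3):
                if k in sources:
                    classes[j, k] = rng.choice(DELETERIOUS_CLASSES, p=[0.8, 0.1, 0.1])
                else:
                    classes[j, k] = rng.choice(["synonymous", "unknown"])
        else:
            classes[j, :] = rng.choice(["synonymous", "unknown"], size=3)

    reference_freq = np.clip(
        freq * np.exp(rng.normal(0.0, 0.05, size=p)), 1e-6, 1 - 1e-6
    )

    variant_ids = [f"v{j:05d}" for j in range(p)]
    return pd.DataFrame(
        {
            "variant_id": variant_ids,
            "gene_region": gene_of,
            "class_source1": classes[:, 0],
            "class_source2": classes[:, 1],
            "class_source3": classes[:, 2],
            "reference_freq": reference_freq,
        }
    )


def write_fixture(cohort: Cohort, annotation: pd.DataFrame, directory) -> dict[str, Path]:
    """Write a cohort + annotation as the pipeline's on-disk file set.

    Emits genotypes both as TSV and as a bi-allelic VCF; both round-trip
    through the pipeline readers to the identical matrix.
    """
    from . import io as gio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes_tsv": directory / "genotypes.tsv",
        "genotypes_vcf": directory / "genotypes.vcf",
        "subjects": directory / "subjects.tsv",
        "phenotypes": directory / "phenotypes.tsv",
        "annotation": directory / "annotation.tsv",
        "truth": directory / "truth_subtype.tsv",
    }
    gio.write_genotypes_tsv(cohort.genotypes, paths["genotypes_tsv"])
    gio.write_genotypes_vcf(cohort.genotypes, paths["genotypes_vcf"])
    gio.write_table(cohort.subjects_frame(), paths["subjects"])
    gio.write_table(cohort.phenotypes, paths["phenotypes"])
    annotation.to_csv(paths["annotation"], sep="\t", index=False)
    gio.write_table(cohort.truth_subtype.to_frame(), paths["truth"])
    return paths
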