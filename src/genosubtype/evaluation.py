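"""Clinical evaluation of genetic subtypes and cross-run stability.

A subtype split is clinically meaningful when echocardiographic outcome
variables differ in distribution between the subgroups; this is tested
variable-by-variable with the Kruskal–Wallis rank test (the outcomes are
non-normal and group sizes unequal).  Allocation stability compares the
patient partitions of two pipeline configurations after matching their
arbitrary cluster labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nmf import SubtypeAssignment

__all__ = [
    "KWReport",
    "StabilityReport",
    "kruskal_wallis",
    "evaluate_subtypes",
    "allocation_stability",
    "match_labels",
]


@dataclass
class KWReport:
    variable: str
    h_statistic: float
    p_value: float
    n_per_group: dict[int, int]
    significant: bool
    testable: bool = True


@dataclass
class StabilityReport:
    n_unchanged: int
    n_total: int
    mean_margin_changed: float
    mean_margin_unchanged: float
    label_mapping: dict[int, int]


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected midranks) and chi-square p-value.

    Missing values are dropped together with their group label.  If every
    remaining value is identical the test is vacuous: H = 0, p = 1 by
    convention.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups with data")
    samples = [values[groups == g] for g in uniq]
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def evaluate_subtypes(
    phenotypes: pd.DataFrame,
    assignment: SubtypeAssignment,
    alpha: float = 0.1,
) -> tuple[list[KWReport], int]:
    """One Kruskal–Wallis report per outcome variable, plus the count
    of variables significant at ``alpha``.

    Patients absent from the phenotype table raise; variables that are
    entirely missing, or degenerate because all patients fall in one
    cluster, are reported untestable rather than failing.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0,1), got {alpha!r}")
    ids = list(assignment.labels)
    missing = [i for i in ids if i not in phenotypes.index]
    if missing:
        raise ValueError(f"patients missing from phenotype table: {missing[:10]}")
    labels = assignment.label_array(ids)
    n_groups = len(np.unique(labels))
    reports: list[KWReport] = []
    n_significant = 0
    for var in phenotypes.columns:
        values = phenotypes.loc[ids, var].to_numpy(dtype=float)
        ok = ~np.isnan(values)
        counts = {int(g): int(((labels == g) & ok).sum()) for g in np.unique(labels)}
        testable = n_groups >= 2 and sum(c > 0 for c in counts.values()) >= 2
        if not testable:
            reports.append(KWReport(var, np.nan, np.nan, counts, False, testable=False))
            continue
        h, p = kruskal_wallis(values, labels)
        sig = bool(p < alpha)
        n_significant += sig
        reports.append(KWReport(var, h, p, counts, sig))
    return reports, n_significant


def match_labels(assign_a: SubtypeAssignment, assign_b: SubtypeAssignment) -> dict[int, int]:
    """Map b's arbitrary cluster labels onto a's by maximum overlap.

    Exhaustive over label permutations (fine for K <= 5); returns the
    mapping b-label -> a-label that maximizes the number of agreeing
    patients.
    """
    ids = list(assign_a.labels)
    a = assign_a.label_array(ids)
    b = assign_b.label_array(ids)
    labels = sorted(set(a) | set(b))
    if len(labels) > 6:
        raise ValueError("label matching supports at most 6 clusters")
    best_map, best_agree = None, -1
    for perm in permutations(labels):
        mapping = dict(zip(labels, perm))
        agree = int((a == np.vectorize(mapping.get)(b)).sum())
        if agree > best_agree:
            best_agree, best_map = agree, mapping
    return {int(k): int(v) for k, v in best_map.items()}


def allocation_stability(
    assign_a: SubtypeAssignment,
    assign_b: SubtypeAssignment,
    margins_a: Mapping[str, float] | None = None,
) -> StabilityReport:
    """How many patients keep their (label-matched) cluster across two runs.

    Patients who switch clusters are the ambiguous ones; their mean
    assignment margin (from run a) is reported alongside that of the
    stable patients.
    """
    ids_a, ids_b = set(assign_a.labels), set(assign_b.labels)
    if ids_a != ids_b:
        diff = sorted(ids_a ^ ids_b)
        raise ValueError(f"assignments cover different patients: {diff[:10]}")
    mapping = match_labels(assign_a, assign_b)
    ids = list(assign_a.labels)
    a = assign_a.label_array(ids)
    b = np.array([mapping[assign_b.labels[i]] for i in ids])
    unchanged = a == b
    margins_a = assign_a.margins if margins_a is None else margins_a
    m = np.array([margins_a[i] for i in ids], dtype=float)
    mean_changed = float(m[~unchanged].mean()) if (~unchanged).any() else float("nan")
    mean_unchanged = float(m[unchanged].mean()) if unchanged.any() else float("nan")
    return StabilityReport(
        n_unchanged=int(unchanged.sum()),
        n_total=len(ids),
        mean_margin_changed=mean_changed,
        mean_margin_unchanged=mean_unchanged,
        label_mapping=mapping,
    )


def plot_significant_boxplots(phenotypes, assignment, reports, directory):
    """Box plots of each significant variable by cluster (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = list(assignment.labels)
    labels = assignment.label_array(ids)
    written = []
    for rep in reports:
        if not (rep.testable and rep.significant):
            continue
        values = phenotypes.loc[ids, rep.variable].to_numpy(dtype=float)
        groups = sorted(set(labels))
        data = [values[(labels == g) & ~np.isnan(values)] for g in groups]
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.boxplot(data, tick_labels=[f"cluster {g}" for g in groups])
        ax.set_title(f"{rep.variable} (p={rep.p_value:.3g})")
        ax.set_ylabel(rep.variable)
        path = directory / f"box_{rep.variable}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
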