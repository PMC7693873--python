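"""Fixation-index style F statistic for ranking variants.

For a bi-allelic variant with allele frequencies p1 and p2 in two
population classes (here: hypertensive vs normotensive),

    F = Var(p) / (pbar * qbar),
    pbar = (p1 + p2) / 2,  qbar = 1 - pbar,
    Var(p) = ((p1 - pbar)^2 + (p2 - pbar)^2) / 2.

F lies in [0, 1] for two classes, is 0 iff p1 = p2, reaches 1 at complete
divergence (p1, p2) = (0, 1), and is invariant to which allele is counted.
Variants with larger F separate the two classes better and are ranked first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["FScore", "class_allele_freq", "f_statistic", "score_variants", "rank_and_cut"]


@dataclass
class FScore:
    variant_id: str
    p1: float
    p2: float
    f_value: float
    rank: int = 0


def class_allele_freq(genotypes, status) -> tuple[float, float]:
    """Alternate-allele frequency in each status class.

    ``pc = (sum of allele counts in class c) / (2 * class size)``; missing
    genotypes are excluded from numerator and denominator.  Class 1 is
    status==1 (hypertensive), class 2 is status==0.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(status)
    freqs = []
    for cls in (1, 0):
        sel = g[y == cls]
        sel = sel[~np.isnan(sel)]
        if sel.size == 0:
            raise ValueError(f"status class {cls} is empty (or entirely missing)")
        freqs.append(float(sel.sum() / (2 * sel.size)))
    return freqs[0], freqs[1]


def f_statistic(p1: float, p2: float) -> float:
    """Between-class allele-frequency divergence, bounded in [0, 1].

    The monomorphic limits pbar in {0, 1} are defined as F = 0: a variant
    fixed in both classes carries no classification information.
    """
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError(f"allele frequencies must lie in [0,1], got ({p1}, {p2})")
    pbar = (p1 + p2) / 2.0
    qbar = 1.0 - pbar
    if pbar == 0.0 or qbar == 0.0:
        return 0.0
    var_p = ((p1 - pbar) ** 2 + (p2 - pbar) ** 2) / 2.0
    return var_p / (pbar * qbar)


def score_variants(genotypes, status) -> list[FScore]:
    """Per-variant F scores over a genotype matrix, ranked decreasing.

    ``genotypes`` is a subjects x variants DataFrame (or array); ties in
    f_value are ranked by variant id so the ordering is total.
    """
    import pandas as pd

    if isinstance(genotypes, pd.DataFrame):
        ids = [str(c) for c in genotypes.columns]
        G = genotypes.to_numpy(dtype=float)
    else:
        G = np.asarray(genotypes, dtype=float)
        ids = [f"v{j}" for j in range(G.shape[1])]
    scores = []
    for j, vid in enumerate(ids):
        p1, p2 = class_allele_freq(G[:, j], status)
        scores.append(FScore(vid, p1, p2, f_statistic(p1, p2)))
    scores.sort(key=lambda s: (-s.f_value, s.variant_id))
    for i, s in enumerate(scores, start=1):
        s.rank = i
    return scores


def rank_and_cut(scores: Sequence[FScore], top_fraction: float) -> list[str]:
    """The ceil(top_fraction * N) variant ids of highest F, in decreasing order.

    Ties broken lexicographically by variant id; the ceiling guarantees a
    non-empty cut at any positive fraction.
    """
    if not scores:
        raise ValueError("empty score list")
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError(f"top_fraction must be in (0,1], got {top_fraction!r}")
    n_keep = math.ceil(top_fraction * len(scores))
    ordered = sorted(scores, key=lambda s: (-s.f_value, s.variant_id))
    return [s.variant_id for s in ordered[:n_keep]]
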