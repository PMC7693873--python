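"""KL-divergence NMF consensus clustering for subtype discovery.

Implements the classic metagene approach: factorize the nonnegative
feature-by-patient count matrix A (N x M) as A ~ WH with multiplicative
updates minimizing the generalized Kullback–Leibler divergence

    D(A || WH) = sum_ij [ A_ij log(A_ij / (WH)_ij) - A_ij + (WH)_ij ],

the objective implied by a Poisson likelihood on the counts.  Each patient
is assigned to the meta-feature (row of H) with the highest level in their
column.  Because the factorization is non-convex and seeded randomly, rank
K is chosen by consensus clustering: many restarts, a co-clustering
consensus matrix, and the cophenetic correlation coefficient (CCC) of its
induced hierarchy — a rank whose partitions are reproducible across
restarts scores near 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .aggregation import FeatureMatrix

__all__ = [
    "NMFResult",
    "ConsensusResult",
    "SubtypeAssignment",
    "kl_divergence",
    "nmf_brunet",
    "assign_clusters",
    "connectivity_matrix",
    "consensus_run",
    "cophenetic_coefficient",
    "pick_best_rank",
    "select_rank",
]

_EPS = 1e-12


@dataclass
class NMFResult:
    W: np.ndarray
    H: np.ndarray
    divergence_trace: list[float]
    n_iter: int
    seed: int

    @property
    def divergence(self) -> float:
        return self.divergence_trace[-1]


@dataclass
class ConsensusResult:
    K: int
    consensus: np.ndarray
    ccc: float
    n_runs: int
    best_run: NMFResult | None = None
    sample_ids: list[str] = field(default_factory=list)


@dataclass
class SubtypeAssignment:
    """Cluster label (1..K) per patient with an ambiguity margin.

    The margin is (largest - second largest) H entry of the patient's
    column, normalized by the column sum: 0 means the patient sits exactly
    between two meta-features, 1 means all weight on one.
    """

    labels: dict[str, int]
    margins: dict[str, float]
    K: int

    def label_array(self, ids=None) -> np.ndarray:
        ids = list(self.labels) if ids is None else list(ids)
        return np.array([self.labels[i] for i in ids])


def _as_matrix(A) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(A, FeatureMatrix):
        return A.values.astype(float), list(A.row_ids), list(A.col_ids)
    A = np.asarray(A, dtype=float)
    return A, [f"r{i}" for i in range(A.shape[0])], [f"c{j}" for j in range(A.shape[1])]


def kl_divergence(A: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(A || WH); 0 log 0 taken as 0."""
    WH = np.maximum(WH, _EPS)
    pos = A > 0
    term = np.where(pos, A * np.log(np.maximum(A, _EPS) / WH) - A, 0.0)
    return float(term.sum() + WH.sum())


def nmf_brunet(
    A,
    K: int,
    seed: int = 0,
    max_iter: int = 2000,
    conv_checks: int = 40,
    check_every: int = 10,
) -> NMFResult:
    """Multiplicative-update KL NMF with connectivity-based stopping.

    W and H are initialized uniform random in (0, 1] from ``seed`` and
    updated with the divergence-reducing multiplicative rules.  Every
    ``check_every`` iterations the patient connectivity (who shares a
    max-H cluster with whom) is recomputed; the run stops once it has been
    unchanged for ``conv_checks`` consecutive checks, or at ``max_iter``.
    """
    M_values, rows, cols = _as_matrix(A)
    N, M = M_values.shape
    if (M_values < 0).any():
        raise ValueError("input matrix must be nonnegative")
    if (M_values.sum(axis=1) == 0).any() or (M_values.sum(axis=0) == 0).any():
        raise ValueError("input has all-zero rows or columns; drop them first "
                         "(build_feature_matrix does this)")
    if not (1 <= K < max(min(N, M), 2)):
        raise ValueError(f"rank K={K} out of range for a {N}x{M} matrix")

    rng = np.random.default_rng(seed)
    W = 1.0 - rng.random((N, K))  # uniform in (0, 1]
    H = 1.0 - rng.random((K, M))

    trace: list[float] = []
    stable = 0
    prev_labels: np.ndarray | None = None
    n_iter = max_iter
    for it in range(1, max_iter + 1):
        WH = W @ H
        H *= (W.T @ (M_values / np.maximum(WH, _EPS))) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = W @ H
        W *= ((M_values / np.maximum(WH, _EPS)) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)

        if it % check_every == 0 or it == max_iter:
            trace.append(kl_divergence(M_values, W @ H))
            labels = H.argmax(axis=0)
            if prev_labels is not None and np.array_equal(labels, prev_labels):
                stable += 1
            else:
                stable = 0
            prev_labels = labels
            if stable >= conv_checks:
                n_iter = it
                break
    return NMFResult(W=W, H=H, divergence_trace=trace, n_iter=n_iter, seed=seed)


def assign_clusters(H, col_ids=None) -> SubtypeAssignment:
    """Max-H cluster assignment: each patient joins the meta-feature with the
    highest level in their H column; ties go to the smallest index."""
    H = np.asarray(H, dtype=float)
    if (H < 0).any():
        raise ValueError("H must be nonnegative")
    K, M = H.shape
    col_sums = H.sum(axis=0)
    if (col_sums == 0).any():
        raise ValueError("H has an all-zero column; assignment undefined")
    ids = [f"c{j}" for j in range(M)] if col_ids is None else [str(c) for c in col_ids]
    labels, margins = {}, {}
    for j, cid in enumerate(ids):
        col = H[:, j]
        order = np.argsort(-col, kind="stable")
        labels[cid] = int(order[0]) + 1
        second = col[order[1]] if K > 1 else 0.0
        margins[cid] = float((col[order[0]] - second) / col_sums[j])
    return SubtypeAssignment(labels=labels, margins=margins, K=K)


def connectivity_matrix(labels: np.ndarray) -> np.ndarray:
    """Binary sample-by-sample matrix: 1 where two samples share a cluster."""
    labels = np.asarray(labels)
    return (labels[:, None] == labels[None, :]).astype(float)


def consensus_run(A, K: int, n_runs: int = 30, base_seed: int = 0) -> ConsensusResult:
    """Average the connectivity matrices of ``n_runs`` seeded restarts.

    Seeds are ``base_seed .. base_seed + n_runs - 1``.  The restart with the
    lowest final divergence is kept as ``best_run`` for downstream cluster
    assignment.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    M_values, _, cols = _as_matrix(A)
    M = M_values.shape[1]
    consensus = np.zeros((M, M))
    best: NMFResult | None = None
    for r in range(n_runs):
        res = nmf_brunet(A, K, seed=base_seed + r)
        labels = res.H.argmax(axis=0)
        consensus += connectivity_matrix(labels)
        if best is None or res.divergence < best.divergence:
            best = res
    consensus /= n_runs
    np.fill_diagonal(consensus, 1.0)
    ccc = cophenetic_coefficient(consensus)
    return ConsensusResult(K=K, consensus=consensus, ccc=ccc, n_runs=n_runs,
                           best_run=best, sample_ids=cols)


def _is_perfect_block(consensus: np.ndarray) -> bool:
    """True when consensus is exactly 0/1 and 'same cluster' is transitive."""
    binary = np.isin(consensus, (0.0, 1.0)).all()
    if not binary:
        return False
    # Transitive closure check: rows of identical patterns per cluster.
    labels = {}
    next_label = 0
    for i in range(consensus.shape[0]):
        key = consensus[i].tobytes()
        if key not in labels:
            labels[key] = next_label
            next_label += 1
    lab = np.array([labels[consensus[i].tobytes()] for i in range(consensus.shape[0])])
    return np.array_equal(connectivity_matrix(lab), consensus)


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Cophenetic correlation of the consensus matrix's average-linkage tree.

    Distances are 1 - consensus; the coefficient is the Pearson correlation
    between those distances and the cophenetic distances of the dendrogram.
    A perfect 0/1 block consensus returns exactly 1; a consensus with zero
    distance variance (no structure to correlate) returns 0 by convention.
    """
    consensus = np.asarray(consensus, dtype=float)
    n = consensus.shape[0]
    if consensus.ndim != 2 or consensus.shape[0] != consensus.shape[1]:
        raise ValueError("consensus must be square")
    if n < 3:
        raise ValueError("cophenetic correlation requires at least 3 samples")
    if not np.allclose(consensus, consensus.T, atol=1e-12):
        raise ValueError("consensus must be symmetric")
    if consensus.min() < -1e-12 or consensus.max() > 1 + 1e-12:
        raise ValueError("consensus entries must lie in [0,1]")
    if _is_perfect_block(consensus):
        return 1.0
    d = squareform(1.0 - consensus, checks=False)
    if np.ptp(d) == 0:
        return 0.0
    Z = linkage(d, method="average")
    c, _ = cophenet(Z, d)
    if not np.isfinite(c):
        return 0.0
    return float(np.clip(c, 0.0, 1.0))


def pick_best_rank(ccc_by_k) -> int:
    """Argmax-CCC rank; exact ties break toward the smaller K (parsimony)."""
    if not ccc_by_k:
        raise ValueError("no candidate ranks")
    return min(ccc_by_k, key=lambda k: (-ccc_by_k[k], k))


def select_rank(
    A,
    K_values=(2, 3, 4, 5),
    n_runs: int = 30,
    base_seed: int = 0,
) -> tuple[int, dict[int, ConsensusResult]]:
    """Consensus-cluster at each candidate rank and pick the highest CCC.

    Ties break toward the smaller rank (parsimony).
    """
    K_values = sorted(set(int(k) for k in K_values))
    if not K_values:
        raise ValueError("K_values is empty")
    results: dict[int, ConsensusResult] = {}
    for K in K_values:
        results[K] = consensus_run(A, K, n_runs=n_runs, base_seed=base_seed)
    best_k = pick_best_rank({k: r.ccc for k, r in results.items()})
    return best_k, results
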