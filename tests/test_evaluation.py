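"""Kruskal–Wallis evaluation and allocation-stability comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from genosubtype import (
    SubtypeAssignment,
    allocation_stability,
    evaluate_subtypes,
    kruskal_wallis,
)


def make_assignment(labels, margins=None):
    ids = [f"p{i}" for i in range(len(labels))]
    margins = margins if margins is not None else [1.0] * len(labels)
    return SubtypeAssignment(
        labels=dict(zip(ids, labels)),
        margins=dict(zip(ids, margins)),
        K=max(labels),
    )


class TestKruskalWallis:
    def test_hand_rank_formula(self):
        """Two groups {1,2,3} vs {4,5,6}: H = 12/(6*7)*(6^2/3 + 15^2/3) - 3*7."""
        h, p = kruskal_wallis([1, 2, 3, 4, 5, 6], [1, 1, 1, 2, 2, 2])
        assert h == pytest.approx(3.857, abs=5e-4)
        assert 0 < p < 1

    def test_identical_constant_groups_vacuous(self):
        h, p = kruskal_wallis([2.0, 2.0, 2.0, 2.0], [1, 1, 2, 2])
        assert h == 0.0 and p == 1.0

    def test_single_group_is_error(self):
        with pytest.raises(ValueError, match="2 groups"):
            kruskal_wallis([1.0, 2.0], [1, 1])

    def test_missing_values_dropped_pairwise(self):
        h1, p1 = kruskal_wallis([1, 2, np.nan, 4, 5, 6], [1, 1, 1, 2, 2, 2])
        h2, p2 = kruskal_wallis([1, 2, 4, 5, 6], [1, 1, 2, 2, 2])
        assert h1 == pytest.approx(h2) and p1 == pytest.approx(p2)

    def test_two_group_h_equals_squared_standardized_ranksum(self):
        """Tie-free two-sample case: H = z^2 of the Wilcoxon rank-sum statistic."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            n1, n2 = rng.integers(4, 12, size=2)
            values = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # distinct => no ties
            groups = np.r_[np.ones(n1), np.full(n2, 2)]
            h, _ = kruskal_wallis(values, groups)
            ranks = rankdata(values)
            w = ranks[groups == 1].sum()
            n = n1 + n2
            z = (w - n1 * (n + 1) / 2) / np.sqrt(n1 * n2 * (n + 1) / 12)
            assert h == pytest.approx(z**2, rel=1e-10)

    def test_null_type_one_error_calibrated(self):
        """Permuting labels of a null sample: rejection rate at 0.05 is 0.05±0.03."""
        rng = np.random.default_rng(17)
        rejections = 0
        n_sim = 2000
        groups = np.r_[np.ones(15), np.full(15, 2)]
        for _ in range(n_sim):
            values = rng.standard_normal(30)
            _, p = kruskal_wallis(values, groups)
            rejections += p < 0.05
        assert abs(rejections / n_sim - 0.05) <= 0.03

    def test_agrees_with_permutation_oracle(self):
        """Chi-square p matches a 10,000-permutation null on a small two-group
        fixture with a moderate shift (the regime where significance calls are
        made; the approximation is known to be loose only deep in the right
        tail, far from any decision threshold)."""
        rng = np.random.default_rng(3)
        values = np.r_[rng.standard_normal(10), rng.standard_normal(10) + 1.0]
        groups = np.r_[np.ones(10), np.full(10, 2)]
        h_obs, p_chi2 = kruskal_wallis(values, groups)
        count = 0
        n_perm = 10_000
        g = groups.copy()
        for _ in range(n_perm):
            rng.shuffle(g)
            h, _ = kruskal_wallis(values, g)
            count += h >= h_obs - 1e-12
        p_perm = count / n_perm
        assert abs(p_chi2 - p_perm) <= 0.01


class TestEvaluateSubtypes:
    def _pheno(self, n, shift_labels=None, columns=("gls", "grs")):
        rng = np.random.default_rng(9)
        ids = [f"p{i}" for i in range(n)]
        data = {c: rng.standard_normal(n) for c in columns}
        frame = pd.DataFrame(data, index=pd.Index(ids, name="subject_id"))
        if shift_labels is not None:
            frame.loc[np.asarray(shift_labels) == 2, list(columns)[0]] += 2.0
        return frame

    def test_shifted_variable_detected(self):
        labels = [1] * 20 + [2] * 20
        pheno = self._pheno(40, shift_labels=labels)
        reports, n_sig = evaluate_subtypes(pheno, make_assignment(labels), alpha=0.1)
        by_var = {r.variable: r for r in reports}
        assert by_var["gls"].significant
        assert n_sig >= 1

    def test_single_cluster_all_untestable(self):
        labels = [1] * 10
        reports, n_sig = evaluate_subtypes(self._pheno(10), make_assignment(labels))
        assert n_sig == 0
        assert all(not r.testable for r in reports)

    def test_entirely_missing_variable_untestable_not_error(self):
        labels = [1] * 5 + [2] * 5
        pheno = self._pheno(10)
        pheno["gls"] = np.nan
        reports, _ = evaluate_subtypes(pheno, make_assignment(labels))
        by_var = {r.variable: r for r in reports}
        assert not by_var["gls"].testable
        assert by_var["grs"].testable

    def test_missing_patient_is_error(self):
        labels = [1] * 5 + [2] * 5
        pheno = self._pheno(8)
        with pytest.raises(ValueError, match="missing"):
            evaluate_subtypes(pheno, make_assignment(labels))

    def test_null_significance_rate_matches_alpha(self):
        """With no phenotype shift, each variable is significant with
        probability alpha; check the mean count over repeated draws."""
        rng = np.random.default_rng(31)
        labels = [1] * 25 + [2] * 25
        assignment = make_assignment(labels)
        total, n_rep, n_vars = 0, 200, 5
        for _ in range(n_rep):
            ids = [f"p{i}" for i in range(50)]
            pheno = pd.DataFrame(
                rng.standard_normal((50, n_vars)),
                index=pd.Index(ids, name="subject_id"),
                columns=["gls", "grs", "gcs", "sr_a", "sr_e"],
            )
            _, n_sig = evaluate_subtypes(pheno, assignment, alpha=0.1)
            total += n_sig
        mean_sig = total / n_rep
        assert abs(mean_sig - 0.1 * n_vars) <= 0.2


class TestAllocationStability:
    def test_global_label_swap_leaves_everyone_unchanged(self):
        a = make_assignment([1, 1, 2, 2, 1])
        b = make_assignment([2, 2, 1, 1, 2])
        report = allocation_stability(a, b)
        assert report.n_unchanged == report.n_total == 5

    def test_three_switchers_counted(self):
        labels_a = [1] * 10 + [2] * 10
        labels_b = list(labels_a)
        for i in (0, 5, 12):
            labels_b[i] = 3 - labels_b[i]
        report = allocation_stability(make_assignment(labels_a), make_assignment(labels_b))
        assert report.n_total - report.n_unchanged == 3

    def test_switchers_from_lowest_margin_decile_have_lower_mean_margin(self):
        rng = np.random.default_rng(2)
        n = 100
        margins = rng.uniform(0.0, 1.0, n)
        labels_a = rng.integers(1, 3, n).tolist()
        order = np.argsort(margins)
        labels_b = list(labels_a)
        for i in order[: n // 10]:  # flip exactly the lowest-margin decile
            labels_b[i] = 3 - labels_b[i]
        report = allocation_stability(
            make_assignment(labels_a, margins.tolist()),
            make_assignment(labels_b, margins.tolist()),
        )
        assert report.mean_margin_changed < report.mean_margin_unchanged

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(8)
        a = make_assignment(rng.integers(1, 4, 30).tolist())
        b = make_assignment(rng.integers(1, 4, 30).tolist())
        assert allocation_stability(a, b).n_unchanged == allocation_stability(b, a).n_unchanged

    def test_patient_set_mismatch_listed(self):
        a = make_assignment([1, 2, 1])
        b = SubtypeAssignment(labels={"q0": 1, "q1": 2, "q2": 1},
                              margins={"q0": 1, "q1": 1, "q2": 1}, K=2)
        with pytest.raises(ValueError, match="different patients"):
            allocation_stability(a, b)
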