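"""Evaluation statistics: ROC/Youden, rank tests, Fisher, kappa, reporting."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from amus import (
    ContingencyTable2x2,
    DegenerateInputError,
    DomainError,
    SampleMeasurement,
    auc_mwu_identity_check,
    cohen_kappa,
    fisher_exact_2x2,
    mann_whitney_u,
    proportion_pct,
    roc_with_youden,
    sensitivity_at_cutoff,
    spearman_rho,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def youden_oracle(scores, labels):
    """Exhaustive J maximisation over every candidate threshold."""
    best_j, best_t = -np.inf, None
    labels = np.asarray(labels, dtype=bool)
    for t in sorted(set(scores)):
        pos = np.asarray(scores) >= t
        sens = np.mean(pos[labels])
        spec = np.mean(~pos[~labels])
        j = sens + spec - 1
        if j > best_j + 1e-15:
            best_j, best_t = j, t
    return best_t, best_j


def fisher_oracle(a, b, c, d):
    """Two-sided p by full hypergeometric enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, col1, row1)
    k_min, k_max = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = rv.pmf(a)
    ks = np.arange(k_min, k_max + 1)
    return float(rv.pmf(ks)[rv.pmf(ks) <= p_obs * (1 + 1e-7)].sum())


def midranks(x):
    """Mid-ranks computed from first principles (sorting + tie averaging)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

class TestRocWithYouden:
    def test_perfect_separation(self):
        r = roc_with_youden([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.youden_cutoff == 3
        assert r.youden_j == pytest.approx(1.0)
        assert r.auc == pytest.approx(1.0)

    def test_single_class_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            roc_with_youden([1, 2, 3], [1, 1, 1])

    def test_sensitivity_non_increasing_in_threshold(self):
        rng = np.random.default_rng(0)
        scores = rng.random(200)
        labels = rng.random(200) < 0.4
        r = roc_with_youden(scores, labels)
        assert np.all(np.diff(r.sensitivity) <= 0)
        assert np.all(np.diff(r.specificity) >= 0)
        assert 0.0 <= r.auc <= 1.0

    def test_matches_exhaustive_youden_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = rng.integers(10, 60)
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            r = roc_with_youden(scores, labels)
            t_oracle, j_oracle = youden_oracle(scores, labels)
            assert r.youden_j == pytest.approx(j_oracle, abs=1e-12)
            assert r.youden_cutoff == t_oracle  # smallest threshold on ties

    def test_auc_equals_rank_sum_identity(self):
        rng = np.random.default_rng(7)
        assert auc_mwu_identity_check([1, 2, 3, 4], [0, 0, 1, 1])
        assert auc_mwu_identity_check(np.ones(10), np.arange(10) % 2)  # all tied: 0.5
        for _ in range(100):
            n = rng.integers(8, 80)
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert auc_mwu_identity_check(scores, labels)


# ---------------------------------------------------------------------------
# Spearman / Mann-Whitney
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_monotone_pairs(self):
        x = [1.0, 2.5, 3.0, 7.0]
        assert spearman_rho(x, [2, 4, 9, 11]) == pytest.approx(1.0)
        assert spearman_rho(x, [11, 9, 4, 2]) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.integers(0, 6, 40).astype(float)  # heavy ties
            y = x + rng.normal(0, 2, 40)
            rx, ry = midranks(x), midranks(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert spearman_rho(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])


class TestMannWhitney:
    def test_identical_samples_give_central_u(self):
        u, _ = mann_whitney_u([5, 5, 5], [5, 5, 5, 5])
        assert u == pytest.approx(3 * 4 / 2)

    def test_tiny_exact_case(self):
        # x entirely below y: U = 0; two-sided exact p = 2/C(4,2) = 1/3
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3)

    def test_exact_and_normal_agree_at_boundary(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0.0, 1.0, 6)
        y = rng.normal(0.8, 1.0, 6)
        from scipy.stats import mannwhitneyu

        u_pkg, p_pkg = mann_whitney_u(x, y)  # n = 12, no ties: exact path
        p_norm = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p_pkg == pytest.approx(
            mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        )
        assert abs(p_pkg - p_norm) < 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(DomainError):
            mann_whitney_u([], [1, 2])


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

class TestFisherExact:
    def test_published_style_table(self):
        # 48/60 vs 45/60 successes: no evidence of a group difference
        p = fisher_exact_2x2(ContingencyTable2x2(48, 12, 45, 15))
        assert p == pytest.approx(0.66, abs=0.005)

    def test_identical_rows_give_p_one(self):
        assert fisher_exact_2x2(ContingencyTable2x2(7, 3, 7, 3)) == pytest.approx(1.0)

    def test_empty_margin_rejected(self):
        with pytest.raises(DegenerateInputError):
            fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 4))

    def test_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(13)
        checked = 0
        while checked < 60:
            a, b, c, d = rng.integers(0, 11, 4)
            if a + b + c + d == 0 or a + b + c + d > 40:
                continue
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            p = fisher_exact_2x2(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-10)
            checked += 1


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

class TestCohenKappa:
    def test_perfect_agreement(self):
        r = [0, 1, 2, 0, 1, 2, 2, 1]
        k = cohen_kappa(r, r)
        assert k.kappa == pytest.approx(1.0)

    def test_hand_computed_three_category_table(self):
        # joint table [[20, 5, 0], [10, 30, 5], [0, 5, 25]], n = 100
        r1 = [0] * 25 + [1] * 45 + [2] * 30
        r2 = [0] * 20 + [1] * 5 + [0] * 10 + [1] * 30 + [2] * 5 + [1] * 5 + [2] * 25
        po = (20 + 30 + 25) / 100
        pe = 0.25 * 0.30 + 0.45 * 0.40 + 0.30 * 0.30
        expected = (po - pe) / (1 - pe)
        assert cohen_kappa(r1, r2).kappa == pytest.approx(expected, abs=1e-12)

    def test_independent_raters_give_near_zero(self):
        rng = np.random.default_rng(21)
        r1 = rng.integers(0, 4, 5000)
        r2 = rng.integers(0, 4, 5000)
        assert cohen_kappa(r1, r2).kappa == pytest.approx(0.0, abs=0.05)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.inter_rater import cohens_kappa

        rng = np.random.default_rng(3)
        r1 = rng.integers(0, 4, 300)
        r2 = np.where(rng.random(300) < 0.6, r1, rng.integers(0, 4, 300))
        k = cohen_kappa(r1, r2)
        table = np.zeros((4, 4))
        for a, b in zip(r1, r2):
            table[a, b] += 1
        sm = cohens_kappa(table, return_results=True)
        assert k.kappa == pytest.approx(float(sm.kappa), abs=1e-12)
        assert k.se == pytest.approx(float(sm.std_kappa), rel=2e-2)
        assert k.ci_low < k.kappa < k.ci_high

    def test_both_raters_constant_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            cohen_kappa([1, 1, 1], [1, 1, 1])


# ---------------------------------------------------------------------------
# Report helpers
# ---------------------------------------------------------------------------

class TestProportionPct:
    @pytest.mark.parametrize(
        "num,den,decimals,expected",
        [
            (27, 30, 0, 90.0),
            (93, 120, 0, 78.0),  # 77.5 rounds half-up
            (53, 74, 1, 71.6),
            (66, 120, 0, 55.0),
            (28, 30, 0, 93.0),
            (56, 80, 0, 70.0),
            (25, 31, 1, 80.6),
            (20, 30, 0, 67.0),
        ],
    )
    def test_printed_table_style(self, num, den, decimals, expected):
        assert proportion_pct(num, den, decimals) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(DomainError):
            proportion_pct(1, 0)


class TestSensitivityAtCutoff:
    @staticmethod
    def _cohort():
        rows = [
            ("a", 5.0, 4.0, False),
            ("b", 12.0, 9.0, True),
            ("c", 20.0, 15.0, True),
            ("d", 14.0, 10.0, False),
            ("e", 9.0, 8.0, True),
        ]
        return [
            SampleMeasurement(i, "isolation", length, area, ok)
            for i, length, area, ok in rows
        ]

    def test_hand_counted_cutoff(self):
        r = sensitivity_at_cutoff(self._cohort(), "whitish_area_mm2", 8.0)
        assert (r.numerator, r.denominator) == (3, 4)
        assert r.fraction == pytest.approx(0.75)

    def test_cutoff_below_minimum_gives_whole_cohort_rate(self):
        r = sensitivity_at_cutoff(self._cohort(), "whitish_area_mm2", 0.0)
        assert r.denominator == 5
        assert r.fraction == pytest.approx(3 / 5)

    def test_all_successes(self):
        cohort = [m for m in self._cohort() if m.diagnosis_success]
        r = sensitivity_at_cutoff(cohort, "svwc_length_mm", 0.0)
        assert r.fraction == 1.0

    def test_unreachable_cutoff_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            sensitivity_at_cutoff(self._cohort(), "whitish_area_mm2", 99.0)
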