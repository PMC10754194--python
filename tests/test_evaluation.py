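"""AUROC/DeLong machinery against brute-force oracles, binomial CIs,
per-score mortality and bootstrap calibration."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import beta

from sofa_oxi.cohort import default_config, generate_cohort
from sofa_oxi.evaluation import (
    auc_midrank,
    calibration_bootstrap,
    compare_methods,
    delong_paired_test,
    exact_binomial_ci,
    per_score_mortality,
)
from sofa_oxi.scoring import Method


def auc_bruteforce(scores, labels):
    """O(n_pos * n_neg) pairwise AUROC: mean of 1/0.5/0 over case-control
    pairs. Independent oracle for the midrank implementation."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels][:, None]
    neg = scores[~labels][None, :]
    wins = (pos > neg).sum() + 0.5 * (pos == neg).sum()
    return wins / (pos.size * neg.size)


def delong_components_bruteforce(scores, labels):
    """Explicit per-subject structural components by pairwise loops."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]

    def psi(x, y):
        return 1.0 if x > y else (0.5 if x == y else 0.0)

    v10 = np.array([np.mean([psi(x, y) for y in neg]) for x in pos])
    v01 = np.array([np.mean([psi(x, y) for x in pos]) for y in neg])
    return v10, v01


class TestAucMidrank:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
            ([5, 5, 5, 5], [0, 1, 0, 1], 0.5),
            ([1, 2, 2, 3], [0, 1, 0, 1], 0.875),
            ([4, 3, 2, 1], [0, 0, 1, 1], 0.0),
        ],
    )
    def test_small_exact_values(self, scores, labels, expected):
        est = auc_midrank(scores, labels)
        assert est.auc == pytest.approx(expected, abs=1e-12)

    def test_matches_bruteforce_on_random_tied_instances(self):
        # 1000 random instances with heavy ties, n <= 200
        rng = np.random.default_rng(1234)
        for _ in range(1000):
            n = int(rng.integers(4, 201))
            scores = rng.integers(0, rng.integers(2, 12), size=n).astype(float)
            labels = rng.random(n) < rng.uniform(0.1, 0.9)
            if labels.all() or not labels.any():
                continue
            assert auc_midrank(scores, labels).auc == pytest.approx(
                auc_bruteforce(scores, labels), abs=1e-12
            )

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.3
        base = auc_midrank(scores, labels).auc
        for f in (np.exp, np.arctan, lambda x: 3 * x + 7, lambda x: x**3):
            assert auc_midrank(f(scores), labels).auc == pytest.approx(base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_midrank([1, 2, 3], [1, 1, 1])

    def test_ci_contains_point_estimate_and_is_clipped(self):
        rng = np.random.default_rng(6)
        for mode in ("delong", "binomial_style"):
            scores = rng.normal(size=80) + 2.5 * (rng.random(80) < 0.4)
            labels = np.zeros(80, dtype=bool)
            labels[:30] = True
            est = auc_midrank(scores, labels, ci_mode=mode)
            assert 0.0 <= est.ci_low <= est.auc <= est.ci_high <= 1.0


class TestDeLong:
    def test_variance_matches_bruteforce_components(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = 30
            scores = rng.integers(0, 6, size=n).astype(float)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            est = auc_midrank(scores, labels)
            v10, v01 = delong_components_bruteforce(scores, labels)
            m, k = v10.size, v01.size
            var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
                np.var(v01, ddof=1) / k if k > 1 else 0.0
            )
            assert est.variance == pytest.approx(var, abs=1e-12)
            assert est.auc == pytest.approx(v10.mean(), abs=1e-12)

    def test_identical_scores_degenerate(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        cmp_ = delong_paired_test(scores, scores, labels)
        assert cmp_.degenerate
        assert cmp_.p == 1.0
        assert cmp_.delta == 0.0

    def test_paired_covariance_matches_bruteforce(self):
        rng = np.random.default_rng(17)
        n = 40
        sa = rng.integers(0, 5, size=n).astype(float)
        sb = sa + rng.integers(-1, 2, size=n)
        labels = np.zeros(n, dtype=bool)
        labels[rng.choice(n, 15, replace=False)] = True
        cmp_ = delong_paired_test(sa, sb, labels)
        va10, va01 = delong_components_bruteforce(sa, labels)
        vb10, vb01 = delong_components_bruteforce(sb, labels)
        m, k = va10.size, va01.size
        var_diff = (
            np.var(va10 - vb10, ddof=1) / m + np.var(va01 - vb01, ddof=1) / k
        )
        expected_z = (va10.mean() - vb10.mean()) / np.sqrt(var_diff)
        assert cmp_.z == pytest.approx(expected_z, abs=1e-10)

    def test_detects_a_real_difference(self):
        rng = np.random.default_rng(23)
        n = 4000
        severity = rng.normal(size=n)
        labels = rng.random(n) < 1 / (1 + np.exp(-(severity - 2)))
        if labels.all() or not labels.any():  # pragma: no cover
            pytest.skip("degenerate draw")
        good = severity + 0.3 * rng.normal(size=n)
        bad = severity + 3.0 * rng.normal(size=n)
        cmp_ = delong_paired_test(good, bad, labels)
        assert cmp_.delta > 0
        assert cmp_.p < 0.01


class TestExactBinomial:
    def test_boundary_cases(self):
        lo, hi = exact_binomial_ci(0, 10)
        assert lo == 0.0
        lo, hi = exact_binomial_ci(10, 10)
        assert hi == 1.0

    def test_known_interval(self):
        lo, hi = exact_binomial_ci(1, 20)
        assert lo == pytest.approx(0.00127, abs=1e-3)
        assert hi == pytest.approx(0.2487, abs=1e-3)

    def test_matches_beta_quantile_closed_form(self):
        # Clopper-Pearson: [Beta(k, n-k+1)_{.025}, Beta(k+1, n-k)_{.975}]
        for k, n in [(3, 17), (8, 40), (1, 5), (19, 20)]:
            lo, hi = exact_binomial_ci(k, n)
            assert lo == pytest.approx(beta.ppf(0.025, k, n - k + 1), abs=1e-12)
            assert hi == pytest.approx(beta.ppf(0.975, k + 1, n - k), abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            exact_binomial_ci(5, 4)
        with pytest.raises(ValueError):
            exact_binomial_ci(0, 0)

    def test_coverage_is_conservative(self):
        # nominal >= 95% coverage by construction; spot-check by simulation
        rng = np.random.default_rng(31)
        p_true, n, reps = 0.07, 500, 2000
        covered = 0
        ks = rng.binomial(n, p_true, size=reps)
        for k in ks:
            lo, hi = exact_binomial_ci(int(k), n)
            covered += lo <= p_true <= hi
        assert covered / reps >= 0.93


class TestPerScoreMortality:
    def test_counts_partition_cohort(self):
        rng = np.random.default_rng(41)
        scores = rng.integers(0, 5, size=400)
        labels = rng.random(400) < 0.1
        table = per_score_mortality(scores, labels)
        assert table["n"].sum() == 400
        assert table["deaths"].sum() == labels.sum()
        assert ((table["ci_low"] <= table["rate"]) & (table["rate"] <= table["ci_high"])).all()

    def test_all_survivors_rates_zero(self):
        table = per_score_mortality([0, 1, 1, 2], [False] * 4)
        assert (table["rate"] == 0).all()

    def test_single_level(self):
        table = per_score_mortality([2, 2, 2, 2], [True, False, False, False])
        assert len(table) == 1
        assert table["rate"].iloc[0] == pytest.approx(0.25)


class TestCalibrationBootstrap:
    def _toy(self, n=400, seed=51):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 5, size=n).astype(float)
        labels = rng.random(n) < (0.02 + 0.05 * scores)
        return scores, labels

    def test_deterministic_given_seed(self):
        scores, labels = self._toy()
        a = calibration_bootstrap(scores, labels, n_boot=50, seed=7)
        b = calibration_bootstrap(scores, labels, n_boot=50, seed=7)
        np.testing.assert_array_equal(a.ci_low, b.ci_low)
        np.testing.assert_array_equal(a.ci_high, b.ci_high)
        c = calibration_bootstrap(scores, labels, n_boot=50, seed=8)
        assert not np.array_equal(a.ci_low, c.ci_low)

    def test_single_replicate_flagged_degenerate(self):
        scores, labels = self._toy()
        res = calibration_bootstrap(scores, labels, n_boot=1, seed=0)
        assert res.degenerate
        np.testing.assert_allclose(res.ci_low, res.ci_high)

    def test_ci_width_shrinks_with_cohort_size(self):
        widths = {}
        for n in (500, 5000):
            scores, labels = self._toy(n=n, seed=61)
            res = calibration_bootstrap(scores, labels, n_boot=100, seed=3)
            widths[n] = np.median(res.ci_high - res.ci_low)
        ratio = widths[500] / widths[5000]
        # sqrt(10) ~ 3.16 expected; allow a generous stochastic band
        assert 1.5 < ratio < 6.5

    def test_observed_rates_in_unit_interval(self):
        scores, labels = self._toy()
        res = calibration_bootstrap(scores, labels, n_boot=30, seed=1)
        assert np.all((res.observed >= 0) & (res.observed <= 1))
        assert res.n_per_level.sum() == scores.size


class TestCompareMethods:
    def test_report_structure(self, small_cohort):
        report = compare_methods(small_cohort.records)
        assert len(report) == 7 * 2
        assert set(report["score_type"]) == {"respiratory", "total"}
        assert set(report["method"]) == {m.value for m in Method}
        conv_rows = report[report["method"] == "CONV"]
        assert conv_rows["p_vs_conventional"].isna().all()

    def test_methods_identical_to_conventional_give_p_one(self):
        # with every PaO2 measured, the gap-fill methods reduce to CONV
        cfg = dataclasses.replace(default_config(n=600, seed=9), miss_intercept=50.0)
        cohort = generate_cohort(cfg)
        assert all(r.pao2 is not None for r in cohort.records)
        report = compare_methods(cohort.records)
        for m in ("B", "D", "F"):
            rows = report[report["method"] == m]
            assert (rows["p_vs_conventional"] == 1.0).all()
            assert (rows["delta_vs_conventional"] == 0.0).all()

    def test_method_subset(self, small_cohort):
        report = compare_methods(small_cohort.records, [Method.CONV, Method.E])
        assert len(report) == 2 * 2
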