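"""Discrimination and calibration machinery for ordinal severity scores.

The centerpiece is the nonparametric AUROC with DeLong structural-component
variance, which supports paired comparisons of two scores measured on the
same patients (the design of the method-vs-conventional contrasts). Ties —
ubiquitous with integer SOFA scores — are handled by midranks, i.e. a tied
case/control pair contributes 1/2.

Also provided: exact (Clopper–Pearson) binomial intervals for per-score-level
mortality, bootstrap calibration curves, and :func:`compare_methods`, which
runs the full scoring-strategy comparison on a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.proportion import proportion_confint

from .scoring import ConvImputation, Method, PatientRecord, score_cohort

__all__ = [
    "AucEstimate",
    "AucComparison",
    "CalibrationResult",
    "auc_midrank",
    "delong_paired_test",
    "exact_binomial_ci",
    "per_score_mortality",
    "calibration_bootstrap",
    "compare_methods",
]


@dataclass(frozen=True)
class AucEstimate:
    """AUROC point estimate with DeLong variance and a 95% interval."""

    auc: float
    variance: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class AucComparison:
    """Paired AUROC contrast of one scoring method against a reference."""

    method: Method
    auc_method: AucEstimate
    auc_conv: AucEstimate
    delta: float
    z: float
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class CalibrationResult:
    """Observed event rate per score level with bootstrap percentile CIs."""

    levels: np.ndarray
    n_per_level: np.ndarray
    observed: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    seed: int
    degenerate: bool = False  # True when n_boot < 2 gives zero-width CIs


def _validate_scores_labels(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-d arrays")
    if np.any(~np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if labels.all() or not labels.any():
        raise ValueError("both outcome classes must be present")
    return scores, labels


def _structural_components(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components via midranks, O(n log n).

    V10[i] = mean over controls of psi(case_i, control), V01[j] likewise over
    cases, with psi = 1, 1/2, 0 for win/tie/loss.
    """
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    ranks_all = rankdata(np.concatenate([pos, neg]))
    ranks_pos = rankdata(pos)
    ranks_neg = rankdata(neg)
    v10 = (ranks_all[:m] - ranks_pos) / n
    v01 = 1.0 - (ranks_all[m:] - ranks_neg) / m
    auc = float(v10.mean())
    return auc, v10, v01


def auc_midrank(
    scores: Sequence[float],
    labels: Sequence[bool],
    ci_mode: str = "delong",
) -> AucEstimate:
    """Midrank AUROC with DeLong variance and a 95% confidence interval.

    ``ci_mode``: ``"delong"`` (normal interval on the DeLong standard error,
    the default) or ``"binomial_style"`` (normal interval on the
    Hanley–McNeil binomial-exponential variance). Intervals are clipped to
    [0, 1].
    """
    s, y = _validate_scores_labels(np.asarray(scores), np.asarray(labels))
    auc, v10, v01 = _structural_components(s, y)
    m, n = v10.size, v01.size
    var_delong = (
        (np.var(v10, ddof=1) / m if m > 1 else 0.0)
        + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    )
    if ci_mode == "delong":
        se = np.sqrt(var_delong)
    elif ci_mode == "binomial_style":
        q1 = auc / (2.0 - auc)
        q2 = 2.0 * auc**2 / (1.0 + auc)
        var_hm = (
            auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)
        ) / (m * n)
        se = np.sqrt(max(var_hm, 0.0))
    else:
        raise ValueError(f"unknown ci_mode {ci_mode!r}")
    zcrit = norm.ppf(0.975)
    return AucEstimate(
        auc=auc,
        variance=float(var_delong),
        ci_low=float(np.clip(auc - zcrit * se, 0.0, 1.0)),
        ci_high=float(np.clip(auc + zcrit * se, 0.0, 1.0)),
        n_pos=m,
        n_neg=n,
    )


def delong_paired_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
    method: Method = Method.CONV,
    ci_mode: str = "delong",
) -> AucComparison:
    """DeLong test for the difference of two AUROCs on the same patients.

    z = (AUC_a - AUC_b) / sqrt(var_a + var_b - 2 cov), with variances and
    covariance from the structural components; two-sided p from the standard
    normal. A zero-variance difference (e.g. identical scores) is reported as
    degenerate with p = 1.
    """
    sa, y = _validate_scores_labels(np.asarray(scores_a), np.asarray(labels))
    sb, _ = _validate_scores_labels(np.asarray(scores_b), np.asarray(labels))

    auc_a, v10_a, v01_a = _structural_components(sa, y)
    auc_b, v10_b, v01_b = _structural_components(sb, y)
    m, n = v10_a.size, v01_a.size

    s10 = np.cov(v10_a, v10_b, ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01_a, v01_b, ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n  # 2x2 covariance of (auc_a, auc_b)

    delta = auc_a - auc_b
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]

    est_a = auc_midrank(sa, y, ci_mode=ci_mode)
    est_b = auc_midrank(sb, y, ci_mode=ci_mode)

    if var_diff <= 1e-15:
        return AucComparison(
            method=method, auc_method=est_a, auc_conv=est_b,
            delta=float(delta), z=0.0, p=1.0, degenerate=True,
        )
    z = float(delta / np.sqrt(var_diff))
    p = float(2.0 * norm.sf(abs(z)))
    return AucComparison(
        method=method, auc_method=est_a, auc_conv=est_b,
        delta=float(delta), z=z, p=p,
    )


def exact_binomial_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Clopper–Pearson exact binomial interval for k events in n trials."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
    return float(lo), float(hi)


def per_score_mortality(
    scores: Sequence[float], labels: Sequence[bool]
) -> pd.DataFrame:
    """Observed mortality per score level with exact binomial 95% CIs.

    One row per level actually observed; columns score, n, deaths, rate,
    ci_low, ci_high. The n column partitions the cohort.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.size == 0:
        raise ValueError("empty cohort")
    rows = []
    for level in np.unique(scores):
        mask = scores == level
        n = int(mask.sum())
        k = int(labels[mask].sum())
        lo, hi = exact_binomial_ci(k, n)
        rows.append(
            {"score": level, "n": n, "deaths": k, "rate": k / n,
             "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows)


def calibration_bootstrap(
    scores: Sequence[float],
    labels: Sequence[bool],
    n_boot: int = 100,
    seed: int = 0,
) -> CalibrationResult:
    """Bootstrap calibration curve: per-level mortality with percentile CIs.

    Plain case resampling with replacement (not stratified on outcome);
    2.5/97.5 percentile intervals over ``n_boot`` replicates, computed over
    the replicates in which the level appears. Deterministic given ``seed``.
    """
    s, y = _validate_scores_labels(np.asarray(scores), np.asarray(labels))
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    n = s.size
    levels = np.unique(s)
    n_per_level = np.array([(s == lv).sum() for lv in levels])
    observed = np.array([y[s == lv].mean() for lv in levels])

    rng = np.random.default_rng(seed)
    boot_rates = np.full((n_boot, levels.size), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sb, yb = s[idx], y[idx]
        for j, lv in enumerate(levels):
            mask = sb == lv
            if mask.any():
                boot_rates[b, j] = yb[mask].mean()
    with np.errstate(all="ignore"):
        ci_low = np.nanpercentile(boot_rates, 2.5, axis=0)
        ci_high = np.nanpercentile(boot_rates, 97.5, axis=0)
    return CalibrationResult(
        levels=levels,
        n_per_level=n_per_level,
        observed=observed,
        ci_low=ci_low,
        ci_high=ci_high,
        n_boot=n_boot,
        seed=seed,
        degenerate=n_boot < 2,
    )


def compare_methods(
    records: Sequence[PatientRecord],
    methods: Iterable[Method] = tuple(Method),
    conv_imputation: ConvImputation = ConvImputation.IMPUTE_PAO2_100,
    ci_mode: str = "delong",
    scores: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Tabulate AUROC and DeLong contrasts vs the conventional method.

    For each requested method and for both the respiratory sub-score and the
    total SOFA score, reports AUROC with 95% CI plus the paired DeLong
    p-value against the conventional strategy (blank for CONV itself). Pass
    a precomputed ``scores`` frame from :func:`sofa_oxi.scoring.score_cohort`
    to skip rescoring.
    """
    methods = list(methods)
    if Method.CONV not in methods:
        methods = [Method.CONV] + methods
    if scores is None:
        scores = score_cohort(records, methods, conv_imputation)
    labels = scores["died_in_hospital"].to_numpy(dtype=bool)

    rows = []
    for score_type, prefix in (("respiratory", "resp"), ("total", "total")):
        conv = scores[f"{prefix}_CONV"].to_numpy(dtype=float)
        for m in methods:
            vals = scores[f"{prefix}_{m.value}"].to_numpy(dtype=float)
            est = auc_midrank(vals, labels, ci_mode=ci_mode)
            if m is Method.CONV:
                p = np.nan
                delta = 0.0
            else:
                cmp_ = delong_paired_test(vals, conv, labels, method=m, ci_mode=ci_mode)
                p, delta = cmp_.p, cmp_.delta
            rows.append(
                {
                    "score_type": score_type,
                    "method": m.value,
                    "auc": est.auc,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "delta_vs_conventional": delta,
                    "p_vs_conventional": p,
                }
            )
    return pd.DataFrame(rows)
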