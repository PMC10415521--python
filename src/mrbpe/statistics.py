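"""Repeatability, agreement, group-comparison and regression statistics.

This layer mirrors the study design around the imaging metrics: coefficients
of variation for repeated measurements, Bland–Altman agreement between the
right and left breasts, paired and unpaired two-sample tests (parametric and
rank-based), Spearman correlation, and the multivariable linear regression
of BPE kurtosis on age, risk group and their interaction.

Rank tests with combined n <= 12 are computed exactly by exhaustive
enumeration of the permutation distribution; larger samples use the
tie-corrected normal approximation.  All p-values are two-sided and the
conventional significance level for the reports is 0.05.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

log = logging.getLogger(__name__)

EXACT_ENUMERATION_LIMIT = 12  # combined sample size for exact rank tests


# ---------------------------------------------------------------------------
# Repeatability


@dataclass
class CvResult:
    """Coefficient of variation, (sigma/mu) * 100%, pooled over subjects."""

    cv_pct: float
    per_subject_cv_pct: list[float]
    n_subjects: int
    sigma: list[float]
    mu: list[float]


def coefficient_of_variation(repeats_by_subject) -> CvResult:
    """Per-subject CV = sample SD / mean * 100; pooled CV is the
    root-mean-square of the per-subject CVs.

    Subjects with a zero mean are excluded with a warning (their CV is
    undefined); each subject needs >= 2 repeats.
    """
    cvs, sigmas, mus = [], [], []
    for i, reps in enumerate(repeats_by_subject):
        r = np.asarray(reps, dtype=float)
        if r.size < 2:
            raise ValueError(f"subject {i}: need >= 2 repeats, got {r.size}")
        mu = r.mean()
        if mu == 0:
            warnings.warn(f"subject {i}: zero mean, CV undefined; excluded",
                          RuntimeWarning, stacklevel=2)
            continue
        sd = r.std(ddof=1)
        cvs.append(100.0 * sd / mu)
        sigmas.append(float(sd))
        mus.append(float(mu))
    if not cvs:
        raise ValueError("no subject with a defined CV")
    pooled = float(np.sqrt(np.mean(np.square(cvs))))
    return CvResult(pooled, [float(c) for c in cvs], len(cvs), sigmas, mus)


# ---------------------------------------------------------------------------
# Bland–Altman agreement


@dataclass
class BlandAltmanResult:
    """Agreement between paired right/left measurements.

    ``rpc`` (coefficient of reproducibility) is 1.96 times the sample
    standard deviation of the paired differences; the limits of agreement
    are ``bias -/+ rpc``.  ``points`` holds (pair mean, difference) for
    plotting.
    """

    bias: float
    sd_diff: float
    rpc: float
    loa_low: float
    loa_high: float
    n_pairs: int
    points: np.ndarray = field(repr=False, default=None)


def bland_altman(pairs) -> BlandAltmanResult:
    """Differences are right - left; requires >= 2 pairs."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (n, 2): (right, left)")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    diff = arr[:, 0] - arr[:, 1]
    mean = arr.mean(axis=1)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    rpc = 1.96 * sd
    return BlandAltmanResult(
        bias=bias, sd_diff=sd, rpc=rpc,
        loa_low=bias - rpc, loa_high=bias + rpc,
        n_pairs=arr.shape[0],
        points=np.column_stack([mean, diff]),
    )


# ---------------------------------------------------------------------------
# Two-sample and paired tests


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    n_per_group: tuple[int, ...]
    exact_flag: bool = False


def _mw_u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a via mid-ranks (tie-aware)."""
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    r_a = ranks[: a.size].sum()
    return float(r_a - a.size * (a.size + 1) / 2.0)


def _mw_exact_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact Mann–Whitney p by enumerating all group labelings."""
    na = a.size
    pooled = np.concatenate([a, b])
    n = pooled.size
    u_obs = _mw_u_statistic(a, b)
    mean_u = na * (n - na) / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = total = 0
    for combo in itertools.combinations(range(n), na):
        idx = np.zeros(n, dtype=bool)
        idx[list(combo)] = True
        u = _mw_u_statistic(pooled[idx], pooled[~idx])
        total += 1
        if abs(u - mean_u) >= dev_obs - 1e-12:
            count += 1
    return count / total


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann–Whitney U; exact enumeration for combined n <= 12."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    u = _mw_u_statistic(a, b)
    if a.size + b.size <= EXACT_ENUMERATION_LIMIT:
        p = _mw_exact_p(a, b)
        exact = True
    else:
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic").pvalue)
        exact = False
    return TestResult(u, min(p, 1.0), "mann_whitney_u", (a.size, b.size), exact)


def _wilcoxon_w(d: np.ndarray) -> float:
    """Signed-rank statistic W+ on non-zero differences, mid-ranks for ties."""
    ranks = sps.rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def wilcoxon_signed_rank(a, b) -> TestResult:
    """Two-sided Wilcoxon signed-rank on paired samples.

    Zero differences are discarded (Wilcoxon's rule); all-zero differences
    are degenerate.  Exact p by sign enumeration for n <= 12 non-zero pairs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero: test degenerate")
    w_obs = _wilcoxon_w(d)
    n = d.size
    mean_w = n * (n + 1) / 4.0
    if n <= EXACT_ENUMERATION_LIMIT:
        # exact null distribution of W+ over all 2^n sign assignments,
        # by subset-sum counting over the doubled (integer) mid-ranks
        ranks2 = np.rint(2 * sps.rankdata(np.abs(d))).astype(int)
        total_sum = int(ranks2.sum())
        counts = np.zeros(total_sum + 1)
        counts[0] = 1.0
        for r in ranks2:
            counts[r:] += counts[:-r or None].copy()
        w_support = np.arange(total_sum + 1) / 2.0
        dev_obs = abs(w_obs - mean_w)
        extreme = np.abs(w_support - mean_w) >= dev_obs - 1e-12
        p, exact = float(counts[extreme].sum() / counts.sum()), True
    else:
        p = float(sps.wilcoxon(d, alternative="two-sided",
                               correction=False, mode="approx").pvalue)
        exact = False
    return TestResult(w_obs, min(p, 1.0), "wilcoxon_signed_rank",
                      (a.size,), exact)


def student_t(a, b) -> TestResult:
    """Two-sided two-sample Student's t (equal-variance)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(float(t), float(p), "student_t", (a.size, b.size))


def paired_t(a, b) -> TestResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    t, p = sps.ttest_rel(a, b)
    return TestResult(float(t), float(p), "paired_t", (a.size,))


def spearman_r(x, y, permutation: bool = False, n_perm: int = 10000,
               rng_seed: int = 0) -> tuple[float, float]:
    """Tie-aware Spearman correlation (Pearson on mid-ranks) with an
    optional permutation p-value for small samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance: correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    if permutation:
        rng = np.random.default_rng(rng_seed)
        count = 1  # the observed permutation counts
        for _ in range(n_perm):
            rp = rng.permutation(ry)
            if abs(np.corrcoef(rx, rp)[0, 1]) >= abs(r) - 1e-12:
                count += 1
        p = count / (n_perm + 1)
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return r, p


# ---------------------------------------------------------------------------
# Kurtosis regression (outcome ~ age + risk + age*risk)


@dataclass
class RegressionResult:
    coefficients: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    n: int


def kurtosis_regression(kurtosis, age, risk, with_interaction: bool = True
                        ) -> RegressionResult:
    """OLS of a BPE-kurtosis outcome on age, binary risk group and
    (optionally) their interaction; 95% CIs from the t distribution."""
    y = np.asarray(kurtosis, dtype=float)
    age = np.asarray(age, dtype=float)
    risk = np.asarray(risk, dtype=float)
    cols = {"intercept": np.ones_like(y), "age": age, "risk": risk}
    if with_interaction:
        cols["age:risk"] = age * risk
    x = np.column_stack(list(cols.values()))
    if y.size <= x.shape[1]:
        raise ValueError("need n > number of coefficients")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear terms)")
    model = sm.OLS(y, x).fit()
    ci = model.conf_int(alpha=0.05)
    names = list(cols.keys())
    return RegressionResult(
        coefficients={n: float(c) for n, c in zip(names, model.params)},
        conf_int={n: (float(lo), float(hi))
                  for n, (lo, hi) in zip(names, np.asarray(ci))},
        p_values={n: float(p) for n, p in zip(names, model.pvalues)},
        n=int(y.size),
    )


# ---------------------------------------------------------------------------
# Cohort comparison table


def _normality_screen(x: np.ndarray, alpha: float = 0.05) -> bool:
    """Shapiro–Wilk screen; True if 'normal enough' for a t-test."""
    if x.size < 3 or np.ptp(x) == 0:
        return False
    return sps.shapiro(x).pvalue > alpha


def cohort_compare(
    results: pd.DataFrame,
    metric_list,
    group_col: str = "group",
    group_labels: tuple[str, str] = ("high_risk", "population_risk"),
    test_overrides: dict[str, str] | None = None,
    min_group_n: int = 3,
) -> pd.DataFrame:
    """Per-metric group medians (Q1–Q3), the applied test, and its p-value.

    The parametric/non-parametric choice defaults to a Shapiro–Wilk screen
    of both groups and can be forced per metric via ``test_overrides``
    (values ``"t"`` or ``"mw"``).  Metrics with a group below
    ``min_group_n`` are skipped with a warning.
    """
    overrides = test_overrides or {}
    rows = []
    for metric in metric_list:
        ga = results.loc[results[group_col] == group_labels[0], metric].dropna().to_numpy(float)
        gb = results.loc[results[group_col] == group_labels[1], metric].dropna().to_numpy(float)
        if ga.size < min_group_n or gb.size < min_group_n:
            log.warning("metric %s skipped: group n = (%d, %d)",
                        metric, ga.size, gb.size)
            continue
        choice = overrides.get(metric)
        if choice is None:
            choice = "t" if (_normality_screen(ga) and _normality_screen(gb)) else "mw"
        res = student_t(ga, gb) if choice == "t" else mann_whitney_u(ga, gb)
        qa = np.percentile(ga, [25, 50, 75])
        qb = np.percentile(gb, [25, 50, 75])
        rows.append({
            "metric": metric,
            f"{group_labels[0]}_median": qa[1],
            f"{group_labels[0]}_q1": qa[0],
            f"{group_labels[0]}_q3": qa[2],
            f"{group_labels[1]}_median": qb[1],
            f"{group_labels[1]}_q1": qb[0],
            f"{group_labels[1]}_q3": qb[2],
            "test": res.test_name,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "exact": res.exact_flag,
            "n_per_group": (ga.size, gb.size),
        })
    return pd.DataFrame(rows)


def holm_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Holm step-down adjusted p-values (optional multiplicity control)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
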