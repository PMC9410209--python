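"""Statistical layer: correlation, rank tests, regression, reliability.

Pearson correlation and the tie-corrected Kruskal-Wallis H test wrap
scipy; ordinary least squares and backward elimination build on
statsmodels.  The intraclass correlation ICC(A,1) — single measure,
absolute agreement, two-way model — is computed from the two-way ANOVA
mean squares directly, with the standard F-based confidence interval.
Correlation strengths are labelled on the scale of Chan (2003):
|R| >= 0.8 very strong, 0.6-0.8 moderately strong, 0.3-0.6 fair,
< 0.3 poor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "PearsonResult",
    "KruskalResult",
    "RegressionResult",
    "ICCResult",
    "pearson",
    "kruskal_wallis",
    "ols",
    "backward_eliminate",
    "icc_a1",
    "chan_label",
    "CHAN_THRESHOLDS",
]


@dataclass
class PearsonResult:
    r: float
    p: float
    n: int

    @property
    def label(self) -> str:
        return chan_label(self.r)


@dataclass
class KruskalResult:
    h: float
    p: float
    p_exact: float | None = None


@dataclass
class RegressionResult:
    params: pd.Series  # includes the intercept ("const")
    pvalues: pd.Series
    r_squared: float
    predictors: list[str]
    n: int
    eliminated: list[str] = field(default_factory=list)


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str = "ICC(A,1): two-way, absolute agreement, single measures"


def pearson(x, y) -> PearsonResult:
    """Product-moment correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D series of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return PearsonResult(float(r), float(p), len(x))


def _exact_kruskal_p(groups: list[np.ndarray], h_obs: float) -> float:
    """Permutation p-value: distribute pooled values over the group sizes."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    n = len(pooled)
    idx_all = np.arange(n)
    count = 0
    total = 0
    splits = []

    def partitions(avail, remaining_sizes):
        if not remaining_sizes:
            yield []
            return
        k = remaining_sizes[0]
        for combo in itertools.combinations(avail, k):
            rest = avail - set(combo)
            for tail in partitions(rest, remaining_sizes[1:]):
                yield [list(combo)] + tail

    for assignment in partitions(set(idx_all), sizes):
        total += 1
        try:
            h = sps.kruskal(*[pooled[idx] for idx in assignment]).statistic
        except ValueError:  # all identical within permutation
            h = 0.0
        if h >= h_obs - 1e-12:
            count += 1
        splits.append(h)
    return count / total


def kruskal_wallis(groups, exact_max_n: int = 10) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p-value.

    For pooled sample sizes up to ``exact_max_n`` the exact permutation
    p-value is also computed and reported as ``p_exact``.  Identical
    values everywhere give H = 0, p = 1 rather than an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    total_n = sum(len(g) for g in groups)
    if total_n < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return KruskalResult(0.0, 1.0)
    res = sps.kruskal(*groups)
    p_exact = None
    if total_n <= exact_max_n:
        p_exact = _exact_kruskal_p(groups, float(res.statistic))
    return KruskalResult(float(res.statistic), float(res.pvalue), p_exact)


def _design(X: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(X).astype(float)
    return sm.add_constant(X, has_constant="add")


def ols(y, X) -> RegressionResult:
    """Least-squares linear model with intercept, t-based p-values and R^2.

    Raises on rank deficiency, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    Xd = _design(X)
    n, p = Xd.shape
    if n <= p:
        raise ValueError(f"need n > p + 1 observations (n={n}, predictors={p - 1})")
    rank = np.linalg.matrix_rank(Xd.values)
    if rank < p:
        # identify columns not contributing to the column space
        bad = []
        cols = list(Xd.columns)
        for i in range(1, p):
            sub = Xd.drop(columns=cols[i]).values
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(cols[i])
        raise ValueError(f"design matrix is rank deficient; collinear: {bad}")
    fit = sm.OLS(y, Xd).fit()
    r2 = float(fit.rsquared)
    if not np.isfinite(r2):  # constant response: no variance to explain
        r2 = 0.0
    return RegressionResult(
        params=fit.params,
        pvalues=fit.pvalues,
        r_squared=r2,
        predictors=[c for c in Xd.columns if c != "const"],
        n=n,
    )


def backward_eliminate(y, X, alpha: float = 0.05) -> RegressionResult:
    """Backward elimination of predictors at significance level ``alpha``.

    Iteratively refits, dropping the predictor with the largest p-value
    above ``alpha`` (ties broken by column order) until every retained
    predictor has p <= alpha or none remain.
    """
    X = pd.DataFrame(X)
    eliminated: list[str] = []
    current = list(X.columns)
    result = ols(y, X[current]) if current else None
    while current:
        result = ols(y, X[current])
        pvals = result.pvalues.drop("const")
        worst = None
        worst_p = alpha
        for col in current:  # column order breaks ties deterministically
            if pvals[col] > worst_p:
                worst, worst_p = col, pvals[col]
        if worst is None:
            break
        current.remove(worst)
        eliminated.append(worst)
    if not current:
        # intercept-only model
        yarr = np.asarray(y, dtype=float)
        const = sm.OLS(yarr, np.ones((len(yarr), 1))).fit()
        result = RegressionResult(
            params=pd.Series({"const": float(const.params[0])}),
            pvalues=pd.Series({"const": float(const.pvalues[0])}),
            r_squared=0.0,
            predictors=[],
            n=len(yarr),
        )
    result.eliminated = eliminated
    return result


def icc_a1(ratings, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): single-measure absolute-agreement two-way intraclass
    correlation with its F-based confidence interval.

    ``ratings`` is a complete subjects x raters table.  The estimate is

        (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    from the two-way ANOVA mean squares for rows (subjects), columns
    (raters) and error.  Raises when the between-subject variance is zero
    (the coefficient is undefined).
    """
    data = np.asarray(pd.DataFrame(ratings), dtype=float)
    if data.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters table")
    n, k = data.shape
    if n < 5 or k < 2:
        raise ValueError("need >= 5 subjects and >= 2 raters")
    if not np.all(np.isfinite(data)):
        raise ValueError("ratings table must be complete and finite")

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr <= 0 or np.isclose(ss_rows, 0.0):
        raise ValueError("zero between-subject variance: ICC undefined")

    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    # confidence interval (McGraw & Wong): Satterthwaite df for the
    # denominator combination a*MSC + b*MSE
    r = icc
    a = (k * r) / (n * (1 - r)) if r < 1 else np.inf
    b = 1 + (k * r * (n - 1)) / (n * (1 - r)) if r < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        denom = k * msc + (k * n - k - n) * mse
        low = n * (msr - f_l * mse) / (f_l * denom + n * msr)
        high = n * (f_u * msr - mse) / (denom + n * f_u * msr)
    else:  # perfect agreement
        low = high = 1.0
    low = min(low, icc)
    high = max(high, icc)
    return ICCResult(float(icc), float(low), float(high))


# Chan YH (2003), Biostatistics 104: correlational analysis -- thresholds
# on |R|, lower bound inclusive.
CHAN_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (0.8, "very strong"),
    (0.6, "moderately strong"),
    (0.3, "fair"),
    (0.0, "poor"),
)


def chan_label(r: float, thresholds=CHAN_THRESHOLDS) -> str:
    """Correlation-strength label for ``|r|`` on the Chan (2003) scale."""
    if abs(r) > 1:
        raise ValueError("|R| must not exceed 1")
    for bound, label in thresholds:
        if abs(r) >= bound:
            return label
    return thresholds[-1][1]
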