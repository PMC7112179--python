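"""Statistical kernel shared by every pipeline stage.

Exact contingency tests, Benjamini-Hochberg FDR control, tie-corrected
Kendall rank correlation, ordinary least squares, and the quasi-binomial
framework used to test marker transmission ratios against the Mendelian
expectation of one half.

The quasi-binomial machinery is the one piece implemented from first
principles here: an intercept-only binomial GLM with a logit link whose
extra-binomial variance is absorbed by a Pearson dispersion parameter
``phi``, with a quasi-likelihood F test on the scaled deviance drop.
Standard tests (Fisher exact, Kendall tau, Welch t, exact binomial)
delegate to scipy/statsmodels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "QuasiGLMFit",
    "RegressionResult",
    "fisher_exact_2x2",
    "benjamini_hochberg",
    "kendall_tau_b",
    "quasibinomial_test",
    "binomial_deviance",
    "pearson_dispersion",
    "linear_regression",
    "auxiliary_test",
]

_LINK_EPS = 1e-8  # boundary fits clip the fitted rate at this value


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of non-negative counts; row 1 = group A, row 2 = group B."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("contingency cells must be non-negative")
        if all(x == 0 for x in cells):
            raise ValueError("contingency table must contain at least one count")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass
class TestResult:
    """Uniform test-result container used throughout the package."""

    statistic: float
    p_value: float
    method: str
    alternative: str = "two-sided"
    estimate: Optional[float] = None
    p_adjusted: Optional[float] = None
    flags: list = field(default_factory=list)


@dataclass
class QuasiGLMFit:
    """Intercept-only quasi-binomial fit summary."""

    coefficients: np.ndarray  # [logit(fitted_rate)]
    fitted_rate: float
    deviance: float
    null_deviance: float
    dispersion_phi: float
    residual_df: int
    boundary: bool = False


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_p: float
    r2_adjusted: float
    n: int


# ---------------------------------------------------------------------------
# contingency tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table: ContingencyTable2x2, alternative: str = "two-sided") -> TestResult:
    """Exact hypergeometric test on a 2x2 table.

    Two-sided p sums the probabilities of all tables (with the observed
    margins) no more likely than the observed one, the convention shared
    by R's ``fisher.test`` and scipy. The estimate is the sample odds
    ratio ``(a*d)/(b*c)`` (conditional-MLE conventions differ; the p-value
    does not depend on this choice).
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    arr = table.as_array()
    flags = []
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        warnings.warn("degenerate margin in 2x2 table; p = 1", stacklevel=2)
        flags.append("degenerate_margin")
    odds, p = sps.fisher_exact(arr, alternative=alternative)
    return TestResult(
        statistic=float(odds),
        p_value=float(p),
        method="fisher_exact",
        alternative=alternative,
        estimate=float(odds),
        flags=flags,
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjusted p-values; NaNs pass through and do not count in m."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if ok.sum() > 0:
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Tie-corrected Kendall rank correlation (tau-b) with asymptotic p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(
            statistic=float("nan"),
            p_value=float("nan"),
            method="kendall_tau_b",
            estimate=None,
            flags=["all_tied"],
        )
    res = sps.kendalltau(x, y)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="kendall_tau_b",
        estimate=float(res.statistic),
    )


# ---------------------------------------------------------------------------
# quasi-binomial transmission framework
# ---------------------------------------------------------------------------

def binomial_deviance(successes: np.ndarray, totals: np.ndarray, rate: float) -> float:
    """Binomial deviance of per-ear counts around a common rate.

    ``2 * sum[ y ln(y/(n mu)) + (n-y) ln((n-y)/(n(1-mu))) ]`` with the
    usual 0*ln(0) = 0 convention.
    """
    y = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    mu = min(max(rate, _LINK_EPS), 1.0 - _LINK_EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / (n * mu)), 0.0)
        t2 = np.where(n - y > 0, (n - y) * np.log((n - y) / (n * (1.0 - mu))), 0.0)
    return float(2.0 * np.sum(t1 + t2))


def pearson_dispersion(successes: np.ndarray, totals: np.ndarray, rate: float, df: int) -> float:
    """Pearson dispersion: sum of squared Pearson residuals over ``df``."""
    if df <= 0:
        raise ValueError("dispersion requires positive residual degrees of freedom")
    y = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    mu = min(max(rate, _LINK_EPS), 1.0 - _LINK_EPS)
    chi2 = np.sum((y - n * mu) ** 2 / (n * mu * (1.0 - mu)))
    return float(chi2 / df)


def quasibinomial_test(
    successes: Sequence[int],
    totals: Sequence[int],
    null_rate: float = 0.5,
    phi_override: Optional[float] = None,
    phi_df: Optional[int] = None,
) -> tuple[QuasiGLMFit, TestResult]:
    """Quasi-likelihood test of a common transmission rate against a null.

    Each element of ``successes``/``totals`` is one ear. The intercept-only
    logit-link MLE is the pooled proportion (the IRLS fixed point has this
    closed form), so ``fitted_rate = sum(successes)/sum(totals)``. The
    Pearson dispersion ``phi`` is estimated on k-1 df unless
    ``phi_override`` is given (e.g. pooled across alleles of a class, with
    its df passed as ``phi_df``). The test statistic is

        F = (D_null - D_fit) / phi   on  F(1, phi_df)

    degenerating to chi-square(1) when the dispersion df is unknown or
    infinite (the phi = 1 limit reproduces the binomial likelihood-ratio
    test).
    """
    y = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if y.shape != n.shape or y.ndim != 1 or y.size == 0:
        raise ValueError("successes and totals must be equal-length 1-D vectors")
    if np.any(n <= 0) or np.any(y < 0) or np.any(y > n):
        raise ValueError("need 0 <= successes <= totals and totals > 0")
    if not 0.0 < null_rate < 1.0:
        raise ValueError("null_rate must be in (0, 1)")

    k = y.size
    rate = float(y.sum() / n.sum())
    flags = []
    boundary = rate <= 0.0 or rate >= 1.0
    rate_c = min(max(rate, _LINK_EPS), 1.0 - _LINK_EPS)
    if boundary:
        flags.append("boundary_fit")

    d_fit = binomial_deviance(y, n, rate_c)
    d_null = binomial_deviance(y, n, null_rate)

    if phi_override is not None:
        if phi_override <= 0:
            raise ValueError("phi_override must be positive")
        phi = float(phi_override)
        df_phi = phi_df  # may be None => chi-square reference
    else:
        if k < 2:
            raise ValueError(
                "a single ear leaves no residual df to estimate phi; "
                "supply phi_override (e.g. pooled across a class)"
            )
        df_phi = k - 1
        phi = pearson_dispersion(y, n, rate_c, df_phi)
        if phi <= 0:
            phi = _LINK_EPS
            flags.append("zero_dispersion")

    f_stat = max(d_null - d_fit, 0.0) / phi
    if df_phi is None or not np.isfinite(df_phi):
        p = float(sps.chi2.sf(f_stat, 1))
        method = "quasi_likelihood_chi2"
    else:
        p = float(sps.f.sf(f_stat, 1, df_phi))
        method = "quasi_likelihood_F"

    fit = QuasiGLMFit(
        coefficients=np.array([math.log(rate_c / (1.0 - rate_c))]),
        fitted_rate=rate,
        deviance=d_fit,
        null_deviance=d_null,
        dispersion_phi=phi,
        residual_df=k - 1,
        boundary=boundary,
    )
    result = TestResult(
        statistic=float(f_stat),
        p_value=p,
        method=method,
        estimate=rate,
        flags=flags,
    )
    return fit, result


# ---------------------------------------------------------------------------
# regression and auxiliary tests
# ---------------------------------------------------------------------------

def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS of y on x with a t-test on the slope and adjusted R-squared."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three paired finite observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.var(x) == 0:
        raise ValueError("zero variance in x; slope undefined")
    res = sps.linregress(x, y)
    n = x.size
    r2 = res.rvalue**2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_p=float(res.pvalue),
        r2_adjusted=float(r2_adj),
        n=int(n),
    )


def auxiliary_test(mode: str, **kwargs) -> TestResult:
    """Side tests used by the phenotype and confounder analyses.

    ``welch_t``           -- Welch two-sample t (``a``, ``b`` vectors)
    ``two_proportion_cc`` -- equality of two proportions with Yates
                             continuity correction (``successes``, ``totals``
                             length-2 sequences), as in R ``prop.test``
    ``exact_binomial``    -- exact two-sided binomial test (``k``, ``n``,
                             ``p0``)
    """
    if mode == "welch_t":
        a = np.asarray(kwargs["a"], dtype=float)
        b = np.asarray(kwargs["b"], dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("welch_t needs at least 2 observations per group")
        if np.array_equal(a, b):
            # identical samples: zero statistic by convention (variance may be 0)
            return TestResult(0.0, 1.0, "welch_t", estimate=0.0)
        res = sps.ttest_ind(a, b, equal_var=False)
        return TestResult(
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            method="welch_t",
            estimate=float(np.mean(a) - np.mean(b)),
        )
    if mode == "two_proportion_cc":
        succ = np.asarray(kwargs["successes"], dtype=np.int64)
        tot = np.asarray(kwargs["totals"], dtype=np.int64)
        if succ.size != 2 or tot.size != 2:
            raise ValueError("two_proportion_cc expects two groups")
        if np.any(tot < 1):
            raise ValueError("two_proportion_cc needs at least 1 trial per group")
        table = np.column_stack([succ, tot - succ])
        chi2, p, _, _ = sps.chi2_contingency(table, correction=True)
        est = succ[0] / tot[0] - succ[1] / tot[1]
        return TestResult(float(chi2), float(p), "two_proportion_cc", estimate=float(est))
    if mode == "exact_binomial":
        k, n = int(kwargs["k"]), int(kwargs["n"])
        p0 = float(kwargs.get("p0", 0.5))
        if n < 1:
            raise ValueError("exact_binomial needs n >= 1")
        res = sps.binomtest(k, n, p0)
        return TestResult(
            statistic=float(k),
            p_value=float(res.pvalue),
            method="exact_binomial",
            estimate=k / n,
        )
    raise ValueError(f"unknown auxiliary test mode {mode!r}")
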