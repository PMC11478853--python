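"""Default Bayes factors and classical statistics for the CIT analysis.

Two default Bayes factors are implemented by direct numerical
quadrature, matching the conventions of standard Bayesian statistics
software:

* **JZS t test** (one-sample / paired): a Cauchy(0, r) prior on the
  standardized effect size delta against the point null delta = 0, with
  default scale r = sqrt(2)/2.  The marginal likelihood under H1 is the
  noncentral-t density of the observed t averaged over the prior;
  directional alternatives use the folded (truncated) Cauchy.

* **Pearson correlation** (Jeffreys-style): a stretched symmetric
  beta(1/kappa, 1/kappa) prior on rho with default width kappa = 1
  (uniform on (-1, 1)), combined with the exact reduced likelihood of
  the sample correlation,

      p(r | rho, n)  propto  (1 - rho^2)^((n-1)/2)
                             * (1 - rho * r)^((3 - 2n)/2)
                             * 2F1(1/2, 1/2; n - 1/2; (rho * r + 1)/2).

Both are computed from summary statistics (t or r, and n), so printed
results are reproducible without raw data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats

__all__ = ["BayesResult", "EffectSizeResult", "pearson_r", "paired_t",
           "one_sample_t", "cohen_d_one_sample", "d_from_t", "t_from_d",
           "bf_ttest", "bf_correlation", "sequential_bf", "bonferroni_alpha",
           "correlation_matrix"]

DEFAULT_CAUCHY_SCALE = math.sqrt(2) / 2
_QUAD_OPTS = dict(limit=400, epsabs=1e-12, epsrel=1e-10)


@dataclass(frozen=True)
class BayesResult:
    """A test statistic with its default Bayes factor."""

    statistic_name: str
    statistic_value: float
    n: int
    df: float
    bf10: float
    prior: str

    def __post_init__(self) -> None:
        if self.bf10 <= 0:
            raise ValueError("bf10 must be positive")

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


@dataclass(frozen=True)
class EffectSizeResult:
    """Standardized mean difference with a 95% interval."""

    d: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.d <= self.ci_high:
            raise ValueError("require ci_low <= d <= ci_high")


# ---------------------------------------------------------------------------
# classical statistics


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; requires n >= 3 and non-degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def one_sample_t(values, popmean: float = 0.0) -> tuple[float, int]:
    """One-sample t statistic against ``popmean``; returns (t, df)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 observations")
    res = stats.ttest_1samp(v, popmean)
    return float(res.statistic), v.size - 1


def paired_t(a, b) -> tuple[float, int]:
    """Paired t on the differences a - b; returns (t, df = n - 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), a.size - 1


def d_from_t(t: float, n: int) -> float:
    """One-sample Cohen's d from its t statistic: d = t / sqrt(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return t / math.sqrt(n)


def t_from_d(d: float, n: int) -> float:
    return d * math.sqrt(n)


def cohen_d_one_sample(values=None, *, d: float | None = None,
                       n: int | None = None,
                       method: str = "normal") -> EffectSizeResult:
    """One-sample Cohen's d (mean / SD) with a 95% CI.

    The default CI is the large-sample normal approximation with
    SE = sqrt(1/n + d^2/(2n)); ``method="noncentral"`` inverts the
    noncentral-t distribution instead.
    """
    if values is not None:
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError("need at least 2 observations")
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError("zero SD; effect size undefined")
        d, n = float(v.mean() / sd), v.size
    if d is None or n is None or n < 2:
        raise ValueError("provide values, or both d and n >= 2")

    if method == "normal":
        se = math.sqrt(1 / n + d ** 2 / (2 * n))
        lo, hi = d - 1.959963984540054 * se, d + 1.959963984540054 * se
    elif method == "noncentral":
        t = t_from_d(d, n)
        nc_lo, nc_hi = _noncentral_t_ci(t, n - 1)
        lo, hi = nc_lo / math.sqrt(n), nc_hi / math.sqrt(n)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return EffectSizeResult(d=d, ci_low=lo, ci_high=hi, n=n)


def _noncentral_t_ci(t: float, df: int, level: float = 0.95) -> tuple[float, float]:
    """Noncentrality-parameter interval by inverting the noncentral-t CDF."""
    from scipy.optimize import brentq
    alpha = (1 - level) / 2
    span = abs(t) + 10

    def lower(nc):
        return stats.nct.sf(t, df, nc) - alpha

    def upper(nc):
        return stats.nct.cdf(t, df, nc) - alpha

    lo = brentq(lower, t - span, t)
    hi = brentq(upper, t, t + span)
    return lo, hi


def bonferroni_alpha(m: int, alpha: float = 0.05) -> float:
    """Family-wise corrected per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# Bayes factors


def bf_ttest(t: float, n: int, cauchy_scale: float = DEFAULT_CAUCHY_SCALE,
             alternative: str = "two-sided", epsrel: float | None = None,
             ) -> BayesResult:
    """JZS Bayes factor for a one-sample (or paired) t test.

    BF10 = [integral of nct(t; df, delta*sqrt(n)) over the Cauchy prior
    on delta] / t(t; df).  ``alternative`` is "two-sided", "greater"
    (prior mass folded onto delta > 0) or "less".
    """
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    if n < 2:
        raise ValueError("n must be >= 2")
    df = n - 1
    sqrt_n = math.sqrt(n)
    opts = dict(_QUAD_OPTS)
    if epsrel is not None:
        opts["epsrel"] = epsrel

    def integrand(delta: float) -> float:
        return (stats.nct.pdf(t, df, delta * sqrt_n)
                * stats.cauchy.pdf(delta, scale=cauchy_scale))

    if alternative == "two-sided":
        num, _ = integrate.quad(integrand, -np.inf, np.inf, **opts)
    elif alternative in ("greater", "less"):
        sign = 1.0 if alternative == "greater" else -1.0
        num, _ = integrate.quad(lambda d: 2 * integrand(sign * d),
                                0, np.inf, **opts)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")

    bf10 = num / stats.t.pdf(t, df)
    return BayesResult(
        statistic_name="t", statistic_value=t, n=n, df=df, bf10=bf10,
        prior=f"Cauchy(0, {cauchy_scale:.4g}), {alternative}")


def _corr_log_likelihood(rho: float, r: float, n: int) -> float:
    """Log of the exact reduced likelihood of a sample correlation."""
    return ((n - 1) / 2 * math.log1p(-rho ** 2)
            + (3 - 2 * n) / 2 * math.log1p(-rho * r)
            + math.log(special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)))


def bf_correlation(r: float, n: int, kappa: float = 1.0,
                   alternative: str = "two-sided",
                   epsrel: float | None = None) -> BayesResult:
    """Default Bayes factor for a Pearson correlation.

    Stretched beta(1/kappa, 1/kappa) prior on rho; kappa = 1 is uniform
    on (-1, 1).  One-sided alternatives fold the prior mass onto the
    requested sign.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1; evidence degenerate otherwise")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    a = 1 / kappa
    log_l0 = _corr_log_likelihood(0.0, r, n)
    opts = dict(_QUAD_OPTS)
    if epsrel is not None:
        opts["epsrel"] = epsrel

    def integrand(rho: float) -> float:
        # likelihood ratio vs rho=0 keeps the integrand O(1)
        lr = math.exp(_corr_log_likelihood(rho, r, n) - log_l0)
        return lr * stats.beta.pdf((rho + 1) / 2, a, a) / 2

    if alternative == "two-sided":
        bf10, _ = integrate.quad(integrand, -1, 1, **opts)
    elif alternative in ("greater", "less"):
        lo, hi = (0, 1) if alternative == "greater" else (-1, 0)
        num, _ = integrate.quad(integrand, lo, hi, **opts)
        bf10 = 2 * num
    else:
        raise ValueError(f"unknown alternative {alternative!r}")

    return BayesResult(
        statistic_name="r", statistic_value=r, n=n, df=n - 2, bf10=bf10,
        prior=f"stretched beta(kappa={kappa:.4g}), {alternative}")


def sequential_bf(x, y, min_n: int = 5, kappa: float = 1.0) -> list[tuple[int, float]]:
    """Sequential correlation Bayes factors as observations accumulate.

    Applies ``bf_correlation`` to the first n pairs for
    n = min_n .. len(x); returns (n, bf01) tuples, tracing the
    evidential flow for H0 over H1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < min_n:
        raise ValueError(f"aligned vectors of length >= {min_n} required")
    out = []
    for n in range(min_n, x.size + 1):
        r = pearson_r(x[:n], y[:n])
        out.append((n, bf_correlation(r, n, kappa=kappa).bf01))
    return out


def correlation_matrix(data, labels: list[str] | None = None,
                       kappa: float = 1.0):
    """Pairwise correlations with default BFs, study-report style.

    ``data`` is an (n, k) array or DataFrame of k measures.  Returns a
    k x k DataFrame with Pearson r below the diagonal and the Bayes
    factor (BF10 when > 1, labelled; otherwise stored as BF10) above,
    plus a tidy long-format table of all pairs.
    """
    import pandas as pd
    df = pd.DataFrame(data, columns=labels) if not isinstance(data, pd.DataFrame) \
        else data
    cols = list(df.columns)
    n = len(df)
    mat = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=object)
    tidy = []
    for i, ci in enumerate(cols):
        mat.loc[ci, ci] = "-"
        for j in range(i + 1, len(cols)):
            cj = cols[j]
            r = pearson_r(df[ci], df[cj])
            res = bf_correlation(r, n, kappa=kappa)
            mat.loc[cj, ci] = round(r, 3)
            if res.bf10 >= 1:
                mat.loc[ci, cj] = f"{res.bf10:.3g} (BF10)"
            else:
                mat.loc[ci, cj] = f"{res.bf01:.3g} (BF01)"
            tidy.append({"x": ci, "y": cj, "n": n, "r": r,
                         "bf10": res.bf10, "bf01": res.bf01})
    return mat, pd.DataFrame(tidy)
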