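"""Behavioural statistics and VMI inference models.

Implements the test battery used on the synthetic study: Wilcoxon
signed-rank comparisons of paired compliance measures, one-sample t-tests
of timing criteria, the directional congruency-effect contrast, a Gaussian
linear mixed model of the Box-Cox distortion score with Satterthwaite
degrees of freedom, and Poisson GLMs of per-condition error counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as ss
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM


class ZeroVarianceError(ValueError):
    """All observations identical where variability is required."""


class LMMConvergenceError(RuntimeError):
    """Mixed model failed to converge; no silent fallback is attempted."""


@dataclass
class StatResult:
    """One test or model coefficient: statistic, p, effect size, df, CI, BF10."""

    statistic: float
    p: float
    effect_size: float | None = None
    df: float | None = None
    ci95: tuple[float, float] | None = None
    bf10: float | None = None
    name: str = ""
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "p": self.p,
            "effect_size": self.effect_size,
            "df": self.df,
            "ci95": list(self.ci95) if self.ci95 is not None else None,
            "bf10": self.bf10,
            **self.extra,
        }


@dataclass
class ModelSpec:
    """Fixed/random structure of a (generalised) linear mixed model.

    ``fixed`` lists two-level factor names; all two-way (and, if
    ``full_interactions``, higher) interactions among them are included.
    Factors are sum-coded (-1, 1) by sorted level order.
    """

    response: str
    fixed: Sequence[str]
    random: str = "subject"
    family: str = "gaussian"
    full_interactions: bool = True


def wilcoxon_signed_rank(a, b, alternative: str = "two-sided") -> StatResult:
    """Paired Wilcoxon signed-rank test with common-language effect size.

    Uses the exact null distribution for n <= 25 pairs (after dropping
    zero differences, Wilcoxon's original treatment) and the normal
    approximation above.  CLES is the paired P(a_i > b_i), ties counting
    one half.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) != len(b) or len(a) < 5:
        raise ValueError("need paired samples of equal length >= 5")
    diffs = a - b
    nz = diffs[diffs != 0]
    if len(nz) == 0:
        raise ZeroVarianceError("all paired differences are zero")
    method = "exact" if len(nz) <= 25 else "approx"
    res = ss.wilcoxon(a, b, zero_method="wilcox", alternative=alternative, method=method)
    cles = float(np.mean((a > b) + 0.5 * (a == b)))
    return StatResult(
        statistic=float(res.statistic), p=float(res.pvalue), effect_size=cles,
        name="wilcoxon", extra={"n_nonzero": int(len(nz))},
    )


def one_sample_t(
    values, mu0: float = 0.0, alternative: str = "two-sided", bayes: bool = True
) -> StatResult:
    """One-sample t-test with Cohen's d and (optional) JZS Bayes factor.

    The Bayes factor uses the default JZS Cauchy prior (scale 0.707).
    """
    values = np.asarray(values, float)
    if len(values) < 2:
        raise ValueError("need n >= 2")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("zero variance sample")
    n = len(values)
    res = ss.ttest_1samp(values, mu0, alternative=alternative)
    d = float((values.mean() - mu0) / sd)
    bf = None
    if bayes:
        bf = _jzs_bf10(float(res.statistic), n)
    se = sd / np.sqrt(n)
    tcrit = ss.t.ppf(0.975, n - 1)
    ci = (values.mean() - tcrit * se, values.mean() + tcrit * se)
    return StatResult(
        statistic=float(res.statistic), p=float(res.pvalue), effect_size=d,
        df=float(n - 1), ci95=(float(ci[0]), float(ci[1])), bf10=bf, name="one_sample_t",
    )


def paired_t(a, b, alternative: str = "two-sided", bayes: bool = False) -> StatResult:
    """Paired t-test (one-sample t on the differences)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal shape")
    res = one_sample_t(a - b, 0.0, alternative=alternative, bayes=bayes)
    res.name = "paired_t"
    return res


def _jzs_bf10(t: float, n: int, r: float = 0.707) -> float:
    """Default JZS Bayes factor for a one-sample t statistic.

    BF10 = integral over the Cauchy(0, r) effect-size prior of the
    likelihood ratio against the point null (Rouder's default test).
    """
    from scipy import integrate

    v = n - 1

    def fn(g):
        return (
            (1 + n * g * r**2) ** -0.5
            * (1 + t**2 / ((1 + n * g * r**2) * v)) ** (-(v + 1) / 2)
            * (2 * np.pi) ** -0.5
            * g ** (-1.5)
            * np.exp(-1 / (2 * g))
        )

    num, _ = integrate.quad(fn, 0, np.inf)
    den = (1 + t**2 / v) ** (-(v + 1) / 2)
    return float(num / den)


def congruency_effect(records: pd.DataFrame, value_col: str = "area_boxcox"):
    """Per-subject congruency effects and the directional context test.

    The congruency effect is mean(incongruent) - mean(congruent) distortion
    per subject and context.  The directional hypothesis (interference is
    larger when acting in parallel) is tested with a one-tailed paired t
    across subjects: Parallel effect > Joint effect.

    Returns ``(effects, result)`` where ``effects`` is a tidy DataFrame
    (subject, context, effect) and ``result`` a :class:`StatResult`.
    """
    needed = {"subject", "context", "congruency", value_col}
    if not needed.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(needed)}")
    cell = (
        records.groupby(["subject", "context", "congruency"])[value_col]
        .mean()
        .unstack("congruency")
    )
    if not {"congruent", "incongruent"}.issubset(cell.columns):
        raise ValueError("both congruency levels required")
    incomplete = cell.isna().any(axis=1)
    if incomplete.any():
        bad = sorted({s for s, _ in cell.index[incomplete]})
        warnings.warn(f"dropping subjects with missing cells: {bad}")
        cell = cell[~cell.index.get_level_values("subject").isin(bad)]
    eff = (cell["incongruent"] - cell["congruent"]).unstack("context")
    if {"Joint", "Parallel"} - set(eff.columns) or len(eff) < 2:
        raise ValueError("need both contexts and >= 2 complete subjects")
    result = paired_t(eff["Parallel"], eff["Joint"], alternative="greater", bayes=True)
    result.name = "congruency_effect_parallel_gt_joint"
    effects = eff.reset_index().melt(
        id_vars="subject", var_name="context", value_name="effect"
    )
    return effects, result


# ---------------------------------------------------------------------------
# Linear mixed model with Satterthwaite degrees of freedom
# ---------------------------------------------------------------------------


def _sum_coded_design(table: pd.DataFrame, spec: ModelSpec):
    """Build the sum-coded (-1, 1) fixed-effects design matrix."""
    cols = {"Intercept": np.ones(len(table))}
    codes = {}
    for f in spec.fixed:
        levels = sorted(table[f].unique())
        if len(levels) != 2:
            raise ValueError(f"factor {f!r} must have exactly 2 levels")
        codes[f] = np.where(table[f].to_numpy() == levels[0], -1.0, 1.0)
        cols[f] = codes[f]
    if spec.full_interactions and len(spec.fixed) > 1:
        import itertools

        for k in range(2, len(spec.fixed) + 1):
            for combo in itertools.combinations(spec.fixed, k):
                cols[":".join(combo)] = np.prod([codes[f] for f in combo], axis=0)
    X = np.column_stack(list(cols.values()))
    return X, list(cols.keys())


def _reml_loglik(theta, y_groups, X_groups):
    """Profile REML log-likelihood of a random-intercept Gaussian LMM.

    theta = (sigma2, tau2): residual and intercept variances.  Uses the
    Woodbury identity; constant terms are dropped.
    """
    sigma2, tau2 = theta
    if sigma2 <= 0 or tau2 < 0:
        return -np.inf
    XtVX = 0.0
    XtVy = 0.0
    logdet = 0.0
    for y, X in zip(y_groups, X_groups):
        n = len(y)
        w = tau2 / (sigma2 + n * tau2)
        Xs = X.sum(axis=0)
        ys = y.sum()
        XtVX += (X.T @ X - w * np.outer(Xs, Xs)) / sigma2
        XtVy += (X.T @ y - w * Xs * ys) / sigma2
        logdet += (n - 1) * np.log(sigma2) + np.log(sigma2 + n * tau2)
    beta = np.linalg.solve(XtVX, XtVy)
    quad = 0.0
    for y, X in zip(y_groups, X_groups):
        r = y - X @ beta
        n = len(y)
        w = tau2 / (sigma2 + n * tau2)
        rs = r.sum()
        quad += (r @ r - w * rs * rs) / sigma2
    sign, ld2 = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf
    return -0.5 * (logdet + ld2 + quad)


def _beta_cov(theta, X_groups):
    """Covariance of the GLS fixed effects, C(theta) = (X' V^-1 X)^-1."""
    sigma2, tau2 = theta
    XtVX = 0.0
    for X in X_groups:
        n = len(X)
        w = tau2 / (sigma2 + n * tau2)
        Xs = X.sum(axis=0)
        XtVX += (X.T @ X - w * np.outer(Xs, Xs)) / sigma2
    return np.linalg.inv(XtVX)


def fit_lmm(table: pd.DataFrame, spec: ModelSpec) -> dict[str, StatResult]:
    """REML random-intercept LMM with Satterthwaite-corrected p-values.

    Fits ``response ~ fixed factors (sum-coded) + (1 | random)`` by REML
    (statsmodels MixedLM) and computes per-coefficient Satterthwaite df
    from a finite-difference Hessian of the REML profile log-likelihood
    with respect to the two variance components.

    Raises :class:`LMMConvergenceError` on non-convergence.
    """
    if spec.family != "gaussian":
        raise ValueError("fit_lmm supports the gaussian family only")
    X, names = _sum_coded_design(table, spec)
    y_raw = table[spec.response].to_numpy(dtype=float)
    groups = table[spec.random].to_numpy()

    # standardise the response for optimizer conditioning; estimates are
    # mapped back below (t, df and p are invariant under linear rescaling)
    y_center = float(y_raw.mean())
    y_scale = float(y_raw.std())
    if y_scale == 0:
        raise ZeroVarianceError("response has zero variance")
    y = (y_raw - y_center) / y_scale

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=groups)
        fit = model.fit(reml=True)
        if not fit.converged:  # one retry with a derivative-free optimizer
            fit = model.fit(reml=True, method="powell")
    if not fit.converged:
        raise LMMConvergenceError("MixedLM did not converge")

    sigma2 = float(fit.scale)
    tau2 = float(np.asarray(fit.cov_re).ravel()[0])
    theta = np.array([sigma2, max(tau2, 0.0)])

    uniq = pd.unique(groups)
    y_groups = [y[groups == g] for g in uniq]
    X_groups = [X[groups == g] for g in uniq]

    C = _beta_cov(theta, X_groups)
    # Hessian of the REML loglik at theta (central differences; forward at
    # the tau2 >= 0 boundary)
    steps = np.maximum(np.abs(theta) * 1e-4, 1e-8)
    H = np.zeros((2, 2))
    f0 = _reml_loglik(theta, y_groups, X_groups)

    def f(th):
        return _reml_loglik(th, y_groups, X_groups)

    for i in range(2):
        for j in range(i, 2):
            hi, hj = steps[i], steps[j]
            ei = np.eye(2)[i] * hi
            ej = np.eye(2)[j] * hj
            lo_ok = (theta - ei - ej)[1] >= 0 and (theta - ei)[1] >= 0 and (theta - ej)[1] >= 0
            if lo_ok:
                if i == j:
                    H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / hi**2
                else:
                    H[i, j] = H[j, i] = (
                        f(theta + ei + ej) - f(theta + ei - ej)
                        - f(theta - ei + ej) + f(theta - ei - ej)
                    ) / (4 * hi * hj)
            else:  # forward differences at the boundary
                if i == j:
                    H[i, i] = (f(theta + 2 * ei) - 2 * f(theta + ei) + f0) / hi**2
                else:
                    H[i, j] = H[j, i] = (
                        f(theta + ei + ej) - f(theta + ei) - f(theta + ej) + f0
                    ) / (hi * hj)
    try:
        A = np.linalg.inv(-H)
    except np.linalg.LinAlgError as e:
        raise LMMConvergenceError(f"singular variance-component Hessian: {e}") from e

    results: dict[str, StatResult] = {}
    beta = np.asarray(fit.fe_params)
    for j, name in enumerate(names):
        # gradient of C_jj wrt theta
        g = np.zeros(2)
        for i in range(2):
            hi = steps[i]
            ei = np.eye(2)[i] * hi
            if (theta - ei)[1] >= 0:
                g[i] = (_beta_cov(theta + ei, X_groups)[j, j]
                        - _beta_cov(theta - ei, X_groups)[j, j]) / (2 * hi)
            else:
                g[i] = (_beta_cov(theta + ei, X_groups)[j, j]
                        - _beta_cov(theta, X_groups)[j, j]) / hi
        var_j = C[j, j]
        denom = float(g @ A @ g)
        df = 2 * var_j**2 / denom if denom > 0 else np.inf
        se = np.sqrt(var_j)
        # back to the response's original units (the intercept absorbs the
        # centering shift, so its t is computed after the back-transform)
        shift = y_center if name == "Intercept" else 0.0
        b = beta[j] * y_scale + shift
        se_o = se * y_scale
        tval = b / se_o
        p = 2 * ss.t.sf(abs(tval), df)
        tcrit = ss.t.ppf(0.975, df)
        results[name] = StatResult(
            statistic=float(tval), p=float(p), effect_size=float(b),
            df=float(df), ci95=(float(b - tcrit * se_o), float(b + tcrit * se_o)),
            name=name, extra={"beta": float(b), "se": float(se_o)},
        )
    results["_variance"] = StatResult(
        statistic=np.nan, p=np.nan, name="_variance",
        extra={"sigma2": sigma2 * y_scale**2, "tau2": tau2 * y_scale**2},
    )
    return results


def fit_count_glm(table: pd.DataFrame, spec: ModelSpec) -> dict[str, StatResult]:
    """Poisson GLM of per-subject, per-cell counts with Wald p-values.

    Flags separation/instability (diverging coefficients or standard
    errors) in the ``unstable`` field of each result.
    """
    if spec.family != "poisson":
        raise ValueError("fit_count_glm requires the poisson family")
    counts = table[spec.response].to_numpy(dtype=float)
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise ValueError("counts must be nonnegative integers")
    if counts.sum() == 0:
        raise ZeroVarianceError("all counts are zero")
    X, names = _sum_coded_design(table, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
    unstable = bool(np.any(np.abs(fit.params) > 10) or np.any(fit.bse > 50))
    out = {}
    for j, name in enumerate(names):
        out[name] = StatResult(
            statistic=float(fit.tvalues[j]), p=float(fit.pvalues[j]),
            effect_size=float(fit.params[j]), name=name,
            ci95=tuple(np.asarray(fit.conf_int())[j]),
            extra={"beta": float(fit.params[j]), "se": float(fit.bse[j]),
                   "unstable": unstable},
        )
    return out
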