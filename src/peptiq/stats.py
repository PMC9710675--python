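"""Per-feature differential abundance statistics.

Three tests on log2 intensities: Welch's unequal-variance t-test, one-way
fixed-effects ANOVA, and an empirical-Bayes moderated t-test in which the
per-feature variance is shrunk toward a scaled inverse chi-square prior
(d0, s0^2) fitted across features.  The prior fit is a method of moments
on the log variances: with per-feature residual degrees of freedom d_g,
the bias-corrected quantity

    e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2)

has E[e_g] = log s0^2 - digamma(d0/2) + log(d0/2) and
Var[e_g] = trigamma(d_g/2) + trigamma(d0/2), so d0 solves trigamma(d0/2) = Var(e) - mean trigamma(d_g/2) by monotone
root finding, and s0^2 follows from the mean equation.  When the moment
spread of log variances falls below its theoretical minimum the prior is
degenerate: d0 = infinity and s0^2 is the mean of the sample variances.  The moderated statistic uses the posterior variance
(d0 s0^2 + d s^2)/(d0 + d) and gains d0 extra degrees of freedom.

Missing values are never imputed here; callers opt into imputation
upstream.  Features that fail the replicate minimum are reported with
missing statistics and a reason, not dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps
from statsmodels.stats.multitest import multipletests

from .io import sample_conditions, to_matrix


@dataclass
class TestResult:
    diff: float = math.nan       # log2 fold change (group1 - group2)
    se: float = math.nan
    statistic: float = math.nan
    df: float = math.nan
    p_value: float = math.nan
    n1: int = 0
    n2: int = 0
    reason: str | None = None


@dataclass
class EBayesPrior:
    """Scaled inverse chi-square prior on feature variances."""
    d0: float        # prior degrees of freedom, may be math.inf
    s0_sq: float     # prior variance, > 0

    def __post_init__(self) -> None:
        if not self.d0 >= 0:
            raise ValueError("d0 must be >= 0")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be > 0")


def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[~np.isnan(v)]


def welch_t(group1, group2) -> TestResult:
    """Welch's unequal-variance t-test on two vectors of log2 intensities."""
    g1, g2 = _clean(group1), _clean(group2)
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        return TestResult(n1=n1, n2=n2, reason="insufficient replicates")
    diff = float(g1.mean() - g2.mean())
    v1, v2 = float(g1.var(ddof=1)), float(g2.var(ddof=1))
    se_sq = v1 / n1 + v2 / n2
    if se_sq == 0.0:
        if diff == 0.0:
            return TestResult(diff=0.0, se=0.0, statistic=0.0, df=float(n1 + n2 - 2),
                              p_value=1.0, n1=n1, n2=n2)
        return TestResult(diff=diff, se=0.0, statistic=math.copysign(math.inf, diff),
                          df=float(n1 + n2 - 2), p_value=0.0, n1=n1, n2=n2)
    df = se_sq ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    t = diff / math.sqrt(se_sq)
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(diff=diff, se=math.sqrt(se_sq), statistic=t, df=df,
                      p_value=min(p, 1.0), n1=n1, n2=n2)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (trigamma is strictly decreasing)."""
    if y <= 0:
        return math.inf
    lo, hi = 1e-8, 1e8
    tri = lambda x: float(special.polygamma(1, x))
    if y >= tri(lo):
        return lo
    if y <= tri(hi):
        return hi
    return float(optimize.brentq(lambda x: tri(x) - y, lo, hi, xtol=1e-12, rtol=1e-12))


def fit_ebayes_prior(variances, dfs) -> EBayesPrior:
    """Fit (d0, s0^2) to observed sample variances by moments on the log scale.

    Parameters
    ----------
    variances:
        Per-feature residual variances (finite, > 0 required; others dropped).
    dfs:
        Residual degrees of freedom, scalar or per-feature.

    Raises
    ------
    ValueError
        With fewer than 10 usable variances the fit refuses — the prior
        moments would be dominated by noise.
    """
    var = np.asarray(variances, dtype=float)
    df = np.broadcast_to(np.asarray(dfs, dtype=float), var.shape).copy()
    ok = np.isfinite(var) & (var > 0) & np.isfinite(df) & (df > 0)
    var, df = var[ok], df[ok]
    if len(var) < 10:
        raise ValueError(f"need >= 10 positive finite variances to fit the prior, got {len(var)}")

    z = np.log(var)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        if math.isfinite(d0):
            s0 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
            return EBayesPrior(d0=d0, s0_sq=s0)
    # spread of log variances at or below its sampling minimum: degenerate
    # point prior; its value is the mean of the observed variances
    return EBayesPrior(d0=math.inf, s0_sq=float(np.mean(var)))


def moderated_t(group1, group2, prior: EBayesPrior) -> TestResult:
    """Two-sample moderated t-test with variance shrunk toward the prior."""
    g1, g2 = _clean(group1), _clean(group2)
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2 or n1 + n2 < 3:
        return TestResult(n1=n1, n2=n2, reason="insufficient replicates")
    diff = float(g1.mean() - g2.mean())
    d = n1 + n2 - 2
    pooled = ((n1 - 1) * float(g1.var(ddof=1)) + (n2 - 1) * float(g2.var(ddof=1))) / d
    if math.isinf(prior.d0):
        s_tilde_sq = prior.s0_sq
        df_total = math.inf
    else:
        s_tilde_sq = (prior.d0 * prior.s0_sq + d * pooled) / (prior.d0 + d)
        df_total = prior.d0 + d
    if s_tilde_sq == 0.0:
        if diff == 0.0:
            return TestResult(diff=0.0, se=0.0, statistic=0.0, df=df_total, p_value=1.0, n1=n1, n2=n2)
        return TestResult(diff=diff, se=0.0, statistic=math.copysign(math.inf, diff),
                          df=df_total, p_value=0.0, n1=n1, n2=n2)
    se = math.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    t = diff / se
    if math.isinf(df_total):
        p = 2.0 * float(sps.norm.sf(abs(t)))
    else:
        p = 2.0 * float(sps.t.sf(abs(t), df_total))
    return TestResult(diff=diff, se=se, statistic=t, df=df_total, p_value=min(p, 1.0), n1=n1, n2=n2)


def pooled_variance(group1, group2) -> tuple[float, float]:
    """(pooled residual variance, residual df) of a two-group comparison."""
    g1, g2 = _clean(group1), _clean(group2)
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        return math.nan, math.nan
    d = n1 + n2 - 2
    pooled = ((n1 - 1) * float(g1.var(ddof=1)) + (n2 - 1) * float(g2.var(ddof=1))) / d
    return pooled, float(d)


@dataclass
class AnovaResult:
    statistic: float = math.nan
    df1: float = math.nan
    df2: float = math.nan
    p_value: float = math.nan
    reason: str | None = None


def anova_f(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA F = MSB/MSW across >= 2 groups."""
    cleaned = [_clean(g) for g in groups]
    if len(cleaned) < 2:
        return AnovaResult(reason="need at least 2 groups")
    if any(len(g) < 2 for g in cleaned):
        return AnovaResult(reason="insufficient replicates")
    k = len(cleaned)
    n_total = sum(len(g) for g in cleaned)
    grand = float(np.concatenate(cleaned).mean())
    ssb = sum(len(g) * (float(g.mean()) - grand) ** 2 for g in cleaned)
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in cleaned)
    df1, df2 = float(k - 1), float(n_total - k)
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(statistic=0.0, df1=df1, df2=df2, p_value=1.0)
        return AnovaResult(statistic=math.inf, df1=df1, df2=df2, p_value=0.0)
    f = (ssb / df1) / (ssw / df2)
    p = float(sps.f.sf(f, df1, df2))
    return AnovaResult(statistic=f, df1=df1, df2=df2, p_value=p)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through unchanged.

    Missing p-values are excluded from the number of tests m.
    """
    p = np.asarray(p_values, dtype=float)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def differential_abundance(
    table: pd.DataFrame,
    level: str = "protein",
    method: str = "moderated",
    ref_condition: str | None = None,
) -> pd.DataFrame:
    """Run a per-feature differential test for every condition vs the reference.

    method: "welch", "moderated" (empirical-Bayes prior fitted per
    comparison over all features) or "anova" (one omnibus test per
    feature across all conditions).  BH adjustment is applied within each
    comparison.
    """
    matrix = to_matrix(table, level)
    cond_of = sample_conditions(table)
    conditions = sorted(cond_of.unique())
    if ref_condition is None:
        ref_condition = conditions[0]
    if ref_condition not in conditions:
        raise ValueError(f"reference condition {ref_condition!r} not present")

    samples_of = {c: [s for s in matrix.columns if cond_of.get(s) == c] for c in conditions}

    rows: list[dict] = []
    if method == "anova":
        for feat, row in matrix.iterrows():
            groups = [row[samples_of[c]].to_numpy() for c in conditions]
            res = anova_f(groups)
            rows.append({"feature": feat, "comparison": "omnibus", "diff": math.nan,
                         "se": math.nan, "statistic": res.statistic, "df": res.df1,
                         "df2": res.df2, "p_value": res.p_value,
                         "n1": sum(len(g) for g in groups), "n2": 0,
                         "method": "anova", "reason": res.reason})
        out = pd.DataFrame(rows)
        out["adj_p_value"] = adjust_bh(out["p_value"])
        return out

    if method not in ("welch", "moderated"):
        raise ValueError(f"unknown method {method!r}")

    for cond in conditions:
        if cond == ref_condition:
            continue
        comparison = f"{cond}_vs_{ref_condition}"
        g1_cols, g2_cols = samples_of[cond], samples_of[ref_condition]
        g1 = matrix[g1_cols].to_numpy() if g1_cols else np.empty((len(matrix), 0))
        g2 = matrix[g2_cols].to_numpy() if g2_cols else np.empty((len(matrix), 0))

        prior = None
        if method == "moderated":
            pooled = [pooled_variance(g1[i], g2[i]) for i in range(len(matrix))]
            variances = np.array([v for v, _ in pooled])
            dfs = np.array([d for _, d in pooled])
            prior = fit_ebayes_prior(variances, dfs)

        comp_rows = []
        for i, feat in enumerate(matrix.index):
            if method == "welch":
                res = welch_t(g1[i], g2[i])
            else:
                res = moderated_t(g1[i], g2[i], prior)
            comp_rows.append({"feature": feat, "comparison": comparison, "diff": res.diff,
                              "se": res.se, "statistic": res.statistic, "df": res.df,
                              "df2": math.nan, "p_value": res.p_value,
                              "n1": res.n1, "n2": res.n2, "method": method,
                              "reason": res.reason})
        comp_df = pd.DataFrame(comp_rows)
        comp_df["adj_p_value"] = adjust_bh(comp_df["p_value"])
        rows.extend(comp_df.to_dict("records"))
    return pd.DataFrame(rows)
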