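"""Four-parameter log-logistic dose-response fitting and hit calling.

The model is the LL.4 parameterisation

    f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))

with lower asymptote c, upper asymptote d (both log2 intensities), slope
b (positive b: response decreases with dose) and EC50 e > 0 in
concentration units.  Dose zero is handled through the limit of the
curve: f(0) = d for b > 0 and c for b < 0.

Fitting is deterministic nonlinear least squares with a small multistart:
c0/d0 come from the min/max of per-dose means, e0 from the dose whose
mean lies closest to the half-response level, and both slope signs
b0 in {-1, +1} are tried; the start with the smallest residual sum of
squares wins.  Model relevance is assessed by the F-test of the
4-parameter fit against the intercept-only (flat) model on the raw
observations with (3, n - 4) degrees of freedom; hits are converged
fits that pass a BH threshold on that p-value and a minimum R^2.

R^2 is the fraction of the variance of the per-dose mean responses
explained by the curve.  With replicated designs this makes R^2 a
measure of curve shape rather than of replicate noise: a strong
responder measured with noisy replicates still scores high, while the
F-test retains the full residual degrees of freedom of the raw points.
For one observation per dose it coincides with the ordinary
1 - SSres/SStot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .stats import adjust_bh


@dataclass
class DRFit:
    feature: str
    hill: float = math.nan       # slope b
    lower: float = math.nan      # asymptote c (log2)
    upper: float = math.nan      # asymptote d (log2)
    ec50: float = math.nan       # e, concentration units
    r_squared: float = math.nan
    f_statistic: float = math.nan
    p_value: float = math.nan
    adj_p_value: float = math.nan
    n_points: int = 0
    converged: bool = False
    hit: bool = False
    flat: bool = False           # degenerate constant-response input
    reason: str | None = None


def ll4(x, hill: float, lower: float, upper: float, ec50: float):
    """Evaluate the LL.4 curve, using the asymptote limit at x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty(x.shape)
    pos = x > 0
    with np.errstate(over="ignore"):
        out[pos] = lower + (upper - lower) / (1.0 + np.exp(hill * (np.log(x[pos]) - math.log(ec50))))
    out[~pos] = upper if hill > 0 else lower
    return out


def _residuals(theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    hill, lower, upper, log_e = theta
    return ll4(x, hill, lower, upper, math.exp(log_e)) - y


def _jacobian(theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Analytic Jacobian in (b, c, d, log e); limits used at x = 0."""
    hill, lower, upper, log_e = theta
    jac = np.zeros((len(x), 4))
    pos = x > 0
    lx = np.log(x[pos])
    with np.errstate(over="ignore"):
        g = 1.0 / (1.0 + np.exp(hill * (lx - log_e)))  # logistic weight of d
    gg = g * (1.0 - g)
    jac[pos, 0] = -(upper - lower) * gg * (lx - log_e)
    jac[pos, 1] = 1.0 - g
    jac[pos, 2] = g
    jac[pos, 3] = (upper - lower) * gg * hill
    # x = 0: f -> d (b > 0) or c (b < 0); all other partials vanish
    if hill > 0:
        jac[~pos, 2] = 1.0
    else:
        jac[~pos, 1] = 1.0
    return jac


def fit_4pl(doses, responses, feature: str = "") -> DRFit:
    """Least-squares LL.4 fit of responses (log2 intensities) over doses.

    Requires at least 5 distinct doses.  Constant responses are returned
    as a converged flat fit with p = 1 and the slope flagged
    unidentifiable (``flat=True``).
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if (x < 0).any():
        raise ValueError("doses must be non-negative")
    n = len(y)
    distinct = np.unique(x)
    if len(distinct) < 5:
        raise ValueError(f"need >= 5 distinct doses, got {len(distinct)}")

    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        med_pos = float(np.median(distinct[distinct > 0]))
        return DRFit(feature=feature, hill=0.0, lower=float(y[0]), upper=float(y[0]),
                     ec50=med_pos, r_squared=0.0, f_statistic=0.0, p_value=1.0,
                     n_points=n, converged=True, flat=True,
                     reason="constant responses; slope unidentifiable")

    # dose-binned means drive the starting values
    means = {d: float(y[x == d].mean()) for d in distinct}
    c0 = min(means.values())
    d0 = max(means.values())
    mid = 0.5 * (c0 + d0)
    pos_doses = distinct[distinct > 0]
    e0 = float(pos_doses[np.argmin([abs(means[d] - mid) for d in pos_doses])])

    # Bounds keep the fit off the degenerate ridge where a censored plateau
    # lets an asymptote drift to +-inf at constant residual: asymptotes stay
    # within 3 response-spans of the data, ln(ec50) within 2 decades of the
    # tested dose range.
    span = max(float(y.max() - y.min()), 1.0)
    lo = np.array([-20.0, y.min() - 3 * span, y.min() - 3 * span,
                   math.log(pos_doses.min()) - 2 * math.log(10)])
    hi = np.array([20.0, y.max() + 3 * span, y.max() + 3 * span,
                   math.log(pos_doses.max()) + 2 * math.log(10)])

    best = None
    for b0 in (-1.0, 1.0):
        theta0 = np.clip(np.array([b0, c0, d0, math.log(e0)]), lo + 1e-9, hi - 1e-9)
        try:
            sol = optimize.least_squares(
                _residuals, theta0, jac=_jacobian, args=(x, y), method="trf",
                bounds=(lo, hi), ftol=1e-10, xtol=1e-10, gtol=1e-10, max_nfev=500,
            )
        except Exception:
            continue
        ss_res = float(2.0 * sol.cost)
        if best is None or ss_res < best[0]:
            best = (ss_res, sol)
    if best is None:
        return DRFit(feature=feature, n_points=n, converged=False, reason="no start converged")

    ss_res, sol = best
    hill, lower, upper, log_e = sol.x
    if hill < 0:  # mirror symmetry (b, c, d) -> (-b, d, c); report the b > 0 form
        hill, lower, upper = -hill, upper, lower
    # R^2 against the per-dose mean response (curve shape, not replicate noise)
    dose_means = np.array([means[d] for d in distinct])
    fitted_means = ll4(distinct, hill, lower, upper, math.exp(log_e))
    sst_means = float(((dose_means - dose_means.mean()) ** 2).sum())
    if sst_means > 0:
        r2 = max(0.0, 1.0 - float(((dose_means - fitted_means) ** 2).sum()) / sst_means)
    else:
        r2 = 0.0
    df2 = n - 4
    if df2 <= 0:
        return DRFit(feature=feature, n_points=n, converged=False, reason="too few points for F-test")
    if ss_res <= 0.0:
        f_stat, p = math.inf, 0.0
    else:
        f_stat = ((ss_tot - ss_res) / 3.0) / (ss_res / df2)
        f_stat = max(f_stat, 0.0)
        p = float(sps.f.sf(f_stat, 3, df2))
    return DRFit(feature=feature, hill=float(hill), lower=float(lower), upper=float(upper),
                 ec50=float(math.exp(log_e)), r_squared=min(r2, 1.0),
                 f_statistic=f_stat, p_value=p, n_points=n,
                 converged=bool(sol.success))


def rank_hits(fits: list[DRFit], alpha: float = 0.05, min_r2: float = 0.8) -> list[DRFit]:
    """BH-adjust model-vs-flat p-values and flag/rank hits.

    hit = converged and adj_p < alpha and r_squared >= min_r2; ranked by
    ascending adj_p, ties by descending r_squared, then feature ID.
    """
    p = np.array([f.p_value for f in fits], dtype=float)
    adj = adjust_bh(p)
    for f, a in zip(fits, adj):
        f.adj_p_value = float(a) if not np.isnan(a) else math.nan
        f.hit = bool(f.converged and not np.isnan(a) and a < alpha and f.r_squared >= min_r2)

    def key(f: DRFit):
        a = f.adj_p_value if not math.isnan(f.adj_p_value) else math.inf
        r = f.r_squared if not math.isnan(f.r_squared) else -math.inf
        return (a, -r, f.feature)

    return sorted(fits, key=key)


def fit_dose_response(
    table: pd.DataFrame,
    level: str = "protein",
    alpha: float = 0.05,
    min_r2: float = 0.8,
) -> pd.DataFrame:
    """Fit LL.4 per feature of a long table with a populated dose column.

    All replicate observations at each dose enter the fit as individual
    points; the per-dose means only drive the reported R^2 (see
    :func:`fit_4pl`).  Returns one row per feature with parameters, fit
    quality and hit flag, ranked as in :func:`rank_hits`.
    """
    if table["dose"].isna().all():
        raise ValueError("table has no dose values")
    obs = table.dropna(subset=[level, "intensity_log2", "dose"])
    fits = []
    for feat, grp in obs.groupby(level, sort=True):
        x, y = grp["dose"].to_numpy(), grp["intensity_log2"].to_numpy()
        try:
            fits.append(fit_4pl(x, y, feature=str(feat)))
        except ValueError as exc:
            fits.append(DRFit(feature=str(feat), n_points=len(grp), converged=False,
                              reason=str(exc)))
    fits = rank_hits(fits, alpha=alpha, min_r2=min_r2)
    return pd.DataFrame([{
        "feature": f.feature, "hill": f.hill, "lower": f.lower, "upper": f.upper,
        "ec50": f.ec50, "r_squared": f.r_squared, "f_statistic": f.f_statistic,
        "p_value": f.p_value, "adj_p_value": f.adj_p_value, "n_points": f.n_points,
        "converged": f.converged, "hit": f.hit, "flat": f.flat, "reason": f.reason,
    } for f in fits])
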