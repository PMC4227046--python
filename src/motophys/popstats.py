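"""Group-level statistics: summary grids, nonparametric two-sample tests,
zero-intercept regression and slope comparison.

The regression of rheobase I (nA) on input conductance G (nS) is constrained
through the origin to satisfy Ohm's law I = G * U, so the slope U carries the
dimension of a voltage (mV): U = 1000 * sum(G*I) / sum(G^2). Two group slopes
are compared with a t test on the slope difference (after Shapiro-Wilk
normality checks on each group's residuals) and, independently, with a Chow
F test on the pooled versus separate zero-intercept fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


def summarize(table: pd.DataFrame, group_by: list[str] | str,
              properties: list[str] | None = None) -> pd.DataFrame:
    """Per-group mean, SD, range and N - the population-table layout.

    Missing values are excluded per property; N reflects the non-missing
    count. Raises on an empty table.
    """
    if len(table) == 0:
        raise ValidationError("cannot summarize an empty table")
    if properties is None:
        properties = [c for c in table.columns
                      if pd.api.types.is_numeric_dtype(table[c])
                      and c not in (group_by if isinstance(group_by, list) else [group_by])]
    g = table.groupby(group_by, observed=True)[properties]
    out = g.agg(["mean", "std", "min", "max", "count"])
    out = out.rename(columns={"std": "sd", "count": "n"}, level=1)
    # a single observation has a degenerate range and, by convention, SD 0
    sd_cols = [c for c in out.columns if c[1] == "sd"]
    n_cols = {c[0]: (c[0], "n") for c in out.columns if c[1] == "n"}
    for col in sd_cols:
        single = out[n_cols[col[0]]] == 1
        out.loc[single, col] = 0.0
    return out


def mann_whitney(a, b) -> float:
    """Two-tailed Mann-Whitney U p-value.

    Exact enumeration for small samples (combined n <= 20, no ties), normal
    approximation with continuity and tie correction otherwise.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("Mann-Whitney needs non-empty samples")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 20 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def fisher_exact(k11: int, k12: int, k21: int, k22: int) -> float:
    """Two-tailed Fisher exact p (probability-mass method) on a 2x2 table."""
    for k in (k11, k12, k21, k22):
        if k < 0:
            raise ValidationError("counts must be nonnegative")
    t = np.array([[k11, k12], [k21, k22]])
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("degenerate contingency table (all-zero margin)")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def ks_test(a, b) -> float:
    """Two-sample two-sided Kolmogorov-Smirnov p-value."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("KS test needs non-empty samples")
    return float(stats.ks_2samp(a, b, alternative="two-sided").pvalue)


@dataclass
class RegressionResult:
    """Zero-intercept fit of rheobase on conductance."""

    slope_mV: float          # U, the voltage-dimension slope
    n: int
    residuals: np.ndarray    # nA
    ssr: float               # nA^2
    se_mV: float             # standard error of U


@dataclass
class SlopeComparison:
    slope_a_mV: float
    slope_b_mV: float
    t_stat: float
    t_pvalue: float
    chow_F: float
    chow_pvalue: float
    shapiro_p_a: float
    shapiro_p_b: float


def zero_intercept_fit(G, I) -> RegressionResult:
    """Least-squares line through the origin: I = (U/1000) * G.

    G in nS, I in nA; the returned slope U is in mV. The slope standard
    error uses SSR/(n-1) as the residual variance (the zero-intercept model
    spends one degree of freedom).
    """
    G, I = np.asarray(G, float), np.asarray(I, float)
    if G.size != I.size:
        raise ValidationError("G and I must have equal length")
    if G.size < 1 or not np.any(G != 0):
        raise ValidationError("degenerate predictor")
    sgg = float(np.sum(G * G))
    u_volts = float(np.sum(G * I)) / sgg
    resid = I - u_volts * G
    ssr = float(np.sum(resid**2))
    n = G.size
    se_volts = np.sqrt(ssr / max(n - 1, 1) / sgg)
    return RegressionResult(slope_mV=1000.0 * u_volts, n=n, residuals=resid,
                            ssr=ssr, se_mV=1000.0 * se_volts)


def compare_slopes(Ga, Ia, Gb, Ib) -> SlopeComparison:
    """Compare two zero-intercept slopes (t test + Chow F test).

    The t statistic divides the slope difference by the root sum of squared
    per-group standard errors (df = n_a + n_b - 2). The Chow test contrasts
    the pooled single-slope fit against the two separate fits:
    F = [(SSR_pooled - SSR_a - SSR_b)/k] / [(SSR_a + SSR_b)/(n_a + n_b - 2k)]
    with k = 1 parameter. Shapiro-Wilk p-values for each group's residuals
    accompany the result.
    """
    fa, fb = zero_intercept_fit(Ga, Ia), zero_intercept_fit(Gb, Ib)
    if fa.n < 3 or fb.n < 3:
        raise ValidationError("need at least 3 points per group")
    pooled = zero_intercept_fit(np.concatenate([np.asarray(Ga, float), np.asarray(Gb, float)]),
                                np.concatenate([np.asarray(Ia, float), np.asarray(Ib, float)]))
    df = fa.n + fb.n - 2
    se = np.hypot(fa.se_mV, fb.se_mV)
    t = (fa.slope_mV - fb.slope_mV) / se if se > 0 else 0.0
    t_p = 2.0 * stats.t.sf(abs(t), df)
    ssr_sep = fa.ssr + fb.ssr
    k = 1
    if ssr_sep <= 0:
        chow_f, chow_p = (0.0, 1.0) if pooled.ssr <= 1e-300 else (np.inf, 0.0)
    else:
        chow_f = max(0.0, (pooled.ssr - ssr_sep) / k / (ssr_sep / (fa.n + fb.n - 2 * k)))
        chow_p = float(stats.f.sf(chow_f, k, fa.n + fb.n - 2 * k))
    return SlopeComparison(
        slope_a_mV=fa.slope_mV, slope_b_mV=fb.slope_mV,
        t_stat=float(t), t_pvalue=float(t_p),
        chow_F=float(chow_f), chow_pvalue=float(chow_p),
        shapiro_p_a=float(stats.shapiro(fa.residuals).pvalue),
        shapiro_p_b=float(stats.shapiro(fb.residuals).pvalue),
    )
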