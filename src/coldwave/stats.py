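"""Inference chain for the interval comparisons.

For every recording site and feature, subjects contribute one value per
analysis interval (BL, ST1, ST2).  The chain is: one-way repeated-measures
ANOVA as a gate at alpha = 0.05; if it fires, paired t-tests for the three
interval contrasts with step-down Holm-Bonferroni adjustment; Hedges' g with
a 95% confidence interval is reported for every contrast regardless of
significance.  Reference parameters (SBP, DBP, HR and derived pulse
pressure) are reduced to one value per interval by the median over beats.

Hedges' g follows the independent-groups pooled-standard-deviation form

    g = J(df) * (mean(x) - mean(y)) / s_pooled,
    s_pooled^2 = ((n_x - 1) s_x^2 + (n_y - 1) s_y^2) / (n_x + n_y - 2),
    J(df) = Gamma(df / 2) / (sqrt(df / 2) * Gamma((df - 1) / 2)),

with df = n_x + n_y - 2, even for the paired interval contrasts; the
standardizer is the between-subject spread, not the spread of paired
differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.special import gammaln

__all__ = [
    "interval_reference",
    "rm_anova",
    "paired_t",
    "holm_bonferroni",
    "hedges_g",
    "bias_correction",
    "count_outliers",
    "normalize_for_plot",
    "analyze_study",
    "AnovaResult",
    "EffectResult",
]

ALPHA = 0.05
CONTRASTS = (("BL", "ST1"), ("BL", "ST2"), ("ST1", "ST2"))
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


# ---------------------------------------------------------------------------
# Reference aggregation
# ---------------------------------------------------------------------------

def interval_reference(series: pd.DataFrame, start: float,
                       duration: float = 10.0) -> dict[str, float]:
    """Per-interval scalars from a beat-wise reference series.

    ``series`` has a time column ``t`` and beat-wise SBP, DBP, HR columns.
    Pulse pressure is computed beat-wise as SBP - DBP *before* taking the
    median, then each parameter is reduced to the median of its in-window
    beats.  Returns NaN for parameters with no beat in the window.
    """
    win = series[(series["t"] >= start) & (series["t"] < start + duration)]
    out: dict[str, float] = {}
    for p in ("SBP", "DBP", "HR"):
        out[p] = float(win[p].median()) if len(win) else float("nan")
    if len(win):
        out["PP"] = float((win["SBP"] - win["DBP"]).median())
    else:
        out["PP"] = float("nan")
    return out


# ---------------------------------------------------------------------------
# Core tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_effect: int
    df_error: int
    p: float


def rm_anova(values: np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA on a subjects x conditions table.

    Subject effects are removed; the F statistic is
    (SS_conditions / (k - 1)) / (SS_error / ((k - 1)(n - 1))).
    No sphericity correction is applied.  Zero error variance with a
    non-zero condition effect yields F = inf, p = 0.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need >= 3 subjects and >= 2 conditions")
    n, k = x.shape
    grand = x.mean()
    subj_means = x.mean(axis=1)
    cond_means = x.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_effect = k - 1
    df_error = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_effect
    ms_err = ss_err / df_error
    if ms_err <= 0:
        if ms_cond <= 0:
            return AnovaResult(F=float("nan"), df_effect=df_effect,
                               df_error=df_error, p=float("nan"))
        return AnovaResult(F=float("inf"), df_effect=df_effect,
                           df_error=df_error, p=0.0)
    F = ms_cond / ms_err
    p = float(sstats.f.sf(F, df_effect, df_error))
    return AnovaResult(F=float(F), df_effect=df_effect,
                       df_error=df_error, p=p)


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length samples with n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, x.size - 1, 1.0  # identical samples: no effect
        raise ValueError("zero-variance non-zero differences")
    res = sstats.ttest_rel(x, y)
    return float(res.statistic), x.size - 1, float(res.pvalue)


def holm_bonferroni(p_values) -> np.ndarray:
    """Step-down Holm-Bonferroni adjustment.

    The i-th smallest p value is multiplied by (k - i + 1); adjusted values
    are made monotone non-decreasing along the sorted order (running
    maximum), capped at 1, and returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    k = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (k - np.arange(k))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty_like(p)
    out[order] = adj_sorted
    return out


def bias_correction(df: float) -> float:
    """Small-sample correction J(df) = Gamma(df/2) / (sqrt(df/2) Gamma((df-1)/2))."""
    if df <= 1:
        raise ValueError("df must exceed 1")
    return float(np.exp(gammaln(df / 2.0) - gammaln((df - 1.0) / 2.0)
                        - 0.5 * np.log(df / 2.0)))


def hedges_g(x, y, *, ci_method: str = "normal"
             ) -> tuple[float, float, float]:
    """Bias-corrected standardized mean difference with a 95% CI.

    Returns (g, ci_low, ci_high).  The default CI uses the large-sample
    normal approximation var(g) ~ (n_x + n_y)/(n_x n_y) + g^2 / (2 df);
    ``ci_method="noncentral-t"`` inverts the noncentral-t distribution of
    the t statistic instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("need n >= 2 per group")
    df = nx + ny - 2
    s2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    if s2 <= 0:
        raise ValueError("pooled standard deviation is zero")
    s = np.sqrt(s2)
    g = bias_correction(df) * (x.mean() - y.mean()) / s
    if ci_method == "normal":
        var_g = (nx + ny) / (nx * ny) + g**2 / (2.0 * df)
        half = 1.959963984540054 * np.sqrt(var_g)
        return float(g), float(g - half), float(g + half)
    if ci_method == "noncentral-t":
        scale = np.sqrt(nx * ny / (nx + ny))
        t_obs = g / bias_correction(df) * scale
        lo = _ncp_bound(t_obs, df, 0.975) / scale * bias_correction(df)
        hi = _ncp_bound(t_obs, df, 0.025) / scale * bias_correction(df)
        return float(g), float(lo), float(hi)
    raise ValueError(f"unknown ci_method {ci_method!r}")


def _ncp_bound(t_obs: float, df: float, q: float) -> float:
    """Noncentrality parameter nc with P(T_{df,nc} <= t_obs) = q."""
    from scipy.optimize import brentq
    f = lambda nc: sstats.nct.cdf(t_obs, df, nc) - q
    lo, hi = t_obs - 20 - 5 * abs(t_obs), t_obs + 20 + 5 * abs(t_obs)
    return brentq(f, lo, hi)


def count_outliers(values) -> int:
    """Tukey-fence outlier count: values beyond q1 - 1.5 IQR or
    q3 + 1.5 IQR, with linearly interpolated quartiles.  Reporting only —
    the statistics never drop these points."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least four values for Tukey fences")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return int(np.sum((v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)))


def normalize_for_plot(triplet) -> np.ndarray:
    """Divide a subject's three interval values by their mean (used for
    display of PPG features; reference parameters stay in absolute units)."""
    v = np.asarray(triplet, dtype=float)
    m = v.mean()
    if m == 0 or not np.isfinite(m):
        raise ValueError("triplet mean is zero or non-finite")
    return v / m


# ---------------------------------------------------------------------------
# Study-level analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectResult:
    contrast: str       # e.g. "BL-ST1"
    t: float | None     # None when the ANOVA gate did not fire
    df: int | None
    p_raw: float | None
    p_adj: float | None
    g: float
    ci_low: float
    ci_high: float

    @property
    def stars(self) -> str:
        if self.p_adj is None:
            return ""
        for level, s in STAR_LEVELS:
            if self.p_adj < level:
                return s
        return ""


def analyze_group(pivot: pd.DataFrame, alpha: float = ALPHA,
                  intervals=("BL", "ST1", "ST2")
                  ) -> tuple[AnovaResult, list[EffectResult]]:
    """Run the gated chain for one (site, feature) subjects x intervals table.

    ``pivot`` is indexed by subject with one column per interval.  Hedges' g
    for contrast "A-B" is signed as (B - A): a decrease from A to B gives a
    negative g.
    """
    x = pivot[list(intervals)].to_numpy(dtype=float)
    anova = rm_anova(x)
    run_posthoc = np.isfinite(anova.p) and anova.p < alpha
    raw_ps, trips = [], []
    for a, b in CONTRASTS:
        xa = pivot[a].to_numpy(dtype=float)
        xb = pivot[b].to_numpy(dtype=float)
        g, lo, hi = hedges_g(xb, xa)
        if run_posthoc:
            try:
                t, df, p = paired_t(xb, xa)
            except ValueError:
                # degenerate constant shift: flag as an extreme result
                t = float(np.inf) * np.sign((xb - xa).mean())
                df, p = xb.size - 1, 0.0
        else:
            t = df = p = None
        raw_ps.append(p)
        trips.append((f"{a}-{b}", t, df, p, g, lo, hi))
    if run_posthoc:
        adj = holm_bonferroni([p for p in raw_ps])
    else:
        adj = [None] * len(CONTRASTS)
    effects = [EffectResult(contrast=c, t=t, df=df, p_raw=p,
                            p_adj=(None if a is None else float(a)),
                            g=g, ci_low=lo, ci_high=hi)
               for (c, t, df, p, g, lo, hi), a in zip(trips, adj)]
    return anova, effects


def analyze_study(table: pd.DataFrame, alpha: float = ALPHA
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full chain on a long study table.

    ``table`` columns: subject, site, interval, feature, value.  Subjects
    with any missing (site, interval, feature) cell are dropped from the
    whole analysis (complete-case rule).  Returns (anova_table,
    effects_table) as tidy DataFrames.
    """
    required = {"subject", "site", "interval", "feature", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"study table lacks columns {sorted(missing)}")
    complete = _complete_cases(table)
    anova_rows, effect_rows = [], []
    for (site, feature), grp in complete.groupby(["site", "feature"],
                                                 sort=True):
        pivot = grp.pivot(index="subject", columns="interval",
                          values="value")
        if pivot.isna().any().any() or len(pivot) < 3:
            continue
        anova, effects = analyze_group(pivot, alpha)
        anova_rows.append({"site": site, "feature": feature, "F": anova.F,
                           "df_effect": anova.df_effect,
                           "df_error": anova.df_error, "p": anova.p,
                           "n": len(pivot)})
        for e in effects:
            effect_rows.append({
                "site": site, "feature": feature, "contrast": e.contrast,
                "t": e.t, "df": e.df, "p_raw": e.p_raw, "p_adj": e.p_adj,
                "g": e.g, "ci_low": e.ci_low, "ci_high": e.ci_high,
                "stars": e.stars})
    return pd.DataFrame(anova_rows), pd.DataFrame(effect_rows)


def _complete_cases(table: pd.DataFrame) -> pd.DataFrame:
    """Drop subjects missing any (site, interval, feature) combination."""
    t = table.dropna(subset=["value"])
    n_cells = (t[["site", "interval", "feature"]].drop_duplicates().shape[0])
    counts = t.groupby("subject").size()
    complete_subjects = counts[counts == n_cells].index
    return t[t["subject"].isin(complete_subjects)]
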