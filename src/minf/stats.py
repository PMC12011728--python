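"""Group-level statistical battery for the MI-NF comparisons.

Paired and pooled independent t-tests with Cohen's d, a mixed
repeated-measures ANOVA (classical sums-of-squares decomposition with
Mauchly's sphericity test and Greenhouse-Geisser correction),
Bonferroni-Holm adjustment in two variants, and the Shapiro-Wilk / Levene
assumption checks.

Conventions frozen here: paired tests report df = n - 1 and
d = mean(diff) / SD(diff) = t / sqrt(n); independent tests use the pooled
variance (df = n1 + n2 - 2) and d = (m1 - m2) / s_pooled; the paired-test
confidence interval is on Cohen's d (noncentral-t inversion, one-sided when
the alternative is one-sided) while the independent-test interval is on the
mean difference — matching how the two analyses are conventionally reported.
eta-squared uses the total sum of squares including between-subject variance
(partial eta-squared is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    d: float
    ci: tuple
    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    alternative: str
    p_holm: float | None = None
    shapiro_p: tuple | None = None
    levene_p: float | None = None


@dataclass
class AnovaResult:
    term: str
    F: float
    df_num: float
    df_den: float
    p: float
    eta_squared: float
    ss: float
    mauchly_W: float | None = None
    mauchly_p: float | None = None
    gg_epsilon: float | None = None
    p_gg: float | None = None


# ---------------------------------------------------------------------------
# t-tests and effect sizes
# ---------------------------------------------------------------------------

def d_from_t_paired(t: float, n: int) -> float:
    """Paired Cohen's d from the t statistic: d = t / sqrt(n)."""
    if n < 2:
        raise ValueError("need n >= 2")
    return float(t) / np.sqrt(n)


def _noncentral_d_ci(t: float, n: int, alternative: str) -> tuple:
    """CI on paired Cohen's d by noncentral-t inversion (d = nc / sqrt(n))."""
    df = n - 1
    span = 10 * (abs(t) + 2)

    def nc_at(prob, side):
        # nc such that P(T_df(nc) >= t) == prob
        f = lambda nc: sps.nct.sf(t, df, nc) - prob
        return optimize.brentq(f, -span, span, xtol=1e-10)

    if alternative == "greater":
        lo = nc_at(0.05, "lower") / np.sqrt(n)
        return (float(lo), np.inf)
    lo = nc_at(0.025, "lower") / np.sqrt(n)
    hi = nc_at(0.975, "upper") / np.sqrt(n)
    return (float(lo), float(hi))


def paired_ttest(a, b, alternative: str = "greater",
                 ci: bool = True) -> TTestResult:
    """Paired t-test of a vs b (alternative 'greater': mean(a - b) > 0).

    d = t / sqrt(n); the CI is on d (one bound infinite when one-sided).
    ``ci=False`` skips the noncentral-t inversion (useful in tight loops).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    n = a.size
    t = diff.mean() / (sd / np.sqrt(n))
    df = n - 1
    if alternative == "greater":
        p = float(sps.t.sf(t, df))
    elif alternative == "two-sided":
        p = float(2 * sps.t.sf(abs(t), df))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TTestResult(
        t=float(t), df=df, p=p, d=d_from_t_paired(t, n),
        ci=_noncentral_d_ci(float(t), n, alternative) if ci else (np.nan, np.nan),
        n=n, mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        alternative=alternative,
    )


def independent_ttest(mean1=None, sd1=None, n1=None, mean2=None, sd2=None,
                      n2=None, a=None, b=None,
                      alternative: str = "two-sided") -> TTestResult:
    """Pooled-variance independent t-test from raw samples or summaries.

    Group 1 is the reference orientation: t and d carry the sign of
    mean1 - mean2. The CI is on the mean difference. df = n1 + n2 - 2.
    """
    if a is not None and b is not None:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        mean1, sd1, n1 = a.mean(), a.std(ddof=1), a.size
        mean2, sd2, n2 = b.mean(), b.std(ddof=1), b.size
    if min(n1, n2) < 2:
        raise ValueError("need n >= 2 per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    delta = mean1 - mean2
    t = delta / se
    if alternative == "two-sided":
        p = float(2 * sps.t.sf(abs(t), df))
        tcrit = sps.t.ppf(0.975, df)
        ci = (float(delta - tcrit * se), float(delta + tcrit * se))
    elif alternative == "greater":
        p = float(sps.t.sf(t, df))
        ci = (float(delta - sps.t.ppf(0.95, df) * se), np.inf)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    d = delta / np.sqrt(sp2)
    return TTestResult(
        t=float(t), df=df, p=p, d=float(d), ci=ci, n=int(min(n1, n2)),
        mean_a=float(mean1), sd_a=float(sd1),
        mean_b=float(mean2), sd_b=float(sd2),
        alternative=alternative,
    )


# ---------------------------------------------------------------------------
# Holm adjustment
# ---------------------------------------------------------------------------

def holm_adjust(pvals, variant: str = "standard") -> np.ndarray:
    """Bonferroni-Holm multiplicity adjustment.

    standard: step-down multipliers with cumulative-max monotonicity
    enforcement. raw-multiplier: p_i * (m - rank_i + 1) without the
    monotonicity step (some legacy software prints these). Both cap at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    mult = m - np.arange(m)                     # m, m-1, ..., 1 in sorted order
    scaled = p[order] * mult
    if variant == "standard":
        scaled = np.maximum.accumulate(scaled)
    elif variant != "raw-multiplier":
        raise ValueError(f"unknown Holm variant {variant!r}")
    adj = np.empty(m)
    adj[order] = np.minimum(scaled, 1.0)
    return adj


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _wide(table: pd.DataFrame):
    """participant x block value matrix, group label per participant."""
    wide = table.pivot(index="participant", columns="block", values="value")
    if wide.isna().any().any():
        raise ValueError("unbalanced design: missing participant x block cells")
    groups = None
    if "group" in table.columns:
        g = table.groupby("participant")["group"].first()
        groups = g.loc[wide.index].to_numpy()
    return wide.to_numpy(dtype=float), groups


def _sphericity(y: np.ndarray, groups: np.ndarray | None):
    """Mauchly's W/p and Greenhouse-Geisser epsilon on the within covariance.

    The covariance of the k repeated measures is pooled within groups
    (group-mean-centered) and projected onto k-1 orthonormal contrasts.
    """
    n, k = y.shape
    if groups is None:
        centered = y - y.mean(axis=0)
        n_groups = 1
    else:
        centered = y.copy()
        for g in np.unique(groups):
            centered[groups == g] -= y[groups == g].mean(axis=0)
        n_groups = len(np.unique(groups))
    n_e = n - n_groups
    sigma = centered.T @ centered / n_e
    # orthonormal contrasts: Helmert basis, normalized
    c = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1].T
    s = c @ sigma @ c.T
    eigs = np.linalg.eigvalsh(s)
    eigs = np.maximum(eigs, 1e-300)
    kk = k - 1
    w = float(np.prod(eigs) / (eigs.mean() ** kk))
    f_corr = (2 * kk**2 + kk + 2) / (6 * kk)
    chi2 = -(n_e - f_corr) * np.log(max(w, 1e-300))
    df_chi = k * (k - 1) / 2 - 1
    p = float(sps.chi2.sf(chi2, df_chi)) if df_chi > 0 else 1.0
    eps = float(np.trace(s) ** 2 / (kk * np.sum(s * s)))
    eps = min(max(eps, 1.0 / kk), 1.0)
    return w, p, eps


def rm_anova_mixed(table: pd.DataFrame) -> list[AnovaResult]:
    """Mixed (or within-only) repeated-measures ANOVA.

    ``table`` is long format with columns participant, block, value and
    optionally group (between-subjects factor). Classical SS decomposition;
    eta-squared = SS_term / SS_total. For k > 2 repeated levels, Mauchly's
    test and Greenhouse-Geisser-corrected p-values accompany every
    within-subject term. Unbalanced tables raise (no imputation).
    """
    y, groups = _wide(table)
    n, k = y.shape
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    subj_means = y.mean(axis=1)
    ss_between_subj = k * ((subj_means - grand) ** 2).sum()
    ss_within = ss_total - ss_between_subj
    block_means = y.mean(axis=0)
    ss_block = n * ((block_means - grand) ** 2).sum()

    results: list[AnovaResult] = []
    if groups is None:
        ss_err_within = ss_within - ss_block
        df_b, df_e = k - 1, (n - 1) * (k - 1)
        f = (ss_block / df_b) / (ss_err_within / df_e)
        res = AnovaResult(
            term="block", F=float(f), df_num=df_b, df_den=df_e,
            p=float(sps.f.sf(f, df_b, df_e)),
            eta_squared=float(ss_block / ss_total), ss=float(ss_block),
        )
        _attach_sphericity(res, y, None, f, df_b, df_e)
        results.append(res)
        return results

    glabels = np.unique(groups)
    n_g = len(glabels)
    group_means = {g: y[groups == g].mean() for g in glabels}
    counts = {g: (groups == g).sum() for g in glabels}
    ss_group = k * sum(counts[g] * (group_means[g] - grand) ** 2 for g in glabels)
    ss_err_between = ss_between_subj - ss_group
    ss_inter = 0.0
    for g in glabels:
        cell = y[groups == g].mean(axis=0)
        ss_inter += counts[g] * ((cell - group_means[g] - block_means + grand) ** 2).sum()
    ss_err_within = ss_within - ss_block - ss_inter

    df_group, df_eb = n_g - 1, n - n_g
    df_block = k - 1
    df_inter = (n_g - 1) * (k - 1)
    df_ew = (n - n_g) * (k - 1)

    f_group = (ss_group / df_group) / (ss_err_between / df_eb)
    results.append(AnovaResult(
        term="group", F=float(f_group), df_num=df_group, df_den=df_eb,
        p=float(sps.f.sf(f_group, df_group, df_eb)),
        eta_squared=float(ss_group / ss_total), ss=float(ss_group),
    ))
    for term, ss, dfn in (("block", ss_block, df_block),
                          ("block*group", ss_inter, df_inter)):
        f = (ss / dfn) / (ss_err_within / df_ew)
        res = AnovaResult(
            term=term, F=float(f), df_num=dfn, df_den=df_ew,
            p=float(sps.f.sf(f, dfn, df_ew)),
            eta_squared=float(ss / ss_total), ss=float(ss),
        )
        _attach_sphericity(res, y, groups, f, dfn, df_ew)
        results.append(res)
    return results


def _attach_sphericity(res: AnovaResult, y: np.ndarray,
                       groups: np.ndarray | None, f: float,
                       dfn: float, dfd: float) -> None:
    k = y.shape[1]
    if k <= 2:
        res.mauchly_W, res.mauchly_p = 1.0, 1.0
        res.gg_epsilon, res.p_gg = 1.0, res.p
        return
    w, p_m, eps = _sphericity(y, groups)
    res.mauchly_W, res.mauchly_p = w, p_m
    res.gg_epsilon = eps
    res.p_gg = float(sps.f.sf(f, dfn * eps, dfd * eps))


def eta_squared_partial(res: AnovaResult, ss_error: float) -> float:
    """Partial eta-squared alternative: SS_term / (SS_term + SS_error)."""
    return float(res.ss / (res.ss + ss_error))


# ---------------------------------------------------------------------------
# assumption checks
# ---------------------------------------------------------------------------

def assumption_checks(a, b) -> dict:
    """Shapiro-Wilk normality p per group and mean-centered Levene p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(a.size, b.size) < 3:
        raise ValueError("need n >= 3 per group")
    for x in (a, b):
        if x.std() == 0:
            raise ValueError("Shapiro-Wilk undefined for a constant sample")
    sw_a = sps.shapiro(a)
    sw_b = sps.shapiro(b)
    lev = sps.levene(a, b, center="mean")
    return {
        "shapiro_p": (float(sw_a.pvalue), float(sw_b.pvalue)),
        "shapiro_W": (float(sw_a.statistic), float(sw_b.statistic)),
        "levene_stat": float(lev.statistic),
        "levene_p": float(lev.pvalue),
    }
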