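"""Statistical layer: factor extraction, ANOVA, post hocs, correlations.

Two routes to every ANOVA are provided: :func:`one_way_anova` on raw
per-rat values, and :func:`anova_from_summary` which reconstructs the same
decomposition from printed group means, standard errors and sizes. The two
agree exactly when the summaries are computed from the raw data without
rounding, which is what makes the summary route usable as an oracle against
published tables.

Factor extraction is principal-component style on the Pearson correlation
matrix: loadings are the first eigenvector scaled by the square root of its
eigenvalue, and the retained-factor count follows the eigenvalue-1 rule.
With this convention the variance fraction equals the mean of the squared
loadings, so a printed loading triple and a printed variance percentage can
be checked against each other directly (:func:`variance_from_loadings`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "FactorSolution",
    "pearson_correlation_matrix",
    "extract_single_factor",
    "variance_from_loadings",
    "one_way_anova",
    "anova_from_summary",
    "tukey_hsd",
    "unpaired_t",
    "unpaired_t_from_summary",
    "pearson_r",
    "mixed_rm_anova",
]


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- standard error of one group of ``n`` observations."""

    mean: float
    se: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("GroupSummary requires n >= 2")
        if self.se <= 0:
            raise ValueError("GroupSummary requires se > 0")

    @property
    def sd(self) -> float:
        return self.se * np.sqrt(self.n)


@dataclass(frozen=True)
class AnovaResult:
    """One-way (or reconstructed) ANOVA: F, degrees of freedom, p, MS terms."""

    F: float
    df_between: int
    df_within: int
    p: float
    group_means: tuple[float, ...]
    ms_between: float
    ms_within: float


@dataclass(frozen=True)
class FactorSolution:
    """Eigenstructure of a criterion correlation matrix.

    ``loadings`` belong to the first (largest-eigenvalue) component, scaled
    by sqrt(eigenvalue) and signed so their sum is non-negative;
    ``variance_fraction`` is the share of total variance (= trace) that the
    first component carries; ``n_retained`` counts eigenvalues >= 1, ties
    at exactly 1.0 included.
    """

    correlation_matrix: np.ndarray = field(repr=False)
    eigenvalues: tuple[float, ...]
    loadings: tuple[float, ...]
    variance_fraction: float
    n_retained: int


def pearson_correlation_matrix(scores: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the columns of a score table.

    Requires at least 3 complete rows and non-degenerate columns.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need a 2-D table with at least 3 rows")
    if np.any(~np.isfinite(x)):
        raise ValueError("score table contains missing or non-finite values")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        cols = list(scores.columns[sd == 0]) if isinstance(scores, pd.DataFrame) else list(np.flatnonzero(sd == 0))
        raise ValueError(f"zero-variance column(s): {cols}")
    return np.corrcoef(x, rowvar=False)


def extract_single_factor(R: np.ndarray) -> FactorSolution:
    """Principal-component factor extraction with the eigenvalue-1 rule."""
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have a unit diagonal")
    eigvals, eigvecs = np.linalg.eigh(R)
    if eigvals[0] < -1e-10:
        raise ValueError(f"matrix is not positive semidefinite (min eigenvalue {eigvals[0]:.3g})")
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = np.clip(eigvals[order], 0.0, None), eigvecs[:, order]
    loadings = eigvecs[:, 0] * np.sqrt(eigvals[0])
    if loadings.sum() < 0:
        loadings = -loadings
    return FactorSolution(
        correlation_matrix=R,
        eigenvalues=tuple(eigvals),
        loadings=tuple(loadings),
        variance_fraction=float(eigvals[0] / np.trace(R)),
        n_retained=int(np.sum(eigvals >= 1.0)),
    )


def variance_from_loadings(loadings, ndigits: int | None = None) -> float:
    """Percent variance of a principal component from its loadings.

    For component-style extraction the variance share is the mean of the
    squared loadings, times 100. ``ndigits`` rounds the result (0 gives the
    integer-percent convention of published factor tables).
    """
    l = np.asarray(loadings, dtype=float)
    if np.any(np.abs(l) > 1.0 + 1e-12):
        raise ValueError("loadings must lie in [-1, 1]")
    pct = 100.0 * float(np.mean(l**2))
    return round(pct, ndigits) if ndigits is not None else pct


def one_way_anova(groups) -> AnovaResult:
    """Textbook one-way fixed-effects ANOVA on raw per-group values."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    n = np.array([len(g) for g in gs])
    means = np.array([g.mean() for g in gs])
    grand = np.concatenate(gs).mean()
    ss_between = float(np.sum(n * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(gs, means)))
    df_b, df_w = len(gs) - 1, int(n.sum()) - len(gs)
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    if ms_w == 0.0:
        F = 0.0 if ss_between == 0.0 else np.inf
    else:
        F = ms_b / ms_w
    p = float(sps.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    return AnovaResult(float(F), df_b, df_w, p, tuple(means), ms_b, ms_w)


def anova_from_summary(summaries) -> AnovaResult:
    """One-way ANOVA reconstructed from group means, SEs and sizes.

    SD = SE * sqrt(n); SS_within = sum (n_i - 1) SD_i^2; SS_between from the
    group means about the size-weighted grand mean. Equals
    :func:`one_way_anova` exactly when the summaries come from raw data
    without rounding.
    """
    ss = list(summaries)
    if len(ss) < 2:
        raise ValueError("need >= 2 group summaries")
    n = np.array([s.n for s in ss])
    means = np.array([s.mean for s in ss])
    sds = np.array([s.sd for s in ss])
    grand = float(np.sum(n * means) / n.sum())
    ss_between = float(np.sum(n * (means - grand) ** 2))
    ss_within = float(np.sum((n - 1) * sds**2))
    df_b, df_w = len(ss) - 1, int(n.sum()) - len(ss)
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    F = ms_b / ms_w
    return AnovaResult(float(F), df_b, df_w, float(sps.f.sf(F, df_b, df_w)), tuple(means), ms_b, ms_w)


def tukey_hsd(groups) -> dict[tuple[int, int], float]:
    """Tukey-Kramer pairwise adjusted p-values, keyed by group-index pair.

    Standard errors use the Kramer correction for unequal group sizes and p
    comes from the studentized-range distribution, so with two groups the
    adjusted p equals the pooled-variance t-test p.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    res = sps.tukey_hsd(*gs)
    return {
        (i, j): float(res.pvalue[i, j])
        for i, j in itertools.combinations(range(len(gs)), 2)
    }


def unpaired_t(x, y) -> tuple[float, int, float]:
    """Pooled-variance two-sample Student t: (t, df, two-tailed p)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) + len(y) < 4 or min(len(x), len(y)) < 2:
        raise ValueError("need n1 + n2 >= 4 with >= 2 per group")
    df = len(x) + len(y) - 2
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), df, float(p)


def unpaired_t_from_summary(s1: GroupSummary, s2: GroupSummary) -> tuple[float, int, float]:
    """Pooled-variance t test reconstructed from two group summaries."""
    res = sps.ttest_ind_from_stats(s1.mean, s1.sd, s1.n, s2.mean, s2.sd, s2.n, equal_var=True)
    return float(res.statistic), s1.n + s2.n - 2, float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with its two-tailed p (t transform, n-2 df)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if x.std(ddof=1) == 0.0 or y.std(ddof=1) == 0.0:
        raise ValueError("zero-variance input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def _check_balanced(data: pd.DataFrame, subject: str, within: str) -> None:
    levels = data[within].unique()
    counts = data.groupby(subject, observed=True)[within].agg(["count", "nunique"])
    bad = counts[(counts["count"] != len(levels)) | (counts["nunique"] != len(levels))]
    if len(bad):
        raise ValueError(
            "unbalanced within-subject design; every subject must be observed "
            f"exactly once at each of the {len(levels)} levels. Offending subjects: "
            f"{bad.index.tolist()}"
        )


def mixed_rm_anova(
    data: pd.DataFrame,
    dv: str = "value",
    between: str = "group",
    within: str = "level",
    subject: str = "subject",
    contrasts: bool = True,
) -> dict:
    """Two-way mixed (split-plot) ANOVA for a balanced between x within design.

    Returns the between-group, within-level and interaction effects (no
    sphericity correction, matching how such designs are conventionally
    reported for these assays) plus, optionally, Bonferroni-adjusted
    between-group pooled-t contrasts at each within level. Exactly two
    between groups are required for the contrasts.
    """
    for col in (dv, between, within, subject):
        if col not in data.columns:
            raise ValueError(f"column '{col}' missing from data")
    _check_balanced(data, subject, within)
    grp_per_subject = data.groupby(subject, observed=True)[between].nunique()
    if (grp_per_subject != 1).any():
        raise ValueError("each subject must belong to exactly one between-group")

    import pingouin as pg  # deferred: heavy import

    try:
        aov = pg.mixed_anova(data=data, dv=dv, within=within, subject=subject,
                             between=between).set_index("Source")
        out = {
            "between": _row(aov, between),
            "within": _row(aov, within),
            "interaction": _row(aov, "Interaction"),
        }
    except (KeyError, ZeroDivisionError, FloatingPointError):
        # noise-free degenerate designs break the sphericity machinery;
        # fall back to the plain split-plot decomposition
        out = _split_plot_fallback(data, dv, between, within, subject)
    if contrasts:
        groups = data[between].unique()
        if len(groups) != 2:
            raise ValueError("per-level contrasts require exactly 2 between-groups")
        levels = list(data[within].unique())
        rows = []
        for lev in levels:
            sub = data[data[within] == lev]
            t, df, p = unpaired_t(
                sub.loc[sub[between] == groups[0], dv],
                sub.loc[sub[between] == groups[1], dv],
            )
            rows.append({
                "level": lev, "t": t, "df": df, "p_uncorrected": p,
                "p_bonferroni": min(1.0, p * len(levels)),
            })
        out["contrasts"] = rows
    return out


def _split_plot_fallback(data, dv, between, within, subject) -> dict:
    """Textbook split-plot SS decomposition with 0/0 -> F=0 conventions."""
    d = data
    grand = d[dv].mean()
    p = d[within].nunique()
    subj_mean = d.groupby(subject, observed=True)[dv].mean()
    grp_of = d.groupby(subject, observed=True)[between].first()
    grp_mean = d.groupby(between, observed=True)[dv].mean()
    lev_mean = d.groupby(within, observed=True)[dv].mean()
    cell = d.groupby([between, within], observed=True)[dv].mean()
    n_per = grp_of.value_counts()
    k, N = len(grp_mean), len(subj_mean)
    ss_a = p * float(sum(n_per[g] * (grp_mean[g] - grand) ** 2 for g in grp_mean.index))
    ss_subj = p * float(sum((subj_mean[s] - grp_mean[grp_of[s]]) ** 2 for s in subj_mean.index))
    ss_b = N * float(sum((lev_mean[l] - grand) ** 2 for l in lev_mean.index))
    ss_ab = float(sum(n_per[g] * (cell[g, l] - grp_mean[g] - lev_mean[l] + grand) ** 2
                      for g in grp_mean.index for l in lev_mean.index))
    ss_err = float(((d[dv] - grand) ** 2).sum()) - ss_a - ss_subj - ss_b - ss_ab
    ss_err = max(ss_err, 0.0)

    def eff(ss, df1, ss_e, df2):
        if ss_e <= 0.0:
            F = 0.0 if ss <= 1e-12 else np.inf
            return {"F": F, "df1": df1, "df2": df2, "p": 1.0 if F == 0.0 else 0.0}
        F = (ss / df1) / (ss_e / df2)
        return {"F": float(F), "df1": df1, "df2": df2, "p": float(sps.f.sf(F, df1, df2))}

    return {
        "between": eff(ss_a, k - 1, ss_subj, N - k),
        "within": eff(ss_b, p - 1, ss_err, (N - k) * (p - 1)),
        "interaction": eff(ss_ab, (k - 1) * (p - 1), ss_err, (N - k) * (p - 1)),
    }


def _row(aov: pd.DataFrame, source: str) -> dict:
    r = aov.loc[source]
    F = float(r["F"])
    p = float(r["p_unc"] if "p_unc" in r.index else r["p-unc"])
    # degenerate noise-free designs: 0/0 means no effect and no error (F=0),
    # a positive SS over zero error is an infinite-F flag
    if not np.isfinite(F):
        if float(r["SS"]) == 0.0:
            F, p = 0.0, 1.0
        else:
            F, p = np.inf, 0.0
    return {"F": F, "df1": int(r["DF1"]), "df2": int(r["DF2"]), "p": p}
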