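"""Three-criteria screening: percentile flags, addiction score, groups.

The screen is cohort-relative: each criterion (persistence in no-drug
periods, progressive-ratio breakpoint, punished responding) is thresholded
on its own within-cohort distribution, a rat being positive when its score
lies in the 66th-99th percentile window. The addiction score is the sum of
the three criterion z-scores (sample SD, n-1 denominator), a severity index
that is zero-sum over the cohort by construction. Rats meeting at least two
criteria form the vulnerable group, the rest the resilient group.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import ScreeningConfig

__all__ = [
    "criterion_scores_from_sessions",
    "percentile_threshold",
    "classify_criteria",
    "addiction_score",
    "assign_groups",
    "screen",
    "criterion_count_distribution",
]

CRITERIA = ("persistence", "breakpoint", "punished")
FLAG_COLUMNS = ("flag_persistence", "flag_motivation", "flag_punishment")


def criterion_scores_from_sessions(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a tidy session log into per-rat criterion scores.

    persistence: mean active presses over the no-drug unavailable periods
    (3 sessions x 3 cycles; pooling periods and averaging session means
    coincide because the design is balanced). breakpoint: mean over the 3
    PR sessions of the last completed response requirement (recovered from
    the session's reward count via the PR progression). punished: mean
    active presses over the 3 punishment sessions. Each rat must have
    exactly 3 sessions of each test phase.
    """
    from .cohort import pr_ratio_sequence

    required = {"rat_id", "phase", "session_index", "period", "active_presses", "rewards"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise ValueError(f"session table lacks columns: {sorted(missing_cols)}")
    rats = records["rat_id"].unique()
    problems = []
    for phase in ("nodrug_test", "pr_test", "punishment_test"):
        sub = records[records["phase"] == phase]
        counts = sub.groupby("rat_id", observed=True)["session_index"].nunique()
        counts = counts.reindex(rats, fill_value=0)
        for rat, k in counts[counts != 3].items():
            problems.append(f"{rat}: {k} {phase} sessions (expected 3)")
    if problems:
        raise ValueError("malformed test-session structure: " + "; ".join(problems))

    unavail = records[(records["phase"] == "nodrug_test") & (records["period"] == "unavailable")]
    persistence = unavail.groupby("rat_id", observed=True)["active_presses"].mean()

    pr = records[records["phase"] == "pr_test"].copy()
    max_rewards = int(pr["rewards"].max())
    seq = np.concatenate([[0], pr_ratio_sequence(max_rewards)]) if max_rewards else np.array([0])
    pr["final_ratio"] = seq[pr["rewards"].to_numpy()]
    breakpoint_ = pr.groupby("rat_id", observed=True)["final_ratio"].mean()

    pun = records[records["phase"] == "punishment_test"]
    punished = pun.groupby("rat_id", observed=True)["active_presses"].mean()

    out = pd.DataFrame({
        "rat_id": rats,
        "persistence": persistence.reindex(rats).to_numpy(),
        "breakpoint": breakpoint_.reindex(rats).to_numpy(),
        "punished": punished.reindex(rats).to_numpy(),
    })
    return out


def percentile_threshold(values, percentile: float) -> float:
    """Linear-interpolation quantile (the p-quantile at rank 1 + (n-1)p).

    Degenerate (all-equal) distributions raise: a percentile window on a
    constant sample cannot separate rats.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need a 1-D sample of at least 2 values")
    if np.any(~np.isfinite(v)):
        raise ValueError("values contain missing entries")
    if np.unique(v).size < 2:
        raise ValueError("degenerate distribution: all values equal, classification meaningless")
    if not 0.0 <= percentile <= 100.0:
        raise ValueError("percentile must lie in [0, 100]")
    return float(np.percentile(v, percentile, method="linear"))


def classify_criteria(scores: pd.DataFrame, config: ScreeningConfig | None = None) -> pd.DataFrame:
    """Flag each rat on each criterion via the percentile window.

    A flag is set when the score is >= the lower-percentile threshold of
    that criterion's cohort distribution (boundary inclusive). Scores
    strictly above the upper-percentile threshold follow
    ``config.above_upper_policy``: counted positive with a warning
    (default), or excluded from positivity.
    """
    config = ScreeningConfig() if config is None else config
    flags = pd.DataFrame({"rat_id": scores["rat_id"].to_numpy()})
    for crit, col in zip(CRITERIA, FLAG_COLUMNS):
        v = scores[crit].to_numpy(dtype=float)
        lo = percentile_threshold(v, config.lower_percentile)
        hi = percentile_threshold(v, config.upper_percentile)
        above = v > hi
        if above.any():
            extremes = scores.loc[above, "rat_id"].tolist()
            warnings.warn(
                f"{crit}: score(s) above the {config.upper_percentile:g}th percentile "
                f"for {extremes} ({config.above_upper_policy})",
                stacklevel=2,
            )
        positive = v >= lo
        if config.above_upper_policy == "exclude_flagged":
            positive &= ~above
        flags[col] = positive
    return flags


def addiction_score(scores: pd.DataFrame) -> pd.Series:
    """Sum of the three criterion z-scores (cohort mean 0 by construction)."""
    if len(scores) < 2:
        raise ValueError("need at least 2 rats to standardize")
    z_sum = np.zeros(len(scores))
    for crit in CRITERIA:
        v = scores[crit].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if sd == 0.0:
            raise ValueError(f"zero-variance criterion '{crit}': z-score undefined")
        z_sum += (v - v.mean()) / sd
    return pd.Series(z_sum, index=scores.index, name="addiction_score")


def assign_groups(flags: pd.DataFrame, config: ScreeningConfig | None = None) -> pd.Series:
    """resilient / vulnerable labels from the per-rat criterion count."""
    config = ScreeningConfig() if config is None else config
    n_criteria = flags[list(FLAG_COLUMNS)].sum(axis=1)
    return pd.Series(
        np.where(n_criteria >= config.vulnerable_min_criteria, "vulnerable", "resilient"),
        index=flags.index, name="group",
    )


def screen(scores: pd.DataFrame, config: ScreeningConfig | None = None) -> pd.DataFrame:
    """Full screening result: flags, criterion count, addiction score, group."""
    config = ScreeningConfig() if config is None else config
    result = classify_criteria(scores, config)
    result["n_criteria"] = result[list(FLAG_COLUMNS)].sum(axis=1).astype(int)
    result["addiction_score"] = addiction_score(scores).to_numpy()
    result["group"] = assign_groups(result, config).to_numpy()
    return result


def criterion_count_distribution(result: pd.DataFrame) -> pd.DataFrame:
    """Counts and one-decimal percentages of rats by criterion count 0..3."""
    counts = result["n_criteria"].value_counts().reindex(range(4), fill_value=0)
    n = int(counts.sum())
    pct = (100.0 * counts / n).round(1) if n else counts.astype(float)
    return pd.DataFrame({"n_criteria": range(4), "count": counts.to_numpy(),
                         "percent": pct.to_numpy()})
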