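"""Synthetic operant-behavior cohort generator.

Simulates cohorts of rats with the statistical structure the three-criteria
screen assumes: a single latent addiction liability drives all three
criterion scores (persistence in no-drug periods, progressive-ratio
breakpoint, punished responding), an anxiety latent is coupled to the
liability, and the downstream assays (session logs, two-lever choice,
elevated plus maze, blood-alcohol time course) are derived from those
latents. Default parameters are calibrated to the published summary
statistics of the reference 59-rat cohort (see :mod:`threecrit.reference`),
so simulated cohorts reproduce its group means, inter-criterion
correlations and single-factor structure in distribution.

The criterion-count model is a shared-factor Poisson-log-normal (optionally
negative-binomial) mixture: criterion ``j`` of rat ``i`` has latent
``x_ij = l_j L_i + sqrt(1 - l_j^2) e_ij`` with liability ``L_i ~ N(0,1)``,
conditional mean ``m_ij = exp(a_j + b_j x_ij)``, and an integer count drawn
around ``m_ij``. Both the inter-criterion correlation of the *counts* and
the correlation matrix implied by a set of published score-criterion
correlations are available in closed form, which is what makes the
calibration exact rather than fitted.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import BALConfig, ChoiceConfig, EPMConfig, SessionConfig, TraitConfig

__all__ = [
    "sample_latent_traits",
    "implied_criterion_correlations",
    "score_correlations_from_matrix",
    "implied_count_correlations",
    "calibrate_trait_config",
    "simulate_criterion_scores",
    "pr_ratio_sequence",
    "snap_to_pr_requirement",
    "simulate_sessions",
    "simulate_choice",
    "simulate_epm",
    "simulate_bal",
]

_CRITERIA = ("persistence", "breakpoint", "punished")


# ---------------------------------------------------------------------------
# latent layer

def _rat_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"rat_{i:0{width}d}" for i in range(1, n + 1)]


def sample_latent_traits(config: TraitConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-rat liability and anxiety latents.

    Both are marginally standard normal with correlation
    ``config.anxiety_liability_corr``. The returned frame is the generative
    ground truth against which recovery can be checked.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rho = config.anxiety_liability_corr
    liability = rng.standard_normal(config.n_rats)
    anxiety = rho * liability + math.sqrt(1.0 - rho**2) * rng.standard_normal(config.n_rats)
    return pd.DataFrame({
        "rat_id": _rat_ids(config.n_rats),
        "liability": liability,
        "anxiety": anxiety,
    })


# ---------------------------------------------------------------------------
# correlation algebra

def implied_criterion_correlations(score_criterion_corrs) -> np.ndarray:
    """Invert score-criterion correlations into the 3x3 criterion matrix.

    If the addiction score is the sum of the three criterion z-scores, then
    ``corr(score, z_j) = (row sum of R)_j / sqrt(1'R1)``. Summing over j
    gives ``1'R1 = (sum of the inputs)^2``, after which the three row sums,
    and hence the three off-diagonal correlations, follow by a linear solve.
    The result is validated (entries in [-1, 1], positive semidefinite) and
    round-trips through :func:`score_correlations_from_matrix`.
    """
    c = np.asarray(score_criterion_corrs, dtype=float)
    if c.shape != (3,):
        raise ValueError("need exactly 3 score-criterion correlations")
    if np.any(c <= 0) or np.any(c > 1):
        raise ValueError(f"score-criterion correlations must lie in (0, 1], got {c}")
    total = float(c.sum()) ** 2          # 1'R1
    row_sums = c * c.sum()               # per-criterion row sums of R
    half_off = (total - 3.0) / 2.0       # sum of the three off-diagonals
    r23 = half_off - (row_sums[0] - 1.0)
    r13 = half_off - (row_sums[1] - 1.0)
    r12 = half_off - (row_sums[2] - 1.0)
    R = np.array([[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]])
    off = {"r12": r12, "r13": r13, "r23": r23}
    bad = {k: v for k, v in off.items() if abs(v) > 1.0 + 1e-12}
    if bad:
        raise ValueError(f"inputs imply off-diagonal correlations outside [-1, 1]: {bad}")
    min_eig = float(np.linalg.eigvalsh(R)[0])
    if min_eig < -1e-10:
        raise ValueError(
            f"inputs imply a non-positive-semidefinite matrix (min eigenvalue {min_eig:.3g})"
        )
    return R


def score_correlations_from_matrix(R: np.ndarray) -> np.ndarray:
    """Forward map: criterion correlation matrix -> score-criterion corrs."""
    R = np.asarray(R, dtype=float)
    row_sums = R.sum(axis=1)
    return row_sums / np.sqrt(R.sum())


def implied_count_correlations(config: TraitConfig) -> np.ndarray:
    """Closed-form Pearson correlations of the simulated criterion counts.

    For the Poisson/NB log-normal mixture,
    ``cov(s_j, s_k) = mu_j mu_k (e^{b_j b_k rho_jk} - 1)`` with
    ``rho_jk = l_j l_k``, and the marginal variances are the configured
    ``criterion_sds`` squared (by construction of the slopes).
    """
    a, b = config.log_normal_slopes()
    l = np.asarray(config.factor_loadings)
    mu = np.asarray(config.criterion_means)
    sd = np.asarray(config.criterion_sds)
    rho = np.outer(l, l)
    cov = np.outer(mu, mu) * (np.exp(np.outer(b, b) * rho) - 1.0)
    R = cov / np.outer(sd, sd)
    np.fill_diagonal(R, 1.0)
    return R


def calibrate_trait_config(
    score_criterion_corrs=(0.794, 0.818, 0.641),
    criterion_means=(8.382881, 34.019322, 12.412373),
    criterion_sds=(5.238123, 14.381755, 9.073362),
    n_rats: int = 59,
    anxiety_liability_corr: float = 0.7,
    nb_size=None,
    seed: int = 0,
) -> TraitConfig:
    """Solve factor loadings so simulated counts hit a target correlation.

    Inverts the log-normal link: the target count correlation matrix
    (implied by the score-criterion correlations) fixes the products
    ``beta_j beta_k = log(1 + r_jk sd_j sd_k / (mu_j mu_k))`` of the shared
    log-scale slopes, which a triple product solves uniquely; dividing by
    the total slope ``b_j`` from the variance identity yields the loading.
    Defaults reproduce the reference cohort calibration.
    """
    R = implied_criterion_correlations(score_criterion_corrs)
    mu = np.asarray(criterion_means, dtype=float)
    sd = np.asarray(criterion_sds, dtype=float)
    c = {}
    for j, k in ((0, 1), (0, 2), (1, 2)):
        arg = 1.0 + R[j, k] * sd[j] * sd[k] / (mu[j] * mu[k])
        if arg <= 0:
            raise ValueError(f"target correlation r{j+1}{k+1} infeasible for these moments")
        c[(j, k)] = math.log(arg)
    beta0 = math.sqrt(c[(0, 1)] * c[(0, 2)] / c[(1, 2)])
    beta = np.array([beta0, c[(0, 1)] / beta0, c[(0, 2)] / beta0])
    probe = TraitConfig(
        n_rats=n_rats, criterion_means=tuple(mu), criterion_sds=tuple(sd),
        anxiety_liability_corr=anxiety_liability_corr, nb_size=nb_size, seed=seed,
    )
    _, b = probe.log_normal_slopes()
    loadings = beta / b
    if np.any(loadings > 1.0 + 1e-9):
        raise ValueError(
            "target correlations need more shared log-scale variance than the "
            f"marginal SDs allow (required loadings {loadings})"
        )
    return TraitConfig(
        n_rats=n_rats,
        factor_loadings=tuple(np.clip(loadings, 0.0, 1.0)),
        criterion_means=tuple(mu),
        criterion_sds=tuple(sd),
        anxiety_liability_corr=anxiety_liability_corr,
        nb_size=nb_size,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# progressive-ratio schedule

def pr_ratio_sequence(n_rewards: int) -> list[int]:
    """Response requirements of the progressive-ratio schedule.

    The i-th requirement is ``round(5 e^{0.2 i} - 5)`` (i = 1..n_rewards),
    rounded half away from zero; the first sixteen are
    1, 2, 4, 6, 9, 12, 15, 20, 25, 32, 40, 50, 62, 77, 95, 118.
    """
    if n_rewards < 0:
        raise ValueError("n_rewards must be non-negative")
    return [math.floor(5.0 * math.exp(0.2 * i) - 5.0 + 0.5) for i in range(1, n_rewards + 1)]


def _pr_table_covering(max_value: float) -> np.ndarray:
    """Requirements up to (at least) ``max_value``."""
    n = max(1, int(math.ceil(5.0 * (math.log1p(max(max_value, 1.0) / 5.0)))) + 2)
    seq = pr_ratio_sequence(n)
    while seq[-1] < max_value:
        n *= 2
        seq = pr_ratio_sequence(n)
    return np.asarray(seq)


def snap_to_pr_requirement(values) -> np.ndarray:
    """Snap values to the nearest attainable PR requirement (ties downward).

    Values below the first requirement snap to 0 only when closer to 0
    than to 1.
    """
    v = np.asarray(values, dtype=float)
    table = np.concatenate([[0], _pr_table_covering(float(v.max(initial=1.0)))])
    idx = np.searchsorted(table, v)
    lo = table[np.clip(idx - 1, 0, len(table) - 1)]
    hi = table[np.clip(idx, 0, len(table) - 1)]
    return np.where(v - lo <= hi - v, lo, hi).astype(int)


# ---------------------------------------------------------------------------
# criterion scores

def simulate_criterion_scores(
    traits: pd.DataFrame,
    config: TraitConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw the per-rat criterion-score triple from the latent liability.

    Counts are conditionally Poisson (or negative binomial when
    ``config.nb_size`` is set) around a log-normal mean shifted by the
    rat's criterion latent. Breakpoint scores are snapped to the nearest
    attainable PR requirement, since a 3-session breakpoint average of a
    noise-free animal can only be a requirement value.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = len(traits)
    a, b = config.log_normal_slopes()
    l = np.asarray(config.factor_loadings)
    liability = traits["liability"].to_numpy()
    x = l * liability[:, None] + np.sqrt(1.0 - l**2) * rng.standard_normal((n, 3))
    m = np.exp(a + b * x)
    if config.nb_size is None:
        counts = rng.poisson(m)
    else:
        theta = np.asarray(config.nb_size)
        counts = rng.negative_binomial(theta, theta / (theta + m))
    scores = counts.astype(float)
    scores[:, 1] = snap_to_pr_requirement(scores[:, 1])
    return pd.DataFrame({
        "rat_id": traits["rat_id"].to_numpy(),
        "persistence": scores[:, 0],
        "breakpoint": scores[:, 1],
        "punished": scores[:, 2],
    })


# ---------------------------------------------------------------------------
# session-level simulation

def _noisy_counts(target: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    """Non-negative integer counts around ``target`` with SD ~ noise*sqrt(t+1)."""
    if noise == 0.0:
        return np.asarray(target, dtype=int)
    jitter = rng.normal(0.0, noise * np.sqrt(np.asarray(target, dtype=float) + 1.0))
    return np.maximum(0, np.rint(target + jitter)).astype(int)


def simulate_sessions(
    traits: pd.DataFrame,
    scores: pd.DataFrame,
    sconfig: SessionConfig | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Emit the tidy session log behind a cohort's criterion scores.

    Per rat: ``baseline_sessions`` conditioning sessions (saccharine then
    ethanol phases, whole-session rows), three no-drug test sessions with
    one row per available/unavailable period, three progressive-ratio test
    sessions and three punishment test sessions. With
    ``sconfig.session_noise = 0`` the per-rat 3-session averages equal the
    configured criterion scores exactly; PR sessions are internally
    consistent with :func:`pr_ratio_sequence` (cumulative presses equal the
    sum of completed requirements).
    """
    sconfig = SessionConfig() if sconfig is None else sconfig
    rng = np.random.default_rng(seed + 2) if rng is None else rng
    missing = set(traits["rat_id"]) - set(scores["rat_id"])
    if missing:
        raise ValueError(f"criterion scores missing for rats: {sorted(missing)}")
    merged = traits.merge(scores, on="rat_id", validate="one_to_one")
    noise = sconfig.session_noise
    cols = {k: [] for k in (
        "rat_id", "phase", "session_index", "period",
        "active_presses", "inactive_presses", "rewards", "shocks",
    )}

    def emit(rat, phase, idx, period, active, inactive, rewards, shocks):
        cols["rat_id"].append(rat)
        cols["phase"].append(phase)
        cols["session_index"].append(idx)
        cols["period"].append(period)
        cols["active_presses"].append(int(active))
        cols["inactive_presses"].append(int(inactive))
        cols["rewards"].append(int(rewards))
        cols["shocks"].append(int(shocks))

    n_base = sconfig.baseline_sessions
    n_sacc = min(sconfig.saccharine_sessions, n_base)
    n_test = sconfig.test_sessions_per_criterion
    for row in merged.itertuples(index=False):
        # -- baseline conditioning: drifting FR1 response rate. The
        # liability-linked component ramps in over training, so early
        # sessions are uninformative about the final phenotype and
        # low-liability rats drift downward late in training.
        for s in range(1, n_base + 1):
            phase = "saccharine_training" if s <= n_sacc else "ethanol_training"
            ramp = max(0.0, (s - n_sacc) / max(1, n_base - n_sacc))
            rate = sconfig.baseline_rate * math.exp(
                ramp * sconfig.baseline_liability_slope * (row.liability - 0.5)
            )
            active = rng.poisson(rate)
            emit(row.rat_id, phase, s, "whole", active, rng.poisson(3.0), active, 0)
        # -- no-drug test: per-period rows; unavailable-period presses
        # average to the persistence score.
        for s in range(1, n_test + 1):
            for cycle in range(sconfig.nodrug_cycles):
                avail = rng.poisson(sconfig.baseline_rate * sconfig.nodrug_avail_min
                                    / sconfig.baseline_duration_min)
                emit(row.rat_id, "nodrug_test", s, "available", avail, rng.poisson(1.0), avail, 0)
                unavail = _noisy_counts(np.array(row.persistence), noise, rng)
                emit(row.rat_id, "nodrug_test", s, "unavailable", unavail, rng.poisson(1.0), 0, 0)
        # -- progressive-ratio test: realized breakpoint is the largest
        # requirement <= the session's target effort.
        for s in range(1, n_test + 1):
            target = row.breakpoint if noise == 0.0 else max(
                0.0, row.breakpoint * (1.0 + rng.normal(0.0, noise / 2.0)))
            table = _pr_table_covering(max(target, 1.0))
            k = int(np.searchsorted(table, target, side="right"))
            cum = int(table[:k].sum())
            emit(row.rat_id, "pr_test", s, "whole", cum, rng.poisson(1.0), k, 0)
        # -- punishment test: every press earns a reward and a footshock.
        for s in range(1, n_test + 1):
            pressed = int(_noisy_counts(np.array(row.punished), noise, rng))
            emit(row.rat_id, "punishment_test", s, "whole", pressed, rng.poisson(1.0),
                 pressed, pressed)
    out = pd.DataFrame(cols)
    out["session_index"] = out["session_index"].astype(int)
    return out


# ---------------------------------------------------------------------------
# downstream assays

def simulate_choice(
    traits: pd.DataFrame,
    concentrations=None,
    config: ChoiceConfig | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-lever ethanol vs saccharine choice records across the fading ladder.

    Ethanol preference follows a logistic model whose liability effect
    grows as saccharine fades, so high-liability rats separate from the
    rest only at the low-concentration end. Records with zero total
    presses are flagged (``preference_defined = False``).
    """
    config = ChoiceConfig() if config is None else config
    concentrations = config.concentrations if concentrations is None else tuple(concentrations)
    unknown = set(concentrations) - set(config.concentrations)
    if unknown:
        raise ValueError(f"concentrations not on the configured fading ladder: {sorted(unknown)}")
    rng = np.random.default_rng(seed + 3) if rng is None else rng
    cmax = max(config.concentrations)
    base_by_conc = dict(zip(config.concentrations, config.baseline_logits))
    liability = traits["liability"].to_numpy()
    taste = config.taste_sd * rng.standard_normal(len(traits))
    rows = []
    for conc in concentrations:
        slope = config.liability_effect * (
            config.liability_slope_base
            + config.liability_slope_fade * (1.0 - conc / cmax)
        )
        logit = base_by_conc[conc] + slope * liability + taste
        p = 1.0 / (1.0 + np.exp(-logit))
        total = rng.poisson(config.mean_total_presses, size=len(traits))
        ethanol = rng.binomial(total, p)
        for rid, tot, eth in zip(traits["rat_id"], total, ethanol):
            rows.append({
                "rat_id": rid,
                "saccharine_conc_pct_wv": conc,
                "ethanol_presses": int(eth),
                "saccharine_presses": int(tot - eth),
                "preference_defined": bool(tot > 0),
            })
    out = pd.DataFrame(rows)
    tot = out["ethanol_presses"] + out["saccharine_presses"]
    out["preference_pct"] = np.where(tot > 0, 100.0 * out["ethanol_presses"] / tot.where(tot > 0, 1), np.nan)
    return out


def simulate_epm(
    traits: pd.DataFrame,
    config: EPMConfig | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Elevated-plus-maze open-arm percentages with MCAR dropout.

    Open-arm time decreases with the anxiety latent; ``config.n_dropout``
    rats get a missing value (lost completely at random, the mechanism the
    reference study reported for its technical failure).
    """
    config = EPMConfig() if config is None else config
    rng = np.random.default_rng(seed + 4) if rng is None else rng
    n = len(traits)
    open_pct = np.clip(
        config.baseline
        - config.anxiety_slope * traits["anxiety"].to_numpy()
        + config.noise_sd * rng.standard_normal(n),
        0.0, 100.0,
    )
    observed = np.ones(n, dtype=bool)
    if config.n_dropout > 0:
        if config.n_dropout >= n:
            raise ValueError("n_dropout must be smaller than the cohort")
        observed[rng.choice(n, size=config.n_dropout, replace=False)] = False
    return pd.DataFrame({
        "rat_id": traits["rat_id"].to_numpy(),
        "open_arm_pct": np.where(observed, open_pct, np.nan),
        "observed": observed,
    })


def simulate_bal(
    traits: pd.DataFrame,
    bconfig: BALConfig | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Blood-alcohol level time series after a single oral gavage.

    One-compartment first-order absorption with zero-order elimination;
    the post-absorption decline is linear with slope ``-elimination_rate``.
    With ``group_effect = 0`` (default) the trajectory distribution is
    identical across liability levels, reproducing the null group
    difference of the reference assay. Output metadata records the g/kg
    unit convention.
    """
    bconfig = BALConfig() if bconfig is None else bconfig
    rng = np.random.default_rng(seed + 5) if rng is None else rng
    times = np.asarray(bconfig.sample_times_min)
    n = len(traits)
    peak = (
        bconfig.dose_g_per_kg * bconfig.peak_per_dose
        + bconfig.subject_sd * rng.standard_normal(n)
        + bconfig.group_effect * traits["liability"].to_numpy()
    )[:, None]
    k0 = (bconfig.elimination_rate + bconfig.elimination_sd * rng.standard_normal(n))[:, None]
    curve = peak * (1.0 - np.exp(-bconfig.absorption_rate * times)) - k0 * times
    curve = curve + bconfig.noise_sd * rng.standard_normal((n, len(times)))
    curve = np.clip(curve, 0.0, None)
    out = pd.DataFrame({
        "rat_id": np.repeat(traits["rat_id"].to_numpy(), len(times)),
        "time_min": np.tile(times, n),
        "bal_g_per_kg": curve.ravel(),
    })
    out.attrs["units"] = "g/kg (reference assay convention; g/L is the common alternative)"
    return out
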