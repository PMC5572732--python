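"""Run configuration dataclasses and their YAML (de)serialization.

Every tunable of the simulator, the screening rule and the statistics layer
lives in one of the frozen dataclasses below, so that a run is a pure
function of (config, seed) and can be re-executed byte-identically from the
``cohort_config.yaml`` echo each run writes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "TraitConfig",
    "SessionConfig",
    "ScreeningConfig",
    "ChoiceConfig",
    "EPMConfig",
    "BALConfig",
    "RunConfig",
    "load_config",
    "dump_config",
    "config_hash",
]


def _triple(x: Sequence[float], name: str) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError(f"{name} must have exactly 3 entries, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class TraitConfig:
    """Latent-trait and criterion-count model of a simulated cohort.

    Each rat carries a standard-normal addiction *liability* and an
    *anxiety* latent, drawn with correlation ``anxiety_liability_corr``.
    Criterion j's latent is ``x_j = l_j * liability + sqrt(1-l_j^2) * eps_j``
    (``l_j`` = ``factor_loadings[j]``), and the observed count is drawn
    with log-normal conditional mean ``exp(a_j + b_j x_j)`` -- conditionally
    Poisson by default, negative binomial when ``nb_size`` is finite.
    ``a_j``/``b_j`` are solved from the requested marginal mean and SD.

    Parameters
    ----------
    n_rats:
        Cohort size; the reference design used 59.
    factor_loadings:
        Per-criterion weights in [0, 1] on the shared liability factor.
    criterion_means, criterion_sds:
        Marginal mean and standard deviation of each criterion score
        (presses for persistence/punishment, presses of the final completed
        ratio for the breakpoint).
    anxiety_liability_corr:
        Correlation between the anxiety and liability latents, in [-1, 1].
    nb_size:
        Optional per-criterion negative-binomial size (dispersion)
        parameters; ``None`` means conditionally Poisson counts with all
        overdispersion carried by the log-normal mean.
    """

    n_rats: int = 59
    # Default loadings are calibrated so that the induced count-level
    # correlations reproduce the inter-criterion correlation matrix implied
    # by the published score-criterion correlations (0.794, 0.818, 0.641).
    factor_loadings: tuple[float, float, float] = (0.835982, 0.953867, 0.340726)
    criterion_means: tuple[float, float, float] = (8.382881, 34.019322, 12.412373)
    criterion_sds: tuple[float, float, float] = (5.238123, 14.381755, 9.073362)
    anxiety_liability_corr: float = 0.7
    nb_size: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "factor_loadings", _triple(self.factor_loadings, "factor_loadings"))
        object.__setattr__(self, "criterion_means", _triple(self.criterion_means, "criterion_means"))
        object.__setattr__(self, "criterion_sds", _triple(self.criterion_sds, "criterion_sds"))
        if self.nb_size is not None:
            object.__setattr__(self, "nb_size", _triple(self.nb_size, "nb_size"))
            if any(t <= 0 for t in self.nb_size):
                raise ValueError("nb_size entries must be positive")
        if self.n_rats < 4:
            raise ValueError("n_rats must be >= 4: the percentile screen needs a distribution")
        if not all(0.0 <= l <= 1.0 for l in self.factor_loadings):
            raise ValueError(f"factor_loadings must lie in [0, 1], got {self.factor_loadings}")
        if not -1.0 <= self.anxiety_liability_corr <= 1.0:
            raise ValueError("anxiety_liability_corr must lie in [-1, 1]")
        if any(m <= 0 for m in self.criterion_means) or any(s <= 0 for s in self.criterion_sds):
            raise ValueError("criterion means and SDs must be strictly positive")
        # With loadings in [0,1] the implied latent correlation matrix
        # I + ll' - diag(l^2) is automatically PSD; the count layer adds its
        # own feasibility bound, checked here so bad configs fail early.
        self.log_normal_slopes()

    def log_normal_slopes(self) -> tuple[np.ndarray, np.ndarray]:
        """Solve the log-normal intercepts/slopes (a_j, b_j) from the moments.

        The marginal variance identity for a conditionally Poisson/NB count
        with log-normal mean m = exp(a + b x) is
        ``sigma^2 = mu + mu^2 (e^{b^2} (1 + 1/theta) - 1)``, giving
        ``e^{b^2} = (sigma^2 - mu + mu^2) / (mu^2 (1 + 1/theta))``.
        Raises if the requested SD is too small to accommodate the NB noise.
        """
        mu = np.asarray(self.criterion_means)
        var = np.asarray(self.criterion_sds) ** 2
        inv_theta = 0.0 if self.nb_size is None else 1.0 / np.asarray(self.nb_size)
        w = (var - mu + mu**2) / (mu**2 * (1.0 + inv_theta))
        if np.any(w < 1.0):
            bad = [c for c, ok in zip(("persistence", "breakpoint", "punished"), w >= 1.0) if not ok]
            raise ValueError(
                f"criterion_sds too small for the requested count model on {bad}: "
                "the variance identity e^(b^2)(1+1/theta) = (sd^2-mu+mu^2)/mu^2 "
                "requires the right-hand side to be >= 1"
            )
        b = np.sqrt(np.log(w))
        a = np.log(mu) - b**2 / 2.0
        return a, b


@dataclass(frozen=True)
class SessionConfig:
    """Operant session schedule parameters (reference protocol defaults).

    Baseline: 30-min FR1 sessions, 4-s timeout, 0.1 mL of 10% w/v ethanol.
    No-drug test: 3 cycles of 8 min reward availability + 4 min signaled
    unavailability (36 min). PR test: 90-min cap, stops after 20 min of
    inactivity. Punishment test: each reward paired with a 0.22 mA, 0.5 s
    footshock. Each criterion is scored over 3 consecutive daily sessions.
    ``session_noise`` scales the between-session variability the simulator
    adds around a rat's criterion score (0 = noise-free sessions).
    """

    baseline_duration_min: float = 30.0
    baseline_sessions: int = 80
    saccharine_sessions: int = 20
    fixed_ratio: int = 1
    timeout_s: float = 4.0
    reward_volume_ml: float = 0.1
    ethanol_conc_pct_wv: float = 10.0
    nodrug_avail_min: float = 8.0
    nodrug_unavail_min: float = 4.0
    nodrug_cycles: int = 3
    pr_max_min: float = 90.0
    pr_inactivity_stop_min: float = 20.0
    shock_mA: float = 0.22
    shock_s: float = 0.5
    test_sessions_per_criterion: int = 3
    session_noise: float = 0.25
    baseline_rate: float = 45.0
    baseline_liability_slope: float = 0.35

    def __post_init__(self) -> None:
        positives = (
            self.baseline_duration_min, self.timeout_s, self.reward_volume_ml,
            self.ethanol_conc_pct_wv, self.nodrug_avail_min, self.nodrug_unavail_min,
            self.pr_max_min, self.pr_inactivity_stop_min, self.shock_mA, self.shock_s,
        )
        if any(v <= 0 for v in positives):
            raise ValueError("all durations, volumes and intensities must be strictly positive")
        if self.nodrug_cycles < 1 or self.test_sessions_per_criterion < 1:
            raise ValueError("cycle and session counts must be >= 1")
        if self.session_noise < 0:
            raise ValueError("session_noise must be non-negative")

    @property
    def nodrug_total_min(self) -> float:
        return self.nodrug_cycles * (self.nodrug_avail_min + self.nodrug_unavail_min)


@dataclass(frozen=True)
class ScreeningConfig:
    """Percentile-window positivity rule and group assignment.

    A rat is positive for a criterion when its score falls in the
    ``lower_percentile``..``upper_percentile`` window of the cohort
    distribution for that criterion; rats meeting at least
    ``vulnerable_min_criteria`` criteria form the vulnerable group.
    ``above_upper_policy`` decides what happens to scores strictly above the
    upper percentile: ``"count_positive"`` (default) still flags them,
    ``"exclude_flagged"`` does not.
    """

    lower_percentile: float = 66.0
    upper_percentile: float = 99.0
    above_upper_policy: str = "count_positive"
    vulnerable_min_criteria: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.lower_percentile < self.upper_percentile <= 100.0):
            raise ValueError("require 0 < lower_percentile < upper_percentile <= 100")
        if self.above_upper_policy not in ("count_positive", "exclude_flagged"):
            raise ValueError("above_upper_policy must be 'count_positive' or 'exclude_flagged'")
        if not 1 <= self.vulnerable_min_criteria <= 3:
            raise ValueError("vulnerable_min_criteria must be in 1..3")


@dataclass(frozen=True)
class ChoiceConfig:
    """Two-lever ethanol vs saccharine choice test generator parameters.

    Preference for the ethanol lever follows a logistic model in the
    saccharine concentration and the rat's liability: the baseline log-odds
    rise as saccharine fades, and the liability effect is strongest at the
    lowest concentrations (``liability_slope_fade``), so vulnerable rats
    separate from resilient ones only near the water end of the ladder.
    ``liability_effect = 0`` switches the group difference off entirely.
    """

    concentrations: tuple[float, ...] = (0.2, 0.1, 0.05, 0.025, 0.0125, 0.00625, 0.0)
    baseline_logits: tuple[float, ...] = (-1.7, -1.4, -1.1, -0.75, -0.5, -0.2, 0.0)
    liability_effect: float = 1.0
    liability_slope_base: float = 0.08
    liability_slope_fade: float = 0.42
    taste_sd: float = 0.8
    mean_total_presses: float = 60.0

    def __post_init__(self) -> None:
        if len(self.baseline_logits) != len(self.concentrations):
            raise ValueError("baseline_logits must match concentrations in length")
        if self.mean_total_presses <= 0:
            raise ValueError("mean_total_presses must be positive")


@dataclass(frozen=True)
class EPMConfig:
    """Elevated-plus-maze generator: open-arm % falls with the anxiety latent.

    ``open_pct = clip(baseline - anxiety_slope * anxiety + noise, 0, 100)``.
    Defaults are calibrated so that screened resilient/vulnerable groups
    reproduce the reference open-arm means (30.4 / 12.0 %) and an unpaired
    t near 2.6. ``n_dropout`` rats are lost completely at random.
    """

    baseline: float = 23.0
    anxiety_slope: float = 22.0
    noise_sd: float = 13.0
    n_dropout: int = 8

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.n_dropout < 0:
            raise ValueError("noise_sd and n_dropout must be non-negative")


@dataclass(frozen=True)
class BALConfig:
    """Blood-alcohol time-course model after a single oral gavage.

    One-compartment first-order absorption with zero-order (saturated)
    elimination: ``C(t) = peak * (1 - e^(-ka t)) - k0 t``, floored at zero.
    ``peak = dose_g_per_kg * peak_per_dose`` plus a per-rat normal offset;
    the elimination rate is shared across rats by default
    (``elimination_sd = 0``), matching the observation that resilient and
    vulnerable rats eliminate alcohol identically. ``group_effect`` scales
    a liability-proportional shift of the peak (0 = no group difference).
    BAL is reported in g/kg, the unit convention of the reference assay
    (g/L is the more common convention; the output metadata carries a note).
    """

    dose_g_per_kg: float = 1.0
    sample_times_min: tuple[float, ...] = (15.0, 30.0, 60.0, 180.0)
    absorption_rate: float = 0.15
    elimination_rate: float = 0.0038
    peak_per_dose: float = 0.95
    subject_sd: float = 0.06
    elimination_sd: float = 0.0
    noise_sd: float = 0.1
    group_effect: float = 0.0
    n_resilient: int = 12
    n_vulnerable: int = 7

    def __post_init__(self) -> None:
        if self.absorption_rate <= 0 or self.elimination_rate < 0:
            raise ValueError("absorption_rate must be positive and elimination_rate non-negative")
        if self.elimination_sd < 0 or self.noise_sd < 0 or self.subject_sd < 0:
            raise ValueError("rate/noise SDs must be non-negative")
        times = tuple(float(t) for t in self.sample_times_min)
        if any(t <= 0 for t in times) or list(times) != sorted(times):
            raise ValueError("sample_times_min must be positive and sorted ascending")
        object.__setattr__(self, "sample_times_min", times)


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of an end-to-end pipeline run."""

    seed: int = 0
    cohort: TraitConfig = field(default_factory=TraitConfig)
    sessions: SessionConfig = field(default_factory=SessionConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    choice: ChoiceConfig = field(default_factory=ChoiceConfig)
    epm: EPMConfig = field(default_factory=EPMConfig)
    bal: BALConfig = field(default_factory=BALConfig)
    output_dir: str = "threecrit_run"


_SECTIONS = {
    "cohort": TraitConfig,
    "sessions": SessionConfig,
    "screening": ScreeningConfig,
    "choice": ChoiceConfig,
    "epm": EPMConfig,
    "bal": BALConfig,
}


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_as_plain(v) for v in obj]
    return obj


def dump_config(config: RunConfig, path: str | Path | None = None) -> str:
    """Serialize a RunConfig to YAML (optionally writing it to ``path``)."""
    text = yaml.safe_dump(_as_plain(config), sort_keys=True)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def load_config(source: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML (or JSON, a YAML subset) file or string.

    Unknown sections or fields raise, so typos do not silently fall back to
    defaults.
    """
    text = Path(source).read_text(encoding="utf-8") if Path(str(source)).is_file() else str(source)
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            names = {f.name for f in dataclasses.fields(cls)}
            unknown = set(value) - names
            if unknown:
                raise ValueError(f"unknown fields in section '{key}': {sorted(unknown)}")
            value = {k: tuple(v) if isinstance(v, list) else v for k, v in value.items()}
            kwargs[key] = cls(**value)
        elif key in ("seed", "output_dir"):
            kwargs[key] = value
        else:
            raise ValueError(f"unknown config section '{key}'")
    return RunConfig(**kwargs)


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 hash of the resolved configuration."""
    blob = json.dumps(_as_plain(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
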