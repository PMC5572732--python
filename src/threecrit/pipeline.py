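"""End-to-end binding: simulate -> screen -> analyze -> report.

:func:`run_pipeline` executes the whole chain from a :class:`RunConfig`,
writes every stage table plus a ``stats_report.json`` and a plain-text
report, and returns the in-memory :class:`ResultBundle`. The bundle hash is
a pure function of the configuration, so identical configs reproduce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, cohort, screening, stats
from .config import RunConfig, config_hash, dump_config
from . import io as tcio

__all__ = ["ResultBundle", "run_pipeline", "format_report"]

log = logging.getLogger("threecrit")


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage it occurred in."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[stage: {stage}] {original}")
        self.stage = stage
        self.original = original


@dataclass
class ResultBundle:
    """Everything one pipeline run produced."""

    screening: pd.DataFrame
    criteria: pd.DataFrame
    stats_report: dict
    provenance: dict = field(default_factory=dict)

    @property
    def bundle_hash(self) -> str:
        blob = (
            self.screening.to_csv(index=False)
            + self.criteria.to_csv(index=False)
            + json.dumps(self.stats_report, sort_keys=True)
        ).encode()
        return hashlib.sha256(blob).hexdigest()


def _anova_block(values: np.ndarray, groups: np.ndarray) -> dict:
    present = [g for g in range(4) if (groups == g).sum() >= 2]
    samples = [values[groups == g] for g in present]
    res = stats.one_way_anova(samples)
    tukey = stats.tukey_hsd(samples)
    return {
        "F": res.F, "df": [res.df_between, res.df_within], "p": res.p,
        "group_summaries": {
            str(g): {"mean": float(s.mean()), "se": float(s.std(ddof=1) / np.sqrt(len(s))),
                     "n": int(len(s))}
            for g, s in zip(present, samples)
        },
        "tukey_p": {f"{present[i]}crit_vs_{present[j]}crit": p for (i, j), p in tukey.items()},
    }


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Run the full cohort simulation, screening and statistics chain.

    Writes ``traits.csv``, ``sessions.csv``, ``criteria.csv``,
    ``screening.csv``, ``choice.csv``, ``epm.csv``, ``bal.csv``,
    ``cohort_config.yaml``, ``stats_report.json`` and ``report.txt`` under
    ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "version": __version__,
    }
    root = np.random.SeedSequence(config.seed)
    keys = ("traits", "scores", "sessions", "choice", "epm", "bal")
    rngs = dict(zip(keys, map(np.random.default_rng, root.spawn(len(keys)))))

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 -- re-labelled, not swallowed
            raise PipelineError(name, exc) from exc
        rows = len(result) if hasattr(result, "__len__") else "-"
        log.info("stage %-10s done (%s rows)", name, rows)
        return result

    trait_cfg = config.cohort
    traits = stage("simulate", cohort.sample_latent_traits, trait_cfg, rng=rngs["traits"])
    scores_true = stage("simulate", cohort.simulate_criterion_scores, traits, trait_cfg,
                        rng=rngs["scores"])
    sessions = stage("simulate", cohort.simulate_sessions, traits, scores_true,
                     config.sessions, rng=rngs["sessions"])
    choice = stage("simulate", cohort.simulate_choice, traits, config=config.choice,
                   rng=rngs["choice"])
    epm = stage("simulate", cohort.simulate_epm, traits, config.epm, rng=rngs["epm"])

    criteria = stage("screen", screening.criterion_scores_from_sessions, sessions)
    result = stage("screen", screening.screen, criteria, config.screening)
    result = criteria[["rat_id"]].merge(result, on="rat_id")

    # BAL assay on a subset: first n_resilient resilient and n_vulnerable
    # vulnerable rats in id order, mirroring the reference subset design.
    merged = traits.merge(result[["rat_id", "group"]], on="rat_id")
    subset = pd.concat([
        merged[merged["group"] == "resilient"].head(config.bal.n_resilient),
        merged[merged["group"] == "vulnerable"].head(config.bal.n_vulnerable),
    ])
    bal = stage("simulate", cohort.simulate_bal, subset, config.bal, rng=rngs["bal"])

    report = stage("analyze", _analyze, result, criteria, choice, epm, bal, merged, config)

    stage("write", tcio.write_table, traits, out / "traits.csv", provenance)
    stage("write", tcio.write_sessions, sessions, out / "sessions.csv", provenance)
    stage("write", tcio.write_table, criteria, out / "criteria.csv", provenance)
    stage("write", tcio.write_table, result, out / "screening.csv", provenance)
    stage("write", tcio.write_table, choice, out / "choice.csv", provenance)
    stage("write", tcio.write_table, epm, out / "epm.csv", provenance)
    stage("write", tcio.write_table, bal, out / "bal.csv", provenance)
    dump_config(config, out / "cohort_config.yaml")
    report_with_prov = {"provenance": provenance, **report}
    (out / "stats_report.json").write_text(json.dumps(report_with_prov, indent=2, sort_keys=True),
                                           encoding="utf-8")
    (out / "report.txt").write_text(format_report(report_with_prov), encoding="utf-8")
    return ResultBundle(result, criteria, report, provenance)


def _analyze(result, criteria, choice, epm, bal, merged, config: RunConfig) -> dict:
    values = criteria.merge(result[["rat_id", "n_criteria", "addiction_score", "group"]],
                            on="rat_id")
    nc = values["n_criteria"].to_numpy()
    report: dict = {"units": {"bal": "g/kg"}}

    dist = screening.criterion_count_distribution(result)
    report["criterion_count_distribution"] = dist.to_dict(orient="list")

    for name in ("persistence", "breakpoint", "punished", "addiction_score"):
        report[f"anova_{name}"] = _anova_block(values[name].to_numpy(dtype=float), nc)

    report["score_criterion_correlations"] = {
        crit: dict(zip(("r", "p"), stats.pearson_r(values[crit], values["addiction_score"])))
        for crit in screening.CRITERIA
    }
    R = stats.pearson_correlation_matrix(values[list(screening.CRITERIA)])
    sol = stats.extract_single_factor(R)
    report["factor_analysis"] = {
        "correlation_matrix": np.round(R, 6).tolist(),
        "eigenvalues": list(sol.eigenvalues),
        "loadings": list(sol.loadings),
        "variance_pct": 100.0 * sol.variance_fraction,
        "n_retained": sol.n_retained,
    }

    epm_obs = epm.merge(values[["rat_id", "group"]], on="rat_id").dropna(subset=["open_arm_pct"])
    t, df, p = stats.unpaired_t(
        epm_obs.loc[epm_obs["group"] == "resilient", "open_arm_pct"],
        epm_obs.loc[epm_obs["group"] == "vulnerable", "open_arm_pct"],
    )
    report["epm_t_test"] = {
        "t": t, "df": df, "p": p,
        "group_means": epm_obs.groupby("group")["open_arm_pct"].mean().to_dict(),
        "n_observed": int(len(epm_obs)),
    }

    choice_full = choice.merge(values[["rat_id", "group"]], on="rat_id")
    defined = choice_full[choice_full["preference_defined"]]
    report["choice_mixed_anova"] = stats.mixed_rm_anova(
        defined.rename(columns={"saccharine_conc_pct_wv": "level",
                                "preference_pct": "value", "rat_id": "subject"}),
        dv="value", between="group", within="level", subject="subject",
    )
    water = defined[defined["saccharine_conc_pct_wv"] == 0.0].merge(
        values[["rat_id", "addiction_score"]], on="rat_id")
    r, p = stats.pearson_r(water["addiction_score"], water["preference_pct"])
    report["score_water_choice_correlation"] = {"r": r, "p": p}

    bal_full = bal.merge(values[["rat_id", "group"]], on="rat_id")
    report["bal_mixed_anova"] = stats.mixed_rm_anova(
        bal_full.rename(columns={"time_min": "level", "bal_g_per_kg": "value",
                                 "rat_id": "subject"}),
        dv="value", between="group", within="level", subject="subject",
        contrasts=False,
    )
    return report


def _fmt_p(p: float) -> str:
    return "< 0.0001" if p < 0.0001 else f"= {p:.4f}"


def format_report(report: dict) -> str:
    """Render the stats report as plain text mirroring a Results section."""
    lines = []
    prov = report.get("provenance", {})
    if prov:
        lines += [f"threecrit {prov.get('version', '?')} | seed {prov.get('seed', '?')} "
                  f"| config {str(prov.get('config_hash', ''))[:12]}", ""]
    dist = report["criterion_count_distribution"]
    total = sum(dist["count"])
    parts = [f"{c} rats with {k} criteria ({p}%)"
             for k, c, p in zip(dist["n_criteria"], dist["count"], dist["percent"])]
    lines += [f"Of the total {total} rats: " + ", ".join(parts) + ".", ""]
    titles = {
        "anova_persistence": "Persistence in lever pressing during the no-drug period",
        "anova_breakpoint": "Motivation: progressive-ratio breakpoint",
        "anova_punished": "Resistance to punishment",
        "anova_addiction_score": "Addiction score",
    }
    for key, title in titles.items():
        blk = report[key]
        means = ", ".join(
            f"{s['mean']:.2f} +/- {s['se']:.2f} ({g}crit)"
            for g, s in sorted(blk["group_summaries"].items())
        )
        lines += [title, f"  Group means: {means}",
                  f"  One-way ANOVA: F({blk['df'][0]},{blk['df'][1]}) = {blk['F']:.3f}, "
                  f"p {_fmt_p(blk['p'])}", ""]
    fa = report["factor_analysis"]
    lines += ["Factor analysis (eigenvalue-1 rule)",
              "  Loadings: " + ", ".join(f"{l:.3f}" for l in fa["loadings"])
              + f"; variance {fa['variance_pct']:.0f}%; factors retained: {fa['n_retained']}", ""]
    epm = report["epm_t_test"]
    lines += ["Elevated plus maze (open-arm %)",
              f"  t({epm['df']}) = {epm['t']:.2f}, p {_fmt_p(epm['p'])} "
              f"(n = {epm['n_observed']} observed)", ""]
    cma = report["choice_mixed_anova"]
    lines += ["Two-choice (ethanol vs saccharine), mixed RM ANOVA",
              f"  group F({cma['between']['df1']},{cma['between']['df2']}) = "
              f"{cma['between']['F']:.2f}, p {_fmt_p(cma['between']['p'])}; "
              f"fading F({cma['within']['df1']},{cma['within']['df2']}) = "
              f"{cma['within']['F']:.2f}, p {_fmt_p(cma['within']['p'])}", ""]
    bma = report["bal_mixed_anova"]
    lines += ["Blood alcohol levels (g/kg), mixed RM ANOVA",
              f"  time F({bma['within']['df1']},{bma['within']['df2']}) = "
              f"{bma['within']['F']:.2f}, p {_fmt_p(bma['within']['p'])}; "
              f"group F({bma['between']['df1']},{bma['between']['df2']}) = "
              f"{bma['between']['F']:.2f}, p {_fmt_p(bma['between']['p'])}", ""]
    return "\n".join(lines)
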