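"""Published summary statistics of the reference 59-rat cohort.

The screening procedure this package implements was established on a single
cohort of 59 outbred male Wistar rats trained to self-administer 10% w/v
ethanol for 80 sessions and then screened on three addiction-like criteria.
No raw data were deposited; what survives are the printed summary tables.
This module records those numbers verbatim, as package data: they are the
calibration anchors for the synthetic cohort generator and the inputs to
the summary-statistic reconstruction routines
(:func:`threecrit.stats.anova_from_summary`,
:func:`threecrit.stats.unpaired_t_from_summary`).

Group labels 0crit..3crit refer to the number of addiction-like criteria a
rat met; groups R (resilient) and V (vulnerable) pool 0-1 and 2-3 criteria.
"""

from __future__ import annotations

from .stats import GroupSummary

#: Number of rats in the reference cohort.
N_RATS = 59

#: Rats per criterion-count group (0, 1, 2, 3 criteria).
GROUP_SIZES = (25, 14, 13, 7)

#: Percentile window for criterion positivity.
LOWER_PERCENTILE = 66.0
UPPER_PERCENTILE = 99.0

#: Canonical criterion order used everywhere in this package.
CRITERIA = ("persistence", "breakpoint", "punished")

#: Mean +/- SE lever presses during signaled no-drug periods, by group.
PERSISTENCE_SUMMARIES = tuple(
    GroupSummary(mean=m, se=s, n=n)
    for m, s, n in zip((5.07, 7.78, 11.28, 16.04), (0.55, 0.92, 1.6, 1.17), GROUP_SIZES)
)

#: Mean +/- SE progressive-ratio breakpoint, by group.
BREAKPOINT_SUMMARIES = tuple(
    GroupSummary(mean=m, se=s, n=n)
    for m, s, n in zip((23.17, 34.19, 48.2, 46.09), (1.76, 3.65, 2.24, 2.90), GROUP_SIZES)
)

#: Mean +/- SE lever presses under footshock punishment, by group.
PUNISHED_SUMMARIES = tuple(
    GroupSummary(mean=m, se=s, n=n)
    for m, s, n in zip((7.17, 11.93, 16.44, 24.62), (0.5, 2.53, 2.33, 3.99), GROUP_SIZES)
)

#: Mean +/- SE addiction score (z-sum), by group.
ADDICTION_SCORE_SUMMARIES = tuple(
    GroupSummary(mean=m, se=s, n=n)
    for m, s, n in zip((-1.96, -0.15, 1.98, 3.64), (0.2, 0.25, 0.26, 0.6), GROUP_SIZES)
)

#: One-way ANOVA F statistics printed for the four measures above (df 3, 55).
F_PERSISTENCE = 18.345
F_BREAKPOINT = 22.217
F_PUNISHED = 12.53
F_ADDICTION_SCORE = 71.33

#: Pearson correlations between each criterion and the addiction score.
SCORE_CRITERION_CORRELATIONS = (0.794, 0.818, 0.641)

#: Printed single-factor loadings and the variance they account for.
FACTOR_LOADINGS = (0.819, 0.818, 0.641)
FACTOR_VARIANCE_PCT = 58.0

#: Elevated-plus-maze open-arm time (% of 5 min), resilient then vulnerable.
#: Eight of the 59 rats were lost to a technical failure, leaving 51.
EPM_RESILIENT = GroupSummary(mean=30.36, se=4.58, n=35)
EPM_VULNERABLE = GroupSummary(mean=11.99, se=2.34, n=16)
EPM_T = 2.65
EPM_DF = 49
EPM_DROPOUT = 8

#: Saccharine fading ladder for the two-lever choice test (% w/v).
SACCHARINE_LADDER = (0.2, 0.1, 0.05, 0.025, 0.0125, 0.00625, 0.0)

#: Blood-alcohol sampling design: 1 g/kg oral gavage, four sample times.
BAL_DOSE_G_PER_KG = 1.0
BAL_SAMPLE_TIMES_MIN = (15.0, 30.0, 60.0, 180.0)
BAL_GROUP_SIZES = (12, 7)  # resilient, vulnerable subset

#: Printed progressive-ratio requirement sequence (first 16 rewards).
PR_SEQUENCE_16 = (1, 2, 4, 6, 9, 12, 15, 20, 25, 32, 40, 50, 62, 77, 95, 118)
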