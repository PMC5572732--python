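"""Factor extraction, ANOVA (raw and summary), post hocs, t, r, mixed RM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import threecrit as tc
from threecrit import reference


class TestCorrelationMatrix:
    def test_collinear_columns(self):
        x = np.arange(10.0)
        R = tc.pearson_correlation_matrix(np.column_stack([x, 2 * x + 1, x]))
        np.testing.assert_allclose(R, 1.0)

    def test_zero_variance_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5], "c": [1.0, 0, 2]})
        with pytest.raises(ValueError, match="b"):
            tc.pearson_correlation_matrix(df)

    def test_independent_columns_near_zero(self, rng):
        x = rng.standard_normal((100_000, 3))
        R = tc.pearson_correlation_matrix(x)
        assert np.all(np.abs(R[np.triu_indices(3, 1)]) < 0.01)


class TestFactorExtraction:
    def test_identity_matrix_boundary(self):
        sol = tc.extract_single_factor(np.eye(3))
        np.testing.assert_allclose(sol.eigenvalues, (1.0, 1.0, 1.0))
        assert sol.variance_fraction == pytest.approx(1 / 3)
        assert sol.n_retained == 3  # ties at exactly 1.0 are retained

    def test_equicorrelation_exact_solution(self):
        # R = (1-a) I + a J has top eigenvalue 1 + 2a, eigenvector (1,1,1)/sqrt(3)
        a = 0.64
        R = np.full((3, 3), a)
        np.fill_diagonal(R, 1.0)
        sol = tc.extract_single_factor(R)
        assert sol.eigenvalues[0] == pytest.approx(1 + 2 * a)
        np.testing.assert_allclose(sol.loadings, np.sqrt((1 + 2 * a) / 3), atol=1e-12)
        assert sol.n_retained == 1

    def test_reference_implied_matrix(self):
        """The implied criterion matrix yields one factor near 58% variance."""
        R = tc.implied_criterion_correlations(reference.SCORE_CRITERION_CORRELATIONS)
        sol = tc.extract_single_factor(R)
        assert sol.eigenvalues[0] == pytest.approx(1.729, abs=0.005)
        assert sol.variance_fraction == pytest.approx(0.576, abs=0.005)
        assert sol.n_retained == 1
        assert sum(sol.eigenvalues) == pytest.approx(3.0, abs=1e-9)

    def test_variance_identity_on_own_loadings(self, rng):
        x = rng.standard_normal((50, 3)) @ rng.standard_normal((3, 3))
        R = tc.pearson_correlation_matrix(x)
        sol = tc.extract_single_factor(R)
        assert tc.variance_from_loadings(sol.loadings) == pytest.approx(
            100 * sol.eigenvalues[0] / 3, abs=1e-9)

    def test_non_psd_rejected(self):
        R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="positive semidefinite"):
            tc.extract_single_factor(R)

    def test_variance_from_loadings_cases(self):
        assert tc.variance_from_loadings(reference.FACTOR_LOADINGS, ndigits=0) == 58.0
        assert tc.variance_from_loadings((1, 1, 1)) == 100.0
        assert tc.variance_from_loadings((0, 0, 0)) == 0.0
        with pytest.raises(ValueError):
            tc.variance_from_loadings((1.2, 0.5, 0.5))


class TestOneWayAnova:
    def test_identical_means_give_zero_F(self):
        res = tc.one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.F == 0.0

    def test_two_groups_F_is_t_squared(self, rng):
        x, y = rng.normal(0, 1, 12), rng.normal(0.4, 1, 9)
        res = tc.one_way_anova([x, y])
        t, _, p = tc.unpaired_t(x, y)
        assert res.F == pytest.approx(t**2, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_hand_decomposition(self):
        # groups {1,2,3}, {2,3,4}: SSb = 1.5, MSw = 1 -> F = 1.5 on (1, 4)
        res = tc.one_way_anova([[1, 2, 3], [2, 3, 4]])
        assert res.F == pytest.approx(1.5)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_matches_scipy(self, rng):
        groups = [rng.normal(m, 1.0, size=n) for m, n in ((0, 8), (0.5, 12), (1.0, 6))]
        res = tc.one_way_anova(groups)
        F, p = sps.f_oneway(*groups)
        assert res.F == pytest.approx(F, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)


class TestAnovaFromSummary:
    @pytest.mark.parametrize("summaries, printed_F", [
        (reference.PERSISTENCE_SUMMARIES, reference.F_PERSISTENCE),
        (reference.BREAKPOINT_SUMMARIES, reference.F_BREAKPOINT),
        (reference.PUNISHED_SUMMARIES, reference.F_PUNISHED),
        (reference.ADDICTION_SCORE_SUMMARIES, reference.F_ADDICTION_SCORE),
    ])
    def test_reference_reconstructions(self, summaries, printed_F):
        """Printed group summaries reproduce the printed F (rounding-limited)."""
        res = tc.anova_from_summary(summaries)
        assert (res.df_between, res.df_within) == (3, 55)
        assert res.F == pytest.approx(printed_F, rel=0.015)
        assert res.p < 0.0001

    def test_round_trip_equals_raw_anova(self, rng):
        groups = [rng.normal(m, 2.0, size=n) for m, n in ((0, 7), (1, 11), (3, 5))]
        summaries = [
            tc.GroupSummary(mean=float(g.mean()),
                            se=float(g.std(ddof=1) / np.sqrt(len(g))), n=len(g))
            for g in groups
        ]
        raw, rec = tc.one_way_anova(groups), tc.anova_from_summary(summaries)
        assert rec.F == pytest.approx(raw.F, rel=1e-10)
        assert rec.ms_within == pytest.approx(raw.ms_within, rel=1e-10)

    def test_equal_means_give_zero_F(self):
        res = tc.anova_from_summary([tc.GroupSummary(5.0, 1.0, 10)] * 3)
        assert res.F == 0.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            tc.GroupSummary(mean=1.0, se=0.5, n=1)


class TestTukey:
    def test_identical_groups_p_one(self):
        p = tc.tukey_hsd([[1.0, 2, 3, 4], [1.0, 2, 3, 4]])
        assert p[(0, 1)] == pytest.approx(1.0, abs=1e-9)

    def test_two_groups_equals_pooled_t(self, rng):
        x, y = rng.normal(0, 1, 9), rng.normal(0.8, 1, 14)
        p_tukey = tc.tukey_hsd([x, y])[(0, 1)]
        _, _, p_t = tc.unpaired_t(x, y)
        assert p_tukey == pytest.approx(p_t, abs=1e-9)

    def test_unequal_n_matches_statsmodels(self, rng):
        """Tukey-Kramer p-values agree with an independent implementation."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = [rng.normal(m, 1.5, size=n) for m, n in ((0, 6), (1.2, 10), (2.0, 7))]
        ours = tc.tukey_hsd(groups)
        values = np.concatenate(groups)
        labels = np.repeat([0, 1, 2], [len(g) for g in groups])
        sm = pairwise_tukeyhsd(values, labels)
        for (i, j), p_sm in zip(((0, 1), (0, 2), (1, 2)), sm.pvalues):
            assert ours[(i, j)] == pytest.approx(p_sm, abs=1e-6)


class TestUnpairedT:
    def test_equal_means_zero_t(self):
        t, df, p = tc.unpaired_t([1.0, 1.0, 1.0], [1.0, 1.0])
        assert (t, p) == (0.0, 1.0) and df == 3

    def test_hand_case(self):
        # means 1 vs 0, sd 1, n=2 per group: t = 1 on df 2
        h = 1 / np.sqrt(2)  # two points m +/- h have sample SD 1
        t, df, _ = tc.unpaired_t([1 - h, 1 + h], [-h, h])
        assert t == pytest.approx(1.0) and df == 2

    def test_epm_summary_reconstruction(self):
        t, df, p = tc.unpaired_t_from_summary(reference.EPM_RESILIENT,
                                              reference.EPM_VULNERABLE)
        assert df == reference.EPM_DF
        assert t == pytest.approx(reference.EPM_T, rel=0.01)
        assert p == pytest.approx(0.0106, abs=0.002)

    def test_degenerate_unequal_means_rejected(self):
        with pytest.raises(ValueError, match="zero pooled variance"):
            tc.unpaired_t([1.0, 1.0], [2.0, 2.0])


class TestPearsonR:
    def test_exact_lines(self):
        x = np.arange(5.0)
        assert tc.pearson_r(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert tc.pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_closed_form_p_for_half_correlation(self):
        # engineered sample with r exactly 0.5 at n=10:
        # t = 0.5 sqrt(8 / 0.75) = 1.633, two-tailed p ~ 0.141
        rng = np.random.default_rng(3)
        x = rng.standard_normal(10)
        e = rng.standard_normal(10)
        xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
        ec = e - e.mean() - (e - e.mean()) @ xc * xc
        y = 0.5 * xc + np.sqrt(0.75) * ec / np.linalg.norm(ec)
        r, p = tc.pearson_r(x, y)
        assert r == pytest.approx(0.5, abs=1e-12)
        t = r * np.sqrt(8 / (1 - r**2))
        assert t == pytest.approx(1.633, abs=1e-3)
        assert p == pytest.approx(2 * sps.t.sf(t, 8), rel=1e-9)
        assert p == pytest.approx(0.141, abs=0.001)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            tc.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _split_plot_oracle(df):
    """Hand split-plot decomposition for a balanced 2-group mixed design."""
    groups = sorted(df["group"].unique())
    levels = sorted(df["level"].unique())
    subjects = df["subject"].unique()
    N, p = len(subjects), len(levels)
    grand = df["value"].mean()
    subj_means = df.groupby("subject", observed=True)["value"].mean()
    grp_of = df.groupby("subject", observed=True)["group"].first()
    grp_means = df.groupby("group", observed=True)["value"].mean()
    lev_means = df.groupby("level", observed=True)["value"].mean()
    cell = df.groupby(["group", "level"], observed=True)["value"].mean()
    n_per_group = grp_of.value_counts()
    ss_a = p * sum(n_per_group[g] * (grp_means[g] - grand) ** 2 for g in groups)
    ss_subj = p * sum((subj_means[s] - grp_means[grp_of[s]]) ** 2 for s in subjects)
    ss_b = N * sum((lev_means[l] - grand) ** 2 for l in levels)
    ss_ab = sum(n_per_group[g] * (cell[g, l] - grp_means[g] - lev_means[l] + grand) ** 2
                for g in groups for l in levels)
    ss_tot = ((df["value"] - grand) ** 2).sum()
    ss_err = ss_tot - ss_a - ss_subj - ss_b - ss_ab
    df_a, df_subj = len(groups) - 1, N - len(groups)
    df_b = p - 1
    df_ab, df_err = df_a * df_b, df_subj * df_b
    return {
        "between": ss_a / df_a / (ss_subj / df_subj),
        "within": ss_b / df_b / (ss_err / df_err),
        "interaction": ss_ab / df_ab / (ss_err / df_err),
    }


class TestMixedRmAnova:
    @staticmethod
    def _frame(rng, n1=6, n2=5, p=4, group_shift=0.0):
        rows = []
        for s in range(n1 + n2):
            grp = "A" if s < n1 else "B"
            base = rng.normal()
            for l in range(p):
                val = base + 0.3 * l + rng.normal()
                if grp == "B":
                    val += group_shift
                rows.append({"subject": f"s{s}", "group": grp, "level": l, "value": val})
        return pd.DataFrame(rows)

    def test_matches_hand_decomposition(self, rng):
        df = self._frame(rng, group_shift=0.7)
        res = tc.mixed_rm_anova(df, dv="value", between="group", within="level",
                                subject="subject")
        oracle = _split_plot_oracle(df)
        for effect in ("between", "within", "interaction"):
            assert res[effect]["F"] == pytest.approx(oracle[effect], rel=1e-6), effect

    def test_additive_group_constant_zero_noise(self):
        rows = [
            {"subject": f"s{s}", "group": "A" if s < 4 else "B", "level": l,
             "value": float(l) + (5.0 if s >= 4 else 0.0)}
            for s in range(8) for l in range(3)
        ]
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            res = tc.mixed_rm_anova(pd.DataFrame(rows), dv="value", between="group",
                                    within="level", subject="subject", contrasts=False)
        # no subject noise: between F explodes, interaction vanishes
        assert res["between"]["F"] == np.inf
        assert res["interaction"]["F"] == pytest.approx(0.0, abs=1e-9)

    def test_null_Fs_near_one(self, rng):
        means = {k: [] for k in ("between", "within", "interaction")}
        for _ in range(150):
            df = self._frame(rng)
            df["value"] = rng.standard_normal(len(df))  # pure noise
            res = tc.mixed_rm_anova(df, dv="value", between="group", within="level",
                                    subject="subject", contrasts=False)
            for k in means:
                means[k].append(res[k]["F"])
        for k, v in means.items():
            assert 0.6 < np.mean(v) < 1.6, k

    def test_unbalanced_design_rejected(self, rng):
        df = self._frame(rng).iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            tc.mixed_rm_anova(df, dv="value", between="group", within="level",
                              subject="subject")

    def test_bal_null_group_effect_type_I(self):
        """With no group effect, the BAL group test is null-calibrated."""
        rng = np.random.default_rng(17)
        cfg = tc.BALConfig(group_effect=0.0)
        nonsig = 0
        reps = 300
        for _ in range(reps):
            traits = pd.DataFrame({
                "rat_id": [f"r{i}" for i in range(19)],
                "liability": rng.standard_normal(19),
            })
            bal = tc.simulate_bal(traits, cfg, rng=rng)
            bal["group"] = np.where(
                bal["rat_id"].str[1:].astype(int) < 12, "R", "V")
            res = tc.mixed_rm_anova(
                bal.rename(columns={"time_min": "level", "bal_g_per_kg": "value",
                                    "rat_id": "subject"}),
                dv="value", between="group", within="level", subject="subject",
                contrasts=False)
            nonsig += res["between"]["p"] > 0.05
        # true rate >= 94%, asserted with a two-sigma Monte-Carlo allowance
        # for 300 replicates (2 * sqrt(0.94 * 0.06 / 300) ~ 0.027)
        assert nonsig / reps >= 0.94 - 0.03
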