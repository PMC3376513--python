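import math

import numpy as np
import pytest
from scipy import stats

from stepadvice import (
    GroupSummary,
    ParticipantRecord,
    TableVariable,
    TrialDataset,
    ValidationError,
    build_anova_table,
    build_comparison_table,
    chi_square,
    format_table,
    intent_to_treat,
    log_transform_outcome,
    mixed_anova,
    proportion,
    read_cohort_csv,
    welch_t,
    write_cohort_csv,
)
from stepadvice.trialstats import OUTCOMES


def make_dataset(tailored, standard, outcome="steps", dropout_post_missing=()):
    """Build a steps-only dataset from per-arm (base, post) pairs."""
    records = []
    for cond, pairs in (("tailored", tailored), ("standard", standard)):
        for i, (base, post) in enumerate(pairs):
            missing = (cond, i) in dropout_post_missing or post is None
            outcomes = {outcome: (base, None if missing else post)}
            records.append(
                ParticipantRecord(
                    id=f"{cond}-{i}",
                    condition=cond,
                    dropout=missing,
                    outcomes=outcomes,
                )
            )
    return TrialDataset(records=tuple(records))


class TestWelchT:
    def test_identical_summaries_give_zero(self):
        g = GroupSummary(20, 50.0, 5.0)
        res = welch_t(g, g)
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_sign_flips_under_group_swap(self):
        a, b = GroupSummary(30, 7690, 2416), GroupSummary(13, 10_730, 4319)
        fwd, rev = welch_t(a, b), welch_t(b, a)
        assert fwd.statistic == pytest.approx(-rev.statistic)
        assert fwd.df == pytest.approx(rev.df)
        assert fwd.p == pytest.approx(rev.p)

    def test_matches_scipy_from_stats(self):
        a, b = GroupSummary(45, 46.6, 10.9), GroupSummary(47, 47.7, 11.4)
        ours = welch_t(a, b)
        ref = stats.ttest_ind_from_stats(
            a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=False
        )
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue)

    def test_pooled_variant_uses_classic_df(self):
        a, b = GroupSummary(30, 7690, 2416), GroupSummary(13, 10_730, 4319)
        pooled = welch_t(a, b, pooled=True)
        assert pooled.df == 41
        ref = stats.ttest_ind_from_stats(
            a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
        )
        assert pooled.statistic == pytest.approx(ref.statistic)

    def test_degenerate_zero_variance(self):
        res = welch_t(GroupSummary(5, 3.0, 0.0), GroupSummary(5, 3.0, 0.0))
        assert res.statistic == 0.0
        with pytest.raises(ValidationError):
            GroupSummary(1, 3.0, 0.0)

    def test_p_monotone_in_statistic_at_fixed_df(self):
        ps = [2 * stats.t.sf(t, 20) for t in (0.5, 1.0, 2.0, 3.0)]
        assert ps == sorted(ps, reverse=True)


class TestChiSquare:
    def test_equal_proportions_give_zero(self):
        res = chi_square([[10, 20], [10, 20]])
        assert res.statistic == pytest.approx(0.0)

    def test_invariant_under_permutation(self):
        table = np.array([[23, 19], [11, 8], [9, 15]])
        base = chi_square(table)
        assert chi_square(table[::-1]).statistic == pytest.approx(base.statistic)
        assert chi_square(table[:, ::-1]).statistic == pytest.approx(base.statistic)
        assert chi_square(table.T).statistic == pytest.approx(base.statistic)

    def test_2x2_equals_squared_two_proportion_z(self):
        # independent oracle: z test for two proportions, chi2 = z^2
        table = np.array([[170, 280], [210, 260]], dtype=float)
        n1, n2 = table[0].sum(), table[1].sum()
        p1, p2 = table[0, 0] / n1, table[1, 0] / n2
        p_pool = (table[0, 0] + table[1, 0]) / (n1 + n2)
        z = (p1 - p2) / math.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
        assert chi_square(table).statistic == pytest.approx(z**2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError, match="margin"):
            chi_square([[0, 0], [5, 3]])
        with pytest.raises(ValidationError):
            chi_square([[1, 2]])
        with pytest.raises(ValidationError):
            chi_square([[-1, 2], [3, 4]])


class TestLogTransform:
    def test_zero_maps_to_zero_with_unit_offset(self):
        assert log_transform_outcome([0.0])[0] == 0.0

    def test_round_trip(self):
        vals = np.array([0.0, 12.5, 163.6])
        back = np.exp(log_transform_outcome(vals)) - 1
        assert back == pytest.approx(vals)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            log_transform_outcome([-1.0])


class TestMixedAnova:
    def test_identical_changes_give_zero_interaction(self):
        ds = make_dataset(
            tailored=[(8000, 9000), (7000, 8000), (9000, 10_000)],
            standard=[(8500, 9500), (7700, 8700), (6000, 7000)],
        )
        res = mixed_anova(ds, "steps")
        assert res.f_interaction == pytest.approx(0.0)
        assert res.f_time > 0

    def test_no_change_gives_zero_time_effect(self):
        ds = make_dataset(
            tailored=[(8000, 8000), (7000, 7000)],
            standard=[(9000, 9000), (6000, 6000)],
        )
        res = mixed_anova(ds, "steps")
        assert res.f_time == pytest.approx(0.0)
        assert res.f_interaction == pytest.approx(0.0)

    @staticmethod
    def _brute_force_ss(groups):
        """Textbook sums-of-squares decomposition for balanced groups x (2 times)."""
        y = np.array(groups, dtype=float)  # (G, n, 2)
        G, n, T = y.shape
        N = G * n
        grand = y.mean()
        time_means = y.mean(axis=(0, 1))
        group_means = y.mean(axis=(1, 2))
        cell_means = y.mean(axis=1)  # (G, T)
        subj_means = y.mean(axis=2)  # (G, n)
        ss_time = N * ((time_means - grand) ** 2).sum()
        ss_int = n * (
            (cell_means - group_means[:, None] - time_means[None, :] + grand) ** 2
        ).sum()
        ss_err = (
            (
                y
                - subj_means[:, :, None]
                - cell_means[:, None, :]
                + group_means[:, None, None]
            )
            ** 2
        ).sum()
        df_err = N - G
        return (
            ss_time / (ss_err / df_err),
            ss_int / (ss_err / df_err),
            ss_time,
            ss_int,
            ss_err,
        )

    def test_matches_brute_force_decomposition_on_random_balanced_data(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(3, 12))
            t_arm = rng.normal(100, 15, size=(n, 2))
            s_arm = rng.normal(90, 20, size=(n, 2))
            ds = make_dataset(tailored=t_arm.tolist(), standard=s_arm.tolist())
            res = mixed_anova(ds, "steps")
            f_time, f_int, ss_time, ss_int, ss_err = self._brute_force_ss(
                [t_arm, s_arm]
            )
            assert res.f_time == pytest.approx(f_time)
            assert res.f_interaction == pytest.approx(f_int)
            assert min(ss_time, ss_int, ss_err) >= 0

    def test_matches_pingouin_on_balanced_data(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        n = 12
        rows = []
        for cond in ("tailored", "standard"):
            for i in range(n):
                base, post = rng.normal(100, 15, size=2)
                rows += [
                    {"subject": f"{cond}{i}", "condition": cond, "time": "base", "y": base},
                    {"subject": f"{cond}{i}", "condition": cond, "time": "post", "y": post},
                ]
        long = pd.DataFrame(rows)
        ref = pg.mixed_anova(
            long, dv="y", within="time", subject="subject", between="condition"
        ).set_index("Source")

        def arm_pairs(cond):
            sub = long[long["condition"] == cond]
            wide = sub.pivot(index="subject", columns="time", values="y")
            return list(zip(wide["base"], wide["post"]))

        ds = make_dataset(tailored=arm_pairs("tailored"), standard=arm_pairs("standard"))
        res = mixed_anova(ds, "steps")
        assert res.f_time == pytest.approx(ref.loc["time", "F"], rel=1e-6)
        assert res.f_interaction == pytest.approx(ref.loc["Interaction", "F"], rel=1e-6)

    def test_interaction_equals_squared_pooled_t_on_change_scores(self):
        rng = np.random.default_rng(11)
        t_arm = rng.normal(0, 1, size=(9, 2))
        s_arm = rng.normal(0, 1, size=(14, 2))  # unbalanced on purpose
        ds = make_dataset(tailored=t_arm.tolist(), standard=s_arm.tolist())
        res = mixed_anova(ds, "steps")
        d1, d2 = t_arm[:, 1] - t_arm[:, 0], s_arm[:, 1] - s_arm[:, 0]
        t_ref = stats.ttest_ind(d1, d2, equal_var=True)
        assert res.f_interaction == pytest.approx(t_ref.statistic**2)
        assert res.p_interaction == pytest.approx(t_ref.pvalue)

    def test_change_ci_brackets_the_estimate(self):
        rng = np.random.default_rng(3)
        ds = make_dataset(
            tailored=rng.normal(9000, 2000, size=(10, 2)).tolist(),
            standard=rng.normal(9000, 2000, size=(10, 2)).tolist(),
        )
        res = mixed_anova(ds, "steps")
        for arm in res.arm_changes:
            assert arm.ci_low <= arm.change <= arm.ci_high
            # cross-check against scipy's one-sample t interval on change scores
            d = np.array(
                [
                    r.outcomes["steps"][1] - r.outcomes["steps"][0]
                    for r in ds.arm(arm.condition)
                ]
            )
            lo, hi = stats.t.interval(
                0.95, len(d) - 1, loc=d.mean(), scale=stats.sem(d)
            )
            assert arm.ci_low == pytest.approx(lo)
            assert arm.ci_high == pytest.approx(hi)

    def test_log_scale_analysis_reports_raw_changes(self):
        rng = np.random.default_rng(5)
        base = np.abs(rng.normal(40, 30, size=(12, 2)))
        ds = make_dataset(tailored=base.tolist(),
                          standard=np.abs(rng.normal(50, 30, size=(12, 2))).tolist(),
                          outcome="walking")
        raw = mixed_anova(ds, "walking", log_scale=False)
        logged = mixed_anova(ds, "walking", log_scale=True)
        # F statistics differ (different scale) but reported changes are raw
        assert logged.arm_changes == raw.arm_changes
        assert logged.f_time != pytest.approx(raw.f_time)

    def test_requires_two_per_arm(self):
        ds = make_dataset(
            tailored=[(8000, 9000), (7000, None)],
            standard=[(8500, 9500), (7700, 8700)],
        )
        with pytest.raises(ValidationError, match="fewer than 2"):
            mixed_anova(ds, "steps")


class TestIntentToTreat:
    def test_carries_baseline_forward(self):
        ds = make_dataset(
            tailored=[(8000, None), (7000, 9000)],
            standard=[(8500, 9500), (7700, 8700)],
        )
        itt = intent_to_treat(ds)
        rec = next(r for r in itt.records if r.id == "tailored-0")
        assert rec.outcomes["steps"] == (8000, 8000)
        assert rec.imputed
        completer = next(r for r in itt.records if r.id == "tailored-1")
        assert completer.outcomes["steps"] == (7000, 9000) and not completer.imputed

    def test_idempotent(self):
        ds = make_dataset(
            tailored=[(8000, None), (7000, 9000), (6500, None)],
            standard=[(8500, 9500), (7700, 8700)],
        )
        once = intent_to_treat(ds)
        assert intent_to_treat(once) == once

    def test_imputed_change_is_zero_downstream(self):
        ds = make_dataset(
            tailored=[(8000, None), (7000, 9000), (9000, 9100)],
            standard=[(8500, 9500), (7700, 8700)],
        )
        res = mixed_anova(intent_to_treat(ds), "steps")
        tail = next(a for a in res.arm_changes if a.condition == "tailored")
        # imputed participant contributes a change of exactly 0
        assert tail.change == pytest.approx((0 + 2000 + 100) / 3)

    def test_missing_baseline_lists_ids(self):
        ds = make_dataset(
            tailored=[(None, None), (7000, 9000)],
            standard=[(8500, 9500), (7700, 8700)],
        )
        with pytest.raises(ValidationError, match="tailored-0"):
            intent_to_treat(ds)


class TestProportion:
    @pytest.mark.parametrize(
        "num, den, expected, digits",
        [(107, 1737, 6.2, 1), (30, 43, 70, 0), (0, 50, 0, 0)],
    )
    def test_examples(self, num, den, expected, digits):
        assert round(proportion(num, den), digits) == expected

    def test_errors(self):
        with pytest.raises(ValidationError):
            proportion(1, 0)
        with pytest.raises(ValidationError):
            proportion(5, 4)


class TestTables:
    @pytest.fixture
    def cohort(self):
        from stepadvice import CohortSpec, generate_cohort

        return generate_cohort(CohortSpec(n_per_arm=20, rng_seed=9))

    def test_comparison_table_uses_correct_test_per_kind(self, cohort):
        df = cohort.to_dataframe()
        table = build_comparison_table(
            df,
            [
                TableVariable("Steps", "steps_base", "quantitative"),
                TableVariable("Dropped out", "dropout", "qualitative"),
            ],
        )
        assert list(table["variable"]) == ["Steps", "Dropped out"]
        assert table.loc[0, "test"].startswith("t(")
        assert table.loc[1, "test"].startswith("chi2(")
        assert ((table["p"] >= 0) & (table["p"] <= 1)).all()

    def test_anova_table_one_row_per_arm_per_outcome(self, cohort):
        table = build_anova_table(cohort, outcomes=("steps", "bmi"), itt=True)
        assert len(table) == 4
        assert set(table["condition"]) == {"tailored", "standard"}

    def test_unknown_column_rejected(self, cohort):
        with pytest.raises(ValidationError, match="unknown outcome column"):
            build_comparison_table(
                cohort.to_dataframe(), [TableVariable("x", "nope", "quantitative")]
            )

    def test_format_table(self, cohort):
        table = build_anova_table(cohort, outcomes=("steps",), itt=True)
        tsv = format_table(table, "tsv")
        md = format_table(table, "markdown")
        assert tsv.splitlines()[0].count("\t") == len(table.columns) - 1
        assert md.splitlines()[1].startswith("| ---")


class TestCohortCsv:
    def test_round_trip(self, tmp_path):
        from stepadvice import CohortSpec, generate_cohort

        ds = generate_cohort(CohortSpec(n_per_arm=10, rng_seed=4))
        path = tmp_path / "cohort.csv"
        write_cohort_csv(ds, path)
        back = read_cohort_csv(path)
        assert len(back.records) == len(ds.records)
        for a, b in zip(back.records, ds.records):
            assert a.id == b.id and a.condition == b.condition and a.dropout == b.dropout
            for out in OUTCOMES:
                for x, y in zip(a.outcomes[out], b.outcomes[out]):
                    if y is None:
                        assert x is None
                    else:
                        assert x == pytest.approx(y, rel=1e-5)

    def test_dropout_flag_requires_missing_post(self):
        with pytest.raises(ValidationError, match="dropout"):
            ParticipantRecord(
                id="x", condition="tailored", dropout=True,
                outcomes={"steps": (8000.0, 9000.0)},
            )
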