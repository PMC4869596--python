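"""ROI aggregation, t-tests, mixed ANOVA and the multi-density rule."""

import numpy as np
import pandas as pd
import pytest

from synchnet.groupstats import (
    degree_tmap,
    mixed_anova,
    multi_density_rule,
    paired_t,
    relative_change,
    roi_mean_degree,
    welch_t,
)


class TestROIAndRelativeChange:
    def test_uniform_degree(self):
        labels = ["a", "b", "c"]
        assert roi_mean_degree(np.array([2.0, 2.0, 2.0]), labels, ("a", "b")) == 2.0

    def test_hand_computed_mean(self):
        labels = [f"CH{i}" for i in range(5)]
        deg = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        assert roi_mean_degree(deg, labels, ("CH0", "CH2", "CH4")) == pytest.approx(
            (1 + 3 + 10) / 3
        )

    def test_all_nodes_roi(self):
        labels = ["a", "b"]
        deg = np.array([1.0, 5.0])
        assert roi_mean_degree(deg, labels, tuple(labels)) == 3.0

    def test_unknown_label(self):
        with pytest.raises(KeyError):
            roi_mean_degree(np.array([1.0]), ["a"], ("z",))

    def test_empty_roi(self):
        with pytest.raises(ValueError):
            roi_mean_degree(np.array([1.0]), ["a"], ())

    def test_relative_change_zero(self):
        assert relative_change(3.0, 3.0) == 0.0

    def test_symmetric_three_vs_one(self):
        # 100 * (3 - 1) / 2 = 100 under the symmetric convention
        assert relative_change(3.0, 1.0) == pytest.approx(100.0)

    def test_antisymmetry(self):
        assert relative_change(5.0, 2.0) == -relative_change(2.0, 5.0)

    def test_simple_mode(self):
        assert relative_change(3.0, 2.0, "simple") == pytest.approx(50.0)

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            relative_change(1.0, -1.0)


class TestTTests:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0]
        res = welch_t(x, list(x))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_welch_textbook_case(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 6.0, 8.0])
        # direct formula evaluation
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        se2 = vx / 4 + vy / 4
        t_direct = (x.mean() - y.mean()) / np.sqrt(se2)
        df_direct = se2**2 / ((vx / 4) ** 2 / 3 + (vy / 4) ** 2 / 3)
        res = welch_t(x, y)
        assert res.statistic == pytest.approx(t_direct, abs=1e-12)
        assert res.df == pytest.approx(df_direct, abs=1e-10)

    def test_welch_equals_student_for_equal_variance_sizes(self, rng):
        from scipy import stats

        x = rng.normal(size=30)
        y = rng.normal(size=30) + 0.5
        # enforce exactly equal sample variances by standardizing
        x = (x - x.mean()) / x.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1) + 0.5
        res = welch_t(x, y)
        student = stats.ttest_ind(x, y, equal_var=True)
        assert res.statistic == pytest.approx(student.statistic, abs=1e-12)
        assert res.df == pytest.approx(58.0)

    def test_welch_degenerate(self):
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            welch_t([1.0], [2.0, 3.0])

    def test_paired_identical_errors(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_paired_sign_matches_shift(self, rng):
        x = rng.normal(size=20)
        res = paired_t(x, x + 1.0 + rng.normal(scale=0.1, size=20))
        assert res.statistic < 0

    def test_paired_toy_matches_direct_formula(self):
        x = np.array([3.0, 5.0, 4.0, 6.0, 7.0])
        y = np.array([2.0, 6.0, 2.0, 5.0, 4.0])
        d = x - y
        t_direct = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        res = paired_t(x, y)
        assert res.statistic == pytest.approx(t_direct, abs=1e-12)
        assert res.df == 4


def _mixed_table(values: np.ndarray, groups: list[str]) -> pd.DataFrame:
    """values: (n_subjects, n_conditions); groups: per-subject labels."""
    rows = []
    for s, (row, grp) in enumerate(zip(values, groups)):
        for c, v in enumerate(row):
            rows.append(
                {
                    "subject": f"S{s:02d}",
                    "group": grp,
                    "condition": f"C{c}",
                    "value": float(v),
                }
            )
    return pd.DataFrame(rows)


def anova_oracle(values: np.ndarray, groups: list[str]):
    """From-scratch sums-of-squares decomposition for the 2-way mixed design."""
    groups = np.asarray(groups)
    n_s, n_c = values.shape
    labels = sorted(set(groups))
    grand = values.mean()
    subj_means = values.mean(axis=1)
    cond_means = values.mean(axis=0)
    ss_between_subj = n_c * ((subj_means - grand) ** 2).sum()
    ss_a = n_c * sum(
        (groups == g).sum() * (values[groups == g].mean() - grand) ** 2
        for g in labels
    )
    ss_subj = ss_between_subj - ss_a
    ss_t = n_s * ((cond_means - grand) ** 2).sum()
    ss_cells = sum(
        (groups == g).sum() * (values[groups == g, c].mean() - grand) ** 2
        for g in labels
        for c in range(n_c)
    )
    ss_at = ss_cells - ss_a - ss_t
    ss_total = ((values - grand) ** 2).sum()
    ss_err = ss_total - ss_between_subj - ss_t - ss_at
    a = len(labels)
    df = dict(a=a - 1, subj=n_s - a, t=n_c - 1, at=(a - 1) * (n_c - 1))
    df["err"] = df["subj"] * df["t"]
    f_task = (ss_t / df["t"]) / (ss_err / df["err"])
    f_age = (ss_a / df["a"]) / (ss_subj / df["subj"])
    f_int = (ss_at / df["at"]) / (ss_err / df["err"])
    return f_task, f_age, f_int


class TestMixedAnova:
    def test_all_equal_gives_zero_f(self):
        table = _mixed_table(np.full((6, 3), 2.0), ["g1"] * 3 + ["g2"] * 3)
        for res in mixed_anova(table):
            assert res.statistic == 0.0
            assert res.p_value == pytest.approx(1.0)

    def test_pure_group_offset(self, rng):
        base = rng.normal(size=(8, 1))
        values = np.tile(base, (1, 3))  # no condition effect at all
        values[4:] += 5.0  # strong group offset
        table = _mixed_table(values, ["g1"] * 4 + ["g2"] * 4)
        task, age, inter = mixed_anova(table)
        assert age.statistic > 10.0
        assert task.statistic == pytest.approx(0.0, abs=1e-20)
        assert inter.statistic == pytest.approx(0.0, abs=1e-20)

    def test_toy_dataset_matches_oracle(self, rng):
        values = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1))
        groups = ["g1"] * 4 + ["g2"] * 4
        table = _mixed_table(values, groups)
        task, age, inter = mixed_anova(table)
        f_task, f_age, f_int = anova_oracle(values, groups)
        assert task.statistic == pytest.approx(f_task, abs=1e-8)
        assert age.statistic == pytest.approx(f_age, abs=1e-8)
        assert inter.statistic == pytest.approx(f_int, abs=1e-8)
        assert task.df == (2.0, 12.0)
        assert age.df == (1.0, 6.0)

    def test_unbalanced_groups_match_oracle(self, rng):
        values = rng.normal(size=(9, 3))
        groups = ["g1"] * 5 + ["g2"] * 4
        table = _mixed_table(values, groups)
        task, age, inter = mixed_anova(table)
        f_task, f_age, f_int = anova_oracle(values, groups)
        assert task.statistic == pytest.approx(f_task, abs=1e-8)
        assert age.statistic == pytest.approx(f_age, abs=1e-8)
        assert inter.statistic == pytest.approx(f_int, abs=1e-8)

    def test_against_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        values = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1))
        groups = ["g1"] * 5 + ["g2"] * 5
        table = _mixed_table(values, groups)
        ours = {r.effect: r for r in mixed_anova(table)}
        ref = pingouin.mixed_anova(
            data=table, dv="value", within="condition",
            between="group", subject="subject",
        ).set_index("Source")
        assert ours["condition"].statistic == pytest.approx(
            ref.loc["condition", "F"], rel=1e-6
        )
        assert ours["group"].statistic == pytest.approx(
            ref.loc["group", "F"], rel=1e-6
        )
        assert ours["condition * group"].statistic == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6
        )

    def test_missing_cells_rejected(self):
        table = _mixed_table(np.ones((4, 3)), ["g1"] * 2 + ["g2"] * 2)
        with pytest.raises(ValueError):
            mixed_anova(table.iloc[:-1])


class TestMultiDensityRule:
    def test_three_of_seven_significant(self):
        assert multi_density_rule([0.01, 0.02, 0.04, 0.9, 0.9, 0.9, 0.9])

    def test_two_of_seven_not_significant(self):
        assert not multi_density_rule([0.01, 0.02, 0.9, 0.9, 0.9, 0.9, 0.9])

    def test_all_significant(self):
        assert multi_density_rule([0.01] * 7)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            multi_density_rule([])

    def test_monotone_in_p(self, rng):
        """Lowering any p never flips significant -> not significant."""
        for _ in range(200):
            ps = rng.uniform(size=7)
            before = multi_density_rule(ps)
            i = rng.integers(7)
            lowered = ps.copy()
            lowered[i] *= rng.uniform()
            after = multi_density_rule(lowered)
            assert after or not before


class TestDegreeTmap:
    def _degrees(self, rng, offset=0.0, n_sub=6, channels=("Fz", "Cz", "Pz")):
        rows = []
        for s in range(n_sub):
            for ch in channels:
                base = rng.normal()
                rows.append({"subject": f"S{s}", "condition": "Go",
                             "channel": ch, "degree": base})
                rows.append({"subject": f"S{s}", "condition": "NoGo",
                             "channel": ch,
                             "degree": base + offset + rng.normal(scale=0.1)})
        return pd.DataFrame(rows)

    def test_channel_count(self, rng):
        table = self._degrees(rng, channels=tuple(f"C{i}" for i in range(28)))
        out = degree_tmap(table, ("NoGo", "Go"))
        assert len(out) == 28

    def test_positive_shift_positive_t(self, rng):
        out = degree_tmap(self._degrees(rng, offset=3.0), ("NoGo", "Go"))
        assert (out["t"] > 0).all()

    def test_identical_conditions_degenerate_flagged(self):
        rows = []
        for s in range(4):
            for cond in ("Go", "NoGo"):
                rows.append({"subject": f"S{s}", "condition": cond,
                             "channel": "Cz", "degree": float(s)})
        out = degree_tmap(pd.DataFrame(rows), ("NoGo", "Go"))
        assert out["degenerate"].all()
        assert out["t"].isna().all()

    def test_missing_condition_errors(self, rng):
        table = self._degrees(rng)
        with pytest.raises(KeyError):
            degree_tmap(table, ("NoGo", "Baseline"))
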