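"""Mixed-factorial ANOVA, sphericity handling, Bonferroni and LSD.

The unbalanced-design fixture is checked against values computed
independently with R's car::Anova (Type III, sum-to-zero contrasts) on the
identical data; the balanced fixture against a from-scratch cell-means
split-plot decomposition written in this file.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scanstab import (
    CompleteCaseMatrix,
    ConfigurationError,
    DegenerateDataError,
    MeasurementTable,
    apply_gg_if_violated,
    bonferroni_family,
    gg_epsilon,
    lsd_site_comparison,
    mauchly_test,
    mean_squares,
    mixed_anova,
)
from scanstab.anova import EffectResult, MixedAnovaResult

from conftest import long_records


def make_ccm(y, groups):
    y = np.asarray(y, dtype=float)
    return CompleteCaseMatrix(
        values=y,
        subject_ids=tuple(f"s{i}" for i in range(y.shape[0])),
        group_labels=tuple(groups),
        missing_cases=0,
        measure="m",
    )


def random_ccm(rng, n_a, n_b, k=3, shift=0.0):
    y = np.vstack(
        [rng.normal(0, 1, (n_a, k)), rng.normal(shift, 1, (n_b, k))]
    ) + rng.normal(0, 1, (n_a + n_b, 1))
    return make_ccm(y, ["A"] * n_a + ["B"] * n_b)


def brute_force_balanced(y, groups, k):
    """Classical cell-means split-plot decomposition (balanced designs)."""
    y = np.asarray(y, float)
    labels = sorted(set(groups))
    grand = y.mean()
    n, g = y.shape[0], len(labels)
    nj = n // g
    masks = {lab: np.array([x == lab for x in groups]) for lab in labels}
    col = y.mean(axis=0)
    ss_time = n * ((col - grand) ** 2).sum()
    grp = {lab: y[masks[lab]].mean() for lab in labels}
    ss_group = k * nj * sum((grp[lab] - grand) ** 2 for lab in labels)
    cell = {lab: y[masks[lab]].mean(axis=0) for lab in labels}
    ss_int = nj * sum(
        ((cell[lab] - grp[lab] - col + grand) ** 2).sum() for lab in labels
    )
    m = y.mean(axis=1)
    ss_subj = k * sum(((m[masks[lab]] - grp[lab]) ** 2).sum() for lab in labels)
    sst = ((y - grand) ** 2).sum()
    ss_err = sst - ss_time - ss_group - ss_int - ss_subj
    return {
        "time": (ss_time, (k - 1)),
        "scanner": (ss_group, (g - 1)),
        "interaction": (ss_int, (g - 1) * (k - 1)),
        "subj": (ss_subj, n - g),
        "err": (ss_err, (n - g) * (k - 1)),
    }


class TestMixedAnova:
    def test_df_bookkeeping(self):
        rng = np.random.default_rng(0)
        for n, expected_df2 in [(64, 124), (91, 178)]:
            res = mixed_anova(random_ccm(rng, n // 2, n - n // 2))
            assert (res.time.df1, res.time.df2) == (2.0, float(expected_df2))
            assert (res.scanner.df1, res.scanner.df2) == (1.0, float(n - 2))

    def test_group_shift_toy_design(self):
        # group B = group A + 10 at every visit, subjects flat over time
        y = np.array([[1, 1, 1], [2, 2, 2], [11, 11, 11], [12, 12, 12]], float)
        res = mixed_anova(make_ccm(y, ["A", "A", "B", "B"]))
        assert res.time.ss == pytest.approx(0.0, abs=1e-9)
        assert res.interaction.ss == pytest.approx(0.0, abs=1e-9)
        t = stats.ttest_ind([1, 2], [11, 12], equal_var=True).statistic
        assert res.scanner.f == pytest.approx(t**2, rel=1e-9)

    def test_balanced_matches_brute_force(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, (20, 4)) + rng.normal(0, 1, (20, 1))
        y[10:] += np.array([0.0, 0.5, 1.0, 1.5])
        groups = ["A"] * 10 + ["B"] * 10
        res = mixed_anova(make_ccm(y, groups))
        ref = brute_force_balanced(y, groups, k=4)
        for name, effect in [
            ("time", res.time),
            ("scanner", res.scanner),
            ("interaction", res.interaction),
        ]:
            ss, df1 = ref[name]
            assert effect.ss == pytest.approx(ss, rel=1e-9)
            err_name = "subj" if name == "scanner" else "err"
            ss_e, df_e = ref[err_name]
            assert effect.f == pytest.approx((ss / df1) / (ss_e / df_e), rel=1e-9)

    def test_balanced_matches_reference_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        n = 12
        y = np.vstack(
            [rng.normal(0, 1, (n, 3)) + np.array([0, 0.3, 0.6]),
             rng.normal(0.5, 1, (n, 3))]
        )
        res = mixed_anova(make_ccm(y, ["A"] * n + ["B"] * n))
        long = pd.DataFrame(
            {
                "s": np.repeat(range(2 * n), 3),
                "g": np.repeat(["A"] * n + ["B"] * n, 3),
                "t": np.tile([1, 2, 3], 2 * n),
                "v": y.ravel(),
            }
        )
        ref = pg.mixed_anova(long, dv="v", within="t", between="g", subject="s")
        ref = ref.set_index("Source")
        assert res.scanner.f == pytest.approx(ref.loc["g", "F"], rel=1e-9)
        assert res.time.f == pytest.approx(ref.loc["t", "F"], rel=1e-9)
        assert res.interaction.f == pytest.approx(ref.loc["Interaction", "F"], rel=1e-9)

    def test_unbalanced_matches_type_iii_oracle(self):
        # Frozen oracle: R car::Anova(type=3) with sum-to-zero contrasts on
        # this exact dataset (univariate split-plot table).
        rng = np.random.default_rng(11)
        y_a = rng.normal(0, 1, (9, 3)) + np.array([0, 0.4, 0.8])
        y_b = rng.normal(0.7, 1.3, (14, 3))
        res = mixed_anova(make_ccm(np.vstack([y_a, y_b]), ["A"] * 9 + ["B"] * 14))
        assert res.scanner.ss == pytest.approx(1.8695, abs=1e-4)
        assert res.scanner.f == pytest.approx(1.8489, abs=1e-4)
        assert res.scanner.p == pytest.approx(0.1883339, abs=1e-6)
        assert res.time.ss == pytest.approx(2.0427, abs=1e-4)
        assert res.time.f == pytest.approx(1.0824, abs=1e-4)
        assert res.time.p == pytest.approx(0.3480586, abs=1e-6)
        assert res.interaction.ss == pytest.approx(11.6742, abs=1e-4)
        assert res.interaction.f == pytest.approx(6.1858, abs=1e-4)
        assert res.interaction.p == pytest.approx(0.0044200, abs=1e-6)
        assert res.mauchly_w == pytest.approx(0.91633, abs=1e-5)
        assert res.mauchly_p == pytest.approx(0.41738, abs=1e-4)
        assert res.epsilon_gg == pytest.approx(0.9227923, abs=1e-7)

    def test_single_group_time_f_equals_msc_over_mse(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, (15, 3)) + np.array([0, 0.5, 1.0])
        res = mixed_anova(make_ccm(y, ["A"] * 15))
        ms = mean_squares(y)
        assert res.scanner is None and res.interaction is None
        assert res.time.f == pytest.approx(ms.ms_cols / ms.ms_error, rel=1e-9)

    def test_ss_conservation(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            ccm = random_ccm(rng, 7, 12, k=4, shift=0.5)
            y = ccm.values
            m = y.mean(axis=1)
            ss_between = 4 * ((m - m.mean()) ** 2).sum()
            ss_within = ((y - m[:, None]) ** 2).sum()
            sst = ((y - y.mean()) ** 2).sum()
            assert ss_between + ss_within == pytest.approx(sst, rel=1e-9)

    def test_small_group_rejected(self):
        y = np.random.default_rng(0).normal(0, 1, (4, 3))
        with pytest.raises(DegenerateDataError):
            mixed_anova(make_ccm(y, ["A", "A", "A", "B"]))

    def test_zero_error_variance_flags_infinite_f(self):
        # every subject follows the exact same time profile: no residual
        y = np.tile(np.array([0.0, 1.0, 2.0]), (6, 1)) + np.arange(6)[:, None]
        res = mixed_anova(make_ccm(y, ["A"] * 3 + ["B"] * 3))
        assert res.time.infinite_f
        assert np.isinf(res.time.f)
        assert res.time.p == 0.0


class TestSphericity:
    def test_k2_is_trivially_spherical(self):
        y = np.random.default_rng(0).normal(0, 1, (10, 2))
        w, chi2, df, p = mauchly_test(y)
        assert (w, p) == (1.0, 1.0)
        assert gg_epsilon(y) == 1.0

    def test_null_w_near_one_and_size_controlled(self):
        rng = np.random.default_rng(21)
        ws, ps = [], []
        for _ in range(100):
            w, _, _, p = mauchly_test(rng.normal(0, 1, (200, 3)))
            ws.append(w)
            ps.append(p)
        assert np.mean(ws) > 0.95
        assert 0.0 <= np.mean(np.array(ps) < 0.05) <= 0.12

    def test_power_against_strong_heterogeneity(self):
        rng = np.random.default_rng(22)
        scale = np.sqrt(np.array([1.0, 4.0, 16.0]))
        hits = sum(
            mauchly_test(rng.normal(0, 1, (100, 3)) * scale)[3] < 0.05
            for _ in range(50)
        )
        assert hits / 50 > 0.90

    def test_epsilon_bounds_and_rank_one_floor(self):
        rng = np.random.default_rng(23)
        for k in (3, 4, 5):
            y = rng.normal(0, 1, (30, k)) * np.arange(1, k + 1)
            eps = gg_epsilon(y)
            assert 1.0 / (k - 1) <= eps <= 1.0
        # all columns proportional to one subject vector: one nonzero
        # eigenvalue, so epsilon hits its 1/(k-1) floor
        u = rng.normal(0, 1, 20)
        y = np.outer(u, [1.0, 2.0, 3.0])
        assert gg_epsilon(y) == pytest.approx(0.5, abs=1e-12)

    def test_epsilon_matches_reference_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(24)
        for _ in range(20):
            y = rng.normal(0, 1, (25, 4)) * rng.uniform(0.5, 2.0, 4)
            ref = float(pg.epsilon(pd.DataFrame(y), correction="gg"))
            assert gg_epsilon(y) == pytest.approx(ref, abs=1e-10)

    def test_mauchly_w_matches_reference_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(25)
        y = rng.normal(0, 1, (30, 4)) * np.array([1.0, 2.0, 3.0, 1.0])
        w, chi2, df, _ = mauchly_test(y)
        ref = pg.sphericity(pd.DataFrame(y))
        assert w == pytest.approx(float(ref.W), abs=1e-12)
        assert chi2 == pytest.approx(float(ref.chi2), abs=1e-10)
        assert df == int(ref.dof)


def _result_with(eps, time_df=(2.0, 178.0), mauchly_p=0.001, f=1.61):
    p = float(stats.f.sf(f, *time_df))
    time = EffectResult("time", 1.0, time_df[0], time_df[1], f, p)
    return MixedAnovaResult(
        time=time, scanner=None, interaction=None, epsilon_gg=eps,
        mauchly_w=0.9, mauchly_chi2=5.0, mauchly_df=2, mauchly_p=mauchly_p,
        gg_applied=False, n_complete=91, group_sizes={"A": 91},
    )


class TestGreenhouseGeisser:
    def test_not_applied_when_sphericity_holds(self):
        res = _result_with(eps=0.9, mauchly_p=0.5)
        out = apply_gg_if_violated(res)
        assert out is res
        assert not out.gg_applied

    def test_epsilon_one_keeps_p(self):
        res = _result_with(eps=1.0, mauchly_p=0.001)
        out = apply_gg_if_violated(res)
        assert out.gg_applied
        assert out.time.p == pytest.approx(res.time.p, abs=1e-12)

    def test_adjusted_dfs_arithmetic(self):
        # eps = 0.9 at k = 3, N = 91 deflates (2, 178) to (1.8, 160.2)
        out = apply_gg_if_violated(_result_with(eps=0.9, mauchly_p=0.001))
        assert (out.time.df1, out.time.df2) == (pytest.approx(1.8), pytest.approx(160.2))
        assert out.time.p > stats.f.sf(out.time.f, 2, 178)


class TestBonferroni:
    @pytest.mark.parametrize(
        "c, expected", [(16, 0.003125), (14, 0.05 / 14), (1, 0.05)]
    )
    def test_family_adjusted_alpha(self, c, expected):
        adj, _ = bonferroni_family([], c)
        assert adj == pytest.approx(expected)

    def test_flags_strict_inequality(self):
        adj, flags = bonferroni_family([0.003, 0.003125, 0.004], 16)
        assert flags == [True, False, False]

    def test_family_smaller_than_list_rejected(self):
        with pytest.raises(ConfigurationError):
            bonferroni_family([0.01, 0.02], 1)


def site_table(values_by_site, scanner="Philips", k=3):
    """Constant-over-visits subjects so subject means equal the given values."""
    site_of, scanner_of, values = {}, {}, {}
    for site, subject_values in values_by_site.items():
        scanner_of[site] = scanner
        for i, v in enumerate(subject_values):
            subj = f"{site}_{i}"
            site_of[subj] = site
            values[subj] = [v] * k
    return MeasurementTable(
        pd.DataFrame(long_records(values, site_of=site_of, scanner_of=scanner_of))
    )


class TestLsd:
    def test_permuted_site_gives_t_zero(self):
        table = site_table({"Leiden": [1.0, 2.0, 3.0], "Vancouver": [3.0, 1.0, 2.0]})
        cmp = lsd_site_comparison(table, "m", "Philips")
        assert cmp.t == pytest.approx(0.0, abs=1e-12)
        assert cmp.p == pytest.approx(1.0)

    def test_hand_computed_t(self):
        table = site_table({"Leiden": [9.0, 10.0, 11.0], "Vancouver": [11.0, 12.0, 13.0]})
        cmp = lsd_site_comparison(table, "m", "Philips")
        assert cmp.mean_diff == pytest.approx(-2.0)
        assert cmp.t == pytest.approx(-2.449, abs=1e-3)
        assert cmp.df == 4

    def test_wrong_site_count_is_configuration_error(self):
        table = site_table({"Leiden": [1.0, 2.0, 3.0]})
        with pytest.raises(ConfigurationError):
            lsd_site_comparison(table, "m", "Philips")

    def test_antisymmetry_of_mean_diff(self):
        table = site_table({"Leiden": [9.0, 10.0, 11.0], "Vancouver": [11.0, 12.0, 14.0]})
        cmp = lsd_site_comparison(table, "m", "Philips")
        assert cmp.group_a == "Leiden" and cmp.group_b == "Vancouver"
        assert cmp.mean_diff == pytest.approx(
            -(np.mean([11, 12, 14]) - np.mean([9, 10, 11]))
        )
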