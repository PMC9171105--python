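"""Tests for the permutation-inference stack against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from audiomem.permstats import (
    DegenerateSamplesError,
    StatResult,
    bonferroni,
    cohens_d,
    dist_perm_manova,
    perm_anova,
    perm_t_test,
    validate_model_table,
    welch_t,
)


def make_mixed_table(
    rng, n_per_group=6, group_delta=0.0, diff_delta=0.0, inter_delta=0.0,
    noise=1.0,
):
    """Balanced 2x2 mixed-design table with injected effects."""
    rows = []
    for g_i, group in enumerate(("g1", "g2")):
        for s in range(n_per_group):
            sid = f"{group}_{s}"
            subj_eff = rng.normal(0, 0.5)
            age = rng.uniform(12, 54)
            for d_i, diff in enumerate(("easy", "hard")):
                y = (
                    rng.normal(0, noise)
                    + subj_eff
                    + group_delta * g_i
                    + diff_delta * d_i
                    + inter_delta * g_i * d_i
                )
                rows.append(
                    {"subject_id": sid, "group": group, "difficulty": diff,
                     "age": age, "y": y}
                )
    return pd.DataFrame(rows)


class TestWelchT:
    def test_identical_samples_zero(self):
        x = [1.0, 2.0, 3.0]
        assert welch_t(x, x) == 0.0

    def test_hand_evaluated_formula(self):
        # means 2 and 5, variances 1 and 1, se = sqrt(1/3 + 1/3)
        expected = -3.0 / math.sqrt(2.0 / 3.0)
        assert welch_t([1, 2, 3], [4, 5, 6]) == pytest.approx(expected)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 12))
            y = rng.normal(1, 2, size=rng.integers(2, 12))
            ours = welch_t(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False).statistic
            assert ours == pytest.approx(ref, rel=1e-12)

    def test_antisymmetry(self):
        x, y = [1.0, 4.0, 2.0], [0.5, 9.0]
        assert welch_t(x, y) == pytest.approx(-welch_t(y, x))

    def test_degenerate_constant_samples(self):
        assert welch_t([2.0, 2.0], [2.0, 2.0]) == 0.0
        with pytest.raises(DegenerateSamplesError):
            welch_t([0.0, 0.0], [1.0, 1.0])

    def test_too_small(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestCohensD:
    def test_identical_samples(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_zero_variance_error(self):
        with pytest.raises(DegenerateSamplesError):
            cohens_d([0.0, 0.0], [1.0, 1.0])

    def test_hand_evaluated(self):
        # pooled variance = 1, mean diff = -2
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)


class TestPermTTest:
    def test_exhaustive_2_2_matches_enumeration(self):
        x, y = [1.0, 2.0], [10.0, 11.0]
        res = perm_t_test(x, y, seed=0)
        assert res.exhaustive
        assert res.n_perm == 6
        # independent oracle: enumerate all 6 splits of the pooled sample
        pooled = np.array(x + y)
        t_obs = welch_t(x, y)
        hits = 0
        for combo in itertools.combinations(range(4), 2):
            xs = pooled[list(combo)]
            ys = pooled[[i for i in range(4) if i not in combo]]
            if abs(welch_t(xs, ys)) >= abs(t_obs) - 1e-12:
                hits += 1
        assert res.p_perm == pytest.approx(hits / 6)
        assert res.p_perm == pytest.approx(2 / 6)

    def test_exhaustive_3_3_matches_enumeration(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=3)
        y = rng.normal(2.0, 1.0, size=3)
        res = perm_t_test(x, y, seed=0)
        assert res.exhaustive and res.n_perm == 20
        pooled = np.concatenate([x, y])
        t_obs = welch_t(x, y)
        hits = sum(
            abs(
                welch_t(pooled[list(c)],
                        pooled[[i for i in range(6) if i not in c]])
            ) >= abs(t_obs) - 1e-12
            for c in itertools.combinations(range(6), 3)
        )
        assert res.p_perm == pytest.approx(hits / 20)

    def test_monte_carlo_add_one_convention(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        y = rng.normal(3, 1, 30)
        res = perm_t_test(x, y, n_perm=499, seed=1)
        assert not res.exhaustive
        assert res.p_perm == pytest.approx(1 / 500)
        assert res.p_perm >= 1 / (res.n_perm + 1)

    def test_location_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=8)
        y = rng.normal(size=9)
        r1 = perm_t_test(x, y, n_perm=299, seed=5)
        r2 = perm_t_test(x + 100.0, y + 100.0, n_perm=299, seed=5)
        assert r1.p_perm == pytest.approx(r2.p_perm)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-9)

    def test_cohens_d_attached(self):
        x, y = [1.0, 2.0, 3.0], [3.0, 4.0, 5.0]
        res = perm_t_test(x, y)
        assert res.effect_size_kind == "cohens_d"
        assert res.effect_size == pytest.approx(-2.0)

    def test_type_one_error_small(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_sim = 400
        for i in range(n_sim):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            res = perm_t_test(x, y, n_perm=199, seed=i,
                              enumeration_threshold=0)
            rejections += res.p_perm <= 0.05
        rate = rejections / n_sim
        se = math.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) <= 3 * se


class TestPermAnova:
    def test_constant_response(self):
        rng = np.random.default_rng(0)
        table = make_mixed_table(rng, n_per_group=4)
        table["y"] = 5.0
        res = perm_anova(table, "y", n_perm=99, seed=0)
        for term in res:
            assert res[term].statistic == 0.0
            assert res[term].effect_size == 0.0

    def test_group_effect_detected_difficulty_null(self):
        rng = np.random.default_rng(3)
        table = make_mixed_table(rng, n_per_group=12, group_delta=3.0)
        res = perm_anova(table, "y", n_perm=999, seed=1)
        assert res["group"].p_perm < 0.01
        assert res["difficulty"].p_perm > 0.05

    def test_difficulty_effect_detected(self):
        rng = np.random.default_rng(4)
        table = make_mixed_table(rng, n_per_group=10, diff_delta=2.0,
                                 noise=0.8)
        res = perm_anova(table, "y", n_perm=999, seed=1)
        assert res["difficulty"].p_perm < 0.01

    def test_tiny_design_exhaustive_matches_brute_force(self):
        rng = np.random.default_rng(8)
        table = make_mixed_table(rng, n_per_group=2, group_delta=1.0)
        res = perm_anova(table, "y", n_perm=50, seed=0)
        assert all(r.exhaustive for r in res.values())
        assert res["group"].n_perm == math.factorial(8)
        # independent brute force over all 8! response permutations using
        # statsmodels-free closed-form mixed ANOVA on each permutation
        y = table["y"].to_numpy()
        subj = pd.factorize(table["subject_id"])[0]
        grp = pd.factorize(table["group"])[0]
        lvl = pd.factorize(table["difficulty"])[0]
        f_obs = {t: res[t].statistic for t in res}
        hits = {t: 0 for t in res}
        n_tot = 0
        perm_idx = np.array(list(itertools.permutations(range(8))))
        # relative tie tolerance: the oracle reaches each F through a
        # different float path, so exact-tie orbits land ~1e-12 relative off
        thr = {t: f_obs[t] - 1e-9 * max(1.0, abs(f_obs[t])) for t in f_obs}
        for perm in perm_idx:
            fp = _mixed_f_from_codes(subj, grp, lvl, y[perm])
            n_tot += 1
            for t in hits:
                hits[t] += fp[t] >= thr[t]
        for t in res:
            assert res[t].p_perm == pytest.approx(hits[t] / n_tot)

    def test_statistic_matches_closed_form_oracle(self):
        rng = np.random.default_rng(11)
        table = make_mixed_table(rng, n_per_group=5, group_delta=1.0,
                                 diff_delta=0.5, inter_delta=0.7)
        res = perm_anova(table, "y", n_perm=49, seed=0)
        oracle = _mixed_f_oracle(table, table["y"].to_numpy())
        for t in res:
            assert res[t].statistic == pytest.approx(oracle[t], rel=1e-10)

    def test_residual_scheme_runs_and_detects(self):
        rng = np.random.default_rng(5)
        table = make_mixed_table(rng, n_per_group=10, group_delta=3.0)
        res = perm_anova(table, "y", n_perm=499, seed=2, scheme="residual")
        assert res["group"].p_perm < 0.05

    def test_unbalanced_rejected(self):
        rng = np.random.default_rng(0)
        table = make_mixed_table(rng, n_per_group=4).iloc[:-1]
        with pytest.raises(ValueError):
            perm_anova(table, "y")

    def test_effect_size_in_unit_interval(self):
        rng = np.random.default_rng(6)
        table = make_mixed_table(rng, n_per_group=6, group_delta=1.0)
        res = perm_anova(table, "y", n_perm=99, seed=0)
        for r in res.values():
            assert 0.0 <= r.effect_size <= 1.0
            assert r.effect_size_kind == "partial_eta_sq"


def _mixed_f_oracle(table: pd.DataFrame, y: np.ndarray) -> dict:
    """Closed-form mixed-design F ratios computed cell-by-cell from scratch
    with bincount sums (an independent route from the package's indicator-
    matrix batch implementation)."""
    subj = pd.factorize(table["subject_id"])[0]
    grp = pd.factorize(table["group"])[0]
    lvl = pd.factorize(table["difficulty"])[0]
    return _mixed_f_from_codes(subj, grp, lvl, y)


def _mixed_f_from_codes(subj, grp, lvl, y) -> dict:
    a, b, N = grp.max() + 1, lvl.max() + 1, subj.max() + 1
    n = len(y)
    grand = y.mean()
    subj_means = np.bincount(subj, weights=y, minlength=N) / b
    subj_grp = np.zeros(N, dtype=int)
    subj_grp[subj] = grp
    n_g = np.bincount(subj_grp, minlength=a)
    ss_between_subj = b * np.sum((subj_means - grand) ** 2)
    group_means = np.bincount(grp, weights=y, minlength=a) / (b * n_g)
    ss_A = b * np.sum(n_g * (group_means - grand) ** 2)
    ss_subj = ss_between_subj - ss_A
    level_means = np.bincount(lvl, weights=y, minlength=b) / N
    ss_B = N * np.sum((level_means - grand) ** 2)
    cell = grp * b + lvl
    cell_n = np.bincount(cell, minlength=a * b)
    cell_means = np.bincount(cell, weights=y, minlength=a * b) / cell_n
    ss_cells = np.sum(cell_n * (cell_means - grand) ** 2)
    ss_AB = ss_cells - ss_A - ss_B
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_between_subj - ss_B - ss_AB
    f_A = (ss_A / (a - 1)) / (ss_subj / (N - a)) if ss_subj > 0 else 0.0
    f_B = (ss_B / (b - 1)) / (ss_err / ((N - a) * (b - 1)))
    f_AB = (ss_AB / ((a - 1) * (b - 1))) / (ss_err / ((N - a) * (b - 1)))
    return {"group": f_A, "difficulty": f_B, "group:difficulty": f_AB}


class TestDistPermManova:
    def test_univariate_between_factor_equals_classical_f(self):
        rng = np.random.default_rng(9)
        for rep in range(20):
            y = rng.normal(size=15)
            g = np.repeat(["a", "b", "c"], 5)
            df = pd.DataFrame({"group": g, "resp": y})
            res = dist_perm_manova(df, ["resp"], terms=["group"],
                                   distance="euclidean", n_perm=49, seed=rep)
            f_ref = sps.f_oneway(y[:5], y[5:10], y[10:]).statistic
            assert res["group"].statistic == pytest.approx(f_ref, abs=1e-9)

    def test_six_row_exhaustive_matches_direct_enumeration(self):
        rng = np.random.default_rng(10)
        y = rng.normal(size=6)
        g = np.array(["a", "a", "a", "b", "b", "b"])
        df = pd.DataFrame({"group": g, "resp": y})
        res = dist_perm_manova(df, ["resp"], terms=["group"],
                               distance="euclidean", n_perm=10, seed=0)
        assert res["group"].exhaustive
        assert res["group"].n_perm == 720

        # independent oracle: pseudo-F by the direct distance formula
        # SS_total = sum_{i<j} d_ij^2 / n ; SS_within = per-group analogue
        def pseudo_f(y_perm):
            d2 = (y_perm[:, None] - y_perm[None, :]) ** 2
            n = len(y_perm)
            ss_tot = d2[np.triu_indices(n, 1)].sum() / n
            ss_w = 0.0
            for grp in ("a", "b"):
                idx = np.flatnonzero(g == grp)
                sub = d2[np.ix_(idx, idx)]
                ss_w += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
            ss_a = ss_tot - ss_w
            return (ss_a / 1) / (ss_w / (n - 2))

        f_obs = pseudo_f(y)
        assert res["group"].statistic == pytest.approx(f_obs, abs=1e-9)
        hits = sum(
            pseudo_f(y[list(p)]) >= f_obs - 1e-12
            for p in itertools.permutations(range(6))
        )
        assert res["group"].p_perm == pytest.approx(hits / 720)

    def test_duplication_scales_f_by_residual_df_only(self):
        rng = np.random.default_rng(12)
        table = make_mixed_table(rng, n_per_group=4, group_delta=1.0)
        table["z"] = rng.normal(size=len(table))
        dup = pd.concat([table, table], ignore_index=True)
        r1 = dist_perm_manova(table, ["y", "z"],
                              terms=["group", "difficulty"], n_perm=9, seed=0)
        r2 = dist_perm_manova(dup, ["y", "z"],
                              terms=["group", "difficulty"], n_perm=9, seed=0)
        for term in r1:
            df_res1 = r1[term].df[1]
            df_res2 = r2[term].df[1]
            # variance-explained ratio is exactly invariant; the pseudo-F
            # carries the residual-df normalization
            assert r2[term].statistic * df_res1 / df_res2 == pytest.approx(
                r1[term].statistic, rel=1e-9
            )
            assert r2[term].effect_size == pytest.approx(
                r1[term].effect_size, rel=1e-9
            )

    def test_multivariate_with_covariate_runs(self):
        rng = np.random.default_rng(13)
        table = make_mixed_table(rng, n_per_group=8, group_delta=2.0)
        table["z"] = table["y"] * 0.5 + rng.normal(size=len(table))
        table["w"] = rng.normal(size=len(table))
        res = dist_perm_manova(
            table, ["y", "z", "w"],
            terms=["group", "difficulty", "age", "group:difficulty"],
            n_perm=199, seed=0,
        )
        assert res["group"].p_perm < 0.05
        assert set(res) == {"group", "difficulty", "age", "group:difficulty"}

    def test_strata_restricted_permutations(self):
        rng = np.random.default_rng(14)
        table = make_mixed_table(rng, n_per_group=6, diff_delta=2.0)
        res = dist_perm_manova(
            table, ["y"], terms=["group", "difficulty"],
            n_perm=199, seed=0, strata="subject_id",
        )
        # within-subject permutation preserves exchangeability for the
        # within factor; the test must still detect the difficulty effect
        assert res["difficulty"].p_perm < 0.05

    def test_row_order_invariance(self):
        rng = np.random.default_rng(15)
        table = make_mixed_table(rng, n_per_group=5, group_delta=1.5)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        r1 = dist_perm_manova(table, ["y"], terms=["group", "difficulty"],
                              n_perm=9, seed=0)
        r2 = dist_perm_manova(shuffled, ["y"], terms=["group", "difficulty"],
                              n_perm=9, seed=0)
        for term in r1:
            assert r1[term].statistic == pytest.approx(r2[term].statistic,
                                                       rel=1e-9)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"group": ["a", "a", "b", "b"],
                           "resp": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            dist_perm_manova(df, ["resp"], terms=["group"])


class TestBonferroni:
    def test_definition(self):
        assert bonferroni([0.01, 0.04]) == [0.02, 0.08]

    def test_single_unchanged(self):
        assert bonferroni([0.03]) == [0.03]

    def test_capping(self):
        assert bonferroni([0.6, 0.9]) == [1.0, 1.0]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            bonferroni([])

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_bounds_property(self, ps):
        out = bonferroni(ps)
        assert all(0 < q <= 1 for q in out)
        assert all(q >= p for p, q in zip(ps, out))


class TestModelTableValidation:
    def test_missing_column(self):
        with pytest.raises(ValueError):
            validate_model_table(pd.DataFrame({"subject_id": []}), ["y"])

    def test_missing_response(self):
        rng = np.random.default_rng(0)
        table = make_mixed_table(rng, n_per_group=3)
        table.loc[0, "y"] = np.nan
        with pytest.raises(ValueError):
            validate_model_table(table, ["y"])
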