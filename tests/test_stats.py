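"""Tests for the split-plot ANOVA, sphericity machinery and follow-up
tests, each against an independent oracle."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from magnotrain.stats import (
    gg_epsilon,
    independent_t,
    mann_whitney_u,
    mauchly_test,
    mixed_anova,
    pairwise_within,
    partial_eta_sq_from_f,
    to_wide,
)


def _long(y, groups, sessions=None, measure="m"):
    """Wide matrix (subjects x sessions) to the long cohort format."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    sessions = sessions or [f"s{j}" for j in range(k)]
    rows = []
    for i in range(n):
        for j in range(k):
            rows.append(
                {"participant_id": f"P{i:02d}", "group": groups[i],
                 "session": sessions[j], "measure": measure, "value": y[i, j]}
            )
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_toy_dataset_matches_projection_arithmetic(self):
        """6 subjects, 2 groups x 2 sessions, F from explicit group-mean
        projections computed independently of the implementation."""
        y = np.array([[3.0, 5.0], [4.0, 7.0], [5.0, 6.0],
                      [2.0, 2.0], [3.0, 4.0], [4.0, 3.0]])
        groups = ["a"] * 3 + ["b"] * 3
        res = mixed_anova(_long(y, groups), "m")

        # brute-force oracle: direct sums over projection means
        grand = y.mean()
        subj = y.mean(axis=1)
        sess = y.mean(axis=0)
        ga, gb = y[:3].mean(), y[3:].mean()
        cells = np.array([[y[:3, 0].mean(), y[:3, 1].mean()],
                          [y[3:, 0].mean(), y[3:, 1].mean()]])
        ss_between = 2 * ((subj - grand) ** 2).sum()
        ss_group = 2 * 3 * ((ga - grand) ** 2 + (gb - grand) ** 2)
        ss_subj = ss_between - ss_group
        ss_session = 6 * ((sess - grand) ** 2).sum()
        ss_cells = 3 * ((cells - grand) ** 2).sum()
        ss_inter = ss_cells - ss_group - ss_session
        ss_total = ((y - grand) ** 2).sum()
        ss_error = ss_total - ss_between - ss_session - ss_inter
        f_group = (ss_group / 1) / (ss_subj / 4)
        f_session = (ss_session / 1) / (ss_error / 4)
        f_inter = (ss_inter / 1) / (ss_error / 4)

        assert res.effect("group")["F"] == pytest.approx(f_group, rel=1e-12)
        assert res.effect("session")["F"] == pytest.approx(f_session, rel=1e-12)
        assert res.effect("group:session")["F"] == pytest.approx(f_inter, rel=1e-12)

    def test_ss_conservation_on_random_data(self, rng):
        for _ in range(5):
            n_a, n_b, k = rng.integers(3, 9), rng.integers(3, 9), rng.integers(2, 6)
            y = rng.normal(size=(n_a + n_b, k)) * 3 + 10
            groups = ["a"] * n_a + ["b"] * n_b
            res = mixed_anova(_long(y, groups), "m")
            assert res.table["SS"].sum() == pytest.approx(
                res.table.attrs["ss_total"], rel=1e-10
            )

    def test_partial_eta_sq_identity_on_every_row(self, scenario_table):
        for measure in ("rdk_threshold", "reading_accuracy"):
            res = mixed_anova(scenario_table, measure)
            for effect, df2 in (("group", 22), ("session", 66), ("group:session", 66)):
                row = res.effect(effect)
                assert row["partial_eta_sq"] == pytest.approx(
                    partial_eta_sq_from_f(row["F"], row["df"], df2), rel=1e-10
                )

    def test_agrees_with_pingouin(self, scenario_table):
        pg = pytest.importorskip("pingouin")
        sub = scenario_table[scenario_table["measure"] == "saccade_cycles_per_min"]
        oracle = pg.mixed_anova(
            data=sub, dv="value", within="session",
            subject="participant_id", between="group",
        ).set_index("Source")
        res = mixed_anova(scenario_table, "saccade_cycles_per_min")
        for ours, theirs in (
            ("group", "group"), ("session", "session"),
            ("group:session", "Interaction"),
        ):
            row = res.effect(ours)
            assert row["SS"] == pytest.approx(oracle.loc[theirs, "SS"], rel=1e-9)
            assert row["F"] == pytest.approx(oracle.loc[theirs, "F"], rel=1e-9)
            assert row["p_unc"] == pytest.approx(oracle.loc[theirs, "p_unc"], rel=1e-6)
            assert row["partial_eta_sq"] == pytest.approx(
                oracle.loc[theirs, "np2"], rel=1e-9
            )

    def test_constant_dv_degenerates_to_missing_f(self):
        y = np.full((6, 3), 7.0)
        res = mixed_anova(_long(y, ["a"] * 3 + ["b"] * 3), "m")
        assert res.table["SS"].sum() == pytest.approx(0.0)
        assert math.isnan(res.effect("session")["F"])

    def test_missing_cell_rejected(self):
        y = np.arange(12.0).reshape(6, 2)
        table = _long(y, ["a"] * 3 + ["b"] * 3).iloc[:-1]
        with pytest.raises(ValueError):
            mixed_anova(table, "m")

    def test_session_f_equals_squared_paired_t_for_two_levels(self, rng):
        y = rng.normal(size=(12, 2))
        y[:, 1] += 0.8
        res = mixed_anova(_long(y, ["only"] * 12), "m")
        t, _ = sps.ttest_rel(y[:, 0], y[:, 1])
        assert res.effect("session")["F"] == pytest.approx(t**2, rel=1e-10)


class TestPrintedEffectSizes:
    @pytest.mark.parametrize(
        "f, df1, df2, eta",
        [(6.20, 1, 22, 0.22), (111.11, 1.73, 38.21, 0.83), (5.55, 3, 66, 0.20)],
    )
    def test_reported_f_df_pairs_reproduce_eta(self, f, df1, df2, eta):
        assert partial_eta_sq_from_f(f, df1, df2) == pytest.approx(eta, abs=0.005)


class TestSphericity:
    def test_two_levels_trivially_spherical(self, rng):
        res = mauchly_test(rng.normal(size=(10, 2)))
        assert res.mauchly_w == 1.0 and res.p == 1.0

    def test_null_compound_symmetry_rejection_rate(self):
        rng = np.random.default_rng(77)
        rej = 0
        n_sim = 300
        for _ in range(n_sim):
            x = rng.normal(size=(200, 4)) + rng.normal(size=(200, 1))
            rej += mauchly_test(x).p < 0.05
        assert rej / n_sim == pytest.approx(0.05, abs=0.03)

    def test_dominant_contrast_variance_shrinks_w_and_epsilon(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(100, 1))
        x = np.hstack([base] * 4) + rng.normal(size=(100, 4)) * 0.05
        x[:, 0] += rng.normal(size=100) * 5.0
        res = mauchly_test(x)
        assert res.mauchly_w < 0.01
        assert res.gg_epsilon == pytest.approx(1.0 / 3.0, abs=0.01)

    def test_epsilon_one_for_exactly_spherical_contrasts(self, rng):
        # whiten the contrast space so the sample contrast covariance is I
        from scipy import linalg

        z = rng.normal(size=(40, 3))
        z = (z - z.mean(axis=0)) @ linalg.inv(linalg.cholesky(np.cov(z.T), lower=False))
        c = linalg.helmert(4, full=False)
        x = z @ c  # lift back to 4 sessions
        assert gg_epsilon(x) == pytest.approx(1.0, rel=1e-8)

    def test_epsilon_invariant_to_contrast_basis_oracle(self, rng):
        """Box's formula evaluated from scratch on an independently
        constructed orthonormal (polynomial) contrast basis."""
        x = rng.normal(size=(30, 4)) @ rng.normal(size=(4, 4))
        k = 4
        # orthonormal polynomial contrasts: QR of [1, t, t^2, t^3], drop
        # the constant column
        design = np.vander(np.linspace(-1, 1, k), k, increasing=True)
        q = np.linalg.qr(design)[0][:, 1:]
        s = np.cov(x.T, ddof=1)
        s_c = q.T @ s @ q
        expected = np.trace(s_c) ** 2 / ((k - 1) * np.trace(s_c @ s_c))
        assert gg_epsilon(x) == pytest.approx(expected, rel=1e-10)

    def test_degenerate_covariance_raises(self):
        x = np.tile(np.arange(4.0), (10, 1))
        with pytest.raises(ValueError):
            mauchly_test(x)


class TestPairwiseWithin:
    def test_identical_sessions_give_zero_difference(self):
        y = np.tile(np.arange(6.0)[:, None], (1, 2))
        res = pairwise_within(_long(y, ["a"] * 3 + ["b"] * 3), "m")
        for r in res:
            assert r.estimate == 0.0
            assert r.p == 1.0

    def test_constant_shift_recovered_with_sign_convention(self, rng):
        base = rng.normal(size=6)
        y = np.column_stack([base, base + 5.0])
        res = pairwise_within(_long(y, ["a"] * 3 + ["b"] * 3), "m")
        for r in res:
            assert r.estimate == pytest.approx(-5.0)  # session1 - session2

    def test_t_matches_closed_form(self, rng):
        y = rng.normal(size=(8, 3))
        res = pairwise_within(_long(y, ["a"] * 4 + ["b"] * 4), "m")
        r = res[0]  # group a, s0 vs s1
        d = y[:4, 0] - y[:4, 1]
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert r.statistic == pytest.approx(expected, rel=1e-10)
        assert r.p_bonferroni == pytest.approx(min(1.0, r.p * len(res)))


class TestIndependentT:
    def test_identical_groups(self):
        res = independent_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_study_sized_groups_give_df_22(self, rng):
        res = independent_t(rng.normal(size=13), rng.normal(size=11))
        assert res.df == 22

    def test_matches_pooled_variance_closed_form(self, rng):
        a, b = rng.normal(size=7) + 1, rng.normal(size=5)
        res = independent_t(a, b)
        sp2 = ((6 * a.var(ddof=1)) + (4 * b.var(ddof=1))) / 10
        expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 7 + 1 / 5))
        assert res.statistic == pytest.approx(expected, rel=1e-10)

    def test_zero_variance_separated_groups_edge(self):
        res = independent_t([1.0, 1.0], [2.0, 2.0])
        assert res.p == 0.0 and math.isinf(res.statistic)


class TestMannWhitney:
    def test_complete_separation_gives_max_u(self):
        res = mann_whitney_u([10, 11, 12], [1, 2, 3])
        assert res.statistic == 9.0

    def test_fully_tied_symmetry(self):
        res = mann_whitney_u([5.0, 5.0], [5.0, 5.0])
        assert res.statistic == 2.0  # nA*nB/2

    def test_exact_p_matches_enumeration_oracle(self, rng):
        a, b = rng.normal(size=3), rng.normal(size=4)
        res = mann_whitney_u(a, b)

        def u_stat(x, y):
            return sum(1 for xi in x for yi in y if xi > yi)

        pooled = np.concatenate([a, b])
        u_obs = u_stat(a, b)
        us = []
        for idx in itertools.combinations(range(7), 3):
            x = pooled[list(idx)]
            y = pooled[[i for i in range(7) if i not in idx]]
            us.append(u_stat(x, y))
        us = np.array(us)
        n = len(us)
        # two-sided exact p: fold the symmetric null distribution
        p_expected = min(
            1.0,
            2 * min((us >= u_obs).sum() / n, (us <= u_obs).sum() / n),
        )
        assert res.p == pytest.approx(p_expected, rel=1e-9)


def test_to_wide_preserves_session_order(scenario_table):
    wide, groups = to_wide(scenario_table, "comprehension")
    assert list(wide.columns) == ["pre", "mid", "post", "followup"]
    assert set(groups) == {"experimental", "control"}
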