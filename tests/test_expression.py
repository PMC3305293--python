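"""RPKM, the empirical-Bayes moderated t-test, BH adjustment, fold-change
tiers, and centroid clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from diverseq.expression import (
    ModeratedTParams,
    bh_adjust,
    cluster_expression,
    cluster_newick,
    compute_rpkm,
    differential_expression,
    fit_moderated_params,
    fold_change_tier,
    fold_changes,
    moderated_t_test,
    pooled_variances,
)

from _oracles import bh_stepup, centroid_linkage_bruteforce, moderated_t_rederivation

COLS = ["LM_1", "LM_2", "LM_3", "AO_1", "AO_2", "AO_3", "AO_4"]
GROUPS = {c: c[:2] for c in COLS}


def _log_expr(rng, n=100, effect=None):
    x = rng.normal(5, 1, size=(n, len(COLS))) * 0 + rng.normal(
        5, 0.5, size=(n, len(COLS))
    )
    if effect is not None:
        x[: len(effect), :3] += np.asarray(effect)[:, None]
    return pd.DataFrame(x, columns=COLS, index=[f"c{i}" for i in range(n)])


class TestRpkm:
    def test_unit_scale_identity(self):
        counts = pd.DataFrame({"s": [10]}, index=["g"])
        expr = compute_rpkm(counts, pd.Series({"g": 1000}), pd.Series({"s": 1_000_000}))
        assert expr.rpkm.loc["g", "s"] == 10.0

    def test_zero_count_zero_rpkm(self):
        counts = pd.DataFrame({"s": [0, 5]}, index=["g1", "g2"])
        expr = compute_rpkm(counts, pd.Series({"g1": 500, "g2": 500}))
        assert expr.rpkm.loc["g1", "s"] == 0.0
        assert (expr.rpkm.to_numpy() == 0).sum() == 1

    def test_matches_long_form_formula(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(200, 6)),
            columns=[f"s{i}" for i in range(6)],
            index=[f"g{i}" for i in range(200)],
        )
        lengths = pd.Series(rng.integers(200, 2000, size=200), index=counts.index)
        totals = counts.sum(axis=0)
        expr = compute_rpkm(counts, lengths, totals)
        for g in counts.index[:: 20]:
            for s in counts.columns:
                direct = counts.loc[g, s] / (lengths[g] / 1e3) / (totals[s] / 1e6)
                assert expr.rpkm.loc[g, s] == pytest.approx(direct, rel=1e-12)

    def test_scale_invariances(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 100, size=(50, 4)), columns=list("abcd")
        )
        lengths = pd.Series(rng.integers(100, 1000, size=50), index=counts.index)
        base = compute_rpkm(counts, lengths).rpkm
        doubled = compute_rpkm(counts * 2, lengths, counts.sum(0) * 2).rpkm
        pd.testing.assert_frame_equal(base, doubled)
        halved = compute_rpkm(counts, lengths * 2, counts.sum(0)).rpkm
        np.testing.assert_allclose(halved.to_numpy(), base.to_numpy() / 2)

    def test_zero_totals_rejected(self):
        counts = pd.DataFrame({"s": [0]}, index=["g"])
        with pytest.raises(ValueError):
            compute_rpkm(counts, pd.Series({"g": 100}))


class TestModeratedParams:
    def test_equal_variances_give_infinite_prior(self, rng):
        x = _log_expr(rng, n=50)
        # equalize variances within rounding: use exact identical rows + noise-free shifts
        base = rng.normal(0, 1, size=len(COLS))
        df = pd.DataFrame(
            np.tile(base, (50, 1)) + rng.normal(0, 1, size=50)[:, None],
            columns=COLS,
        )
        params = fit_moderated_params(df, GROUPS)
        assert math.isinf(params.d0)
        common = pooled_variances(df, GROUPS).iloc[0]
        assert params.s0_sq == pytest.approx(common, rel=1e-12)

    def test_recovers_known_prior(self, rng):
        d0_true, s0_true, n = 4.0, 0.05, 5000
        sigma2 = d0_true * s0_true / stats.chi2.rvs(d0_true, size=n, random_state=rng)
        x = np.array(
            [np.random.default_rng(i).normal(0, np.sqrt(s), len(COLS)) for i, s in enumerate(sigma2)]
        )
        df = pd.DataFrame(x, columns=COLS)
        params = fit_moderated_params(df, GROUPS)
        assert params.d0 == pytest.approx(d0_true, rel=0.30)
        assert params.s0_sq == pytest.approx(s0_true, rel=0.10)

    def test_location_shift_leaves_prior_unchanged(self, rng):
        df = _log_expr(rng, n=200)
        p1 = fit_moderated_params(df, GROUPS)
        p2 = fit_moderated_params(df + 1.0, GROUPS)  # doubling on raw scale
        assert p1.d0 == pytest.approx(p2.d0)
        assert p1.s0_sq == pytest.approx(p2.s0_sq)

    def test_degenerate_inputs_rejected(self):
        df = pd.DataFrame(np.ones((20, 7)), columns=COLS)
        with pytest.raises(ValueError):
            fit_moderated_params(df, GROUPS)


class TestModeratedT:
    def test_d0_zero_equals_ordinary_t(self, rng):
        df = _log_expr(rng, n=100)
        params = ModeratedTParams(d0=0.0, s0_sq=1.0, dg=5)
        res = moderated_t_test(df, GROUPS, params)
        lm, ao = df[COLS[:3]], df[COLS[3:]]
        t_ref, _ = stats.ttest_ind(lm, ao, axis=1, equal_var=True)
        np.testing.assert_allclose(res["t"].to_numpy(), t_ref, atol=1e-10)

    def test_equal_means_give_null_point(self):
        row = [3.0, 4.0, 5.0, 3.5, 4.0, 4.5, 4.0]  # both groups mean 4
        df = pd.DataFrame([row], columns=COLS)
        params = ModeratedTParams(d0=4.0, s0_sq=0.3, dg=5)
        res = moderated_t_test(df, GROUPS, params)
        assert res["t"].iloc[0] == pytest.approx(0.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_high_precision_rederivation(self, rng):
        df = _log_expr(rng, n=100)
        params = fit_moderated_params(df, GROUPS)
        res = moderated_t_test(df, GROUPS, params)
        for i in range(0, 100, 7):
            row = df.iloc[i]
            t_oracle = moderated_t_rederivation(
                row[COLS[:3]], row[COLS[3:]], params.d0, params.s0_sq
            )
            assert abs(res["t"].iloc[i] - t_oracle) < 1e-10

    def test_infinite_prior_pools_all_variance(self, rng):
        df = _log_expr(rng, n=50)
        params = ModeratedTParams(d0=math.inf, s0_sq=0.25, dg=5)
        res = moderated_t_test(df, GROUPS, params)
        diff = df[COLS[:3]].mean(1) - df[COLS[3:]].mean(1)
        expected = diff / np.sqrt(0.25 * (1 / 3 + 1 / 4))
        np.testing.assert_allclose(res["t"].to_numpy(), expected, atol=1e-12)

    def test_small_group_rejected(self, rng):
        df = _log_expr(rng, n=20)[["LM_1"] + COLS[3:]]
        with pytest.raises(ValueError):
            moderated_t_test(df, GROUPS, ModeratedTParams(1.0, 1.0, 3))

    def test_power_not_below_ordinary_t(self, rng):
        """Shrinkage should not lose power against planted 8-fold effects."""
        diffs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            n, nde = 400, 40
            x = r.normal(5, 0.5, size=(n, 7))
            signs = np.sign(r.normal(size=nde))
            x[:nde, :3] += 3.0 * signs[:, None]  # 8-fold in log2
            df = pd.DataFrame(x, columns=COLS)
            params = fit_moderated_params(df, GROUPS)
            q_mod = bh_adjust(moderated_t_test(df, GROUPS, params)["p"])
            q_ord = bh_adjust(
                moderated_t_test(df, GROUPS, ModeratedTParams(0.0, 1.0, 5))["p"]
            )
            diffs.append((q_mod[:nde] < 0.05).mean() - (q_ord[:nde] < 0.05).mean())
        assert np.mean(diffs) >= -0.02
        assert min(diffs) > -0.1


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.04, 0.8]), [0.015, 0.06, 0.8]
        )

    def test_null_uniform_p_rarely_significant(self):
        hits = []
        for seed in range(20):
            p = np.random.default_rng(seed).uniform(size=1000)
            hits.append((bh_adjust(p) < 0.05).mean())
        assert np.mean(hits) <= 0.005

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60)
    )
    def test_matches_definition_and_is_order_invariant(self, p):
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_stepup(p), atol=1e-12)
        perm = list(reversed(range(len(p))))
        q_perm = bh_adjust([p[i] for i in perm])
        np.testing.assert_allclose([q_perm[perm.index(i)] for i in range(len(p))], q, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestFoldChange:
    def _results(self, mean_lm, mean_ao):
        means = pd.DataFrame({"mean_LM": mean_lm, "mean_AO": mean_ao})
        return means.assign(fold_change=fold_changes(means, pseudocount=0.0))

    def test_two_fold_kept_at_two_dropped_at_eight(self):
        res = self._results([20.0], [10.0])
        assert len(fold_change_tier(res, 2)) == 1
        assert len(fold_change_tier(res, 8)) == 0

    def test_unit_fold_dropped(self):
        res = self._results([10.0], [10.0])
        assert len(fold_change_tier(res, 2)) == 0

    def test_tiers_nest(self, rng):
        res = self._results(rng.uniform(0.1, 100, 200), rng.uniform(0.1, 100, 200))
        t2 = set(fold_change_tier(res, 2).index)
        t8 = set(fold_change_tier(res, 8).index)
        assert t8 <= t2

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            fold_change_tier(self._results([1.0], [1.0]), 1.0)


class TestClustering:
    def test_identical_samples_merge_first_at_zero(self, rng):
        x = rng.normal(size=(6, 3))
        df = pd.DataFrame(np.c_[x, x[:, 0]], columns=["a", "b", "c", "a2"])
        res = cluster_expression(df)
        first = res.sample_linkage[0]
        assert first[2] == pytest.approx(0.0)
        merged = {int(first[0]), int(first[1])}
        assert merged == {0, 3}  # columns a and a2

    def test_merge_sequence_matches_bruteforce_centroid(self, rng):
        pts = rng.normal(size=(5, 2))
        df = pd.DataFrame(pts, columns=["x", "y"], index=list("abcde"))
        res = cluster_expression(df)
        oracle = centroid_linkage_bruteforce(pts)
        for row, (a, b, dist, size) in zip(res.gene_linkage, oracle):
            assert {int(row[0]), int(row[1])} == {a, b}
            assert row[2] == pytest.approx(dist, rel=1e-9)
            assert int(row[3]) == size

    def test_permutation_equivariance(self, rng):
        pts = rng.normal(size=(4, 6))
        df = pd.DataFrame(pts, columns=[f"s{i}" for i in range(6)])
        perm = [3, 0, 1, 2]
        df2 = df.iloc[perm].reset_index(drop=True)
        h1 = sorted(cluster_expression(df).gene_linkage[:, 2])
        h2 = sorted(cluster_expression(df2).gene_linkage[:, 2])
        np.testing.assert_allclose(h1, h2, rtol=1e-9)

    def test_newick_leaves_cover_labels(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 4)), index=list("abcde"),
                          columns=list("wxyz"))
        genes, samples = cluster_newick(cluster_expression(df))
        assert genes.endswith(";") and samples.endswith(";")
        for label in "abcde":
            assert label in genes
        for label in "wxyz":
            assert label in samples

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            cluster_expression(pd.DataFrame({"a": [1.0]}))


class TestDifferentialExpression:
    def test_pipeline_table_columns_and_significance(self, rng):
        counts = pd.DataFrame(
            rng.integers(20, 200, size=(60, 7)), columns=COLS,
            index=[f"g{i}" for i in range(60)],
        )
        # strong LM up-regulation on two genes (kept few so the boosted
        # library totals don't drag the RPKM fold change near the tier)
        counts.iloc[:2, :3] *= 100
        lengths = pd.Series(rng.integers(300, 900, size=60), index=counts.index)
        expr = compute_rpkm(counts, lengths)
        de = differential_expression(expr, GROUPS, tier=8.0)
        assert {"mean_LM", "mean_AO", "fold_change", "t", "p", "q", "significant"} <= set(de.columns)
        assert (de["q"] >= de["p"] - 1e-12).all()
        assert set(counts.index[:2]) <= set(de.index)
        assert de.loc["g0", "significant"]
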