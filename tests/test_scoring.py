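import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cosubst.mapping import SubstitutionVectorSet
from cosubst.scoring import (
    SIGN_RULES,
    CorrelationSet,
    FilterConfig,
    PartialSet,
    component_scores,
    overall_score,
    partial_by_residual_regression,
    partial_matrix,
    pearson_matrix,
    rank_pairs,
    score_pipeline,
    significance_threshold,
    site_filters,
)


def make_partial(R, n_branches=100):
    R = np.asarray(R, float)
    return PartialSet("x", R, np.zeros(len(R), bool), n_branches)


class TestPearson:
    def test_duplicated_row_gives_one(self, rng):
        v = rng.random(30)
        C = pearson_matrix(np.vstack([v, v + 0.0, rng.random(30)]))
        assert C.C[0, 1] == pytest.approx(1.0)

    def test_negated_row_gives_minus_one(self, rng):
        v = rng.standard_normal(30)
        C = pearson_matrix(np.vstack([v, -v]))
        assert C.C[0, 1] == pytest.approx(-1.0)

    def test_independent_rows_near_zero(self):
        rng = np.random.default_rng(7)
        C = pearson_matrix(rng.standard_normal((8, 1000)))
        off = C.C[~np.eye(8, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_zero_variance_marked_degenerate(self):
        C = pearson_matrix(np.vstack([np.zeros(20), np.ones(20), np.arange(20.0)]))
        assert C.degenerate[0] and C.degenerate[1] and not C.degenerate[2]
        assert np.isnan(C.C[0, 2])

    def test_too_few_branches_error(self):
        with pytest.raises(ValueError):
            pearson_matrix(np.ones((3, 2)))


class TestPartial:
    def test_chain_correlation_removed(self):
        # C12 = C23 = 0.8, C13 = 0.64: site 2 explains the 1-3 correlation
        C = np.array([[1, 0.8, 0.64], [0.8, 1, 0.8], [0.64, 0.8, 1.0]])
        R = partial_matrix(
            CorrelationSet("substitution", C, np.zeros(3, bool), 100)
        )
        assert R.R[0, 2] == pytest.approx(0.0, abs=1e-10)
        assert R.R[0, 1] > 0.5

    def test_identity_input_gives_identity(self):
        C = CorrelationSet("substitution", np.eye(4), np.zeros(4, bool), 50)
        R = partial_matrix(C)
        assert np.abs(R.R - np.eye(4)).max() < 1e-12

    def test_matches_residual_regression_oracle(self, rng):
        for _ in range(5):
            V = rng.standard_normal((10, 40))
            C = pearson_matrix(V)
            R = partial_matrix(C)
            oracle = partial_by_residual_regression(V)
            assert np.abs(R.R - oracle).max() < 1e-8

    def test_degenerate_sites_stay_masked(self, rng):
        V = rng.standard_normal((5, 40))
        V[2] = 3.14  # constant row
        R = partial_matrix(pearson_matrix(V))
        assert R.degenerate[2]
        assert np.isnan(R.R[2]).all()

    def test_singular_matrix_ridge_regularised(self, rng):
        V = rng.standard_normal((12, 8))  # more sites than branches
        R = partial_matrix(pearson_matrix(V), ridge=1e-6)
        good = ~R.degenerate
        assert np.isfinite(R.R[np.ix_(good, good)]).all()


class TestSignificanceThreshold:
    def test_normal_limit(self):
        cfg = FilterConfig(e_value=0.05)
        r = significance_threshold(cfg, n_pairs=1, n_branches=1002)
        assert r == pytest.approx(1.96 / np.sqrt(1000), abs=1e-3)

    def test_monotone_in_evalue(self):
        a = significance_threshold(FilterConfig(e_value=0.01), 100, 400)
        b = significance_threshold(FilterConfig(e_value=0.001), 100, 400)
        assert b > a

    @given(
        n_pairs=st.integers(1, 10**5),
        n_branches=st.integers(10, 10**4),
    )
    @settings(max_examples=50, deadline=None)
    def test_always_in_unit_interval(self, n_pairs, n_branches):
        r = significance_threshold(FilterConfig(), n_pairs, n_branches)
        assert 0.0 < r < 1.0

    def test_no_degrees_of_freedom_error(self):
        with pytest.raises(ValueError):
            significance_threshold(FilterConfig(), 10, 2)


class TestComponentScores:
    def test_negative_substitution_partial_zeroes_everything(self):
        R_sub = make_partial([[1, -0.3], [-0.3, 1]])
        R_x = make_partial([[1, -0.9], [-0.9, 1]])
        for rule in ("positive", "negative", "both"):
            z = component_scores(R_sub, R_x, rule)
            assert z[0, 1] == 0.0

    def test_geometric_mean_value(self):
        R_sub = make_partial([[1, 0.25], [0.25, 1]])
        R_vol = make_partial([[1, -0.16], [-0.16, 1]])
        z = component_scores(R_sub, R_vol, "negative")
        assert z[0, 1] == pytest.approx(0.2)

    def test_zero_feature_partial_gives_zero(self):
        R_sub = make_partial([[1, 0.5], [0.5, 1]])
        R_x = make_partial([[1, 0.0], [0.0, 1]])
        assert component_scores(R_sub, R_x, "both")[0, 1] == 0.0

    def test_sign_rules(self):
        R_sub = make_partial([[1, 0.36], [0.36, 1]])
        R_x = make_partial([[1, 0.25], [0.25, 1]])
        assert component_scores(R_sub, R_x, "positive")[0, 1] == pytest.approx(0.3)
        assert component_scores(R_sub, R_x, "negative")[0, 1] == 0.0
        assert component_scores(R_sub, R_x, "both")[0, 1] == pytest.approx(0.3)

    def test_invalid_rule_errors(self):
        R = make_partial(np.eye(2))
        with pytest.raises(ValueError):
            component_scores(R, R, "sometimes")


def full_partials(n, rng, sub=None):
    out = {}
    for name in ["substitution", *SIGN_RULES]:
        M = rng.uniform(-0.5, 0.5, (n, n))
        M = 0.5 * (M + M.T)
        np.fill_diagonal(M, 1.0)
        out[name] = make_partial(M)
    if sub is not None:
        out["substitution"] = make_partial(sub)
    return out


class TestOverallScore:
    def test_all_zero_components(self, rng):
        partials = {
            name: make_partial(np.eye(3)) for name in ["substitution", *SIGN_RULES]
        }
        st_ = overall_score(partials)
        assert np.abs(st_.zeta).max() == 0.0

    def test_max_combination(self):
        n = 2
        zsub = 0.3
        # choose R_charge so the charge component reaches 0.45
        s = 0.45**2 / zsub
        partials = {
            name: make_partial(np.eye(n)) for name in ["substitution", *SIGN_RULES]
        }
        partials["substitution"] = make_partial([[1, zsub], [zsub, 1]])
        partials["charge"] = make_partial([[1, -s], [-s, 1]])
        st_ = overall_score(partials)
        assert st_.zeta[0, 1] == pytest.approx(0.45)

    def test_overall_never_below_zeta_sub(self, rng):
        partials = full_partials(6, rng)
        st_ = overall_score(partials)
        assert (st_.zeta >= st_.zeta_sub - 1e-12).all()

    def test_alpha_propensity_not_a_component(self, rng):
        st_ = overall_score(full_partials(4, rng))
        assert "alpha_propensity" not in st_.components

    def test_missing_component_errors(self, rng):
        partials = full_partials(4, rng)
        del partials["ionic"]
        with pytest.raises(KeyError):
            overall_score(partials)

    def test_scores_in_unit_interval(self, rng):
        for combiner in ("max", "sum"):
            st_ = overall_score(full_partials(8, rng), FilterConfig(combiner=combiner))
            assert (st_.zeta >= 0).all() and (st_.zeta <= 1).all()


class TestFiltersAndRanking:
    def build_table(self, n, rng, zeta=None):
        partials = full_partials(n, rng)
        st_ = overall_score(partials)
        if zeta is not None:
            st_.zeta = zeta
            st_.zeta_sub = np.minimum(st_.zeta_sub, zeta)
        return st_

    def test_terminal_pairs_fall_back_to_zeta_sub(self, rng):
        n = 8
        st_ = self.build_table(n, rng)
        st_ = site_filters(st_, FilterConfig(), r_thr=0.9)
        for j in range(1, n):
            assert st_.zeta_effective[0, j] == st_.zeta_sub[0, j]
            assert st_.zeta_effective[n - 1, j - 1] == st_.zeta_sub[n - 1, j - 1]
        interior = st_.zeta_effective[1:-1, 1:-1]
        assert np.array_equal(interior, st_.zeta[1:-1, 1:-1])

    def test_hub_site_excluded(self, rng):
        # wire site 0... a middle site to 16 partners above threshold
        n = 20
        st_ = self.build_table(n, rng)
        st_.zeta[:] = 0.0
        hub = 5
        # interior partners only: terminal-site pairs fall back to zeta_sub
        partners = [j for j in range(1, n - 1) if j != hub][:16]
        for j in partners:
            st_.zeta[hub, j] = st_.zeta[j, hub] = 0.8
        st_ = site_filters(st_, FilterConfig(hub_limit=15), r_thr=0.5)
        assert st_.anomalous[hub]
        assert not st_.anomalous[[j for j in range(n) if j != hub]].any()
        preds = rank_pairs(st_, FilterConfig(), k=1)
        assert hub + 1 not in set(preds.frame["pos_i"]) | set(preds.frame["pos_j"])

    def test_fifteen_partners_not_excluded(self, rng):
        n = 20
        st_ = self.build_table(n, rng)
        st_.zeta[:] = 0.0
        hub = 5
        for j in [j for j in range(1, n - 1) if j != hub][:15]:
            st_.zeta[hub, j] = st_.zeta[j, hub] = 0.8
        st_ = site_filters(st_, FilterConfig(hub_limit=15), r_thr=0.5)
        assert not st_.anomalous[hub]

    def test_invariant_sites_never_ranked(self, rng):
        n = 10
        st_ = self.build_table(n, rng)
        st_.degenerate[3] = True
        st_ = site_filters(st_, FilterConfig(min_separation=1), r_thr=0.9)
        preds = rank_pairs(st_, FilterConfig(min_separation=1), k=100)
        assert 4 not in set(preds.frame["pos_i"]) | set(preds.frame["pos_j"])

    def test_minimum_separation(self, rng):
        st_ = self.build_table(12, rng)
        st_ = site_filters(st_, FilterConfig(), r_thr=0.9)
        preds = rank_pairs(st_, FilterConfig(min_separation=6), k=100)
        assert (preds.frame["pos_j"] - preds.frame["pos_i"] >= 6).all()

    def test_k_one_returns_best_pair(self, rng):
        st_ = self.build_table(12, rng)
        st_ = site_filters(st_, FilterConfig(), r_thr=0.9)
        all_preds = rank_pairs(st_, FilterConfig(), k=30)
        top = rank_pairs(st_, FilterConfig(), k=1)
        assert len(top) == 1
        assert top.frame.iloc[0]["zeta"] == all_preds.frame["zeta"].max()

    def test_k_larger_than_available_warns(self, rng):
        st_ = self.build_table(8, rng)
        st_ = site_filters(st_, FilterConfig(), r_thr=0.9)
        with pytest.warns(UserWarning):
            preds = rank_pairs(st_, FilterConfig(), k=10**6)
        assert len(preds) < 10**6

    def test_deterministic_ranking(self, rng):
        st_ = self.build_table(10, rng)
        st_ = site_filters(st_, FilterConfig(), r_thr=0.9)
        a = rank_pairs(st_, FilterConfig(), k=10).frame
        b = rank_pairs(st_, FilterConfig(), k=10).frame
        assert a.equals(b)


class TestPipelineInvariance:
    def test_site_permutation_consistency(self, rng):
        V = {f: rng.standard_normal((9, 60)) for f in ["substitution", *SIGN_RULES]}
        V["alpha_propensity"] = rng.standard_normal((9, 60))
        vecs = SubstitutionVectorSet(V, 9, 60)
        st1, _ = score_pipeline(vecs)
        perm = rng.permutation(9)
        vecs2 = SubstitutionVectorSet({f: v[perm] for f, v in V.items()}, 9, 60)
        st2, _ = score_pipeline(vecs2)
        assert np.abs(
            st2.zeta - st1.zeta[np.ix_(perm, perm)]
        ).max() < 1e-10
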