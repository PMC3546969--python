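import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cosubst.alignment_io import Alignment
from cosubst.likelihood import branch_endpoint_posteriors, site_log_likelihood
from cosubst.mapping import map_feature, map_features, state_delta_matrix
from cosubst.models import poisson_model
from cosubst.properties import AMINO_ACIDS, FEATURES, PropertyTable
from cosubst.tree import read_newick

from _oracles import (
    brute_endpoint_joint,
    brute_posterior_mean,
    column_alignment,
    random_small_model,
)

TABLE = PropertyTable.default()


class TestFeatureDelta:
    @pytest.mark.parametrize(
        "feature,a,b,expected",
        [
            ("substitution", "A", "A", 0.0),
            ("substitution", "A", "V", 1.0),
            ("charge", "K", "E", -2.0),
            ("charge", "E", "K", 2.0),
            ("aromatic", "F", "W", 0.0),
            ("aromatic", "A", "W", 1.0),
            ("branched", "I", "A", -1.0),
            ("crosslink", "A", "S", 1.0),
            ("ionic", "A", "H", 0.1),
            ("hbond", "A", "S", 2.0),  # ser is both acceptor and donor
            ("hbond", "S", "D", -1.0),  # asp: acceptor only
        ],
    )
    def test_printed_indicator_values(self, feature, a, b, expected):
        assert TABLE.feature_delta(feature, a, b) == pytest.approx(expected)

    @given(
        feature=st.sampled_from([f for f in FEATURES if f != "substitution"]),
        a=st.sampled_from(AMINO_ACIDS),
        b=st.sampled_from(AMINO_ACIDS),
    )
    @settings(max_examples=100, deadline=None)
    def test_difference_features_antisymmetric(self, feature, a, b):
        assert TABLE.feature_delta(feature, a, b) == pytest.approx(
            -TABLE.feature_delta(feature, b, a)
        )

    def test_unknown_feature_errors(self):
        with pytest.raises(KeyError):
            TABLE.feature_delta("nope", "A", "V")

    def test_indicator_set_validation(self):
        frame = TABLE.frame.copy()
        frame.loc["A", "aromatic"] = 1
        with pytest.raises(ValueError):
            PropertyTable(frame)


class TestEndpointPosteriors:
    def test_two_leaf_observed_pair_is_point_mass(self, two_state_model):
        t = read_newick("(X:0.2,Y:0.3);")
        aln = Alignment(["X", "Y"], ["A", "R"])
        res = site_log_likelihood(t, two_state_model, None, aln)
        joint = branch_endpoint_posteriors(res)
        assert joint.shape == (1, 2, 2, 1)
        assert joint[0, 0, 1, 0] == pytest.approx(1.0, abs=1e-12)

    def test_sums_to_one_and_matches_enumeration(self, rng):
        m = random_small_model(4, rng)
        t = read_newick("((A:0.3,B:0.5):0.2,C:0.7,D:0.1);")
        cols = ["".join(rng.choice(list("ARND"), 4)) for _ in range(5)]
        aln = column_alignment(t, cols)
        res = site_log_likelihood(t, m, None, aln)
        joint = branch_endpoint_posteriors(res)
        assert np.abs(joint.sum(axis=(1, 2)) - 1.0).max() < 1e-10
        for b in range(t.n_branches):
            for s, col in enumerate(cols):
                obs = {lab: "ARND".index(col[i]) for i, lab in enumerate(t.labels)}
                expected = brute_endpoint_joint(t, m, obs, b)
                assert np.abs(joint[b, :, :, s] - expected).max() < 1e-10

    def test_marginal_consistency_between_adjacent_branches(self, rng):
        # the parent-side marginal of a pendant branch must equal the
        # child-side marginal of the branch above that internal node
        m = random_small_model(4, rng)
        t = read_newick("((A:0.3,B:0.5):0.2,C:0.7,D:0.1);")
        aln = column_alignment(t, ["ARND", "DNAR"])
        res = site_log_likelihood(t, m, None, aln)
        joint = branch_endpoint_posteriors(res)
        branches = t.branches()
        for b1, (u1, v1, _) in enumerate(branches):
            for b2, (u2, v2, _) in enumerate(branches):
                if v2 == u1:
                    m1 = joint[b1].sum(axis=1)  # marginal of the parent u1
                    m2 = joint[b2].sum(axis=0)  # marginal of the child v2
                    assert np.abs(m1 - m2).max() < 1e-10


class TestMapFeatures:
    def test_invariant_column_maps_to_near_zero(self):
        # with observed endpoints (2-leaf tree) the change is exactly 0;
        # with hidden internal nodes a small residual mass remains
        t2 = read_newick("(X:0.4,Y:0.6);")
        vecs2 = map_features(
            t2, poisson_model(), None, Alignment(["X", "Y"], ["W", "W"])
        )
        for feature in vecs2.features:
            assert np.abs(vecs2[feature]).max() < 1e-12
        t4 = read_newick("((A:0.1,B:0.1):0.1,C:0.2,D:0.1);")
        vecs4 = map_features(
            t4, poisson_model(), None, Alignment(list("ABCD"), ["W"] * 4)
        )
        assert np.abs(vecs4["substitution"]).max() < 0.05

    def test_two_leaf_substitution_is_one(self):
        t = read_newick("(X:0.1,Y:0.3);")
        aln = Alignment(["X", "Y"], ["A", "V"])
        V = map_feature(t, poisson_model(), None, aln, "substitution")
        assert V[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration_on_quartet(self, rng):
        m = random_small_model(4, rng)
        t = read_newick("((A:0.3,B:0.5):0.2,C:0.7,D:0.1);")
        cols = ["".join(rng.choice(list("ARND"), 4)) for _ in range(4)]
        aln = column_alignment(t, cols)
        vecs = map_features(t, m, None, aln, ("substitution", "volume", "charge"))
        for feature in ("substitution", "volume", "charge"):
            G = state_delta_matrix(TABLE, feature, m)
            for s, col in enumerate(cols):
                obs = {lab: "ARND".index(col[i]) for i, lab in enumerate(t.labels)}
                expected = brute_posterior_mean(t, m, obs, G)
                assert np.abs(vecs[feature][s, :] - expected).max() < 1e-10

    def test_posterior_mean_linearity(self, rng):
        m = random_small_model(4, rng)
        t = read_newick("((A:0.3,B:0.5):0.2,C:0.7,D:0.1);")
        aln = column_alignment(t, ["ARND", "NDAR"])
        vecs = map_features(t, m, None, aln, ("volume", "charge"))
        res = site_log_likelihood(t, m, None, aln)
        joint = branch_endpoint_posteriors(res)
        G = state_delta_matrix(TABLE, "volume", m) + state_delta_matrix(
            TABLE, "charge", m
        )
        combined = np.einsum("bacs,ac->sb", joint, G)
        assert np.abs(
            combined - (vecs["volume"] + vecs["charge"])
        ).max() < 1e-12

    def test_substitution_entries_in_unit_interval(self, rng):
        m = random_small_model(4, rng)
        t = read_newick("((A:0.3,B:0.5):0.2,C:0.7,D:0.1);")
        cols = ["".join(rng.choice(list("ARND"), 4)) for _ in range(10)]
        V = map_feature(t, m, None, column_alignment(t, cols), "substitution")
        assert (V >= -1e-12).all() and (V <= 1 + 1e-12).all()

    def test_expected_substitutions_monotone_in_branch_length(self):
        # lengthening a pendant branch below a hidden node increases the
        # posterior substitution probability on that branch
        m = poisson_model()
        aln = Alignment(list("ABC"), ["A", "A", "R"])
        vals = []
        for t_len in (0.05, 0.2, 0.5, 1.0, 2.0):
            t = read_newick(f"(A:{t_len},B:0.5,C:0.5);")
            b = [k for k, v in enumerate(t.branch_nodes) if t.labels[v] == "A"][0]
            vals.append(map_feature(t, m, None, aln, "substitution")[0, b])
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_codon_model_synonymous_changes_do_not_count(self):
        from cosubst.models import CodonModelParams, build_codon_model

        m = build_codon_model(CodonModelParams())
        G = state_delta_matrix(TABLE, "substitution", m)
        codons = m.space.symbols
        i = codons.index("CTA")  # leu
        j = codons.index("CTG")  # leu (synonymous)
        k = codons.index("ATG")  # met
        assert G[i, j] == 0.0 and G[i, k] == 1.0
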