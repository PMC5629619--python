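import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import linkdrp as lp
from linkdrp.learners import LearnerSpec
from linkdrp.link_filtering import LabeledPool, Partition, default_committee


def make_paired(features, responses):
    features = np.asarray(features, float)
    return lp.PairedSet(
        sample_ids=[f"s{i}" for i in range(features.shape[0])],
        features=features,
        responses=np.asarray(responses, float),
        lambda_used=0.3,
        k_prime_used=1,
    )


class TestComputeWeights:
    def test_brute_force_example(self):
        w = lp.compute_weights([[0.0, 0.0], [3.0, 4.0]], [[0.0, 1.0]])
        np.testing.assert_allclose(w, [1.0, np.sqrt(9 + 9)])

    def test_identical_row_has_zero_weight(self):
        w = lp.compute_weights([[1.0, 2.0], [5.0, 5.0]], [[1.0, 2.0], [0.0, 0.0]])
        assert w[0] == 0.0

    def test_extra_test_row_never_increases_weights(self):
        rng = np.random.default_rng(3)
        train = rng.standard_normal((6, 4))
        test = rng.standard_normal((3, 4))
        w1 = lp.compute_weights(train, test)
        w2 = lp.compute_weights(train, np.vstack([test, rng.standard_normal(4)]))
        assert (w2 <= w1 + 1e-12).all()

    def test_empty_test_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            lp.compute_weights(np.ones((2, 3)), np.empty((0, 3)))

    def test_column_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            lp.compute_weights(np.ones((2, 3)), np.ones((2, 4)))


class TestMedianPartition:
    def test_even_p_distinct_weights_disjoint_halves(self):
        G = make_paired(np.arange(8).reshape(4, 2), np.zeros(4))
        part = lp.median_partition(G, np.array([1.0, 4.0, 2.0, 3.0]))
        assert len(part.x) == 2 and len(part.z) == 2
        assert not set(part.x_indices) & set(part.z_indices)
        assert set(part.x_indices) == {0, 2}  # two smallest weights

    def test_odd_p_overlap_is_exactly_median_row(self):
        G = make_paired(np.arange(10).reshape(5, 2), np.zeros(5))
        part = lp.median_partition(G, np.array([5.0, 1.0, 3.0, 2.0, 4.0]))
        assert len(part.x) == 3 and len(part.z) == 3
        assert set(part.x_indices) & set(part.z_indices) == {2}

    def test_all_weights_equal_both_halves_full(self):
        G = make_paired(np.arange(6).reshape(3, 2), np.zeros(3))
        part = lp.median_partition(G, np.ones(3))
        assert len(part.x) == 3 and len(part.z) == 3

    def test_tied_weight_fixture_produces_overlap(self, tied_weights):
        D, y, T = tied_weights["D"], tied_weights["y"], tied_weights["T"]
        G = lp.build_paired_training(D, y)
        Gp = lp.build_paired_test(T)
        w = lp.compute_weights(G.features, Gp.features)
        assert len(np.unique(w)) < len(w)  # duplicated rows force ties
        part = lp.median_partition(G, w)
        assert len(part.x) + len(part.z) >= G.features.shape[0]


def _asymmetric_partition():
    """X side exactly linear (y = 2*f2); Z side blind to f2 with flat responses.

    The X-trained seed model is exact on Z (both predict 0 there) while the
    Z-trained model predicts 0 on X, incurring MSE 4.
    """
    x = LabeledPool(
        ["x0", "x1", "x2", "x3"],
        np.array([[1.0, 1.0], [2.0, -1.0], [3.0, 1.0], [4.0, -1.0]]),
        np.array([2.0, -2.0, 2.0, -2.0]),
    )
    z = LabeledPool(
        ["z0", "z1", "z2", "z3"],
        np.array([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0], [5.0, 0.0]]),
        np.zeros(4),
    )
    return Partition(med=0.0, x=x, z=z, x_indices=np.arange(4), z_indices=np.arange(4, 8))


class TestAssignSeedSet:
    def test_higher_error_side_becomes_s(self):
        part = _asymmetric_partition()
        seed = lp.assign_seed_set(part, LearnerSpec("rr", {"alpha": 1e-8}))
        assert seed.per_side_mse[0] == pytest.approx(0.0, abs=1e-6)
        assert seed.per_side_mse[1] == pytest.approx(4.0, rel=1e-6)
        assert seed.j_star == 2
        assert seed.S.sample_ids == part.z.sample_ids

    def test_tie_goes_to_x_side(self):
        pool = LabeledPool(
            ["a", "b", "c"],
            np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 0.5]]),
            np.array([1.0, 2.0, 3.0]),
        )
        part = Partition(0.0, pool, pool, np.arange(3), np.arange(3))
        seed = lp.assign_seed_set(part)
        assert seed.j_star == 1
        assert seed.S.sample_ids == pool.sample_ids

    def test_inverted_rule_flips_assignment(self):
        part = _asymmetric_partition()
        seed = lp.assign_seed_set(
            part, LearnerSpec("rr", {"alpha": 1e-8}), rule="inverted"
        )
        assert seed.j_star == 1
        assert seed.S.sample_ids == part.x.sample_ids

    def test_constant_features_error_names_side(self):
        const = LabeledPool(["a", "b"], np.ones((2, 2)), np.array([1.0, 2.0]))
        ok = LabeledPool(["c", "d"], np.array([[0.0, 1.0], [1.0, 0.0]]), np.ones(2))
        with pytest.raises(ValueError, match="Z"):
            lp.assign_seed_set(Partition(0.0, ok, const, np.arange(2), np.arange(2)))

    @pytest.mark.parametrize("p", range(4, 10))
    def test_seed_size_follows_median_counts(self, p):
        D, y, T, *_ = lp.generate(lp.SyntheticSpec(p=p, q=4, n=6, n_informative=3,
                                                   rng_seed=p))
        G = lp.build_paired_training(D, y)
        Gp = lp.build_paired_test(T)
        w = lp.compute_weights(G.features, Gp.features)
        assert len(np.unique(w)) == p  # continuous features: distinct weights
        seed = lp.assign_seed_set(lp.median_partition(G, w))
        expected = (p + 1) // 2 if p % 2 else p // 2
        assert len(seed.S) == expected


class TestDisagreementScores:
    def test_agreement_scores_zero(self):
        P = np.full((3, 4), 2.5)
        np.testing.assert_allclose(lp.disagreement_scores(P, np.ones(3) / 3), 0.0)

    def test_two_member_example(self):
        scores = lp.disagreement_scores(np.array([[0.0], [2.0]]), [0.5, 0.5])
        np.testing.assert_allclose(scores, [1.0])

    def test_three_member_example(self):
        scores = lp.disagreement_scores(np.array([[1.0], [1.0], [4.0]]), np.ones(3) / 3)
        np.testing.assert_allclose(scores, [2.0])

    def test_weight_sum_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            lp.disagreement_scores(np.ones((2, 3)), [0.5, 0.6])

    @given(
        arrays(float, (3, 5), elements=st.floats(-10, 10, width=32)),
        st.tuples(st.floats(0.01, 1), st.floats(0.01, 1), st.floats(0.01, 1)),
    )
    def test_matches_weighted_variance_oracle(self, P, raw_w):
        w = np.array(raw_w) / sum(raw_w)
        scores = lp.disagreement_scores(P, w)
        for j in range(P.shape[1]):
            mean = sum(w[i] * P[i, j] for i in range(3))
            expected = sum(w[i] * (P[i, j] - mean) ** 2 for i in range(3))
            assert scores[j] == pytest.approx(expected, abs=1e-9)


class TestQbcSelect:
    def _seed(self, rng_seed=0, n_s=8, n_u=6, n_feat=4):
        rng = np.random.default_rng(rng_seed)
        S = LabeledPool(
            [f"s{i}" for i in range(n_s)],
            rng.standard_normal((n_s, n_feat)),
            rng.standard_normal(n_s),
        )
        U = LabeledPool(
            [f"u{i}" for i in range(n_u)],
            rng.standard_normal((n_u, n_feat)),
            rng.standard_normal(n_u),
        )
        return lp.SeedAssignment(S=S, U=U, j_star=1, per_side_mse=(0.0, 0.0))

    def test_zero_iterations_is_identity(self):
        seed = self._seed()
        out = lp.qbc_select(seed, k_doubleprime=0)
        assert out.sample_ids == seed.S.sample_ids
        np.testing.assert_array_equal(out.features, seed.S.features)

    def test_row_conservation_each_iteration(self):
        seed = self._seed()
        total = len(seed.S) + len(seed.U)
        for k in range(0, 5):
            out = lp.qbc_select(seed, k_doubleprime=k)
            assert len(out) == len(seed.S) + k <= total

    def test_transferred_rows_come_from_u_with_their_responses(self):
        seed = self._seed(rng_seed=2)
        out = lp.qbc_select(seed, k_doubleprime=3)
        by_id = dict(zip(seed.U.sample_ids, seed.U.responses))
        for sid, resp in zip(out.sample_ids[len(seed.S):], out.responses[len(seed.S):]):
            assert sid in by_id and resp == by_id[sid]

    def test_selection_invariant_to_u_permutation(self):
        seed = self._seed(rng_seed=5)
        out = lp.qbc_select(seed, k_doubleprime=2)
        perm = np.random.default_rng(1).permutation(len(seed.U))
        seed_perm = lp.SeedAssignment(
            S=seed.S,
            U=LabeledPool(
                [seed.U.sample_ids[i] for i in perm],
                seed.U.features[perm],
                seed.U.responses[perm],
            ),
            j_star=1,
            per_side_mse=(0.0, 0.0),
        )
        out_perm = lp.qbc_select(seed_perm, k_doubleprime=2)
        assert set(out.sample_ids) == set(out_perm.sample_ids)

    def test_exhausted_u_errors(self):
        seed = self._seed(n_u=2)
        with pytest.raises(ValueError, match="exceeds"):
            lp.qbc_select(seed, k_doubleprime=3)


class TestLinkFilterCounts:
    @pytest.mark.parametrize("p,expected", [(20, 15), (21, 16)])
    def test_selected_size_formula_small(self, p, expected):
        """|S_final| = floor(p/2) + k'' (even) or (p+1)/2 + k'' (odd)."""
        D, y, T, *_ = lp.generate(lp.SyntheticSpec(p=p, q=6, n=8, n_informative=3,
                                                   rng_seed=p))
        S = lp.link_filter(lp.build_paired_training(D, y), lp.build_paired_test(T),
                           k_doubleprime=5)
        assert len(S) == expected
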