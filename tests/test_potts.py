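"""Potts model: Hamiltonian, enumeration, PLM, masked training, MCMC."""

import numpy as np
import pytest
from scipy.optimize import approx_fprime

from hpmtools.potts import (
    CapacityError,
    PottsModel,
    apc,
    contact_scores,
    enumerate_probabilities,
    estimate_marginals,
    exact_marginals,
    hamiltonian,
    hamiltonian_batch,
    partition_exact,
    plm_objective,
    sample_mcmc,
    train_masked,
    train_plm,
    _one_hot,
)
from hpmtools.structure import StructureAnnotation

from conftest import random_potts


class TestHamiltonian:
    def test_zero_parameters_give_zero(self):
        p = PottsModel(h=np.zeros((3, 5)), e=np.zeros((3, 3, 5, 5)))
        assert hamiltonian(p, "AC-") == 0.0

    def test_fields_only_additivity(self):
        h = np.arange(10, dtype=float).reshape(2, 5)
        p = PottsModel(h=h, e=np.zeros((2, 2, 5, 5)))
        assert hamiltonian(p, "GU") == h[0, 2] + h[1, 3]

    def test_vectorized_matches_triple_loop(self):
        p = random_potts(4, seed=11)
        rng = np.random.default_rng(0)
        X = rng.integers(0, 5, (20, 4))
        H = hamiltonian_batch(p, X)
        for r in range(20):
            ref = sum(p.h[k, X[r, k]] for k in range(4))
            ref += sum(p.e[k, l, X[r, k], X[r, l]]
                       for k in range(4) for l in range(k + 1, 4))
            assert H[r] == pytest.approx(ref, abs=1e-12)

    def test_length_mismatch_rejected(self):
        p = random_potts(3)
        with pytest.raises(ValueError):
            hamiltonian(p, "AC")


class TestPartition:
    def test_zero_parameters(self):
        p = PottsModel(h=np.zeros((4, 5)), e=np.zeros((4, 4, 5, 5)))
        assert partition_exact(p) == pytest.approx(4 * np.log(5))

    def test_m1_closed_form(self):
        h = np.array([[0.3, -0.2, 1.0, 0.0, -1.5]])
        p = PottsModel(h=h, e=np.zeros((1, 1, 5, 5)))
        assert partition_exact(p) == pytest.approx(
            np.log(np.exp(h[0]).sum()))

    def test_probabilities_sum_to_one(self):
        p = random_potts(3)
        _, probs = enumerate_probabilities(p)
        assert probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_capacity_refusal(self):
        p = PottsModel(h=np.zeros((20, 5)), e=np.zeros((20, 20, 5, 5)))
        with pytest.raises(CapacityError):
            partition_exact(p)

    def test_gauge_shift_invariance(self):
        p = random_potts(3, seed=2)
        _, probs = enumerate_probabilities(p)
        shifted = PottsModel(h=p.h + np.array([[1.7], [-0.4], [3.0]]),
                             e=p.e.copy())
        _, probs2 = enumerate_probabilities(shifted)
        assert np.allclose(probs, probs2, atol=1e-10)


class TestPLM:
    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        M, K = 3, 5
        X = rng.integers(0, K, (12, M))
        w = rng.uniform(0.5, 1.5, 12)
        Xf = _one_hot(X, K)
        theta = rng.normal(0, 0.1, M * K + (M * K) ** 2)
        val, grad = plm_objective(theta, Xf, X, w, M, K, 0.01, 0.1)
        num = approx_fprime(
            theta, lambda t: plm_objective(t, Xf, X, w, M, K, 0.01, 0.1)[0],
            1e-6)
        denom = np.maximum(np.abs(grad), 1.0)
        assert np.max(np.abs(grad - num) / denom) < 1e-4

    def test_independent_uniform_data_gives_tiny_couplings(self):
        # independence limit: couplings are pure sampling noise, O(1/sqrt(N))
        rng = np.random.default_rng(8)
        X = rng.integers(0, 5, (4000, 3))
        model = train_plm(X, lambda_h=0.01, lambda_e=0.1)
        assert np.abs(model.e).max() < 0.3
        assert np.abs(model.e).mean() < 0.05

    def test_perfectly_correlated_pair_gets_positive_diagonal_coupling(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 4, 400)
        b = rng.integers(0, 4, 400)
        X = np.stack([a, a, b], axis=1)  # site 0 == site 1 always
        model = train_plm(X)
        diag = np.mean([model.e[0, 1, c, c] for c in range(4)])
        off = np.mean([model.e[0, 1, c, d]
                       for c in range(4) for d in range(4) if c != d])
        assert diag > off + 0.1

    def test_deterministic_from_zero_init(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 5, (50, 3))
        m1 = train_plm(X)
        m2 = train_plm(X)
        assert np.array_equal(m1.h, m2.h) and np.array_equal(m1.e, m2.e)

    def test_no_couplings_mode_fits_fields_only(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 5, (200, 3))
        m = train_plm(X, no_couplings=True)
        assert np.all(m.e == 0.0)
        # fitted fields reproduce empirical frequencies (softmax of h)
        p = np.exp(m.h) / np.exp(m.h).sum(axis=1, keepdims=True)
        emp = np.stack([np.bincount(X[:, k], minlength=5) / 200
                        for k in range(3)])
        assert np.abs(p - emp).max() < 0.02


class TestMasked:
    def test_paired_joint_equals_smoothed_empirical(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 5, (40, 2))
        ann = StructureAnnotation(nested_pairs=[(0, 1)])
        model = train_masked(X, np.ones(40), pairs=ann)
        seqs, probs = enumerate_probabilities(model)
        joint = np.zeros((5, 5))
        for s, p in zip(seqs, probs):
            joint[s[0], s[1]] += p
        counts = np.zeros((5, 5))
        np.add.at(counts, (X[:, 0], X[:, 1]), 1.0)
        expected = (counts + 1) / (40 + 25)
        assert np.abs(joint - expected).max() < 1e-12
        assert np.all(model.h[[0, 1]] == 0.0)

    def test_unpaired_marginal_equals_smoothed_empirical(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 5, (30, 2))
        model = train_masked(X, np.ones(30), pairs=StructureAnnotation())
        p1, _ = exact_marginals(model)
        counts = np.stack([np.bincount(X[:, k], minlength=5) for k in range(2)])
        expected = (counts + 1) / (30 + 5)
        assert np.abs(p1 - expected).max() < 1e-12

    def test_masked_partition_is_one(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 5, (30, 3))
        ann = StructureAnnotation(nested_pairs=[(0, 2)])
        model = train_masked(X, np.ones(30), pairs=ann)
        assert partition_exact(model) == pytest.approx(0.0, abs=1e-10)

    def test_overlapping_pairs_rejected(self):
        X = np.zeros((5, 3), dtype=int)
        ann = StructureAnnotation(nested_pairs=[(0, 1)],
                                  pseudoknot_pairs=[(1, 2)])
        with pytest.raises(ValueError):
            train_masked(X, np.ones(5), pairs=ann)

    def test_exclude_pseudoknots_zeroes_their_couplings(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 5, (30, 4))
        ann = StructureAnnotation(nested_pairs=[(0, 3)],
                                  pseudoknot_pairs=[(1, 2)])
        m = train_masked(X, np.ones(30), pairs=ann, include_pseudoknots=False)
        assert np.all(m.e[1, 2] == 0.0)
        assert np.any(m.e[0, 3] != 0.0)


class TestMCMC:
    def test_uniform_target_frequencies(self):
        p = PottsModel(h=np.zeros((2, 5)), e=np.zeros((2, 2, 5, 5)))
        X = sample_mcmc(p, 4000, burn_in=300, seed=0)
        freqs = np.bincount(X.ravel(), minlength=5) / X.size
        se = np.sqrt(0.2 * 0.8 / X.size)
        assert np.abs(freqs - 0.2).max() < 3 * se

    def test_marginals_match_enumeration(self):
        p = random_potts(3, seed=9)
        truth, _ = exact_marginals(p)
        X = sample_mcmc(p, 10_000, burn_in=2000, seed=1)
        est, _ = estimate_marginals(X)
        tv = 0.5 * np.abs(truth - est).sum(axis=1)
        assert tv.max() < 0.02

    def test_seed_determinism(self):
        p = random_potts(3)
        X1 = sample_mcmc(p, 50, burn_in=100, seed=42)
        X2 = sample_mcmc(p, 50, burn_in=100, seed=42)
        assert np.array_equal(X1, X2)


class TestMarginalEstimation:
    def test_single_sample_indicator(self):
        p1, p2 = estimate_marginals(np.array([[0, 4, 2]]))
        assert p1[0, 0] == 1.0 and p1[1, 4] == 1.0 and p1[2, 2] == 1.0
        assert p2[0, 1, 0, 4] == 1.0

    def test_pairwise_consistent_with_single_site(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 5, (200, 4))
        p1, p2 = estimate_marginals(X)
        for k in range(4):
            for l in range(4):
                if k == l:
                    continue
                assert np.allclose(p2[k, l].sum(axis=1), p1[k], atol=1e-12)

    def test_converges_to_enumerated_truth(self):
        p = random_potts(3, seed=3)
        seqs, probs = enumerate_probabilities(p)
        rng = np.random.default_rng(7)
        draw = seqs[rng.choice(len(seqs), size=20_000, p=probs)]
        est, _ = estimate_marginals(draw)
        truth, _ = exact_marginals(p)
        assert np.abs(est - truth).max() < 0.02


class TestContacts:
    def test_zero_couplings_all_zero_scores(self):
        p = PottsModel(h=np.zeros((4, 5)), e=np.zeros((4, 4, 5, 5)))
        ranked, S = contact_scores(p)
        assert all(s == 0.0 for s, _, _ in ranked)

    def test_strongly_covarying_pair_ranked_first(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 4, 300)
        comp = 3 - a  # deterministic complementary partner
        other = rng.integers(0, 4, (300, 2))
        X = np.column_stack([a, other[:, 0], comp, other[:, 1]])
        ann = StructureAnnotation(nested_pairs=[(0, 2)])
        model = train_masked(X, np.ones(300), pairs=ann)
        ranked, _ = contact_scores(model)
        assert ranked[0][1:] == (0, 2)

    def test_apc_annihilates_rank_one_matrix(self):
        v = np.array([1.0, 2.0, 0.5, 3.0])
        S = np.outer(v, v)
        np.fill_diagonal(S, 0.0)
        # restore the rank-one diagonal so row means match the outer product
        corrected = apc(np.outer(v, v))
        off = corrected[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 1e-9
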