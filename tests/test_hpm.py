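"""Hidden Potts model: assembly, decompositions, exact oracle, IS scoring."""

import numpy as np
import pytest
from scipy.special import logsumexp

from hpmtools.hpm import (
    AssemblyError,
    Decomposition,
    HiddenPottsModel,
    align_is,
    assemble_hpm,
    emit_sequences,
    enumerate_decompositions,
    exact_score,
    joint_logprob_unnorm,
    map_pi_to_decomposition,
    null_logprob,
    score_is,
)
from hpmtools.phmm import (
    PHMMPath,
    ProfileHMM,
    ZeroProbabilityError,
    forward_glocal,
    viterbi_glocal,
)
from hpmtools.potts import PottsModel

from conftest import enumerate_glocal_paths, random_potts, toy_hpm, toy_phmm


def phmm_equivalent_to(hpm: HiddenPottsModel) -> ProfileHMM:
    """Delete-character pHMM equal in law to a zero-coupling HPM.

    For a coupling-free HPM the deletion probability at node k is the
    normalized field mass on the deletion character, independent of the
    rest of the sequence, so an equivalent pHMM exists: advancing from any
    state at node k chooses D_{k+1} with that probability, and match
    emissions are the fields conditioned on non-deletion.
    """
    M = hpm.M
    p = np.exp(hpm.potts.h)
    p /= p.sum(axis=1, keepdims=True)
    open_, ext = hpm.t_open, hpm.t_ext
    tm = np.zeros((M + 1, 3))
    ti = np.zeros((M + 1, 3))
    td = np.zeros((M + 1, 3))
    for k in range(M + 1):
        # advancing from node k enters node k+1, whose deletion mass is
        # the field probability of the deletion character there
        pd_next = p[k, 4] if k < M else 0.0
        tm[k] = [(1 - open_[k]) * (1 - pd_next), open_[k],
                 (1 - open_[k]) * pd_next]
        ti[k] = [(1 - ext[k]) * (1 - pd_next), ext[k],
                 (1 - ext[k]) * pd_next]
        td[k] = tm[k]
    td[0] = 0.0
    e_match = p[:, :4] / p[:, :4].sum(axis=1, keepdims=True)
    return ProfileHMM(M=M, tm=tm, ti=ti, td=td, e_match=e_match,
                      e_insert=hpm.e_insert.copy(),
                      background=hpm.background.copy())


def zero_coupling_hpm(M: int = 3, seed: int = 5) -> HiddenPottsModel:
    rng = np.random.default_rng(seed)
    h = np.log(rng.dirichlet(np.full(5, 4.0), size=M))
    potts = PottsModel(h=h, e=np.zeros((M, M, 5, 5)))
    return HiddenPottsModel(
        potts=potts,
        t_open=np.array([0.2, 0.1, 0.15, 0.1][: M + 1]
                        if M == 3 else np.full(M + 1, 0.1)),
        t_ext=np.full(M + 1, 0.3),
        e_insert=np.array([0.3, 0.2, 0.25, 0.25]),
        background=np.full(4, 0.25),
    )


class TestAssembly:
    def test_mismatched_m_rejected(self, phmm3):
        with pytest.raises(AssemblyError):
            assemble_hpm(phmm3, random_potts(4))

    def test_transition_collapse(self, phmm3):
        hpm = assemble_hpm(phmm3, random_potts(3))
        assert np.allclose(hpm.t_open, phmm3.tm[:, 1])
        assert np.allclose(hpm.t_ext, phmm3.ti[:, 1])

    def test_serialization_round_trip(self, tmp_path, phmm3):
        from hpmtools.serialize import load_hpm, save_hpm

        hpm = assemble_hpm(phmm3, random_potts(3))
        path = tmp_path / "model.hpm"
        save_hpm(hpm, path)
        again = load_hpm(path)
        assert np.array_equal(again.potts.h, hpm.potts.h)
        assert np.array_equal(again.potts.e, hpm.potts.e)
        assert np.array_equal(again.t_open, hpm.t_open)
        assert np.array_equal(again.e_insert, hpm.e_insert)


class TestDecompositionMapping:
    def test_all_match_path(self):
        pi = PHMMPath([("M", 1), ("M", 2), ("M", 3)])
        dec = map_pi_to_decomposition(pi, "ACG")
        assert list(dec.xm) == [0, 1, 2]
        assert len(dec.xi) == 0
        assert dec.ins_counts.sum() == 0

    def test_delete_contributes_deletion_character(self):
        pi = PHMMPath([("M", 1), ("D", 2), ("M", 3)])
        dec = map_pi_to_decomposition(pi, "AC")
        assert list(dec.xm) == [0, 4, 1]  # "A-C"

    def test_two_to_the_m_labelings_are_distinct(self):
        # all 2^3 M/D labelings of the insert-free sigma map to distinct xm
        import itertools

        seen = set()
        for labels in itertools.product("MD", repeat=3):
            L = labels.count("M")
            x = "ACG"[:L]
            pi = PHMMPath([(lab, k + 1) for k, lab in enumerate(labels)])
            dec = map_pi_to_decomposition(pi, x)
            seen.add(tuple(dec.xm))
        assert len(seen) == 8

    def test_dealign_reconstructs_sequence(self, phmm3, hpm3):
        from hpmtools.phmm import sample_decompositions

        x = "ACGUA"
        fwd = forward_glocal(phmm3, x)
        dec = sample_decompositions(fwd, 200, seed=8)
        codes = hpm3.encode(x)
        for r in range(200):
            d = Decomposition(
                ins_counts=dec.ins_counts[r].astype(np.int64),
                xm=dec.xm[r].astype(np.int64),
                xi=fwd.xi[dec.ins_mask[r]],
            )
            assert np.array_equal(d.dealign(), codes)


class TestJointLogprob:
    def test_zero_potts_no_inserts_reduces_to_transitions(self):
        hpm = toy_hpm(3)
        zero = HiddenPottsModel(
            potts=PottsModel(h=np.zeros((3, 5)), e=np.zeros((3, 3, 5, 5))),
            t_open=hpm.t_open, t_ext=hpm.t_ext,
            e_insert=hpm.e_insert, background=hpm.background)
        dec = Decomposition(ins_counts=np.zeros(4, dtype=np.int64),
                            xm=np.array([0, 1, 2]), xi=np.array([], dtype=np.int64))
        expected = np.log(1 - zero.t_open).sum()
        assert joint_logprob_unnorm(zero, dec) == pytest.approx(expected)

    def test_insert_extension_additivity(self, hpm3):
        d1 = Decomposition(ins_counts=np.array([0, 1, 0, 0]),
                           xm=np.array([0, 1, 2]), xi=np.array([3]))
        d2 = Decomposition(ins_counts=np.array([0, 2, 0, 0]),
                           xm=np.array([0, 1, 2]), xi=np.array([3, 2]))
        delta = joint_logprob_unnorm(hpm3, d2) - joint_logprob_unnorm(hpm3, d1)
        expected = np.log(hpm3.t_ext[1]) + np.log(hpm3.e_insert[2])
        assert delta == pytest.approx(expected)

    def test_hand_computed_m2_toy(self):
        h = np.zeros((2, 5))
        h[0, 0] = 0.5
        e = np.zeros((2, 2, 5, 5))
        e[0, 1, 0, 1] = e[1, 0, 1, 0] = 0.7
        potts = PottsModel(h=h, e=e)
        hpm = HiddenPottsModel(potts=potts, t_open=np.array([0.1, 0.2, 0.3]),
                               t_ext=np.full(3, 0.4),
                               e_insert=np.full(4, 0.25),
                               background=np.full(4, 0.25))
        dec = Decomposition(ins_counts=np.array([0, 1, 0]),
                            xm=np.array([0, 1]), xi=np.array([2]))
        # transitions: no 5' flank, open at node 1, close, no 3' insert
        expected = (np.log(0.9) + np.log(0.2) + np.log(1 - 0.4) + np.log(0.7)
                    + np.log(0.25)   # the inserted G
                    + 0.5 + 0.7)     # h_1(A) + e_12(A, C)
        assert joint_logprob_unnorm(hpm, dec) == pytest.approx(expected)

    def test_dimension_mismatch_rejected(self, hpm3):
        with pytest.raises(ValueError):
            joint_logprob_unnorm(hpm3, Decomposition(
                ins_counts=np.zeros(4, dtype=np.int64),
                xm=np.array([0, 1]), xi=np.array([], dtype=np.int64)))


class TestExactScore:
    def test_single_decomposition_equals_joint(self):
        hpm = zero_coupling_hpm(2)
        # forbid inserts and deletions so only one decomposition remains
        no_ins = HiddenPottsModel(
            potts=hpm.potts, t_open=np.zeros(3), t_ext=np.zeros(3),
            e_insert=hpm.e_insert, background=hpm.background)
        decs = [d for d in enumerate_decompositions(no_ins, "AC")
                if np.isfinite(joint_logprob_unnorm(no_ins, d))]
        finite = [joint_logprob_unnorm(no_ins, d) for d in decs
                  if joint_logprob_unnorm(no_ins, d) > -np.inf]
        assert exact_score(no_ins, "AC") == pytest.approx(logsumexp(finite))

    def test_adding_decompositions_increases_pstar(self, hpm3):
        # P*(x) strictly exceeds the joint of any single decomposition
        decs = enumerate_decompositions(hpm3, "AC")
        joints = [joint_logprob_unnorm(hpm3, d) for d in decs]
        assert exact_score(hpm3, "AC") > max(joints)

    def test_capacity_refusal(self, hpm3):
        with pytest.raises(Exception):
            enumerate_decompositions(hpm3, "ACGU" * 8, limit=100)


class TestImportanceSampling:
    def test_estimate_converges_to_exact(self, hpm3, phmm3):
        for x in ["AC", "ACGU"]:
            ex = exact_score(hpm3, x)
            res = score_is(hpm3, phmm3, x, R=100_000, seed=3)
            rel_se = np.sqrt(max(res.R / res.ess - 1.0, 0.0) / res.R)
            assert abs(res.log_pstar - ex) < 3 * max(rel_se, 1e-3)

    def test_proposal_equals_target_constant_weights(self):
        hpm = zero_coupling_hpm(3)
        prop = phmm_equivalent_to(hpm)
        x = "ACG"
        # equivalence of laws: pHMM forward equals exact HPM score
        assert forward_glocal(prop, x).logp == pytest.approx(
            exact_score(hpm, x), abs=1e-9)
        res = score_is(hpm, prop, x, R=64, seed=0)
        assert res.ess == pytest.approx(64.0, rel=1e-6)
        assert res.log_pstar == pytest.approx(exact_score(hpm, x), abs=1e-6)
        res1 = score_is(hpm, prop, x, R=1, seed=5)
        assert res1.log_pstar == pytest.approx(exact_score(hpm, x), abs=1e-6)

    def test_unbiased_in_probability_space(self, hpm3, phmm3):
        x = "ACG"
        ex = np.exp(exact_score(hpm3, x))
        ests = [np.exp(score_is(hpm3, phmm3, x, R=100, seed=s).log_pstar)
                for s in range(200)]
        se = np.std(ests) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - ex) < 3 * se

    def test_seed_determinism(self, hpm3, phmm3):
        r1 = score_is(hpm3, phmm3, "ACGU", R=500, seed=11)
        r2 = score_is(hpm3, phmm3, "ACGU", R=500, seed=11)
        assert r1.log_pstar == r2.log_pstar
        assert r1.ess == r2.ess
        assert np.array_equal(r1.best_sample.decomposition.xm,
                              r2.best_sample.decomposition.xm)

    def test_zero_probability_sequence_raises(self):
        hmm = toy_phmm(3)
        # remove all delete and insert mass: only L == M is reachable
        tm = np.tile([1.0, 0.0, 0.0], (4, 1))
        rigid = ProfileHMM(M=3, tm=tm, ti=tm.copy(), td=np.vstack(
            [[0, 0, 0]] + [[1.0, 0.0, 0.0]] * 3),
            e_match=hmm.e_match, e_insert=hmm.e_insert,
            background=hmm.background)
        hpm = toy_hpm(3)
        with pytest.raises(ZeroProbabilityError):
            score_is(hpm, rigid, "AC", R=10, seed=0)

    def test_score_independent_of_sample_count_for_forward(self, phmm3):
        # Forward score of the proposal does not depend on R by construction
        f1 = forward_glocal(phmm3, "ACG").logp
        f2 = forward_glocal(phmm3, "ACG").logp
        assert f1 == f2


class TestNullModel:
    def test_uniform_background_length_ten(self, hpm3):
        hpm = hpm3
        assert null_logprob(hpm, "ACGUACGUAC") == pytest.approx(
            -10 * np.log(4))

    def test_concatenation_additivity(self, hpm3):
        a, b = "ACG", "UUA"
        assert null_logprob(hpm3, a + b) == pytest.approx(
            null_logprob(hpm3, a) + null_logprob(hpm3, b))

    def test_empty_sequence(self, hpm3):
        assert null_logprob(hpm3, "") == 0.0


class TestEmission:
    def test_zero_insert_open_emits_match_only(self):
        hpm = zero_coupling_hpm(3)
        rigid = HiddenPottsModel(potts=hpm.potts, t_open=np.zeros(4),
                                 t_ext=np.zeros(4), e_insert=hpm.e_insert,
                                 background=hpm.background)
        res = emit_sequences(rigid, 50, burn_in=200, seed=1)
        for d, s in zip(res.decompositions, res.sequences):
            assert d.ins_counts.sum() == 0
            assert len(s) == np.sum(d.xm != 4)

    def test_emitted_alignment_round_trips(self, tmp_path):
        from hpmtools.stockholm import read_stockholm, write_stockholm

        hpm = toy_hpm(3)
        res = emit_sequences(hpm, 20, burn_in=200, seed=2)
        path = tmp_path / "emit.sto"
        write_stockholm(res.msa, str(path))
        again = read_stockholm(str(path))
        assert again.rows == res.msa.rows

    def test_seed_determinism(self):
        hpm = toy_hpm(3)
        r1 = emit_sequences(hpm, 10, burn_in=100, seed=7)
        r2 = emit_sequences(hpm, 10, burn_in=100, seed=7)
        assert r1.sequences == r2.sequences


class TestRankInversion:
    """A strong non-nested coupling re-ranks alignments the pHMM misorders.

    Toy version of the importance-sampling re-ranking schematic: node pair
    (1, 3) is "base-paired" with a strong G:C coupling. For x = "GC" one
    consensus node must be deleted. The proposal pHMM's emissions make the
    pair-breaking alignment (delete node 3) its Viterbi optimum, but the
    HPM's coupling term prefers the pair-satisfying alignment (delete
    node 2, keeping G and C at the paired nodes).
    """

    def build(self):
        M = 3
        tm = np.tile([0.8, 0.1, 0.1], (M + 1, 1))
        tm[M] = [0.9, 0.1, 0.0]
        ti = np.tile([0.6, 0.3, 0.1], (M + 1, 1))
        ti[M] = [0.7, 0.3, 0.0]
        td = np.vstack([[0, 0, 0]] + [[0.7, 0.1, 0.2]] * (M - 1)
                       + [[0.9, 0.1, 0.0]])
        # pHMM sees node 2 as a C-emitter: Viterbi keeps C there and
        # deletes node 3 instead of node 2
        e_match = np.array([
            [0.05, 0.05, 0.85, 0.05],   # node 1: G
            [0.10, 0.60, 0.10, 0.20],   # node 2: C-leaning
            [0.20, 0.40, 0.20, 0.20],   # node 3: weakly C
        ])
        prop = ProfileHMM(M=M, tm=tm, ti=ti, td=td, e_match=e_match,
                          e_insert=np.full(4, 0.25),
                          background=np.full(4, 0.25))
        h = np.log(np.array([
            [0.05, 0.05, 0.60, 0.05, 0.25],
            [0.15, 0.30, 0.15, 0.15, 0.25],
            [0.15, 0.30, 0.15, 0.15, 0.25],
        ]))
        e = np.zeros((M, M, 5, 5))
        e[0, 2, 2, 1] = 4.0      # strong G:C "pseudoknot" coupling
        e[2, 0, 1, 2] = 4.0
        potts = PottsModel(h=h, e=e)
        hpm = HiddenPottsModel(potts=potts, t_open=tm[:, 1].copy(),
                               t_ext=ti[:, 1].copy(),
                               e_insert=np.full(4, 0.25),
                               background=np.full(4, 0.25))
        return hpm, prop

    def test_hpm_reranks_pair_satisfying_alignment_first(self):
        hpm, prop = self.build()
        x = "GC"
        vit, _ = viterbi_glocal(prop, x)
        vit_dec = map_pi_to_decomposition(vit, x)
        assert list(vit_dec.xm) == [2, 1, 4]  # pair-breaking: "GC-"
        # exhaustive argmax under the HPM selects the pair-satisfying "G-C"
        decs = enumerate_decompositions(hpm, x)
        joints = [joint_logprob_unnorm(hpm, d) for d in decs]
        best = decs[int(np.argmax(joints))]
        assert list(best.xm) == [2, 4, 1]
        # the sampled best alignment agrees with the exhaustive argmax
        sample, _ = align_is(hpm, prop, x, R=3000, seed=2)
        assert list(sample.decomposition.xm) == [2, 4, 1]
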