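"""Hidden Potts model: assembly, emission, and importance-sampling scoring.

A hidden Potts model emits the match columns of an alignment jointly from a
Potts distribution over the 5-letter alphabet (deletions are emitted "dummy"
characters, not states) while insertions follow a profile-HMM-style affine
transition process. Because the all-by-all couplings break the Markov
factorization needed for dynamic programming, sequences are aligned and
scored by importance sampling: alignments are proposed from the exact
posterior of a profile HMM (stochastic traceback of the Forward matrix) and
re-weighted under the HPM:

    P*(x) ~= (1/R) sum_r  P*(xm, xi, sigma | r-th proposal) / Q(r-th proposal)

The estimate is unnormalized (the Potts partition function is never
computed), so log-odds scores are comparable within one model, not across
models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .alphabet import RNA, Alphabet
from .msa import MSA
from .phmm import (
    ForwardResult,
    PHMMPath,
    ProfileHMM,
    SampledDecompositions,
    ZeroProbabilityError,
    forward_glocal,
    sample_decompositions,
)
from .potts import PottsModel, CapacityError, hamiltonian_batch, sample_mcmc

LN2 = np.log(2.0)


class AssemblyError(ValueError):
    """Component models are incompatible (e.g. mismatched M)."""


@dataclass
class HiddenPottsModel:
    """Potts match emission plus insert-only affine transitions.

    ``t_open[k]`` is the probability of opening an insert after node k
    (k = 0 is the 5' flank, k = M the 3' flank); ``t_ext[k]`` the insert
    self-transition. Deletions are characters emitted by the Potts model,
    so the transition process never branches over delete states.
    """

    potts: PottsModel
    t_open: np.ndarray
    t_ext: np.ndarray
    e_insert: np.ndarray
    background: np.ndarray
    alphabet: Alphabet = field(default_factory=lambda: RNA)

    def __post_init__(self) -> None:
        M = self.potts.M
        if self.t_open.shape != (M + 1,) or self.t_ext.shape != (M + 1,):
            raise AssemblyError("insert transition arrays must have length M+1")
        if np.any((self.t_open < 0) | (self.t_open >= 1)):
            raise AssemblyError("insert-open probabilities must be in [0, 1)")
        if np.any((self.t_ext < 0) | (self.t_ext >= 1)):
            raise AssemblyError("insert-extend probabilities must be in [0, 1)")
        if not np.isclose(self.e_insert.sum(), 1.0, atol=1e-9):
            raise AssemblyError("insert emissions must sum to 1")

    @property
    def M(self) -> int:
        return self.potts.M

    def encode(self, x: str) -> np.ndarray:
        return np.array([self.alphabet.index(c) for c in x], dtype=np.int64)


def assemble_hpm(phmm: ProfileHMM, potts: PottsModel) -> HiddenPottsModel:
    """Combine pHMM transitions/insert emissions with a Potts match core.

    The pHMM's nine transition types collapse onto the HPM's insert-only
    process: insert-open at node k is the pHMM's M->I probability,
    insert-extend is I->I, and all delete-related transition mass folds
    into the match advance (every HPM path visits every match node).
    """
    if phmm.M != potts.M:
        raise AssemblyError(f"pHMM M={phmm.M} != Potts M={potts.M}")
    return HiddenPottsModel(
        potts=potts,
        t_open=phmm.tm[:, 1].copy(),
        t_ext=phmm.ti[:, 1].copy(),
        e_insert=phmm.e_insert.copy(),
        background=phmm.background.copy(),
        alphabet=phmm.alphabet,
    )


@dataclass
class Decomposition:
    """One (sigma, xm, xi) triple for a sequence x.

    ``ins_counts`` (length M+1) is the number of insert emissions after
    each node and fully determines sigma; ``xm`` (length M) are Potts
    characters (4 = deletion); ``xi`` are insert residues in order.
    """

    ins_counts: np.ndarray
    xm: np.ndarray
    xi: np.ndarray

    def dealign(self) -> np.ndarray:
        """Reconstruct the unaligned sequence (integer codes)."""
        out: list[int] = []
        pos = 0
        M = len(self.xm)
        for k in range(M + 1):
            if k > 0 and self.xm[k - 1] != 4:
                out.append(int(self.xm[k - 1]))
            c = int(self.ins_counts[k])
            out.extend(int(v) for v in self.xi[pos:pos + c])
            pos += c
        return np.array(out, dtype=np.int64)


@dataclass
class AlignmentSample:
    """A proposed decomposition with its importance weight."""

    decomposition: Decomposition
    log_numerator: float
    log_q: float

    @property
    def log_weight(self) -> float:
        return self.log_numerator - self.log_q


@dataclass
class ScoreResult:
    """Importance-sampling estimate of log P*(x) and the bit score."""

    log_pstar: float
    log_odds_bits: float
    best_sample: AlignmentSample
    R: int
    ess: float


def map_pi_to_decomposition(pi: PHMMPath, x: str,
                            alphabet: Alphabet = RNA) -> Decomposition:
    """Map a pHMM path (with delete states) to the HPM decomposition.

    M and D states both map to the HPM match visit at the same node (D
    contributes the deletion character to xm); I states contribute their
    residues to xi. The mapping is deterministic and injective.
    """
    xi_codes = [alphabet.index(c) for c in x]
    nodes_seen = 0
    xm: list[int] = []
    ins: list[int] = []
    xi_out: list[int] = []
    pos = 0
    counts: dict[int, int] = {}
    cur_node = 0
    for kind, node in pi.states:
        if kind == "M":
            if node != cur_node + 1:
                raise ValueError(f"node jump {cur_node}->{node}")
            xm.append(xi_codes[pos])
            pos += 1
            cur_node = node
        elif kind == "D":
            if node != cur_node + 1:
                raise ValueError(f"node jump {cur_node}->{node}")
            xm.append(4)
            cur_node = node
        else:
            if node != cur_node:
                raise ValueError(f"insert at node {node} while at {cur_node}")
            counts[node] = counts.get(node, 0) + 1
            xi_out.append(xi_codes[pos])
            pos += 1
    if pos != len(xi_codes):
        raise ValueError("path does not account for all residues")
    M = cur_node
    ins_counts = np.array([counts.get(k, 0) for k in range(M + 1)],
                          dtype=np.int64)
    return Decomposition(ins_counts=ins_counts,
                         xm=np.array(xm, dtype=np.int64),
                         xi=np.array(xi_out, dtype=np.int64))


# ---------------------------------------------------------------------------
# Unnormalized joint probability


def _log_transition_terms(hpm: HiddenPottsModel):
    with np.errstate(divide="ignore"):
        return (
            np.log1p(-hpm.t_open),
            np.log(hpm.t_open),
            np.log(hpm.t_ext),
            np.log1p(-hpm.t_ext),
            np.log(hpm.e_insert),
        )


def log_pt_sigma(hpm: HiddenPottsModel, ins_counts: np.ndarray) -> np.ndarray:
    """log P_t(sigma) for an (R, M+1) batch of insert-count vectors."""
    c = np.atleast_2d(ins_counts)
    l_no, l_open, l_ext, l_close, _ = _log_transition_terms(hpm)
    with np.errstate(invalid="ignore"):
        # guard 0 * (-inf) when extensions are impossible but unused
        ext_term = np.where(c > 1, (c - 1) * l_ext, 0.0)
        opened = l_open + ext_term + l_close
    terms = np.where(c == 0, l_no, opened)
    return terms.sum(axis=1)


def joint_logprob_unnorm(hpm: HiddenPottsModel, dec: Decomposition) -> float:
    """log P*(x, xm, xi, sigma) = log P_t + log P_i + H(xm)."""
    if len(dec.xm) != hpm.M or len(dec.ins_counts) != hpm.M + 1:
        raise ValueError("decomposition dimensions do not match the model")
    if len(dec.xi) != int(dec.ins_counts.sum()):
        raise ValueError("insert residue count mismatch")
    lpt = float(log_pt_sigma(hpm, dec.ins_counts[None, :])[0])
    lei = np.log(hpm.e_insert)
    lpi = float(lei[dec.xi].sum()) if len(dec.xi) else 0.0
    H = float(hamiltonian_batch(hpm.potts, dec.xm[None, :])[0])
    return lpt + lpi + H


def null_logprob(hpm: HiddenPottsModel, x: str) -> float:
    """i.i.d. background null model over the observed length."""
    codes = hpm.encode(x)
    if len(codes) == 0:
        return 0.0
    return float(np.log(hpm.background)[codes].sum())


# ---------------------------------------------------------------------------
# Exact enumeration oracle (tiny models only)


def enumerate_decompositions(hpm: HiddenPottsModel, x: str,
                             limit: int = 10**6) -> list[Decomposition]:
    """All decompositions (sigma, xm, xi) consistent with x.

    A decomposition is a choice of which match nodes emit deletions plus a
    placement of the remaining residues into insert runs; residue order is
    fixed, so the assignment of residues to slots is determined. Refuses
    when the count exceeds ``limit``.
    """
    import itertools
    from math import comb

    codes = hpm.encode(x)
    M, L = hpm.M, len(codes)
    total = 0
    for d in range(M + 1):
        n_ins = L - (M - d)
        if n_ins < 0:
            continue
        total += comb(M, d) * comb(n_ins + M, M)
        if total > limit:
            raise CapacityError("too many decompositions to enumerate")
    decs: list[Decomposition] = []
    for d in range(M + 1):
        n_ins = L - (M - d)
        if n_ins < 0:
            continue
        for del_nodes in itertools.combinations(range(1, M + 1), d):
            dset = set(del_nodes)
            for bars in itertools.combinations(range(n_ins + M), M):
                counts = []
                prev = -1
                for b in bars:
                    counts.append(b - prev - 1)
                    prev = b
                counts.append(n_ins + M - 1 - prev)
                ins_counts = np.array(counts, dtype=np.int64)
                xm = np.zeros(M, dtype=np.int64)
                xi: list[int] = []
                pos = 0
                for k in range(M + 1):
                    if k > 0:
                        if k in dset:
                            xm[k - 1] = 4
                        else:
                            xm[k - 1] = codes[pos]
                            pos += 1
                    c = int(ins_counts[k])
                    xi.extend(int(v) for v in codes[pos:pos + c])
                    pos += c
                decs.append(Decomposition(ins_counts=ins_counts, xm=xm,
                                          xi=np.array(xi, dtype=np.int64)))
    return decs


def exact_score(hpm: HiddenPottsModel, x: str, limit: int = 10**6) -> float:
    """log P*(x) by exhaustive summation over all decompositions."""
    decs = enumerate_decompositions(hpm, x, limit=limit)
    if not decs:
        raise ZeroProbabilityError("no decomposition produces this sequence")
    joints = [joint_logprob_unnorm(hpm, d) for d in decs]
    return float(logsumexp(joints))


# ---------------------------------------------------------------------------
# Importance sampling


def _batch_numerators(hpm: HiddenPottsModel, dec: SampledDecompositions,
                      xi_codes: np.ndarray) -> np.ndarray:
    """log P*(x, xm, xi, sigma) for all R samples, vectorized."""
    H = hamiltonian_batch(hpm.potts, dec.xm.astype(np.int64))
    lpt = log_pt_sigma(hpm, dec.ins_counts)
    lei = np.log(hpm.e_insert)
    if len(xi_codes):
        ins_logs = np.where(dec.ins_mask, lei[xi_codes][None, :], 0.0).sum(axis=1)
    else:
        ins_logs = np.zeros(dec.xm.shape[0])
    return H + lpt + ins_logs


def score_is(
    hpm: HiddenPottsModel,
    proposal: ProfileHMM,
    x: str,
    R: int = 10**6,
    seed: int | None = 0,
    fwd: ForwardResult | None = None,
    ess_warn: float = 100.0,
) -> ScoreResult:
    """Importance-sampling estimate of log P*(x) and the bit score.

    Draws R alignments from the pHMM posterior, re-weights each under the
    HPM, and averages in log space. The best sample (largest weight,
    first encountered on ties) doubles as the approximate alignment.
    """
    if proposal.M != hpm.M:
        raise AssemblyError("proposal and HPM differ in M")
    if fwd is None:
        fwd = forward_glocal(proposal, x)
    dec = sample_decompositions(fwd, R, seed=seed)
    xi_codes = fwd.xi
    log_num = _batch_numerators(hpm, dec, xi_codes)
    log_w = log_num - dec.log_q
    log_pstar = float(logsumexp(log_w) - np.log(R))
    # effective sample size of the normalized weights
    l2 = 2.0 * log_w
    ess = float(np.exp(2.0 * logsumexp(log_w) - logsumexp(l2)))
    if ess < ess_warn and R >= 10**4:
        warnings.warn(
            f"importance-sampling ESS={ess:.1f} < {ess_warn}: "
            "weight degeneracy; estimate may be unstable"
        )
    best = int(np.argmax(log_w))
    best_dec = Decomposition(
        ins_counts=dec.ins_counts[best].astype(np.int64),
        xm=dec.xm[best].astype(np.int64),
        xi=xi_codes[dec.ins_mask[best]],
    )
    sample = AlignmentSample(
        decomposition=best_dec,
        log_numerator=float(log_num[best]),
        log_q=float(dec.log_q[best]),
    )
    bits = (log_pstar - null_logprob(hpm, x)) / LN2
    return ScoreResult(log_pstar=log_pstar, log_odds_bits=float(bits),
                       best_sample=sample, R=R, ess=ess)


def align_is(
    hpm: HiddenPottsModel,
    proposal: ProfileHMM,
    x: str,
    R: int = 10**6,
    seed: int | None = 0,
    fwd: ForwardResult | None = None,
) -> tuple[AlignmentSample, ScoreResult]:
    """Approximate maximum-probability alignment of x to the HPM."""
    res = score_is(hpm, proposal, x, R=R, seed=seed, fwd=fwd)
    return res.best_sample, res


# ---------------------------------------------------------------------------
# Generative emission


@dataclass
class EmitResult:
    """Emitted sequences with their ground-truth alignment."""

    sequences: list[str]
    msa: MSA
    decompositions: list[Decomposition]
    hamiltonian_trace: np.ndarray | None = None


def emit_sequences(
    hpm: HiddenPottsModel,
    n: int,
    burn_in: int = 5000,
    seed: int | None = 0,
    record_trace: bool = False,
) -> EmitResult:
    """Generate n sequences: random-walk sigma, MCMC xm, i.i.d. xi.

    The implied alignment (model coordinates, '-' padding in insert
    columns) is retained as ground truth for synthetic experiments.
    """
    rng = np.random.default_rng(seed)
    M = hpm.M
    mcmc_seed = None if seed is None else int(rng.integers(2**31 - 1))
    out = sample_mcmc(hpm.potts, n, burn_in=burn_in, seed=mcmc_seed,
                      record_trace=record_trace)
    if record_trace:
        xm_all, trace = out
    else:
        xm_all, trace = out, None
    ins_counts = np.zeros((n, M + 1), dtype=np.int64)
    for k in range(M + 1):
        opens = rng.random(n) < hpm.t_open[k]
        if hpm.t_ext[k] > 0:
            extra = rng.geometric(1.0 - hpm.t_ext[k], size=n) - 1
        else:
            extra = np.zeros(n, dtype=np.int64)
        ins_counts[:, k] = np.where(opens, 1 + extra, 0)
    decs: list[Decomposition] = []
    seqs: list[str] = []
    syms = list(hpm.alphabet.symbols)
    for i in range(n):
        n_ins = int(ins_counts[i].sum())
        xi = rng.choice(4, size=n_ins, p=hpm.e_insert)
        dec = Decomposition(ins_counts=ins_counts[i], xm=xm_all[i],
                            xi=xi.astype(np.int64))
        decs.append(dec)
        seqs.append("".join(syms[c] for c in dec.dealign()))
    msa = render_alignment(decs, M, alphabet=hpm.alphabet)
    return EmitResult(sequences=seqs, msa=msa, decompositions=decs,
                      hamiltonian_trace=trace)


def render_alignment(decs: list[Decomposition], M: int,
                     names: list[str] | None = None,
                     alphabet: Alphabet = RNA,
                     ss_cons_match: str | None = None) -> MSA:
    """Render decompositions as an MSA in model coordinates.

    Insert runs are left-justified and padded with '-'; match columns keep
    the Potts characters. ``ss_cons_match`` (length M, over the match
    columns only) is expanded with '.' over insert columns.
    """
    widths = np.zeros(M + 1, dtype=np.int64)
    for d in decs:
        widths = np.maximum(widths, d.ins_counts)
    syms = list(alphabet.symbols) + ["-"]
    rows = []
    for d in decs:
        parts = []
        pos = 0
        for k in range(M + 1):
            if k > 0:
                parts.append(syms[int(d.xm[k - 1])])
            c = int(d.ins_counts[k])
            run = "".join(syms[int(v)] for v in d.xi[pos:pos + c])
            parts.append(run + "-" * int(widths[k] - c))
            pos += c
        rows.append("".join(parts))
    if names is None:
        names = [f"seq{i+1}" for i in range(len(decs))]
    ss = None
    if ss_cons_match is not None:
        parts = ["." * int(widths[0])]
        for k in range(1, M + 1):
            parts.append(ss_cons_match[k - 1])
            parts.append("." * int(widths[k]))
        ss = "".join(parts)
    return MSA(names=names, rows=rows, ss_cons=ss, alphabet=alphabet)


def match_column_assignment(dec: Decomposition) -> dict[int, int]:
    """Map residue index of the unaligned sequence -> consensus column.

    Insert-emitted residues are absent from the map (not scored by the
    alignment-accuracy metric).
    """
    out: dict[int, int] = {}
    pos = 0
    M = len(dec.xm)
    for k in range(M + 1):
        if k > 0 and dec.xm[k - 1] != 4:
            out[pos] = k - 1
            pos += 1
        pos += int(dec.ins_counts[k])
    return out
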