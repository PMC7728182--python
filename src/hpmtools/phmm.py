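"""Glocal profile HMM: training, Forward, Viterbi, stochastic traceback.

The model is *glocal*: global to the model (every consensus node 1..M is
visited as a match or delete state) and local to the sequence only through
flanking insert states before node 1 and after node M. It serves two roles:
a primary-sequence baseline aligner/scorer, and the proposal distribution
whose exact alignment posterior is sampled by stochastic traceback of the
Forward matrix for importance sampling.

State layout. Nodes run 0..M; node 0 is the begin state B, with I_0 the
5' flanking insert; I_M is the 3' flank. All nine profile transitions are
present (M->{M,I,D}, I->{M,I,D}, D->{M,I,D}); at node M the "next match"
slot is the end state E. Full transition support matters: it makes the
pHMM posterior cover every hidden-Potts-model decomposition, which the
importance-sampling estimator requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .alphabet import RNA, Alphabet
from .msa import MSA

NEG_INF = -np.inf


class ModelBuildError(ValueError):
    """The MSA cannot parameterize a model (e.g. no consensus columns)."""


class PathValidationError(ValueError):
    """A path is inconsistent with the model or the sequence."""


class ZeroProbabilityError(ValueError):
    """The sequence has probability zero under the model."""


@dataclass
class ProfileHMM:
    """Profile HMM parameters (probability space).

    ``tm``/``ti``/``td`` have shape (M+1, 3) with columns (to next match
    or E, to insert at the same node, to next delete); row 0 of ``td`` is
    unused (there is no D_0), and the delete column of row M is zero.
    ``e_match`` is (M, 4); insert emissions are shared across nodes.
    """

    M: int
    tm: np.ndarray
    ti: np.ndarray
    td: np.ndarray
    e_match: np.ndarray
    e_insert: np.ndarray
    background: np.ndarray
    alphabet: Alphabet = field(default_factory=lambda: RNA)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        M = self.M
        if self.tm.shape != (M + 1, 3) or self.ti.shape != (M + 1, 3):
            raise ModelBuildError("bad transition array shape")
        if self.td.shape != (M + 1, 3):
            raise ModelBuildError("bad delete transition shape")
        if self.e_match.shape != (M, 4):
            raise ModelBuildError("bad match emission shape")
        # delete transitions out of node M are impossible (D column is 0)
        for name, arr in (("tm", self.tm), ("ti", self.ti)):
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-12):
                raise ModelBuildError(f"{name} rows must sum to 1")
        if not np.allclose(self.td[1:].sum(axis=1), 1.0, atol=1e-12):
            raise ModelBuildError("td rows must sum to 1")
        for name, arr in (("e_match", self.e_match),):
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-12):
                raise ModelBuildError(f"{name} rows must sum to 1")
        if not np.isclose(self.e_insert.sum(), 1.0, atol=1e-12):
            raise ModelBuildError("insert emissions must sum to 1")

    # -- log-space views, cached -------------------------------------------
    def _logs(self):
        if not hasattr(self, "_log_cache"):
            with np.errstate(divide="ignore"):
                ltd = np.log(self.td)
                ltd[0, :] = NEG_INF  # no delete state at node 0
                self._log_cache = (
                    np.log(np.maximum(self.tm, 0.0)),
                    np.log(np.maximum(self.ti, 0.0)),
                    ltd,
                    np.log(self.e_match),
                    np.log(self.e_insert),
                )
        return self._log_cache

    def encode(self, x: str) -> np.ndarray:
        return np.array([self.alphabet.index(c) for c in x], dtype=np.int64)


@dataclass
class PHMMPath:
    """A glocal path: ordered (kind, node) visits, kinds in {"M","I","D"}.

    Emitted positions are implicit: each M or I state consumes the next
    residue of the sequence in order.
    """

    states: list[tuple[str, int]]

    @property
    def n_emitted(self) -> int:
        return sum(1 for kind, _ in self.states if kind in ("M", "I"))

    def match_labels(self, M: int) -> list[str]:
        """Per-node "M" or "D" label, checking glocal coverage."""
        labels: dict[int, str] = {}
        for kind, node in self.states:
            if kind in ("M", "D"):
                if node in labels:
                    raise PathValidationError(f"node {node} visited twice")
                labels[node] = kind
        if sorted(labels) != list(range(1, M + 1)):
            raise PathValidationError("path does not cover all match nodes")
        return [labels[k] for k in range(1, M + 1)]


def train_phmm(msa: MSA, weights: np.ndarray | None = None) -> ProfileHMM:
    """Train a glocal profile HMM from an alignment.

    Weighted observed counts with a Laplace +1 pseudocount per legal
    transition and per match residue; insert emissions and the null
    background are both the weighted overall residue frequency. Weights
    are renormalized to sum to the sequence count, so a uniform rescaling
    of the weights leaves the model unchanged.
    """
    mask = msa.get_consensus_mask()
    M = int(mask.sum())
    if M == 0:
        raise ModelBuildError("alignment has no consensus columns")
    if weights is None:
        weights = msa.get_weights()
    weights = np.asarray(weights, dtype=float)
    weights = weights * (len(msa) / weights.sum())
    ab = msa.alphabet
    W = msa.width

    cm = np.zeros((M + 1, 3))
    ci = np.zeros((M + 1, 3))
    cd = np.zeros((M + 1, 3))
    ce = np.zeros((M, 4))
    bg = np.zeros(4)

    # column -> node number for consensus columns (1-based)
    node_of = np.cumsum(mask)

    for row, w in zip(msa.rows, weights):
        state, node = "M", 0  # B
        for c in range(W):
            ch = row[c]
            if mask[c]:
                nxt = "M" if ch != "-" else "D"
                _count_transition(cm, ci, cd, state, node, nxt, w)
                state, node = nxt, node_of[c]
                if nxt == "M":
                    ce[node - 1, ab.index(ch)] += w
                    bg[ab.index(ch)] += w
            elif ch != "-":
                _count_transition(cm, ci, cd, state, node, "I", w)
                state = "I"
                bg[ab.index(ch)] += w
        _count_transition(cm, ci, cd, state, node, "M", w)  # -> E

    # Laplace +1 on every legal transition
    cm += 1.0
    ci += 1.0
    cd += 1.0
    cm[M, 2] = ci[M, 2] = cd[M, 2] = 0.0  # no delete past node M
    cd[0, :] = 0.0

    tm = cm / cm.sum(axis=1, keepdims=True)
    ti = ci / ci.sum(axis=1, keepdims=True)
    td = np.zeros_like(cd)
    td[1:] = cd[1:] / cd[1:].sum(axis=1, keepdims=True)
    e_match = (ce + 1.0) / (ce + 1.0).sum(axis=1, keepdims=True)
    background = (bg + 1.0) / (bg + 1.0).sum()
    return ProfileHMM(
        M=M, tm=tm, ti=ti, td=td, e_match=e_match,
        e_insert=background.copy(), background=background, alphabet=ab,
    )


def _count_transition(cm, ci, cd, state: str, node: int, nxt: str, w: float):
    col = {"M": 0, "I": 1, "D": 2}[nxt]
    if state == "M":
        cm[node, col] += w
    elif state == "I":
        ci[node, col] += w
    else:
        cd[node, col] += w


# ---------------------------------------------------------------------------
# Forward / Viterbi dynamic programming


def _fill(hmm: ProfileHMM, xi: np.ndarray, viterbi: bool = False):
    """Fill glocal DP matrices F_M, F_I, F_D of shape (M+1, L+1), log space.

    Rows for M and D are vectorized over sequence position; the insert row
    needs a sequential scan (self-transition). O(M*L) overall.
    """
    M, L = hmm.M, len(xi)
    ltm, lti, ltd, lem, lei = hmm._logs()
    FM = np.full((M + 1, L + 1), NEG_INF)
    FI = np.full((M + 1, L + 1), NEG_INF)
    FD = np.full((M + 1, L + 1), NEG_INF)
    FM[0, 0] = 0.0
    if viterbi:
        def acc3(a, b, c):
            return np.maximum(np.maximum(a, b), c)
    else:
        def acc3(a, b, c):
            return np.logaddexp(np.logaddexp(a, b), c)
    emit_ins = lei[xi] if L else np.empty(0)
    for k in range(M + 1):
        if k > 0:
            FD[k] = acc3(
                FM[k - 1] + ltm[k - 1, 2],
                FI[k - 1] + lti[k - 1, 2],
                FD[k - 1] + ltd[k - 1, 2],
            )
            FM[k, 1:] = lem[k - 1, xi] + acc3(
                FM[k - 1, :-1] + ltm[k - 1, 0],
                FI[k - 1, :-1] + lti[k - 1, 0],
                FD[k - 1, :-1] + ltd[k - 1, 0],
            )
        a, b, c = ltm[k, 1], lti[k, 1], ltd[k, 1]
        fm, fi, fd = FM[k], FI[k], FD[k]
        prev = NEG_INF
        for i in range(1, L + 1):
            prev = emit_ins[i - 1] + acc3(
                fm[i - 1] + a, prev + b, fd[i - 1] + c
            )
            fi[i] = prev
    total = acc3(
        FM[M, L] + ltm[M, 0],
        FI[M, L] + lti[M, 0],
        FD[M, L] + ltd[M, 0],
    )
    return FM, FI, FD, float(total)


@dataclass
class ForwardResult:
    hmm: ProfileHMM
    x: str
    xi: np.ndarray
    FM: np.ndarray
    FI: np.ndarray
    FD: np.ndarray
    logp: float


def forward_glocal(hmm: ProfileHMM, x: str) -> ForwardResult:
    """Forward log-likelihood log P_HMM(x) over all glocal paths."""
    xi = hmm.encode(x)
    FM, FI, FD, total = _fill(hmm, xi, viterbi=False)
    return ForwardResult(hmm, x, xi, FM, FI, FD, float(total))


def viterbi_glocal(hmm: ProfileHMM, x: str) -> tuple[PHMMPath, float]:
    """Best glocal path and its log joint probability.

    Ties broken deterministically, preferring M over D over I predecessors.
    """
    xi = hmm.encode(x)
    M, L = hmm.M, len(xi)
    ltm, lti, ltd, lem, lei = hmm._logs()
    FM, FI, FD, total = _fill(hmm, xi, viterbi=True)
    if total == NEG_INF:
        raise ZeroProbabilityError("sequence has zero probability under model")

    # backward walk, re-deriving argmaxes (candidates ordered M, D, I)
    def pick(cands: list[tuple[float, tuple[str, int, int]]]):
        best = max(c[0] for c in cands)
        for val, st in cands:
            if val == best:
                return st
        raise AssertionError

    end_cands = [
        (FM[M, L] + ltm[M, 0], ("M", M, L)),
        (FD[M, L] + ltd[M, 0], ("D", M, L)),
        (FI[M, L] + lti[M, 0], ("I", M, L)),
    ]
    kind, k, i = pick(end_cands)
    rev: list[tuple[str, int]] = []
    while not (kind == "M" and k == 0):
        rev.append((kind, k))
        if kind == "M":
            cands = [
                (FM[k - 1, i - 1] + ltm[k - 1, 0], ("M", k - 1, i - 1)),
                (FD[k - 1, i - 1] + ltd[k - 1, 0], ("D", k - 1, i - 1)),
                (FI[k - 1, i - 1] + lti[k - 1, 0], ("I", k - 1, i - 1)),
            ]
        elif kind == "D":
            cands = [
                (FM[k - 1, i] + ltm[k - 1, 2], ("M", k - 1, i)),
                (FD[k - 1, i] + ltd[k - 1, 2], ("D", k - 1, i)),
                (FI[k - 1, i] + lti[k - 1, 2], ("I", k - 1, i)),
            ]
        else:  # I
            cands = [
                (FM[k, i - 1] + ltm[k, 1], ("M", k, i - 1)),
                (FD[k, i - 1] + ltd[k, 1], ("D", k, i - 1)),
                (FI[k, i - 1] + lti[k, 1], ("I", k, i - 1)),
            ]
        kind, k, i = pick(cands)
    return PHMMPath(states=rev[::-1]), float(total)


def path_joint_logprob(hmm: ProfileHMM, x: str, pi: PHMMPath) -> float:
    """log P_HMM(pi, x): transition plus emission terms along the path."""
    xi = hmm.encode(x)
    ltm, lti, ltd, lem, lei = hmm._logs()
    M = hmm.M
    pi.match_labels(M)  # validates glocal coverage
    total = 0.0
    state, node, pos = "M", 0, 0
    for kind, k in pi.states:
        if kind in ("M", "D") and k != node + 1:
            raise PathValidationError(f"node jump {node}->{k}")
        if kind == "I" and k != node:
            raise PathValidationError(f"insert at node {k} while at {node}")
        col = {"M": 0, "I": 1, "D": 2}[kind]
        if state == "M":
            total += ltm[node, col]
        elif state == "I":
            total += lti[node, col]
        else:
            total += ltd[node, col]
        if kind in ("M", "I"):
            if pos >= len(xi):
                raise PathValidationError("path emits more residues than x has")
            total += (lem[k - 1, xi[pos]] if kind == "M" else lei[xi[pos]])
            pos += 1
        if kind in ("M", "D"):
            node = k
        state = kind
    if pos != len(xi):
        raise PathValidationError("path emits fewer residues than x has")
    if state == "M":
        total += ltm[node, 0]
    elif state == "I":
        total += lti[node, 0]
    else:
        total += ltd[node, 0]
    if not np.isfinite(total):
        raise PathValidationError("path uses a zero-probability transition")
    return float(total)


def path_logprob(hmm: ProfileHMM, x: str, pi: PHMMPath,
                 fwd: ForwardResult | None = None) -> float:
    """Exact posterior log Q(pi | x) = log P(pi, x) - log P(x)."""
    if fwd is None:
        fwd = forward_glocal(hmm, x)
    return path_joint_logprob(hmm, x, pi) - fwd.logp


# ---------------------------------------------------------------------------
# Stochastic traceback (exact posterior sampling), vectorized across samples


@dataclass
class SampledDecompositions:
    """R posterior path samples in array form.

    ``xm``: (R, M) Potts characters (0..3 residues, 4 deletion);
    ``ins_counts``: (R, M+1) insert-run lengths after each node;
    ``ins_mask``: (R, L) True where x's residue was insert-emitted;
    ``log_joint``: (R,) log P_HMM(pi, x); posterior log Q = log_joint - logp.
    """

    xm: np.ndarray
    ins_counts: np.ndarray
    ins_mask: np.ndarray
    log_joint: np.ndarray
    logp: float

    @property
    def log_q(self) -> np.ndarray:
        return self.log_joint - self.logp

    def to_path(self, r: int) -> PHMMPath:
        M = self.xm.shape[1]
        states: list[tuple[str, int]] = []
        for j in range(int(self.ins_counts[r, 0])):
            states.append(("I", 0))
        for k in range(1, M + 1):
            states.append(("M" if self.xm[r, k - 1] != 4 else "D", k))
            for j in range(int(self.ins_counts[r, k])):
                states.append(("I", k))
        return PHMMPath(states=states)


def sample_decompositions(
    fwd: ForwardResult, R: int, seed: int | None = 0
) -> SampledDecompositions:
    """Draw R i.i.d. paths from the exact posterior P_HMM(pi | x).

    Backward stochastic traceback of the Forward matrix, run in lockstep
    across all R samples (each traceback is O(L + M)).
    """
    hmm, xi = fwd.hmm, fwd.xi
    M, L = hmm.M, len(xi)
    if not np.isfinite(fwd.logp):
        raise ZeroProbabilityError(
            "sequence has zero probability under the proposal model"
        )
    ltm, lti, ltd, lem, lei = hmm._logs()
    FM, FI, FD = fwd.FM, fwd.FI, fwd.FD
    rng = np.random.default_rng(seed)

    xm = np.full((R, M), -1, dtype=np.int8)
    ins_counts = np.zeros((R, M + 1), dtype=np.int32)
    ins_mask = np.zeros((R, max(L, 1)), dtype=bool)
    log_joint = np.zeros(R)

    # state kinds: 0=M, 1=I, 2=D; "done" flag separate
    kind = np.zeros(R, dtype=np.int8)
    kk = np.full(R, M, dtype=np.int32)
    ii = np.full(R, L, dtype=np.int32)
    done = np.zeros(R, dtype=bool)

    # initial draw: predecessor of E
    end_logits = np.array(
        [FM[M, L] + ltm[M, 0], FI[M, L] + lti[M, 0], FD[M, L] + ltd[M, 0]]
    )
    kind = _gumbel_pick(np.broadcast_to(end_logits, (R, 3)).copy(), rng)
    log_joint += np.where(
        kind == 0, ltm[M, 0], np.where(kind == 1, lti[M, 0], ltd[M, 0])
    )

    max_steps = 2 * (M + L) + 4
    for _ in range(max_steps):
        act = ~done
        if not act.any():
            break
        km, ki = kk[act], ii[act]
        kd = kind[act]
        # record the visit and its emission
        is_m = kd == 0
        is_i = kd == 1
        is_d = kd == 2
        ridx = np.flatnonzero(act)
        xm[ridx[is_m], km[is_m] - 1] = xi[ki[is_m] - 1]
        xm[ridx[is_d], km[is_d] - 1] = 4
        ins_counts[ridx[is_i], km[is_i]] += 1
        ins_mask[ridx[is_i], ki[is_i] - 1] = True
        emit = np.zeros(len(ridx))
        emit[is_m] = lem[km[is_m] - 1, xi[ki[is_m] - 1]]
        emit[is_i] = lei[xi[ki[is_i] - 1]]
        log_joint[ridx] += emit

        # predecessor node/position per kind
        pk = np.where(is_i, km, km - 1)
        pi_ = np.where(is_d, ki, ki - 1)
        # candidate logits: predecessor in {M, I, D}
        logits = np.empty((len(ridx), 3))
        col = np.where(is_m, 0, np.where(is_i, 1, 2))
        logits[:, 0] = FM[pk, pi_] + ltm[pk, col]
        logits[:, 1] = FI[pk, pi_] + lti[pk, col]
        logits[:, 2] = FD[pk, pi_] + ltd[pk, col]
        trans = np.stack([ltm[pk, col], lti[pk, col], ltd[pk, col]], axis=1)
        choice = _gumbel_pick(logits, rng)
        log_joint[ridx] += trans[np.arange(len(ridx)), choice]
        kind[ridx] = choice
        kk[ridx] = pk
        ii[ridx] = pi_
        done[ridx] |= (choice == 0) & (pk == 0)
    if not done.all():
        raise RuntimeError("traceback failed to terminate (model invariant)")
    if (xm < 0).any():
        raise RuntimeError("traceback left unassigned match nodes")
    return SampledDecompositions(
        xm=xm, ins_counts=ins_counts, ins_mask=ins_mask[:, :L],
        log_joint=log_joint, logp=fwd.logp,
    )


def _gumbel_pick(logits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample categorically per row via the Gumbel-max trick (-inf safe)."""
    g = rng.gumbel(size=logits.shape)
    noisy = np.where(np.isneginf(logits), NEG_INF, logits + g)
    return np.argmax(noisy, axis=1).astype(np.int8)


def sample_paths(
    hmm: ProfileHMM, x: str, R: int, seed: int | None = 0
) -> list[PHMMPath]:
    """R i.i.d. samples from the exact alignment posterior P_HMM(pi | x)."""
    fwd = forward_glocal(hmm, x)
    dec = sample_decompositions(fwd, R, seed=seed)
    return [dec.to_path(r) for r in range(R)]
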