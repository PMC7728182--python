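"""Potts model over consensus columns with the 5-letter RNA+deletion alphabet.

The model assigns an unnormalized log-probability (Hamiltonian) to a
fixed-length match sequence:

    H(x) = sum_k h_k(x_k) + sum_{k<l} e_kl(x_k, x_l),   P(x) = e^H / Z.

Training is by weighted pseudolikelihood maximization (PLM, the standard
direct-coupling-analysis estimator) or, for a disjoint set of annotated
base pairs, by the exact analytic "masked" construction in which paired
sites carry couplings equal to log smoothed joint frequencies and unpaired
sites carry fields equal to log smoothed marginals. The partition function
is never computed at realistic M; an exact enumeration oracle exists for
tiny models and tests.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .alphabet import RNA, Alphabet
from .msa import MSA
from .structure import StructureAnnotation

K_DEFAULT = 5


class CapacityError(ValueError):
    """Exact enumeration refused: state space too large."""


@dataclass
class PottsModel:
    """Fields ``h`` (M, K) and couplings ``e`` (M, M, K, K).

    ``e`` is stored fully but kept symmetric, e[k,l,a,b] == e[l,k,b,a],
    with zero diagonal blocks; the Hamiltonian sums each pair once (k<l).
    """

    h: np.ndarray
    e: np.ndarray
    alphabet: Alphabet = field(default_factory=lambda: RNA)

    def __post_init__(self) -> None:
        M, K = self.h.shape
        if self.e.shape != (M, M, K, K):
            raise ValueError("coupling tensor shape mismatch")
        if not np.allclose(self.e, self.e.transpose(1, 0, 3, 2), atol=1e-10):
            raise ValueError("couplings must be symmetric")
        if not np.allclose(self.e[np.arange(M), np.arange(M)], 0.0):
            raise ValueError("self-couplings must be zero")
        if not (np.isfinite(self.h).all() and np.isfinite(self.e).all()):
            raise ValueError("non-finite Potts parameters")

    @property
    def M(self) -> int:
        return self.h.shape[0]

    @property
    def K(self) -> int:
        return self.h.shape[1]

    def pair_matrix(self) -> np.ndarray:
        """(M*K, M*K) flattened coupling matrix for fast Hamiltonians."""
        M, K = self.M, self.K
        return self.e.transpose(0, 2, 1, 3).reshape(M * K, M * K)


def encode_match(xm: str, alphabet: Alphabet = RNA) -> np.ndarray:
    return np.array([alphabet.index(c) for c in xm], dtype=np.int64)


def decode_match(codes: np.ndarray, alphabet: Alphabet = RNA) -> str:
    syms = list(alphabet.symbols) + [alphabet.deletion_symbol]
    return "".join(syms[c] for c in codes)


def hamiltonian(potts: PottsModel, xm: np.ndarray | str) -> float:
    """H(xm) for one match sequence (string or integer codes)."""
    if isinstance(xm, str):
        xm = encode_match(xm, potts.alphabet)
    if xm.shape[-1] != potts.M:
        raise ValueError(f"match sequence length {xm.shape[-1]} != M={potts.M}")
    return float(hamiltonian_batch(potts, xm[None, :])[0])


def hamiltonian_batch(potts: PottsModel, xm: np.ndarray) -> np.ndarray:
    """Vectorized H for an (R, M) integer batch."""
    R, M = xm.shape
    if M != potts.M:
        raise ValueError(f"match length {M} != M={potts.M}")
    K = potts.K
    h_term = potts.h[np.arange(M), xm].sum(axis=1)
    X = np.zeros((R, M * K))
    X[np.arange(R)[:, None], np.arange(M) * K + xm] = 1.0
    E = potts.pair_matrix()
    pair_term = 0.5 * np.einsum("ri,ri->r", X @ E, X)
    return h_term + pair_term


def partition_exact(potts: PottsModel, limit: int = 10**7) -> float:
    """log Z by full enumeration; refuses when K^M exceeds ``limit``."""
    M, K = potts.M, potts.K
    if K**M > limit:
        raise CapacityError(f"K^M = {K**M} exceeds enumeration capacity {limit}")
    all_seqs = np.array(list(itertools.product(range(K), repeat=M)), dtype=np.int64)
    H = hamiltonian_batch(potts, all_seqs)
    return float(logsumexp(H))


def enumerate_probabilities(potts: PottsModel, limit: int = 10**7):
    """All K^M sequences with normalized probabilities (tests/oracles)."""
    M, K = potts.M, potts.K
    if K**M > limit:
        raise CapacityError("model too large to enumerate")
    seqs = np.array(list(itertools.product(range(K), repeat=M)), dtype=np.int64)
    H = hamiltonian_batch(potts, seqs)
    p = np.exp(H - logsumexp(H))
    return seqs, p


def exact_marginals(potts: PottsModel, limit: int = 10**7):
    """Exact single-site (M, K) and pairwise (M, M, K, K) marginals."""
    seqs, p = enumerate_probabilities(potts, limit)
    M, K = potts.M, potts.K
    p1 = np.zeros((M, K))
    p2 = np.zeros((M, M, K, K))
    for k in range(M):
        for a in range(K):
            sel = seqs[:, k] == a
            p1[k, a] = p[sel].sum()
            for l in range(M):
                if l == k:
                    continue
                for b in range(K):
                    p2[k, l, a, b] = p[sel & (seqs[:, l] == b)].sum()
    return p1, p2


# ---------------------------------------------------------------------------
# Pseudolikelihood training


def _one_hot(X: np.ndarray, K: int) -> np.ndarray:
    N, M = X.shape
    F = np.zeros((N, M * K))
    F[np.arange(N)[:, None], np.arange(M) * K + X] = 1.0
    return F


def plm_objective(
    theta: np.ndarray,
    Xf: np.ndarray,
    X: np.ndarray,
    w: np.ndarray,
    M: int,
    K: int,
    lambda_h: float,
    lambda_e: float,
):
    """Weighted negative log-pseudolikelihood with L2 penalties; returns
    (value, gradient). ``theta`` packs h (M*K) then the asymmetric coupling
    matrix (M*K, M*K) whose diagonal blocks are ignored."""
    N = X.shape[0]
    h = theta[: M * K].reshape(M, K)
    E = theta[M * K:].reshape(M * K, M * K).copy()
    # zero diagonal blocks (self-couplings are not parameters)
    blk = np.arange(M)
    Eb = E.reshape(M, K, M, K)
    Eb[blk, :, blk, :] = 0.0
    logits = (Xf @ E.T).reshape(N, M, K) + h[None, :, :]
    lse = logsumexp(logits, axis=2)
    picked = np.take_along_axis(logits, X[:, :, None], axis=2)[:, :, 0]
    nll = float(np.sum(w[:, None] * (lse - picked)))
    P = np.exp(logits - lse[:, :, None])
    G = w[:, None, None] * (P - _one_hot_inplace(X, K, N, M))
    dh = G.sum(axis=0)
    dE = G.reshape(N, M * K).T @ Xf
    dEb = dE.reshape(M, K, M, K)
    dEb[blk, :, blk, :] = 0.0
    nll += lambda_h * float(np.sum(h * h)) + lambda_e * float(np.sum(E * E))
    dh = dh + 2.0 * lambda_h * h
    dE = dE + 2.0 * lambda_e * E
    grad = np.concatenate([dh.ravel(), dE.ravel()])
    return nll, grad


def _one_hot_inplace(X, K, N, M):
    F = np.zeros((N, M, K))
    np.put_along_axis(F, X[:, :, None], 1.0, axis=2)
    return F


def train_plm(
    msa_consensus: np.ndarray | MSA,
    weights: np.ndarray | None = None,
    lambda_h: float = 0.01,
    lambda_e: float | None = None,
    no_couplings: bool = False,
    gtol: float = 1e-5,
    maxiter: int = 5000,
    alphabet: Alphabet = RNA,
) -> PottsModel:
    """Pseudolikelihood-maximization Potts training.

    Input is either an MSA (restricted internally to consensus columns,
    gaps recoded as the deletion character) or an (N, M) integer matrix
    over the 5-letter alphabet. Couplings are estimated asymmetrically
    (one conditional per site) and symmetrized by averaging, the standard
    PLM convention. ``lambda_e`` defaults to 0.2 * (M - 1) / 2, a
    length-scaled ridge in the style of standard plmDCA trainers.

    With ``no_couplings=True`` all e_kl are constrained to zero and only
    the fields are fit (the "no e_kl" model variant).
    """
    if isinstance(msa_consensus, MSA):
        X = msa_consensus.consensus_int_matrix()
        if weights is None:
            weights = msa_consensus.get_weights()
        alphabet = msa_consensus.alphabet
    else:
        X = np.asarray(msa_consensus, dtype=np.int64)
    N, M = X.shape
    K = alphabet.K
    if weights is None:
        weights = np.ones(N)
    if lambda_e is None:
        lambda_e = 0.2 * (M - 1) / 2.0
    Xf = _one_hot(X, K)

    if no_couplings:
        # fields-only PLM decouples into independent per-site fits
        def f(ht):
            h = ht.reshape(M, K)
            lse = logsumexp(h, axis=1)
            counts = (weights[:, None, None] * _one_hot_inplace(X, K, N, M)).sum(0)
            nll = float(weights.sum() * lse.sum() - np.sum(counts * h))
            P = np.exp(h - lse[:, None])
            grad = weights.sum() * P - counts + 2 * lambda_h * h
            return nll + lambda_h * float(np.sum(h * h)), grad.ravel()

        res = minimize(f, np.zeros(M * K), jac=True, method="L-BFGS-B",
                       options={"gtol": gtol, "maxiter": maxiter})
        h = res.x.reshape(M, K)
        return PottsModel(h=h, e=np.zeros((M, M, K, K)), alphabet=alphabet)

    theta0 = np.zeros(M * K + (M * K) ** 2)
    res = minimize(
        plm_objective, theta0,
        args=(Xf, X, weights, M, K, lambda_h, lambda_e),
        jac=True, method="L-BFGS-B",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    if not res.success and "ABNORMAL" in str(res.message):
        warnings.warn(f"PLM optimizer did not fully converge: {res.message}")
    h = res.x[: M * K].reshape(M, K)
    E = res.x[M * K:].reshape(M, K, M, K).transpose(0, 2, 1, 3)  # (M, M, K, K)
    e = 0.5 * (E + E.transpose(1, 0, 3, 2))
    e[np.arange(M), np.arange(M)] = 0.0
    return PottsModel(h=h, e=e, alphabet=alphabet)


def train_masked(
    msa_consensus: np.ndarray | MSA,
    weights: np.ndarray | None = None,
    pairs: StructureAnnotation | None = None,
    include_pseudoknots: bool = True,
    alphabet: Alphabet = RNA,
) -> PottsModel:
    """Analytic masked training on a disjoint set of annotated base pairs.

    Paired sites (k, l): e_kl(a, b) = log p_kl(a, b), the Laplace-smoothed
    weighted joint frequency (+1 over K^2 cells), with h_k = h_l = 0.
    Unpaired sites: h_k(a) = log p_k(a) (+1 over K cells), all couplings
    zero. The resulting Boltzmann distribution factorizes over pairs and
    singletons, so its exact marginals reproduce the smoothed training
    frequencies and Z = 1.
    """
    if isinstance(msa_consensus, MSA):
        X = msa_consensus.consensus_int_matrix()
        if weights is None:
            weights = msa_consensus.get_weights()
        alphabet = msa_consensus.alphabet
    else:
        X = np.asarray(msa_consensus, dtype=np.int64)
    N, M = X.shape
    K = alphabet.K
    if weights is None:
        weights = np.ones(N)
    if pairs is None:
        pairs = StructureAnnotation()
    use_pairs = list(pairs.nested_pairs)
    if include_pseudoknots:
        use_pairs += list(pairs.pseudoknot_pairs)
    seen: set[int] = set()
    for i, j in use_pairs:
        if i in seen or j in seen or i == j:
            raise ValueError("masked training requires disjoint pairs")
        seen.update((i, j))
    W = float(weights.sum())
    h = np.zeros((M, K))
    e = np.zeros((M, M, K, K))
    paired = set(seen)
    for k in range(M):
        if k in paired:
            continue
        counts = np.zeros(K)
        np.add.at(counts, X[:, k], weights)
        h[k] = np.log((counts + 1.0) / (W + K))
    for i, j in use_pairs:
        counts = np.zeros((K, K))
        np.add.at(counts, (X[:, i], X[:, j]), weights)
        pij = (counts + 1.0) / (W + K * K)
        e[i, j] = np.log(pij)
        e[j, i] = np.log(pij).T
    return PottsModel(h=h, e=e, alphabet=alphabet)


# ---------------------------------------------------------------------------
# MCMC emission and marginal estimation


def sample_mcmc(
    potts: PottsModel,
    n: int,
    burn_in: int = 5000,
    seed: int | None = 0,
    record_trace: bool = False,
):
    """Emit ``n`` independent match sequences by Metropolis-Hastings.

    Each chain starts from an i.i.d. uniform sequence; one proposal per
    iteration resamples a uniformly chosen site to a uniformly chosen
    character and is accepted with min(1, e^dH). The state after
    ``burn_in`` proposal iterations is returned. Chains are independent
    but advanced in lockstep for speed. With ``record_trace`` the mean and
    standard deviation of H across chains is recorded each iteration.
    """
    M, K = potts.M, potts.K
    rng = np.random.default_rng(seed)
    X = rng.integers(0, K, size=(n, M))
    e = potts.e
    h = potts.h
    H = hamiltonian_batch(potts, X)
    trace = []
    rows = np.arange(n)
    for it in range(burn_in):
        sites = rng.integers(0, M, size=n)
        props = rng.integers(0, K, size=n)
        old = X[rows, sites]
        # dH = field change + coupling change against all other sites
        dh = h[sites, props] - h[sites, old]
        # e[site, :, char, :] gathered at current X
        e_new = e[sites, :, props, :]  # (n, M, K)
        e_old = e[sites, :, old, :]
        d_pair = np.take_along_axis(e_new - e_old, X[:, :, None], axis=2)[:, :, 0]
        # diagonal block is zero, but the proposed site's own column uses the
        # *old* character in X; e[k,k]=0 makes that term vanish either way
        dH = dh + d_pair.sum(axis=1)
        accept = np.log(rng.random(n)) < dH
        X[rows[accept], sites[accept]] = props[accept]
        H[accept] += dH[accept]
        if record_trace:
            trace.append((float(H.mean()), float(H.std())))
    if record_trace:
        return X, np.array(trace)
    return X


def estimate_marginals(samples: np.ndarray, K: int = K_DEFAULT):
    """Empirical single-site (M, K) and pairwise (M, M, K, K) frequencies."""
    X = np.asarray(samples, dtype=np.int64)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need at least one sample")
    N, M = X.shape
    F = _one_hot(X, K).reshape(N, M, K)
    p1 = F.mean(axis=0)
    Ff = F.reshape(N, M * K)
    p2 = (Ff.T @ Ff / N).reshape(M, K, M, K).transpose(0, 2, 1, 3)
    return p1, p2


# ---------------------------------------------------------------------------
# Contact ranking


def apc(S: np.ndarray) -> np.ndarray:
    """Average-product correction of a symmetric score matrix.

    corrected_ij = S_ij - mean_i * mean_j / mean, with means taken over the
    matrix as given; a rank-one S is annihilated exactly. The diagonal of
    the output is zeroed (self-pairs are never contacts).
    """
    row_mean = S.mean(axis=1)
    total_mean = S.mean()
    if total_mean == 0:
        corr = S.copy()
    else:
        corr = S - np.outer(row_mean, row_mean) / total_mean
    np.fill_diagonal(corr, 0.0)
    return corr


def contact_scores(potts: PottsModel, top: int | None = None):
    """Rank site pairs by APC-corrected Frobenius norm of the couplings.

    The deletion row/column is excluded: contacts are residue-residue
    signal. Returns (ranked list of (score, k, l), full score matrix);
    the ranked list is truncated to ``top`` (default ceil(M/2)).
    """
    M = potts.M
    nres = potts.alphabet.n_residues
    sub = potts.e[:, :, :nres, :nres]
    S = np.sqrt(np.sum(sub**2, axis=(2, 3)))
    np.fill_diagonal(S, 0.0)
    Sc = apc(S)
    pairs = [(float(Sc[k, l]), k, l) for k in range(M) for l in range(k + 1, M)]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    if top is None:
        top = (M + 1) // 2
    return pairs[:top], Sc
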