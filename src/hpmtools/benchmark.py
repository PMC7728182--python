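"""Scoring (ROC) and alignment-accuracy benchmarks; parameter recovery.

All comparisons are within-model: the unnormalized bit scores of a single
model are ranked against each other (homologs vs decoys), and alignment
accuracy is the fraction of residues in consensus columns placed in the
same column as the reference, pooled across test sequences. Insert-column
placements are not scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .benchmark_split import BenchmarkSplit
from .hpm import (
    Decomposition,
    HiddenPottsModel,
    assemble_hpm,
    emit_sequences,
    match_column_assignment,
    null_logprob,
    _batch_numerators,
    LN2,
)
from .infostats import pair_mutual_info
from .msa import MSA
from .phmm import ProfileHMM, forward_glocal, sample_decompositions, train_phmm
from .potts import PottsModel, estimate_marginals, train_masked, train_plm
from .structure import StructureAnnotation, parse_wuss
from scipy.special import logsumexp


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    pos_scores: np.ndarray
    decoy_scores: np.ndarray

    def tpr_at_fpr(self, fpr_target: float) -> float:
        ok = self.fpr <= fpr_target
        return float(self.tpr[ok].max()) if ok.any() else 0.0


def roc_curve(pos_scores, decoy_scores) -> ROCResult:
    """ROC by threshold sweep; ties counted as "score >= threshold"."""
    pos = np.asarray(pos_scores, dtype=float)
    dec = np.asarray(decoy_scores, dtype=float)
    if pos.size == 0 or dec.size == 0:
        raise ValueError("need nonempty positive and decoy score sets")
    thresholds = np.unique(np.concatenate([pos, dec]))[::-1]
    tpr = np.array([(pos >= t).mean() for t in thresholds])
    fpr = np.array([(dec >= t).mean() for t in thresholds])
    thresholds = np.concatenate([[np.inf], thresholds])
    tpr = np.concatenate([[0.0], tpr])
    fpr = np.concatenate([[0.0], fpr])
    return ROCResult(thresholds, tpr, fpr, pos, dec)


@dataclass
class AccuracyResult:
    total_accuracy: float
    nested_accuracy: float | None
    pseudoknot_accuracy: float | None
    other_accuracy: float | None
    per_sequence: list[tuple[int, int]]  # (correct, total) per sequence


def row_to_assignment(row: str, mask: np.ndarray) -> dict[int, int]:
    """Residue index (in the dealigned sequence) -> consensus column."""
    cons_index = np.cumsum(mask) - 1
    out: dict[int, int] = {}
    pos = 0
    for c, ch in enumerate(row):
        if ch != "-" and not ch.islower() and ch != ".":
            if mask[c]:
                out[pos] = int(cons_index[c])
            pos += 1
    return out


def alignment_accuracy(
    predicted: list[dict[int, int]] | list[Decomposition],
    reference: list[dict[int, int]] | list[Decomposition],
    structure: StructureAnnotation | None = None,
) -> AccuracyResult:
    """Fraction of reference consensus-column residues placed correctly.

    Inputs are per-sequence maps from residue index to consensus column
    (insert residues absent); :class:`Decomposition` objects are accepted
    directly. Pooled over sequences; the class breakdown follows the
    structure annotation of the columns.
    """
    def as_map(obj):
        return match_column_assignment(obj) if isinstance(obj, Decomposition) else obj

    if len(predicted) != len(reference):
        raise ValueError("predicted/reference sequence count mismatch")
    nested_cols: set[int] = set()
    pk_cols: set[int] = set()
    if structure is not None:
        for i, j in structure.nested_pairs:
            nested_cols.update((i, j))
        for i, j in structure.pseudoknot_pairs:
            pk_cols.update((i, j))
    counts = {"nested": [0, 0], "pk": [0, 0], "other": [0, 0]}
    per_seq: list[tuple[int, int]] = []
    for p, r in zip(predicted, reference):
        pm, rm = as_map(p), as_map(r)
        c_seq = t_seq = 0
        for pos, col in rm.items():
            cls = ("nested" if col in nested_cols
                   else "pk" if col in pk_cols else "other")
            counts[cls][1] += 1
            t_seq += 1
            if pm.get(pos) == col:
                counts[cls][0] += 1
                c_seq += 1
        per_seq.append((c_seq, t_seq))
    total_c = sum(v[0] for v in counts.values())
    total_t = sum(v[1] for v in counts.values())

    def frac(key):
        c, t = counts[key]
        return c / t if t else None

    return AccuracyResult(
        total_accuracy=total_c / total_t if total_t else 0.0,
        nested_accuracy=frac("nested"),
        pseudoknot_accuracy=frac("pk"),
        other_accuracy=frac("other"),
        per_sequence=per_seq,
    )


# ---------------------------------------------------------------------------
# Model-variant scoring benchmark


@dataclass
class VariantModels:
    phmm: ProfileHMM
    variants: dict[str, HiddenPottsModel]
    structure: StructureAnnotation | None


def train_variants(
    train: MSA,
    which: tuple[str, ...] = ("hpm", "no_ekl", "nested", "pseudoknotted"),
    lambda_h: float = 0.01,
    lambda_e: float | None = None,
) -> VariantModels:
    """Train the benchmark model variants on one training alignment.

    "hpm" = full PLM couplings; "no_ekl" = couplings constrained to zero;
    "nested"/"pseudoknotted" = analytic masked models on the annotated
    nested / nested+pseudoknot pairs (skipped without SS_cons).
    """
    phmm = train_phmm(train)
    structure = None
    if train.ss_cons is not None:
        structure = parse_wuss(train.ss_cons, train.get_consensus_mask())
    out: dict[str, HiddenPottsModel] = {}
    for name in which:
        if name == "hpm":
            potts = train_plm(train, lambda_h=lambda_h, lambda_e=lambda_e)
        elif name == "no_ekl":
            potts = train_plm(train, lambda_h=lambda_h, no_couplings=True)
        elif name in ("nested", "pseudoknotted"):
            if structure is None:
                continue
            potts = train_masked(
                train, pairs=structure,
                include_pseudoknots=(name == "pseudoknotted"))
        else:
            raise ValueError(f"unknown variant {name!r}")
        out[name] = assemble_hpm(phmm, potts)
    return VariantModels(phmm=phmm, variants=out, structure=structure)


def score_sequences_shared(
    models: VariantModels,
    seqs: list[str],
    R: int,
    seed: int | None = 0,
    collect_best: bool = False,
):
    """Score sequences under all variants, sharing proposal samples.

    One Forward fill and one batch of R stochastic tracebacks per sequence
    serve every HPM variant (the variants differ only in re-weighting);
    the pHMM baseline score is the Forward bit score. Returns
    ``scores[name][i]`` in bits and, optionally, each variant's best
    decomposition per sequence.
    """
    rng = np.random.default_rng(seed)
    names = list(models.variants)
    scores: dict[str, list[float]] = {n: [] for n in names}
    scores["phmm"] = []
    best: dict[str, list[Decomposition]] = {n: [] for n in names}
    for x in seqs:
        fwd = forward_glocal(models.phmm, x)
        dec = sample_decompositions(fwd, R, seed=int(rng.integers(2**31 - 1)))
        for name in names:
            hpm = models.variants[name]
            log_num = _batch_numerators(hpm, dec, fwd.xi)
            log_w = log_num - dec.log_q
            log_pstar = float(logsumexp(log_w) - np.log(R))
            scores[name].append((log_pstar - null_logprob(hpm, x)) / LN2)
            if collect_best:
                b = int(np.argmax(log_w))
                best[name].append(Decomposition(
                    ins_counts=dec.ins_counts[b].astype(np.int64),
                    xm=dec.xm[b].astype(np.int64),
                    xi=fwd.xi[dec.ins_mask[b]]))
        null_bits = float(np.log(models.phmm.background)[fwd.xi].sum())
        scores["phmm"].append((fwd.logp - null_bits) / LN2)
    if collect_best:
        return scores, best
    return scores


def run_scoring_benchmark(
    split: BenchmarkSplit,
    R: int = 10**4,
    seed: int | None = 0,
    which: tuple[str, ...] = ("hpm", "no_ekl"),
) -> dict[str, ROCResult]:
    """Train variants on the split's training MSA and build per-model ROCs."""
    models = train_variants(split.train, which=which)
    pos = score_sequences_shared(models, split.test_seqs, R, seed=seed)
    dec = score_sequences_shared(models, split.decoys, R,
                                 seed=None if seed is None else seed + 1)
    return {
        name: roc_curve(pos[name], dec[name])
        for name in pos
    }


# ---------------------------------------------------------------------------
# Synthetic parameter-recovery experiment (MSA1 -> MSA2 -> MSA3)


@dataclass
class RecoveryReport:
    """Everything the recovery experiment measures.

    ``h_true``/``h_fit`` and ``e_true``/``e_fit`` are flattened parameter
    scatters (training vs synthetic HPM); the marginal and MI comparisons
    contrast MSA2 (from the training HPM) with MSA3 (from the synthetic
    HPM); ``realignment_accuracy`` is MSA2 realigned to the synthetic HPM
    against its ground-truth emission alignment.
    """

    hamiltonian_trace: np.ndarray
    h_true: np.ndarray
    h_fit: np.ndarray
    e_true: np.ndarray
    e_fit: np.ndarray
    p1_msa2: np.ndarray
    p1_msa3: np.ndarray
    p2_msa2: np.ndarray
    p2_msa3: np.ndarray
    mi_msa2: np.ndarray
    mi_msa3: np.ndarray
    mi_attenuation_fraction: float
    realignment_accuracy: AccuracyResult


def _msa_mi_pairs(msa: MSA, pairs: list[tuple[int, int]]) -> np.ndarray:
    cons = np.flatnonzero(msa.get_consensus_mask())
    w = np.ones(len(msa))
    return np.array([
        pair_mutual_info(msa, w, int(cons[i]), int(cons[j])) for i, j in pairs
    ])


def synthetic_recovery_experiment(
    seed_msa: MSA,
    n: int = 1000,
    burn_in: int = 5000,
    seed: int | None = 0,
    R_align: int = 2000,
    trainer: str = "plm",
    structure: StructureAnnotation | None = None,
) -> RecoveryReport:
    """Ground-truth positive control: train, emit, re-train, compare.

    An HPM trained on ``seed_msa`` (MSA1) emits n aligned sequences
    (MSA2); a second HPM trained on MSA2 emits MSA3. The report compares
    parameters and emitted statistics, and realigns MSA2's sequences to
    the MSA2-trained model against their known true alignment.
    ``trainer`` selects "plm" or "masked" Potts training for both models.
    """
    rng = np.random.default_rng(seed)
    if structure is None and seed_msa.ss_cons is not None:
        structure = parse_wuss(seed_msa.ss_cons, seed_msa.get_consensus_mask())

    def fit(msa: MSA, strc) -> tuple[ProfileHMM, PottsModel]:
        phmm = train_phmm(msa)
        if trainer == "masked":
            if strc is None:
                raise ValueError("masked trainer needs a structure annotation")
            potts = train_masked(msa, pairs=strc, include_pseudoknots=True)
        else:
            potts = train_plm(msa)
        return phmm, potts

    phmm1, potts1 = fit(seed_msa, structure)
    hpm1 = assemble_hpm(phmm1, potts1)
    M = hpm1.M

    emit2 = emit_sequences(hpm1, n, burn_in=burn_in,
                           seed=int(rng.integers(2**31 - 1)),
                           record_trace=True)
    msa2 = emit2.msa
    if msa2.n_consensus != M:
        warnings.warn(
            f"MSA2 consensus length {msa2.n_consensus} != M={M}; "
            "recovery comparison requires matching coordinates")
    # structure in MSA2's coordinates equals the model's (same match columns)
    struct2 = structure

    phmm2, potts2 = fit(msa2, struct2)
    hpm2 = assemble_hpm(phmm2, potts2)

    emit3 = emit_sequences(hpm2, n, burn_in=burn_in,
                           seed=int(rng.integers(2**31 - 1)))
    msa3 = emit3.msa

    p1_2, p2_2 = estimate_marginals(np.stack([d.xm for d in emit2.decompositions]))
    p1_3, p2_3 = estimate_marginals(np.stack([d.xm for d in emit3.decompositions]))

    pairs = structure.all_pairs if structure is not None else []
    mi2 = _msa_mi_pairs_from_xm(emit2.decompositions, pairs)
    mi3 = _msa_mi_pairs_from_xm(emit3.decompositions, pairs)
    atten = float(np.mean(mi3 < mi2)) if len(pairs) else float("nan")

    # realign MSA2's sequences to the synthetic HPM
    preds: list[Decomposition] = []
    for i, x in enumerate(emit2.sequences):
        fwd = forward_glocal(phmm2, x)
        dec = sample_decompositions(fwd, R_align,
                                    seed=int(rng.integers(2**31 - 1)))
        log_w = _batch_numerators(hpm2, dec, fwd.xi) - dec.log_q
        b = int(np.argmax(log_w))
        preds.append(Decomposition(
            ins_counts=dec.ins_counts[b].astype(np.int64),
            xm=dec.xm[b].astype(np.int64),
            xi=fwd.xi[dec.ins_mask[b]]))
    acc = alignment_accuracy(preds, emit2.decompositions, structure)

    return RecoveryReport(
        hamiltonian_trace=emit2.hamiltonian_trace,
        h_true=potts1.h.ravel().copy(),
        h_fit=potts2.h.ravel().copy(),
        e_true=potts1.e.ravel().copy(),
        e_fit=potts2.e.ravel().copy(),
        p1_msa2=p1_2, p1_msa3=p1_3, p2_msa2=p2_2, p2_msa3=p2_3,
        mi_msa2=mi2, mi_msa3=mi3, mi_attenuation_fraction=atten,
        realignment_accuracy=acc,
    )


def _mi_from_counts(joint: np.ndarray) -> float:
    p = joint / joint.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    nz = p > 0
    return max(float(np.sum(p[nz] * np.log2(p[nz] / np.outer(pa, pb)[nz]))), 0.0)


def _msa_mi_pairs_from_xm(decs: list[Decomposition],
                          pairs: list[tuple[int, int]]) -> np.ndarray:
    """MI per annotated pair from ground-truth match sequences.

    Uses the residue-only (non-deletion) joint distribution of the match
    characters, so the statistic matches what an alignment-based MI sees.
    """
    if not pairs:
        return np.array([])
    X = np.stack([d.xm for d in decs])
    out = []
    for i, j in pairs:
        sel = (X[:, i] != 4) & (X[:, j] != 4)
        joint = np.zeros((4, 4))
        np.add.at(joint, (X[sel, i], X[sel, j]), 1.0)
        out.append(_mi_from_counts(joint) if joint.sum() else 0.0)
    return np.array(out)
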