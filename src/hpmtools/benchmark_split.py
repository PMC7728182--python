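"""Train/test splitting for remote-homology benchmarks, plus decoys.

The split emulates a search for distant homologs: sequences are clustered
by single linkage at a 60% identity threshold, whole clusters are assigned
to either the training or the test side (so no test sequence is more than
60% identical to any training sequence), and the test pool is greedily
thinned until no two test sequences exceed 70% identity.

Decoys are non-homologous negatives: residues drawn i.i.d. from the pooled
nucleotide composition of the positive test sequences, each decoy matching
the length of a randomly chosen positive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .msa import MSA, pairwise_identity


class SplitInfeasibleError(RuntimeError):
    """The identity constraints cannot be satisfied for this alignment."""


@dataclass
class BenchmarkSplit:
    """A benchmark: training MSA, positive test sequences, decoys.

    ``test_rows`` keeps the test sequences' reference alignment rows (used
    for alignment-accuracy scoring); ``test_seqs`` are the dealigned
    versions actually given to the aligner.
    """

    train: MSA
    test_names: list[str]
    test_rows: list[str]
    decoys: list[str]

    @property
    def test_seqs(self) -> list[str]:
        return [r.replace("-", "") for r in self.test_rows]


def identity_matrix(rows: list[str]) -> np.ndarray:
    n = len(rows)
    ident = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = pairwise_identity(rows[i], rows[j])
    return ident


def _single_linkage_components(ident: np.ndarray, threshold: float) -> list[list[int]]:
    """Connected components of the graph linking pairs with identity > threshold."""
    n = ident.shape[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if ident[i, j] > threshold:
                parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def split_train_test(
    msa: MSA,
    test_max_id: float = 0.60,
    test_pairwise_max_id: float = 0.70,
    seed: int | None = 0,
    min_test: int = 5,
    n_decoys: int = 0,
) -> BenchmarkSplit:
    """Split an alignment into an in-clade training set and a remote test set.

    Single-linkage clusters at ``test_max_id`` are assigned whole to one
    side. Clusters are shuffled (seeded) and moved to the test pool,
    smallest first, until it holds at least ``min_test`` sequences; the
    pool is then thinned so no pair exceeds ``test_pairwise_max_id``.
    """
    rows = msa.rows
    ident = identity_matrix(rows)
    comps = _single_linkage_components(ident, test_max_id)
    if len(comps) < 2:
        raise SplitInfeasibleError(
            "alignment has a single linkage component at the identity "
            "threshold; cannot form a disjoint test set"
        )
    rng = np.random.default_rng(seed)
    order = sorted(rng.permutation(len(comps)), key=lambda c: len(comps[c]))
    test_idx: list[int] = []
    test_comps: set[int] = set()
    for c in order:
        if len(test_idx) >= min_test:
            break
        if len(test_comps) == len(comps) - 1:
            break  # keep at least one cluster for training
        test_comps.add(c)
        test_idx.extend(comps[c])
    train_idx = sorted(
        i for c, comp in enumerate(comps) if c not in test_comps for i in comp
    )
    if not train_idx or not test_idx:
        raise SplitInfeasibleError("empty train or test pool after assignment")

    # greedy thinning of the test pool at the 70% threshold
    test_idx = sorted(test_idx)
    while True:
        over = {
            i: sum(
                1
                for j in test_idx
                if j != i and ident[i, j] > test_pairwise_max_id
            )
            for i in test_idx
        }
        worst = max(test_idx, key=lambda i: (over[i], i))
        if over[worst] == 0:
            break
        test_idx.remove(worst)
    if not test_idx:
        raise SplitInfeasibleError("test pool empty after identity thinning")

    train = MSA(
        names=[msa.names[i] for i in train_idx],
        rows=[rows[i] for i in train_idx],
        ss_cons=msa.ss_cons,
        alphabet=msa.alphabet,
    )
    split = BenchmarkSplit(
        train=train,
        test_names=[msa.names[i] for i in test_idx],
        test_rows=[rows[i] for i in test_idx],
        decoys=[],
    )
    if n_decoys:
        split.decoys = generate_decoys(split.test_seqs, n_decoys, seed=seed)
    return split


def save_split(split: BenchmarkSplit, outdir) -> None:
    """Serialize a split: train.sto, test.fa, decoys.fa and a manifest."""
    import os

    from .stockholm import write_fasta, write_stockholm

    os.makedirs(outdir, exist_ok=True)
    write_stockholm(split.train, os.path.join(outdir, "train.sto"))
    write_fasta(list(zip(split.test_names, split.test_seqs)),
                os.path.join(outdir, "test.fa"))
    write_fasta([(f"decoy{i}", d) for i, d in enumerate(split.decoys)],
                os.path.join(outdir, "decoys.fa"))
    with open(os.path.join(outdir, "manifest.txt"), "w") as fh:
        fh.write(f"train_sequences\t{len(split.train)}\n")
        fh.write(f"test_sequences\t{len(split.test_rows)}\n")
        fh.write(f"decoys\t{len(split.decoys)}\n")
        fh.write("test_names\t" + ",".join(split.test_names) + "\n")


def generate_decoys(
    test_positives: list[str], n: int, seed: int | None = 0
) -> list[str]:
    """Draw ``n`` i.i.d.-composition decoys matched in length to positives."""
    if not test_positives:
        raise ValueError("need at least one positive test sequence")
    rng = np.random.default_rng(seed)
    pooled = Counter("".join(test_positives))
    letters = sorted(pooled)
    counts = np.array([pooled[c] for c in letters], dtype=float)
    probs = counts / counts.sum()
    lengths = [len(s) for s in test_positives]
    decoys = []
    for _ in range(n):
        L = lengths[rng.integers(len(lengths))]
        decoys.append("".join(rng.choice(letters, size=L, p=probs)))
    return decoys
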