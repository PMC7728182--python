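"""Multiple sequence alignment container, consensus columns, and weights.

A consensus column is one with fewer than 50% gap characters (strict
inequality, unweighted counts); consensus columns become the match sites of
the profile models. Sequence weights are Henikoff position-based weights,
renormalized to sum to the number of sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import RNA, Alphabet


class FormatError(ValueError):
    """Malformed alignment input (ragged rows, bad annotation length)."""


@dataclass
class MSA:
    """An alignment: rows of equal length plus optional annotation.

    ``rows`` hold normalized characters (uppercase residues, '-' gaps);
    ``ss_cons`` is the consensus-structure annotation (WUSS) if present;
    ``weights`` and ``consensus_mask`` are filled in lazily by
    :func:`henikoff_weights` and :func:`consensus_columns`.
    """

    names: list[str]
    rows: list[str]
    ss_cons: str | None = None
    weights: np.ndarray | None = None
    consensus_mask: np.ndarray | None = None
    alphabet: Alphabet = field(default_factory=lambda: RNA)

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError("empty alignment")
        W = len(self.rows[0])
        if any(len(r) != W for r in self.rows):
            raise FormatError("ragged alignment: rows differ in length")
        if self.ss_cons is not None and len(self.ss_cons) != W:
            raise FormatError(
                f"SS_cons length {len(self.ss_cons)} != alignment width {W}"
            )
        if len(self.names) != len(self.rows):
            raise FormatError("names/rows length mismatch")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])

    @property
    def n_consensus(self) -> int:
        """M, the number of consensus columns."""
        return int(np.count_nonzero(self.get_consensus_mask()))

    def char_matrix(self) -> np.ndarray:
        """(N, W) array of single characters."""
        return np.array([list(r) for r in self.rows], dtype="U1")

    def gap_matrix(self) -> np.ndarray:
        return self.char_matrix() == "-"

    def get_weights(self) -> np.ndarray:
        if self.weights is None:
            self.weights = henikoff_weights(self)
        return self.weights

    def get_consensus_mask(self) -> np.ndarray:
        if self.consensus_mask is None:
            self.consensus_mask = consensus_columns(self)
        return self.consensus_mask

    def consensus_rows(self) -> list[str]:
        """Rows restricted to consensus columns (gaps kept as '-')."""
        mask = self.get_consensus_mask()
        idx = np.flatnonzero(mask)
        return ["".join(r[i] for i in idx) for r in self.rows]

    def consensus_int_matrix(self) -> np.ndarray:
        """(N, M) integer matrix over the 5-letter Potts alphabet.

        Gaps inside consensus columns are recoded as the deletion character.
        """
        rows = self.consensus_rows()
        ab = self.alphabet
        return np.array([[ab.index(c) for c in r] for r in rows], dtype=np.int64)

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


def consensus_columns(msa: MSA) -> np.ndarray:
    """Boolean mask: column is consensus iff its gap fraction is < 0.5.

    Counts are unweighted; the boundary (exactly half gaps) is non-consensus.
    """
    gaps = msa.gap_matrix()
    frac = gaps.mean(axis=0)
    mask = frac < 0.5
    msa.consensus_mask = mask
    return mask


def henikoff_weights(msa: MSA) -> np.ndarray:
    """Henikoff & Henikoff position-based sequence weights.

    In each column, a sequence showing residue ``a`` receives 1/(r*s) where
    r is the number of distinct residue types in the column and s the count
    of ``a``; gaps contribute nothing. Per-sequence sums are renormalized to
    sum to N.
    """
    chars = msa.char_matrix()
    N = len(msa)
    raw = np.zeros(N)
    for col in chars.T:
        residues = col[col != "-"]
        if residues.size == 0:
            continue
        types, counts = np.unique(residues, return_counts=True)
        r = len(types)
        share = {t: 1.0 / (r * s) for t, s in zip(types, counts)}
        for i, c in enumerate(col):
            if c != "-":
                raw[i] += share[c]
    total = raw.sum()
    if total == 0:
        w = np.full(N, 1.0)
    else:
        w = raw * (N / total)
    msa.weights = w
    return w


def pairwise_identity(a: str, b: str) -> float:
    """Fractional identity between two aligned rows.

    Identity = matching residue pairs / number of columns where both rows
    carry residues. Pairs with a gap in either row do not count in the
    denominator; a pair with no co-occupied column scores 0.
    """
    if not a.replace("-", "") or not b.replace("-", ""):
        raise ValueError("pairwise identity undefined for empty sequences")
    if len(a) != len(b):
        raise FormatError("aligned rows differ in length")
    both = matches = 0
    for ca, cb in zip(a, b):
        if ca != "-" and cb != "-":
            both += 1
            if ca == cb:
                matches += 1
    return matches / both if both else 0.0
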