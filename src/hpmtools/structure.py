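"""WUSS consensus-structure parsing.

The SS_cons line of a Stockholm alignment annotates base pairs in WUSS
notation: matched brackets (``<>``, ``()``, ``[]``, ``{}``) mark nested
pairs, and uppercase/lowercase letter pairs (``Aa``, ``Bb``, ...) mark
pseudoknotted (non-nested) pairs. Everything else is unpaired. Pairs are
projected into consensus-column coordinates; a pair with either partner in
a non-consensus column is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class StructureParseError(ValueError):
    """Unbalanced brackets or unmatched pseudoknot letters."""


OPEN_BRACKETS = {"<": ">", "(": ")", "[": "]", "{": "}"}
CLOSE_BRACKETS = {v: k for k, v in OPEN_BRACKETS.items()}


@dataclass
class StructureAnnotation:
    """Base pairs in consensus-column coordinates (0-based, i < j)."""

    nested_pairs: list[tuple[int, int]] = field(default_factory=list)
    pseudoknot_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def all_pairs(self) -> list[tuple[int, int]]:
        return list(self.nested_pairs) + list(self.pseudoknot_pairs)

    def paired_columns(self) -> set[int]:
        cols: set[int] = set()
        for i, j in self.all_pairs:
            cols.add(i)
            cols.add(j)
        return cols

    def validate_disjoint(self) -> None:
        """Each column may belong to at most one pair."""
        seen: set[int] = set()
        for i, j in self.all_pairs:
            if i >= j:
                raise StructureParseError(f"pair ({i},{j}) not ordered i<j")
            if i in seen or j in seen:
                raise StructureParseError(
                    f"column in more than one pair: ({i},{j})"
                )
            seen.update((i, j))


def _match_pairs(ss: str) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Pair up brackets and pseudoknot letters in full-alignment coordinates."""
    stacks: dict[str, list[int]] = {b: [] for b in OPEN_BRACKETS}
    pk_stacks: dict[str, list[int]] = {}
    nested: list[tuple[int, int]] = []
    pk: list[tuple[int, int]] = []
    for pos, c in enumerate(ss):
        if c in OPEN_BRACKETS:
            stacks[c].append(pos)
        elif c in CLOSE_BRACKETS:
            opener = CLOSE_BRACKETS[c]
            if not stacks[opener]:
                raise StructureParseError(
                    f"unbalanced bracket {c!r} at column {pos}"
                )
            nested.append((stacks[opener].pop(), pos))
        elif c.isalpha():
            if c.isupper():
                pk_stacks.setdefault(c, []).append(pos)
            else:
                stack = pk_stacks.get(c.upper(), [])
                if not stack:
                    raise StructureParseError(
                        f"unmatched pseudoknot letter {c!r} at column {pos}"
                    )
                pk.append((stack.pop(), pos))
        # '.', ',', ':', '-', '_', '~' and any other character: unpaired
    leftovers = [b for b, s in stacks.items() if s]
    if leftovers:
        raise StructureParseError(f"unclosed bracket(s): {leftovers}")
    pk_left = [c for c, s in pk_stacks.items() if s]
    if pk_left:
        raise StructureParseError(f"unclosed pseudoknot letter(s): {pk_left}")
    return sorted(nested), sorted(pk)


def parse_wuss(ss_cons: str, mask: np.ndarray) -> StructureAnnotation:
    """Parse a WUSS SS_cons string against a consensus-column mask.

    Returns pairs as 0-based indices into the ordered list of consensus
    columns. Pairs touching non-consensus columns are dropped.
    """
    if len(ss_cons) != len(mask):
        raise StructureParseError(
            f"SS_cons length {len(ss_cons)} != mask length {len(mask)}"
        )
    nested_full, pk_full = _match_pairs(ss_cons)
    # map full-alignment column -> consensus coordinate
    cons_index = np.cumsum(mask) - 1
    def project(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
        out = []
        for i, j in pairs:
            if mask[i] and mask[j]:
                out.append((int(cons_index[i]), int(cons_index[j])))
        return sorted(out)
    ann = StructureAnnotation(project(nested_full), project(pk_full))
    return ann


def render_wuss(ann: StructureAnnotation, m: int) -> str:
    """Render a structure over ``m`` consensus columns back to WUSS.

    Nested pairs become angle brackets; pseudoknot pairs are assigned
    letters A, B, ... by order of appearance.
    """
    chars = ["."] * m
    for i, j in ann.nested_pairs:
        chars[i] = "<"
        chars[j] = ">"
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    # group pseudoknot pairs that interleave into the same letter greedily
    for n, (i, j) in enumerate(sorted(ann.pseudoknot_pairs)):
        letter = letters[n % len(letters)]
        chars[i] = letter
        chars[j] = letter.lower()
    return "".join(chars)
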