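"""RNA alphabet with an explicit deletion character.

The models in this package emit match columns from a Potts distribution over
a 5-letter alphabet: the four nucleotides plus a "deletion" character that
stands for the absence of a residue at a consensus column. Deletions are
therefore emitted characters, not hidden states.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class AlphabetError(ValueError):
    """A sequence contains a character outside the accepted alphabet."""


@dataclass(frozen=True)
class Alphabet:
    """Ordered residue symbols plus deletion and gap conventions.

    ``symbols`` are the residue characters (A, C, G, U); ``deletion_symbol``
    is the extra Potts character standing in for an absent residue at a
    consensus column; ``gap_symbols`` are the characters accepted as
    alignment gaps on input (normalized to '-' internally).
    """

    symbols: tuple[str, ...] = ("A", "C", "G", "U")
    deletion_symbol: str = "-"
    gap_symbols: frozenset[str] = field(
        default_factory=lambda: frozenset({"-", ".", "_", "~"})
    )

    def __post_init__(self) -> None:
        if self.deletion_symbol in self.symbols:
            raise ValueError("deletion symbol must not be a residue symbol")

    @property
    def n_residues(self) -> int:
        return len(self.symbols)

    @property
    def K(self) -> int:
        """Potts alphabet size: residues plus the deletion character."""
        return len(self.symbols) + 1

    @property
    def deletion_index(self) -> int:
        return len(self.symbols)

    def index(self, char: str) -> int:
        """Map a residue or the deletion character to its integer code."""
        try:
            return self.symbols.index(char)
        except ValueError:
            if char == self.deletion_symbol:
                return self.deletion_index
            raise AlphabetError(f"unknown character {char!r}") from None

    def normalize_char(self, char: str) -> str:
        """Uppercase, map T to U, and canonicalize gap characters to '-'."""
        c = char.upper()
        if c == "T":
            c = "U"
        if c in self.gap_symbols or char in self.gap_symbols:
            return "-"
        if c not in self.symbols:
            raise AlphabetError(f"unknown residue character {char!r}")
        return c

    def normalize(self, seq: str) -> str:
        return "".join(self.normalize_char(c) for c in seq)


RNA = Alphabet()
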