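"""Stockholm 1.0 and FASTA input/output (Biopython-backed).

Reading normalizes sequences to the RNA alphabet: uppercase, T mapped to U,
and any of the gap characters '-', '.', '_', '~' canonicalized to '-'.
The ``#=GC SS_cons`` line, when present (possibly split across wrapped
blocks, which Biopython concatenates), is carried on :class:`~hpmtools.msa.MSA`.
"""

from __future__ import annotations

import io
import os

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import RNA, Alphabet
from .msa import MSA, FormatError


def read_stockholm(path: str | os.PathLike | io.TextIOBase,
                   alphabet: Alphabet = RNA) -> MSA:
    """Read a Stockholm 1.0 alignment into an :class:`MSA`."""
    try:
        aln = AlignIO.read(path, "stockholm")
    except ValueError as exc:
        raise FormatError(f"not a valid Stockholm alignment: {exc}") from exc
    names = [rec.id for rec in aln]
    rows = [alphabet.normalize(str(rec.seq)) for rec in aln]
    ss = aln.column_annotations.get("secondary_structure")
    return MSA(names=names, rows=rows, ss_cons=ss, alphabet=alphabet)


def write_stockholm(msa: MSA, path: str | os.PathLike | io.TextIOBase) -> None:
    """Write an :class:`MSA` (with SS_cons if set) as Stockholm 1.0."""
    records = [
        SeqRecord(Seq(row), id=name, description="")
        for name, row in zip(msa.names, msa.rows)
    ]
    aln = MultipleSeqAlignment(records)
    if msa.ss_cons is not None:
        aln.column_annotations["secondary_structure"] = msa.ss_cons
    AlignIO.write(aln, path, "stockholm")


def read_fasta(path: str | os.PathLike | io.TextIOBase,
               alphabet: Alphabet = RNA) -> list[tuple[str, str]]:
    """Read unaligned FASTA sequences as (name, normalized sequence) pairs."""
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        seq = alphabet.normalize(str(rec.seq)).replace("-", "")
        out.append((rec.id, seq))
    return out


def write_fasta(seqs: list[tuple[str, str]],
                path: str | os.PathLike | io.TextIOBase) -> None:
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in seqs]
    SeqIO.write(records, path, "fasta")
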