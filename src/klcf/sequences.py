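"""Sequence containers, FASTA input, alphabet encoding and per-symbol indexing.

Sequences are stored as small integer code arrays (0-based positions
throughout the Python API).  Characters outside the alphabet -- ambiguity
codes like ``N``, IUPAC wildcards, gaps -- are encoded as a *sentinel* code
that never matches anything, including itself, so undefined regions always
count as mismatches and can never seed spurious common substrings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

#: Code used for every character outside the alphabet.  Negative, so the
#: in-alphabet codes 0..len(symbols)-1 never collide with it.
SENTINEL: int = -1


@dataclass(frozen=True)
class Alphabet:
    """An ordered residue alphabet with a never-matching sentinel.

    Two codes *match* iff they are equal and neither is the sentinel.
    Lower-case input is upper-cased before encoding (no soft-masking
    semantics).
    """

    symbols: str = "ACGT"
    unknown_char: str = "N"

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if not self.symbols:
            raise ValueError("alphabet must contain at least one symbol")
        table = np.full(256, SENTINEL, dtype=np.int8)
        for code, ch in enumerate(self.symbols):
            table[ord(ch.upper())] = code
            table[ord(ch.lower())] = code
        object.__setattr__(self, "_table", table)

    @property
    def size(self) -> int:
        return len(self.symbols)

    def encode(self, text: str) -> np.ndarray:
        """Encode ``text`` to an int8 code array (sentinel for non-alphabet)."""
        raw = np.frombuffer(text.encode("latin-1"), dtype=np.uint8)
        return self._table[raw]

    def decode(self, codes: np.ndarray) -> str:
        """Decode codes back to upper-case text; sentinels become ``unknown_char``."""
        chars = np.array([self.unknown_char.upper()] + [c.upper() for c in self.symbols])
        return "".join(chars[np.asarray(codes, dtype=np.int64) + 1])


#: Default DNA alphabet.
DNA = Alphabet("ACGT")

#: Binary alphabet, handy for stress-testing the filters (dense matches).
BINARY = Alphabet("01", unknown_char="?")


@dataclass(frozen=True)
class EncodedSequence:
    """An integer-coded residue sequence with its identifier."""

    id: str
    codes: np.ndarray
    alphabet: Alphabet = DNA

    def __post_init__(self) -> None:
        codes = np.ascontiguousarray(self.codes, dtype=np.int8)
        object.__setattr__(self, "codes", codes)

    @property
    def n(self) -> int:
        return int(self.codes.shape[0])

    def __len__(self) -> int:
        return self.n

    def __str__(self) -> str:
        return self.alphabet.decode(self.codes)


def encode_sequence(text: str, id: str = "seq", alphabet: Alphabet = DNA) -> EncodedSequence:
    """Convenience constructor from a plain string."""
    return EncodedSequence(id=id, codes=alphabet.encode(text), alphabet=alphabet)


def read_fasta(path: str | Path, alphabet: Alphabet = DNA) -> list[EncodedSequence]:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    Raises ``ValueError`` naming the record on empty files or empty records.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    out = []
    for rec in records:
        text = str(rec.seq)
        if not text:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        out.append(EncodedSequence(id=rec.id, codes=alphabet.encode(text), alphabet=alphabet))
    return out


def write_fasta(seqs: Iterable[EncodedSequence], path: str | Path, width: int = 70) -> None:
    """Write sequences to FASTA (used by the synthetic-data CLI paths)."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            text = str(s)
            for off in range(0, len(text), width):
                fh.write(text[off : off + width] + "\n")


def random_sequences(
    count: int,
    length: int,
    seed: int,
    alphabet: Alphabet = DNA,
    id_prefix: str = "rand",
) -> list[EncodedSequence]:
    """Generate i.i.d. uniform random sequences over ``alphabet``.

    Deterministic: identical ``(count, length, seed, alphabet)`` reproduce
    identical sequences bit-for-bit.  This is the synthetic stand-in for the
    random test panels: uniform DNA at mitochondrial-genome scale
    (~16,500 bp) when used with the defaults of the benchmark commands.
    """
    if count < 1 or length < 1:
        raise ValueError("count and length must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for idx in range(count):
        codes = rng.integers(0, alphabet.size, size=length, dtype=np.int8)
        out.append(EncodedSequence(id=f"{id_prefix}_{idx + 1}", codes=codes, alphabet=alphabet))
    return out


@dataclass(frozen=True)
class SymbolPositionIndex:
    """Per-symbol boolean occurrence masks over a sequence ``y``.

    ``masks[s, r]`` is True iff ``y[r]`` is symbol ``s``.  Sentinel positions
    are set in no mask, so the masks plus the sentinel positions partition
    ``range(m)``.
    """

    masks: np.ndarray  # bool, shape (alphabet.size, m)
    alphabet: Alphabet

    @property
    def m(self) -> int:
        return int(self.masks.shape[1])


def build_symbol_index(y: EncodedSequence) -> SymbolPositionIndex:
    """Build the per-symbol occurrence masks used by the candidate filters."""
    size = y.alphabet.size
    masks = np.zeros((size, y.n), dtype=bool)
    for s in range(size):
        masks[s] = y.codes == s
    return SymbolPositionIndex(masks=masks, alphabet=y.alphabet)
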