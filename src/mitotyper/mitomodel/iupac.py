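"""IUPAC nucleotide ambiguity algebra.

Every symbol denotes a set of unambiguous bases; ambiguity-aware scoring
throughout the package is defined on those sets.  Symbols are encoded as
small integers (``encode``) so per-site operations can be table lookups
over numpy arrays.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import AlphabetError

GAP = "-"

#: Canonical symbol order; the integer code of a symbol is its index here.
SYMBOLS = "ACGTRYSWKMBDHVN" + GAP

_SET_BY_SYMBOL = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
    GAP: "",
}

BASE_SETS: dict[str, frozenset[str]] = {
    sym: frozenset(bases) for sym, bases in _SET_BY_SYMBOL.items()
}

_SYMBOL_BY_SET = {bases: sym for sym, bases in BASE_SETS.items()}

_BASE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

COMPLEMENT: dict[str, str] = {
    sym: _SYMBOL_BY_SET[frozenset(_BASE_COMPLEMENT[b] for b in bases)]
    for sym, bases in BASE_SETS.items()
}

GAP_CODE = SYMBOLS.index(GAP)
_CODE_BY_SYMBOL = {sym: i for i, sym in enumerate(SYMBOLS)}

# 256-entry lookup so bytes -> codes is a single numpy take.
_ENCODE_TABLE = np.full(256, -1, dtype=np.int8)
for _sym, _i in _CODE_BY_SYMBOL.items():
    _ENCODE_TABLE[ord(_sym)] = _i
    _ENCODE_TABLE[ord(_sym.lower())] = _i


@dataclass(frozen=True)
class IUPACBase:
    """A single IUPAC symbol together with the base set it denotes."""

    symbol: str

    def __post_init__(self) -> None:
        if self.symbol not in BASE_SETS:
            raise AlphabetError(f"not an IUPAC nucleotide symbol: {self.symbol!r}")

    @property
    def base_set(self) -> frozenset[str]:
        return BASE_SETS[self.symbol]

    @property
    def is_gap(self) -> bool:
        return self.symbol == GAP

    @property
    def is_ambiguous(self) -> bool:
        return len(self.base_set) > 1

    def complement(self) -> "IUPACBase":
        return IUPACBase(COMPLEMENT[self.symbol])


def is_valid(seq: str) -> bool:
    return all(c.upper() in BASE_SETS for c in seq)


def validate(seq: str, context: str = "sequence") -> None:
    for i, c in enumerate(seq):
        if c.upper() not in BASE_SETS:
            raise AlphabetError(f"illegal symbol {c!r} at position {i} in {context}")


def encode(seq: str) -> np.ndarray:
    """Encode a string as int8 codes (index into :data:`SYMBOLS`)."""
    arr = _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = int(np.argmax(arr < 0))
        raise AlphabetError(f"illegal symbol {seq[bad]!r} at position {bad}")
    return arr


def decode(codes: np.ndarray) -> str:
    return "".join(SYMBOLS[c] for c in codes)


def complement_seq(seq: str) -> str:
    try:
        return "".join(COMPLEMENT[c.upper()] for c in seq)
    except KeyError as exc:  # pragma: no cover - validated upstream normally
        raise AlphabetError(f"cannot complement symbol {exc.args[0]!r}") from exc


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement; an involution on valid strings."""
    return complement_seq(seq)[::-1]


def ambiguity_symbol(bases: set[str] | frozenset[str]) -> str:
    """The IUPAC symbol denoting exactly ``bases``."""
    if not bases:
        raise AlphabetError("no IUPAC symbol denotes an empty base set")
    try:
        return _SYMBOL_BY_SET[frozenset(bases)]
    except KeyError as exc:
        raise AlphabetError(f"no IUPAC symbol for base set {sorted(bases)}") from exc


def _build_match_matrix() -> np.ndarray:
    """Expected-match score ``|Sa & Sb| / (|Sa| * |Sb|)`` per symbol pair.

    Gap rows/columns are NaN: gap handling is a policy decision for the
    caller, never a score.
    """
    m = np.full((len(SYMBOLS), len(SYMBOLS)), np.nan)
    for i, a in enumerate(SYMBOLS):
        for j, b in enumerate(SYMBOLS):
            sa, sb = BASE_SETS[a], BASE_SETS[b]
            if not sa or not sb:
                continue
            m[i, j] = len(sa & sb) / (len(sa) * len(sb))
    return m


def _build_overlap_matrix() -> np.ndarray:
    """1.0 where base sets are disjoint, 0.0 where they overlap, NaN for gaps."""
    m = np.full((len(SYMBOLS), len(SYMBOLS)), np.nan)
    for i, a in enumerate(SYMBOLS):
        for j, b in enumerate(SYMBOLS):
            sa, sb = BASE_SETS[a], BASE_SETS[b]
            if not sa or not sb:
                continue
            m[i, j] = 0.0 if sa & sb else 1.0
    return m


#: Pairwise expected-match scores, indexed by symbol codes.
MATCH_SCORE = _build_match_matrix()

#: Conservative mismatch indicator (0 when base sets share an allele).
SET_MISMATCH = _build_overlap_matrix()
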