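"""Vertebrate mitochondrial genetic code (NCBI translation table 2).

The table is taken from Biopython's codon table registry; this module adds
the small amount of algebra the rest of the package needs: codon
translation, synonymous/nonsynonymous classification of substitutions, and
enumeration of single-base codon neighbours.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from Bio.Data import CodonTable

from ..errors import AlphabetError

STOP = "*"
_BASES = "ACGT"

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"


def _table_from_ncbi(table_id: int) -> dict[str, str]:
    ncbi = CodonTable.unambiguous_dna_by_id[table_id]
    table = {"".join(c): aa for c, aa in ncbi.forward_table.items() if len(c) == 3}
    for codon in ncbi.stop_codons:
        table[codon] = STOP
    # every triplet must be covered
    assert len(table) == 64
    return table


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino-acid map (stops encoded as ``*``)."""

    name: str
    table: dict[str, str] = field(repr=False)

    @classmethod
    def from_ncbi_id(cls, table_id: int) -> "GeneticCode":
        return cls(name=f"ncbi_table_{table_id}", table=_table_from_ncbi(table_id))

    def translate_codon(self, codon: str) -> str:
        codon = codon.upper()
        if codon not in self.table:
            raise AlphabetError(
                f"codon {codon!r} contains ambiguity or gap symbols; "
                "mask ambiguous sites before codon classification"
            )
        return self.table[codon]

    def translate(self, seq: str) -> str:
        """Translate a nucleotide string codon by codon (trailing partial
        codons are dropped)."""
        n = len(seq) - len(seq) % 3
        return "".join(self.translate_codon(seq[i : i + 3]) for i in range(0, n, 3))

    def is_stop(self, codon: str) -> bool:
        return self.translate_codon(codon) == STOP

    def sense_codons(self) -> list[str]:
        return [c for c in ("".join(p) for p in product(_BASES, repeat=3))
                if self.table[c] != STOP]

    def stop_codons(self) -> list[str]:
        return [c for c, aa in self.table.items() if aa == STOP]

    # -- substitution classification -----------------------------------

    def classify_change(self, codon: str, position: int, alt_base: str) -> str:
        """Classify substituting ``alt_base`` at ``position`` of ``codon``."""
        codon = codon.upper()
        alt_base = alt_base.upper()
        if alt_base not in _BASES:
            raise AlphabetError(f"alternate base must be unambiguous, got {alt_base!r}")
        if codon[position] == alt_base:
            raise ValueError("alternate base equals the reference base")
        alt = codon[:position] + alt_base + codon[position + 1 :]
        return SYNONYMOUS if self.translate_codon(alt) == self.translate_codon(codon) else NONSYNONYMOUS

    def synonymous_alternatives(self, codon: str, position: int) -> list[str]:
        """Bases that can replace ``codon[position]`` without changing the
        encoded residue."""
        codon = codon.upper()
        out = []
        for b in _BASES:
            if b == codon[position]:
                continue
            if self.classify_change(codon, position, b) == SYNONYMOUS:
                out.append(b)
        return out

    def nonsynonymous_alternatives(
        self, codon: str, position: int, exclude_stops: bool = False
    ) -> list[str]:
        codon = codon.upper()
        out = []
        for b in _BASES:
            if b == codon[position]:
                continue
            alt = codon[:position] + b + codon[position + 1 :]
            if self.translate_codon(alt) == self.translate_codon(codon):
                continue
            if exclude_stops and self.is_stop(alt):
                continue
            out.append(b)
        return out


#: NCBI translation table 2 (AGA/AGG stop, TGA=Trp, ATA=Met).
VERTEBRATE_MITO = GeneticCode.from_ncbi_id(2)


def classify_site(codon_ref: str, codon_alt: str, code: GeneticCode = VERTEBRATE_MITO) -> str:
    """Classify a codon replacement: synonymous iff both codons translate
    to the same residue.  Both codons must be unambiguous triplets with at
    least one differing position."""
    codon_ref, codon_alt = codon_ref.upper(), codon_alt.upper()
    if len(codon_ref) != 3 or len(codon_alt) != 3:
        raise ValueError("codons must be triplets")
    if codon_ref == codon_alt:
        raise ValueError("codons are identical; nothing to classify")
    same = code.translate_codon(codon_ref) == code.translate_codon(codon_alt)
    return SYNONYMOUS if same else NONSYNONYMOUS


def classify_substitutions(
    codon_ref: str, codon_alt: str, code: GeneticCode = VERTEBRATE_MITO
) -> list[tuple[int, str]]:
    """Per-position classification of a (possibly multi-base) codon change.

    Each differing position is classified independently by substituting the
    alternate base into the reference codon (reference-context counting);
    mutational paths are deliberately not enumerated.
    """
    codon_ref, codon_alt = codon_ref.upper(), codon_alt.upper()
    if len(codon_ref) != 3 or len(codon_alt) != 3:
        raise ValueError("codons must be triplets")
    out = []
    for pos, (a, b) in enumerate(zip(codon_ref, codon_alt)):
        if a != b:
            out.append((pos, code.classify_change(codon_ref, pos, b)))
    if not out:
        raise ValueError("codons are identical; nothing to classify")
    return out
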