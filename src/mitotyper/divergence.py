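"""Ambiguity-aware percent identity and per-element divergence profiling.

Heterozygous (heteroplasmic) sites carry IUPAC ambiguity symbols; identity
between two symbols is credited as the probability that bases drawn
uniformly from each symbol's base set match, ``|Sa & Sb| / (|Sa| * |Sb|)``.
This makes Y score 0.5 against C or T and 0 against A or G, i.e. a
heterozygous site has more identity with a shared allele than with a
foreign one.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GroupingError, InputError, UndefinedIdentityError
from .mitomodel import CDS, LabeledAlignment, MitogenomeModel
from .mitomodel import iupac
from .mitomodel.model import COMPLEXES

GENOME_SCOPE = "genome"

PAIRING_BETWEEN = "between-mitotypes"
PAIRING_VS_REFERENCE = "vs-reference"


def site_identity(a: str, b: str) -> float:
    """Expected-match identity of two IUPAC symbols, in [0, 1].

    Gaps are a policy decision for the caller and are rejected here.
    """
    sa, sb = iupac.BASE_SETS.get(a.upper()), iupac.BASE_SETS.get(b.upper())
    if sa is None or sb is None:
        raise iupac.AlphabetError(f"not IUPAC symbols: {a!r}, {b!r}")
    if not sa or not sb:
        raise UndefinedIdentityError(
            "site_identity is undefined for gaps; exclude gap columns first"
        )
    return len(sa & sb) / (len(sa) * len(sb))


def pairwise_identity(
    seq_a: str | np.ndarray,
    seq_b: str | np.ndarray,
    columns: np.ndarray | None = None,
) -> float:
    """Percent identity of two aligned sequences over selected columns.

    Columns where either sequence is gapped are excluded from both
    numerator and denominator.
    """
    a = iupac.encode(seq_a) if isinstance(seq_a, str) else seq_a
    b = iupac.encode(seq_b) if isinstance(seq_b, str) else seq_b
    if len(a) != len(b):
        raise InputError("sequences must be equal length")
    if columns is not None:
        a, b = a[columns], b[columns]
    ok = (a != iupac.GAP_CODE) & (b != iupac.GAP_CODE)
    n = int(ok.sum())
    if n == 0:
        raise UndefinedIdentityError("no gap-free columns to compare")
    return 100.0 * float(iupac.MATCH_SCORE[a[ok], b[ok]].sum()) / n


@dataclass
class IdentityProfile:
    """Per-pair percent identity for one scope (element, complex or the
    whole genome)."""

    scope: str
    kind: str  # "element" | "complex" | "genome"
    pairs: list[tuple[str, str]]
    values: np.ndarray
    length: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.pairs):
            raise InputError("one identity value per pair required")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass
class DivergenceSummary:
    """Between-group per-site nucleotide divergence (1 - identity/100)."""

    pairs: list[tuple[str, str]]
    per_pair: np.ndarray
    mean: float = field(init=False)
    minimum: float = field(init=False)
    maximum: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_pair = np.asarray(self.per_pair, dtype=float)
        self.mean = float(np.mean(self.per_pair))
        self.minimum = float(np.min(self.per_pair))
        self.maximum = float(np.max(self.per_pair))


def make_pairs(
    alignment: LabeledAlignment,
    pairing: str = PAIRING_BETWEEN,
    reference_id: str | None = None,
) -> list[tuple[str, str]]:
    """Sample pairs for a profiling run.

    ``between-mitotypes``: all TNP x ENA pairs.  ``vs-reference``: the
    reference sample (default: the first TNP sample) against every ENA
    sample.
    """
    tnp = alignment.samples_by_mitotype("TNP")
    ena = alignment.samples_by_mitotype("ENA")
    if pairing == PAIRING_BETWEEN:
        if not tnp or not ena:
            raise GroupingError("both mitotypes need at least one sample")
        return [(a, b) for a in tnp for b in ena]
    if pairing == PAIRING_VS_REFERENCE:
        if reference_id is None:
            if not tnp:
                raise GroupingError("no TNP sample available as reference")
            reference_id = tnp[0]
        if reference_id not in alignment.ids:
            raise GroupingError(f"reference sample {reference_id!r} not in alignment")
        if not ena:
            raise GroupingError("no ENA samples to compare against the reference")
        return [(reference_id, b) for b in ena]
    raise InputError(f"unknown pairing {pairing!r}")


def _pair_identity_over(alignment, pairs, columns):
    mat = alignment.matrix
    idx = {s: i for i, s in enumerate(alignment.ids)}
    return np.array(
        [pairwise_identity(mat[idx[a]], mat[idx[b]], columns) for a, b in pairs]
    )


def profile_elements(
    alignment: LabeledAlignment,
    model: MitogenomeModel,
    pairing: str = PAIRING_BETWEEN,
    reference_id: str | None = None,
) -> list[IdentityProfile]:
    """Identity profiles for every element, every OXPHOS complex with
    annotated CDSs, and the genome-wide scope (in that order).

    The genome profile's mean is the baseline ("red line") against which
    per-element deviations are judged.
    """
    pairs = make_pairs(alignment, pairing, reference_id)
    profiles = []
    for e in model.elements:
        cols = alignment.positions_of(e.start, e.end)
        profiles.append(
            IdentityProfile(
                scope=e.name,
                kind="element",
                pairs=pairs,
                values=_pair_identity_over(alignment, pairs, cols),
                length=e.length,
            )
        )
    for cx in COMPLEXES:
        members = model.by_complex(cx)
        if not members:
            continue
        cols = np.concatenate(
            [alignment.positions_of(e.start, e.end) for e in members]
        )
        profiles.append(
            IdentityProfile(
                scope=f"complex-{cx}",
                kind="complex",
                pairs=pairs,
                values=_pair_identity_over(alignment, pairs, cols),
                length=sum(e.length for e in members),
            )
        )
    profiles.append(
        IdentityProfile(
            scope=GENOME_SCOPE,
            kind=GENOME_SCOPE,
            pairs=pairs,
            values=_pair_identity_over(alignment, pairs, None),
            length=alignment.length,
        )
    )
    return profiles


def genome_baseline(profiles: list[IdentityProfile]) -> float:
    """Mean genome-wide identity from a profile list."""
    for p in profiles:
        if p.kind == GENOME_SCOPE:
            return p.mean
    raise InputError("no genome-scope profile present")


def divergence_summary(
    alignment: LabeledAlignment,
    pairing: str = PAIRING_BETWEEN,
    reference_id: str | None = None,
) -> DivergenceSummary:
    """Per-site between-group divergence over all compared columns,
    reported as mean plus the min-max range across pairs."""
    pairs = make_pairs(alignment, pairing, reference_id)
    identities = _pair_identity_over(alignment, pairs, None)
    return DivergenceSummary(pairs=pairs, per_pair=1.0 - identities / 100.0)
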