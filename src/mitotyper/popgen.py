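"""Population-genetic statistics on masked alignments.

Implements the conservative ambiguity policy (every column carrying any
ambiguity symbol in any sample is dropped before counting), fixed vs
polymorphic site partitioning per element, McDonald-Kreitman 2x2 tests
with the Neutrality Index, and Tajima's D.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import GroupingError, InputError, StatsError
from .mitomodel import CDS, LabeledAlignment, MitogenomeModel
from .mitomodel import iupac
from .mitomodel.genetic_code import (
    NONSYNONYMOUS,
    SYNONYMOUS,
    GeneticCode,
    VERTEBRATE_MITO,
)

_UNAMBIGUOUS = frozenset("ACGT")

CALL_PURIFYING = "purifying"
CALL_POSITIVE = "positive"
CALL_NEUTRAL = "neutral"
CALL_UNDEFINED = "undefined"

ALPHA = 0.05


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

def mask_ambiguous(
    alignment: LabeledAlignment,
) -> tuple[LabeledAlignment, np.ndarray]:
    """Remove every column containing a non-{A,C,G,T,gap} symbol in any
    sample; returns the masked alignment and the original coordinates of
    the removed columns."""
    mat = alignment.matrix
    ambiguous = (mat >= 4) & (mat != iupac.GAP_CODE)
    bad_cols = ambiguous.any(axis=0)
    removed = alignment.columns[bad_cols].copy()
    if not bad_cols.any():
        return alignment, removed
    return alignment.take_columns(np.nonzero(~bad_cols)[0]), removed


# ---------------------------------------------------------------------------
# Site partitioning
# ---------------------------------------------------------------------------

@dataclass
class MKCounts:
    """Fixed/polymorphic x nonsyn/syn counts for one CDS."""

    d_n: int = 0
    d_s: int = 0
    p_n: int = 0
    p_s: int = 0
    unclassified: int = 0  # variant sites with no usable codon context


@dataclass
class NonCodingCounts:
    """Variable-site categories for one non-coding element (mutually
    exclusive by construction)."""

    fixed: int = 0
    poly_focal: int = 0
    poly_other: int = 0
    poly_shared: int = 0


@dataclass
class SitePartition:
    focal: str
    other: str
    cds: dict[str, MKCounts] = field(default_factory=dict)
    noncoding: dict[str, NonCodingCounts] = field(default_factory=dict)
    masked_columns: np.ndarray = field(default_factory=lambda: np.arange(0))


def _consensus_base(codes: np.ndarray) -> str:
    """Majority unambiguous base (ties broken alphabetically), or 'N'."""
    codes = codes[codes < 4]
    if codes.size == 0:
        return "N"
    counts = np.bincount(codes, minlength=4)
    return "ACGT"[int(np.argmax(counts))]


def _codon_context(consensus: str, element, coord: int) -> tuple[str, int, int] | None:
    """Focal-consensus codon around a genomic coordinate of a CDS.

    Returns (codon on the coding strand, position within codon, coding
    position), or None when the coordinate falls in a trailing incomplete
    codon or the context contains no usable consensus.
    """
    if element.strand == "+":
        p = coord - element.start
    else:
        p = element.end - 1 - coord
    n_full = element.length // 3
    if p // 3 >= n_full:
        return None  # trailing partial codon, completed by polyadenylation
    codon_start = p - p % 3
    if element.strand == "+":
        g0 = element.start + codon_start
        codon = consensus[g0 : g0 + 3]
    else:
        g0 = element.end - codon_start - 3
        codon = iupac.reverse_complement(consensus[g0 : g0 + 3])
    if any(c not in _UNAMBIGUOUS for c in codon):
        return None
    return codon, p % 3, p


def partition_sites(
    alignment: LabeledAlignment,
    model: MitogenomeModel,
    focal_pop: str,
    other_pop: str,
    code: GeneticCode = VERTEBRATE_MITO,
) -> SitePartition:
    """Partition variable sites into fixed/polymorphic categories per
    element.

    Ambiguity masking is applied (idempotently) first; columns with a gap
    in any focal/other sample are excluded.  A site is FIXED when each
    group is internally monomorphic for different bases; polymorphic
    categories follow the group(s) showing within-group variation.  CDS
    variants are classified synonymous/nonsynonymous in the focal-consensus
    codon context, one substituted base at a time; for CDSs only focal
    polymorphisms are tallied.
    """
    masked, removed = mask_ambiguous(alignment)
    focal_ids = masked.select_group(focal_pop)
    other_ids = masked.select_group(other_pop)
    if set(focal_ids) & set(other_ids):
        raise GroupingError("focal and other groups overlap")

    part = SitePartition(focal=focal_pop, other=other_pop, masked_columns=removed)
    for e in model.elements:
        if e.kind == CDS:
            part.cds[e.name] = MKCounts()
        else:
            part.noncoding[e.name] = NonCodingCounts()

    mat = masked.matrix
    idx = {s: i for i, s in enumerate(masked.ids)}
    f_rows = np.array([idx[s] for s in focal_ids])
    o_rows = np.array([idx[s] for s in other_ids])
    fo = np.concatenate([f_rows, o_rows])

    sub = mat[fo]
    has_gap = (sub == iupac.GAP_CODE).any(axis=0)
    variable = (sub != sub[0]).any(axis=0)
    cand = np.nonzero(variable & ~has_gap)[0]

    # focal consensus over the full (original-coordinate) genome, for codon
    # context lookups; positions missing after masking fall back to 'N'.
    genome_len = int(alignment.columns.max()) + 1 if alignment.length else 0
    consensus = ["N"] * genome_len
    f_mat = mat[f_rows]
    for j in range(masked.length):
        consensus[int(masked.columns[j])] = _consensus_base(f_mat[:, j])
    consensus = "".join(consensus)

    elem_by_coord = {}
    for e in model.elements:
        for c in range(e.start, e.end):
            elem_by_coord[c] = e

    for j in cand:
        coord = int(masked.columns[j])
        e = elem_by_coord.get(coord)
        if e is None:
            continue  # intergenic
        f_set = {int(x) for x in mat[f_rows, j]}
        o_set = {int(x) for x in mat[o_rows, j]}
        fixed = len(f_set) == 1 and len(o_set) == 1 and f_set != o_set
        poly_f = len(f_set) > 1
        poly_o = len(o_set) > 1
        assert not (fixed and (poly_f or poly_o))

        if e.kind != CDS:
            nc = part.noncoding[e.name]
            if fixed:
                nc.fixed += 1
            elif poly_f and poly_o:
                nc.poly_shared += 1
            elif poly_f:
                nc.poly_focal += 1
            elif poly_o:
                nc.poly_other += 1
            continue

        counts = part.cds[e.name]
        ctx = _codon_context(consensus, e, coord)
        if fixed:
            if ctx is None:
                counts.unclassified += 1
                continue
            codon, pos, _ = ctx
            alt = iupac.SYMBOLS[next(iter(o_set))]
            if e.strand == "-":
                alt = iupac.COMPLEMENT[alt]
            if codon[pos] == alt:
                counts.unclassified += 1  # consensus disagrees with context
                continue
            if code.classify_change(codon, pos, alt) == SYNONYMOUS:
                counts.d_s += 1
            else:
                counts.d_n += 1
        elif poly_f:
            if ctx is None:
                counts.unclassified += 1
                continue
            codon, pos, _ = ctx
            major = codon[pos]
            for b_code in sorted(f_set):
                b = iupac.SYMBOLS[b_code]
                if e.strand == "-":
                    b = iupac.COMPLEMENT[b]
                if b == major:
                    continue
                if code.classify_change(codon, pos, b) == SYNONYMOUS:
                    counts.p_s += 1
                else:
                    counts.p_n += 1
    return part


# ---------------------------------------------------------------------------
# McDonald-Kreitman
# ---------------------------------------------------------------------------

@dataclass
class MKResult:
    element: str
    d_n: int
    d_s: int
    p_n: int
    p_s: int
    ni: float | None
    chi2_yates: float | None
    p_yates: float | None
    p_fisher: float | None
    call: str
    reason: str | None = None

    @property
    def table(self) -> tuple[int, int, int, int]:
        return (self.d_n, self.d_s, self.p_n, self.p_s)

    @property
    def ni_rounded(self) -> float | None:
        return None if self.ni is None else round(self.ni, 2)


def yates_chi2(d_n: int, d_s: int, p_n: int, p_s: int) -> float:
    """Yates-corrected chi-square for the 2x2 table [[d_n, d_s], [p_n, p_s]]."""
    a, b, c, d = d_n, d_s, p_n, p_s
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise StatsError("a table margin is zero; chi-square undefined")
    num = n * (abs(a * d - b * c) - n / 2) ** 2
    return num / denom


def mk_test(
    partition: SitePartition | MKCounts | tuple[int, int, int, int],
    element: str = "",
) -> MKResult:
    """McDonald-Kreitman test for one element.

    Accepts a :class:`SitePartition` (with ``element`` naming the CDS),
    an :class:`MKCounts`, or a raw ``(D_N, D_S, P_N, P_S)`` tuple.

    NI = (P_N/P_S) / (D_N/D_S), defined only when D_N, D_S and P_S are all
    positive.  Significance uses the Yates-corrected chi-square (1 df) and
    Fisher's exact test; the call is purifying for NI > 1 and positive for
    NI < 1 at alpha = 0.05, neutral otherwise.
    """
    if isinstance(partition, SitePartition):
        if element not in partition.cds:
            raise InputError(f"no CDS counts for element {element!r}")
        c = partition.cds[element]
        d_n, d_s, p_n, p_s = c.d_n, c.d_s, c.p_n, c.p_s
    elif isinstance(partition, MKCounts):
        d_n, d_s, p_n, p_s = partition.d_n, partition.d_s, partition.p_n, partition.p_s
    else:
        d_n, d_s, p_n, p_s = partition

    if min(d_n, d_s, p_n, p_s) < 0:
        raise InputError("MK counts must be nonnegative")

    ni = None
    if d_n > 0 and d_s > 0 and p_s > 0:
        ni = (p_n / p_s) / (d_n / d_s)

    chi2 = p_chi = p_fisher = None
    reason = None
    margins = (d_n + d_s, p_n + p_s, d_n + p_n, d_s + p_s)
    if 0 in margins:
        reason = "a table margin is zero; tests skipped"
    else:
        chi2 = yates_chi2(d_n, d_s, p_n, p_s)
        p_chi = float(stats.chi2.sf(chi2, df=1))
        _, p_fisher = stats.fisher_exact([[d_n, d_s], [p_n, p_s]])
        p_fisher = float(p_fisher)

    if ni is None:
        call = CALL_UNDEFINED
        if reason is None:
            reason = "NI undefined (needs D_N > 0, D_S > 0, P_S > 0)"
    elif reason is not None:
        call = CALL_NEUTRAL
    else:
        significant = min(p_chi, p_fisher) < ALPHA
        if significant and ni > 1:
            call = CALL_PURIFYING
        elif significant and ni < 1:
            call = CALL_POSITIVE
        else:
            call = CALL_NEUTRAL

    return MKResult(
        element=element,
        d_n=d_n, d_s=d_s, p_n=p_n, p_s=p_s,
        ni=ni,
        chi2_yates=chi2,
        p_yates=p_chi,
        p_fisher=p_fisher,
        call=call,
        reason=reason,
    )


def mk_tests(partition: SitePartition, model: MitogenomeModel) -> list[MKResult]:
    """MK tests for every CDS, in genome order."""
    return [
        mk_test(partition, e.name)
        for e in model.elements
        if e.name in partition.cds
    ]


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

@dataclass
class TajimaResult:
    population: str
    n: int
    s: int
    pi: float
    d: float | None
    significant: bool | None = None


def tajima_constants(n: int) -> dict[str, float]:
    """The standard constants of the D normalisation for sample size n."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(alignment: LabeledAlignment, population: str) -> TajimaResult:
    """Tajima's D for one population.

    Ambiguity masking is applied first and columns with gaps in the
    population are skipped.  pi is the mean number of pairwise differences;
    S the number of segregating sites.  D is undefined (None) when S = 0.
    Significance uses the conventional |D| > 2 bounds of the beta
    approximation.
    """
    masked, _ = mask_ambiguous(alignment)
    ids = masked.select_group(population)
    n = len(ids)
    if n < 2:
        raise InputError(f"Tajima's D needs at least 2 sequences, got {n}")
    mat = masked.matrix[[masked.ids.index(s) for s in ids]]
    ok = (mat != iupac.GAP_CODE).all(axis=0)
    mat = mat[:, ok]

    seg = (mat != mat[0]).any(axis=0)
    s = int(seg.sum())

    diffs = 0
    for i in range(n):
        for j in range(i + 1, n):
            diffs += int((mat[i] != mat[j]).sum())
    n_pairs = n * (n - 1) // 2
    pi = diffs / n_pairs

    if s == 0:
        return TajimaResult(population=population, n=n, s=0, pi=pi, d=None)

    k = tajima_constants(n)
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    if var <= 0:  # e.g. n=3 with a single segregating site: c1 = 0
        return TajimaResult(population=population, n=n, s=s, pi=pi, d=None)
    d = (pi - s / k["a1"]) / math.sqrt(var)
    return TajimaResult(
        population=population, n=n, s=s, pi=pi, d=d, significant=abs(d) > 2.0
    )
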