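"""Annotated mitogenome model: stranded elements, OXPHOS complex map and the
default two-mitotype template layout.

Coordinates are 0-based half-open internally.  GFF3 is written 1-based
inclusive and BED 0-based half-open, the standard dialects.

The default template follows the universal vertebrate mitochondrial gene
order (control region excluded) with 13 protein-coding genes, 22 tRNAs and
two rRNAs and 65 bp of intergenic spacer.  Published per-gene lengths are
used where available; the remaining tRNA lengths and the placement of the
intergenic spacer are template choices.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

from ..errors import AnnotationError, CoordinateError, InputError

CDS = "CDS"
TRNA = "tRNA"
RRNA = "rRNA"
CONTROL = "control"
KINDS = (CDS, TRNA, RRNA, CONTROL)

COMPLEXES = ("I", "III", "IV", "V")
NO_COMPLEX = "none"


@dataclass(frozen=True)
class Element:
    """A single annotated mitogenome feature."""

    name: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    complex: str = NO_COMPLEX

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise AnnotationError(f"unknown element kind {self.kind!r}")
        if self.start < 0 or self.start >= self.end:
            raise CoordinateError(
                f"{self.name}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise AnnotationError(f"{self.name}: strand must be '+' or '-'")
        if self.kind == CDS and self.complex not in COMPLEXES:
            raise AnnotationError(
                f"{self.name}: CDS elements must carry an OXPHOS complex"
            )
        if self.kind != CDS and self.complex != NO_COMPLEX:
            raise AnnotationError(f"{self.name}: only CDS elements belong to a complex")

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "Element":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class MitogenomeModel:
    """Ordered, non-overlapping element annotations over a linearised
    (control-region-trimmed) mitogenome."""

    sequence_length: int
    elements: tuple[Element, ...]

    def __post_init__(self) -> None:
        ordered = sorted(self.elements, key=lambda e: e.start)
        object.__setattr__(self, "elements", tuple(ordered))
        prev = None
        for e in self.elements:
            if e.end > self.sequence_length:
                raise CoordinateError(
                    f"{e.name} extends past the sequence end "
                    f"({e.end} > {self.sequence_length})"
                )
            if prev is not None and e.start < prev.end:
                raise AnnotationError(f"{prev.name} and {e.name} overlap")
            prev = e

    @property
    def intergenic_bp(self) -> int:
        return self.sequence_length - sum(e.length for e in self.elements)

    def by_kind(self, kind: str) -> list[Element]:
        return [e for e in self.elements if e.kind == kind]

    def by_complex(self, cx: str) -> list[Element]:
        return [e for e in self.elements if e.complex == cx]

    def get(self, name: str) -> Element:
        for e in self.elements:
            if e.name == name:
                return e
        raise AnnotationError(f"no element named {name!r} in the model")

    def __contains__(self, name: str) -> bool:
        return any(e.name == name for e in self.elements)

    def without_control_region(self) -> "MitogenomeModel":
        """Drop control-region elements and re-base everything downstream."""
        controls = [e for e in self.elements if e.kind == CONTROL]
        if not controls:
            return self
        kept = []
        for e in self.elements:
            if e.kind == CONTROL:
                continue
            offset = sum(c.length for c in controls if c.end <= e.start)
            kept.append(e.shifted(-offset))
        new_len = self.sequence_length - sum(c.length for c in controls)
        return MitogenomeModel(sequence_length=new_len, elements=tuple(kept))


# ---------------------------------------------------------------------------
# Default template
# ---------------------------------------------------------------------------

# (name, kind, length, strand, complex). Lengths for all 13 CDSs, both rRNAs
# and 12 of the tRNAs are the published per-gene lengths; the other ten tRNA
# lengths are standard vertebrate values.
_TEMPLATE_ROWS: list[tuple[str, str, int, str, str]] = [
    ("tRNA-phe", TRNA, 68, "+", NO_COMPLEX),
    ("12S-rRNA", RRNA, 946, "+", NO_COMPLEX),
    ("tRNA-val", TRNA, 72, "+", NO_COMPLEX),
    ("16S-rRNA", RRNA, 1690, "+", NO_COMPLEX),
    ("tRNA-leu-1", TRNA, 75, "+", NO_COMPLEX),
    ("ND1", CDS, 975, "+", "I"),
    ("tRNA-ile", TRNA, 70, "+", NO_COMPLEX),
    ("tRNA-gln", TRNA, 71, "-", NO_COMPLEX),
    ("tRNA-met", TRNA, 69, "+", NO_COMPLEX),
    ("ND2", CDS, 1047, "+", "I"),
    ("tRNA-trp", TRNA, 70, "+", NO_COMPLEX),
    ("tRNA-ala", TRNA, 69, "-", NO_COMPLEX),
    ("tRNA-asn", TRNA, 73, "-", NO_COMPLEX),
    ("tRNA-cys", TRNA, 65, "-", NO_COMPLEX),
    ("tRNA-tyr", TRNA, 70, "-", NO_COMPLEX),
    ("COI", CDS, 1551, "+", "IV"),
    ("tRNA-ser-1", TRNA, 72, "-", NO_COMPLEX),
    ("tRNA-asp", TRNA, 73, "+", NO_COMPLEX),
    ("COII", CDS, 691, "+", "IV"),
    ("tRNA-lys", TRNA, 74, "+", NO_COMPLEX),
    ("ATPase8", CDS, 168, "+", "V"),
    ("ATPase6", CDS, 684, "+", "V"),
    ("COIII", CDS, 786, "+", "IV"),
    ("tRNA-gly", TRNA, 71, "+", NO_COMPLEX),
    ("ND3", CDS, 351, "+", "I"),
    ("tRNA-arg", TRNA, 69, "+", NO_COMPLEX),
    ("ND4L", CDS, 297, "+", "I"),
    ("ND4", CDS, 1381, "+", "I"),
    ("tRNA-his", TRNA, 68, "+", NO_COMPLEX),
    ("tRNA-ser-2", TRNA, 68, "+", NO_COMPLEX),
    ("tRNA-leu-2", TRNA, 74, "+", NO_COMPLEX),
    ("ND5", CDS, 1839, "+", "I"),
    ("ND6", CDS, 522, "-", "I"),
    ("tRNA-glu", TRNA, 69, "-", NO_COMPLEX),
    ("CytB", CDS, 1141, "+", "III"),
    ("tRNA-thr", TRNA, 72, "+", NO_COMPLEX),
    ("tRNA-pro", TRNA, 70, "-", NO_COMPLEX),
]

# Intergenic spacer (bp) inserted BEFORE the named element; totals 65.
_SPACER_BEFORE = {
    "tRNA-trp": 5,
    "tRNA-cys": 30,
    "tRNA-asp": 5,
    "tRNA-gly": 5,
    "ND6": 10,
    "CytB": 10,
}

DEFAULT_CONTROL_REGION_BP = 800


def default_model(include_control_region: bool = False) -> MitogenomeModel:
    """The default 37-element template (13 CDS, 22 tRNA, 2 rRNA, 65 bp
    intergenic).  With ``include_control_region`` a control element is
    appended after tRNA-pro."""
    elements = []
    pos = 0
    for name, kind, length, strand, cx in _TEMPLATE_ROWS:
        pos += _SPACER_BEFORE.get(name, 0)
        elements.append(Element(name, kind, pos, pos + length, strand, cx))
        pos += length
    if include_control_region:
        elements.append(
            Element("control-region", CONTROL, pos, pos + DEFAULT_CONTROL_REGION_BP)
        )
        pos += DEFAULT_CONTROL_REGION_BP
    return MitogenomeModel(sequence_length=pos, elements=tuple(elements))


# ---------------------------------------------------------------------------
# Annotation IO
# ---------------------------------------------------------------------------

_GFF_SEQID = "mitogenome"


def write_gff3(model: MitogenomeModel, path: str | Path) -> Path:
    """Write the model as GFF3 (1-based inclusive coordinates)."""
    path = Path(path)
    lines = ["##gff-version 3",
             f"##sequence-region {_GFF_SEQID} 1 {model.sequence_length}"]
    for e in model.elements:
        attrs = f"ID={e.name}"
        if e.complex != NO_COMPLEX:
            attrs += f";oxphos_complex={e.complex}"
        lines.append(
            "\t".join(
                [_GFF_SEQID, "mitotyper", e.kind, str(e.start + 1), str(e.end),
                 ".", e.strand, ".", attrs]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_gff3(path: str | Path) -> MitogenomeModel:
    path = Path(path)
    elements = []
    seq_len = None
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##sequence-region"):
            seq_len = int(line.split()[-1])
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise InputError(f"{path}: malformed GFF3 line: {raw!r}")
        _, _, kind, start, end, _, strand, _, attrs = fields
        attr_map = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        name = attr_map.get("ID")
        if name is None:
            raise InputError(f"{path}: feature without ID attribute: {raw!r}")
        elements.append(
            Element(
                name=name,
                kind=kind,
                start=int(start) - 1,
                end=int(end),
                strand=strand,
                complex=attr_map.get("oxphos_complex", NO_COMPLEX),
            )
        )
    if not elements:
        raise InputError(f"{path}: no features found")
    if seq_len is None:
        seq_len = max(e.end for e in elements)
    return MitogenomeModel(sequence_length=seq_len, elements=tuple(elements))


def write_bed(model: MitogenomeModel, path: str | Path) -> Path:
    """Write the model as BED6 (0-based half-open).  BED carries less
    metadata than GFF3; use GFF3 for lossless round trips."""
    path = Path(path)
    lines = [
        "\t".join([_GFF_SEQID, str(e.start), str(e.end), e.name, "0", e.strand])
        for e in model.elements
    ]
    path.write_text("\n".join(lines) + "\n")
    return path
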