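"""Labeled alignments: equal-length IUPAC sequences with mitotype and
population labels, plus the column bookkeeping needed after masking."""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..errors import (
    AlignmentError,
    CoordinateError,
    GroupingError,
    LabelingError,
)
from . import iupac
from .model import CONTROL, Element, MitogenomeModel

MITOTYPES = ("TNP", "ENA")


@dataclass
class LabeledAlignment:
    """An alignment with per-sample mitotype/population labels.

    ``columns`` maps current column index -> original genome coordinate, so
    element lookups stay valid after ambiguity masking or trimming.
    """

    ids: list[str]
    seqs: list[str]
    mitotypes: dict[str, str]
    populations: dict[str, str]
    columns: np.ndarray | None = None
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and sequences differ in number")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise AlignmentError(
                f"sequences are not aligned: lengths {sorted(lengths)}"
            )
        self.seqs = [s.upper() for s in self.seqs]
        for sid, seq in zip(self.ids, self.seqs):
            iupac.validate(seq, context=f"sample {sid}")
        for sid in self.ids:
            if sid not in self.mitotypes:
                raise LabelingError(f"sample {sid!r} missing from mitotype labels")
            if self.mitotypes[sid] not in MITOTYPES:
                raise LabelingError(
                    f"sample {sid!r} has mitotype {self.mitotypes[sid]!r}; "
                    f"expected one of {MITOTYPES}"
                )
            if sid not in self.populations:
                raise LabelingError(f"sample {sid!r} missing from population labels")
        if self.columns is None and self.seqs:
            self.columns = np.arange(len(self.seqs[0]))
        elif self.columns is None:
            self.columns = np.arange(0)
        self.columns = np.asarray(self.columns, dtype=np.int64)
        if self.seqs and len(self.columns) != len(self.seqs[0]):
            raise AlignmentError("column map length does not match alignment length")

    # -- basic accessors ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def sequence(self, sample_id: str) -> str:
        try:
            return self.seqs[self.ids.index(sample_id)]
        except ValueError as exc:
            raise LabelingError(f"no sample {sample_id!r} in alignment") from exc

    @property
    def matrix(self) -> np.ndarray:
        """(n_samples, length) int8 matrix of IUPAC symbol codes."""
        if self._matrix is None:
            if self.n_samples:
                self._matrix = np.stack([iupac.encode(s) for s in self.seqs])
            else:
                self._matrix = np.zeros((0, self.length), dtype=np.int8)
        return self._matrix

    def samples_by_mitotype(self, mitotype: str) -> list[str]:
        out = [s for s in self.ids if self.mitotypes[s] == mitotype]
        return out

    def samples_by_population(self, population: str) -> list[str]:
        return [s for s in self.ids if self.populations[s] == population]

    def select_group(self, label: str) -> list[str]:
        """Resolve a group label: a mitotype, then a population name."""
        ids = self.samples_by_mitotype(label) if label in MITOTYPES else []
        if not ids:
            ids = self.samples_by_population(label)
        if not ids:
            raise GroupingError(f"group {label!r} selects no samples")
        return ids

    # -- derived alignments --------------------------------------------

    def subset_samples(self, keep_ids: list[str]) -> "LabeledAlignment":
        missing = [s for s in keep_ids if s not in self.ids]
        if missing:
            raise LabelingError(f"samples not in alignment: {missing}")
        return LabeledAlignment(
            ids=list(keep_ids),
            seqs=[self.sequence(s) for s in keep_ids],
            mitotypes={s: self.mitotypes[s] for s in keep_ids},
            populations={s: self.populations[s] for s in keep_ids},
            columns=self.columns.copy(),
        )

    def take_columns(self, idx: np.ndarray) -> "LabeledAlignment":
        idx = np.asarray(idx, dtype=np.int64)
        return LabeledAlignment(
            ids=list(self.ids),
            seqs=["".join(np.array(list(s))[idx]) if len(idx) else "" for s in self.seqs],
            mitotypes=dict(self.mitotypes),
            populations=dict(self.populations),
            columns=self.columns[idx],
        )

    def positions_of(self, start: int, end: int) -> np.ndarray:
        """Current column indices whose original coordinate lies in
        [start, end)."""
        return np.nonzero((self.columns >= start) & (self.columns < end))[0]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a TSV with columns sample_id, mitotype, population."""
    path = Path(path)
    mitotypes: dict[str, str] = {}
    populations: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "mitotype", "population"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise LabelingError(
                f"{path}: sample sheet must have columns {sorted(required)}"
            )
        for row in reader:
            sid = row["sample_id"].strip()
            mitotypes[sid] = row["mitotype"].strip()
            populations[sid] = row["population"].strip()
    return mitotypes, populations


def write_sample_sheet(alignment: LabeledAlignment, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "mitotype", "population"])
        for sid in alignment.ids:
            writer.writerow([sid, alignment.mitotypes[sid], alignment.populations[sid]])
    return path


def load_alignment(fasta_path: str | Path, sample_sheet_path: str | Path) -> LabeledAlignment:
    """Load an aligned multi-FASTA plus its sample sheet.

    Every FASTA record id must appear in the sheet with a valid mitotype;
    sequences must be equal length over the IUPAC alphabet.
    """
    mitotypes, populations = read_sample_sheet(sample_sheet_path)
    ids, seqs = [], []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in mitotypes:
            raise LabelingError(
                f"FASTA record {rec.id!r} is missing from the sample sheet"
            )
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    return LabeledAlignment(
        ids=ids,
        seqs=seqs,
        mitotypes={s: mitotypes[s] for s in ids},
        populations={s: populations[s] for s in ids},
    )


def write_alignment(alignment: LabeledAlignment, path: str | Path) -> Path:
    path = Path(path)
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(alignment.ids, alignment.seqs)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return path


# ---------------------------------------------------------------------------
# Alignment surgery
# ---------------------------------------------------------------------------

def trim_to_coding(
    alignment: LabeledAlignment, model: MitogenomeModel
) -> tuple[LabeledAlignment, MitogenomeModel]:
    """Drop control-region columns; element coordinates are re-based.

    A model without control-region elements passes through unchanged.
    """
    controls = [e for e in model.elements if e.kind == CONTROL]
    if not controls:
        return alignment, model
    for c in controls:
        if c.end > alignment.length:
            raise CoordinateError(
                f"control region [{c.start}, {c.end}) exceeds alignment "
                f"length {alignment.length}"
            )
    drop = np.zeros(alignment.length, dtype=bool)
    for c in controls:
        idx = alignment.positions_of(c.start, c.end)
        drop[idx] = True
    trimmed = alignment.take_columns(np.nonzero(~drop)[0])
    new_model = model.without_control_region()
    # re-base alignment coordinates to the trimmed model's frame
    offsets = np.zeros(len(trimmed.columns), dtype=np.int64)
    for c in controls:
        offsets[trimmed.columns >= c.end] += c.length
    trimmed.columns = trimmed.columns - offsets
    return trimmed, new_model


def extract_element(alignment: LabeledAlignment, element: Element) -> LabeledAlignment:
    """Sub-alignment of an element's columns, reverse-complemented for
    minus-strand elements so downstream codon work sees the coding strand."""
    top = alignment.columns.max() + 1 if alignment.length else 0
    if element.end > top:
        raise CoordinateError(
            f"{element.name} [{element.start}, {element.end}) is outside the alignment"
        )
    idx = alignment.positions_of(element.start, element.end)
    if len(idx) == 0:
        raise CoordinateError(f"{element.name} selects no alignment columns")
    sub = alignment.take_columns(idx)
    if element.strand == "-":
        sub = LabeledAlignment(
            ids=list(sub.ids),
            seqs=[iupac.reverse_complement(s) for s in sub.seqs],
            mitotypes=dict(sub.mitotypes),
            populations=dict(sub.populations),
            columns=sub.columns[::-1].copy(),
        )
    return sub
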