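"""FASTA input/output and IUPAC-aware base algebra.

All other modules build on the primitives here: normalized DNA records,
gapped alignments with a target/background taxon partition, IUPAC
reverse-complementation and set-intersection base compatibility.

Coordinates are 1-based inclusive everywhere a user sees them; internal
indices are 0-based half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .errors import ParseError, ValidationError

GAP = "-"

#: IUPAC nucleotide codes mapped to the set of unambiguous bases they denote.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

UNAMBIGUOUS = frozenset("ACGT")
ALLOWED_SYMBOLS = frozenset(IUPAC_EXPANSION) | {GAP}

#: IUPAC complement (R<->Y, S<->S, W<->W, K<->M, B<->V, D<->H, N<->N).
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}


def normalize_residues(raw: str, *, record_id: str = "?") -> str:
    """Uppercase, map U->T and '.'->'-', and validate the symbol set.

    Raises :class:`ParseError` naming the record and 1-based position of the
    first illegal symbol.
    """
    seq = raw.upper().replace("U", "T").replace(".", GAP)
    for pos, sym in enumerate(seq, start=1):
        if sym not in ALLOWED_SYMBOLS:
            raise ParseError(
                f"record {record_id!r}: illegal residue symbol {sym!r} at position {pos}"
            )
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """One named DNA sequence (possibly gapped, IUPAC codes permitted)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record has an empty id")
        object.__setattr__(
            self, "residues", normalize_residues(self.residues, record_id=self.id)
        )

    def __len__(self) -> int:
        return len(self.residues)

    def degapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped records in input order."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise ValidationError("alignment has no records")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValidationError(
                f"ragged alignment: record lengths {sorted(lengths)} differ"
            )
        if self.n_columns < 1:
            raise ValidationError("alignment must have at least one column")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate record id(s): {', '.join(dup)}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def get(self, record_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)

    def column(self, column_1based: int) -> str:
        """All symbols of one alignment column, in record order."""
        if not 1 <= column_1based <= self.n_columns:
            raise ValidationError(
                f"column {column_1based} outside [1, {self.n_columns}]"
            )
        i = column_1based - 1
        return "".join(r.residues[i] for r in self.records)


@dataclass(frozen=True)
class TaxonPartition:
    """Disjoint, non-empty target and background record-id sets."""

    target_ids: frozenset[str]
    background_ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_ids", frozenset(self.target_ids))
        object.__setattr__(self, "background_ids", frozenset(self.background_ids))
        if not self.target_ids or not self.background_ids:
            raise ValidationError("both target and background groups must be non-empty")
        overlap = self.target_ids & self.background_ids
        if overlap:
            raise ValidationError(
                f"ids in both target and background groups: {sorted(overlap)}"
            )

    def validate_against(self, aln: Alignment) -> None:
        known = set(aln.ids)
        missing = (self.target_ids | self.background_ids) - known
        if missing:
            raise ValidationError(
                f"partition ids absent from alignment: {sorted(missing)}"
            )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized records, preserving order.

    Raises :class:`ParseError` on an empty file or duplicate ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            desc = rec.description[len(rec.id):].strip() if rec.description else ""
            records.append(SequenceRecord(id=rec.id, residues=str(rec.seq), description=desc))
    if not records:
        raise ParseError(f"{path}: no records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, *, width: int = 60) -> None:
    """Write records as FASTA with fixed-width line wrapping."""
    with open(path, "w") as out:
        for r in records:
            header = f">{r.id} {r.description}".rstrip()
            out.write(header + "\n")
            for i in range(0, len(r.residues), width):
                out.write(r.residues[i : i + width] + "\n")


def fasta_string(records: Iterable[SequenceRecord], *, width: int = 60) -> str:
    buf = io.StringIO()
    for r in records:
        buf.write(f">{r.id} {r.description}".rstrip() + "\n")
        for i in range(0, len(r.residues), width):
            buf.write(r.residues[i : i + width] + "\n")
    return buf.getvalue()


def read_partition(path: str | Path) -> TaxonPartition:
    """Read a two-column TSV ``record_id<TAB>target|background``."""
    target: set[str] = set()
    background: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'id<TAB>group'")
            rec_id, group = parts[0].strip(), parts[1].strip().lower()
            if group == "target":
                target.add(rec_id)
            elif group == "background":
                background.add(rec_id)
            else:
                raise ParseError(
                    f"{path}:{lineno}: group must be 'target' or 'background', got {group!r}"
                )
    return TaxonPartition(target_ids=frozenset(target), background_ids=frozenset(background))


def read_alignment(path: str | Path, partition_path: str | Path) -> tuple[Alignment, TaxonPartition]:
    """Read an aligned FASTA plus its taxon partition and validate both."""
    aln = Alignment(records=tuple(read_fasta(path)))
    part = read_partition(partition_path)
    part.validate_against(aln)
    return aln, part


def write_partition(part: TaxonPartition, path: str | Path) -> None:
    with open(path, "w") as out:
        for rec_id in sorted(part.target_ids):
            out.write(f"{rec_id}\ttarget\n")
        for rec_id in sorted(part.background_ids):
            out.write(f"{rec_id}\tbackground\n")


def reverse_complement(seq: str) -> str:
    """IUPAC-correct reverse complement of a gap-free residue string."""
    if GAP in seq or "." in seq:
        raise ValidationError("cannot reverse-complement a gapped sequence")
    try:
        return "".join(IUPAC_COMPLEMENT[s] for s in reversed(seq.upper().replace("U", "T")))
    except KeyError as exc:
        raise ValidationError(f"not an IUPAC symbol: {exc.args[0]!r}") from exc


def bases_compatible(a: str, b: str) -> bool:
    """True iff the IUPAC expansion sets of ``a`` and ``b`` intersect."""
    try:
        ea, eb = IUPAC_EXPANSION[a.upper()], IUPAC_EXPANSION[b.upper()]
    except KeyError as exc:
        raise ValidationError(f"not an IUPAC symbol: {exc.args[0]!r}") from exc
    return bool(ea & eb)


def expand(symbol: str) -> frozenset[str]:
    """The set of unambiguous bases an IUPAC symbol denotes."""
    try:
        return IUPAC_EXPANSION[symbol.upper()]
    except KeyError as exc:
        raise ValidationError(f"not an IUPAC symbol: {exc.args[0]!r}") from exc
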