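"""Core sequence containers and FASTA readers/writers.

Sequences are plain protein strings over the 20 standard amino acids plus
``X`` (unknown residue); alignments add ``-`` as the only gap symbol
(``.`` on input is normalized to ``-``).  Parsing is done with Biopython's
``SeqIO``; this module layers the validation the pipeline relies on
(unique ids, legal alphabet with error positions, a single species-from-
header rule) on top.

Header convention: the record id is the header text up to the first
whitespace or ``|``, whichever comes first; the species tag is the text
after the first ``|`` (first whitespace-delimited chunk), or ``"unknown"``
when no ``|`` is present.  ``write_fasta`` emits ``>id|species`` so that a
write/read round trip is the identity on (id, species, residues).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: full residue alphabet: the 20 standard amino acids plus unknown
ALPHABET = AMINO_ACIDS + "X"
GAP = "-"

_RESIDUE_SET = frozenset(ALPHABET)
#: canonical Hanks subdomain labels, N- to C-terminal
SUBDOMAIN_IDS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI")


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with an id and a species tag.

    Residues are stored uppercase; every character must be one of the 20
    standard amino acids or ``X``.
    """

    id: str
    residues: str
    species: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be nonempty")
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r}: residues must be nonempty")
        object.__setattr__(self, "residues", self.residues.upper())
        for pos, ch in enumerate(self.residues):
            if ch not in _RESIDUE_SET:
                raise ValidationError(
                    f"sequence {self.id!r}: illegal residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Msa:
    """A multiple sequence alignment with optional Hanks-subdomain annotation.

    ``rows`` is an ordered list of ``(id, aligned_string)``; all aligned
    strings have identical length ``ncol``.  ``subdomain_annotation`` maps a
    subdomain id (``"I"``..``"XI"``) to a half-open column interval
    ``[start, end)``; intervals must be pairwise non-overlapping and ordered
    I..XI.
    """

    rows: list[tuple[str, str]]
    subdomain_annotation: dict[str, tuple[int, int]] | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError("alignment must have at least one row")
        ncol = len(self.rows[0][1])
        norm: list[tuple[str, str]] = []
        seen: set[str] = set()
        for rid, aligned in self.rows:
            aligned = aligned.upper().replace(".", GAP)
            if len(aligned) != ncol:
                raise ValidationError(
                    f"ragged alignment: row {rid!r} has length {len(aligned)}, expected {ncol}"
                )
            if rid in seen:
                raise ValidationError(f"duplicate row id {rid!r} in alignment")
            seen.add(rid)
            for pos, ch in enumerate(aligned):
                if ch not in _RESIDUE_SET and ch != GAP:
                    raise ValidationError(
                        f"row {rid!r}: illegal character {ch!r} at column {pos}"
                    )
            norm.append((rid, aligned))
        self.rows = norm
        if self.subdomain_annotation is not None:
            self._check_annotation(ncol)

    def _check_annotation(self, ncol: int) -> None:
        ann = self.subdomain_annotation
        assert ann is not None
        prev_end = 0
        for sd in [s for s in SUBDOMAIN_IDS if s in ann]:
            start, end = ann[sd]
            if not (0 <= start <= end <= ncol):
                raise ValidationError(f"subdomain {sd}: interval ({start},{end}) outside [0,{ncol})")
            if start < prev_end:
                raise ValidationError(f"subdomain {sd}: intervals overlap or out of order")
            prev_end = end
        unknown = set(ann) - set(SUBDOMAIN_IDS)
        if unknown:
            raise ValidationError(f"unknown subdomain ids: {sorted(unknown)}")

    @property
    def ncol(self) -> int:
        return len(self.rows[0][1])

    @property
    def nrow(self) -> int:
        return len(self.rows)

    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def column(self, c: int) -> str:
        return "".join(aligned[c] for _, aligned in self.rows)

    def degapped(self, species: str = "unknown") -> list[ProteinSequence]:
        """Rows as plain sequences with gaps removed."""
        return [
            ProteinSequence(rid, aligned.replace(GAP, ""), species)
            for rid, aligned in self.rows
        ]


def _split_header(description: str) -> tuple[str, str]:
    head = description.split(None, 1)[0] if description.split() else ""
    if "|" in head:
        seq_id, _, species = head.partition("|")
    else:
        seq_id, species = head, "unknown"
    return seq_id, (species or "unknown")


def read_fasta(path: str | Path, species_from_header: bool = True) -> list[ProteinSequence]:
    """Read a plain (unaligned) protein FASTA file.

    One :class:`ProteinSequence` per entry, in file order.  Raises
    :class:`ValidationError` on duplicate ids or illegal residues and
    ``FileNotFoundError`` for a missing file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id, species = _split_header(rec.description)
        if not species_from_header:
            species = "unknown"
        if not seq_id:
            raise ParseError(f"{path}: empty FASTA header")
        if seq_id in seen:
            raise ValidationError(f"{path}: duplicate sequence id {seq_id!r}")
        seen.add(seq_id)
        out.append(ProteinSequence(seq_id, str(rec.seq), species))
    return out


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA, encoding the species tag as ``>id|species``."""
    records = []
    for s in sequences:
        header = s.id if s.species == "unknown" else f"{s.id}|{s.species}"
        records.append(SeqRecord(Seq(s.residues), id=header, description=""))
    handle = io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
    writer.write_file(records)
    Path(path).write_text(handle.getvalue())


def read_aligned_fasta(
    path: str | Path,
    subdomain_annotation: dict[str, tuple[int, int]] | None = None,
) -> Msa:
    """Read an aligned FASTA file into an :class:`Msa`.

    All rows must share a common length; ``.`` gaps are normalized to ``-``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id, _ = _split_header(rec.description)
        rows.append((seq_id, str(rec.seq)))
    if not rows:
        raise ValidationError(f"{path}: empty alignment file")
    return Msa(rows, subdomain_annotation=subdomain_annotation)


def write_aligned_fasta(msa: Msa, path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(aligned), id=rid, description="") for rid, aligned in msa.rows]
    handle = io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
    writer.write_file(records)
    Path(path).write_text(handle.getvalue())


def read_subdomain_table(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read a subdomain annotation TSV with columns subdomain, start, end.

    Coordinates are 0-based half-open column intervals on an alignment.
    """
    ann: dict[str, tuple[int, int]] = {}
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines):
        if not line.strip() or line.startswith("#") or (i == 0 and line.lower().startswith("subdomain")):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(f"{path}: line {i + 1}: expected 3 tab-separated fields")
        sd, start, end = parts
        if sd in ann:
            raise ValidationError(f"{path}: duplicate subdomain {sd!r}")
        ann[sd] = (int(start), int(end))
    return ann


def write_subdomain_table(ann: dict[str, tuple[int, int]], path: str | Path) -> None:
    lines = ["subdomain\tstart\tend"]
    for sd in SUBDOMAIN_IDS:
        if sd in ann:
            s, e = ann[sd]
            lines.append(f"{sd}\t{s}\t{e}")
    Path(path).write_text("\n".join(lines) + "\n")


def sequences_to_msa(sequences: Sequence[ProteinSequence]) -> Msa:
    """Treat equal-length ungapped sequences as a trivially aligned Msa."""
    return Msa([(s.id, s.residues) for s in sequences])
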