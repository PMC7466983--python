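"""Sequence and interval I/O: FASTA, BED6 and region strings.

Coordinates are 0-based, half-open throughout; the span of an interval is
``end - start``.  DNA is stored uppercase over the alphabet {A,C,G,T,N}.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaFormatError(ValueError):
    """Raised when a FASTA file or a DNA string violates the expected format."""


@dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence, normalized to uppercase {A,C,G,T,N}."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or re.search(r"\s", self.id):
            raise ValueError(f"record id must be non-empty without whitespace: {self.id!r}")
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) < 1:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise FastaFormatError(
                f"record {self.id!r}: invalid residue {self.residues[pos]!r} at position {pos + 1}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be non-negative, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of +, -, . : {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start


def reverse_complement(s: str) -> str:
    """Watson-Crick reverse complement; N maps to N. Case-insensitive input."""
    s = s.upper()
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ValueError(f"invalid residue(s) for reverse complement: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a (multi-)FASTA file into normalized records, preserving order.

    Gap characters ``-`` are stripped with a logged warning (curated
    alignments are sometimes pasted in).  Any other residue outside
    {A,C,G,T,N} raises :class:`FastaFormatError` naming the record and the
    1-based offending position.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if "-" in raw:
            logger.warning(
                "record %r: stripping %d gap character(s) from input", rec.id, raw.count("-")
            )
            raw = raw.replace("-", "")
        description = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SeqRecord(id=rec.id, residues=raw, description=description))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


_REGION_RE = re.compile(r"^\s*(?P<chrom>[^\s:]+)\s*:\s*(?P<start>[\d,]+)\s*-\s*(?P<end>[\d,]+)\s*$")


def parse_region(text: str) -> GenomicInterval:
    """Parse a region string like ``"chr3L: 6,821,518-6,823,267"``.

    Thousands separators (commas) and internal whitespace are tolerated.
    The resulting span is ``end - start``.
    """
    m = _REGION_RE.match(text)
    if m is None:
        raise ValueError(f"malformed region string: {text!r}")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    if end <= start:
        raise ValueError(f"region end ({end}) must exceed start ({start}): {text!r}")
    return GenomicInterval(chrom=m.group("chrom"), start=start, end=end)


def write_bed6(
    rows: Sequence[tuple[GenomicInterval, str, int]], path: str | Path
) -> None:
    """Write (interval, name, score) rows as BED6."""
    with open(path, "w") as fh:
        for iv, name, score in rows:
            strand = iv.strand if iv.strand != "." else "+"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{strand}\n")


def read_bed6(path: str | Path) -> list[tuple[GenomicInterval, str, int]]:
    """Read BED6 back into (interval, name, score) rows."""
    rows: list[tuple[GenomicInterval, str, int]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{line_no}: expected 6 BED columns, got {len(fields)}")
            chrom, start, end, name, score, strand = fields[:6]
            rows.append(
                (GenomicInterval(chrom, int(start), int(end), strand), name, int(score))
            )
    return rows
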