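"""Genome input and coordinate conventions.

Genomes are plain multi-record FASTA files read into memory as uppercase
strings over the alphabet A/C/G/T/N.  All coordinates inside the package are
0-based half-open (BED convention); the CLI converts from 1-based inclusive
``chrom:start-end`` strings as printed by genome browsers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator

from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "Region",
    "FastaFormatError",
    "read_fasta",
    "extract_region",
    "reverse_complement",
    "normalize_sequence",
    "parse_region",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# every IUPAC code outside the working alphabet collapses to N
_NON_ACGTN = re.compile(r"[^ACGTN]")


class FastaFormatError(ValueError):
    """Raised for empty FASTA input or duplicate record names."""


def normalize_sequence(seq: str) -> str:
    """Uppercase ``seq`` and map any character outside A/C/G/T/N to N.

    Soft-masked (lowercase) bases are treated as normal sequence; IUPAC
    ambiguity codes other than N carry no information the site scanner can
    use, so they are collapsed to N (which never matches a spacer or PAM
    position).
    """
    return _NON_ACGTN.sub("N", seq.upper())


@dataclass(frozen=True)
class Region:
    """A half-open genomic interval ``[start, end)`` on one contig."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and start < self.end and end > self.start


class GenomeSequence:
    """Named contigs with normalized uppercase DNA.

    A thin ordered mapping from contig name to sequence string; iteration
    order is the order records appeared in the source FASTA so downstream
    scans are deterministic.
    """

    def __init__(self, records: dict[str, str]):
        if not records:
            raise FastaFormatError("genome contains no records")
        self.records: dict[str, str] = {}
        for name, seq in records.items():
            seq = normalize_sequence(seq)
            if not seq:
                raise FastaFormatError(f"record {name!r} has an empty sequence")
            self.records[name] = seq

    def __getitem__(self, chrom: str) -> str:
        return self.records[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.records

    def __iter__(self) -> Iterator[str]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def items(self):
        return self.records.items()

    def length_of(self, chrom: str) -> int:
        return len(self.records[chrom])


def read_fasta(path) -> GenomeSequence:
    """Read a multi-record FASTA file into a :class:`GenomeSequence`.

    Wrapped and unwrapped line layouts are both accepted.  Raises
    :class:`FastaFormatError` on an empty file or a duplicate record name.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FastaFormatError(f"duplicate record name {rec.id!r}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return GenomeSequence(records)


def extract_region(genome: GenomeSequence, region: Region) -> str:
    """Return the ``end - start`` bases of ``region`` from ``genome``."""
    if region.chrom not in genome:
        raise KeyError(f"unknown contig {region.chrom!r}")
    seq = genome[region.chrom]
    if region.end > len(seq):
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} exceeds contig "
            f"length {len(seq)}"
        )
    return seq[region.start : region.end]


def reverse_complement(seq: str) -> str:
    """Reverse complement over A/C/G/T/N (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def parse_region(text: str, one_based: bool = True) -> Region:
    """Parse ``chrom:start-end`` (commas allowed in numbers) into a Region.

    With ``one_based=True`` (the CLI default) the input is interpreted as
    1-based inclusive, the convention genome browsers print, and converted
    to the internal 0-based half-open form.
    """
    m = re.fullmatch(r"(.+):([\d,]+)-([\d,]+)", text.strip())
    if not m:
        raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end")
    chrom = m.group(1)
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    if one_based:
        start -= 1
    return Region(chrom, start, end)
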