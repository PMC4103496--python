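"""Genome sequence and repeat-annotation I/O.

Reads multi-contig FASTA into an in-memory genome store, extracts
variant-centred flank queries (the variant base plus up to ``flank``
reference bases on each side), and answers repeat-interval membership
queries against BED or UCSC ``nestedRepeats`` annotations.

All internal coordinates are 0-based half-open; 1-based positions (VCF
convention) are converted at the API boundary and are always named
``pos`` with a docstring note.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Union

from Bio import SeqIO
from intervaltree import IntervalTree

__all__ = [
    "GenomeSequence",
    "Interval",
    "FlankQuery",
    "RepeatIndex",
    "load_fasta",
    "extract_flank",
    "load_repeat_bed",
    "convert_nested_repeats",
    "merge_intervals",
    "in_repeat",
]

_VALID_SEQ = re.compile(r"[ACGTN]*\Z")

DEFAULT_FLANK = 100


class GenomeIOError(ValueError):
    """Raised for malformed FASTA/BED/nestedRepeats input."""


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"invalid interval {self.contig}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomeSequence:
    """Contig-name -> uppercase nucleotide sequence store.

    Sequences are validated to the {A,C,G,T,N} alphabet on construction.
    """

    contigs: Dict[str, str]
    lengths: Dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise GenomeIOError("no records: genome has no contigs")
        clean: Dict[str, str] = {}
        for name, seq in self.contigs.items():
            seq = seq.upper()
            if not seq:
                raise GenomeIOError(f"contig {name!r} has empty sequence")
            if not _VALID_SEQ.match(seq):
                bad = sorted(set(seq) - set("ACGTN"))
                raise GenomeIOError(
                    f"contig {name!r} contains non-ACGTN characters: {bad}"
                )
            clean[name] = seq
        self.contigs = clean
        self.lengths = {name: len(seq) for name, seq in clean.items()}

    def sequence(self, contig: str) -> str:
        try:
            return self.contigs[contig]
        except KeyError:
            raise GenomeIOError(f"unknown contig {contig!r}") from None

    def base(self, contig: str, pos: int) -> str:
        """Reference base at 1-based position ``pos``."""
        seq = self.sequence(contig)
        if not 1 <= pos <= len(seq):
            raise GenomeIOError(
                f"position {pos} out of range for contig {contig!r} "
                f"(length {len(seq)})"
            )
        return seq[pos - 1]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs


@dataclass(frozen=True)
class FlankQuery:
    """The variant base plus up to ``flank`` bases of reference context per side.

    ``variant_offset`` is the 0-based index of the variant base within
    ``sequence``; the nominal full query is ``2*flank + 1`` bases (201 by
    default) and is shorter only when the variant sits within ``flank``
    bases of a contig end (recorded in the truncation flags).
    """

    source_contig: str
    source_pos: int  # 1-based
    sequence: str
    variant_offset: int
    left_truncated: bool
    right_truncated: bool


def _open_text(path: Union[str, Path]) -> io.TextIOBase:
    """Open plain or gzip-compressed text transparently."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def load_fasta(path: Union[str, Path]) -> GenomeSequence:
    """Read a (possibly gzipped) multi-record FASTA into a :class:`GenomeSequence`.

    Contig names are the first whitespace-delimited token of each header.
    Sequences are case-folded to uppercase. Duplicate contig names and
    empty files are errors.
    """
    path = Path(path)
    if not path.exists():
        raise GenomeIOError(f"no such file: {path}")
    with _open_text(path) as handle:
        # SeqIO silently skips junk before the first '>'; reject it explicitly.
        head = handle.readline()
        while head and not head.strip():
            head = handle.readline()
        if not head:
            raise GenomeIOError(f"no records in FASTA {path}")
        if not head.startswith(">"):
            raise GenomeIOError(
                f"malformed FASTA {path}: line 1 does not start with '>'"
            )
        handle.seek(0)
        contigs: Dict[str, str] = {}
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in contigs:
                raise GenomeIOError(f"duplicate contig name {rec.id!r} in {path}")
            contigs[rec.id] = str(rec.seq)
    if not contigs:
        raise GenomeIOError(f"no records in FASTA {path}")
    return GenomeSequence(contigs)


def extract_flank(
    genome: GenomeSequence,
    contig: str,
    pos: int,
    flank: int = DEFAULT_FLANK,
) -> FlankQuery:
    """Extract the flank query centred on 1-based position ``pos``.

    Near contig ends the window is truncated to the available sequence
    (never padded); the affected side is flagged so downstream coverage
    tests can keep the fixed nominal denominator.
    """
    seq = genome.sequence(contig)
    length = len(seq)
    if not 1 <= pos <= length:
        raise GenomeIOError(
            f"position {pos} out of range for contig {contig!r} (length {length})"
        )
    start = max(0, pos - 1 - flank)
    end = min(length, pos + flank)
    return FlankQuery(
        source_contig=contig,
        source_pos=pos,
        sequence=seq[start:end],
        variant_offset=pos - 1 - start,
        left_truncated=pos - 1 < flank,
        right_truncated=length - pos < flank,
    )


def _sorted_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    return sorted(intervals, key=lambda iv: (iv.contig, iv.start, iv.end))


def load_repeat_bed(path: Union[str, Path]) -> List[Interval]:
    """Read a BED3+ file (0-based half-open) of repeat intervals, sorted.

    Overlapping intervals are permitted; see :func:`merge_intervals` for a
    merged view. ``start >= end`` is rejected with the offending line number.
    """
    out: List[Interval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GenomeIOError(
                    f"{path}: line {lineno}: expected >=3 tab-separated BED fields"
                )
            contig, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GenomeIOError(
                    f"{path}: line {lineno}: non-integer BED coordinates"
                ) from None
            if start >= end or start < 0:
                raise GenomeIOError(
                    f"{path}: line {lineno}: invalid interval start={start} end={end}"
                )
            out.append(Interval(contig, start, end))
    return _sorted_intervals(out)


def convert_nested_repeats(path: Union[str, Path]) -> List[Interval]:
    """Read a UCSC ``nestedRepeats`` table dump into sorted intervals.

    The table is tab-separated with a leading ``bin`` column; columns 2-4
    (1-based) are chrom, chromStart, chromEnd in 0-based half-open
    convention. Gzip-compressed input is accepted transparently.
    """
    out: List[Interval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise GenomeIOError(
                    f"{path}: line {lineno}: expected >=4 nestedRepeats columns"
                )
            contig = fields[1]
            try:
                start, end = int(fields[2]), int(fields[3])
            except ValueError:
                raise GenomeIOError(
                    f"{path}: line {lineno}: non-integer chromStart/chromEnd"
                ) from None
            if start >= end or start < 0:
                raise GenomeIOError(
                    f"{path}: line {lineno}: invalid interval start={start} end={end}"
                )
            out.append(Interval(contig, start, end))
    return _sorted_intervals(out)


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Merge overlapping/adjacent intervals per contig; result is sorted."""
    merged: List[Interval] = []
    for iv in _sorted_intervals(intervals):
        if merged and merged[-1].contig == iv.contig and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = Interval(iv.contig, merged[-1].start, iv.end)
        else:
            merged.append(Interval(iv.contig, iv.start, iv.end))
    return merged


class RepeatIndex:
    """Interval-tree index over repeat intervals for point membership tests."""

    def __init__(self, intervals: Iterable[Interval]):
        self._trees: Dict[str, IntervalTree] = {}
        for iv in intervals:
            self._trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end)

    def contains(self, contig: str, pos: int) -> bool:
        """True iff 1-based ``pos`` falls inside an interval on ``contig``."""
        tree = self._trees.get(contig)
        if tree is None:
            return False
        return bool(tree.at(pos - 1))


def in_repeat(
    intervals: Union[Sequence[Interval], RepeatIndex], contig: str, pos: int
) -> bool:
    """True iff 1-based ``pos`` lies inside a repeat interval on ``contig``.

    Accepts either a plain interval list (indexed on the fly) or a
    prebuilt :class:`RepeatIndex` for repeated queries.
    """
    if isinstance(intervals, RepeatIndex):
        return intervals.contains(contig, pos)
    return RepeatIndex(intervals).contains(contig, pos)
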