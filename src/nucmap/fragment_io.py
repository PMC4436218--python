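"""Readers and writers for regions, fragments, motifs, sequences and tracks.

Coordinate conventions
----------------------
Region tables on disk are 1-based inclusive (the convention of the BAC
region tables this package consumes); everything in memory is 0-based
half-open. Conversion happens only here, at the I/O boundary. Fragment
intervals (BED3) are already 0-based half-open on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO, motifs as bio_motifs

from .errors import FormatError, ParseError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_FRAGMENT_LENGTH_CAP = 500

BASE_ORDER = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}


@dataclass(frozen=True)
class GenomicRegion:
    """A named genomic interval, stored 0-based half-open."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise ValidationError(f"region {self.name}: negative start {self.start}")
        if self.start >= self.end:
            raise ValidationError(
                f"region {self.name}: empty or inverted interval "
                f"[{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_1based_inclusive(cls, name: str, chrom: str, start: int, end: int) -> "GenomicRegion":
        """Build from 1-based inclusive coordinates (table convention)."""
        if start >= end:
            raise ValidationError(
                f"region {name}: 1-based inclusive interval requires start < end, "
                f"got [{start}, {end}]"
            )
        return cls(name=name, chrom=chrom, start=start - 1, end=end)

    def to_1based_inclusive(self) -> tuple[int, int]:
        return self.start + 1, self.end


@dataclass(frozen=True)
class FragmentRecord:
    """One uniquely mapped mononucleosome fragment, 0-based half-open."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MotifMatrix:
    """A position-frequency matrix, rows ordered A, C, G, T."""

    counts: np.ndarray  # shape (4, width), nonnegative
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )  # base frequencies, sum 1

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValidationError("motif counts must be a 4 x width matrix")
        if counts.shape[1] < 1:
            raise ValidationError("motif width must be >= 1")
        if (counts < 0).any():
            raise ValidationError("motif counts must be nonnegative")
        if not (counts.sum(axis=0) > 0).all():
            raise ValidationError("every motif position needs at least one positive count")
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or (bg <= 0).any():
            raise ValidationError("background must be 4 positive frequencies summing to 1")

    @property
    def width(self) -> int:
        return int(self.counts.shape[1])

    def consensus(self) -> str:
        return "".join(BASE_ORDER[i] for i in self.counts.argmax(axis=0))


def read_regions(path) -> list[GenomicRegion]:
    """Read a tab-separated region table (name, chrom, start, end; 1-based inclusive).

    A header line is allowed and detected by a non-integer start field.
    Reported lengths equal the 1-based inclusive span (end - start + 1).
    """
    regions: list[GenomicRegion] = []
    first_content_line = True
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            is_first, first_content_line = first_content_line, False
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"expected >= 4 tab-separated fields, got {len(fields)}",
                    path=path, line_number=lineno,
                )
            name, chrom, start_s, end_s = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                if is_first:
                    continue  # header line
                raise ParseError(
                    f"non-integer coordinates {start_s!r}, {end_s!r}",
                    path=path, line_number=lineno,
                )
            regions.append(GenomicRegion.from_1based_inclusive(name, chrom, start, end))
    return regions


def write_regions(regions: Iterable[GenomicRegion], path) -> None:
    """Write a region table in the 1-based inclusive convention, with header."""
    with open(path, "w") as fh:
        fh.write("name\tchrom\tstart\tend\tlength\n")
        for r in regions:
            s1, e1 = r.to_1based_inclusive()
            fh.write(f"{r.name}\t{r.chrom}\t{s1}\t{e1}\t{r.length}\n")


class FragmentReader:
    """Iterate FragmentRecords from a BED3 file, counting rejects and skips.

    Attributes ``n_parsed``, ``n_rejected`` and ``n_skipped`` are updated as
    the stream is consumed; parsed + rejected + skipped equals the number of
    non-comment, non-blank input lines.
    """

    def __init__(self, path, max_length: int = DEFAULT_FRAGMENT_LENGTH_CAP,
                 chroms: set[str] | None = None):
        self.path = Path(path)
        self.max_length = max_length
        self.chroms = chroms
        self.n_parsed = 0
        self.n_rejected = 0
        self.n_skipped = 0

    def __iter__(self) -> Iterator[FragmentRecord]:
        with open(self.path) as fh:
            for raw in fh:
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    fields = line.split()
                if len(fields) < 3:
                    self.n_rejected += 1
                    continue
                chrom = fields[0]
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError:
                    self.n_rejected += 1
                    continue
                if start < 0 or end <= start or end - start > self.max_length:
                    self.n_rejected += 1
                    continue
                if self.chroms is not None and chrom not in self.chroms:
                    self.n_skipped += 1
                    continue
                self.n_parsed += 1
                yield FragmentRecord(chrom=chrom, start=start, end=end)


def read_fragments(path, max_length: int = DEFAULT_FRAGMENT_LENGTH_CAP,
                   chroms: set[str] | None = None) -> FragmentReader:
    """Open a BED3 fragment file for streaming (see FragmentReader)."""
    return FragmentReader(path, max_length=max_length, chroms=chroms)


def write_fragments(fragments: Iterable[FragmentRecord], path) -> int:
    n = 0
    with open(path, "w") as fh:
        for frag in fragments:
            fh.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\n")
            n += 1
    return n


def read_motif(path, background=None) -> MotifMatrix:
    """Read a position-frequency matrix in JASPAR or raw 4-row PFM text."""
    path = Path(path)
    text = path.read_text()
    fmt = "jaspar" if text.lstrip().startswith(">") else "pfm"
    try:
        with open(path) as fh:
            motif = bio_motifs.read(fh, fmt)
    except Exception as exc:  # biopython raises bare ValueError/Exception
        raise FormatError(f"{path}: cannot parse {fmt} motif: {exc}") from exc
    counts = np.array([motif.counts[b] for b in BASE_ORDER], dtype=float)
    kwargs = {} if background is None else {"background": np.asarray(background, float)}
    return MotifMatrix(counts=counts, **kwargs)


def write_motif(motif: MotifMatrix, path, name: str = "motif") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i, base in enumerate(BASE_ORDER):
            row = " ".join(f"{v:g}" for v in motif.counts[i])
            fh.write(f"{base} [ {row} ]\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {record id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def write_track(track, path) -> None:
    """Write an occupancy track as bedGraph, one line per run of equal value."""
    with open(path, "w") as fh:
        for region in track.regions:
            values = track.values[region.name]
            if values.size == 0:
                continue
            # run-length encode
            change = np.flatnonzero(np.diff(values) != 0)
            starts = np.concatenate(([0], change + 1))
            ends = np.concatenate((change + 1, [values.size]))
            for s, e in zip(starts, ends):
                fh.write(
                    f"{region.chrom}\t{region.start + s}\t{region.start + e}"
                    f"\t{values[s]:.8g}\n"
                )


def read_track(path, regions: list[GenomicRegion], stage: str = "raw",
               dataset_label: str = ""):
    """Read a bedGraph file back into an OccupancyTrack over known regions.

    Intervals outside every region are ignored; uncovered positions are 0.
    """
    from .occupancy import OccupancyTrack  # local import: avoid cycle

    values = {r.name: np.zeros(r.length) for r in regions}
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError("expected 4 bedGraph fields", path=path,
                                 line_number=lineno)
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            for r in by_chrom.get(chrom, ()):
                lo, hi = max(start, r.start), min(end, r.end)
                if lo < hi:
                    values[r.name][lo - r.start:hi - r.start] = value
    return OccupancyTrack(regions=list(regions), values=values, stage=stage,
                          dataset_label=dataset_label)
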