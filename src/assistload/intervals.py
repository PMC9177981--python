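"""Genomic interval algebra and BED-dialect I/O.

Coordinates are 0-based, half-open throughout: an interval [start, end)
covers ``end - start`` bases and two intervals that merely abut
(``a.end == b.start``) do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Malformed BED/narrowPeak record; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class GenomicInterval:
    """A region on a chromosome, 0-based half-open, optionally stranded.

    ``extra`` holds any BED columns beyond the canonical six (e.g. the
    narrowPeak signal/p/q/summit columns), preserved opaquely as strings.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0
    extra: tuple = ()

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return self.start + self.length // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class MergedInterval:
    """Span produced by :func:`merge_sites`; remembers contributing sets."""

    chrom: str
    start: int
    end: int
    sources: frozenset = field(default_factory=frozenset)

    def to_interval(self, name: str = "") -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=name)

    @property
    def center(self) -> int:
        return self.start + (self.end - self.start) // 2


def read_bed(path) -> list[GenomicInterval]:
    """Read a 3-6 column BED (or 10-column narrowPeak) file.

    Columns beyond the sixth are preserved verbatim in ``extra``.
    Raises :class:`BedParseError` with the offending line number on
    malformed records.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError("fewer than 3 columns", lineno)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"non-integer coordinate: {exc}", lineno)
            name = fields[3] if len(fields) > 3 else ""
            score = 0.0
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise BedParseError(f"bad score {fields[4]!r}", lineno)
            strand = fields[5] if len(fields) > 5 else "."
            extra = tuple(fields[6:])
            try:
                out.append(
                    GenomicInterval(chrom, start, end, strand, name, score, extra)
                )
            except ValueError as exc:
                raise BedParseError(str(exc), lineno)
    return out


def write_bed(intervals, path) -> None:
    """Write intervals as 6+ column BED (extra columns appended)."""
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [
                iv.chrom,
                str(iv.start),
                str(iv.end),
                iv.name,
                format(iv.score, "g"),
                iv.strand,
                *iv.extra,
            ]
            fh.write("\t".join(cols) + "\n")


def merge_sites(*interval_sets, labels=None) -> list[MergedInterval]:
    """Collapse the union of one or more interval sets.

    Any two intervals overlapping by >= 1 bp are merged into their span;
    abutting half-open intervals are kept separate.  Each merged record
    retains the labels of the input sets that contributed to it.
    """
    if not interval_sets:
        raise ValueError("merge_sites requires at least one interval set")
    if labels is None:
        labels = list(range(len(interval_sets)))
    if len(labels) != len(interval_sets):
        raise ValueError("labels must match the number of interval sets")
    tagged = []
    for label, ivs in zip(labels, interval_sets):
        for iv in ivs:
            tagged.append((iv.chrom, iv.start, iv.end, label))
    tagged.sort(key=lambda t: (t[0], t[1], t[2]))
    merged: list[MergedInterval] = []
    cur = None  # [chrom, start, end, set(labels)]
    for chrom, start, end, label in tagged:
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].add(label)
        else:
            if cur is not None:
                merged.append(
                    MergedInterval(cur[0], cur[1], cur[2], frozenset(cur[3]))
                )
            cur = [chrom, start, end, {label}]
    if cur is not None:
        merged.append(MergedInterval(cur[0], cur[1], cur[2], frozenset(cur[3])))
    return merged


def nearest_distance(query, reference):
    """Signed center-to-center distance from each query to its nearest reference.

    Returns a list of ``(distance, reference_index)`` pairs where
    ``distance = reference_center - query_center``.  Ties are broken in
    favour of the reference with the smaller coordinate.  Queries on a
    chromosome absent from the reference get ``(None, None)``.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for idx, iv in enumerate(reference):
        by_chrom.setdefault(iv.chrom, []).append((iv.center, idx))
    arrays = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        arrays[chrom] = (
            np.array([p[0] for p in pairs]),
            np.array([p[1] for p in pairs]),
        )
    out = []
    for iv in query:
        if iv.chrom not in arrays:
            out.append((None, None))
            continue
        centers, idxs = arrays[iv.chrom]
        c = iv.center
        j = int(np.searchsorted(centers, c))
        best = None  # (abs_dist, center, ref_idx)
        for k in (j - 1, j):
            if 0 <= k < len(centers):
                cand = (abs(int(centers[k]) - c), int(centers[k]), int(idxs[k]))
                if best is None or cand[:2] < best[:2]:
                    best = cand
        out.append((best[1] - c, best[2]))
    return out
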