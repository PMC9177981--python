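"""Per-base tag coverage tracks: bedGraph I/O, window quantification, metaplots."""

from __future__ import annotations

import warnings

import numpy as np

from .intervals import GenomicInterval


class CoverageTrack:
    """Tag counts per base, one array per chromosome."""

    def __init__(self, data: dict[str, np.ndarray]):
        self.data = {}
        for chrom, arr in data.items():
            arr = np.asarray(arr)
            if np.any(arr < 0):
                raise ValueError(f"negative coverage on {chrom}")
            self.data[chrom] = arr
        self._cumsums: dict[str, np.ndarray] = {}

    @property
    def total_tags(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def chrom_length(self, chrom: str) -> int:
        return len(self.data[chrom])

    def cumsum(self, chrom: str) -> np.ndarray:
        """Cached prefix sums with a leading zero (length L + 1)."""
        if chrom not in self._cumsums:
            arr = self.data[chrom]
            cs = np.zeros(len(arr) + 1, dtype=np.float64)
            np.cumsum(arr, out=cs[1:])
            self._cumsums[chrom] = cs
        return self._cumsums[chrom]

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of coverage in [start, end), clipped at chromosome bounds."""
        cs = self.cumsum(chrom)
        n = len(cs) - 1
        start = min(max(start, 0), n)
        end = min(max(end, 0), n)
        if end <= start:
            return 0.0
        return float(cs[end] - cs[start])

    @classmethod
    def from_bedgraph(cls, path, lengths: dict[str, int] | None = None):
        """Read a 4-column bedGraph; chromosome lengths default to max end seen."""
        spans: dict[str, list[tuple[int, int, float]]] = {}
        maxend: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                chrom, start, end, value = line.split("\t")
                start, end, value = int(start), int(end), float(value)
                spans.setdefault(chrom, []).append((start, end, value))
                maxend[chrom] = max(maxend.get(chrom, 0), end)
        data = {}
        for chrom, recs in spans.items():
            L = lengths[chrom] if lengths else maxend[chrom]
            arr = np.zeros(L, dtype=np.float64)
            for start, end, value in recs:
                arr[start:end] = value
            data[chrom] = arr
        return cls(data)

    def to_bedgraph(self, path) -> None:
        """Write runs of equal non-zero coverage as bedGraph records."""
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                arr = self.data[chrom]
                if len(arr) == 0:
                    continue
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def quantify_tags(
    sites,
    track: CoverageTrack,
    halfwidth: int,
    normalize: bool = False,
) -> np.ndarray:
    """Tag count in center +/- halfwidth for each site, clipped at chrom edges.

    With ``normalize=True`` counts are scaled to tags per 10^7 total tags,
    the convention used when comparing signal across conditions.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    out = np.zeros(len(sites), dtype=np.float64)
    missing = set()
    for i, iv in enumerate(sites):
        if iv.chrom not in track.data:
            missing.add(iv.chrom)
            continue
        c = iv.center
        out[i] = track.window_sum(iv.chrom, c - halfwidth, c + halfwidth)
    if missing:
        warnings.warn(f"site chromosomes absent from track: {sorted(missing)}")
    if normalize:
        total = track.total_tags
        if total > 0:
            out = out * (1e7 / total)
    return out


def aggregate_profile(
    anchors,
    track: CoverageTrack,
    halfwidth: int = 4000,
    binsize: int = 10,
) -> np.ndarray:
    """Mean tags per bin across anchors, strand-aware, over center +/- halfwidth.

    Minus-strand anchors are flipped so bin 0 is always the most upstream
    position.  Anchors near chromosome edges contribute only to the bins
    they cover; the mean divides per-bin by the number of covering anchors.
    """
    if len(anchors) == 0:
        raise ValueError("aggregate_profile requires at least one anchor")
    if halfwidth % binsize != 0:
        raise ValueError("halfwidth must be divisible by binsize")
    nbins = 2 * halfwidth // binsize
    sums = np.zeros(nbins)
    counts = np.zeros(nbins)
    for iv in anchors:
        if iv.chrom not in track.data:
            continue
        L = track.chrom_length(iv.chrom)
        c = iv.center
        cs = track.cumsum(iv.chrom)
        edges = c - halfwidth + binsize * np.arange(nbins + 1)
        inside = (edges[:-1] >= 0) & (edges[1:] <= L)
        clipped = np.clip(edges, 0, L)
        vals = cs[clipped[1:]] - cs[clipped[:-1]]
        if iv.strand == "-":
            vals = vals[::-1]
            inside = inside[::-1]
        sums[inside] += vals[inside]
        counts[inside] += 1
    with np.errstate(invalid="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return profile
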