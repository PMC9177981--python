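"""PWM log-odds scanning and motif-occurrence statistics.

Scanning follows the relaxed-threshold convention used for targeted motif
searches: a window is a hit when its log-odds score reaches the motif's
default threshold minus ``threshold_offset`` (default 3 nats), which admits
near-consensus instances that a stringent threshold would miss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pwm import PWM, ALPHABET

_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT -> 0..3; anything else (N) -> -1."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int
    end: int
    strand: str
    score: float
    norm_score: float
    pwm_name: str

    @property
    def center(self) -> int:
        return self.start + (self.end - self.start) // 2


def _window_scores(codes: np.ndarray, lom: np.ndarray):
    """Scores of every window under a 4 x L log-odds matrix.

    Returns (scores, valid) where windows containing non-ACGT bases are
    marked invalid.
    """
    L = lom.shape[1]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for offset in range(L):
        col = codes[offset : offset + n]
        bad = col < 0
        valid &= ~bad
        scores += np.where(bad, 0.0, lom[np.clip(col, 0, 3), offset])
    return scores, valid


def pwm_logodds_scan(
    sequence: str,
    pwm: PWM,
    threshold_offset: float = 3.0,
    chrom: str = "seq",
    offset: int = 0,
    dedupe: bool = True,
) -> list[MotifHit]:
    """Scan both strands of ``sequence`` for matches to ``pwm``.

    ``offset`` shifts reported coordinates so hits land in genome space.
    With ``dedupe`` (default), overlapping hits on the same strand are
    reduced to the best-scoring position.  Sequences shorter than the
    motif yield an empty list.
    """
    codes = encode_sequence(sequence)
    L = pwm.length
    if len(codes) < L:
        return []
    threshold = pwm.default_threshold - threshold_offset
    consensus = pwm.consensus_score
    hits = []
    for strand, lom in (("+", pwm.log_odds), ("-", pwm.reverse_complement_matrix())):
        scores, valid = _window_scores(codes, lom)
        for pos in np.flatnonzero(valid & (scores >= threshold)):
            s = float(scores[pos])
            hits.append(
                MotifHit(
                    chrom,
                    offset + int(pos),
                    offset + int(pos) + L,
                    strand,
                    s,
                    s / consensus,
                    pwm.name,
                )
            )
    if dedupe:
        hits = _dedupe_overlaps(hits)
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _dedupe_overlaps(hits):
    """Keep, per strand, only the best-scoring hit among mutual overlaps."""
    kept = []
    for strand in ("+", "-"):
        cand = sorted(
            (h for h in hits if h.strand == strand),
            key=lambda h: (-h.score, h.start),
        )
        chosen: list[MotifHit] = []
        for h in cand:
            if not any(
                h.start < c.end and c.start < h.end for c in chosen
            ):
                chosen.append(h)
        kept.extend(chosen)
    return kept


def _site_id(iv, i: int) -> str:
    return iv.name or f"{iv.chrom}:{iv.start}-{iv.end}#{i}"


def _site_sequence(genome: dict[str, str], iv) -> str:
    return genome[iv.chrom][iv.start : iv.end]


def scan_sites(sites, genome, pwm, threshold_offset=3.0) -> dict[str, list[MotifHit]]:
    """Per-site motif hits, scanning each site's own sequence only."""
    out = {}
    for i, iv in enumerate(sites):
        out[_site_id(iv, i)] = pwm_logodds_scan(
            _site_sequence(genome, iv),
            pwm,
            threshold_offset,
            chrom=iv.chrom,
            offset=iv.start,
        )
    return out


def motif_occurrence(sites, genome, pwm, threshold_offset=3.0):
    """Fraction of sites containing >= 1 hit (and the per-site booleans)."""
    hits = scan_sites(sites, genome, pwm, threshold_offset)
    flags = pd.Series({k: len(v) > 0 for k, v in hits.items()})
    fraction = float(flags.mean()) if len(flags) else 0.0
    return fraction, flags


def mean_motif_score(sites, genome, pwm, threshold_offset=3.0):
    """Mean, over sites with a hit, of the best hit's normalized score.

    The normalized score is log-odds / consensus log-odds, so 1.0 means the
    consensus sequence.  Raises if no site has any hit.
    """
    hits = scan_sites(sites, genome, pwm, threshold_offset)
    best = {
        k: max(h.norm_score for h in v) for k, v in hits.items() if v
    }
    if not best:
        raise ValueError("no motif hits in any site; mean score undefined")
    scores = pd.Series(best)
    return float(scores.mean()), scores


def inter_motif_distance(
    sites, genome, pwm_a, pwm_b, bins=10, threshold_offset=3.0
):
    """|center(best A hit) - center(best B hit)| per site with both motifs.

    Returns (distances, (hist_counts, bin_edges), n_excluded) where excluded
    sites lack a hit for at least one of the motifs.
    """
    hits_a = scan_sites(sites, genome, pwm_a, threshold_offset)
    hits_b = scan_sites(sites, genome, pwm_b, threshold_offset)
    dists = {}
    n_excluded = 0
    for key in hits_a:
        if hits_a[key] and hits_b[key]:
            best_a = max(hits_a[key], key=lambda h: h.score)
            best_b = max(hits_b[key], key=lambda h: h.score)
            dists[key] = abs(best_a.center - best_b.center)
        else:
            n_excluded += 1
    distances = pd.Series(dists, dtype=float)
    counts, edges = np.histogram(distances, bins=bins) if len(dists) else (
        np.zeros(0, dtype=int),
        np.zeros(0),
    )
    return distances, (counts, edges), n_excluded
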