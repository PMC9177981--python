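"""Peak calling, replicate reproducibility, GRBS classification, proximity."""

import numpy as np
import pandas as pd
import pytest

from assistload.chipseq import (
    call_peaks,
    classify_grbs,
    nearest_gene,
    promoter_proximal,
    reproducible_sites,
)
from assistload.coverage import CoverageTrack
from assistload.intervals import GenomicInterval


def background_track(rng, rate=0.05, length=200_000):
    return CoverageTrack({"chr1": rng.poisson(rate, length).astype(float)})


def add_peak(track, center, amplitude, halfwidth=300, rng=None):
    arr = track.data["chr1"]
    xs = np.arange(
        max(center - halfwidth + 1, 0), min(center + halfwidth, len(arr))
    )
    expected = amplitude * (1 - np.abs(xs - center) / halfwidth)
    arr[xs] += rng.poisson(np.maximum(expected, 0))


def test_call_peaks_null_calibration():
    """Pure background yields essentially no peaks at padj <= 0.05."""
    total = 0
    for seed in range(10):
        rng = np.random.default_rng(1000 + seed)
        total += len(call_peaks(background_track(rng)))
    assert total <= 2


def test_call_peaks_recovers_single_planted_peak():
    rng = np.random.default_rng(42)
    track = background_track(rng)
    add_peak(track, 100_000, amplitude=0.5, rng=rng)  # 10x background
    peaks = call_peaks(track)
    assert len(peaks) == 1
    (peak,) = peaks
    assert peak.start <= 100_000 < peak.end


def test_call_peaks_stay_within_chromosome():
    rng = np.random.default_rng(7)
    track = CoverageTrack({"chr1": rng.poisson(0.05, 5000).astype(float)})
    add_peak(track, 4950, amplitude=1.0, rng=rng)
    for peak in call_peaks(track):
        assert 0 <= peak.start < peak.end <= 5000


def test_call_peaks_monotone_in_enrichment():
    counts = []
    for amplitude in (0.1, 0.25, 0.5):  # 2x, 5x, 10x over 0.05 background
        rng = np.random.default_rng(99)
        track = background_track(rng)
        for center in range(10_000, 200_000, 10_000):
            add_peak(track, center, amplitude, rng=rng)
        counts.append(len(call_peaks(track)))
    assert counts == sorted(counts)


def test_call_peaks_control_suppresses_shared_enrichment():
    rng = np.random.default_rng(5)
    track = background_track(rng, length=100_000)
    control = background_track(rng, length=100_000)
    add_peak(track, 50_000, 0.5, rng=rng)
    add_peak(control, 50_000, 0.5, rng=rng)
    assert len(call_peaks(track, control=control)) == 0


def _iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def test_reproducible_sites_support_and_blacklist():
    rep1 = [_iv(0, 100), _iv(500, 600), _iv(2000, 2100)]
    rep2 = [_iv(50, 150), _iv(2050, 2150)]
    rep3 = [_iv(40, 90)]
    out = reproducible_sites([rep1, rep2, rep3], min_support=2)
    spans = [(s.start, s.end) for s in out.sites]
    assert spans == [(0, 150), (2000, 2150)]      # 500-600 seen once: dropped
    assert out.support == [3, 2]
    black = reproducible_sites(
        [rep1, rep2, rep3], min_support=2, blacklist=[_iv(2040, 2060)]
    )
    assert [(s.start, s.end) for s in black.sites] == [(0, 150)]


def test_reproducible_sites_matches_brute_force_support(rng):
    reps = []
    for _ in range(3):
        starts = np.sort(rng.choice(50_000, size=200, replace=False))
        reps.append([_iv(int(s), int(s) + int(rng.integers(20, 80)))
                     for s in starts])
    out = reproducible_sites(reps, min_support=2)
    for site in out.sites:
        support = sum(
            any(site.overlaps(iv) for iv in rep) for rep in reps
        )
        assert support >= 2


def test_classify_grbs_definitions():
    idx = pd.Index(["s1", "s2", "s3", "s4"])

    def de(induced):
        lfc = pd.Series(0.0, index=idx)
        padj = pd.Series(1.0, index=idx)
        lfc[list(induced)] = 1.5
        padj[list(induced)] = 0.001
        return pd.DataFrame({"base_mean": 50.0, "log2fc": lfc, "p": padj,
                             "padj": padj, "untestable": False})

    # s1: cort-increased, flat dual-vs-cort -> unassisted
    # s2: dual-vs-cort increased (regardless of cort status) -> assisted
    # s3: increased in both -> assisted
    # s4: neither -> other
    table, summary = classify_grbs(de(["s1", "s3"]), de(["s2", "s3"]))
    assert table.loc["s1", "cls"] == "unassisted"
    assert table.loc["s2", "cls"] == "assisted"
    assert table.loc["s3", "cls"] == "assisted"
    assert table.loc["s4", "cls"] == "other"
    assert summary["n_cort_increased"] == 2
    assert summary["n_assisted_and_cort_increased"] == 1
    # classes are disjoint and exhaustive
    assert set(table["cls"]) <= {"assisted", "unassisted", "other"}


def test_classify_grbs_universe_mismatch():
    de = pd.DataFrame(
        {"base_mean": [1.0], "log2fc": [0.0], "p": [1.0], "padj": [1.0],
         "untestable": [False]}, index=["s1"],
    )
    with pytest.raises(ValueError):
        classify_grbs(de, de.set_axis(["other"]))


def tss(pos, strand, name="gene", chrom="chr1"):
    return GenomicInterval(chrom, pos, pos + 1, strand=strand, name=name)


def test_promoter_proximal_asymmetric_window():
    t = [tss(10_000, "+")]
    upstream = [_iv(9450, 9550)]    # center 9500: 500 bp upstream -> proximal
    downstream = [_iv(10_450, 10_550)]  # 500 bp downstream -> remote
    flags_up, _ = promoter_proximal(upstream, t)
    flags_dn, _ = promoter_proximal(downstream, t)
    assert bool(flags_up.iloc[0]) and not bool(flags_dn.iloc[0])


def test_promoter_proximal_respects_strand():
    t = [tss(10_000, "-")]
    # for a minus-strand TSS "upstream" is to the right
    flags, _ = promoter_proximal([_iv(10_450, 10_550)], t)
    assert bool(flags.iloc[0])
    flags2, _ = promoter_proximal([_iv(9450, 9550)], t)
    assert not bool(flags2.iloc[0])


def test_promoter_proximal_requires_strands():
    with pytest.raises(ValueError):
        promoter_proximal([_iv(0, 10)], [GenomicInterval("chr1", 5, 6)])


def test_promoter_proximal_matches_exhaustive_check(rng):
    tss_list = [
        tss(int(p), str(rng.choice(["+", "-"])), name=f"g{i}")
        for i, p in enumerate(rng.integers(2000, 98_000, size=50))
    ]
    sites = [_iv(int(s), int(s) + 100) for s in rng.integers(0, 100_000, 300)]
    flags, remote = promoter_proximal(sites, tss_list)
    for iv, flag in zip(sites, flags):
        c = iv.center
        expected = any(
            (-1000 <= (c - t.start if t.strand == "+" else t.start - c) <= 100)
            for t in tss_list
        )
        assert flag == expected
    assert remote == pytest.approx(1 - flags.mean())


def test_nearest_gene_single_tss_and_composition():
    t = [tss(5000, "+", name="geneA")]
    sites = [_iv(0, 100), _iv(9000, 9100)]
    names, comp = nearest_gene(sites, t, gene_classes={"geneA": "synergistic"})
    assert set(names) == {"geneA"}
    assert comp == {"synergistic": 1.0}
    assert sum(comp.values()) == pytest.approx(1.0)


def test_nearest_gene_empty_reference_errors():
    with pytest.raises(ValueError):
        nearest_gene([_iv(0, 10)], [])
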