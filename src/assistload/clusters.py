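"""Enhancer-cluster detection and cluster-level motif / signal analysis.

An enhancer cluster is a focal GR binding site together with the DNase
hypersensitive (DHS) enhancer units whose centers lie within a fixed
window (default +/- 12.5 kb, boundary inclusive) of the focal site center.
Sites with fewer than ``min_units`` units in the window are excluded but
counted.  Motif scanning and signal quantification within a cluster are
restricted to the member units themselves, never the inaccessible gaps
between them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import CoverageTrack, quantify_tags
from .motifs import pwm_logodds_scan


@dataclass
class EnhancerCluster:
    focal: object                 # GenomicInterval of the focal GRBS
    focal_id: str
    units: list = field(default_factory=list)
    contains_focal: list = field(default_factory=list)  # bool per unit
    cls: str = ""                 # optional focal-site class label

    @property
    def n_units(self) -> int:
        return len(self.units)


def detect_clusters(
    focal_sites,
    dhs,
    cluster_window: int = 12_500,
    min_units: int = 2,
    site_classes: dict | None = None,
):
    """Build enhancer clusters around focal sites.

    Returns (clusters, stats) where stats reports ``n_no_units`` (focal
    sites with zero DHS units in the window), ``n_below_min`` (some units
    but fewer than ``min_units``) and the unit-count distribution of the
    accepted clusters.
    """
    by_chrom: dict[str, list] = {}
    for u in dhs:
        by_chrom.setdefault(u.chrom, []).append(u)
    for units in by_chrom.values():
        units.sort(key=lambda u: u.center)
    centers = {
        chrom: np.array([u.center for u in units])
        for chrom, units in by_chrom.items()
    }

    clusters, n_no_units, n_below_min = [], 0, 0
    for i, site in enumerate(focal_sites):
        sid = site.name or f"focal_{i}"
        c = site.center
        units = []
        if site.chrom in by_chrom:
            arr = centers[site.chrom]
            lo = int(np.searchsorted(arr, c - cluster_window, side="left"))
            hi = int(np.searchsorted(arr, c + cluster_window, side="right"))
            units = by_chrom[site.chrom][lo:hi]
        if not units:
            n_no_units += 1
            continue
        if len(units) < min_units:
            n_below_min += 1
            continue
        contains = [u.contains(site.chrom, c) for u in units]
        cls = site_classes.get(sid, "") if site_classes else ""
        clusters.append(EnhancerCluster(site, sid, units, contains, cls))
    stats = {
        "n_no_units": n_no_units,
        "n_below_min": n_below_min,
        "unit_count_distribution": Counter(cl.n_units for cl in clusters),
    }
    return clusters, stats


def cluster_co_occurrence(
    clusters, genome, pwm_a, pwm_b, threshold_offset: float = 3.0
):
    """Percentage of clusters whose member units jointly contain >= 1 hit of
    each PWM.  Scanning is restricted to the union of unit intervals (each
    unit scanned separately, so motifs in inter-unit gaps never count).

    Returns (percentage, per-cluster DataFrame with has_a / has_b / both).
    """
    if not clusters:
        raise ValueError("no clusters to analyze")
    rows = {}
    for cl in clusters:
        has = {pwm_a.name: False, pwm_b.name: False}
        for pwm in (pwm_a, pwm_b):
            for u in cl.units:
                seq = genome[u.chrom][u.start : u.end]
                if pwm_logodds_scan(
                    seq, pwm, threshold_offset, chrom=u.chrom, offset=u.start
                ):
                    has[pwm.name] = True
                    break
        rows[cl.focal_id] = {
            "has_a": has[pwm_a.name],
            "has_b": has[pwm_b.name],
            "both": has[pwm_a.name] and has[pwm_b.name],
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return 100.0 * float(table["both"].mean()), table


def cluster_signal(
    clusters,
    track: CoverageTrack,
    halfwidth: int,
    exclude_focal_unit: bool = False,
    normalize: bool = True,
):
    """Per-unit and per-cluster tag quantification.

    With ``exclude_focal_unit`` the unit containing the focal site is
    dropped before aggregating; clusters left with no units are reported
    with NaN and flagged ``empty``.  Returns (per_unit, per_cluster)
    DataFrames.
    """
    unit_rows = []
    cluster_rows = {}
    for cl in clusters:
        keep = [
            (u, is_focal)
            for u, is_focal in zip(cl.units, cl.contains_focal)
            if not (exclude_focal_unit and is_focal)
        ]
        if not keep:
            cluster_rows[cl.focal_id] = {"mean_signal": np.nan, "n_units": 0,
                                         "empty": True}
            continue
        vals = quantify_tags(
            [u for u, _ in keep], track, halfwidth, normalize=normalize
        )
        for (u, is_focal), v in zip(keep, vals):
            unit_rows.append(
                {
                    "cluster": cl.focal_id,
                    "unit": u.name or f"{u.chrom}:{u.start}-{u.end}",
                    "is_focal_unit": is_focal,
                    "signal": float(v),
                }
            )
        cluster_rows[cl.focal_id] = {
            "mean_signal": float(np.mean(vals)),
            "n_units": len(keep),
            "empty": False,
        }
    per_unit = pd.DataFrame(unit_rows)
    per_cluster = pd.DataFrame.from_dict(cluster_rows, orient="index")
    return per_unit, per_cluster
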