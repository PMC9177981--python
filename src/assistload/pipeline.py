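"""End-to-end analysis on a simulated experiment.

``run`` chains every stage the package provides — differential expression,
crosstalk classification, pattern clustering, GR peak calling and
differential binding, assisted/unassisted classification, motif statistics
and enhancer-cluster analysis — and returns one results dictionary.  With
``outdir`` set, the main tables are written as TSV with fixed float
formatting, so two runs with the same config produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import chipseq, clusters, crosstalk, diffexpr
from .counts import CONDITIONS
from .diffexpr import AnalysisThresholds, DEFAULT_THRESHOLDS
from .intervals import GenomicInterval, merge_sites
from .pwm import cre_pwm, gre_pwm
from .simulate import SimulationConfig, simulate_experiment

#: The gene-level pairwise contrasts used by the crosstalk definitions.
GENE_CONTRASTS = (
    ("gluc", "nt"),
    ("cort", "nt"),
    ("dual", "nt"),
    ("dual", "gluc"),
    ("dual", "cort"),
    ("gluc", "dual"),
    ("cort", "dual"),
)


def gene_analysis(cm, thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS,
                  sum_rule: str = "delta", seed: int = 0) -> dict:
    """All gene-level stages on one count matrix."""
    de = {
        f"{b}_vs_{a}": diffexpr.nb_wald_test(cm, a, b) for b, a in GENE_CONTRASTS
    }
    rpkm_means = cm.condition_means(diffexpr.rpkm(cm))
    table = crosstalk.crosstalk_table(de, rpkm_means, thresholds, sum_rule)
    induced_any = sorted(
        set().union(
            *(
                diffexpr.call_differential(de[f"{b}_vs_nt"], thresholds)["induced"]
                for b in ("gluc", "cort", "dual")
            )
        )
    )
    kmeans = None
    if len(induced_any) >= thresholds.k:
        labels, centroids = crosstalk.kmeans_patterns(
            rpkm_means.loc[induced_any], k=thresholds.k, seed=seed
        )
        kmeans = {"labels": labels, "centroids": centroids}
    return {
        "de": de,
        "rpkm_means": rpkm_means,
        "crosstalk": table,
        "induced_any": induced_any,
        "kmeans": kmeans,
    }


def gr_site_analysis(exp, thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS) -> dict:
    """Peak calling per condition on pooled GR coverage, a merged site
    universe, window counts, differential binding and GRBS classification."""
    reps = exp.config.replicates
    tracks, conditions = exp.tracks("GR")
    pooled = {}
    for cond in CONDITIONS:
        arrs = [
            tracks[f"{cond}_rep{r + 1}"].data[exp.annotation.chrom]
            for r in range(reps)
        ]
        pooled[cond] = chipseq.CoverageTrack(
            {exp.annotation.chrom: np.sum(arrs, axis=0)}
        )
    peaks = {
        cond: chipseq.call_peaks(pooled[cond], assay="GR", condition=cond)
        for cond in CONDITIONS
    }
    merged = merge_sites(*(list(peaks[c]) for c in CONDITIONS), labels=CONDITIONS)
    universe = [
        GenomicInterval(m.chrom, m.start, m.end, name=f"site{i:04d}")
        for i, m in enumerate(merged)
    ]
    cm_sites = chipseq.site_counts(
        universe, tracks, conditions, thresholds.tf_halfwidth
    )
    de_cort = chipseq.differential_binding(cm_sites, "nt", "cort", thresholds)
    de_dual_vs_cort = chipseq.differential_binding(cm_sites, "cort", "dual", thresholds)
    de_gluc = chipseq.differential_binding(cm_sites, "nt", "gluc", thresholds)
    grbs_table, grbs_summary = chipseq.classify_grbs(
        de_cort, de_dual_vs_cort, thresholds
    )
    return {
        "peaks": peaks,
        "universe": universe,
        "site_counts": cm_sites,
        "de_cort_vs_nt": de_cort,
        "de_dual_vs_cort": de_dual_vs_cort,
        "de_gluc_vs_nt": de_gluc,
        "grbs_table": grbs_table,
        "grbs_summary": grbs_summary,
    }


def map_sites_to_truth(universe, exp) -> pd.Series:
    """Truth class of the planted GRBS overlapping each universe site
    ('none' when a site overlaps no planted GRBS)."""
    out = {}
    planted = exp.annotation.grbs
    for iv in universe:
        cls = "none"
        for p in planted:
            if iv.overlaps(p):
                cls = exp.truth.site_class[p.name]
                break
        out[iv.name] = cls
    return pd.Series(out)


def motif_and_cluster_analysis(
    exp,
    grbs_table: pd.DataFrame,
    universe,
    thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS,
) -> dict:
    """Motif occurrence/score statistics and enhancer-cluster analysis for
    the classified assisted vs unassisted sites."""
    from . import motifs as motifs_mod

    gre, cre = gre_pwm(), cre_pwm()
    genome = exp.annotation.genome
    # motif statistics use fixed-width windows around site centers, the
    # same convention as the binding quantification windows
    halfw = exp.config.site_halfwidth
    by_id = {
        iv.name: GenomicInterval(
            iv.chrom, iv.center - halfw, iv.center + halfw, name=iv.name
        )
        for iv in universe
    }
    assisted = [by_id[s] for s in grbs_table.index[grbs_table["cls"] == "assisted"]]
    unassisted = [
        by_id[s] for s in grbs_table.index[grbs_table["cls"] == "unassisted"]
    ]
    out: dict = {}
    off = thresholds.logodds_offset
    if assisted and unassisted:
        out["gre_score_assisted"] = motifs_mod.mean_motif_score(
            assisted, genome, gre, off
        )[0]
        out["gre_score_unassisted"] = motifs_mod.mean_motif_score(
            unassisted, genome, gre, off
        )[0]
        out["cre_fraction_assisted"] = motifs_mod.motif_occurrence(
            assisted, genome, cre, off
        )[0]
        out["cre_fraction_unassisted"] = motifs_mod.motif_occurrence(
            unassisted, genome, cre, off
        )[0]

    det, stats = clusters.detect_clusters(
        assisted, exp.annotation.dhs, thresholds.cluster_window,
        thresholds.min_units,
    )
    out["clusters"] = det
    out["cluster_stats"] = stats
    if det:
        pct, co_table = clusters.cluster_co_occurrence(det, genome, gre, cre, off)
        out["cluster_cooccurrence_pct"] = pct
        focal_sites = [cl.focal for cl in det]
        frac_gre = motifs_mod.motif_occurrence(focal_sites, genome, gre, off)[1]
        frac_cre = motifs_mod.motif_occurrence(focal_sites, genome, cre, off)[1]
        out["focal_cooccurrence_pct"] = 100.0 * float(
            (frac_gre & frac_cre).mean()
        )
        k27_gluc = exp.coverage("H3K27ac", "gluc")
        k27_nt = exp.coverage("H3K27ac", "nt")
        for label, excl in (("all_units", False), ("excl_focal", True)):
            _, per_cl_gluc = clusters.cluster_signal(
                det, k27_gluc, thresholds.k27_halfwidth, exclude_focal_unit=excl
            )
            _, per_cl_nt = clusters.cluster_signal(
                det, k27_nt, thresholds.k27_halfwidth, exclude_focal_unit=excl
            )
            out[f"k27_gluc_vs_nt_{label}"] = float(
                per_cl_gluc["mean_signal"].mean() / per_cl_nt["mean_signal"].mean()
            )
    return out


def run(
    config: SimulationConfig,
    outdir=None,
    thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS,
) -> dict:
    """Simulate one experiment and run every analysis stage on it."""
    exp = simulate_experiment(config)
    genes = gene_analysis(exp.counts, thresholds, seed=config.seed)
    sites = gr_site_analysis(exp, thresholds)
    mc = motif_and_cluster_analysis(
        exp, sites["grbs_table"], sites["universe"], thresholds
    )
    results = {"experiment": exp, "genes": genes, "sites": sites,
               "motifs_clusters": mc}
    if outdir is not None:
        _write_tables(results, Path(outdir))
    return results


def _write_tables(results, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = {"sep": "\t", "float_format": "%.6g"}
    genes = results["genes"]
    for name, de in genes["de"].items():
        de.to_csv(outdir / f"de_{name}.tsv", **fmt)
    genes["crosstalk"].to_csv(outdir / "crosstalk.tsv", **fmt)
    genes["rpkm_means"].to_csv(outdir / "rpkm_means.tsv", **fmt)
    if genes["kmeans"] is not None:
        genes["kmeans"]["labels"].to_csv(outdir / "kmeans_labels.tsv", sep="\t")
    sites = results["sites"]
    sites["grbs_table"].to_csv(outdir / "grbs_classification.tsv", **fmt)
    for name in ("de_cort_vs_nt", "de_dual_vs_cort", "de_gluc_vs_nt"):
        sites[name].to_csv(outdir / f"grbs_{name}.tsv", **fmt)
    mc = results["motifs_clusters"]
    scalars = {
        k: v for k, v in mc.items() if isinstance(v, (int, float, np.floating))
    }
    pd.Series(scalars, name="value").sort_index().to_csv(
        outdir / "motif_cluster_summary.tsv", sep="\t", float_format="%.6g"
    )
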