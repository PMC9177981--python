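"""Gene-level hormone crosstalk: antagonism, synergy, pattern clustering.

The classifications operate on pairwise differential-expression contrasts
between the four conditions (nt, gluc, cort, dual):

* a glucagon-induced gene is *antagonized by corticosterone* when it is
  induced in gluc vs nt AND in gluc vs dual (the dual treatment dampens it);
* a gene is *synergistically induced* when it is induced in dual vs each of
  nt, gluc and cort, AND its dual-treatment expression increase exceeds the
  sum of the two single-treatment increases (on mean RPKM).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.cluster import KMeans

from .counts import CONDITIONS
from .diffexpr import AnalysisThresholds, DEFAULT_THRESHOLDS, is_induced


def _check_universe(*de_tables):
    first = de_tables[0].index
    for de in de_tables[1:]:
        if not first.equals(de.index):
            raise ValueError("DE contrasts computed on mismatched feature universes")
    return first


def classify_antagonism(
    de_gluc_vs_nt: pd.DataFrame,
    de_gluc_vs_dual: pd.DataFrame,
    de_cort_vs_nt: pd.DataFrame,
    de_cort_vs_dual: pd.DataFrame,
    thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS,
):
    """Return (antag_by_cort, antag_by_gluc) gene index sets.

    ``de_x_vs_y`` is the contrast of condition x over condition y, so
    induction in gluc vs dual means the dual treatment dampened the gene.
    """
    _check_universe(
        de_gluc_vs_nt, de_gluc_vs_dual, de_cort_vs_nt, de_cort_vs_dual
    )
    antag_by_cort = de_gluc_vs_nt.index[
        is_induced(de_gluc_vs_nt, thresholds)
        & is_induced(de_gluc_vs_dual, thresholds)
    ]
    antag_by_gluc = de_cort_vs_nt.index[
        is_induced(de_cort_vs_nt, thresholds)
        & is_induced(de_cort_vs_dual, thresholds)
    ]
    return antag_by_cort, antag_by_gluc


def classify_synergy(
    de_dual_vs_nt: pd.DataFrame,
    de_dual_vs_gluc: pd.DataFrame,
    de_dual_vs_cort: pd.DataFrame,
    rpkm_means: pd.DataFrame,
    thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS,
    sum_rule: str = "delta",
) -> pd.Index:
    """Genes synergistically induced by the dual treatment.

    ``rpkm_means`` must have one column per condition (mean over
    replicates).  ``sum_rule='delta'`` requires
    (dual - nt) > (gluc - nt) + (cort - nt); ``'raw'`` requires
    dual > gluc + cort.  Both inequalities are strict.
    """
    idx = _check_universe(de_dual_vs_nt, de_dual_vs_gluc, de_dual_vs_cort)
    missing = [c for c in CONDITIONS if c not in rpkm_means.columns]
    if missing:
        raise ValueError(f"rpkm_means missing conditions: {missing}")
    r = rpkm_means.reindex(idx)
    if sum_rule == "delta":
        above_sum = (r["dual"] - r["nt"]) > (r["gluc"] - r["nt"]) + (
            r["cort"] - r["nt"]
        )
    elif sum_rule == "raw":
        above_sum = r["dual"] > r["gluc"] + r["cort"]
    else:
        raise ValueError(f"unknown sum_rule {sum_rule!r}")
    passed = (
        is_induced(de_dual_vs_nt, thresholds)
        & is_induced(de_dual_vs_gluc, thresholds)
        & is_induced(de_dual_vs_cort, thresholds)
        & above_sum
    )
    return idx[passed]


def crosstalk_table(
    de: dict[str, pd.DataFrame],
    rpkm_means: pd.DataFrame,
    thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS,
    sum_rule: str = "delta",
) -> pd.DataFrame:
    """One row per gene: crosstalk class plus the supporting RPKM deltas.

    ``de`` maps contrast names ('gluc_vs_nt', 'gluc_vs_dual', 'cort_vs_nt',
    'cort_vs_dual', 'dual_vs_nt', 'dual_vs_gluc', 'dual_vs_cort') to DE
    tables on a shared universe.  Synergy takes precedence; synergy and
    antagonism are mutually exclusive by construction (a gene cannot be
    induced both in dual-vs-gluc and gluc-vs-dual).
    """
    synergistic = classify_synergy(
        de["dual_vs_nt"], de["dual_vs_gluc"], de["dual_vs_cort"],
        rpkm_means, thresholds, sum_rule,
    )
    antag_by_cort, antag_by_gluc = classify_antagonism(
        de["gluc_vs_nt"], de["gluc_vs_dual"], de["cort_vs_nt"],
        de["cort_vs_dual"], thresholds,
    )
    idx = de["dual_vs_nt"].index
    r = rpkm_means.reindex(idx)
    ind_g = is_induced(de["gluc_vs_nt"], thresholds)
    ind_c = is_induced(de["cort_vs_nt"], thresholds)
    ind_d = is_induced(de["dual_vs_nt"], thresholds)
    cls = pd.Series("none", index=idx)
    cls[ind_g & ~ind_c] = "induced_gluc"
    cls[ind_c & ~ind_g] = "induced_cort"
    cls[(ind_g & ind_c) | (ind_d & ~ind_g & ~ind_c)] = "induced_dual"
    cls[antag_by_cort] = "antag_by_cort"
    cls[antag_by_gluc] = "antag_by_gluc"
    cls[synergistic] = "synergistic"
    return pd.DataFrame(
        {
            "cls": cls,
            "delta_gluc": r["gluc"] - r["nt"],
            "delta_cort": r["cort"] - r["nt"],
            "delta_dual": r["dual"] - r["nt"],
        }
    )


def kmeans_patterns(
    profiles: pd.DataFrame, k: int = 5, seed: int = 0, n_init: int = 10
):
    """Cluster per-gene condition profiles (row z-scored) with k-means.

    ``profiles`` is genes x conditions (typically the 4 condition means of
    induced genes).  Returns (labels, centroids); constant rows z-score
    to all zeros.  Deterministic for a fixed seed.
    """
    if len(profiles) < k:
        raise ValueError(f"need at least k={k} genes, got {len(profiles)}")
    vals = profiles.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (vals - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = pd.Series(km.fit_predict(z), index=profiles.index, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_, columns=profiles.columns)
    return labels, centroids


def format_percent(k: int, n: int) -> str:
    """Percentage printing convention: nearest integer, except one decimal
    place when the value is >= 99% but below 100%."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    v = 100.0 * k / n
    if 99.0 <= v < 100.0:
        return f"{v:.1f}%"
    return f"{v:.0f}%"


def overlap_summary(set_a, set_b, universe) -> dict:
    """Overlap counts, percentages and a one-sided hypergeometric p value.

    Both sets must be subsets of ``universe``.  The enrichment p is the
    probability of observing at least the seen overlap when |A| draws are
    made from the universe containing |B| successes.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u or not b <= u:
        raise ValueError("sets must be subsets of the universe")
    k = len(a & b)
    p = float(hypergeom.sf(k - 1, len(u), len(b), len(a))) if a else 1.0
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_overlap": k,
        "n_a_only": len(a - b),
        "n_b_only": len(b - a),
        "p": p,
        "pct_a_in_b": format_percent(k, len(a)) if a else "0%",
        "pct_b_in_a": format_percent(k, len(b)) if b else "0%",
    }
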