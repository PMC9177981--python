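"""Negative-binomial differential analysis for gene and site counts.

A deliberately compact DESeq2-style workflow: median-of-ratios size factors
(or total-tag normalization for TF ChIP contrasts), gene-wise
method-of-moments dispersion estimates shrunk toward a fitted
mean-dispersion trend, and a Wald test on the log fold change of a
two-group negative-binomial GLM.  Multi-factor designs, LFC shrinkage and
outlier filtering are out of scope; calibration is validated by simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

from .counts import CountMatrix

_LN2 = np.log(2.0)

#: Floor/ceiling for dispersion estimates (variance = mu + alpha * mu^2).
_ALPHA_MIN = 1e-8
_ALPHA_MAX = 20.0

#: Prior degrees of freedom pulling gene-wise dispersions toward the trend.
#: A method-of-moments estimate from 3 + 3 replicates has only 4 residual
#: df and is extremely noisy, so the trend (pooled across all features)
#: carries most of the weight: gene weight = 4 / (4 + 20) ~ 0.17.
PRIOR_DF = 20.0


@dataclass
class AnalysisThresholds:
    """Every fixed analysis parameter, with the values used throughout."""

    fc_min: float = 1.5            # linear fold-change cutoff
    padj_max: float = 0.05         # BH-adjusted p cutoff
    k: int = 5                     # k-means cluster count
    cluster_window: int = 12_500   # bp around a focal GRBS
    min_units: int = 2             # DHS units required for cluster status
    logodds_offset: float = 3.0    # PWM threshold relaxation (nats)
    promoter_window: tuple = (-1000, 100)  # bp around the TSS, strand-oriented
    tf_halfwidth: int = 200        # bp, TF ChIP / DNase quantification
    k27_halfwidth: int = 500       # bp, H3K27ac quantification
    profile_halfwidth: int = 4000  # bp, aggregate profiles
    profile_bin: int = 10          # bp per profile bin

    def __post_init__(self):
        if self.fc_min <= 1:
            raise ValueError("fc_min must exceed 1")
        if not 0 < self.padj_max < 1:
            raise ValueError("padj_max must lie in (0, 1)")


DEFAULT_THRESHOLDS = AnalysisThresholds()


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    Uses only features with strictly positive counts in every sample; with
    ``pseudo_reference=True`` the geometric mean ignores zeros instead
    (useful for sparse site-count matrices).
    """
    mat = counts.to_numpy(dtype=np.float64)
    with np.errstate(divide="ignore"):
        logmat = np.log(mat)
    allpos = np.all(mat > 0, axis=1)
    if allpos.any() and not pseudo_reference:
        logref = logmat[allpos].mean(axis=1)
        ratios = logmat[allpos] - logref[:, None]
    elif pseudo_reference:
        anypos = mat > 0
        usable = anypos.sum(axis=1) > 0
        logref = np.where(
            usable,
            np.where(anypos, logmat, 0).sum(axis=1)
            / np.maximum(anypos.sum(axis=1), 1),
            np.nan,
        )
        ratios = np.where(anypos, logmat - logref[:, None], np.nan)[usable]
    else:
        raise ValueError(
            "no feature has positive counts in every sample; "
            "retry with pseudo_reference=True"
        )
    factors = np.exp(np.nanmedian(ratios, axis=0))
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("could not compute positive size factors")
    return pd.Series(factors, index=counts.columns)


def total_tag_factors(counts: pd.DataFrame) -> pd.Series:
    """Per-sample totals rescaled to geometric mean 1 (norm2total analog)."""
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise ValueError("every sample needs a positive total count")
    return totals / np.exp(np.log(totals).mean())


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values.

    NaN entries propagate as NaN and are excluded from the number of tests.
    """
    p = np.asarray(p, dtype=np.float64)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def _dispersion_trend(base_mean: np.ndarray, alpha_hat: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1 / mu (nonnegative) to gene-wise estimates."""
    ok = (base_mean > 0) & np.isfinite(alpha_hat)
    mu, a = base_mean[ok], np.clip(alpha_hat[ok], 0.0, _ALPHA_MAX)
    if len(mu) < 10:
        fallback = float(np.median(a)) if len(a) else 0.01
        return np.full(base_mean.shape, max(fallback, _ALPHA_MIN))
    X = np.column_stack([np.ones_like(mu), 1.0 / mu])
    coef, _ = nnls(X, a)
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.maximum(base_mean, 1e-12)
    return np.maximum(trend, _ALPHA_MIN)


def nb_wald_test(
    cm: CountMatrix,
    condition_a: str,
    condition_b: str,
    norm: str = "size_factors",
    factors: pd.Series | None = None,
    prior_df: float = PRIOR_DF,
) -> pd.DataFrame:
    """Two-group negative-binomial Wald test, contrast B over A.

    Returns a DataFrame indexed by feature with columns ``base_mean``,
    ``log2fc``, ``p``, ``padj`` and ``untestable``.  Features with zero
    counts in all samples of both groups are flagged untestable with
    p = 1 and log2fc = 0.
    """
    samples_a = cm.samples_for(condition_a)
    samples_b = cm.samples_for(condition_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each condition needs at least 2 replicates")
    sub = cm.counts[samples_a + samples_b]
    if factors is not None:
        s = factors.reindex(sub.columns).to_numpy(dtype=float)
    elif norm == "total_tags":
        if cm.sample_totals is not None:
            totals = cm.sample_totals.reindex(sub.columns).astype(float)
            s = (totals / np.exp(np.log(totals).mean())).to_numpy()
        else:
            s = total_tag_factors(sub).to_numpy()
    elif norm == "size_factors":
        s = size_factors(sub).to_numpy()
    else:
        raise ValueError(f"unknown normalization {norm!r}")

    k = sub.to_numpy(dtype=np.float64)
    n_a, n_b = len(samples_a), len(samples_b)
    in_a = np.arange(k.shape[1]) < n_a
    q = k / s  # normalized counts
    sum_s_a, sum_s_b = s[in_a].sum(), s[~in_a].sum()
    mu_a = k[:, in_a].sum(axis=1) / sum_s_a
    mu_b = k[:, ~in_a].sum(axis=1) / sum_s_b
    base_mean = q.mean(axis=1)
    untestable = (mu_a == 0) & (mu_b == 0)

    # Method-of-moments gene-wise dispersion on normalized counts,
    # then shrinkage toward the fitted mean-dispersion trend.
    resid = np.where(in_a, (q.T - mu_a).T, (q.T - mu_b).T)
    df = n_a + n_b - 2
    v = (resid**2).sum(axis=1) / df
    mean_inv_s = np.mean(1.0 / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = (v - base_mean * mean_inv_s) / base_mean**2
    alpha_hat = np.where(np.isfinite(alpha_hat), alpha_hat, 0.0)
    trend = _dispersion_trend(base_mean, alpha_hat)
    clipped = np.clip(alpha_hat, trend / 20.0, trend * 20.0)
    clipped = np.maximum(clipped, _ALPHA_MIN)
    w_gene = df / (df + prior_df)
    alpha = np.exp(w_gene * np.log(clipped) + (1 - w_gene) * np.log(trend))
    alpha = np.clip(alpha, _ALPHA_MIN, _ALPHA_MAX)

    # Pseudo-mean for groups observed at zero so the LFC and its SE exist.
    mu_a_star = np.where(mu_a > 0, mu_a, 0.5 / sum_s_a)
    mu_b_star = np.where(mu_b > 0, mu_b, 0.5 / sum_s_b)
    lfc_nat = np.log(mu_b_star) - np.log(mu_a_star)

    mu_mat = np.where(in_a, np.outer(mu_a_star, s), np.outer(mu_b_star, s))
    w = mu_mat / (1.0 + alpha[:, None] * mu_mat)
    se = np.sqrt(1.0 / w[:, in_a].sum(axis=1) + 1.0 / w[:, ~in_a].sum(axis=1))
    z = lfc_nat / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    lfc_nat[untestable] = 0.0
    p[untestable] = 1.0
    res = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": lfc_nat / _LN2,
            "p": p,
            "untestable": untestable,
        },
        index=sub.index,
    )
    res["padj"] = bh_adjust(res["p"].to_numpy())
    return res[["base_mean", "log2fc", "p", "padj", "untestable"]]


def rpkm(cm: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase of feature per million mapped reads."""
    if cm.lengths is None:
        raise ValueError("RPKM requires feature lengths")
    totals = cm.counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise ValueError("zero sample total")
    return (
        cm.counts * 1e9
    ).div(cm.lengths, axis=0).div(totals, axis=1)


def call_differential(
    de: pd.DataFrame, thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS
) -> dict:
    """Split a DE table into induced and repressed feature sets.

    Induced: linear FC >= fc_min and padj <= padj_max (boundary inclusive,
    with a tiny numeric tolerance); repressed symmetric at FC <= 1/fc_min.
    """
    fc = np.power(2.0, de["log2fc"].to_numpy())
    padj = de["padj"].to_numpy()
    sig = ~np.isnan(padj) & (padj <= thresholds.padj_max + 1e-12)
    eps = 1e-9
    induced = de.index[sig & (fc >= thresholds.fc_min * (1 - eps))]
    repressed = de.index[sig & (fc <= (1.0 / thresholds.fc_min) * (1 + eps))]
    return {"induced": induced, "repressed": repressed}


def is_induced(
    de: pd.DataFrame, thresholds: AnalysisThresholds = DEFAULT_THRESHOLDS
) -> pd.Series:
    """Boolean per-feature induced call (same rule as call_differential)."""
    induced = call_differential(de, thresholds)["induced"]
    return pd.Series(de.index.isin(induced), index=de.index)
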