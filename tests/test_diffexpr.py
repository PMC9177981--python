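"""Negative-binomial differential testing: normalization, BH, calibration."""

import numpy as np
import pandas as pd
import pytest

from assistload.counts import CountMatrix
from assistload.diffexpr import (
    bh_adjust,
    call_differential,
    nb_wald_test,
    rpkm,
    size_factors,
    total_tag_factors,
)
from assistload.simulate import SimulationConfig, simulate_counts


def make_cm(counts: pd.DataFrame, lengths=None):
    return CountMatrix(
        counts, {c: c.rsplit("_rep", 1)[0] for c in counts.columns},
        lengths=lengths,
    )


# ---------------------------------------------------------------- size factors


def test_size_factors_identity_and_scaling(rng):
    base = pd.DataFrame({"a": [10, 50, 200], "b": [10, 50, 200]})
    assert np.allclose(size_factors(base), 1.0)
    doubled = base.assign(b=base["a"] * 2)
    f = size_factors(doubled)
    assert f["b"] / f["a"] == pytest.approx(2.0)
    assert np.exp(np.log(f).mean()) == pytest.approx(1.0, rel=1e-9)


def test_size_factors_matches_literal_median_of_ratios(rng):
    counts = pd.DataFrame(
        rng.poisson(50, size=(50, 4)) + 1, columns=list("abcd")
    )
    got = size_factors(counts)
    # literal hand calculation
    logref = np.log(counts).mean(axis=1)
    expected = np.exp(np.median(np.log(counts).sub(logref, axis=0), axis=0))
    assert np.allclose(got, expected)


def test_size_factors_matches_pydeseq2(rng):
    """Independent cross-check against the DESeq2 reimplementation."""
    pydeseq2 = pytest.importorskip("pydeseq2")
    from pydeseq2.preprocessing import deseq2_norm

    counts = pd.DataFrame(rng.poisson(80, size=(100, 6)) + 1)
    _, sf = deseq2_norm(counts.T)
    assert np.allclose(size_factors(counts), np.asarray(sf), rtol=1e-9)


def test_size_factors_all_zero_feature_paths():
    counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
    with pytest.raises(ValueError, match="pseudo_reference"):
        size_factors(counts)
    f = size_factors(counts, pseudo_reference=True)
    assert (f > 0).all()


# ------------------------------------------------------------------------- BH


def test_bh_single_p_is_identity():
    assert bh_adjust([0.04])[0] == pytest.approx(0.04)


def test_bh_worked_example():
    # hand-computed step-up: min over i>=rank of p_(i) * m / i
    got = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])


def naive_bh(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        out[i] = min(running, 1.0)
    return out


def test_bh_matches_definition_on_random_vectors(rng):
    for _ in range(1000):
        p = rng.uniform(size=rng.integers(1, 30))
        assert np.allclose(bh_adjust(p), naive_bh(p))


def test_bh_nan_propagates_and_is_excluded_from_m():
    p = np.array([0.01, np.nan, 0.02])
    got = bh_adjust(p)
    assert np.isnan(got[1])
    assert np.allclose(got[[0, 2]], naive_bh([0.01, 0.02]))


def test_bh_never_below_raw_p(rng):
    p = rng.uniform(size=200)
    assert (bh_adjust(p) >= p - 1e-12).all()


# ----------------------------------------------------------------------- RPKM


def test_rpkm_closed_form():
    counts = pd.DataFrame({"s_rep1": [100, 10_000_000 - 100]})
    cm = make_cm(counts, lengths=pd.Series([1000, 10_000], index=counts.index))
    assert rpkm(cm).iloc[0, 0] == pytest.approx(10.0)


def test_rpkm_depth_invariance(rng):
    counts = pd.DataFrame({"a_rep1": rng.poisson(100, 50) + 1})
    lengths = pd.Series(rng.integers(500, 5000, 50), index=counts.index)
    cm1 = make_cm(counts, lengths)
    cm2 = make_cm(counts * 2, lengths)
    assert np.allclose(rpkm(cm1), rpkm(cm2))


def test_rpkm_matrix_matches_scalar_formula(rng):
    counts = pd.DataFrame(rng.poisson(50, size=(20, 3)) + 1,
                          columns=["x_rep1", "x_rep2", "x_rep3"])
    lengths = pd.Series(rng.integers(200, 3000, 20), index=counts.index)
    got = rpkm(make_cm(counts, lengths))
    totals = counts.sum(axis=0)
    for i in range(20):
        for j in range(3):
            expected = counts.iat[i, j] * 1e9 / (lengths.iloc[i] * totals.iloc[j])
            assert got.iat[i, j] == pytest.approx(expected)


# ---------------------------------------------------------------- Wald test


def test_nb_wald_null_feature_is_flat():
    counts = pd.DataFrame(
        {
            "a_rep1": [50, 7], "a_rep2": [50, 7], "a_rep3": [50, 7],
            "b_rep1": [50, 7], "b_rep2": [50, 7], "b_rep3": [50, 7],
        }
    )
    de = nb_wald_test(make_cm(counts), "a", "b")
    assert de["log2fc"].abs().max() < 1e-9
    assert (de["p"] > 0.9).all()


def test_nb_wald_all_zero_feature_flagged_untestable():
    counts = pd.DataFrame(
        {
            "a_rep1": [0, 10], "a_rep2": [0, 12], "a_rep3": [0, 9],
            "b_rep1": [0, 11], "b_rep2": [0, 10], "b_rep3": [0, 13],
        }
    )
    de = nb_wald_test(make_cm(counts), "a", "b")
    assert bool(de["untestable"].iloc[0])
    assert de["p"].iloc[0] == 1.0 and de["log2fc"].iloc[0] == 0.0


def test_nb_wald_requires_replicates():
    counts = pd.DataFrame({"a_rep1": [5], "b_rep1": [5], "b_rep2": [6]})
    with pytest.raises(ValueError, match="replicates"):
        nb_wald_test(make_cm(counts), "a", "b")


def test_nb_wald_monotone_in_group_b_counts(rng):
    base = pd.DataFrame(
        rng.poisson(60, size=(30, 6)) + 1,
        columns=[f"{g}_rep{r}" for g in "ab" for r in (1, 2, 3)],
    )
    factors = pd.Series(1.0, index=base.columns)
    lfc = []
    for bump in (0, 20, 60, 150):
        counts = base.copy()
        counts.loc[0, ["b_rep1", "b_rep2", "b_rep3"]] += bump
        de = nb_wald_test(make_cm(counts), "a", "b", factors=factors)
        lfc.append(de["log2fc"].iloc[0])
    assert all(b >= a - 1e-12 for a, b in zip(lfc, lfc[1:]))


def test_nb_wald_type_one_error_calibrated():
    """Raw p <= 0.05 fraction on simulator-null NB data stays near nominal."""
    cfg = SimulationConfig(seed=11, n_per_class={"null": 2000}, n_housekeeping=0)
    cm, _ = simulate_counts(cfg)
    de = nb_wald_test(cm, "nt", "gluc")
    frac = float((de["p"] <= 0.05).mean())
    assert 0.03 <= frac <= 0.07


def test_nb_wald_recovers_planted_induction():
    """Strong effects (4x) are recovered at >= 0.9 sensitivity, FDR <= 0.1."""
    cfg = SimulationConfig(
        seed=5,
        effect_single=4.0,
        n_per_class={"null": 1500, "gluc_only": 150},
        n_housekeeping=100,
    )
    cm, truth = simulate_counts(cfg)
    de = nb_wald_test(cm, "nt", "gluc")
    induced = set(call_differential(de)["induced"])
    planted = {g for g, c in truth.gene_class.items() if c == "gluc_only"}
    tp = len(induced & planted)
    assert tp / len(planted) >= 0.9
    assert (len(induced) - tp) / max(len(induced), 1) <= 0.1


# ------------------------------------------------------------- call gating


def test_call_differential_boundary_semantics():
    de = pd.DataFrame(
        {
            "base_mean": [10.0, 10.0, 10.0],
            "log2fc": [np.log2(1.5), 3.0, -np.log2(1.5)],
            "p": [0.01, 0.01, 0.01],
            "padj": [0.05, 0.2, 0.05],
            "untestable": [False] * 3,
        },
        index=["boundary", "high_fc_bad_fdr", "repressed"],
    )
    calls = call_differential(de)
    assert "boundary" in calls["induced"]          # >= / <= inclusive
    assert "high_fc_bad_fdr" not in calls["induced"]
    assert "repressed" in calls["repressed"]


def test_called_sets_nest_with_fdr_level():
    rng = np.random.default_rng(3)
    de = pd.DataFrame(
        {
            "base_mean": 10.0,
            "log2fc": rng.normal(1, 1, 200),
            "p": rng.uniform(size=200),
            "untestable": False,
        }
    )
    de["padj"] = bh_adjust(de["p"])
    from assistload.diffexpr import AnalysisThresholds

    loose = call_differential(de, AnalysisThresholds(padj_max=0.2))["induced"]
    strict = call_differential(de, AnalysisThresholds(padj_max=0.05))["induced"]
    assert set(strict) <= set(loose)


def test_total_tag_factors_proportional_to_depth():
    counts = pd.DataFrame({"a": [10, 20], "b": [30, 60]})
    f = total_tag_factors(counts)
    assert f["b"] / f["a"] == pytest.approx(3.0)
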