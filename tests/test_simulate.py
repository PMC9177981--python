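"""The synthetic-data generator: planted classes, genome layout, coverage."""

import numpy as np
import pandas as pd
import pytest

from assistload.counts import CONDITIONS
from assistload.motifs import pwm_logodds_scan
from assistload.pwm import cre_pwm, gre_pwm
from assistload.simulate import (
    SimulationConfig,
    class_condition_means,
    simulate_counts,
    simulate_coverage,
    simulate_experiment,
    simulate_genome,
)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"antagonism_residual": 1.0},
        {"synergy_factor": 1.0},
        {"dispersion": -0.1},
        {"cluster_span": 26_000},
        {"n_per_class": {"null": 0}},
        # infeasible packing: 5 units of 600 bp will not fit in 2 kb
        {"cluster_span": 2000, "units_per_cluster_range": (2, 5)},
    ],
)
def test_config_validation(kwargs):
    with pytest.raises(ValueError):
        SimulationConfig(**kwargs)


def test_config_yaml_round_trip(tmp_path):
    cfg = SimulationConfig(seed=3, n_clusters=9, synergy_factor=2.0)
    cfg.to_yaml(tmp_path / "cfg.yaml")
    assert SimulationConfig.from_yaml(tmp_path / "cfg.yaml") == cfg


def test_class_means_follow_definitions():
    cfg = SimulationConfig(effect_single=3.0, synergy_factor=1.5)
    m = class_condition_means("synergistic", 100.0, cfg)
    # baseline 100, single delta 200 each, dual = 100 + 1.5 * 400 = 700
    assert m == {"nt": 100.0, "gluc": 300.0, "cort": 300.0, "dual": 700.0}
    add = class_condition_means("additive", 100.0, cfg)
    assert add["dual"] == 500.0
    antag = class_condition_means("antag_by_cort", 100.0,
                                  SimulationConfig(antagonism_residual=0.1))
    assert antag["gluc"] == 300.0 and antag["dual"] == pytest.approx(120.0)


def test_no_effect_degenerate_case():
    cfg = SimulationConfig(effect_single=1.0, n_per_class={"gluc_only": 5,
                                                          "synergistic": 5})
    _, truth = simulate_counts(cfg)
    em = truth.expected_means
    assert (em.nunique(axis=1) == 1).all()  # identical means in all conditions


def test_counts_determinism():
    cfg = SimulationConfig(seed=12, n_per_class={"null": 50, "synergistic": 50})
    cm1, _ = simulate_counts(cfg)
    cm2, _ = simulate_counts(cfg)
    pd.testing.assert_frame_equal(cm1.counts, cm2.counts)


def test_counts_match_nb_moments():
    """Empirical mean and variance track mu and mu + alpha mu^2."""
    cfg = SimulationConfig(seed=4, dispersion=0.05,
                           n_per_class={"null": 2000}, n_housekeeping=0)
    cm, truth = simulate_counts(cfg)
    mu = truth.expected_means["nt"].to_numpy()  # null: same mean everywhere
    vals = cm.counts.to_numpy()  # 12 samples per gene, all same mean
    emp_mean = vals.mean(axis=1)
    emp_var = vals.var(axis=1, ddof=1)
    expected_var = mu + cfg.dispersion * mu**2
    assert abs(np.mean(emp_mean / mu) - 1) < 0.1
    assert abs(np.mean(emp_var / expected_var) - 1) < 0.1


def test_every_gene_in_exactly_one_class():
    cfg = SimulationConfig(seed=2, n_per_class={"null": 30, "additive": 30})
    cm, truth = simulate_counts(cfg)
    assert set(cm.features) == set(truth.gene_class)


def test_genome_unit_range_collapse():
    cfg = SimulationConfig(seed=9, n_clusters=9, units_per_cluster_range=(2, 2))
    ann, truth = simulate_genome(cfg)
    assert all(n == 2 for n in truth.unit_counts.values())


def test_genome_structure_invariants(small_exp):
    ann, truth = small_exp.annotation, small_exp.truth
    # conservation: every planted GRBS carries exactly one site class
    assert len(ann.grbs) == len(truth.site_class) == small_exp.config.n_clusters
    classes = pd.Series(truth.site_class)
    assert set(classes.unique()) == {"assisted", "unassisted", "inactive"}
    # every cluster holds >= 2 non-overlapping units inside genome bounds
    units_by_cluster = pd.Series(truth.cluster_membership)
    assert (units_by_cluster.value_counts() >= 2).all()
    by_pos = sorted(ann.dhs, key=lambda u: u.start)
    for a, b in zip(by_pos, by_pos[1:]):
        assert a.end <= b.start
    for m in truth.planted_motifs:
        assert 0 <= m.interval.start < m.interval.end <= ann.length


def test_planted_weak_gre_scores_below_strong(small_exp):
    truth = small_exp.truth
    genome = small_exp.annotation.sequence
    gre = gre_pwm()
    scores = {"assisted": [], "unassisted": []}
    site_by_cluster = truth.site_of_cluster
    grbs = {s.name: s for s in small_exp.annotation.grbs}
    for m in truth.planted_motifs:
        if m.pwm_name != "GRE":
            continue
        cls = None
        for cid, sid in site_by_cluster.items():
            if grbs[sid].contains("chrS", m.interval.center):
                cls = truth.site_class[sid]
        if cls in scores:
            scores[cls].append(m.logodds)
    assert scores["assisted"] and scores["unassisted"]
    assert max(scores["assisted"]) < min(scores["unassisted"])


def test_planted_motifs_rescanned_exactly(small_exp):
    """Round trip: rescanning every planted interval recovers the planted
    strand, position and log-odds for 100% of instances."""
    genome = small_exp.annotation.sequence
    pwms = {"GRE": gre_pwm(), "CRE": cre_pwm()}
    for m in small_exp.truth.planted_motifs:
        seq = genome[m.interval.start : m.interval.end]
        hits = pwm_logodds_scan(seq, pwms[m.pwm_name], threshold_offset=3)
        best = max(hits, key=lambda h: h.score)
        assert best.start == 0
        assert best.strand == m.strand
        assert best.score == pytest.approx(m.logodds, abs=1e-6)


def test_coverage_rule_table_and_labels(small_exp):
    cfg = small_exp.config
    with pytest.raises(ValueError):
        simulate_coverage(small_exp.annotation, small_exp.truth, "fed", "GR", cfg)
    with pytest.raises(ValueError):
        simulate_coverage(small_exp.annotation, small_exp.truth, "nt", "ATAC", cfg)


def test_gr_track_is_pure_background_without_hormone(small_exp):
    """GR in the untreated condition has no planted enrichment anywhere."""
    cfg = small_exp.config
    track = small_exp.coverage("GR", "nt")
    arr = track.data["chrS"]
    expected_total = cfg.background_rate * len(arr)
    assert abs(arr.sum() / expected_total - 1) < 0.05
    # site windows look like background, not peaks
    from assistload.coverage import quantify_tags

    window = quantify_tags(small_exp.annotation.grbs, track, 200)
    assert window.mean() < 2.5 * cfg.background_rate * 400


def test_track_total_matches_planted_mass():
    """Total tags = background + planted peak areas, within 5% over seeds."""
    for seed in range(5):
        cfg = SimulationConfig(seed=seed, n_clusters=9,
                               n_per_class={"null": 10})
        ann, truth = simulate_genome(cfg)
        track = simulate_coverage(ann, truth, "dual", "GR", cfg)
        amp = cfg.peak_enrichment * cfg.background_rate
        h = cfg.kernel_halfwidth_tf
        n_active = sum(
            1 for cls in truth.site_class.values() if cls != "inactive"
        )
        expected = cfg.background_rate * ann.length + n_active * amp * h
        assert abs(track.total_tags / expected - 1) < 0.05


def test_assisted_sites_gain_gr_in_dual_vs_cort(small_exp):
    from assistload.coverage import quantify_tags

    truth = small_exp.truth
    assisted = [
        s for s in small_exp.annotation.grbs
        if truth.site_class[s.name] == "assisted"
    ]
    cort = quantify_tags(assisted, small_exp.coverage("GR", "cort"), 200)
    dual = quantify_tags(assisted, small_exp.coverage("GR", "dual"), 200)
    assert (dual > cort).mean() >= 0.95


def test_experiment_determinism_and_linkage(small_config, small_exp):
    exp2 = simulate_experiment(small_config)
    pd.testing.assert_frame_equal(small_exp.counts.counts, exp2.counts.counts)
    assert small_exp.annotation.sequence == exp2.annotation.sequence
    t1 = small_exp.coverage("H3K27ac", "gluc", replicate=1)
    t2 = exp2.coverage("H3K27ac", "gluc", replicate=1)
    assert np.array_equal(t1.data["chrS"], t2.data["chrS"])
    # genes attached to assisted clusters are planted synergistic
    for cid, cls in small_exp.truth.cluster_class.items():
        gene = small_exp.truth.gene_of_cluster[cid]
        expected = {"assisted": "synergistic", "unassisted": "cort_only",
                    "inactive": "null"}[cls]
        assert small_exp.truth.gene_class[gene] == expected


def test_rng_streams_independent_across_assays(small_config):
    """Adding an assay does not perturb another assay's draws."""
    exp = simulate_experiment(small_config)
    before = exp.coverage("GR", "cort").data["chrS"].copy()
    _ = exp.coverage("H3K27ac", "cort")
    after = exp.coverage("GR", "cort").data["chrS"]
    assert np.array_equal(before, after)
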