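"""Ground-truthed synthetic data for the four-condition hormone experiment.

Two generators share one master seed:

* ``simulate_counts`` draws negative-binomial RNA-seq-like counts for genes
  in planted interaction classes (null, single-hormone, additive,
  synergistic, antagonized), under the mean/dispersion parameterization
  variance = mu + alpha * mu^2;
* ``simulate_genome`` lays out a synthetic chromosome of enhancer clusters
  (>= 2 DHS units around a focal GR binding site), plants weak/strong GRE
  and CRE motif instances encoding assisted-loading logic, and
  ``simulate_coverage`` renders condition-dependent ChIP/DNase coverage
  tracks on top of Poisson background.

Every draw comes from a dedicated RNG stream derived from the master seed
(one stream for counts, one for the genome, one per assay/condition/
replicate track), so identical configs give bit-identical outputs and
adding an assay never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .counts import CONDITIONS, CountMatrix
from .coverage import CoverageTrack
from .intervals import GenomicInterval, write_bed
from .pwm import PWM, cre_pwm, gre_pwm, reverse_complement

GENE_CLASSES = (
    "null",
    "gluc_only",
    "cort_only",
    "additive",
    "synergistic",
    "antag_by_cort",
    "antag_by_gluc",
)
SITE_CLASSES = ("assisted", "unassisted", "inactive")
ASSAYS = ("H3K27ac", "GR", "CREB", "DNase")

#: H3K27ac activation multipliers per cluster class and condition: assisted
#: clusters are activated by glucagon alone and further in the dual
#: treatment; unassisted clusters respond to corticosterone only.
_K27_RULE = {
    "assisted": {"nt": 0.4, "gluc": 1.0, "cort": 0.4, "dual": 1.5},
    "unassisted": {"nt": 0.4, "gluc": 0.4, "cort": 1.0, "dual": 1.0},
    "inactive": {"nt": 0.4, "gluc": 0.4, "cort": 0.4, "dual": 0.4},
}


@dataclass
class SimulationConfig:
    """All data-generating assumptions, with the study's default conditions."""

    seed: int = 0
    replicates: int = 3
    n_per_class: dict = field(
        default_factory=lambda: {
            "null": 1000,
            "gluc_only": 200,
            "cort_only": 200,
            "additive": 200,
            "synergistic": 200,
            "antag_by_cort": 200,
            "antag_by_gluc": 200,
        }
    )
    baseline_mean: float = 100.0
    baseline_sigma: float = 0.5    # lognormal spread of per-gene baselines
    dispersion: float = 0.05       # NB alpha; variance = mu + alpha mu^2
    #: hormone-unresponsive housekeeping background: a block of highly
    #: expressed null genes that dominates the library mass, so per-sample
    #: totals stay nearly constant across conditions (as in real
    #: transcriptomes, where responsive genes are a small mass fraction)
    n_housekeeping: int = 500
    housekeeping_mean: float = 1000.0
    effect_single: float = 3.0     # fold change of an inducing single hormone
    synergy_factor: float = 1.5    # dual delta = factor * sum of single deltas
    antagonism_residual: float = 0.1  # fraction of the single delta kept in dual

    chrom: str = "chrS"
    n_clusters: int = 150
    units_per_cluster_range: tuple = (2, 5)
    cluster_span: int = 12_000     # bp containing a cluster's units (<= 25 kb)
    #: gap between clusters; exceeds the 12.5 kb cluster window so a focal
    #: site never recruits units from a neighboring cluster
    intercluster_gap: int = 13_000
    unit_length: int = 600
    margin: int = 5_000
    site_halfwidth: int = 100      # GRBS interval = focal unit center +/- this

    motif_score_strong: float = 0.89  # target normalized log-odds, strong GRE
    motif_score_weak: float = 0.78    # target normalized log-odds, weak GRE
    cre_in_site_fraction: float = 1 / 3  # assisted sites with a CRE inside

    peak_enrichment: float = 5.0   # summit fold over background coverage
    background_rate: float = 0.05  # tags per bp
    assisted_cort_fraction: float = 0.3  # GR strength at assisted sites, cort only
    kernel_halfwidth_tf: int = 300
    kernel_halfwidth_broad: int = 700

    def __post_init__(self):
        positives = {
            "replicates": self.replicates,
            "baseline_mean": self.baseline_mean,
            "effect_single": self.effect_single,
            "n_clusters": self.n_clusters,
            "cluster_span": self.cluster_span,
            "unit_length": self.unit_length,
            "peak_enrichment": self.peak_enrichment,
            "background_rate": self.background_rate,
        }
        for name, value in positives.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if any(n <= 0 for n in self.n_per_class.values()):
            raise ValueError("class counts must be strictly positive")
        if not 0 <= self.antagonism_residual < 1:
            raise ValueError("antagonism_residual must lie in [0, 1)")
        if self.synergy_factor <= 1:
            raise ValueError("synergy_factor must exceed 1")
        if self.cluster_span > 25_000:
            raise ValueError("cluster_span must not exceed 2 x 12,500 bp")
        lo, hi = self.units_per_cluster_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid units_per_cluster_range")
        if self.cluster_span < hi * (self.unit_length + 200):
            raise ValueError(
                "infeasible packing: cluster_span too small for "
                f"{hi} units of {self.unit_length} bp with 200 bp gaps"
            )
        if self.unit_length < 2 * self.site_halfwidth + 100:
            raise ValueError("unit_length too small to host a focal site")

    @property
    def genome_length(self) -> int:
        slot = self.cluster_span + self.intercluster_gap
        return 2 * self.margin + self.n_clusters * slot

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["units_per_cluster_range"] = list(self.units_per_cluster_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["units_per_cluster_range"] = tuple(d["units_per_cluster_range"])
        return cls(**d)


@dataclass(frozen=True)
class PlantedMotif:
    interval: GenomicInterval
    pwm_name: str
    strand: str
    logodds: float


@dataclass
class GroundTruth:
    """Planted structure the analysis stages are expected to recover."""

    gene_class: dict = field(default_factory=dict)
    site_class: dict = field(default_factory=dict)
    planted_motifs: list = field(default_factory=list)
    cluster_membership: dict = field(default_factory=dict)  # unit -> cluster
    cluster_class: dict = field(default_factory=dict)
    cre_unit_ids: set = field(default_factory=set)
    gene_of_cluster: dict = field(default_factory=dict)
    site_of_cluster: dict = field(default_factory=dict)
    expected_means: pd.DataFrame | None = None
    unit_counts: dict = field(default_factory=dict)  # cluster -> planted units


@dataclass
class GenomeAnnotation:
    chrom: str
    length: int
    sequence: str
    tss: list = field(default_factory=list)
    dhs: list = field(default_factory=list)
    grbs: list = field(default_factory=list)
    ctcf: list = field(default_factory=list)

    @property
    def genome(self) -> dict:
        return {self.chrom: self.sequence}


def _rng(seed: int, *key) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    return np.random.Generator(np.random.PCG64(ss))


def class_condition_means(cls: str, baseline: float, config: SimulationConfig):
    """Expected NB mean per condition for one gene of the given class."""
    b, e = baseline, config.effect_single
    delta = b * (e - 1.0)
    if cls == "null":
        means = (b, b, b, b)
    elif cls == "gluc_only":
        means = (b, b * e, b, b * e)
    elif cls == "cort_only":
        means = (b, b, b * e, b * e)
    elif cls == "additive":
        means = (b, b * e, b * e, b + 2 * delta)
    elif cls == "synergistic":
        means = (b, b * e, b * e, b + config.synergy_factor * 2 * delta)
    elif cls == "antag_by_cort":
        means = (b, b * e, b, b + config.antagonism_residual * delta)
    elif cls == "antag_by_gluc":
        means = (b, b, b * e, b + config.antagonism_residual * delta)
    else:
        raise ValueError(f"unknown gene class {cls!r}")
    return dict(zip(CONDITIONS, means))


def simulate_counts(
    config: SimulationConfig, gene_table: pd.DataFrame | None = None
):
    """Draw the four-condition count matrix with planted gene classes.

    ``gene_table`` (index = gene ids, column ``cls``) lets the caller
    prepend genes tied to genomic clusters; it is padded to the configured
    per-class totals.  Returns (CountMatrix, GroundTruth) where the truth
    carries the class map and the exact expected means used.
    """
    rng = _rng(config.seed, 0)
    rows = []
    if gene_table is not None:
        rows.extend(zip(gene_table.index, gene_table["cls"]))
    existing = pd.Series([c for _, c in rows]).value_counts()
    i = 0
    for cls in GENE_CLASSES:
        target = config.n_per_class.get(cls, 0)
        have = int(existing.get(cls, 0))
        for _ in range(max(target - have, 0)):
            rows.append((f"g{i:05d}", cls))
            i += 1
    for j in range(config.n_housekeeping):
        rows.append((f"hk{j:05d}", "null"))
    gene_ids = [g for g, _ in rows]
    classes = [c for _, c in rows]

    n_regular = len(gene_ids) - config.n_housekeeping
    mean_of = np.concatenate(
        [
            np.full(n_regular, config.baseline_mean),
            np.full(config.n_housekeeping, config.housekeeping_mean),
        ]
    )
    baselines = rng.lognormal(
        mean=np.log(mean_of) - config.baseline_sigma**2 / 2.0,
        sigma=config.baseline_sigma,
        size=len(gene_ids),
    )
    mean_rows = [
        class_condition_means(cls, b, config)
        for cls, b in zip(classes, baselines)
    ]
    expected = pd.DataFrame(mean_rows, index=gene_ids)[list(CONDITIONS)]
    if (expected.to_numpy() <= 0).any():
        raise ValueError("configuration produces non-positive expected means")

    samples = [
        f"{cond}_rep{r + 1}" for cond in CONDITIONS for r in range(config.replicates)
    ]
    mu = np.repeat(expected.to_numpy(), config.replicates, axis=1)
    if config.dispersion > 0:
        n = 1.0 / config.dispersion
        counts = rng.negative_binomial(n, n / (n + mu))
    else:
        counts = rng.poisson(mu)
    lengths = pd.Series(
        np.round(rng.lognormal(np.log(2000), 0.5, len(gene_ids))).astype(int) + 1,
        index=gene_ids,
    )
    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=samples),
        {s: s.rsplit("_rep", 1)[0] for s in samples},
        lengths=lengths,
    )
    truth = GroundTruth(
        gene_class=dict(zip(gene_ids, classes)), expected_means=expected
    )
    return cm, truth


def degrade_to_target(pwm: PWM, target_norm: float):
    """Degrade the consensus sequence, one least-costly substitution at a
    time, until its log-odds is as close as possible to
    target_norm * consensus score.

    Mirrors the notion of a 'weaker' motif instance with a measurable
    strength knob; returns (sequence, log-odds score).
    """
    lom = pwm.log_odds
    cons_idx = list(lom.argmax(axis=0))
    score = float(lom.max(axis=0).sum())
    target = target_norm * pwm.consensus_score
    # (loss, position, replacement base index), cheapest degradations first
    options = []
    for pos in range(pwm.length):
        col = lom[:, pos]
        order = np.argsort(col)[::-1]
        loss = float(col[order[0]] - col[order[1]])
        if loss > 1e-9:
            options.append((loss, pos, int(order[1])))
    options.sort()
    seq = cons_idx[:]
    for loss, pos, alt in options:
        if abs(score - loss - target) >= abs(score - target):
            break
        seq[pos] = alt
        score -= loss
    return "".join("ACGT"[i] for i in seq), score


def simulate_genome(config: SimulationConfig):
    """Lay out enhancer clusters and plant motif instances on a synthetic
    chromosome.  Returns (GenomeAnnotation, GroundTruth)."""
    rng = _rng(config.seed, 1)
    gre, cre = gre_pwm(), cre_pwm()
    strong_seq, strong_score = degrade_to_target(gre, config.motif_score_strong)
    weak_seq, weak_score = degrade_to_target(gre, config.motif_score_weak)
    cre_seq, cre_score = degrade_to_target(cre, 0.90)

    length = config.genome_length
    seq_arr = np.frombuffer(b"ACGT", dtype=np.uint8)[
        rng.integers(0, 4, size=length)
    ].copy()

    ann = GenomeAnnotation(config.chrom, length, "")
    truth = GroundTruth()
    chrom = config.chrom
    slot = config.cluster_span + config.intercluster_gap
    half_site = config.site_halfwidth

    def plant(seq: str, start: int, pwm_name: str, score: float):
        strand = str(rng.choice(["+", "-"]))
        written = seq if strand == "+" else reverse_complement(seq)
        seq_arr[start : start + len(seq)] = np.frombuffer(
            written.encode(), dtype=np.uint8
        )
        truth.planted_motifs.append(
            PlantedMotif(
                GenomicInterval(chrom, start, start + len(seq)),
                pwm_name,
                strand,
                score,
            )
        )

    lo, hi = config.units_per_cluster_range
    for i in range(config.n_clusters):
        cls = SITE_CLASSES[i % len(SITE_CLASSES)]
        cluster_id = f"cl{i:03d}"
        cstart = config.margin + i * slot
        cend = cstart + config.cluster_span
        n_u = int(rng.integers(lo, hi + 1))
        slot_w = config.cluster_span / n_u
        units = []
        for j in range(n_u):
            slack = max((slot_w - config.unit_length - 200) / 2.0, 0.0)
            jitter = float(rng.uniform(-slack, slack)) if slack > 0 else 0.0
            ucenter = int(cstart + slot_w * j + slot_w / 2.0 + jitter)
            unit = GenomicInterval(
                chrom,
                ucenter - config.unit_length // 2,
                ucenter - config.unit_length // 2 + config.unit_length,
                name=f"u{i:03d}_{j}",
            )
            units.append(unit)
            truth.cluster_membership[unit.name] = cluster_id
        ann.dhs.extend(units)

        focal_idx = int(rng.integers(n_u))
        focal = units[focal_idx]
        site_id = f"grbs{i:03d}"
        site = GenomicInterval(
            chrom,
            focal.center - half_site,
            focal.center + half_site,
            name=site_id,
        )
        ann.grbs.append(site)
        truth.site_class[site_id] = cls
        truth.cluster_class[cluster_id] = cls
        truth.site_of_cluster[cluster_id] = site_id
        truth.unit_counts[cluster_id] = n_u

        if cls == "assisted":
            plant(weak_seq, site.center - gre.length // 2, "GRE", weak_score)
            cre_starts = []
            if rng.random() < config.cre_in_site_fraction:
                sign = 1 if rng.random() < 0.5 else -1
                off = sign * int(rng.integers(15, half_site - cre.length - 2))
                cre_starts.append(site.center + off - cre.length // 2)
            sibling = units[(focal_idx + 1) % n_u]
            if sibling.name == focal.name:
                cre_starts.append(focal.center + 200 - cre.length // 2)
            else:
                off = int(
                    rng.integers(
                        -(config.unit_length // 2 - 20),
                        config.unit_length // 2 - 20,
                    )
                )
                cre_starts.append(sibling.center + off - cre.length // 2)
            for pos in cre_starts:
                plant(cre_seq, pos, "CRE", cre_score)
                for u in units:  # units hosting a CRE get CREB signal
                    if u.start <= pos < u.end:
                        truth.cre_unit_ids.add(u.name)
        elif cls == "unassisted":
            plant(strong_seq, site.center - gre.length // 2, "GRE", strong_score)

        strand = "+" if i % 2 == 0 else "-"
        gene_id = f"g_{cluster_id}"
        if strand == "+":
            tpos = cend + 1500
        else:
            tpos = cstart - 1500
        ann.tss.append(
            GenomicInterval(chrom, tpos, tpos + 1, strand=strand, name=gene_id)
        )
        truth.gene_of_cluster[cluster_id] = gene_id
        truth.gene_class[gene_id] = {
            "assisted": "synergistic",
            "unassisted": "cort_only",
            "inactive": "null",
        }[cls]
        ann.ctcf.append(
            GenomicInterval(chrom, cstart - 400, cstart - 200, name=f"ctcf{i:03d}_L")
        )
        ann.ctcf.append(
            GenomicInterval(chrom, cend + 200, cend + 400, name=f"ctcf{i:03d}_R")
        )

    ann.sequence = seq_arr.tobytes().decode("ascii")
    return ann, truth


def _gr_strength(cls: str, condition: str, config: SimulationConfig) -> float:
    if cls == "assisted":
        return {"cort": config.assisted_cort_fraction, "dual": 1.0}.get(
            condition, 0.0
        )
    if cls == "unassisted":
        return {"cort": 1.0, "dual": 1.0}.get(condition, 0.0)
    return 0.0


def simulate_coverage(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    condition: str,
    assay: str,
    config: SimulationConfig,
    replicate: int = 0,
) -> CoverageTrack:
    """Render one coverage track: Poisson background plus triangular peaks
    following the assisted-loading rule table.

    GR binds unassisted sites equally in cort and dual but assisted sites
    only weakly without glucagon; CREB binds CRE-bearing units in gluc and
    dual; H3K27ac rises across assisted-cluster units already under
    glucagon alone; DNase marks every cluster unit in all conditions.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if assay not in ASSAYS:
        raise ValueError(f"unknown assay {assay!r}")
    rng = _rng(
        config.seed, 2, ASSAYS.index(assay), CONDITIONS.index(condition), replicate
    )
    arr = rng.poisson(config.background_rate, annotation.length).astype(np.float64)

    events = []  # (center, strength, kernel halfwidth)
    if assay == "GR":
        for site in annotation.grbs:
            m = _gr_strength(truth.site_class[site.name], condition, config)
            if m > 0:
                events.append((site.center, m, config.kernel_halfwidth_tf))
    elif assay == "CREB":
        if condition in ("gluc", "dual"):
            for unit in annotation.dhs:
                if unit.name in truth.cre_unit_ids:
                    events.append((unit.center, 1.0, config.kernel_halfwidth_tf))
    elif assay == "H3K27ac":
        for unit in annotation.dhs:
            cls = truth.cluster_class[truth.cluster_membership[unit.name]]
            m = _K27_RULE[cls][condition]
            events.append((unit.center, m, config.kernel_halfwidth_broad))
    elif assay == "DNase":
        for unit in annotation.dhs:
            events.append((unit.center, 1.0, config.kernel_halfwidth_broad))

    amp0 = config.peak_enrichment * config.background_rate
    for center, strength, h in sorted(events):
        xs = np.arange(max(center - h + 1, 0), min(center + h, annotation.length))
        expected = amp0 * strength * (1.0 - np.abs(xs - center) / h)
        arr[xs[0] : xs[-1] + 1] += rng.poisson(np.maximum(expected, 0.0))
    return CoverageTrack({annotation.chrom: arr})


@dataclass
class SimulatedExperiment:
    """Everything one seed generates: counts, genome, truth, lazy tracks."""

    config: SimulationConfig
    counts: CountMatrix
    annotation: GenomeAnnotation
    truth: GroundTruth

    def coverage(self, assay: str, condition: str, replicate: int = 0):
        return simulate_coverage(
            self.annotation, self.truth, condition, assay, self.config, replicate
        )

    def tracks(self, assay: str, replicates: int | None = None):
        """{sample -> CoverageTrack} over all conditions, plus the
        sample -> condition map, ready for site_counts."""
        reps = replicates or self.config.replicates
        tracks, conditions = {}, {}
        for cond in CONDITIONS:
            for r in range(reps):
                sample = f"{cond}_rep{r + 1}"
                tracks[sample] = self.coverage(assay, cond, r)
                conditions[sample] = cond
        return tracks, conditions


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate the full linked experiment: genome first (its clusters name
    genes with known crosstalk classes), then counts padded to the
    configured class totals."""
    annotation, truth = simulate_genome(config)
    gene_table = pd.DataFrame(
        {"cls": [truth.gene_class[g.name] for g in annotation.tss]},
        index=[g.name for g in annotation.tss],
    )
    cm, counts_truth = simulate_counts(config, gene_table)
    truth.gene_class = counts_truth.gene_class
    truth.expected_means = counts_truth.expected_means
    return SimulatedExperiment(config, cm, annotation, truth)


def write_experiment(exp: SimulatedExperiment, outdir) -> None:
    """Write counts, annotation, ground truth and config as plain text."""
    from pathlib import Path
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp.counts.to_tsv(outdir / "counts.tsv", outdir / "conditions.tsv")
    write_bed(exp.annotation.tss, outdir / "tss.bed")
    write_bed(exp.annotation.dhs, outdir / "dhs.bed")
    write_bed(exp.annotation.grbs, outdir / "grbs.bed")
    write_bed(exp.annotation.ctcf, outdir / "ctcf.bed")
    SeqIO.write(
        [SeqRecord(Seq(exp.annotation.sequence), id=exp.annotation.chrom,
                   description="")],
        outdir / "genome.fa",
        "fasta",
    )
    pd.Series(exp.truth.gene_class, name="cls").rename_axis("gene").to_csv(
        outdir / "gene_truth.tsv", sep="\t"
    )
    pd.Series(exp.truth.site_class, name="cls").rename_axis("site").to_csv(
        outdir / "site_truth.tsv", sep="\t"
    )
    exp.config.to_yaml(outdir / "config.yaml")
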