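# assistload

Hormone-crosstalk regulatory genomics at desk scale.

When fasting hormones act together, hepatocytes do not simply add their
responses: glucagon and glucocorticoids **synergistically** induce
gluconeogenic genes, and the mechanism is enhancer-level *assisted
loading* — the glucagon-activated factor CREB binds and activates an
enhancer (raising H3K27ac and accessibility), which lets the
glucocorticoid receptor (GR) bind a weak GRE it could not occupy on its
own. `assistload` implements the complete analysis stack for this kind of
four-condition (nt / gluc / cort / dual) experiment:

- **Differential expression & binding** — a compact DESeq2-style
  negative-binomial Wald test: median-of-ratios size factors (or total-tag
  normalization for TF ChIP), method-of-moments dispersions shrunk to a
  mean-dispersion trend, Benjamini–Hochberg FDR. Calls use the standard
  gates: linear fold change ≥ 1.5 and adjusted p ≤ 0.05.
- **Crosstalk classification** — a gene is *synergistic* when it is induced
  in dual vs each of nt, gluc and cort **and** its dual increase exceeds
  the sum of the single-treatment increases (on mean RPKM); *antagonized*
  when one hormone's induction is significantly dampened in the dual
  treatment. Plus k-means pattern clustering (k = 5) and set-overlap
  summaries with hypergeometric enrichment.
- **ChIP-seq site analysis** — a simplified local-Poisson peak caller,
  replicate-reproducible site filtering, differential GR binding, and the
  assisted/unassisted GRBS classification (assisted: binding increased in
  dual vs cort; unassisted: cort-increased but not further increased).
- **Motifs** — PWM log-odds scanning of both strands with the relaxed
  threshold convention (default threshold − 3 nats), normalized motif
  scores (1.0 = consensus), occurrence fractions and inter-motif distances.
- **Enhancer clusters** — ≥ 2 DNase-hypersensitive units within ±12.5 kb of
  a focal GRBS, cluster-level GRE/CRE co-occurrence (units only, never the
  inaccessible gaps) and cluster-level signal with or without the focal unit.
- **Synthetic data** — a ground-truthed generator that plants all of the
  above: NB counts with interaction classes (null, single-hormone,
  additive, synergistic, antagonized), a synthetic chromosome of enhancer
  clusters with weak/strong GREs and CREs, and condition-dependent coverage
  tracks encoding the assisted-loading rules. Same seed ⇒ bit-identical
  outputs.

## Worked example

```bash
python examples/02_assisted_gr_sites.py
```

prints (seed 1, the default study conditions):

```
Peaks called per condition: {'nt': 0, 'gluc': 0, 'cort': 100, 'dual': 103}
GRBS classification summary: {'n_assisted': 52, 'n_unassisted': 52, 'n_cort_increased': 100, ...}
Sites gaining GR binding under glucagon alone: 0 (glucagon by itself does not recruit GR)

Mean GRE motif score (1.0 = consensus):
  unassisted sites: 0.892  (strong GRE)
  assisted sites:   0.784  (weak GRE)
CRE occurrence: 33% of assisted vs 17% of unassisted sites
```

GR only binds after corticosterone (no nt/gluc peaks); of the sites it
binds, the *assisted* ones gain further binding when glucagon is added,
carry a measurably weaker GRE (0.784 vs 0.892 — GR needs help there) and
are enriched for the CREB motif that supplies that help.
`examples/01_synergy_classification.py` does the gene-level analysis
(synergy sensitivity 0.85, precision 0.81 against the planted truth) and
`examples/03_enhancer_clusters.py` the cluster-level one (GRE+CRE
co-occurrence rises from 33% of focal sites to 98% of whole clusters;
glucagon raises cluster H3K27ac 1.7× even after removing the focal unit).

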