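# regact

Regulon inference and transcription-factor activity analysis for T-ALL-style
cohort studies, with the companion genomics statistics that such a study
chains together — and a synthetic-data layer that plants ground truth so the
whole pipeline is testable end to end without any external downloads.

## The scientific problem

In pediatric T-cell acute lymphoblastic leukemia (T-ALL), loss of one copy of
a regulator gene (haploinsufficiency, e.g. of the deubiquitinase *USP7*) can
shift the activity of the E-protein transcription factors (E2A/TCF3,
HEB/TCF12) that gate thymocyte development. A transcription factor's *activity*
is poorly read from its own mRNA; it is better estimated from its **regulon**
— the set of target genes it drives. This package implements that whole
reasoning chain as a reusable library:

1. **Network inference** (`regact.network`) — ARACNe-style reverse
   engineering: pairwise mutual information `I(X;Y) = Σ p(x,y) ln
   p(x,y)/(p(x)p(y))` on rank-transformed, equal-frequency-binned expression,
   a permutation-calibrated significance threshold (network-wise by default),
   and data-processing-inequality (DPI) pruning: in any triangle the edge
   with `MI < (1-ε)·min` of the other two is discarded as likely indirect.
2. **Activity scoring** (`regact.activity`) — activity of regulator *r* in
   sample *s* is the unweighted mean of the per-gene z-scored expression of
   its regulon targets; group differences are tested with an unpaired
   two-sided *t* test (pooled or Welch) and Benjamini–Hochberg adjustment.
3. **Signature enrichment** (`regact.gsea`) — E-protein target signatures
   built from knock-down log2FC profiles (down after E2A *and* HEB knock-down
   at a −0.5 log2FC threshold, up after TAL1 knock-down), signal-to-noise
   ranking `s2n = (μ₁−μ₂)/(σ₁+σ₂)` with the classic σ floor
   `max(0.2·|μ|, 0.2)`, and weighted Kolmogorov–Smirnov GSEA with
   gene-set-permutation p-values and NES.
4. **Peak co-occupancy** (`regact.peaks`) — BED6/narrowPeak parsing, ≥1-bp
   half-open overlap fractions by sorted sweep, and a genome-binned two-sided
   Fisher exact test of co-occupancy.
5. **AP-MS interactomics** (`regact.proteomics`) — protein-length-normalized
   spectral abundance, per-protein 2-cell G-tests (`G = 2 Σ O ln(O/E)`,
   χ² with 1 df) of bait vs IgG counts, and Fisher tests of interactome
   overlap.
6. **Preprocessing** (`regact.preprocess`) — FPKM normalization,
   low-expression (expressed in <10% of samples) and IQR filters, Ward
   clustering for ETP-like sample classification, and the exact two-sided
   binomial test for allele balance.
7. **Synthetic data** (`regact.synthetic`) — planted truth networks, cohorts,
   knock-down profiles, peak sets with controlled overlap, spectral counts
   with planted interactors, and binomial allele counts; every generator is
   seed-deterministic and ships a machine-readable truth record.
8. **Pipeline** (`regact.pipeline`, CLI `regact`) — orchestrates
   preprocess → network → activity → differential activity → GSEA
   (→ peak overlap → AP-MS), with plain-text stage outputs and a
   provenance-stamped report.

## Worked example

Infer a network from a development-style cohort, score activities in a
wt-vs-mut cohort in which regulator `TF01`'s activity is attenuated in the
mut group, and test differential activity:

```python
import pandas as pd
from regact import (make_truth_network, simulate_expression_cohort, infer_regulons,
                    infer_activity, differential_activity, NetworkConfig)

net = make_truth_network(n_regulators=5, n_targets_per_regulator=30, n_genes=400, seed=1)
dev, _ = simulate_expression_cohort(
    net, {"dev": 200}, {"dev": {r: 0.0 for r in net.regulators}},
    noise_sd=0.5, seed=2, activity_sd=1.0)
profiles = {
    "wt":  {r: (1.0 if r == "TF01" else 0.0) for r in net.regulators},
    "mut": {r: (-1.0 if r == "TF01" else 0.0) for r in net.regulators},
}
expr, truth = simulate_expression_cohort(
    net, {"wt": 20, "mut": 20}, profiles, noise_sd=0.5, seed=3, activity_sd=0.5)

regulons = infer_regulons(dev, net.regulators, NetworkConfig(seed=4))
activity = infer_activity(expr, regulons)
table = differential_activity(activity, pd.Series(truth.group_of), group1="wt", group2="mut")
print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
```

which prints

```
regulator  delta_activity  t_stat        p    adj_p
     TF01            1.52    10.2 1.76e-12 8.79e-12
     TF04           0.309    1.46    0.153    0.336
     TF02           0.303     1.3    0.201    0.336
     TF05           0.139    0.64    0.526    0.658
     TF03          0.0379    0.17    0.866    0.866
```

The attenuated regulator tops the table with a large positive activity
difference (wt − mut ≈ 1.5, close to the planted gap of 2 after z-scoring
shrinkage) and a vanishing p-value, while the four unperturbed regulators are
indistinguishable from the null — the volcano-plot readout the analysis is
built to produce.

The same flow runs end to end from a YAML config:

```bash
regact run-all --config config.yaml       # stages under outdir/00_inputs ... 07_report
regact benchmark --seed 7 --out bench.tsv # score every stage against planted truth
```

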