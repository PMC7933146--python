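# Methods

This note documents the models and estimators implemented in `regact`, the
parameters that matter, the numerical conventions, and the limits of what the
synthetic benchmarks demonstrate.

## Generative model of the synthetic cohorts

All benchmarks run against data with planted ground truth. A truth network
assigns each of `k` regulators `m` targets drawn from a shared gene pool,
each edge carrying an effect size (uniform in [0.5, 1.5] by default) and a
sign (+1 activation; a configurable fraction −1 repression). Consecutive
regulators share `round(overlap_fraction · m)` targets, which lets signature
construction exercise genes co-regulated by two factors.

Expression is generated on log2 scale. Regulator activity in sample `s` is
the sample's group profile value plus optional per-sample Gaussian jitter
(`activity_sd`); a target's expression is `Σ_r sign·effect·activity_r(s)`
plus `N(0, noise_sd)` noise; non-targets are pure noise; a regulator's own
transcript tracks its activity plus noise so expression-based and
regulon-based readouts can be contrasted. Two cohort archetypes are used:

- **development cohort** — one population with continuous per-sample
  activity (`activity_sd = 1`), the reference the network is inferred from.
  Continuous activity is what makes regulator–target dependence detectable by
  mutual information and keeps distinct regulators' activities independent.
- **wt/mut cohort** — two groups in which designated regulators' mean
  activity drops by a gap (default 2: +1 vs −1) in the mut group, with
  `activity_sd = 0.5` within-group jitter and 20 samples per group.

Default sizes (10 regulators × 30 targets in 500 genes, 200 development
samples, `noise_sd = 0.5`) keep each benchmark in seconds while leaving every
statistical property measurable. These synthetic cohorts are *not* real
RNA-seq: noise is homoscedastic Gaussian on log scale, no library-size,
batch, GC or mapping artifacts, no correlated background co-expression, and
activity is exactly linear in targets. Passing benchmarks therefore
demonstrates correctness and calibration of the estimators under their own
model assumptions, not performance on real cohorts.

## Mutual-information network inference

`estimate_mi` rank-transforms each vector (average ranks, so ties share a
bin), assigns equal-frequency bins (`⌈√n⌉` by default), and returns plug-in
MI in nats over the joint histogram; constant vectors yield 0. The plug-in
estimator carries an upward bias of roughly `(b−1)²/(2n)` nats under
independence — about 0.5 nats at the default binning — which cancels in
threshold comparisons (the null shares it) but matters for ratio-based rules
(see DPI below).

`calibrate_mi_threshold` builds an empirical null by repeatedly choosing a
random gene pair and permuting one member, then returns the
`⌈(1−α)·P⌉`-th smallest of the `P` null MI values.

**Edge significance is network-wise by default.** A raw `(1−α)` quantile
admits ~α of every independent candidate pair, which with thousands of
regulator×gene candidates caps precision near 0.55 regardless of signal
strength. `infer_regulons` therefore treats α as a family-wise error rate:
the per-pair tail becomes `α / n_candidate_pairs`, and because that deep tail
is beyond the resolution of a few thousand permutations, the threshold is
read from a two-moment gamma fit to `2n·MI` of the same permutation null
(the fit was checked against a 2×10⁵-draw empirical null and is slightly
conservative at the 10⁻⁵ tail). `edge_correction="none"` restores the raw
quantile. Bootstrap consensus (`n_bootstraps`, edges kept when present in
more than `consensus_fraction` of bootstrap re-inferences) is available but
is not a substitute for multiplicity control: spurious dependence lives in
the realized sample, and bootstraps preserve it.

DPI pruning removes, from every triangle of the pre-pruning graph, the edge
with `MI < (1−ε)·min` of the other two (ε defaults to 0.1). Evaluating all
triangles against the pre-pruning graph makes the result order-independent,
and only the weakest edge of a triangle can be removed. In the indirect-chain
benchmark MI is estimated with 8 bins rather than `⌈√n⌉`: the shared plug-in
bias inflates all three MIs additively and compresses the ratio the DPI rule
compares, so coarser binning (smaller bias) is the right operating point for
ratio tests.

Regulons are regulator-centered stars; no direction or sign of regulation is
inferred; regulons below `min_regulon_size` (default 5) are dropped; the
returned set carries a provenance snapshot (estimator, bins, α, permutations,
thresholds, ε, seed).

## Activity and differential activity

Activity of regulator `r` in sample `s` is the unweighted mean of the
per-gene z-scores (sample sd, ddof 1) of its regulon targets; genes constant
across the cohort z-score to 0, and regulators with no covered target are
dropped with a warning. Unweighted averaging means repressed targets are not
sign-flipped; with signed regulons this attenuates rather than inverts the
score, a deliberate simplification.

Differential activity between two groups uses the unpaired two-sided *t*
test — pooled-variance Student by default, Welch as an option — with
`delta = mean(group1) − mean(group2)`, BH adjustment across regulators, and
rows sorted by p. The degenerate zero-variance case (both groups constant) is
defined as p = 1 when the means agree and p = 0 otherwise.

## Signature construction and GSEA

The E-protein target signature takes the intersection universe of three
knock-down log2FC profiles and keeps genes below −0.5 log2FC after knock-down
of both E-protein-like factors and strictly above 0 after knock-down of the
TAL1-like repressor (both thresholds configurable; the up-threshold has no
canonical value and defaults to the strict sign rule).

Ranking uses the GSEA signal-to-noise metric with each group σ floored at
`max(0.2·|μ|, 0.2)`; FPKM matrices are filtered at mean FPKM ≥ 1 and
log2(x+1)-transformed first; ties are broken lexicographically by gene id so
ranked lists are strictly ordered and reproducible.

The enrichment score is the signed maximum deviation of the standard weighted
KS running sum (hit increments `|metric|^p / Σ_hits |metric|^p` with p = 1,
miss decrements `1/(N−N_hits)`); the leading edge is the set members at or
before the extremum (positive ES) or at or after it (negative ES).
Significance uses gene-set permutation: the null is the ES of random
same-size gene sets, `p = (1 + #{same-sign null ≥ |ES|}) / (1 + #same-sign
null)`, `NES = ES / mean|same-sign null ES|`, and FDR is BH over the
reported sets' permutation p-values (simpler than the original NES-based
GSEA FDR; a documented deviation). Sets with fewer than `set_min = 4`
covered members are skipped and recorded. Within one `gsea` call the null is
cached per set size — correct for ranking many sets against one list, but
p-values of same-size sets then share a null; the calibration benchmark
gives every set its own permutations for exactly that reason.

## Peak co-occupancy

Intervals are BED-standard 0-based half-open; strand is ignored; duplicate
identical intervals collapse on read with a logged count. A query peak
overlaps if it intersects ≥1 bp of any reference peak ([0,100) and [100,200)
do not overlap); counting merges the reference per chromosome and uses a
searchsorted sweep, verified against an O(n·m) oracle. Significance tiles
the genome into fixed bins (default 2 kb), cross-classifies bins by
query/reference occupancy, and applies the two-sided Fisher exact test; a
zero margin yields the degenerate p = 1. The binned Fisher test is exact for
the binning null, not a peak-shuffling null; under independent placement its
p-values are near-uniform (verified by simulation).

## AP-MS interactor calling

Length-normalized abundance divides each count by protein length and
normalizes runs to proportions. Calling sums replicates per condition and
applies a per-protein 2-cell G-test (`G = 2 Σ O ln(O/E)`, +0.5 to zero
observed cells, χ² with 1 df) with expected counts proportional to the
estimated condition loading. Loading defaults to DESeq-style
median-of-ratios size factors rather than raw condition totals: when a
minority of proteins is strongly bait-enriched, raw totals absorb that
signal and set each interactor's expected bait share high enough to mask it;
the median ratio is robust to the enriched minority (`loading="total"`
retains the raw-sum behavior). A call requires both direction (normalized
bait rate above control) and significance; raw-p and BH-adjusted calls are
both emitted. Interactome overlap uses the 2×2 membership Fisher test over a
user-supplied universe.

## Preprocessing conventions

FPKM is `count / (length_kb · mapped_millions)` with column sums standing in
for mapped totals when absent. "Expressed" in the <10%-of-samples filter
means value > 0 on the matrix's own unit (configurable, e.g. FPKM ≥ 1). The
IQR filter uses linear-interpolation quartiles and a strict `>` cutoff
(default 0 drops only constant-spread genes); both filters are idempotent.
ETP-like classification sorts samples lexicographically (order-invariance),
runs Ward linkage on Euclidean distance over signature-gene expression, cuts
at `k`, and labels the higher-centroid cluster ETP-like for k = 2. Allele
balance uses the exact two-sided binomial test (minimum-likelihood method).

## Pipeline and reproducibility

`run_cohort_analysis` executes preprocess → network (or regulon load) →
activity → differential activity → signature + GSEA (→ peak overlap →
AP-MS), writing plain-text tables per stage (floats as `%.6g`) and a report
whose provenance block carries the config hash (output directory excluded),
seed, and per-file SHA-256 checksums; identical config + seed reproduces
every byte. The synthetic mode generates the network from a 200-sample
development cohort and scores activity in the wt/mut cohort, mirroring the
two-cohort design the analysis assumes. All randomness flows from
`numpy.random.default_rng` seeded per call; no global state.

## Known limitations

- The MI estimator is plug-in with fixed equal-frequency binning; no
  adaptive partitioning or analytic p-values, and MI values are
  bias-inflated (comparisons, not magnitudes, are meaningful).
- Regulon activity ignores regulation sign and MI weights (unweighted mean).
- Empirical-Bayes moderation (limma-style) of differential activity is out
  of scope; the t test matches the volcano readout the analysis targets.
- The GSEA FDR is BH over permutation p-values, not the original NES-bucket
  FDR.
- The binned Fisher test's independence null ignores peak clustering along
  real genomes; for real ChIP-seq a shuffle-based null would be more
  faithful.
- Synthetic cohorts omit the failure modes of real data listed above, so
  green benchmarks bound correctness, not real-world accuracy.
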