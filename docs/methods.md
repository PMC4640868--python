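# Methods

## Overview

`triotarget` reconstructs, as a reusable pipeline, the integrative
procedure by which a lineage transcription factor's direct transcriptional
targets are nominated: knockdown transcriptomics identifies factor-
sustained genes, ChIP-seq peak annotation identifies factor-bound genes,
and a copy-number-stratified tumor cohort identifies genes whose
expression tracks amplification of the factor's locus in primary disease.
The intersection of the three layers, per cell line, is the candidate
table. Everything downstream of quantification is in scope: the pipeline
starts from expression tables (RPKM-like units), called peak lists (BED)
and a processed cohort matrix; read mapping, RPKM computation and peak
calling are deliberately outside it.

## Knockdown response

A gene is *well measured* when its abundance is ≥ `min_abundance`
(default 1, RPKM units) in **both** the knockdown and the control
condition; all comparisons are inclusive. Well-measured genes get
r = kd/ctrl and the call

    down       r ≤ 1 − threshold      (default: r ≤ 0.75)
    up         r ≥ 1 + threshold      (default: r ≥ 1.25)
    unchanged  otherwise

with `threshold` = 0.25 ("at least 25% changed" read inclusively — a
published candidate table in this design contains ratios of exactly 0.750).
Genes failing the filter, and genes absent from a line's table, are
`not_measured`, never `unchanged`: absence of evidence is kept distinct
from evidence of no change. Down-ranks are assigned by ascending ratio
with lexicographic gene-identifier tie-breaks, a convention applied to
every ordering in the package so outputs are byte-reproducible.

Cross-line correlation operates on log₂ r (symmetric treatment of up- and
down-regulation) over the union of each line's top-100 down and up genes,
with two-sided Pearson tests Bonferroni-corrected over the number of line
pairs — the most conservative of the reasonable corrections, and
configurable. Pairs sharing fewer than 3 measured genes are reported NaN
rather than raising, since sparse overlap is an expected data condition.

## Peak-to-gene annotation

Coordinates are BED-style 0-based half-open throughout; GTF input
(1-based closed) is converted on load. A peak's reference point is its
midpoint by default, or the recorded summit when requested; the choice is
configurable because peak callers differ and the convention cannot be
recovered from a finished analysis. Distance is measured to the TSS (not
the gene body), signed and strand-oriented (positive = downstream), which
is what a TSS-distance histogram of binding sites presumes. Each peak is
assigned to the single nearest TSS on its chromosome within `window`
(default 100 kb), ties to the lexicographically first gene; the reverse
map gene → best (lowest) peak rank is emitted alongside, because the
integration layer consumes peak evidence per gene.

De novo motif discovery is replaced by scanning for the known consensus:
IUPAC patterns (`CACTY` by default; the extended `CHCTY` is equally
supported) are matched exactly on both strands, overlapping hits included,
minus-strand hits reported at plus-strand offsets. Enrichment is scored
against per-sequence nucleotide shuffles (composition-preserving), with
fold = observed/mean-shuffled and the +1-smoothed empirical p, which is
bounded below by 1/(n_shuffles + 1). This supports the downstream use the
pipeline actually makes of motifs — confirming consensus presence in peak
windows — without reimplementing discovery.

## Cohort stratification and SAM

Samples are called `amplified` when the tumor/normal copy-number ratio at
the index locus exceeds 1.5 (strict), `non_amplified` below 1.1 (strict),
otherwise indeterminate and excluded. High expression of the index gene is
the top quartile of the whole cohort, computed with the linear-
interpolation percentile convention and an inclusive cut — stated
explicitly because "top 25 percentile" is convention-sensitive at small n.
Group sizes are whatever the data yields; nothing is hard-coded.

The two-class comparison is the SAM statistic in its original form:
d_i = (x̄_A − x̄_B)/(s_i + s₀) with pooled-variance gene-wise standard
error s_i. The fudge constant s₀ is selected among the 0, 5, …, 100th
percentiles of {s_i} to minimize the coefficient of variation of the
median-absolute-deviation spread of d across quantile bins of s (bin count
adapts to gene count, capped at 100). FDR estimation uses seeded label
permutations: order statistics d_(i) are compared with their permutation
means d̄_(i); for a cutoff Δ the called set is closed upward/downward from
the first order statistic whose gap exceeds Δ, false calls are permuted
d-values beyond those cutpoints, and

    FDR(Δ) = π̂₀ · median_b(#false_b) / #called,

with π̂₀ the fraction of observed d inside the central 50% of the pooled
permuted d (capped at 1). A gene's q is the smallest FDR(Δ) over the Δ
grid at which it is called. Defaults: n_perm = 200 (100 in the repeated
calibration simulations, where 20 replicates are run), seed mandatory.
Expression declared linear is log2(x+1)-transformed on load since the
statistic assumes a roughly additive scale. The candidate gate is d > 0
and q ≤ 0.10 by default, with 0.05 available — both bounds circulate for
this design, and the package surfaces the choice rather than resolving it.

Measured behavior (recomputed by the test suite and `scripts/acceptance.py`
at every run, not quoted from elsewhere): on complete-null cohorts of 200
genes at 30 vs 60 samples the fraction of genes at q ≤ 0.05 stays well
under 10% in each of 20 replicates, and genes with a planted 1.5-SD mean
shift are recovered at q ≤ 0.10 with sensitivity far above the 0.5 floor
the suite asserts.

## GSEA

The ranking metric is signal-to-noise (μ_A − μ_B)/(σ_A + σ_B) with each σ
floored at max(0.2·|μ|, 1e−8), mirroring the desktop implementation's
documented default. The enrichment score is the signed maximum of the
weighted running sum (hits weighted |metric|^p normalized to 1 over the
set, p = 1 default; misses −1/(N − N_hit)); with p = 0 it reduces to the
classic KS statistic on set ranks, which the tests check directly.
NES = ES / mean(|same-sign permuted ES|); nominal p is one-sided empirical
with +1 smoothing; FDR follows the NES-based estimator (pooled same-sign
permutation NES vs observed NES), clipped to [0, 1]. Permutation is by
phenotype when both classes have ≥ 7 samples, otherwise by gene — below
that the label-permutation space is too small for stable tail estimates.
Set-size filters default to 15–500 members present in the data.

## Integration

A candidate row requires, in one cell line: call = down, an annotated peak
(the gene appears in that line's gene → best-rank map), and cohort
membership (d > 0, q ≤ threshold). The three evidence values pass through
untransformed; rendering the FDR as a percentage is presentation-layer
only. The per-line requirement matches a per-line candidate table's
semantics; a cross-line union mode (peak from any line) is available.
Overlap summaries report the regulated ∩ peak-associated intersection with
fractions in both directions, and a one-sided hypergeometric tail
(exact, via the survival function) serves the generic
gene-set-overlap question.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical regime the analysis assumes, on
the scale the analysis operates at:

* **Expression**: per-gene baselines are log-normal (meanlog 3, sdlog 1 in
  natural log — median ≈ 20 RPKM, realistic dynamic range), with
  multiplicative log-normal noise (σ = 0.15 per condition, i.e. ≈ 21%
  SD on the ratio) — typical biological+technical scatter for deep bulk
  RNA-seq of cell lines. Planted knockdown ratios are U(0.2, 0.7) for
  regulated genes (effects comfortably but not uniformly below the 0.75
  call boundary, so noise makes borderline calls possible), ratios jittered
  around 1 (σ_ln = 0.05) for null genes, and 5% of genes sit below the
  RPKM filter to exercise the not-measured path.
* **Geometry**: TSSs on a 10-kb grid, 100 genes per ~1-Mb contig, so the
  genome stays small enough to regenerate per run while 100-kb windows
  remain meaningful. Planted peaks sit N(0, 2 kb) from their target's TSS,
  clipped to ±4.5 kb — under half the grid spacing, guaranteeing the
  planted peak is nearest to its own target. 500 decoy peaks per line are
  uniform, 10% of them on a geneless contig (exercising the unassigned
  path). Per line, each direct target carries a peak with probability 0.9.
* **Motifs**: consensus instances are written into the genome inside true
  peak windows at rate 0.9, so window extraction + scanning shows strong
  enrichment over shuffles.
* **Cohort**: 40 amplified / 200 non-amplified / 60 indeterminate samples
  (amplified a minority, as in tumor cohorts), log2-scale expression with
  unit-SD noise, a +1.5 log2 shift at direct targets in amplified samples
  (the 1.5-SD regime of the calibration simulations), and a +2 dosage
  shift of the index gene so amplified samples dominate the top-quartile
  expression gate. Only direct targets receive the cohort shift: the
  cohort layer models dosage-driven overexpression of bound targets, which
  is exactly the evidence the integration gates on.

All draws flow from a single integer seed through one generator in a fixed
order, so identical seeds give byte-identical files.

Deliberately **not** emulated: read-level data and count noise (the
analysis consumes RPKM-scale ratios, so the generator matches the analyzed
scale rather than a negative-binomial count layer), fragment-level ChIP
coverage, realistic gene-length/GC structure, correlated co-regulation
among null genes, and real tumor-cohort marginals (subtype structure,
purity, batch). Passing tests therefore demonstrate that the pipeline's
logic and statistics behave correctly under the assumed noise model — not
that the thresholds are optimal for any particular real dataset.

## Problem sizes and numerical choices

The reference validation bundle is 2000 genes × 3 lines × 50 direct + 100
indirect targets with a 300-sample cohort; calibration simulations use 200
genes at 30 vs 60 samples with 20 replicates, and GSEA recovery 1000 genes
at 6 vs 6 with 10 replicates — sizes at which every property of interest
is measurable in seconds. Degenerate inputs are handled explicitly:
all-zero in-set metrics fall back to unweighted ES steps; constant genes
get d = 0 when group means agree and an error only when s + s₀ = 0 with a
nonzero difference; correlation pairs with < 3 shared genes and NES with
an empty same-sign permutation tail are NaN, not exceptions. The Δ grid
for SAM q-values is the set of observed |d_(i) − d̄_(i)| gaps, thinned to
≤ 300 quantile points for large gene counts (the called-set closure makes
FDR piecewise-constant between gap values, so thinning only coarsens q
slightly and monotonically).

## Known limitations

* SAM settings (s₀ grid, Δ handling, π̂₀ window) follow the method's
  original published definition; a finished analysis made with any
  particular desktop build may differ in minor numerical conventions.
* Nearest-gene annotation considers TSS distance only; annotation to gene
  bodies or to multiple genes per peak (enhancer skipping) is not modeled
  beyond the configurable distance mode.
* The GSEA FDR estimator shares the known conservatism/instability of
  NES pooling at small permutation counts; nominal p and NES rank are the
  robust quantities at n_perm ≈ 100–200.
* The hypergeometric overlap utility assumes a well-defined finite gene
  universe supplied by the caller; results are sensitive to that choice.
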