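# Methods

`phagoscreen` implements the computational analysis of a FACS-sorted,
SLC-focused pooled CRISPR knockout screen for phagosome acidification,
together with the flow-cytometry gating model, the assay statistics used
on gated fractions, and BCECF ratiometric pH quantification. Every stage
is exercised against a synthetic-data generator that emulates the screen
design, so the pipeline is fully testable without instrument or
sequencing data.

## The screen model

A pooled lentiviral library covers 391 SLC (solute carrier) genes with
six sgRNAs per gene, plus 120 sgRNAs against 20 genes essential in
haploid leukemia lines (positive depletion controls) and 120
non-targeting sgRNAs (negative controls) — 2,586 guides in total.
Macrophage-like cells carrying single knockouts are challenged with
dual-labelled beads and sorted into a phagocytosis-and-acidification-
positive gate (PhagoLate) and a phagocytosis-negative gate (PhagoNeg).
A gene required for phagosome acidification depletes from PhagoLate:
its guides shift toward PhagoNeg, and sequencing the sgRNA cassettes of
both sorted populations turns the phenotype into a count contrast.

## Synthetic-data generator

`simulate_screen` draws, per replicate:

1. **Library skew** — one log-normal factor per guide (σ = 0.3 by
   default, a typical representation spread for pooled libraries),
   shared across replicates because it is a property of the cloned
   library.
2. **Infection** — multinomial allocation of `coverage × n_guides`
   founder cells (coverage 1000× by default, matching the screen design)
   over the skewed library. Infection at MOI 0.2–0.3 is modelled as a
   single integration per infected cell; multi-integration events are
   rare at that MOI and are not modelled.
3. **Editing and selection** — each integrated guide yields a functional
   knockout with probability 0.8; essential-gene knockouts survive to
   the sort with relative fitness 0.2. Cells then expand tenfold
   (deterministic clonal outgrowth) between selection and sorting; the
   design's cell numbers (≥3 × 10⁶ sorted per gate from 2.6 × 10⁶
   infected founders) are only reachable with such outgrowth.
4. **Phenotype and sort** — a cell is PhagoLate with probability
   `0.4 × multiplier(gene)` if edited (baseline 0.4 if not), PhagoNeg
   otherwise; each gate is multinomially subsampled to `sort_depth`
   (3 × 10⁶ by default; tests and the acceptance script scale this down
   to 3 × 10⁵ to keep runs fast — the statistical behaviour is unchanged
   because read depth, not cell depth, is limiting there).
5. **Amplification and sequencing** — reads per guide are gamma-Poisson
   (negative binomial) around cell-share × read budget with dispersion
   0.05, absorbing PCR and sequencing overdispersion. Default read
   budget is 500 reads per guide.

What the generator does **not** emulate: PCR jackpotting beyond a
constant dispersion, guide-specific editing efficiencies and off-target
effects, cell-cycle or differentiation heterogeneity, sorting impurity,
index hopping. Passing recovery tests therefore demonstrates the
statistical machinery is correct and calibrated under the declared
generative model, not that any particular real screen meets these
assumptions.

`emit_fastq` inverts counting: each guide contributes exactly its count
in reads of the form `upstream flank + spacer + downstream flank`
(defaults mirror the lentiCRISPRv2 cassette context: U6 tail ending in
`CACCG` upstream, scaffold start downstream), with optional per-base
substitution errors over the whole read. With error rate *e* the
expected assignable fraction under exact matching is
`(1 − e)^(|up| + 20 + 4)`, since the upstream flank, the spacer, and the
four checked downstream bases must all be intact.

## Guide-level statistics

Counts are normalized by **median-of-ratios** size factors: the
reference profile is the per-guide geometric mean across samples (rows
containing a zero are excluded), and a sample's factor is the median of
its count/reference ratios, taken in linear space. A pseudo-reference
fallback (`counts + 0.5`) is available for sparse matrices with no
all-nonzero row.

**Dispersion.** Per guide, a method-of-moments estimate
`α̂ = max(0, (pooled within-group variance − μ)/μ²)` on normalized
counts; a trend `α(μ) = a₁/μ + a₀` fitted by least squares over guides
with positive `α̂`, with one trimming round discarding values above 10×
the first fit. The fit targets the *mean* of the raw dispersions
deliberately: the raw-dispersion distribution is right-skewed and a
median-targeting robust loss would understate the trend. By default the
test uses the **trend value alone** (`shrinkage_weight = 1.0`): with two
or three replicates per gate a per-guide dispersion carries ~2–4 degrees
of freedom, and blending it in (log-space weighting toward the trend is
available via `shrinkage_weight < 1`) lets the low tail of the raw
estimates understate standard errors and inflate the type-I error — with
50 % weight the null false-positive rate at p < 0.05 measured 0.086
rather than the nominal 0.05; trend-only measured 0.050.

**Wald test.** For the two-group contrast the NB GLM mean per group is
taken as the group mean of normalized counts (a pseudo-count of 0.5 is
applied only when a group mean is zero, so nonzero cases are unbiased);
`LFC = log₂(μ_Late/μ_Neg)`, standard error
`SE = sqrt(Σ_g (1/μ_g + α)/n_g)/ln 2` from the NB information, `z =
LFC/SE`, and a two-sided p-value from the standard normal. Guides with
zero counts everywhere are flagged undefined and excluded from ranking.
Benjamini–Hochberg step-up adjustment controls the FDR.

Exact parity with DESeq2 is not a goal (no IRLS GLM, no empirical-Bayes
dispersion prior, no LFC shrinkage, no independent filtering or outlier
handling), but the simplification is close where it matters: on planted
two-group data the fold changes agree with pyDESeq2 to ~10⁻³ and the
significance calls coincide (see the cross-check test).

A note on normalization invariance: rescaling *all* columns by a
constant leaves size factors and fold changes exactly unchanged (the
row reference absorbs the scale) and moves p-values only through the
Poisson 1/μ term of the standard error; rescaling a *single* column is
absorbed by its size factor up to a common reference shift `c^(1/m)`,
leaving fold changes exactly invariant.

## Gene aggregation

Guides are ranked by the signed metric
`sign(LFC) × (−log₁₀(p_adj + 10⁻³⁰⁰))`, descending, with deterministic
tie-breaking (|LFC| descending, then guide id). A p-value sort alone
would lose direction while the screen's question is specifically
depletion from PhagoLate; the signed metric keeps the adjusted-p
ordering within each direction (an unsigned `padj_only` metric is
available). Each gene's guides are scored with the weighted
Kolmogorov–Smirnov running sum of gene-set enrichment analysis: hits
increment by `|r|^q` normalized over the set (weight exponent q = 1 by
default, configurable because the classic choice is not the only one),
misses decrement by `1/(N − m)`; the enrichment score (ES) is the
running-sum extremum, −1 ≤ ES ≤ 1, negative when the gene's guides
concentrate at the depleted bottom of the list.

Significance comes from a permutation null of uniformly drawn same-size
guide sets: `p = (1 + #{|ES_null| ≥ |ES_obs|, matching sign}) /
(1 + #{matching sign})`. Null distributions are shared across genes of
the same set size, which makes a 20,000-permutation default affordable
and the table fully deterministic under one seed. The default is 20,000
rather than a smaller round number because the sign-matched denominator
is about half the permutation count: with 411 genes under test, the
attainable p-value floor must sit below 0.05/411 for a perfectly
depleted gene to survive BH adjustment, which requires ≥ ~16,400
permutations. Non-targeting guides participate in the ranking (they
inform the null ordering) but are never aggregated — they carry no gene
identity. Gene-level BH adjustment yields the volcano table: mean LFC
over the gene's guides (x-axis), −log₁₀ p_adj (y-axis), and the number
of individually significant guides (dot size).

## Flow gating

Events carry a pH-insensitive uptake channel (YG) and a pH-sensitive
acidification channel (pHrodo). Quadrants: YG ≤ cut → PhagoNeg; YG >
cut, pHrodo ≤ cut → PhagoEarly; both above → PhagoLate. The anomalous
YG⁻/pHrodo⁺ corner is folded into PhagoNeg (without the uptake marker an
event cannot be phagocytosis-positive) and reported separately as a
diagnostic. Cuts are placed at the 0.995 quantile of a negative-control
population per channel — a reproducible surrogate for manual gate
placement, which the original instrument sessions do not document.
Intensities are compared on the raw scale; log transformation is a
display concern. The synthetic event generator draws three bivariate
log-normal clusters whose default separations (~1.7 decades between
negative and positive medians, geometric σ = 0.45) keep quantile-gated
misclassification below 1 %.

Welch's unequal-variance t test (with Welch–Satterthwaite degrees of
freedom and 95 % confidence intervals) and the Wilcoxon–Mann–Whitney
test (exact enumeration for combined n ≤ 12 without ties, tie-corrected
normal approximation otherwise) are the statistics applied to gated
fractions and survival percentages; degenerate zero-variance inputs
return p = 1 (equal means) or a flagged p = 0.

## BCECF pH quantification

The 490/440 excitation ratio follows
`R(pH) = r_min + (r_max − r_min)/(1 + 10^(hill·(pKa − pH)))`, fitted by
bounded nonlinear least squares with multi-start initialization (r_min
and r_max from the data extremes, pKa from the half-maximum crossing,
hill ∈ {0.5, 1, 2}), requiring ≥ 5 distinct pH points spanning ≥ 3 units
and a monotone trend (Spearman |ρ| ≥ 0.5). The free Hill slope covers
in-situ calibrations, which are often shallower than the dye's cuvette
behaviour. Inversion is closed-form; ratios at or beyond the asymptotes
clamp to the calibrated pH range with an out-of-range flag. Image
reduction is deliberately minimal — maximum z-projection, background
subtraction (default estimate: median of the lowest-decile pixels,
clamped at zero), and per-ROI channel means; ROI masks are inputs, not
computed, because segmentation is out of scope. Phagosomal acidification
is reported as pHrodo intensity only: pHrodo is not calibrated to
absolute pH, and the module mirrors that asymmetry on purpose.

## Numerical choices and degenerate inputs

- Dispersion floor 10⁻⁸; BH values capped at 1; ranking epsilon 10⁻³⁰⁰
  guards log of exact-zero adjusted p-values.
- ES permutation draws use rejection sampling to enforce
  without-replacement sets; the running-sum extremum is computed from
  hit positions alone (maxima occur immediately after hits, minima
  immediately before hits or at the end), O(m log m) per permutation.
- All-zero guides, empty gates, empty ROI masks, non-monotone
  calibrations, and infeasible effect multipliers raise typed errors
  naming the offender; short or flankless reads are unassigned, never
  errors.
- Every stochastic stage takes an explicit seed; the pipeline writes
  immutable, hash-stamped run directories and reproduces byte-identical
  tables under identical configuration.

## Problem sizes in the test suite

Unit tests run miniature libraries (8–10 genes). The end-to-end checks
use the full 2,586-guide design: counting round-trips at 100–500 reads
per guide, null calibration pooled over 3–5 simulated screens (~8,000–
13,000 guide-level p-values), and hit recovery over 10–20 seeds at
sort depth 3 × 10⁵ and 300 reads per guide — sizes chosen so the whole
suite completes in well under an hour on a laptop while keeping every
statistical assertion at the scale the claims are made for.

## Known limitations

- The NB test's normal Wald approximation is slightly liberal for very
  low counts; the calibration band is verified at the default depths.
- Gene-level p-values share per-size permutation nulls, so they are
  marginally uniform but weakly dependent within one run; BH is robust
  to this in practice but strict FDR control under dependence is not
  proven here.
- The generator's binary sort (PhagoLate vs everything else) omits the
  intermediate PhagoEarly gate that the flow model distinguishes; the
  count contrast only uses the two sorted populations, as the screen
  itself did.
- Exact-match counting discards reads with any spacer or flank error;
  at real-world error rates this costs depth but not bias. A
  reverse-complement search and a mismatch-tolerant mode are explicitly
  out of scope for the default path.
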