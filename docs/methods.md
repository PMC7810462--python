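# Methods

`mitransfer` implements a statistical pipeline for asking whether bacteria
are transferred from the maternal vaginal microbiome to the infant's fecal
and airway microbiota, using 16S amplicon sequence variant (ASV) count
tables from mother–child dyads. This note documents the models, the
estimators, the synthetic cohort the test suite runs on, and the numerical
conventions, in that order.

## The transfer model

The unit of analysis is the **dyad**: a mother's vaginal week-36 sample
paired with one child sample from a **stratum** defined by compartment
(fecal or airway), child age (7, 30, 300 days for fecal; 7, 30, 90 for
airway) and delivery mode (vaginal birth VAG, or cesarean CS, optionally
split into in-labor CS-L and scheduled CS-S). The full factorial gives 12
strata (18 with the CS split). Children enter a stratum only when a
corresponding maternal week-36 vaginal sample survived depth filtering.

### Per-ASV Fisher transfer odds

For ASV *i* in one stratum the dyads are cross-tabulated by presence
(count ≥ 1 on the unrarefied table):

|               | child +  | child −  |
|---------------|----------|----------|
| **mother +**  | a        | b        |
| **mother −**  | c        | d        |

Only *testable* ASVs — no zero margin, i.e. present in ≥ 1 and absent in
≥ 1 mother **and** child — are analyzed. The transfer odds ratio is
OR = ad/bc, with 0.5 added to every cell when any cell is zero
(Haldane–Anscombe; applied to the point estimate only, never to p). The
p-value is the exact conditional hypergeometric tail in the direction of
the observed association: upper tail P(X ≥ a) when ad ≥ bc, else lower
tail. This keeps both the enrichment (OR > 1) and depletion (OR < 1)
half-planes of the volcano informative, which the WTR below requires;
the cost is that the p-values are not marginally uniform (a value near 1
is impossible by construction), so they are treated as evidence weights
and for per-ASV inference are BH-adjusted *within* each stratum.

### The weighted transfer ratio

Per-ASV tests are hopeless against the sparsity of infant microbiota, so
evidence is pooled over the volcano plot geometry:

    WP = Σ_{i: OR_i > 1} |ln OR_i| · (−log10 p_i)
    WN = Σ_{i: OR_i < 1} |ln OR_i| · (−log10 p_i)
    raw WTR = WP / WN

ASVs with OR exactly 1 contribute to neither side; p = 1 contributes zero
weight. The base of the OR logarithm cancels in the ratio (log-base
invariance); natural log is used. Because sparsity skews the ratio even
without transfer, the null is built by **scrambling the child side of the
dyad pairing** and re-running the *entire* downstream pipeline (testable
ASV selection, Fisher tests, WP/WN) per permutation. The reported value is

    WTR = raw WTR / median(null raw WTRs)

with a one-sided permutation p = (1 + #{null ≥ observed}) / (n_perm + 1).
Defaults: n_perm = 1000 in the library API (the calibration and power
studies below use 200 to keep runtimes reasonable), recorded in every
record.

Infinite raw ratios (WN = 0 < WP) are legitimate outcomes; they
participate in the null median and permutation count by ordering, and are
dropped (with a count) from moment-based summaries such as the bootstrap
SE, which is the standard deviation of ln(raw WTR) over ASV-level
bootstrap resamples (default 500).

**Order-level analysis** repeats the whole machinery on each bacterial
order's ASVs alone. An order is included when it has ≥ 2 testable ASVs in
every stratum and > 10 in at least one; records whose mean testable count
across strata is below 15 carry a low-support flag. For plotting exports
the WTR is clamped to [0.625, 16] in a separate column; the analysis
columns are never truncated.

**Delivery-mode contrasts** compare ln(raw WTR) between two strata
differing only in mode, with a null that permutes the mode labels over
the pooled dyads (group sizes preserved).

### Secondary transfer statistics

- Transfer of the *dominant* maternal ASV: per dyad, the week-36 ASV with
  the highest count (ties: higher population-wide abundance, then
  lexicographic) is checked in the child; the fraction of carrying dyads
  is tested against the scrambled-dyad null.
- Spearman correlation (Pearson optional) between per-ASV log OR and the
  mean maternal relative abundance across the stratum's mothers.

## Community state typing

Vaginal profiles are rarefied to 2000 reads (samples under 2000 reads are
excluded; rarefaction is used *only* for beta diversity) and compared by
Jensen–Shannon divergence (natural log, bounded by ln 2, reported as the
divergence — a `sqrt` flag gives the metric variant). Clustering is
partitioning around medoids run directly on the JSD matrix, implemented
deterministically: greedy BUILD seeding, steepest-descent SWAP, all ties
broken by the lowest sample index, so the same matrix always yields the
same clusters with no seed. The number of clusters is chosen from four
internal indices (average silhouette width, Pearson gamma, dunn2, and
Calinski–Harabasz computed from the distance-based sum-of-squares
identity W_c = (1/n_c) Σ_{i<j∈c} d²ᵢⱼ, which is exact for Euclidean
distances and well-defined for any dissimilarity). ASW decides by default
(smaller k on ties) because the four indices come with no combination
rule; the full table is always returned for manual override. Each cluster
is named by its dominant ASV (highest mean relative abundance; exact ties
resolved lexicographically with a warning).

Longitudinal stability between gestational weeks 24 and 36 is measured
two ways: (1) per-CST 2×2 χ² tests (this CST vs the rest × stable vs
not) without continuity correction, BH-adjusted across CSTs, plus the
overall stable fraction; (2) a permutation test on the median paired JSD
against 2500 scrambles of the week-36 side.

## The synthetic cohort generator

The generator supplies ground truth; it emulates the *structure* of a
pregnancy-cohort dataset, not any particular cohort's numbers.

- **Vaginal communities** are a mixture of Dirichlet components: five
  low-diversity types, each dominated by one ASV (mean dominant share
  0.90–0.95, total background concentration 0.5), and one diverse type
  (dominant share 0.35, background concentration 8) that is *depleted* of
  the five dominants — the defining feature of the Lactobacillus-poor,
  Gardnerella-rich state. Mixture weights (0.30, 0.20, 0.15, 0.10, 0.10,
  0.15). At week 36 each woman resamples from her week-24 component with
  probability `stability` (default 0.85), else from a freshly drawn
  component.
- **Child communities** decouple presence from abundance. Presence of
  ASV j is Bernoulli with logit = baseline(compartment) + β(order(j),
  mode)·1[mother carries j]; the planted β is therefore *exactly* the log
  odds ratio the pipeline estimates, making parameter recovery
  well-posed. Abundances of present ASVs follow a compartment-specific
  Dirichlet baseline (each compartment favors a different third of the
  ASV pool), and every present ASV receives at least one read so that
  count-level presence coincides with the latent Bernoulli draw.
  Baseline presence logits: fecal −1.4, airway −1.8 (≈ 20% and 14%
  carriage).
- **Depths** are lognormal (meanlog ln 30000, sdlog 0.7, floor 1000),
  giving realistic uneven sequencing depth with rare sub-2000 samples
  that exercise the depth filter.
- **Delivery mode** is drawn once per dyad (VAG 0.78, CS-L 0.12,
  CS-S 0.10) and shared by all of that child's samples.
- **Reproducibility**: one root seed, with sub-streams keyed by (dyad,
  compartment, timepoint), so tables are bit-identical regardless of
  iteration order. Defaults: 665 dyads (cohort scale), 150 ASVs
  round-robin across ten bacterial orders.

What the generator does **not** emulate: longitudinal correlation within
a child (each timepoint redraws presence independently), correlation
between presence probability and abundance (so the abundance–OR
correlation is null by construction), phylogenetic structure, chimeras or
PCR/sequencing bias, and compositional competition between transferred
and resident taxa. Passing tests therefore demonstrate correctness and
calibration of the *estimators*, not realism of any particular biological
effect size.

## Problem sizes and numerical choices

- Calibration studies use 200 null cohorts of 100 dyads × 150 ASVs with
  200 permutations each; power studies use 200 dyads, 50 seeds per
  planted effect size (log OR 0, 0.7, 1.6, 2.3); CST recovery uses 40
  cohorts of 300 mothers. `scripts/acceptance.py` re-runs the same
  studies at reduced replication (40/15/10 seeds) so a full from-scratch
  reproduction stays in the minutes range.
- Exact-test correctness is verified against exhaustive integer
  enumeration of every 2×2 table with n ≤ 20 (tolerance 1e-12), and the
  BH step-up against its defining formula on random p-vectors.
- Permutation p-values always use the add-one form (1 + hits)/(B + 1)
  and never equal zero. KS-based uniformity checks of permutation tests
  allow for the 1/(B+1) grid discreteness.
- The χ² example values and all frozen test constants were computed with
  independent oracles (hand evaluation or brute-force enumeration) before
  being asserted.
- `filter_min_depth` keeps the ASV column set unchanged (columns may
  become all-zero) so tables from different strata stay aligned.
- Dyads with several candidate child samples in one stratum are rejected
  as a validation error rather than silently picked from.

## Known limitations

- The direction-of-observed one-sided Fisher p is conservative and
  non-uniform by construction (see above); treat per-ASV q-values as
  screening, and rely on the permutation-calibrated WTR for inference.
- The WTR bootstrap SE resamples ASVs, ignoring between-ASV dependence
  induced by compositionality; it is a dispersion summary, not a basis
  for Wald tests — use the permutation p.
- PAM is O(k·n²) per SWAP iteration; matrices beyond a few thousand
  samples will be slow.
- Weighted-UniFrac-style phylogenetic beta diversity is out of scope
  (no phylogeny is carried); JSD is the supported beta metric.
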