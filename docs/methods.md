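# Methods

## The data model

A conserved extended haplotype (CEH) is the ordered tuple of alleles at
HLA-A, C, B, DRB1, DQB1 plus an 11-character binary SNP haplotype from the
Class II region; identity is the full 16-symbol tuple, so two CEHs that
differ only in their SNP string are distinct haplotypes. The canonical
text encoding joins the six fields with `~` in locus order; motif patterns
use the same encoding with `*` wildcards, and the SNP field of a pattern
may name a published tag (`a1`, …) resolved through the catalogue. HLA
allele names are normalized to two-field resolution (`DRB1*15:01`);
higher-resolution input is truncated.

A diplotype is an unordered pair of CEHs stored in lexicographic order of
the joined encoding; this ordering is the tie-break used everywhere a
deterministic choice among equivalent haplotype pairs is needed.

## Synthetic cohorts

The generator emulates the structure of a large (tens of thousands)
European case-control cohort typed across the MHC, which is the regime the
statistics in this package target:

- **Frequency spectrum.** The default pool combines ~48 named catalogue
  CEHs at their observed cohort frequencies (together ~27% of haplotype
  mass, top-10 ≈ 20%) with a generated tail of ~10,000 rare haplotypes
  whose frequencies follow a truncated power law in rank. The tail
  exponent (default 0.42; 0.3 for recipe-built pools) is deliberately
  shallow: steep exponents concentrate the "rare" mass into a few
  effectively common haplotypes, while shallow ones keep every tail
  member at singleton-to-few-copies scale at realistic sample sizes,
  which is the shape a skewed MHC spectrum actually presents.
- **Tag–motif linkage.** A generated rare haplotype whose SNP string
  coincides with a published tag is given that tag's Class II motif, so
  the tight SNP-haplotype/Class II coupling of real MHC data holds in the
  pool by construction (a handful of re-draws after key collisions leave
  carriage marginally below 100%).
- **Disease model.** Per-CEH genotype relative risks (rr₀=1, rr₁, rr₂)
  multiply a baseline odds (default 0.25, prevalence ≈ 0.2 under the
  null, matching a case-enriched case-control cohort rather than a
  population prevalence); a recessive CEH is encoded rr₁=1, rr₂>1 and a
  dose-dependent one rr₁=r, rr₂=r². Because effects act on the odds
  scale, the carrier odds ratio of "k copies vs 0" equals rr_k exactly,
  which makes programmed effects recoverable without bias corrections.
- **Substructure.** A subpopulation scheme draws the subpopulation first
  and both haplotypes from its frequencies — the Wahlund construction —
  which is the generator's mechanism for homozygote excess.
- **Determinism.** All draws flow from one `numpy` generator stream per
  entry point, so identical configs and seeds give byte-identical files.

What the generator does **not** emulate: genotyping/imputation error,
within-generator recombination or mutation (class conversion lives in the
selection model), linkage maps, and realistic allele-name ontologies for
the generated rare tail. Passing tests therefore demonstrate correctness
of the estimators under clean sampling assumptions, not robustness to
typing artifacts.

## EM phasing

Standard multi-locus EM with explicit enumeration of compatible pairs
(2^(k−1) for k heterozygous loci; exact combinatorics are unit-tested
against exhaustive enumeration). Choices that the cohort literature leaves
open are fixed as follows: initialization is uniform over
observed-compatible haplotypes; the heterozygous pair weight carries the
factor 2; haplotypes falling below 1/(4N) are pruned after iteration 5
(with a rescue that keeps each genotype explainable); convergence is
max |Δf| < 1e-6 with a 200-iteration cap, non-convergence flagged rather
than raised. The log-likelihood is recorded each iteration and is
non-decreasing; the pruning step may perturb it by at most the pruned
mass, which is the tolerance the tests assert. Individuals with missing
calls at the loci being phased are excluded from that phasing stage.

Six-locus phasing is staged: the 11-SNP window is phased first, each
individual's most probable SNP pair is collapsed into one multi-allelic
"SNP-haplotype locus", and EM then runs jointly over the five HLA loci
plus that locus. Best-pair assignment reports the posterior
(pair weight / total compatible weight), breaking ties lexicographically.

The sliding-window scan phases every window of width 2–15, scores each
window by the smallest carrier chi-square p-value over haplotypes with at
least `min_copies` assigned copies, and selects the smallest-p window
(ties to smaller width, then leftmost).

## Association testing

Carrier tables compare exactly `copies` copies of the target against 0
copies; individuals with the other copy count are excluded, as are — under
the motif-exclusion rule — individuals carrying the exclusion motif on a
haplotype that is not the target (so when the target itself bears the
motif, its carriers stay and all *other* motif carriers leave). Zero cells
take the Haldane–Anscombe correction (0.5 on all four cells); a structural
zero margin is an error, not a number. All tests are two-sided; OR
p-values are normal on |ln OR|/SE. The z-test for two ORs recovers each SE
from its 95% CI as (ln hi − ln lo)/(2·1.96).

Class I × Class II association uses the Fisher exact test when any
expected cell is ≤ 5 and the Pearson chi-square (no continuity
correction) otherwise; the two-sided Fisher p sums hypergeometric tables
with probability ≤ the observed (with a 1+1e-7 relative slack against
floating-point ties), and is verified against integer-arithmetic
enumeration on all tables with total ≤ 40.

Dose regression is a statsmodels logistic fit of case status on per-CEH
dose plus covariates; region labels are dummy-coded with the first level
dropped; zero-variance covariates are treated as no-ops (they are absorbed
by the intercept); separation is flagged per-coefficient rather than
raised; rank deficiency raises an error naming the collinear columns.
Haplotypes are analyzed only at ≥ 50 cohort copies by default
(configurable).

## Homozygote excess and the two-class model

The excess test uses q = Σfᵢ² and the binomial variance Nq(1−q) — each
individual is homozygous independently with probability q. On the printed
cohort inputs (O = 383, E = 269, N = 29,942) this gives z = 6.98; the
cohort literature prints 6.97, consistent within rounding, though no
single simple variance convention reproduces all published z-values
exactly, which is why the tests carry a ±0.05 tolerance on this statistic.

The two-class model classifies haplotypes as "rare" (observed once) or
"frequent" (more than once) and treats class homozygotes interchangeably.
One generation is: random union of gametes → viability weighting of the
three diplotype classes by (w_ff = 1, w_fr, w_rr) → gamete output →
class conversion at rates c_fr, c_rf. Conversion acting *after* selection
is a modelling choice (the ordering is not externally fixed); w_fr
defaults to 1 so selection distinguishes the homozygote classes.
Equilibria are found by bisection on the one-generation displacement and
verified against long forward iteration.

Inversion estimates (c, w_rr) — with c_fr = c_rf = c — from two
observables of an adult sample: the frequent-class haplotype share and
the rare–rare homozygote count divided by its HWE expectation at adult
class frequencies. A zoomed grid search (25×25, six refinements) with a
tie-break preferring smaller c and survival nearer 1 handles the
degenerate ridge: observations with no homozygosity deviation and
balanced classes are compatible with any conversion rate at w_rr = 1, and
return the neutral model (c = 0, w_rr = 1) by convention. Note that with
w_fr = 1 the model's adult population shows a homozygote *deficit* when
w_rr < 1; the model's purpose here is the recoverable mapping between
(c, w_rr) and the observables, not a claim about the sign of the deviation
in any particular cohort.

## Problem sizes and numerical conventions

Simulation-based checks run at the sizes where their targets are sharp:
phasing recovery at n = 5,000 on a 20-CEH pool (seed-averaged L1 < 0.05),
odds-ratio CI coverage over 100 replicates at n = 2,000, type-I error
over 1,000 null replicates at n = 2,000, and the conversion–selection
round trip at N = 30,000 adults. Frequencies are validated as simplexes
to 1e-9; equilibrium fixed points to 1e-10; percentages are reported
rounded to integers with raw doubles retained. VCF coordinates are
1-based; internal window indices are 0-based half-open.

## Known limitations

- The EM phasing model assumes random mating within the phased sample;
  strong substructure biases haplotype frequencies toward homozygote
  over-assignment.
- The window scan's selected-window p-value is a minimum over correlated
  tests and is not corrected for the scan itself.
- The two-class inversion uses equilibrium assumptions; cohorts far from
  conversion–selection balance will return feasible=False fits.
- Catalogue SNP strings for tags a16/a18 are synthetic stand-ins (flagged
  in `cehkit.catalog`); all other tag strings are the published ones.
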