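# cehkit

Analysis of **conserved extended haplotypes (CEHs)** of the human major
histocompatibility complex (MHC) and their relationship to disease
susceptibility, built for population geneticists and immunogenetics
researchers working with case-control cohorts typed at classical HLA loci
and dense SNPs.

A CEH here is a specific combination of alleles at the five classical loci
HLA-A, -C, -B, -DRB1, -DQB1 together with an 11-SNP haplotype from the
Class II region around *HLA-DRB1*, inherited as a unit across more than
2.7 Mb. The package covers the full analysis cycle on such data:

- **Synthetic cohorts** (`cehkit.simulate`) — diploid case-control datasets
  drawn from a configurable CEH pool with a realistically skewed frequency
  spectrum, tight SNP-tag/Class II motif linkage, dominant/dose-dependent
  versus recessive per-haplotype disease effects, and optional
  subpopulation structure (Wahlund homozygote excess).
- **EM phasing** (`cehkit.phasing`) — haplotype frequency estimation from
  unphased genotypes and most-likely pair assignment with posteriors:
  the E-step weights each compatible pair (h₁, h₂) of genotype g by
  `2^[h₁≠h₂] f(h₁) f(h₂)` normalized within the individual; the M-step sets
  `f ← E[dose]/2N`. Includes the 2–15-SNP sliding-window association scan
  and staged 6-locus phasing (SNP window collapsed to one multi-allelic
  locus).
- **Frequency spectra** (`cehkit.spectrum`) — copy-count spectra, top-k
  coverage, cumulative curves, per-region rank orders.
- **Association tests** (`cehkit.association`) — carrier odds ratios
  `OR = ad/bc` with Wald 95% CIs (`exp(ln OR ± 1.96·SE)`,
  `SE = √(1/a+1/b+1/c+1/d)`), conditional testing with motif-exclusion
  rules, z-tests on differences of log odds ratios, Fisher/chi-square
  tests for Class I × Class II combinations, Bonferroni and
  Benjamini–Hochberg corrections, and covariate-adjusted logistic dose
  regression.
- **Selection dynamics** (`cehkit.selection`) — homozygote-excess z-tests
  against Hardy–Weinberg expectations (`E = Nq`, `q = Σfᵢ²`, binomial
  variance) and a two-class (rare/frequent) haplotype
  conversion–selection equilibrium model with parameter inversion.
- **Hamming profiling** (`cehkit.similarity`) — HLA-motif carriage as a
  function of SNP-haplotype Hamming distance from an anchor haplotype.

`cehkit.catalog` ships the published 11-SNP haplotype tags (a1, a2, …)
with their Class II motif associations and a table of named European CEHs
(c1, c2, …) with cohort copy counts and reported odds ratios; these drive
the simulator's realistic defaults.

## Worked example

Simulate a 4,000-individual cohort from the catalogue pool, phase it, and
test every CEH with ≥ 50 copies conditionally on the
DRB1\*15:01~DQB1\*06:02~a1 exclusion rule (`examples/04_association_tests.py`):

```
7 CEHs tested; Bonferroni threshold 0.05/7 = 7.1e-03
  A*01:01~C*07:01~B*08:01~DRB1*03:01~DQB1*02:01~01011100100  n=499   OR= 1.3 (1.0-1.7) p_BH=0.028
  A*03:01~C*07:02~B*07:02~DRB1*15:01~DQB1*06:02~10110100010  n=442   OR= 3.7 (2.9-4.6) p_BH=5.3e-30
  A*02:01~C*07:02~B*07:02~DRB1*15:01~DQB1*06:02~10110100010  n=193   OR= 2.3 (1.6-3.2) p_BH=3.5e-06
  A*02:01~C*05:01~B*44:02~DRB1*04:01~DQB1*03:01~00000010001  n=95    OR= 0.3 (0.1-0.7) p_BH=0.0087
  ...
```

Reading the output: the recessive a6-tagged haplotype (first row) shows a
single-copy OR near 1 — heterozygous carriers are at the null, as
programmed — while the dose-dependent a1-tagged risk haplotypes show
single-copy ORs of 2–4 around their programmed per-copy effects, and the
a3-tagged haplotype is protective (OR < 1). The Bonferroni threshold is
`0.05/m` for the m haplotypes analyzed.

The other example scripts each exercise one capability end to end
(`01` simulation, `02` phasing posteriors, `03` spectrum skew,
`05` homozygote excess and conversion–selection inversion, `06` Hamming
carriage profiles); each prints its numbers with a line on what they mean.

A thin CLI mirrors the pipeline stages:

```sh
cehkit run-all --outdir run1 --seed 7       # simulate → phase → … → hamming
cehkit simulate --outdir run2 --seed 3      # single stage
```

Every stage writes its tables (TSV/VCF/JSON) plus a provenance sidecar
recording inputs, seed and thresholds.

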