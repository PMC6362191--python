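# Methods

## Model

Association Z statistics of variants in a region are treated as one draw from
a multivariate normal N(0, V) under the null, where V is the LD correlation
(r) matrix of the variants; under a polygenic alternative the same covariance
structure governs the statistics' co-movement locally.  Splitting the region's
markers into typed SNPs and untyped variants (HLA classical alleles,
amino-acid residues, untyped SNPs), the untyped statistics are imputed as the
conditional mean

    z_imp = Σ_HLA,SNP (Σ_SNP,SNP + λI)⁻¹ z_typed

with a ridge constant λ on the typed-SNP diagonal.  Although the matrices are
conventionally called variance–covariance matrices, for standardized Z scores
they **are** the Pearson LD correlation matrices, and that is what this
package stores: Pearson r between binary 0/1 haplotype columns.

Per-variant imputation reliability is reported as the explained variance

    r²pred = σᵀ (Σ_SNP,SNP + λI)⁻¹ σ

with σ the variant's cross-correlation row.  A literal reading of "the
variance of the conditional variable Z_HLA | Z_SNP" would instead give the
residual variance 1 − σᵀΣ⁻¹σ; that quantity is *small* for well-imputed
variants and therefore cannot be the reliability score that is kept when
≥ 0.5.  We follow the explained-variance convention used by the
summary-statistics imputation literature this formula comes from, under which
r²pred = 1 means a perfectly predicted statistic.  At λ = 0 and with an exact
correlation matrix, r²pred is also exactly the variance of z_imp under null
draws of z_typed (verified by Monte-Carlo in the test suite); with λ > 0 both
the weights and r²pred are shrunk, consistently.

Why λ appears in both places: the ridge is a statement that the reference
correlations are noisy estimates, so it must damp the predicted variance as
well as the weights — otherwise r²pred would overstate the reliability that
the shrunken predictor actually achieves.

## Multi-allelic variants: binary encoding

HLA classical alleles and amino-acid positions are multi-allelic; the MVN
machinery is biallelic.  Each variant is therefore expanded into
presence/absence markers on phased haplotypes:

* one marker per distinct two-field allele (`DRB1*15:01 → HLA_DRB1_1501`),
* one per distinct one-field allele (`HLA_DRB1_15`), set by any of its
  two-field children,
* one per distinct residue at each polymorphic amino-acid position
  (`AA_DRB1_11_S`); indels count as one more residue symbol.

A position or gene with a single observed state yields no usable marker; the
matrix-store builder additionally drops markers with counted-allele frequency
outside (maf_min, 1 − maf_min).  **maf_min defaults to 0.005**: the Pearson r
of a binary column carried by a handful of haplotypes is dominated by those
few observations and destabilises the conditioning matrix.  Markers with ≥ 5%
missing haplotype calls are dropped; below that, correlations are computed
pairwise-complete.

## Allele harmonisation of summary statistics

Summary records are matched to panel SNPs id-first (marker names survive
genome-build changes; positions do not), optionally falling back to
(position, allele-pair) matching.  Alleles are compared directly and as
reverse complements; the Z sign is flipped when the effect allele aligns to
the panel's non-counted allele.  Strand-ambiguous A/T and C/G SNPs are dropped
by default because complementation cannot distinguish a strand flip from an
allele swap — for these SNPs a wrong guess silently negates the Z.  A summary
file listing the same id twice with conflicting statistics has both records
dropped (choosing one arbitrarily would be unverifiable).  Z is taken from a
`Z` column when present, else `beta/se`, else `sign(log OR)·|Φ⁻¹(P/2)|`.

Typed SNPs are never overwritten: their observed (sign-aligned) Z is reported
with r²pred = 1 and status `typed`.  All matched SNPs in the region form a
single conditioning set — no sliding windows and no per-variant tag selection,
matching the single-matrix design of the method.  Rows with r²pred below the
reporting threshold (default 0.5) are flagged `low_r2pred`, never removed.

## Numerical choices

* The linear system (Σ + λI) w = σ is solved by Cholesky factorisation; the
  matrix is never explicitly inverted.  An explicit-inverse implementation
  exists only as a test oracle.
* λ = 0 on a singular system raises a dedicated error advising λ > 0 rather
  than returning garbage from a pseudo-inverse.
* r²pred is clipped at 0 from below; values within 1e−8 above 1 (round-off on
  an exactly PSD matrix) are reported as 1.
* Two-sided P = 2Φ(−|z|) is computed from the scipy complementary-error
  function tail; beyond float64's range (|z| ≳ 38.5) the value is
  reconstructed as exp(logsf + log 2) in extended precision, keeping P
  strictly positive to |z| ≥ 41 (P ≈ 10⁻³⁶⁸).  `z_to_neglog10_p` gives the
  exact −log₁₀P at any magnitude.
* The matrix store serialises to a versioned HDF5 container (marker metadata,
  the two correlation blocks, the haplotype count — no individual-level data);
  round-trips are bit-exact, and version mismatch or truncation raises an
  explicit error.  Three audit TSVs can be exported alongside.

## Association oracle

Validation needs Z scores computed from individual-level data.  The package
uses the covariate-free score test (Cochran–Armitage trend type) on dosages,

    Z = Σᵢ (yᵢ − ȳ) gᵢ / sqrt( ȳ(1 − ȳ) Σᵢ (gᵢ − ḡ)² ),

signed so Z > 0 means counted-allele enrichment in cases.  It is
deterministic, covariate-free (matching the imputation method's own
no-covariate regime) and asymptotically equivalent to the logistic Wald Z
under the null; the test suite cross-checks it against a logistic regression
fit (agreement within 5% at |Z| < 6).

## Synthetic MHC-like data

The generator emulates the features of the MHC that the method exploits,
without claiming human realism:

* **Block-mosaic founders.** The 5-Mb region (frame: chr6, 29–34 Mb) is cut
  into `n_blocks` LD blocks of `snps_per_block` SNPs.  Each block carries
  `founders_per_block` founder haplotypes (binary vectors with per-SNP
  frequencies drawn once per seed from U(0.1, 0.9)) and block-level founder
  frequencies drawn from a symmetric Dirichlet(α).  A haplotype keeps its
  founder index across adjacent blocks except with probability
  `recomb_between_blocks`, producing the long-range LD characteristic of the
  region.
* **Embedded HLA loci.** Each of `n_hla_loci` genes sits in one block; its
  classical allele is a deterministic surjective function of the founder index
  (allele = founder mod `alleles_per_locus`), so HLA alleles are in strong LD
  with surrounding SNPs by construction.  Allele names pair consecutive
  indices into one-field groups (01:01, 01:02, 02:01, …) so the one-/two-field
  marker hierarchy is exercised.  Binarisation uses the same code path as real
  panels.
* **Cohorts.** Individuals are pairs of fresh haplotype draws from the same
  model as the reference panel (disjoint draws, identical marker frame).
  Null cohorts assign the phenotype by permutation with exact case/control
  counts.  Causal cohorts use P(y=1) = expit(α + ln(OR)·g) with α solved by
  root-finding to hit the target prevalence, then sample cases and controls
  to the exact counts (retrospective sampling, which preserves the odds
  ratio).

Defaults — 8 blocks × 25 SNPs, 6 founders, Dirichlet α = 1, 3 HLA loci × 4
alleles, between-block recombination 0.1, 1,000 reference haplotypes, cohorts
of 1,000 cases + 1,000 controls — give a desk-scale region with a few hundred
polymorphic SNPs whose LD decays over blocks, and HLA markers tagged at
r²pred ≈ 0.9.

**What the generator does not emulate** (so what passing benchmarks do and do
not show): human MHC allele frequencies and ancestry-specific LD; mutation
and genotyping error (haplotypes are exact founder copies); population
structure and covariates; overlapping-sample resampling (each replicate draws
a fresh cohort rather than re-labelling one fixed cohort, so pooled
correlations treat replicates as independent).  Passing the null benchmark
shows the imputation pipeline is statistically faithful to its model
assumptions at realistic LD strength — not that any particular human dataset
would reach the same correlation.

A structural property worth knowing: with founder-determined SNPs, each
block's SNP columns have rank at most `founders_per_block`, so the full
typed-SNP correlation matrix is exactly rank-deficient and λ = 0 is singular
by construction.  Limits that conceptually use λ → 0 are therefore taken with
a vanishing ridge (λ = 1e−6) in the tests.

## Benchmarks

* **Null-model benchmark** (`run_null_benchmark`): one reference panel and
  matrix store; per replicate, a fresh null cohort, typed-SNP Z by the trend
  test, HLA Z imputed from them, true HLA Z from the cohort's actual HLA
  dosages; (imputed, true) pairs with r²pred ≥ 0.5 pooled across replicates
  for Pearson/Spearman r.  **200 replicates by default** — a desk-scale run
  of the 10,000-replicate design, sized so the full benchmark completes in
  well under a minute; the harness accepts any count.  At the default
  configuration the pooled r is ≈ 0.99, comfortably above the 0.90 the
  acceptance property requires and qualitatively matching the published
  validation of this class of method (r ≈ 0.93–0.96 on real panels, where
  LD is weaker and panels imperfect).
* **Causal-allele recovery** (`run_causal_benchmark`): a two-field allele is
  made causal (default check: OR 1.5); per replicate the causal cohort's
  imputed HLA Z scores are ranked within the causal gene's two-field alleles,
  and the benchmark reports how often the causal allele is top-|Z|.  The
  recovery configuration uses Dirichlet α = 25 so founder frequencies
  concentrate near 1/founders, putting a single-founder allele's frequency
  near 1/6 ≈ 0.17 — the intended "frequency ≈ 0.15" condition — instead of
  leaving it to the long tails of α = 1.  Ranking is restricted to two-field
  alleles of the causal gene because one-field parents are near-duplicates of
  their children (comparing like with like).

Randomness is hierarchical: a single seed spawns separate streams for the
population model, the reference panel, and each replicate, so any replicate
is reproducible in isolation and panel and cohorts are independent draws.

## Known limitations

Inherited from the summary-statistics setting: only biallelic
(presence/absence) tests — no multi-allelic omnibus statistics; no covariate
adjustment; no conditional (stepwise) analysis.  Imputed P values are
approximations whose log-scale error grows with |Z| even when ranking is
stable.  Panel-side: phasing and HLA typing are out of scope (input must be
phased); the haplotype-table and phased-VCF readers cover the common
interchange cases, not every panel dialect.
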