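# dish — direct imputation of HLA summary association statistics

`dish` imputes disease-association **Z scores, P values and imputation
reliability (r²pred)** of untyped HLA variants — classical alleles at one- and
two-field resolution, polymorphic amino-acid residues, and untyped SNPs — in
the ~5-Mb MHC region, **directly from typed-SNP GWAS summary statistics**.  No
individual-level genotypes are needed on the analysis side: the LD structure
comes from precomputed correlation matrices built once from a phased SNP+HLA
reference panel, so the panel's individual-level haplotypes never have to be
shared.

It is aimed at researchers doing HLA fine-mapping who have access to MHC-region
SNP summary statistics (the common case, given data-sharing constraints) but
not to the underlying genotypes or to a distributable reference panel.

## The method

Association Z scores of variants in LD are jointly approximately multivariate
normal with covariance equal to the LD correlation (r) matrix.  Partitioning a
region's variants into typed SNPs and untyped HLA variants, the imputed Z is
the conditional expectation

```
E(Z_HLA | Z_SNP) = Σ_HLA,SNP (Σ_SNP,SNP + λI)⁻¹ Z_SNP
```

where Σ_SNP,SNP is the typed-SNP correlation matrix, Σ_HLA,SNP the
cross-correlation of each untyped variant with the typed SNPs, and λ (default
**0.15**) a ridge constant on the diagonal that guarantees invertibility and
damps reference-panel sampling noise.  Per-variant reliability is the
explained variance

```
r²pred = σᵀ (Σ_SNP,SNP + λI)⁻¹ σ,       σ = that variant's row of Σ_HLA,SNP
```

and variants with r²pred < 0.5 are flagged as unreliable by convention.
Multi-allelic HLA variants enter this biallelic machinery through binary
presence/absence encoding: every distinct classical allele (one- and two-field)
and every residue at each polymorphic amino-acid position becomes its own 0/1
marker on the panel haplotypes.

Because real SNP+HLA reference panels are access-restricted, the package also
ships a synthetic MHC-like simulator (block-LD founder haplotypes with embedded
multi-allelic HLA loci, null or causal case-control cohorts) and a benchmark
harness that validates the whole pipeline against Z scores computed directly
from the simulated cohorts' true HLA dosages.

## Worked example

Build an LD matrix store from a toy phased panel, then impute from summary
statistics:

```bash
cat > haps.tsv <<'EOF'
rs1	1	1	0	0
rs2	1	0	1	0
HLA_A_01	P	A	P	A
HLA_A_0101	1	0	1	0
EOF
cat > markers.tsv <<'EOF'
id	position	counted_allele	other_allele
rs1	100	A	G
rs2	200	C	T
EOF
cat > sumstats.tsv <<'EOF'
SNP	BP	A1	A2	Z
rs1	100	A	G	3.0
rs2	200	C	T	-1.0
EOF

dish build-panel --haplotypes haps.tsv --markers markers.tsv --maf-min 0.0 --out store.h5
dish impute --sumstats sumstats.tsv --panel store.h5 --out imputed.tsv
```

`build-panel` prints the retained marker counts by kind:

```
HLA_1FIELD	1
HLA_2FIELD	1
SNP	2
haplotypes	4
```

and `imputed.tsv` contains one row per panel variant:

```
id	kind	pos	z	p	r2pred	n_typed	status	lambda_used
HLA_A_01	HLA_1FIELD	0	-0.869565	0.384538	0.869565	2	imputed	0.15
HLA_A_0101	HLA_2FIELD	0	-0.869565	0.384538	0.869565	2	imputed	0.15
rs1	SNP	100	3	0.0026998	1	2	typed	0.15
rs2	SNP	200	-1	0.317311	1	2	typed	0.15
```

Typed SNPs keep their observed Z (sign-aligned to the panel's counted allele,
r²pred = 1).  Both HLA markers' haplotype columns equal rs2's column and are
uncorrelated with rs1, so each imputed Z is rs2's Z shrunk by the ridge,
−1/1.15 = −0.8696, with r²pred = 1/1.15 = 0.8696; `status` reads `low_r2pred`
for any variant below the `--r2pred-min` threshold (flagged, never removed).
P values
are two-sided normal tails and remain strictly positive out to |Z| ≈ 41
(P ~ 10⁻³⁶⁸).

Synthetic validation uses the same machinery end to end:

```bash
dish benchmark --set seed=2026 --replicates 200 --out bench.tsv
```

```
replicates:        200
lambda:            0.15
r2pred filter:     >= 0.5
pooled pairs:      3600
pooled Pearson r:  0.9968
pooled Spearman r: 0.9969
```

i.e. across 200 null-model cohorts (1,000 cases + 1,000 controls each),
HLA Z scores imputed from typed-SNP summary statistics correlate at r ≈ 0.99
with Z scores computed from the cohorts' actual HLA dosages, restricted to
variants with r²pred ≥ 0.5.

The library API mirrors the CLI (`dish.build_matrix_store`, `dish.run_dish`,
`dish.run_null_benchmark`, ...); see the module docstrings and
`docs/methods.md`.

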