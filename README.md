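# cosnp

Coincident-SNP (coSNP) enrichment analysis for orthologous protein-coding
sequences of two species.

A **coSNP** is an orthologous genomic position observed to be polymorphic in
both of two compared species (e.g. human and chimpanzee); the two species'
alleles need not match. Because independent mutation should rarely strike
the same base twice, the prevalence of coSNPs is informative about cryptic
mutation-rate variation and about selection. The core statistic is the
observed/expected ratio

```
coSNP_O/E = P_coSNP / (P_SNP_A × P_SNP_B) = n_co · n_sites / (n_A · n_B)
```

where `n_sites` counts the examined orthologous coding sites, `n_A`/`n_B`
the sites polymorphic in each species and `n_co` the sites polymorphic in
both. Under independent uniform placement `coSNP_O/E = 1`. Two mechanisms
raise it above 1 in closed form:

* a per-site mutation-rate field shared by the species (mean 1, squared
  coefficient of variation CV²) gives `coSNP_O/E → 1 + CV²`;
* purifying selection that confines SNPs to a tolerant fraction `f` of the
  sites (the rest being effectively immutable in both species) gives
  `coSNP_O/E → 1/f`.

The second mechanism predicts that zero-fold degenerate sites — where every
substitution changes the amino acid, so constraint is strongest — show an
*elevated* coSNP_O/E relative to four-fold degenerate and neutral sites,
and that the elevation grows with the strength of constraint (lower dN/dS,
higher conservation). The package measures all of this:

* `cosnp.annotation` — orthologous coding-site tables from FASTA + VCF +
  a TSV orthology block map: codon degeneracy (zero / two-three / four-fold,
  ambiguous positions excluded), CpG-dinucleotide flags, interval masks;
* `cosnp.stats` — site classification, coSNP_O/E, chi-square independence,
  per-pattern O/E for the six dimorphic nucleotide patterns (with the
  same-allele diagonal used to screen for shared ancestral polymorphism),
  folded site-frequency spectra, rare-variant fractions;
* `cosnp.strata` — Tajima's D with 100-kb window classes, 1-Mb SNP-density
  and recombination covariates, constraint binning with Spearman trend
  tests, nearest-neighbor paired comparisons of conservation and impact
  scores, 2×2 enrichment tests;
* `cosnp.extrapolate` — SNP/coSNP discovery curves by individual
  subsampling and log-linear projection to large cohorts;
* `cosnp.simulate` — a two-population forward Wright–Fisher simulator under
  purifying selection (finite sites, recombination, codominant fitness),
  with a diffusion-equivalent scaled preset, Wilcoxon selection contrasts
  and two-way ANOVA;
* `cosnp.synth` — synthetic genomes, SNP sets, genotype panels and
  annotation tables with every mechanism behind an explicit knob;
* `cosnp.cli` / `cosnp.workflow` — a `cosnp` command with `synth`,
  `annotate`, `cosnp`, `simulate`, `extrapolate` and `pipeline`
  subcommands.

## Worked example

Run the full pipeline on a synthetic dataset (60 two-exon genes, 27,000
orthologous coding sites, 2% SNP density, a unit-CV shared rate field, and
zero-fold tolerant fractions falling to 0.2 in the most constrained genes):

```
$ cosnp pipeline --seed 7 --out demo
  stratum  n_sites  n_a  n_b  n_co       oe      chi2      p_value  low_expected
      all    23377  389  430    23 3.214390 36.348619 1.649961e-09         False
     zero    15014  241  296    19 3.998907 44.301001 2.815721e-11          True
two_three     4575   82   72     2 1.549797  0.403556 5.252587e-01          True
     four     3788   66   62     2 1.851417  0.810236 3.680506e-01          True
wrote 11 tables to demo
```

Reading the table: 23 of the examined 23,377 sites (CpG-flagged sites
excluded from numerator and denominator) are polymorphic in both species,
3.2× the expectation from the per-species SNP frequencies, and the excess
concentrates at zero-fold degenerate sites (O/E ≈ 4.0, chi-square
p ≈ 3e-11) exactly as the planted tolerant-fraction constraint predicts;
at two-/three-fold and four-fold sites the estimate stays near the
rate-field baseline with too few coincidences for significance at this
dataset size. `demo/` also receives the per-site classification, pattern
O/E, SFS comparison, Tajima's-D window classes, constraint-trend,
nearest-neighbor, enrichment and discovery-curve/projection tables, plus a
run log recording the seed and config hash. Reruns with the same seed are
byte-identical.

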