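# Methods

## The statistic

For a set of orthologous coding sites examined in species A and B, let
`n_sites` be the number of unmasked, unambiguous sites (after any CpG
exclusion), `n_A` and `n_B` the sites polymorphic in each species and
`n_co` the sites polymorphic in both. The coincident-SNP observed/expected
ratio is

    coSNP_O/E = (n_co / n_sites) / ((n_A / n_sites)(n_B / n_sites))
              = n_co · n_sites / (n_A · n_B).

A coSNP requires polymorphism in both species; allele identity is *not*
required (the pattern analysis treats identity separately, because shared
ancestral polymorphisms must show the same allele pair). The ratio is
undefined when either species contributes no SNPs; such strata are
reported with NaN and excluded from trend tests.

Two mechanisms give closed-form expectations used throughout the tests.
With per-site hit probabilities `p_i = d·r_i` for a shared rate field
`r_i` (mean 1, squared CV = CV²) and small `d`, the expectation of the
ratio is `E[r²]/E[r]² = 1 + CV²`. With hits confined to a shared tolerant
subset comprising a fraction `f` of sites (density within the subset
`d/f`, marginal density `d`), the expectation is `1/f`. Both neglect a
small negative bias of the ratio estimator, O(1/n_co) (≈1–2% at the
problem sizes used), which the test tolerances absorb.

## Site annotation

Coordinates are 0-based half-open internally; VCF positions are converted
at I/O. The orthology map is a TSV of colinear, equal-length, indel-free
CDS blocks listed in coding order; it replaces chain-file liftover with a
bit-exact contract. Degeneracy of each codon position is classified under
the standard genetic code from the species-A codon: zero-fold if all three
substitutions change the amino acid, four-fold if none does, two-/three-fold
otherwise. Substitutions creating a stop codon count as amino-acid-changing
(the usual convention). Positions covered by more than one gene with
conflicting classes become AMBIGUOUS and leave every denominator. Genes
whose CDS length is not a multiple of 3, whose block lengths disagree
between species, or which contain an internal stop are skipped with a
warning.

A site is CpG-flagged if it participates in a CG dinucleotide in the
reference of either species (configurable to A-only/B-only/both; "either"
is the conservative default since CpG context is strand-symmetric but not
species-symmetric after divergence). When CpG exclusion is on, flagged
sites are removed from numerator *and* denominator, keeping observed and
expected frequencies on the same site universe. Variants are ingested per
species as biallelic SNVs only; multiallelic and indel records are counted
and dropped, and alleles of minus-strand genes are complemented so that
degeneracy and pattern analyses share one frame.

## Statistical machinery

Chi-square independence uses the 2×2 {SNP in A} × {SNP in B} table,
Pearson statistic, 1 df, no continuity correction by default (counts are
large in intended use; the correction is available for small tables).
Pattern O/E compares, for each ordered pair of the six dimorphic
nucleotide patterns, the observed fraction among coSNPs with the product
of the per-species marginal pattern frequencies among the stratum's SNPs;
the diagonal is the same-allele subset. Site-frequency spectra are folded
(MAF in (0, 0.5]); the spectra of coSNPs and non-coSNPs are compared by a
two-sample KS test on raw MAFs and by the rare-variant fraction
(MAF < 1%) with a two-tailed Fisher exact test. Tajima's D follows the
standard constants (a1, a2, b1, b2, c1, c2, e1, e2); windows without
segregating sites are excluded rather than scored zero. Window classes
follow a dominance hierarchy (any zero-fold coSNP ⇒ the zero-fold class,
else two-/three-fold, else four-fold) and are compared by two-sample KS on
D plus a chi-square test of equal proportions of windows with D ≥ 2.
Constraint binning uses quantile groups of similar size (ties to the lower
bin; windows anchored at position 0 of each chromosome) and a Spearman
rank correlation of group order with group O/E, one-tailed positive by
default. Nearest-neighbor matching pairs each zero-fold coSNP with the
closest candidate site of the requested class within the same gene,
distance in species-A coordinates, ties broken toward the lower
coordinate, which makes the output invariant to input order; paired
comparisons default to the paired t-test with Wilcoxon signed-rank
available. Damaging-change thresholds: SIFT ≤ 0.05 (inclusive),
Grantham > 100 (strict), PolyPhen-2 "possibly"/"probably". Enrichment
tests report the sample odds ratio with the two-tailed Fisher exact p.
Standard tests are delegated to scipy.stats and the two-way ANOVA (type II
sums of squares) to statsmodels.

## Discovery curves and projection

For each cohort size k the SNP count (sites segregating within the
subsample) and coSNP count (those also in a fixed partner-species SNP set)
are averaged over 5 random subsets without replacement (all subsets when
fewer than 5 exist, so k = K is exact). Both counts are fitted by OLS of
log(count) on log(k) — natural logs, a power-law discovery model; a switch
to log(count) ~ k is deliberately not provided because the power law is
the interpretable choice for variant discovery — and projected to a target
cohort (default 1000 individuals). The projected O/E recombines the two
projected counts with the fixed partner SNP count and the fixed site
universe. The projection is only as good as the power-law assumption: the
recovery test generates panels with uniform rare frequencies
(2e-5 … 2e-4), the regime in which discovery is genuinely near-linear in
cohort size through k = 1000; for panels with a substantial common-variant
component the early curve is steeper than the asymptote and projection
from six individuals overshoots severalfold. That caveat applies equally
to real cohorts.

## The forward simulator

Two populations of `n` diploids each descend from one ancestral
population, then evolve independently for `generations_post_split`
generations under: finite-sites mutation (Poisson(2N·μ·L) events per
generation; a recurrent hit at a segregating site flips the carrier back,
keeping sites biallelic), Poisson(r·L) crossovers per gamete with uniform
breakpoints, and multiplicative viability selection with per-site genotype
fitness 1, 1+h·s, 1+s (h = 0.5 by default). SNPs are ascertained as sites
segregating in the whole population (or a configurable sample);
coSNP_O/E uses n_sites = L. Configs with 1+s ≤ 0 are rejected.

Ancestral-state preparation is the main design choice. The default is a
10·2N-generation burn-in from a monomorphic start — unbiased but expensive.
The scaled preset instead draws per-site frequencies from the stationary
Poisson-random-field density for semidominant selection,
f(x) ∝ θ(1−e^{−S(1−x)})/((1−e^{−S})x(1−x)) with S = 2Ns, assigns carriers
binomially (no linkage disequilibrium), and settles for 200 generations of
real dynamics before the split. Marginal site frequencies are then already
stationary and the settling phase rebuilds short-range LD; the neutral
calibration test (segregating sites within 10% of Watterson's θ·L·a_{n−1})
runs on the monomorphic path, so the two initialisations cross-check each
other.

The scaled preset maps the full-scale experiment (N = 1e4, L = 2.5 Mb,
t = 1000 generations) to N = 500 and L = 20 kb by preserving the
diffusion-scale parameters θ = 4Nμ and ρ = 4Nr per site and t/(2N); the
selection coefficients are left at face value, since rescaling them would
make homozygote fitness negative. Grid runs use one independent
SeedSequence stream per scenario and are bitwise reproducible.

**What the simulation shows.** With a shared ancestral population and a
*single* selection coefficient applied to every new mutation, the
per-iteration coSNP_O/E distributions separate sharply between selection
levels at every mutation rate (two-tailed Wilcoxon rank-sum p < 1e-5 with
200 iterations per scenario) — but the direction is a *decline* with |s|:
median O/E of order 10–100 at s = −0.01 against ≈0–1 at s = −0.15. The
mechanism is that the excess coincidence in this design comes entirely
from shared ancestral polymorphism, which decays at rate ≈ h|s| per
generation after the split, so stronger selection destroys cross-species
sharing faster; with homogeneous s there is no tolerant-site heterogeneity
to concentrate the surviving SNPs. The elevation of coSNP_O/E *at
constrained sites* — the phenomenon of scientific interest — is produced
by the tolerant-fraction mechanism (O/E → 1/f) and recovered by the
constraint-trend analysis on synthetic data; the homogeneous-s two-
population run is kept as the clean demonstration that selection strength
alone reshapes the coSNP_O/E distribution.

## The synthetic-data generator

The generator's defaults describe the regime the analysis is meant for: 60
two-exon genes of 150 codons on two chromosomes (27,000 orthologous coding
sites), 1% coding divergence between the species (human–chimpanzee-like),
per-species SNP density 2%, a shared gamma rate field with CV = 1 (the
magnitude of mutation-rate heterogeneity needed to explain genome-wide
coSNP excesses of roughly 2), five constraint tiers whose zero-fold
tolerant fraction falls linearly from 1.0 to 0.2, a 20% share of
identical-allele coincident pairs (shared-ancestral look), MAFs from a
folded neutral (∝1/x) spectrum discretised on 100 chromosomes with a 50%
uniform admixture for coSNPs (the "flatter SFS" feature), transitions
making up 2/3 of new alleles (Ts/Tv = 2), 30% of genes on the minus
strand and 20% of orthologues on the opposite strand in species B.
Annotation tables plant: exon conservation rising and gene dN/dS falling
with constraint tier, a 1-SD conservation deficit and a 0.15
damaging-probability deficit at coSNP sites, and 2:1 enrichment odds for
GWAS/disease labels (1:2 for essential/housekeeping) in zero-fold-coSNP
carriers. Every knob set to its null (CV = 0, f = 1, shifts 0, odds 1)
yields calibrated downstream p-values, which the test suite checks by KS
against uniform over 200 seeds.

What the generator does *not* emulate: linkage disequilibrium between
sites (each site is hit independently), realistic base composition or
codon usage, indels, overlapping genes (available only through hand-built
models in tests), and sequencing/mapping error. Passing tests therefore
validate the statistical machinery and the mechanism arithmetic, not
robustness to the correlated noise of real resequencing data.

## Numerical choices and limitations

Problem sizes in the test suite are chosen so that two to three standard
errors of each Monte-Carlo mean fit inside the stated tolerance band:
168,000 sites × 100 replicates for the 1 + CV² check, × 250 for the 1/f
check, 200 iterations per scenario in the simulation grid, 100 iterations
for the Watterson calibration, 20 seeds for projection recovery. The
chi-square warns (flag, not failure) when an expected cell drops below 5.
Group binning with heavily tied scores can make group sizes uneven; ties
always move whole score classes into the lower bin. The simulator's
stationary initialisation ignores dominance beyond its additive
approximation in the initial frequency draw (exact dynamics apply from the
first settled generation) and the biallelic finite-sites model slightly
understates diversity when θ per site approaches 1, far above any regime
used here.
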