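"""Synthetic orthologous-coding-sequence data with known, planted structure.

Generates everything the analysis consumes — paired reference genomes, an
orthology block map, per-species SNP sets, per-individual genotypes and
annotation tables — with the statistical features the coSNP analysis is
sensitive to, each behind an explicit knob:

* per-site mutation-rate heterogeneity: a gamma rate field with mean 1 and
  coefficient of variation ``rate_cv`` shared by both species (expected
  coSNP_O/E of 1 + CV^2 at low SNP density),
* purifying selection at zero-fold degenerate sites: in a gene of
  constraint tier with tolerant fraction f, SNPs land only in a shared
  tolerant subset comprising a fraction f of the zero-fold sites
  (expected zero-fold coSNP_O/E of 1/f),
* shared ancestral polymorphism: a fraction ``shared_ancestral_fraction``
  of coincident SNPs carries the identical allele pair in both species,
* a flatter folded SFS for coSNPs via a uniform mixture component,
* conservation/impact scores and disease/essential/housekeeping/GWAS
  labels with planted effect sizes and enrichment odds.

Every generator is deterministic given the spec's seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    build_site_table,
    load_gene_models,
    reverse_complement,
)
from .stats import pattern_of

logger = logging.getLogger("cosnp")

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "gen_ortholog_genome",
    "gen_snp_sets",
    "gen_genotypes",
    "gen_annotations",
    "generate_dataset",
    "write_dataset",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = np.array(
    [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
     if a + b + c not in _STOPS]
)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SyntheticSpec:
    """Knobs of the synthetic data regime.

    Defaults describe a small exome-like universe: 60 two-exon genes of
    150 codons on two chromosomes (27,000 orthologous coding sites), 1%
    human-chimp-like coding divergence, per-species SNP density 2% with a
    unit-CV shared mutation-rate field, five constraint tiers whose
    zero-fold tolerant fraction falls from 1.0 to 0.2, and a 20% share of
    identical-allele (ancestral-looking) coincident SNPs.
    """

    n_genes: int = 60
    codons_per_gene: int = 150
    n_chromosomes: int = 2
    divergence: float = 0.01
    rate_cv: float = 1.0
    n_constraint_tiers: int = 5
    tolerant_fractions: tuple[float, ...] | None = None  # default 1.0 -> 0.2
    shared_ancestral_fraction: float = 0.2
    target_snp_density: float = 0.02
    maf_model: str = "neutral"          # "neutral" | "uniform" | "beta"
    beta_params: tuple[float, float] = (0.5, 2.0)
    maf_chromosomes: int = 100          # 2n grid for the folded neutral SFS
    cosnp_flat_weight: float = 0.5      # uniform component of coSNP MAFs
    conservation_tier_shift: float = 1.0   # score shift per tier (SD units)
    cosnp_conservation_shift: float = 1.0  # planted deficit at coSNP sites (SD)
    damaging_base: float = 0.5
    damaging_diff: float = 0.15         # coSNP damaging-probability deficit
    label_enrichment_odds: float = 2.0
    ts_prob: float = 2.0 / 3.0          # transition share of new alleles
    minus_strand_prob: float = 0.3
    opposite_strand_prob: float = 0.2   # orthologue on the other strand in B
    intron_length: int = 60
    intergenic_length: int = 200
    n_individuals: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerant_fractions is None:
            self.tolerant_fractions = tuple(
                np.linspace(1.0, 0.2, self.n_constraint_tiers)
            )
        if len(self.tolerant_fractions) != self.n_constraint_tiers:
            raise ValueError("one tolerant fraction per constraint tier")
        if any(not 0.0 < f <= 1.0 for f in self.tolerant_fractions):
            raise ValueError("tolerant fractions must lie in (0, 1]")
        if not 0.0 <= self.shared_ancestral_fraction <= 1.0:
            raise ValueError("shared_ancestral_fraction must lie in [0, 1]")
        worst = self.target_snp_density / min(self.tolerant_fractions)
        if worst >= 0.1:
            raise ValueError(
                "expected per-site hit probability exceeds 0.1; lower "
                "target_snp_density or raise the tolerant fractions"
            )


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    genome_a: dict[str, str]
    genome_b: dict[str, str]
    orthology: pd.DataFrame
    gene_table: pd.DataFrame        # gene_id, tier, tolerant_fraction
    sites: pd.DataFrame             # coding-site table (annotation module)
    variants_a: pd.DataFrame        # site, species, allele_ref, allele_alt, maf
    variants_b: pd.DataFrame
    genotypes_a: np.ndarray         # individuals x sites, diploid 0/1/2
    annotations: dict[str, pd.DataFrame] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genomes and gene models
# ---------------------------------------------------------------------------


def gen_ortholog_genome(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Random sense-codon genes in two diverged species.

    Returns (genome_a, genome_b, orthology map, gene table). Each gene has
    two equal-length-per-species CDS blocks separated by an intron; species
    B is derived from species A by per-site substitution at the spec's
    divergence rate, resampled where a substitution would create an
    internal stop. Gene order and spacing differ between the assemblies.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    chroms_a: dict[str, list[str]] = {}
    chroms_b: dict[str, list[str]] = {}
    cursors_a: dict[str, int] = {}
    cursors_b: dict[str, int] = {}
    ortho_rows = []
    gene_rows = []
    for i in range(spec.n_genes):
        gene_id = f"g{i:04d}"
        tier = i % spec.n_constraint_tiers
        chrom = f"chr{(i % spec.n_chromosomes) + 1}"
        cds_a = "".join(rng.choice(_SENSE_CODONS, size=spec.codons_per_gene))
        cds_b = _diverge_cds(cds_a, spec.divergence, rng)
        n = len(cds_a)
        cut = (n // 2) - ((n // 2) % 1)   # split point into two blocks
        block_lengths = [cut, n - cut]
        strand_a = "-" if rng.random() < spec.minus_strand_prob else "+"
        strand_b = strand_a
        if rng.random() < spec.opposite_strand_prob:
            strand_b = "+" if strand_a == "-" else "-"
        start_a, blocks_a = _place_gene(
            chroms_a, cursors_a, chrom, cds_a, block_lengths, strand_a, spec, rng
        )
        start_b, blocks_b = _place_gene(
            chroms_b, cursors_b, chrom, cds_b, block_lengths, strand_b, spec, rng
        )
        for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
            ortho_rows.append(
                (gene_id, chrom, sa, ea, strand_a, chrom, sb, eb, strand_b)
            )
        gene_rows.append((gene_id, tier, spec.tolerant_fractions[tier]))
    genome_a = {c: "".join(parts) for c, parts in chroms_a.items()}
    genome_b = {c: "".join(parts) for c, parts in chroms_b.items()}
    orthology = pd.DataFrame(
        ortho_rows,
        columns=["gene_id", "chrom_A", "start_A", "end_A", "strand_A",
                 "chrom_B", "start_B", "end_B", "strand_B"],
    )
    gene_table = pd.DataFrame(gene_rows, columns=["gene_id", "tier", "tolerant_fraction"])
    return genome_a, genome_b, orthology, gene_table


def _diverge_cds(cds: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return cds
    seq = np.array(list(cds))
    hit = rng.random(seq.size) < rate
    for pos in np.flatnonzero(hit):
        alts = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = alts[rng.integers(3)]
    # revert any codon the substitutions turned into a stop
    for ci in range(seq.size // 3):
        codon = "".join(seq[3 * ci: 3 * ci + 3])
        if codon in _STOPS:
            seq[3 * ci: 3 * ci + 3] = list(cds[3 * ci: 3 * ci + 3])
    return "".join(seq)


def _random_bases(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _place_gene(chrom_parts, cursors, chrom, cds, block_lengths, strand, spec, rng):
    """Append one gene to a growing chromosome; return (start, coding-order blocks)."""
    parts = chrom_parts.setdefault(chrom, [])
    cursor = cursors.get(chrom, 0)
    gap = spec.intergenic_length + int(rng.integers(0, spec.intergenic_length))
    parts.append(_random_bases(gap, rng))
    cursor += gap
    segs = []
    off = 0
    for length in block_lengths:
        segs.append(cds[off: off + length])
        off += length
    intron = _random_bases(spec.intron_length, rng)
    start = cursor
    if strand == "+":
        genomic = [segs[0], intron, segs[1]]
        blocks = [
            (start, start + len(segs[0])),
            (start + len(segs[0]) + len(intron),
             start + len(segs[0]) + len(intron) + len(segs[1])),
        ]
    else:
        # ascending genomic order holds the last coding block first
        genomic = [reverse_complement(segs[1]), intron, reverse_complement(segs[0])]
        second_start = start + len(segs[1]) + len(intron)
        blocks = [
            (second_start, second_start + len(segs[0])),
            (start, start + len(segs[1])),
        ]
    parts.extend(genomic)
    cursor += sum(len(p) for p in genomic)
    cursors[chrom] = cursor
    return start, blocks


# ---------------------------------------------------------------------------
# SNP sets
# ---------------------------------------------------------------------------


def gen_snp_sets(
    sites: pd.DataFrame,
    gene_table: pd.DataFrame,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species variant tables in site-table space.

    Per-site hit probability = density * rate_i * tolerance_i / f, where
    rate_i is the shared gamma field and the tolerance indicator restricts
    zero-fold sites of a tier with tolerant fraction f to a shared
    tolerant subset (keeping the marginal density at ``density``). Hits
    are independent between species given the shared field; a fraction
    ``shared_ancestral_fraction`` of double hits is forced to the
    identical allele pair (where the two references still agree). MAFs
    come from the spec's model, with an extra uniform component for coSNPs.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    n = len(sites)
    usable = (~sites["masked"]).to_numpy()
    if spec.rate_cv > 0:
        shape = 1.0 / spec.rate_cv**2
        rates = rng.gamma(shape, 1.0 / shape, size=n)
    else:
        rates = np.ones(n)
    frac = gene_table.set_index("gene_id")["tolerant_fraction"]
    f_site = sites["gene_id"].map(frac).fillna(1.0).to_numpy()
    constrained = (sites["degeneracy"] == "zero").to_numpy() & (f_site < 1.0)
    f_eff = np.where(constrained, f_site, 1.0)
    tolerant = np.ones(n, dtype=bool)
    tolerant[constrained] = rng.random(constrained.sum()) < f_site[constrained]
    p = spec.target_snp_density * rates * tolerant / f_eff
    p = np.minimum(p, 0.4) * usable
    if p[usable].mean() == 0:
        raise ValueError("requested density unreachable: every usable site masked out")
    hit_a = rng.random(n) < p
    hit_b = rng.random(n) < p
    both = hit_a & hit_b
    same_allele = both & (rng.random(n) < spec.shared_ancestral_fraction)
    same_allele &= (sites["ref_a"] == sites["ref_b"]).to_numpy()

    alt_a = _draw_alts(sites["ref_a"].to_numpy(), spec, rng)
    alt_b = _draw_alts(sites["ref_b"].to_numpy(), spec, rng)
    alt_b[same_allele] = alt_a[same_allele]

    var_a = _variant_frame(sites, hit_a, alt_a, "A", both, spec, rng)
    var_b = _variant_frame(sites, hit_b, alt_b, "B", both, spec, rng)
    return var_a, var_b


def _draw_alts(refs: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator
               ) -> np.ndarray:
    n = refs.size
    alts = np.empty(n, dtype=object)
    is_ts = rng.random(n) < spec.ts_prob
    pick = rng.integers(0, 2, size=n)
    for i in range(n):
        ref = refs[i]
        if is_ts[i]:
            alts[i] = _TRANSITION[ref]
        else:
            tv = [b for b in "ACGT" if b != ref and b != _TRANSITION[ref]]
            alts[i] = tv[pick[i]]
    return alts


def _variant_frame(sites, hits, alts, species, both, spec, rng) -> pd.DataFrame:
    idx = np.flatnonzero(hits)
    ref_col = f"ref_{species.lower()}"
    maf = _draw_maf(idx.size, spec, rng)
    flat = rng.random(idx.size) < spec.cosnp_flat_weight
    is_co = both[idx]
    flatten = is_co & flat
    maf[flatten] = rng.uniform(0.01, 0.5, size=int(flatten.sum()))
    return pd.DataFrame(
        {
            "site": idx,
            "species": species,
            "allele_ref": sites[ref_col].to_numpy()[idx],
            "allele_alt": alts[idx],
            "maf": maf,
        }
    )


def _draw_maf(n: int, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.maf_model == "uniform":
        return rng.uniform(0.005, 0.5, size=n)
    if spec.maf_model == "beta":
        a, b = spec.beta_params
        maf = 0.5 * rng.beta(a, b, size=n)
        return np.clip(maf, 1e-3, 0.5)
    if spec.maf_model == "neutral":
        two_n = spec.maf_chromosomes
        j = np.arange(1, two_n // 2 + 1)
        w = 1.0 / j + 1.0 / (two_n - j)
        w[-1] = 1.0 / j[-1] if two_n % 2 == 0 else w[-1]
        w /= w.sum()
        return rng.choice(j, size=n, p=w) / two_n
    raise ValueError(f"unknown maf_model {spec.maf_model!r}")


def gen_discovery_panel(
    n_sites: int,
    n_panel: int,
    n_subsample: int,
    rng: np.random.Generator,
    q_low: float = 2e-5,
    q_high: float = 2e-4,
    partner_fraction: float = 0.3,
) -> dict:
    """Large-cohort panel for discovery-curve extrapolation checks.

    Population frequencies are uniform on [q_low, q_high] — the
    rare-variant-dominated regime in which SNP discovery grows as a power
    law of cohort size, so the log-linear projection model is correctly
    specified. Returns carrier counts for the full ``n_panel``-diploid
    panel, genotypes of a nested ``n_subsample``-individual subsample
    (drawn hypergeometrically), a partner-species SNP mask, and the
    realized full-panel SNP/coSNP counts the projection is judged against.
    """
    if n_subsample > n_panel:
        raise ValueError("subsample larger than panel")
    q = rng.uniform(q_low, q_high, n_sites)
    two_n = 2 * n_panel
    carriers = rng.binomial(two_n, q)
    seg = (carriers > 0) & (carriers < two_n)
    partner = rng.random(n_sites) < partner_fraction
    sub_carriers = rng.hypergeometric(carriers, two_n - carriers, 2 * n_subsample)
    genotypes = np.zeros((n_subsample, n_sites), dtype=np.int8)
    for site in np.flatnonzero(sub_carriers > 0):
        chroms = rng.choice(2 * n_subsample, size=sub_carriers[site], replace=False)
        for c in chroms:
            genotypes[c // 2, site] += 1
    return {
        "q": q,
        "carriers": carriers,
        "genotypes": genotypes,
        "partner_mask": partner,
        "realized_snps": int(seg.sum()),
        "realized_cosnps": int((seg & partner).sum()),
    }


def gen_genotypes(
    variants: pd.DataFrame, n_sites: int, n_individuals: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Diploid genotype matrix (individuals x sites) from variant MAFs.

    Sites without a variant are monomorphic (0); variant sites get
    binomial(2, maf) derived-allele counts per individual.
    """
    g = np.zeros((n_individuals, n_sites), dtype=np.int8)
    idx = variants["site"].to_numpy()
    maf = variants["maf"].to_numpy()
    g[:, idx] = rng.binomial(2, maf, size=(n_individuals, idx.size)).astype(np.int8)
    return g


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def gen_annotations(
    sites: pd.DataFrame,
    gene_table: pd.DataFrame,
    variants_a: pd.DataFrame,
    variants_b: pd.DataFrame,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Score and label tables with planted effects.

    exons: per-block PhastCons-like conservation rising with constraint
    tier. genes: dN/dS falling with tier, plus disease / essential /
    housekeeping flags whose odds depend on carrying a zero-fold coSNP.
    site_scores: PhyloP/GERP-like per-site conservation, lower at coSNP
    sites by the planted shift. impact: SIFT/Grantham/PolyPhen-like scores
    for zero-fold variants of species A, coSNPs less damaging, plus a GWAS
    flag enriched at coSNPs. recomb: a gamma-distributed per-1Mb-window
    rate map. With all effect sizes zero the tables are pure noise and the
    downstream tests are calibrated.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    co_sites = np.intersect1d(variants_a["site"].to_numpy(),
                              variants_b["site"].to_numpy())
    is_co = np.zeros(len(sites), dtype=bool)
    is_co[co_sites] = True

    tiers = gene_table.set_index("gene_id")["tier"]
    t_max = max(spec.n_constraint_tiers - 1, 1)

    # exon-level conservation
    exon_rows = []
    for gene_id, tier in tiers.items():
        base = 0.2 + 0.75 * tier / t_max * min(spec.conservation_tier_shift, 1.0)
        for block in range(2):
            score = np.clip(base + rng.normal(0, 0.05), 0.0, 1.0)
            exon_rows.append((f"{gene_id}_e{block}", gene_id, score))
    exons = pd.DataFrame(exon_rows, columns=["exon_id", "gene_id", "phastcons"])

    # gene-level dN/dS and labels
    zero_co = set(
        sites.loc[np.flatnonzero(is_co)]
        .loc[lambda d: d["degeneracy"] == "zero", "gene_id"]
    )
    genes = gene_table.copy()
    genes["dn_ds"] = np.exp(
        -1.2 * genes["tier"] / t_max * spec.conservation_tier_shift
        + rng.normal(0, 0.25, len(genes))
    ) * 0.6
    genes["has_cosnp_i0"] = genes["gene_id"].isin(zero_co)
    odds = spec.label_enrichment_odds
    for label, gene_odds in (("disease", odds), ("essential", 1.0 / odds),
                             ("housekeeping", 1.0 / odds)):
        base_p = 0.25
        p_hit = base_p * gene_odds / (1 - base_p + base_p * gene_odds)
        prob = np.where(genes["has_cosnp_i0"], p_hit, base_p)
        genes[label] = rng.random(len(genes)) < prob

    # per-site conservation, lower where a coSNP sits
    tier_site = sites["gene_id"].map(tiers).fillna(0).to_numpy()
    base = tier_site / t_max * spec.conservation_tier_shift
    shift = spec.cosnp_conservation_shift * is_co
    site_scores = pd.DataFrame(
        {
            "site": sites.index,
            "phylop": base - shift + rng.normal(0, 1, len(sites)),
            "gerp": 2.0 * (base - shift) + rng.normal(0, 2, len(sites)),
        }
    )

    # impact scores for nonsynonymous (zero-fold) A-variants + GWAS flag
    zero_idx = set(np.flatnonzero((sites["degeneracy"] == "zero").to_numpy()))
    va = variants_a[variants_a["site"].isin(zero_idx)].copy()
    co = is_co[va["site"].to_numpy()]
    p_dam = np.where(co, spec.damaging_base - spec.damaging_diff, spec.damaging_base)
    damaging = rng.random(len(va)) < p_dam
    va["sift"] = np.where(damaging, rng.uniform(0.0, 0.05, len(va)),
                          rng.uniform(0.06, 1.0, len(va)))
    va["grantham"] = np.where(damaging, rng.uniform(101, 215, len(va)),
                              rng.uniform(5, 100, len(va)))
    cat = np.where(damaging,
                   np.where(rng.random(len(va)) < 0.5, "probably", "possibly"),
                   "benign")
    va["polyphen"] = cat
    base_p = 0.05
    p_gwas = np.where(co, base_p * odds / (1 - base_p + base_p * odds), base_p)
    va["gwas"] = rng.random(len(va)) < p_gwas
    impact = va[["site", "sift", "grantham", "polyphen", "gwas"]].reset_index(drop=True)

    # recombination map, 1-Mb windows covering species-A coordinates
    recomb_rows = []
    for chrom, sub in sites.groupby("chrom_a"):
        for w in range(int(sub["coord_a"].max() // 1_000_000) + 1):
            recomb_rows.append((chrom, w, float(rng.gamma(2.0, 0.6))))
    recomb = pd.DataFrame(recomb_rows, columns=["chrom", "window", "rate"])

    return {"exons": exons, "genes": genes, "site_scores": site_scores,
            "impact": impact, "recomb": recomb}


# ---------------------------------------------------------------------------
# one-call dataset and writers
# ---------------------------------------------------------------------------


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Full synthetic dataset: genomes, site table, SNPs, genotypes, scores."""
    rng = np.random.default_rng(spec.seed)
    genome_a, genome_b, orthology, gene_table = gen_ortholog_genome(spec, rng)
    models = load_gene_models(orthology, genome_a, genome_b)
    sites = build_site_table(models, genome_a, genome_b)
    variants_a, variants_b = gen_snp_sets(sites, gene_table, spec, rng)
    genotypes_a = gen_genotypes(variants_a, len(sites), spec.n_individuals, rng)
    annotations = gen_annotations(sites, gene_table, variants_a, variants_b, spec, rng)
    return SyntheticDataset(
        spec=spec, genome_a=genome_a, genome_b=genome_b, orthology=orthology,
        gene_table=gene_table, sites=sites, variants_a=variants_a,
        variants_b=variants_b, genotypes_a=genotypes_a, annotations=annotations,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as FASTA / VCF / TSV files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, genome in (("genome_a", ds.genome_a), ("genome_b", ds.genome_b)):
        path = outdir / f"{name}.fa"
        with open(path, "w") as fh:
            for chrom, seq in genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        paths[name] = path
    paths["orthology"] = outdir / "orthology.tsv"
    ds.orthology.to_csv(paths["orthology"], sep="\t", index=False)
    paths["genes"] = outdir / "gene_table.tsv"
    ds.gene_table.to_csv(paths["genes"], sep="\t", index=False)
    for name, variants, genome in (
        ("snps_a", ds.variants_a, ds.genome_a),
        ("snps_b", ds.variants_b, ds.genome_b),
    ):
        path = outdir / f"{name}.vcf"
        _write_vcf(path, ds.sites, variants, genome)
        paths[name] = path
    for name, table in ds.annotations.items():
        path = outdir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False)
        paths[name] = path
    paths["genotypes_a"] = outdir / "genotypes_a.tsv"
    pd.DataFrame(
        ds.genotypes_a,
        index=[f"ind{i}" for i in range(ds.genotypes_a.shape[0])],
    ).to_csv(paths["genotypes_a"], sep="\t")
    return paths


def _write_vcf(path: Path, sites: pd.DataFrame, variants: pd.DataFrame,
               genome: dict[str, str]) -> None:
    import pysam

    species = variants["species"].iloc[0].lower() if len(variants) else "a"
    chrom_col, coord_col, strand_col = (
        f"chrom_{species}", f"coord_{species}", f"strand_{species}",
    )
    header = pysam.VariantHeader()
    header.add_meta("source", "cosnp-synth")
    for chrom, seq in genome.items():
        header.contigs.add(chrom, length=len(seq))
    header.info.add("AF", "A", "Float", "Alternate allele frequency")
    comp = str.maketrans("ACGT", "TGCA")
    records = []
    for _, var in variants.iterrows():
        site = sites.loc[var["site"]]
        ref, alt = var["allele_ref"], var["allele_alt"]
        if site[strand_col] == "-":
            ref, alt = ref.translate(comp), alt.translate(comp)
        records.append(
            (site[chrom_col], int(site[coord_col]), ref, alt, float(var["maf"]))
        )
    records.sort(key=lambda r: (r[0], r[1]))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for chrom, pos, ref, alt, maf in records:
            rec = vcf.new_record(contig=chrom, start=pos, stop=pos + 1,
                                 alleles=(ref, alt))
            rec.info["AF"] = maf
            vcf.write(rec)
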