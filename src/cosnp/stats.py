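"""Core coincident-SNP statistics.

A coSNP is an orthologous site polymorphic in both compared species (the
alleles need not match). Its prevalence is summarised by the
observed/expected ratio

    coSNP_O/E = P_coSNP / (P_SNP_A * P_SNP_B)
              = n_co * n_sites / (n_A * n_B),

which equals 1 when SNPs are placed independently at random in the two
species. Supporting statistics: chi-square independence on the 2x2
SNP-presence table, per-pattern O/E for the six dimorphic nucleotide
patterns, folded site-frequency spectra, and rare-variant fractions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import Degeneracy, cpg_flags

logger = logging.getLogger("cosnp")

__all__ = [
    "CoSNPCounts",
    "PATTERNS",
    "classify_sites",
    "count_sites",
    "cosnp_oe",
    "chisq_independence",
    "stratified_counts",
    "pattern_oe",
    "site_frequency_spectrum",
    "compare_sfs",
    "rare_variant_fraction",
    "compare_rare_fraction",
]

#: the six dimorphic nucleotide patterns, coding strand, alphabetical
PATTERNS = tuple(f"{a}/{b}" for a, b in itertools.combinations("ACGT", 2))


@dataclass(frozen=True)
class CoSNPCounts:
    """Stratum-level tallies from which coSNP_O/E is computed."""

    stratum: str
    n_sites: int
    n_a: int
    n_b: int
    n_co: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_co <= min(self.n_a, self.n_b) <= self.n_sites:
            raise ValueError(
                f"inconsistent counts: n_co={self.n_co}, n_a={self.n_a}, "
                f"n_b={self.n_b}, n_sites={self.n_sites}"
            )


def pattern_of(allele1: str, allele2: str) -> str:
    a, b = sorted((allele1.upper(), allele2.upper()))
    if a == b:
        raise ValueError("pattern requires two distinct alleles")
    return f"{a}/{b}"


def classify_sites(
    variants_a: pd.DataFrame, variants_b: pd.DataFrame, sites: pd.DataFrame
) -> pd.Series:
    """Per-site class: ``cosnp``, ``nonco_a_only``, ``nonco_b_only``, ``nonsnp``.

    Only unmasked, unambiguous sites are examined; variant rows pointing
    elsewhere are dropped with a logged count. Sites hit more than once in
    one species (multiallelic after upstream filtering) are excluded from
    the examined universe entirely (class NaN), logged.
    """
    usable = _usable_mask(sites)
    cls = pd.Series(np.where(usable, "nonsnp", None), index=sites.index, dtype=object)
    hits = {}
    for name, var in (("a", variants_a), ("b", variants_b)):
        idx = var["site"].to_numpy()
        ok = usable.reindex(idx, fill_value=False).to_numpy()
        if (~ok).any():
            logger.info("classify_sites: dropped %d species-%s variants at "
                        "masked/ambiguous sites", int((~ok).sum()), name.upper())
        idx = idx[ok]
        unique, counts = np.unique(idx, return_counts=True)
        multi = unique[counts > 1]
        if multi.size:
            logger.warning("classify_sites: %d species-%s sites with multiple "
                           "variant records excluded", multi.size, name.upper())
            cls[multi] = None
            unique = unique[counts == 1]
        hits[name] = set(unique.tolist())
    in_a = cls.index.isin(hits["a"]) & cls.notna()
    in_b = cls.index.isin(hits["b"]) & cls.notna()
    cls[in_a & in_b] = "cosnp"
    cls[in_a & ~in_b] = "nonco_a_only"
    cls[~in_a & in_b] = "nonco_b_only"
    return cls


def _usable_mask(sites: pd.DataFrame) -> pd.Series:
    return (~sites["masked"]) & (sites["degeneracy"] != Degeneracy.AMBIGUOUS.value)


def count_sites(classes: pd.Series, stratum: str = "all") -> CoSNPCounts:
    """Collapse a per-site classification into CoSNPCounts."""
    valid = classes.dropna()
    n_co = int((valid == "cosnp").sum())
    return CoSNPCounts(
        stratum=stratum,
        n_sites=len(valid),
        n_a=n_co + int((valid == "nonco_a_only").sum()),
        n_b=n_co + int((valid == "nonco_b_only").sum()),
        n_co=n_co,
    )


def cosnp_oe(counts: CoSNPCounts) -> float:
    """Observed/expected coSNP ratio, n_co * n_sites / (n_A * n_B)."""
    if counts.n_a == 0 or counts.n_b == 0:
        raise ValueError("coSNP_O/E undefined: no SNPs in one species")
    return counts.n_co * counts.n_sites / (counts.n_a * counts.n_b)


def chisq_independence(
    counts: CoSNPCounts, correction: bool = False
) -> tuple[float, float, bool]:
    """Pearson chi-square (1 df) on the 2x2 SNP-presence contingency table.

    Table: {SNP in A yes/no} x {SNP in B yes/no}. No continuity correction
    by default. Returns (statistic, p, low_expected) where the flag warns
    of any expected cell below 5.
    """
    table = np.array(
        [
            [counts.n_co, counts.n_a - counts.n_co],
            [counts.n_b - counts.n_co,
             counts.n_sites - counts.n_a - counts.n_b + counts.n_co],
        ]
    )
    res = sps.chi2_contingency(table, correction=correction)
    low = bool((res.expected_freq < 5).any())
    if low:
        logger.debug("chisq_independence: expected cell below 5 in stratum %s",
                     counts.stratum)
    return float(res.statistic), float(res.pvalue), low


def stratified_counts(
    sites: pd.DataFrame,
    classes: pd.Series,
    exclude_cpg: bool = True,
    cpg_mode: str = "either",
) -> pd.DataFrame:
    """Per-degeneracy-class CoSNPCounts with O/E and chi-square columns.

    With CpG exclusion on, CpG-flagged sites leave both the numerator and
    the denominator, keeping observed and expected frequencies on the same
    site universe. An ``all`` row covers every examined coding site.
    """
    keep = classes.notna()
    if exclude_cpg:
        keep &= ~cpg_flags(sites, cpg_mode)
    rows = []
    strata: list[tuple[str, pd.Series]] = [("all", keep)]
    for degen in (Degeneracy.ZERO, Degeneracy.TWO_THREE, Degeneracy.FOUR):
        strata.append((degen.value, keep & (sites["degeneracy"] == degen.value)))
    for label, mask in strata:
        counts = count_sites(classes[mask], stratum=label)
        row = {
            "stratum": label,
            "n_sites": counts.n_sites,
            "n_a": counts.n_a,
            "n_b": counts.n_b,
            "n_co": counts.n_co,
        }
        if counts.n_a and counts.n_b:
            row["oe"] = cosnp_oe(counts)
            stat, p, low = chisq_independence(counts)
            row.update(chi2=stat, p_value=p, low_expected=low)
        else:
            row.update(oe=np.nan, chi2=np.nan, p_value=np.nan, low_expected=True)
        rows.append(row)
    return pd.DataFrame(rows)


def pattern_oe(
    classes: pd.Series,
    variants_a: pd.DataFrame,
    variants_b: pd.DataFrame,
    stratum_sites: pd.Index | None = None,
) -> pd.DataFrame:
    """Observed/expected table over pattern pairs of the two species.

    For pattern pair (p, q): O = fraction of coSNPs with pattern p in A and
    q in B; E = (marginal frequency of p among the stratum's A-SNPs) x
    (marginal of q among B-SNPs). The 6-entry diagonal is the same-allele
    subset used to screen for shared ancestral polymorphism. Returns a long
    table with columns pattern_a, pattern_b, observed, expected, oe,
    same_pattern; empty for an empty stratum.
    """
    snp_sites = classes[classes.isin(["cosnp", "nonco_a_only", "nonco_b_only"])].index
    if stratum_sites is not None:
        snp_sites = snp_sites.intersection(stratum_sites)
    pat_a = _patterns_by_site(variants_a, snp_sites)
    pat_b = _patterns_by_site(variants_b, snp_sites)
    co_sites = classes[classes == "cosnp"].index
    if stratum_sites is not None:
        co_sites = co_sites.intersection(stratum_sites)
    if len(co_sites) == 0 or pat_a.empty or pat_b.empty:
        return pd.DataFrame(
            columns=["pattern_a", "pattern_b", "observed", "expected", "oe",
                     "same_pattern"]
        )
    marg_a = pat_a.value_counts(normalize=True)
    marg_b = pat_b.value_counts(normalize=True)
    joint = (
        pd.DataFrame({"pa": pat_a.reindex(co_sites), "pb": pat_b.reindex(co_sites)})
        .value_counts(normalize=True)
    )
    rows = []
    for pa in PATTERNS:
        for pb in PATTERNS:
            obs = float(joint.get((pa, pb), 0.0))
            exp = float(marg_a.get(pa, 0.0) * marg_b.get(pb, 0.0))
            if obs == 0.0 and exp == 0.0:
                continue
            rows.append(
                {
                    "pattern_a": pa,
                    "pattern_b": pb,
                    "observed": obs,
                    "expected": exp,
                    "oe": obs / exp if exp > 0 else np.nan,
                    "same_pattern": pa == pb,
                }
            )
    return pd.DataFrame(rows)


def _patterns_by_site(variants: pd.DataFrame, site_index: pd.Index) -> pd.Series:
    var = variants[variants["site"].isin(site_index)]
    var = var.drop_duplicates(subset="site", keep=False)  # dimorphic only
    return pd.Series(
        [pattern_of(r, a) for r, a in zip(var["allele_ref"], var["allele_alt"])],
        index=var["site"].to_numpy(),
    )


def site_frequency_spectrum(
    maf: np.ndarray | pd.Series, bin_edges: np.ndarray | None = None
) -> pd.DataFrame:
    """Folded SFS: proportion of variants per minor-allele-frequency bin.

    MAF must lie in (0, 0.5]. Default bins: ten equal bins over (0, 0.5].
    Proportions sum to 1.
    """
    maf = np.asarray(maf, dtype=float)
    if maf.size == 0:
        raise ValueError("empty variant set")
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("minor allele frequencies must lie in (0, 0.5]")
    if bin_edges is None:
        bin_edges = np.linspace(0.0, 0.5, 11)
    counts, edges = np.histogram(maf, bins=bin_edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "proportion": counts / counts.sum(),
        }
    )


def compare_sfs(maf_1, maf_2) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on raw (unbinned) MAF values."""
    x = np.asarray(maf_1, dtype=float)
    y = np.asarray(maf_2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 variants in each sample")
    res = sps.ks_2samp(x, y)
    return float(res.statistic), float(res.pvalue)


def rare_variant_fraction(maf, cutoff: float = 0.01) -> float:
    """Fraction of variants with MAF below ``cutoff`` (default 1%)."""
    maf = np.asarray(maf, dtype=float)
    if maf.size == 0:
        raise ValueError("empty variant group")
    if not 0.0 < cutoff < 0.5:
        raise ValueError("cutoff must lie in (0, 0.5)")
    return float(np.mean(maf < cutoff))


def compare_rare_fraction(maf_1, maf_2, cutoff: float = 0.01
                          ) -> tuple[float, float, float, float]:
    """Rare-variant fractions of two groups with a two-tailed Fisher test.

    Returns (fraction_1, fraction_2, odds_ratio, p).
    """
    f1 = rare_variant_fraction(maf_1, cutoff)
    f2 = rare_variant_fraction(maf_2, cutoff)
    n1, n2 = len(np.atleast_1d(maf_1)), len(np.atleast_1d(maf_2))
    r1, r2 = round(f1 * n1), round(f2 * n2)
    odds, p = sps.fisher_exact([[r1, n1 - r1], [r2, n2 - r2]], alternative="two-sided")
    return f1, f2, float(odds), float(p)
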