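"""Window-, group- and pairing-based analyses around coSNP_O/E.

Covers: Tajima's D and its 100-kb window classes (shared-ancestral-
polymorphism screen), 1-Mb SNP-density/recombination covariates,
constraint binning with Spearman trend tests, nearest-neighbor functional
comparisons at zero-fold sites, damaging-change fractions, and generic 2x2
enrichment tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import Degeneracy
from .stats import CoSNPCounts, cosnp_oe

logger = logging.getLogger("cosnp")

__all__ = [
    "tajimas_d",
    "classify_cosnp_windows",
    "compare_window_classes",
    "window_covariates",
    "equal_size_groups",
    "group_oe_trend",
    "nearest_neighbor_match",
    "paired_score_test",
    "damaging_fraction",
    "compare_damaging",
    "two_by_two_enrichment",
    "equal_proportions_test",
]

#: dominance hierarchy of window classes (a zero-fold coSNP wins, etc.)
_CLASS_ORDER = [Degeneracy.ZERO.value, Degeneracy.TWO_THREE.value, Degeneracy.FOUR.value]
_CLASS_LABEL = {
    Degeneracy.ZERO.value: "cosnp_i0",
    Degeneracy.TWO_THREE.value: "cosnp_i23",
    Degeneracy.FOUR.value: "cosnp_i4",
}


def tajimas_d(genotypes: np.ndarray) -> float:
    """Tajima's D from a haplotype-by-site 0/1 matrix.

    D = (theta_pi - theta_W) / sqrt(e1*S + e2*S*(S-1)) with the standard
    a1, a2, b1, b2, c1, c2, e1, e2 constants. Requires >= 4 haplotypes and
    >= 1 segregating site (raises ``ValueError`` otherwise: the window is
    excluded rather than scored 0).
    """
    g = np.asarray(genotypes)
    n = g.shape[0]
    if n < 4:
        raise ValueError("Tajima's D requires at least 4 haplotypes")
    counts = g.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    s = int(seg.sum())
    if s == 0:
        raise ValueError("no segregating sites; D undefined")
    counts = counts[seg]
    # mean pairwise differences
    pi = float(np.sum(2.0 * counts * (n - counts)) / (n * (n - 1)))
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * s + e2 * s * (s - 1)
    return float((pi - s / a1) / np.sqrt(var))


def classify_cosnp_windows(
    cosnps: pd.DataFrame, width: int = 100_000
) -> pd.DataFrame:
    """Assign fixed windows a coSNP-degeneracy class by dominance.

    ``cosnps`` needs columns chrom, coord, degeneracy. Windows are anchored
    at position 0 of each chromosome. Any zero-fold coSNP makes the window
    ``cosnp_i0``; else any two-/three-fold makes it ``cosnp_i23``; else
    ``cosnp_i4``. Ambiguous-degeneracy coSNPs are dropped with a warning.
    Only windows containing at least one coSNP are returned.
    """
    df = cosnps.copy()
    known = df["degeneracy"].isin(_CLASS_ORDER)
    if (~known).any():
        logger.warning("classify_cosnp_windows: dropped %d coSNPs without a "
                       "usable degeneracy class", int((~known).sum()))
        df = df[known]
    if df.empty:
        return pd.DataFrame(columns=["chrom", "window", "cosnp_class"])
    df["window"] = df["coord"] // width
    rank = df["degeneracy"].map({c: i for i, c in enumerate(_CLASS_ORDER)})
    best = (
        df.assign(rank=rank)
        .groupby(["chrom", "window"], as_index=False)["rank"]
        .min()
    )
    best["cosnp_class"] = best.pop("rank").map(
        {i: _CLASS_LABEL[c] for i, c in enumerate(_CLASS_ORDER)}
    )
    return best


def compare_window_classes(
    windows: pd.DataFrame, d_threshold: float = 2.0
) -> pd.DataFrame:
    """Compare Tajima's D between coSNP window classes.

    ``windows`` needs columns cosnp_class and tajimas_d. Each class pair is
    compared by a two-sample KS test on D and the classes jointly by a
    chi-square test of equal proportions of windows with D >= threshold.
    Returns one row per pair plus an ``equal_proportions`` row.
    """
    groups = {
        label: sub["tajimas_d"].dropna().to_numpy()
        for label, sub in windows.groupby("cosnp_class")
    }
    labels = sorted(groups)
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            res = sps.ks_2samp(groups[la], groups[lb])
            rows.append(
                {
                    "comparison": f"{la}_vs_{lb}",
                    "test": "ks",
                    "statistic": float(res.statistic),
                    "p_value": float(res.pvalue),
                }
            )
    successes = np.array([(groups[lb] >= d_threshold).sum() for lb in labels])
    totals = np.array([len(groups[lb]) for lb in labels])
    stat, p = equal_proportions_test(successes, totals)
    rows.append(
        {
            "comparison": "high_d_fraction:" + "|".join(labels),
            "test": "chi2_equal_proportions",
            "statistic": stat,
            "p_value": p,
        }
    )
    return pd.DataFrame(rows)


def window_covariates(
    sites: pd.DataFrame,
    variants: pd.DataFrame,
    recomb_map: pd.DataFrame | None = None,
    width: int = 1_000_000,
) -> pd.DataFrame:
    """Single-species SNP density and mean recombination rate per window.

    Density = SNP count / examined (unmasked, unambiguous) sites in the
    window, species-A coordinates. Windows with zero examined sites are
    excluded; with a recombination map (columns chrom, window, rate),
    windows absent from the map are excluded.
    """
    usable = sites[
        (~sites["masked"]) & (sites["degeneracy"] != Degeneracy.AMBIGUOUS.value)
    ]
    examined = (
        usable.assign(window=usable["coord_a"] // width)
        .groupby(["chrom_a", "window"])
        .size()
        .rename("n_sites")
    )
    snp_sites = usable.loc[usable.index.intersection(pd.Index(variants["site"]))]
    snps = (
        snp_sites.assign(window=snp_sites["coord_a"] // width)
        .groupby(["chrom_a", "window"])
        .size()
        .rename("n_snps")
    )
    out = pd.concat([examined, snps], axis=1).fillna({"n_snps": 0}).reset_index()
    out = out.rename(columns={"chrom_a": "chrom"})
    out = out[out["n_sites"] > 0]
    out["snp_density"] = out["n_snps"] / out["n_sites"]
    if recomb_map is not None:
        out = out.merge(recomb_map, on=["chrom", "window"], how="inner")
    return out.reset_index(drop=True)


def equal_size_groups(scores: np.ndarray | pd.Series, k_groups: int) -> np.ndarray:
    """Quantile bins of similar size; ties go to the lower bin.

    With all-distinct scores the group sizes differ by at most 1. If every
    score is identical a single group is returned with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if k_groups < 2:
        raise ValueError("k_groups must be >= 2")
    if n < k_groups:
        raise ValueError("need at least as many records as groups")
    if np.all(scores == scores[0]):
        logger.warning("equal_size_groups: all scores identical; single group")
        return np.zeros(n, dtype=int)
    order = np.argsort(scores, kind="stable")
    provisional = np.empty(n, dtype=int)
    provisional[order] = np.arange(n) * k_groups // n
    labels = provisional.copy()
    # all records sharing a score take the lowest bin seen for that score
    for value in np.unique(scores):
        mask = scores == value
        if mask.sum() > 1:
            labels[mask] = provisional[mask].min()
    return labels


def group_oe_trend(
    grouped_counts: pd.DataFrame,
    alternative: str = "greater",
) -> tuple[pd.DataFrame, float, float]:
    """Per-group coSNP_O/E plus Spearman rank correlation with group order.

    ``grouped_counts`` needs columns group (ordered by increasing
    constraint), n_sites, n_a, n_b, n_co. Groups with undefined O/E are
    dropped with a note. ``alternative``: 'greater' (one-tailed positive,
    the default), 'less', or 'two-sided'. Returns (table, rho, p).
    """
    rows = []
    for _, rec in grouped_counts.iterrows():
        counts = CoSNPCounts("g", int(rec["n_sites"]), int(rec["n_a"]),
                             int(rec["n_b"]), int(rec["n_co"]))
        if counts.n_a == 0 or counts.n_b == 0:
            logger.info("group_oe_trend: group %s dropped (undefined O/E)",
                        rec["group"])
            continue
        rows.append({"group": rec["group"], "oe": cosnp_oe(counts)})
    table = pd.DataFrame(rows)
    if len(table) < 3:
        raise ValueError("need at least 3 groups with defined O/E")
    res = sps.spearmanr(table["group"], table["oe"], alternative=alternative)
    return table, float(res.statistic), float(res.pvalue)


def nearest_neighbor_match(
    focal: pd.DataFrame, candidates: pd.DataFrame
) -> pd.DataFrame:
    """Nearest candidate site per focal coSNP within the same gene.

    Both frames need columns gene_id, coord_a (plus any score columns).
    Distance is absolute species-A genomic distance; ties break toward the
    lower coordinate; a focal site sharing its coordinate with a candidate
    is never matched to itself. Focal sites without any candidate in their
    gene are dropped (logged). Output order follows sorted (gene_id,
    coord_a), so the result is invariant to input ordering.
    """
    cand_by_gene = {
        g: sub.sort_values("coord_a", kind="stable").reset_index(drop=True)
        for g, sub in candidates.groupby("gene_id")
    }
    rows = []
    n_dropped = 0
    focal_sorted = focal.sort_values(["gene_id", "coord_a"], kind="stable")
    for _, frow in focal_sorted.iterrows():
        sub = cand_by_gene.get(frow["gene_id"])
        if sub is None or sub.empty:
            n_dropped += 1
            continue
        pool = sub[sub["coord_a"] != frow["coord_a"]]
        if pool.empty:
            n_dropped += 1
            continue
        dist = (pool["coord_a"] - frow["coord_a"]).abs()
        best = dist.min()
        match = pool.loc[dist == best].nsmallest(1, "coord_a").iloc[0]
        rows.append(
            {
                "gene_id": frow["gene_id"],
                "focal_coord": frow["coord_a"],
                "match_coord": match["coord_a"],
                "distance": int(best),
                **{f"focal_{c}": frow[c] for c in focal.columns
                   if c not in ("gene_id", "coord_a")},
                **{f"match_{c}": match[c] for c in candidates.columns
                   if c not in ("gene_id", "coord_a")},
            }
        )
    if n_dropped:
        logger.info("nearest_neighbor_match: %d focal sites without candidates",
                    n_dropped)
    return pd.DataFrame(rows)


def paired_score_test(
    focal_scores, matched_scores, method: str = "t"
) -> tuple[float, float]:
    """Paired comparison of attached scores: t-test (default) or Wilcoxon
    signed-rank (``method="wilcoxon"``)."""
    x = np.asarray(focal_scores, dtype=float)
    y = np.asarray(matched_scores, dtype=float)
    if method == "t":
        res = sps.ttest_rel(x, y)
    elif method == "wilcoxon":
        res = sps.wilcoxon(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def damaging_fraction(
    scores: pd.DataFrame,
    sift_threshold: float = 0.05,
    grantham_threshold: float = 100.0,
) -> pd.Series:
    """Fraction of damaging changes per impact metric.

    Damaging means SIFT <= 0.05 (boundary inclusive), Grantham > 100
    (strict), or a PolyPhen-2 category of 'possibly' or 'probably'.
    Missing scores exclude a variant from that metric only.
    """
    out = {}
    if "sift" in scores:
        vals = scores["sift"].dropna()
        out["sift"] = float((vals <= sift_threshold).mean()) if len(vals) else np.nan
    if "grantham" in scores:
        vals = scores["grantham"].dropna()
        out["grantham"] = float((vals > grantham_threshold).mean()) if len(vals) else np.nan
    if "polyphen" in scores:
        vals = scores["polyphen"].dropna()
        out["polyphen"] = (
            float(vals.isin(["possibly", "probably"]).mean()) if len(vals) else np.nan
        )
    return pd.Series(out, name="damaging_fraction")


def compare_damaging(
    scores_1: pd.DataFrame, scores_2: pd.DataFrame, **thresholds
) -> pd.DataFrame:
    """Per-metric damaging fractions of two groups with Fisher exact p."""
    rows = []
    for metric in ("sift", "grantham", "polyphen"):
        if metric not in scores_1 or metric not in scores_2:
            continue
        d1 = _damaging_counts(scores_1[metric].dropna(), metric, thresholds)
        d2 = _damaging_counts(scores_2[metric].dropna(), metric, thresholds)
        if d1 is None or d2 is None:
            continue
        (k1, n1), (k2, n2) = d1, d2
        odds, p = sps.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])
        rows.append(
            {
                "metric": metric,
                "fraction_1": k1 / n1,
                "fraction_2": k2 / n2,
                "odds_ratio": float(odds),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


def _damaging_counts(vals: pd.Series, metric: str, thresholds) -> tuple[int, int] | None:
    if len(vals) == 0:
        return None
    if metric == "sift":
        k = int((vals <= thresholds.get("sift_threshold", 0.05)).sum())
    elif metric == "grantham":
        k = int((vals > thresholds.get("grantham_threshold", 100.0)).sum())
    else:
        k = int(vals.isin(["possibly", "probably"]).sum())
    return k, len(vals)


def two_by_two_enrichment(
    in_class: tuple[int, int], out_class: tuple[int, int]
) -> tuple[float, float]:
    """Sample odds ratio and two-tailed Fisher exact p for a 2x2 table.

    ``in_class``/``out_class`` are (positives, negatives). A zero margin
    leaves the OR undefined (inf/nan) but the exact p is still computed;
    an empty class raises ``ValueError``.
    """
    a, b = in_class
    c, d = out_class
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0:
        raise ValueError("empty class")
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)


def equal_proportions_test(successes, totals) -> tuple[float, float]:
    """K-sample chi-square test of equal proportions (no correction)."""
    successes = np.asarray(successes, dtype=int)
    totals = np.asarray(totals, dtype=int)
    if successes.size < 2:
        raise ValueError("need at least 2 classes")
    if (totals <= 0).any():
        raise ValueError("zero total in a class")
    table = np.stack([successes, totals - successes], axis=1)
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)
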