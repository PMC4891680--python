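"""SNP/coSNP discovery curves and log-linear projection to large cohorts.

Counts of SNPs (sites segregating within a subsample of individuals) and
coSNPs (those also polymorphic in a fixed partner-species SNP set) are
averaged over random subsamples at each cohort size k, fitted with
ordinary least squares on (log k, log count) — a power-law discovery
model — and projected to a large target cohort (e.g. 1000 individuals).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("cosnp")

__all__ = [
    "DiscoveryCurve",
    "LogLinearFit",
    "discovery_curve",
    "fit_log_linear",
    "project_count",
    "project_oe",
]


@dataclass
class DiscoveryCurve:
    """Mean SNP/coSNP counts at each subsample size k."""

    points: pd.DataFrame  # columns: k, mean_snp_count, mean_cosnp_count
    draws_per_k: int
    seed: int | None


@dataclass
class LogLinearFit:
    """log(count) = intercept + slope * log(k), natural logs."""

    intercept: float
    slope: float
    r_squared: float

    def predict(self, k: float) -> float:
        return math.exp(self.intercept + self.slope * math.log(k))


def discovery_curve(
    genotypes: np.ndarray,
    partner_snp_mask: np.ndarray,
    draws: int = 5,
    seed: int | None = None,
    k_max: int | None = None,
) -> DiscoveryCurve:
    """Subsampled discovery curve over cohort sizes k = 2..K.

    ``genotypes`` is individuals x sites with diploid derived-allele counts
    in {0, 1, 2}; a site is a SNP within a subsample when both alleles are
    present among its 2k chromosomes. ``partner_snp_mask`` marks sites
    polymorphic in the fixed partner species; a coSNP is a subsample SNP at
    a marked site. Each k is averaged over ``draws`` random subsets without
    replacement — or over all C(K, k) subsets when there are no more than
    ``draws`` of them (so k = K is a single exact draw).
    """
    g = np.asarray(genotypes)
    n_ind = g.shape[0]
    if n_ind < 2:
        raise ValueError("need at least 2 individuals")
    partner = np.asarray(partner_snp_mask, dtype=bool)
    k_top = n_ind if k_max is None else min(k_max, n_ind)
    if k_top < 2:
        raise ValueError("k_max must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(2, k_top + 1):
        n_subsets = math.comb(n_ind, k)
        if n_subsets <= draws:
            subsets = [np.asarray(c) for c in itertools.combinations(range(n_ind), k)]
        else:
            subsets = [rng.choice(n_ind, size=k, replace=False) for _ in range(draws)]
        snp_counts = []
        co_counts = []
        for sub in subsets:
            totals = g[sub].sum(axis=0)
            seg = (totals > 0) & (totals < 2 * k)
            snp_counts.append(int(seg.sum()))
            co_counts.append(int((seg & partner).sum()))
        rows.append((k, float(np.mean(snp_counts)), float(np.mean(co_counts))))
    points = pd.DataFrame(rows, columns=["k", "mean_snp_count", "mean_cosnp_count"])
    return DiscoveryCurve(points=points, draws_per_k=draws, seed=seed)


def fit_log_linear(k: np.ndarray, counts: np.ndarray) -> LogLinearFit:
    """OLS of log(count) on log(k), natural logarithms.

    Points with zero count are dropped with a warning; fewer than 2
    remaining distinct k raise ``ValueError``.
    """
    k = np.asarray(k, dtype=float)
    counts = np.asarray(counts, dtype=float)
    positive = counts > 0
    if (~positive).any():
        logger.warning("fit_log_linear: dropped %d zero-count points",
                       int((~positive).sum()))
    k, counts = k[positive], counts[positive]
    if np.unique(k).size < 2:
        raise ValueError("need at least 2 distinct k with positive counts")
    x = np.log(k)
    y = np.log(counts)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return LogLinearFit(intercept=float(intercept), slope=float(slope), r_squared=r2)


def fit_curve(curve: DiscoveryCurve) -> tuple[LogLinearFit, LogLinearFit]:
    """Fit the SNP and coSNP discovery curves separately."""
    pts = curve.points
    return (
        fit_log_linear(pts["k"], pts["mean_snp_count"]),
        fit_log_linear(pts["k"], pts["mean_cosnp_count"]),
    )


def project_count(fit: LogLinearFit, k_target: int) -> float:
    return fit.predict(k_target)


def project_oe(
    fit_snp: LogLinearFit,
    fit_cosnp: LogLinearFit,
    n_partner_snps: int,
    n_sites: int,
    k_target: int = 1000,
) -> dict[str, float]:
    """coSNP_O/E at a projected cohort size.

    Both counts are projected from their own fits (the partner species'
    SNP set and the examined site universe stay fixed) and recombined with
    the coSNP_O/E formula. A projected coSNP count exceeding the projected
    SNP count is flagged as an extrapolation inconsistency.
    """
    snp_proj = project_count(fit_snp, k_target)
    co_proj = project_count(fit_cosnp, k_target)
    if co_proj > snp_proj:
        logger.warning("project_oe: projected coSNP count %.1f exceeds projected "
                       "SNP count %.1f", co_proj, snp_proj)
    oe = co_proj * n_sites / (snp_proj * n_partner_snps)
    return {
        "k_target": float(k_target),
        "projected_snp_count": snp_proj,
        "projected_cosnp_count": co_proj,
        "projected_oe": oe,
    }
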