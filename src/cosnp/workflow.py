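"""End-to-end pipeline: synthetic data -> site table -> every coSNP analysis.

Chains the generator, annotation, coSNP statistics, stratified analyses and
discovery-curve extrapolation over one synthetic dataset, writing tabular
outputs plus a run log (seed, config hash, dropped-record counts) to a
directory. All stages are deterministic given the spec's seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import extrapolate as ex
from . import stats as cs
from . import strata as st
from .synth import SyntheticDataset, SyntheticSpec, generate_dataset, write_dataset

logger = logging.getLogger("cosnp")

__all__ = ["run_pipeline", "pseudo_haplotypes"]


def pseudo_haplotypes(genotypes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random phasing of diploid 0/1/2 genotypes into a 2n x sites 0/1 matrix."""
    g = np.asarray(genotypes)
    toss = rng.integers(0, 2, size=g.shape)
    hap1 = (g == 2).astype(np.int8) + ((g == 1) & (toss == 1)).astype(np.int8)
    hap2 = (g - hap1).astype(np.int8)
    return np.concatenate([hap1, hap2], axis=0)


def run_pipeline(
    spec: SyntheticSpec,
    outdir: str | Path,
    exclude_cpg: bool = True,
    cpg_mode: str = "either",
    k_groups: int = 5,
    tajima_window: int = 100_000,
    covariate_window: int = 1_000_000,
    k_target: int = 1000,
) -> dict[str, pd.DataFrame]:
    """Generate a dataset and run the full analysis; returns the result tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(spec)
    write_dataset(ds, outdir / "data")
    results: dict[str, pd.DataFrame] = {}

    classes = cs.classify_sites(ds.variants_a, ds.variants_b, ds.sites)
    site_report = ds.sites[["gene_id", "chrom_a", "coord_a", "chrom_b", "coord_b",
                            "degeneracy"]].copy()
    site_report["cpg"] = ds.sites["cpg_a"] | ds.sites["cpg_b"]
    site_report["class"] = classes
    results["site_classes"] = site_report

    results["cosnp_oe"] = cs.stratified_counts(
        ds.sites, classes, exclude_cpg=exclude_cpg, cpg_mode=cpg_mode
    )
    results["patterns"] = cs.pattern_oe(classes, ds.variants_a, ds.variants_b)

    # SFS and rare-variant comparison, species A, coSNPs vs non-coSNPs
    co_idx = classes[classes == "cosnp"].index
    va = ds.variants_a.set_index("site")
    maf_co = va.loc[va.index.intersection(co_idx), "maf"]
    maf_non = va.loc[va.index.difference(co_idx), "maf"]
    sfs_rows = []
    if len(maf_co) >= 2 and len(maf_non) >= 2:
        ks_stat, ks_p = cs.compare_sfs(maf_co, maf_non)
        f_co, f_non, odds, fisher_p = cs.compare_rare_fraction(maf_co, maf_non)
        sfs_rows.append(
            {"comparison": "cosnp_vs_noncosnp_A", "ks_stat": ks_stat, "ks_p": ks_p,
             "rare_frac_cosnp": f_co, "rare_frac_non": f_non,
             "fisher_odds": odds, "fisher_p": fisher_p}
        )
    results["sfs"] = pd.DataFrame(sfs_rows)

    # Tajima's D window classes on pseudo-phased species-A genotypes
    rng = np.random.default_rng(spec.seed + 7)
    haps = pseudo_haplotypes(ds.genotypes_a, rng)
    cosnp_table = ds.sites.loc[co_idx, ["chrom_a", "coord_a", "degeneracy"]].rename(
        columns={"chrom_a": "chrom", "coord_a": "coord"}
    )
    windows = st.classify_cosnp_windows(cosnp_table, width=tajima_window)
    d_vals = []
    for _, wrow in windows.iterrows():
        lo = wrow["window"] * tajima_window
        in_win = (
            (ds.sites["chrom_a"] == wrow["chrom"]).to_numpy()
            & (ds.sites["coord_a"] >= lo).to_numpy()
            & (ds.sites["coord_a"] < lo + tajima_window).to_numpy()
        )
        try:
            d_vals.append(st.tajimas_d(haps[:, in_win]))
        except ValueError:
            d_vals.append(np.nan)
    windows["tajimas_d"] = d_vals
    results["windows"] = windows
    if windows["cosnp_class"].nunique() >= 2 and windows["tajimas_d"].notna().any():
        results["window_tests"] = st.compare_window_classes(
            windows.dropna(subset=["tajimas_d"])
        )

    # 1-Mb SNP density / recombination covariates
    results["covariates"] = st.window_covariates(
        ds.sites, ds.variants_a, ds.annotations["recomb"], width=covariate_window
    )

    # constraint binning: genes grouped by dN/dS, zero-fold O/E trend
    genes = ds.annotations["genes"]
    order = np.argsort(-genes["dn_ds"].to_numpy())  # increasing constraint
    group_of = np.empty(len(genes), dtype=int)
    group_of[order] = st.equal_size_groups(-genes["dn_ds"].to_numpy()[order], k_groups)
    gene_group = pd.Series(group_of, index=genes["gene_id"])
    zero = ds.sites["degeneracy"] == "zero"
    rows = []
    for grp in range(k_groups):
        in_grp = ds.sites["gene_id"].map(gene_group).to_numpy() == grp
        sub = classes[in_grp & zero.to_numpy()]
        counts = cs.count_sites(sub, stratum=f"group{grp}")
        rows.append({"group": grp, "n_sites": counts.n_sites, "n_a": counts.n_a,
                     "n_b": counts.n_b, "n_co": counts.n_co})
    trend_counts = pd.DataFrame(rows)
    try:
        trend_table, rho, trend_p = st.group_oe_trend(trend_counts)
        trend_table["rho"] = rho
        trend_table["p_one_tailed"] = trend_p
        results["constraint_trend"] = trend_table
    except ValueError as exc:
        logger.warning("constraint trend skipped: %s", exc)

    # nearest-neighbor conservation comparison at zero-fold sites
    scores = ds.annotations["site_scores"].set_index("site")
    focal = ds.sites.loc[co_idx][zero.loc[co_idx]][["gene_id", "coord_a"]].copy()
    nonco_idx = classes[classes == "nonco_a_only"].index
    cands = ds.sites.loc[nonco_idx][zero.loc[nonco_idx]][["gene_id", "coord_a"]].copy()
    focal["phylop"] = scores["phylop"].reindex(focal.index).to_numpy()
    cands["phylop"] = scores["phylop"].reindex(cands.index).to_numpy()
    matched = st.nearest_neighbor_match(focal, cands)
    nn_rows = []
    if len(matched) >= 3:
        t_stat, t_p = st.paired_score_test(matched["focal_phylop"],
                                           matched["match_phylop"])
        nn_rows.append({"comparison": "cosnp_vs_nonco_A_phylop", "n_pairs": len(matched),
                        "t_stat": t_stat, "p_value": t_p})
    results["nearest_neighbor"] = pd.DataFrame(nn_rows)

    # enrichment: GWAS at zero-fold coSNPs; gene labels; dN/dS contrast
    impact = ds.annotations["impact"]
    enr_rows = []
    if len(impact):
        is_co = impact["site"].isin(co_idx)
        in_cls = (int(impact.loc[is_co, "gwas"].sum()), int((is_co & ~impact["gwas"]).sum()))
        out_cls = (int(impact.loc[~is_co, "gwas"].sum()),
                   int((~is_co & ~impact["gwas"]).sum()))
        if in_cls[0] + in_cls[1] > 0 and out_cls[0] + out_cls[1] > 0:
            odds, p = st.two_by_two_enrichment(in_cls, out_cls)
            enr_rows.append({"label": "gwas_site", "odds_ratio": odds, "p_value": p})
    for label in ("disease", "essential", "housekeeping"):
        has = genes["has_cosnp_i0"]
        in_cls = (int(genes.loc[has, label].sum()), int((has & ~genes[label]).sum()))
        out_cls = (int(genes.loc[~has, label].sum()), int((~has & ~genes[label]).sum()))
        try:
            odds, p = st.two_by_two_enrichment(in_cls, out_cls)
        except ValueError:
            continue
        enr_rows.append({"label": label, "odds_ratio": odds, "p_value": p})
    if genes["has_cosnp_i0"].nunique() == 2:
        res = sps.mannwhitneyu(genes.loc[genes["has_cosnp_i0"], "dn_ds"],
                               genes.loc[~genes["has_cosnp_i0"], "dn_ds"],
                               alternative="two-sided")
        enr_rows.append({"label": "dn_ds_wilcoxon", "odds_ratio": np.nan,
                         "p_value": float(res.pvalue)})
    results["enrichment"] = pd.DataFrame(enr_rows)

    # discovery curve and projection (species A individuals, B as partner)
    partner = np.zeros(len(ds.sites), dtype=bool)
    partner[ds.variants_b["site"].to_numpy()] = True
    curve = ex.discovery_curve(ds.genotypes_a, partner, draws=5, seed=spec.seed + 11)
    results["discovery_curve"] = curve.points
    try:
        fit_snp, fit_co = ex.fit_curve(curve)
        proj = ex.project_oe(fit_snp, fit_co, n_partner_snps=len(ds.variants_b),
                             n_sites=int((~ds.sites["masked"]).sum()),
                             k_target=k_target)
        results["projection"] = pd.DataFrame(
            [{"slope_snp": fit_snp.slope, "slope_cosnp": fit_co.slope,
              "r2_snp": fit_snp.r_squared, "r2_cosnp": fit_co.r_squared, **proj}]
        )
    except ValueError as exc:
        logger.warning("projection skipped: %s", exc)

    _write_results(results, outdir)
    _write_log(spec, outdir)
    return results


def _write_results(results: dict[str, pd.DataFrame], outdir: Path) -> None:
    for name, table in results.items():
        table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                     float_format="%.10g")


def _write_log(spec: SyntheticSpec, outdir: Path) -> None:
    payload = json.dumps(asdict(spec), sort_keys=True, default=str)
    digest = hashlib.sha256(payload.encode()).hexdigest()[:16]
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"seed\t{spec.seed}\n")
        fh.write(f"config_sha256\t{digest}\n")
        fh.write(f"spec\t{payload}\n")
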