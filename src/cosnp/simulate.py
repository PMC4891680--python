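"""Two-population forward Wright-Fisher simulation under purifying selection.

The experiment: a single ancestral population of ``n`` diploids evolves to
(approximate) mutation-selection-drift balance, is duplicated into two
populations that then evolve independently for ``generations_post_split``
generations, and the coincident-SNP observed/expected ratio (coSNP_O/E) is
computed from the two resulting SNP sets over the ``length``-bp region.

Model summary
-------------
* finite sites: ``length`` positions, biallelic (ancestral/derived); a
  recurrent mutation at a segregating site toggles the carrier back to the
  other allele, so sites never become triallelic,
* multiplicative viability selection across sites with per-site genotype
  fitness 1, 1+h*s, 1+s (codominant by default, h = 0.5),
* recombination as Poisson(r * length) crossovers per gamete with uniform
  breakpoints,
* optional per-site mutation-rate field (gamma with mean 1 and coefficient
  of variation ``rate_cv``) shared by the two populations, to emulate
  cryptic mutation-rate heterogeneity.

Ancestral state is prepared either by a long burn-in from a monomorphic
start (``init="monomorphic"``, the default, with burn-in 10 * 2N) or by
drawing site frequencies from the stationary Poisson-random-field density
for semidominant selection followed by a short settling phase
(``init="stationary"``); the latter makes large scenario grids affordable
on one CPU and is used by the scaled-down preset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SimulationConfig",
    "SimResult",
    "simulate_pair",
    "run_scenario",
    "run_grid",
    "scaled_config",
    "selection_contrast",
    "interaction_anova",
    "watterson_expected_segregating",
]


@dataclass
class SimulationConfig:
    """One scenario of the two-population forward simulation.

    Defaults mirror the full-scale experiment (N = 1e4 diploids per
    population, a 2.5-Mb region, r = 1e-8, 1000 post-split generations);
    use :func:`scaled_config` for a desk-scale, diffusion-equivalent
    parameterisation.
    """

    n: int = 10_000                       # diploid individuals per population
    length: int = 2_500_000               # region length, bp
    mu: float = 1e-8                      # per-base per-generation mutation rate
    s: float = -0.01                      # selection coefficient of new mutations
    h: float = 0.5                        # dominance coefficient
    r: float = 1e-8                       # per-base recombination rate
    generations_post_split: int = 1_000
    burn_in: int | None = None            # None -> 10 * 2N (monomorphic init)
    init: str = "monomorphic"             # or "stationary"
    sample_size: int | None = None        # diploids ascertained; None = whole pop
    rate_cv: float = 0.0                  # CV of the shared per-site rate field
    iterations: int = 1_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1 or self.length < 1 or self.iterations < 1:
            raise ValueError("n, length and iterations must be >= 1")
        if self.mu < 0 or self.r < 0:
            raise ValueError("mu and r must be >= 0")
        if self.s > 0:
            raise ValueError("only neutral or deleterious mutations (s <= 0)")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("h must lie in [0, 1]")
        if 1.0 + self.s <= 0.0:
            raise ValueError(
                "1 + s <= 0 gives non-positive homozygote fitness; "
                "use a weaker selection coefficient"
            )
        if self.init not in ("monomorphic", "stationary"):
            raise ValueError("init must be 'monomorphic' or 'stationary'")

    @property
    def two_n(self) -> int:
        return 2 * self.n

    @property
    def effective_burn_in(self) -> int:
        if self.burn_in is not None:
            return self.burn_in
        return 10 * self.two_n if self.init == "monomorphic" else 0


@dataclass
class SimResult:
    """Per-iteration outcomes of one scenario."""

    s: float
    mu: float
    seg_a: np.ndarray        # segregating sites in population A
    seg_b: np.ndarray
    n_co: np.ndarray         # positions segregating in both
    oe: np.ndarray           # coSNP_O/E; NaN where undefined (no SNPs in a pop)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s": self.s,
                "mu": self.mu,
                "iteration": np.arange(len(self.oe)),
                "seg_a": self.seg_a,
                "seg_b": self.seg_b,
                "n_co": self.n_co,
                "oe": self.oe,
            }
        )


def scaled_config(
    s: float,
    mu: float,
    *,
    n: int = 500,
    length: int = 20_000,
    iterations: int = 200,
    settle: int = 200,
    seed: int | None = None,
    **kwargs,
) -> SimulationConfig:
    """Desk-scale scenario preserving the diffusion-scale parameters.

    ``mu`` and ``r`` are the full-scale (N = 1e4) rates; they are rescaled
    by N_full / n so that theta = 4*N*mu and rho = 4*N*r per site are
    preserved, and the post-split time is rescaled to preserve t / (2N).
    The ancestral population is initialised from the stationary
    single-site density and settled for ``settle`` generations.
    """
    n_full = 10_000
    t_full = 1_000
    factor = n_full / n
    return SimulationConfig(
        n=n,
        length=length,
        mu=mu * factor,
        s=s,
        r=1e-8 * factor,
        generations_post_split=max(1, round(t_full / factor)),
        burn_in=settle,
        init="stationary",
        iterations=iterations,
        seed=seed,
        **kwargs,
    )


def watterson_expected_segregating(n_haplotypes: int, theta_site: float, length: int) -> float:
    """Neutral expectation of segregating sites: theta * L * a_{n-1}."""
    a = np.sum(1.0 / np.arange(1, n_haplotypes))
    return theta_site * length * a


# ---------------------------------------------------------------------------
# internal machinery
# ---------------------------------------------------------------------------


class _Population:
    """Haplotype matrix over currently tracked segregating positions."""

    __slots__ = ("hap", "positions", "pos_index")

    def __init__(self, hap: np.ndarray, positions: np.ndarray):
        self.hap = hap                      # (2N, S) uint8
        self.positions = positions          # (S,) int64, unsorted
        self.pos_index = {int(p): i for i, p in enumerate(positions)}

    def copy(self) -> "_Population":
        return _Population(self.hap.copy(), self.positions.copy())

    def prune(self) -> None:
        if self.positions.size == 0:
            return
        colsum = self.hap.sum(axis=0, dtype=np.int64)
        keep = (colsum > 0) & (colsum < self.hap.shape[0])
        if not keep.all():
            self.hap = self.hap[:, keep]
            self.positions = self.positions[keep]
            self.pos_index = {int(p): i for i, p in enumerate(self.positions)}

    def segregating_positions(self, sample_rows: np.ndarray | None = None) -> np.ndarray:
        hap = self.hap if sample_rows is None else self.hap[sample_rows]
        if self.positions.size == 0:
            return np.empty(0, dtype=np.int64)
        colsum = hap.sum(axis=0, dtype=np.int64)
        seg = (colsum > 0) & (colsum < hap.shape[0])
        return self.positions[seg]


def _stationary_frequency_table(cfg: SimulationConfig) -> tuple[np.ndarray, float]:
    """Per-site stationary distribution of derived-allele counts.

    Poisson-random-field sojourn density for semidominant selection with
    scaled coefficient S = 2*N*s (per-allele effect h*s, h = 1/2):
    f(x) = theta * (1 - exp(-S*(1-x))) / ((1 - exp(-S)) * x * (1-x)),
    reducing to theta/x when S -> 0. Returns (p_j for j=1..2N-1, P_seg).
    """
    two_n = cfg.two_n
    theta = 4.0 * cfg.n * cfg.mu
    j = np.arange(1, two_n)
    x = j / two_n
    big_s = 2.0 * cfg.n * (2.0 * cfg.h * cfg.s)
    if abs(big_s) < 1e-12:
        dens = theta / x
    else:
        # numerically stable for strongly negative S
        with np.errstate(over="ignore"):
            num = -np.expm1(-big_s * (1.0 - x))
            den = -math.expm1(-big_s)
            dens = theta * (num / den) / (x * (1.0 - x))
        if not np.all(np.isfinite(dens)):
            # fall back to the strong-selection asymptotic exp(-|S| x)/(x(1-x))
            dens = theta * np.exp(big_s * x) / (x * (1.0 - x))
    p = dens / two_n
    return p, float(p.sum())


def _init_stationary(cfg: SimulationConfig, rng: np.random.Generator,
                     rates: np.ndarray | None) -> _Population:
    p_j, p_seg = _stationary_frequency_table(cfg)
    if p_seg >= 0.5:
        raise ValueError(
            "per-site segregation probability too high for the biallelic "
            "finite-sites model; reduce mu or length"
        )
    two_n = cfg.two_n
    if rates is None:
        seg_mask = rng.random(cfg.length) < p_seg
    else:
        seg_mask = rng.random(cfg.length) < np.minimum(p_seg * rates, 0.5)
    positions = np.flatnonzero(seg_mask).astype(np.int64)
    k = positions.size
    hap = np.zeros((two_n, k), dtype=np.uint8)
    if k:
        counts = rng.choice(np.arange(1, two_n), size=k, p=p_j / p_seg)
        for col, c in enumerate(counts):
            hap[rng.choice(two_n, size=c, replace=False), col] = 1
    return _Population(hap, positions)


def _evolve(pop: _Population, generations: int, cfg: SimulationConfig,
            rng: np.random.Generator, rate_cum: np.ndarray | None) -> None:
    """Advance ``pop`` in place for ``generations`` WF generations."""
    two_n = cfg.two_n
    n = cfg.n
    log_het = math.log1p(cfg.h * cfg.s) if cfg.s else 0.0
    log_hom = math.log1p(cfg.s) if cfg.s else 0.0
    mut_rate = two_n * cfg.mu * cfg.length
    rec_rate = two_n * cfg.r * max(cfg.length - 1, 0)

    for gen in range(generations):
        hap = pop.hap
        s_sites = pop.positions.size

        # --- selection + parent sampling -------------------------------
        if cfg.s != 0.0 and s_sites:
            dip = hap[0::2] + hap[1::2]               # (N, S) derived counts
            n_het = np.count_nonzero(dip == 1, axis=1)
            n_hom = np.count_nonzero(dip == 2, axis=1)
            logw = n_het * log_het + n_hom * log_hom
            w = np.exp(logw - logw.max())
            cum = np.cumsum(w)
            parents = np.searchsorted(cum, rng.random(two_n) * cum[-1], side="right")
            parents = np.minimum(parents, n - 1)
        else:
            parents = rng.integers(0, n, size=two_n)

        which = rng.integers(0, 2, size=two_n)
        new_hap = hap[2 * parents + which]

        # --- recombination (rare at these map lengths) -----------------
        if rec_rate > 0.0 and s_sites > 1:
            n_events = rng.poisson(rec_rate)
            if n_events:
                gametes = rng.integers(0, two_n, size=n_events)
                breaks = rng.integers(1, cfg.length, size=n_events)
                for g, bp in zip(gametes, breaks):
                    other = hap[2 * parents[g] + 1 - which[g]]
                    right = pop.positions >= bp
                    new_hap[g, right] = other[right]

        pop.hap = new_hap

        # --- mutation --------------------------------------------------
        n_mut = rng.poisson(mut_rate)
        if n_mut:
            gametes = rng.integers(0, two_n, size=n_mut)
            if rate_cum is None:
                sites = rng.integers(0, cfg.length, size=n_mut)
            else:
                sites = np.searchsorted(
                    rate_cum, rng.random(n_mut) * rate_cum[-1], side="right"
                )
            width = pop.hap.shape[1]
            new_sites: list[int] = []
            extra_cols: list[np.ndarray] = []
            for g, site in zip(gametes, sites):
                col = pop.pos_index.get(int(site))
                if col is None:
                    pop.pos_index[int(site)] = width + len(new_sites)
                    new_sites.append(int(site))
                    extra = np.zeros(two_n, dtype=np.uint8)
                    extra[g] = 1
                    extra_cols.append(extra)
                elif col >= width:
                    # second hit this generation on a brand-new site
                    extra_cols[col - width][g] ^= 1
                else:
                    # recurrent hit: flip the carrier to the other allele
                    pop.hap[g, col] ^= 1
            if new_sites:
                pop.hap = np.concatenate(
                    [pop.hap, np.stack(extra_cols, axis=1)], axis=1
                )
                pop.positions = np.concatenate(
                    [pop.positions, np.asarray(new_sites, dtype=np.int64)]
                )

        if gen % 16 == 15:
            pop.prune()
    pop.prune()


def _cosnp_oe_from_sets(seg_a: np.ndarray, seg_b: np.ndarray, n_sites: int) -> tuple[int, float]:
    n_co = np.intersect1d(seg_a, seg_b, assume_unique=True).size
    if seg_a.size == 0 or seg_b.size == 0:
        return n_co, math.nan
    return n_co, n_co * n_sites / (seg_a.size * seg_b.size)


def simulate_pair(cfg: SimulationConfig, rng: np.random.Generator | None = None
                  ) -> tuple[int, int, int, float]:
    """One iteration: burn-in, split, independent evolution, coSNP_O/E.

    Returns ``(seg_a, seg_b, n_co, oe)``; ``oe`` is NaN when either SNP set
    is empty (flagged iteration).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    if cfg.rate_cv > 0.0:
        shape = 1.0 / cfg.rate_cv**2
        rates = rng.gamma(shape, 1.0 / shape, size=cfg.length)
        rate_cum = np.cumsum(rates)
    else:
        rates = None
        rate_cum = None

    if cfg.init == "stationary":
        ancestral = _init_stationary(cfg, rng, rates)
    else:
        ancestral = _Population(
            np.zeros((cfg.two_n, 0), dtype=np.uint8), np.empty(0, dtype=np.int64)
        )
    _evolve(ancestral, cfg.effective_burn_in, cfg, rng, rate_cum)

    pop_a = ancestral
    pop_b = ancestral.copy()
    _evolve(pop_a, cfg.generations_post_split, cfg, rng, rate_cum)
    _evolve(pop_b, cfg.generations_post_split, cfg, rng, rate_cum)

    if cfg.sample_size is not None and cfg.sample_size < cfg.n:
        rows_a = _sample_rows(rng, cfg.n, cfg.sample_size)
        rows_b = _sample_rows(rng, cfg.n, cfg.sample_size)
    else:
        rows_a = rows_b = None
    seg_a = pop_a.segregating_positions(rows_a)
    seg_b = pop_b.segregating_positions(rows_b)
    n_co, oe = _cosnp_oe_from_sets(np.sort(seg_a), np.sort(seg_b), cfg.length)
    return seg_a.size, seg_b.size, n_co, oe


def _sample_rows(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    individuals = rng.choice(n, size=k, replace=False)
    return np.sort(np.concatenate([2 * individuals, 2 * individuals + 1]))


def run_scenario(cfg: SimulationConfig) -> SimResult:
    """Run ``cfg.iterations`` independent iterations of one scenario."""
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.iterations)
    seg_a = np.zeros(cfg.iterations, dtype=np.int64)
    seg_b = np.zeros(cfg.iterations, dtype=np.int64)
    n_co = np.zeros(cfg.iterations, dtype=np.int64)
    oe = np.full(cfg.iterations, np.nan)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        seg_a[i], seg_b[i], n_co[i], oe[i] = simulate_pair(cfg, rng)
    return SimResult(s=cfg.s, mu=cfg.mu, seg_a=seg_a, seg_b=seg_b, n_co=n_co, oe=oe)


def run_grid(
    base: SimulationConfig,
    s_levels: Sequence[float],
    mu_levels: Sequence[float],
    iterations: int | None = None,
    *,
    scaled: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run every (s, mu) scenario combination with independent seed streams.

    With ``scaled=True``, ``mu_levels`` are full-scale rates passed through
    :func:`scaled_config` (keeping ``base``'s n/length/iterations).
    """
    if not len(s_levels) or not len(mu_levels):
        raise ValueError("selection and mutation grids must be non-empty")
    iters = iterations if iterations is not None else base.iterations
    ss = np.random.SeedSequence(seed if seed is not None else base.seed)
    scenario_seeds = ss.generate_state(len(s_levels) * len(mu_levels)) >> 1
    frames = []
    k = 0
    for s in s_levels:
        for mu in mu_levels:
            if scaled:
                cfg = scaled_config(
                    s, mu, n=base.n, length=base.length,
                    iterations=iters, settle=base.effective_burn_in,
                    seed=int(scenario_seeds[k]),
                    sample_size=base.sample_size, rate_cv=base.rate_cv,
                )
            else:
                cfg = replace(base, s=s, mu=mu, iterations=iters,
                              seed=int(scenario_seeds[k]))
            frames.append(run_scenario(cfg).to_frame())
            k += 1
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# statistical summaries of a scenario grid
# ---------------------------------------------------------------------------


def selection_contrast(results: pd.DataFrame) -> pd.DataFrame:
    """Two-tailed Wilcoxon rank-sum p-values between selection levels.

    Within each mutation rate, every pair of selection levels is compared
    on the per-iteration coSNP_O/E values (tie-corrected normal
    approximation). Iterations with undefined O/E are dropped.
    """
    rows = []
    for mu, sub in results.groupby("mu"):
        levels = sorted(sub["s"].unique(), reverse=True)  # weakest first
        for i in range(len(levels)):
            for jdx in range(i + 1, len(levels)):
                x = sub.loc[sub["s"] == levels[i], "oe"].dropna().to_numpy()
                y = sub.loc[sub["s"] == levels[jdx], "oe"].dropna().to_numpy()
                if len(x) < 2 or len(y) < 2:
                    raise ValueError("need >= 2 valid iterations per level")
                if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                    stat, p = 0.0, 1.0
                else:
                    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                                           method="asymptotic")
                    stat, p = float(res.statistic), float(res.pvalue)
                rows.append(
                    {
                        "mu": mu,
                        "s_weak": levels[i],
                        "s_strong": levels[jdx],
                        "median_weak": float(np.median(x)),
                        "median_strong": float(np.median(y)),
                        "statistic": stat,
                        "p_value": p,
                    }
                )
    return pd.DataFrame(rows)


def interaction_anova(results: pd.DataFrame) -> pd.DataFrame:
    """Two-way ANOVA of coSNP_O/E on selection level and mutation rate.

    Type-II sums of squares (identical to type I/III on a balanced grid).
    Requires >= 2 levels per factor and residual degrees of freedom.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = results.dropna(subset=["oe"]).copy()
    if data["s"].nunique() < 2 or data["mu"].nunique() < 2:
        raise ValueError("need >= 2 levels of both factors")
    cell_sizes = data.groupby(["s", "mu"]).size()
    if (cell_sizes < 2).any():
        raise ValueError("need >= 2 replicates per cell for a residual term")
    model = smf.ols("oe ~ C(s) * C(mu)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table.index = table.index.str.replace("C(s)", "selection", regex=False)
    table.index = table.index.str.replace("C(mu)", "mutation_rate", regex=False)
    table.index = table.index.str.replace(
        "selection:mutation_rate", "interaction", regex=False
    )
    return table
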