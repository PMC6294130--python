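"""Pairwise Weir-Cockerham F_ST, Rousset linearization, island-model migration
rates and migration-network group summaries.

The F_ST estimator is the two-population Weir-Cockerham (1984)
variance-components estimator computed from per-population sample sizes,
allele frequencies and observed heterozygosities at each locus; the
multi-locus estimate is the ratio of summed components,
theta-hat = sum(a) / sum(a + b + c).

Migrants per generation are recovered from the island-model equilibrium
F_ST = 1 / (1 + 4 Nm): the default closed-form moment estimator is
Nm = (1 - theta) / (4 theta); an optional grid pseudo-maximum-likelihood
variant fits per-locus theta values to the same equilibrium curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix, SampleTable

logger = logging.getLogger(__name__)

__all__ = [
    "FstResult",
    "MigrationEstimate",
    "MigrationSummary",
    "pairwise_fst",
    "fst_matrix",
    "linearized_fst",
    "nem_from_fst",
    "migration_summary",
]

#: Ceiling applied to Nm when theta-hat <= 0 (undifferentiated pair).
DEFAULT_NEM_CEILING = 20.0


@dataclass
class FstResult:
    pop_a: str
    pop_b: str
    theta: float
    components: pd.DataFrame  # per-locus a, b, c (usable loci only)
    n_loci_used: int
    n_loci_dropped: int


@dataclass
class MigrationEstimate:
    pop_a: str
    pop_b: str
    nem: float
    estimator: str
    theta: float
    linearized: float
    capped: bool = False


@dataclass
class MigrationSummary:
    table: pd.DataFrame  # per category: mean, se, ci_low, ci_high, n_pairs
    contrast_test: dict  # Mann-Whitney U between the two contrast categories
    edges: pd.DataFrame  # pop_a, pop_b, fst, linearized_fst, nem, panmictic
    graph: nx.Graph = field(default=None, repr=False)


def _pop_locus_stats(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (n, p, h) for one population's dosage block: sample count,
    allele frequency and observed heterozygote frequency."""
    obs = ~np.isnan(dosage)
    n = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, np.nansum(dosage, axis=0) / (2.0 * np.maximum(n, 1)), np.nan)
        h = np.where(n > 0, np.nansum(dosage == 1.0, axis=0) / np.maximum(n, 1), np.nan)
    return n, p, h


def _wc_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) per-locus variance components for two populations.

    Returns (a, b, c, usable): among-population, among-individual-within-
    population and within-individual components, plus a mask of loci where the
    components are defined (both populations observed, n_c > 0, nbar > 1).
    """
    r = 2.0
    nsum = n1 + n2
    nbar = nsum / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (n1**2 + n2**2) / nsum) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / nsum
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / nsum
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    usable = (n1 > 0) & (n2 > 0) & (nbar > 1) & (nc > 0)
    usable &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a, b, c, usable


def pairwise_fst(
    G: GenotypeMatrix, S: SampleTable, pop_a: str, pop_b: str
) -> FstResult:
    """Two-population Weir-Cockerham F_ST over all usable loci.

    Loci where either population has no non-missing call, or where all
    components vanish (monomorphic across both populations), are excluded and
    counted in ``n_loci_dropped``.  Per-locus components (including negative
    values) are retained in ``components``.
    """
    pop_of = S.population_of()
    sample_pop = np.array([pop_of.get(s) for s in G.sample_ids])
    ia = sample_pop == pop_a
    ib = sample_pop == pop_b
    if ia.sum() < 2 or ib.sum() < 2:
        raise ValueError(f"both populations need >= 2 samples ({pop_a}: {ia.sum()}, {pop_b}: {ib.sum()})")
    n1, p1, h1 = _pop_locus_stats(G.dosage[ia])
    n2, p2, h2 = _pop_locus_stats(G.dosage[ib])
    a, b, c, usable = _wc_components(n1, p1, h1, n2, p2, h2)
    denom_nonzero = usable & ((a + b + c) != 0)
    if not denom_nonzero.any():
        raise ValueError(f"no usable loci for pair ({pop_a}, {pop_b})")
    theta = float(a[denom_nonzero].sum() / (a + b + c)[denom_nonzero].sum())
    comp = pd.DataFrame(
        {"a": a[denom_nonzero], "b": b[denom_nonzero], "c": c[denom_nonzero]},
        index=[l for l, u in zip(G.locus_ids, denom_nonzero) if u],
    )
    return FstResult(
        pop_a=pop_a,
        pop_b=pop_b,
        theta=theta,
        components=comp,
        n_loci_used=int(denom_nonzero.sum()),
        n_loci_dropped=int(G.n_loci - denom_nonzero.sum()),
    )


def fst_matrix(
    G: GenotypeMatrix, S: SampleTable, populations: list[str] | None = None
) -> tuple[pd.DataFrame, list[FstResult]]:
    """All-pairs Weir-Cockerham F_ST; returns the symmetric matrix and the
    per-pair results.  Pairs with no usable loci get NaN."""
    pops = populations if populations is not None else S.populations
    pop_of = S.population_of()
    sample_pop = np.array([pop_of.get(s) for s in G.sample_ids])
    stats_by_pop = {}
    for p in pops:
        rows = sample_pop == p
        stats_by_pop[p] = _pop_locus_stats(G.dosage[rows]) if rows.sum() else None
    M = pd.DataFrame(0.0, index=pops, columns=pops)
    results = []
    for pa, pb in combinations(pops, 2):
        try:
            res = pairwise_fst(G, S, pa, pb)
            results.append(res)
            M.loc[pa, pb] = M.loc[pb, pa] = res.theta
        except ValueError as exc:
            logger.warning("F_ST undefined for (%s, %s): %s", pa, pb, exc)
            M.loc[pa, pb] = M.loc[pb, pa] = np.nan
    return M, results


def linearized_fst(theta: float, clip_negative: bool = True) -> float:
    """Rousset linearization theta / (1 - theta).

    Negative theta maps to a negative value; by default it is clipped to 0 for
    distance-matrix use (logged).  theta = 1 returns +inf with a warning.
    """
    if theta >= 1.0:
        logger.warning("theta >= 1: linearized F_ST is infinite")
        return float("inf")
    v = theta / (1.0 - theta)
    if v < 0 and clip_negative:
        logger.debug("negative theta %.4f clipped to 0 in linearization", theta)
        return 0.0
    return float(v)


def nem_from_fst(
    theta: float,
    estimator: str = "island_moment",
    pop_a: str = "",
    pop_b: str = "",
    per_locus_theta: np.ndarray | None = None,
    ceiling: float = DEFAULT_NEM_CEILING,
) -> MigrationEstimate:
    """Migrants per generation from F_ST under island-model equilibrium.

    ``island_moment``: Nm = (1 - theta) / (4 theta).  ``grid_ml``: maximizes a
    Gaussian pseudo-likelihood of per-locus theta values around
    theta(Nm) = 1 / (1 + 4 Nm) over a log grid Nm in [1e-2, 1e2].  A
    non-positive multi-locus theta yields Nm capped at ``ceiling`` (logged).
    """
    capped = False
    if estimator == "island_moment":
        if theta <= 0:
            nem = ceiling
            capped = True
            logger.info("theta <= 0 for (%s, %s): Nm capped at %g", pop_a, pop_b, ceiling)
        elif theta >= 1:
            nem = 0.0
        else:
            nem = min((1.0 - theta) / (4.0 * theta), ceiling)
            capped = nem == ceiling
    elif estimator == "grid_ml":
        if per_locus_theta is None:
            raise ValueError("grid_ml requires per_locus_theta")
        vals = np.asarray(per_locus_theta, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("grid_ml: no finite per-locus theta values")
        grid = np.logspace(-2, 2, 401)
        expect = 1.0 / (1.0 + 4.0 * grid)
        sse = ((vals[:, None] - expect[None, :]) ** 2).sum(axis=0)
        nem = float(grid[np.argmin(sse)])
    else:
        raise ValueError(f"unknown estimator: {estimator!r}")
    return MigrationEstimate(
        pop_a=pop_a,
        pop_b=pop_b,
        nem=float(nem),
        estimator=estimator,
        theta=float(theta),
        linearized=linearized_fst(theta),
        capped=capped,
    )


def _categorize(pop_a: str, pop_b: str, info: pd.DataFrame) -> str | None:
    la, lb = info.loc[pop_a, "locality"], info.loc[pop_b, "locality"]
    ha, hb = info.loc[pop_a, "habitat"], info.loc[pop_b, "habitat"]
    if la == lb and ha != hb:
        return "among_habitats_within_locality"
    if la != lb and ha == hb:
        return "within_habitat_across_localities"
    return None


def migration_summary(
    estimates: list[MigrationEstimate],
    S: SampleTable,
    panmixia_nem: float = 1.0,
) -> MigrationSummary:
    """Category means of pairwise migration rates and the habitat-vs-locality contrast.

    Categories: all pairs; pairs of different habitats within the same
    locality; pairs of the same habitat across localities.  Each row reports
    mean +/- SE (sd / sqrt(pairs)) and the empirical 2.5-97.5 percentile CI.
    The two contrast categories are compared by a two-sided Mann-Whitney U
    test.  Edges carry a panmixia flag at Nm > ``panmixia_nem`` (the
    conventional one-migrant threshold).
    """
    info = S.population_info()
    rows = {"all": [], "among_habitats_within_locality": [], "within_habitat_across_localities": []}
    edges = []
    graph = nx.Graph()
    for est in estimates:
        rows["all"].append(est.nem)
        cat = _categorize(est.pop_a, est.pop_b, info)
        if cat is not None:
            rows[cat].append(est.nem)
        edges.append(
            {
                "pop_a": est.pop_a,
                "pop_b": est.pop_b,
                "fst": est.theta,
                "linearized_fst": est.linearized,
                "nem": est.nem,
                "panmictic": est.nem > panmixia_nem,
            }
        )
        graph.add_edge(est.pop_a, est.pop_b, nem=est.nem, fst=est.theta)

    recs = []
    for cat, vals in rows.items():
        if len(vals) < 2:
            logger.warning("category %s has %d pairs; summary omitted", cat, len(vals))
            continue
        v = np.array(vals)
        recs.append(
            {
                "category": cat,
                "mean": v.mean(),
                "se": v.std(ddof=1) / np.sqrt(v.size),
                "ci_low": np.percentile(v, 2.5),
                "ci_high": np.percentile(v, 97.5),
                "n_pairs": v.size,
            }
        )
    table = pd.DataFrame(recs).set_index("category") if recs else pd.DataFrame()

    a = np.array(rows["among_habitats_within_locality"])
    b = np.array(rows["within_habitat_across_localities"])
    if a.size >= 2 and b.size >= 2:
        if np.unique(np.concatenate([a, b])).size == 1:
            test = {"U": float(a.size * b.size / 2.0), "p_value": 1.0}
        else:
            u = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = {"U": float(u.statistic), "p_value": float(u.pvalue)}
    else:
        test = {"U": float("nan"), "p_value": float("nan")}
    return MigrationSummary(
        table=table,
        contrast_test=test,
        edges=pd.DataFrame(edges),
        graph=graph,
    )
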