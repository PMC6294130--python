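"""Population-structure summaries: PCoA, hierarchical AMOVA, and Evanno's delta-K.

PCoA is classical metric scaling of a distance matrix (the default genetic
distance elsewhere in the package is 1 - IBS allele sharing).  AMOVA
partitions squared-distance variation into among-locality,
among-population-within-locality and within-population components with the
standard unequal-group-size coefficients.  ``evanno_delta_k`` consumes
externally produced clustering log-likelihoods (one row per (K, run)) and
computes the second-difference statistic used to choose K; the clustering MCMC
itself is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, SampleTable

logger = logging.getLogger(__name__)

__all__ = ["PcoaResult", "AmovaResult", "pcoa", "amova", "evanno_delta_k"]


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # objects x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, decreasing
    explained_pct: np.ndarray  # per positive-eigenvalue axis, sums to 100
    negative_eigenvalues: np.ndarray


@dataclass
class AmovaResult:
    """Nested variance components and their percentages of the total.

    Components may be negative and are reported raw; ``percentages`` are
    computed after truncating negative components at zero when
    ``truncate_negative`` was set (the default), otherwise from raw values.
    ``degenerate`` flags an all-zero total.
    """

    sigma2: dict[str, float]  # among_locality, among_pop_within_locality, within_pop
    percentages: dict[str, float]
    df: dict[str, int]
    ss: dict[str, float]
    degenerate: bool = False


def pcoa(D: np.ndarray | pd.DataFrame, n_axes: int | None = None) -> PcoaResult:
    """Classical scaling (principal coordinates) of a distance matrix.

    Double-centers ``-0.5 * D**2``, eigendecomposes, and scales eigenvectors by
    the square root of their (positive) eigenvalues.  Axis signs follow a
    deterministic convention: the largest-magnitude loading on each axis is
    positive.  Negative eigenvalues (non-Euclidean input) are excluded from the
    explained-variance normalization and reported separately.
    """
    if isinstance(D, pd.DataFrame):
        labels = list(D.index)
        D = D.to_numpy(dtype=float)
    else:
        D = np.asarray(D, dtype=float)
        labels = list(range(D.shape[0]))
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")

    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = max(abs(evals).max(), 1.0) * 1e-10
    pos = evals > tol
    neg = evals < -tol
    k = int(pos.sum())
    if n_axes is not None:
        k = min(k, n_axes)
    coords = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    # sign convention: largest-|loading| coordinate positive on each axis
    for a in range(k):
        col = coords[:, a]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, a] = -col
    pos_sum = evals[pos].sum()
    explained = 100.0 * evals[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=labels, columns=[f"axis{i+1}" for i in range(k)]),
        eigenvalues=evals,
        explained_pct=explained,
        negative_eigenvalues=evals[neg],
    )


def _squared_distance_matrix(G: GenotypeMatrix) -> np.ndarray:
    """Pairwise mean squared dosage difference over pairwise-complete loci."""
    D = G.dosage
    obs = ~np.isnan(D)
    Df = np.nan_to_num(D, nan=0.0)
    n = G.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        shared = obs[i] & obs
        diff2 = (Df[i] - Df) ** 2
        diff2[~shared] = 0.0
        cnt = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[i] = np.where(cnt > 0, diff2.sum(axis=1) / np.maximum(cnt, 1), np.nan)
    np.fill_diagonal(out, 0.0)
    return out


def amova(
    G: GenotypeMatrix, S: SampleTable, truncate_negative: bool = True
) -> AmovaResult:
    """Hierarchical AMOVA: locality / population-within-locality / within-population.

    Sums of squares come from squared Euclidean distances between dosage
    vectors (pairwise-complete, normalized by shared-locus count); variance
    components follow the nested ANOVA expectations with unequal-group-size
    coefficients.  Significance permutations are not implemented.
    """
    pop_of = S.population_of()
    pops = np.array([pop_of[s] for s in G.sample_ids])
    info = S.population_info()
    loc_of_pop = info["locality"].to_dict()
    locs = np.array([loc_of_pop[p] for p in pops])

    uniq_locs = np.unique(locs)
    uniq_pops = np.unique(pops)
    if len(uniq_locs) < 2:
        raise ValueError("AMOVA requires at least two localities")
    for p in uniq_pops:
        if (pops == p).sum() < 2:
            raise ValueError(f"population {p} has fewer than 2 samples")

    D2 = _squared_distance_matrix(G)
    if np.isnan(D2).any():
        raise ValueError("sample pairs with no shared loci; AMOVA undefined")
    N = len(pops)
    L = len(uniq_locs)
    P = len(uniq_pops)

    def ss_within(groups: np.ndarray) -> float:
        total = 0.0
        for g in np.unique(groups):
            idx = np.where(groups == g)[0]
            sub = D2[np.ix_(idx, idx)]
            total += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
        return total

    ss_total = D2[np.triu_indices(N, k=1)].sum() / N
    ss_wp = ss_within(pops)
    ss_wl = ss_within(locs)
    ss_ap = ss_wl - ss_wp  # among populations within localities
    ss_al = ss_total - ss_wl  # among localities

    df_al, df_ap, df_wp = L - 1, P - L, N - P
    if df_ap <= 0 or df_wp <= 0:
        raise ValueError("degenerate design: need >1 population per locality and >1 sample per population")

    n_p = pd.Series(pops).value_counts()
    n_l = pd.Series(locs).value_counts()
    pop_loc = {p: loc_of_pop[p] for p in uniq_pops}
    sum_np2_over_nl = sum(n_p[p] ** 2 / n_l[pop_loc[p]] for p in uniq_pops)
    sum_np2_over_N = sum(n_p[p] ** 2 for p in uniq_pops) / N
    sum_nl2_over_N = sum(n_l[l] ** 2 for l in uniq_locs) / N

    n1 = (N - sum_np2_over_nl) / df_ap
    n2 = (sum_np2_over_nl - sum_np2_over_N) / df_al
    n3 = (N - sum_nl2_over_N) / df_al

    ms_al, ms_ap, ms_wp = ss_al / df_al, ss_ap / df_ap, ss_wp / df_wp
    s2_wp = ms_wp
    s2_ap = (ms_ap - s2_wp) / n1
    s2_al = (ms_al - s2_wp - n2 * s2_ap) / n3

    sigma2 = {
        "among_locality": float(s2_al),
        "among_pop_within_locality": float(s2_ap),
        "within_pop": float(s2_wp),
    }
    vals = np.array(list(sigma2.values()))
    basis = np.maximum(vals, 0.0) if truncate_negative else vals
    total = basis.sum()
    degenerate = not (total > 0)
    if degenerate:
        logger.warning("AMOVA total variance is zero; percentages undefined")
        pct = {k: float("nan") for k in sigma2}
    else:
        pct = {k: float(100.0 * b / total) for k, b in zip(sigma2, basis)}
    return AmovaResult(
        sigma2=sigma2,
        percentages=pct,
        df={"among_locality": df_al, "among_pop_within_locality": df_ap, "within_pop": df_wp},
        ss={"among_locality": float(ss_al), "among_pop_within_locality": float(ss_ap), "within_pop": float(ss_wp)},
        degenerate=degenerate,
    )


def evanno_delta_k(runs: pd.DataFrame) -> pd.DataFrame:
    """Second-difference statistic over clustering log-likelihood runs.

    ``runs`` has columns K, run, loglik with a contiguous K range and >= 2 runs
    per interior K.  Returns a table indexed by K with mean_L, sd_L,
    abs_second_diff ``|L''(K)|`` and ``delta_k = |L''(K)| / sd_L`` for interior
    K; delta_k is NaN (flagged) where the run standard deviation is zero.  The
    attribute ``best_k`` on the returned frame holds the argmax.
    """
    req = {"K", "run", "loglik"}
    if not req.issubset(runs.columns):
        raise ValueError(f"runs table must have columns {sorted(req)}")
    g = runs.groupby("K")["loglik"]
    tab = pd.DataFrame({"mean_L": g.mean(), "sd_L": g.std(ddof=1), "n_runs": g.size()})
    ks = tab.index.to_numpy()
    if len(ks) < 3:
        raise ValueError("need at least three contiguous K values")
    if not np.array_equal(ks, np.arange(ks.min(), ks.max() + 1)):
        raise ValueError("K range must be contiguous")
    interior = tab.index[1:-1]
    if (tab.loc[interior, "n_runs"] < 2).any():
        raise ValueError("interior K values need at least 2 runs")
    mean = tab["mean_L"]
    l2 = pd.Series(np.nan, index=tab.index)
    for k in interior:
        l2[k] = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
    tab["abs_second_diff"] = l2
    with np.errstate(divide="ignore", invalid="ignore"):
        dk = l2 / tab["sd_L"]
    dk[tab["sd_L"] == 0] = np.nan
    tab["delta_k"] = dk
    if tab.loc[interior, "sd_L"].eq(0).any():
        logger.warning("zero run-to-run standard deviation at some K; delta_k undefined there")
    best = tab["delta_k"].idxmax() if tab["delta_k"].notna().any() else None
    tab.attrs["best_k"] = best
    return tab
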