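"""Geographic and ecological distance matrices, permutation Mantel tests, and
the per-partition IBD/IBE correlation table.

Isolation-by-distance (IBD) predicts a positive correlation between
genetic differentiation (linearized F_ST) and geographic distance;
isolation-by-environment (IBE) predicts the same against an ecological
(habitat-rank) distance.  Both are tested with one-sided permutation Mantel
tests (add-one p-value convention) and flagged against a per-dataset
Bonferroni threshold of alpha divided by the number of population pairs.

With n_perm permutations the smallest attainable p-value is
1 / (n_perm + 1); when the Bonferroni threshold falls below that floor
(e.g. 0.05 / 171 pairs at 1,000 permutations) the significance flag uses the
floor instead, i.e. a correlation exceeded by no permutation is called
significant.  The raw p-values and thresholds are always reported alongside.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import divergence
from .genotypes import GenotypeMatrix, HabitatRanking, SampleTable

logger = logging.getLogger(__name__)

__all__ = [
    "EARTH_RADIUS_KM",
    "DistanceBundle",
    "MantelResult",
    "geographic_distances",
    "ecological_distances",
    "mantel",
    "build_distance_bundle",
    "ibd_ibe_table",
]

#: IUGG mean Earth radius.
EARTH_RADIUS_KM = 6371.0087714


@dataclass
class DistanceBundle:
    populations: list[str]
    genetic: pd.DataFrame  # linearized F_ST
    geographic: pd.DataFrame  # km
    ecological_frost: pd.DataFrame
    ecological_moisture: pd.DataFrame

    def __post_init__(self) -> None:
        for name in ("genetic", "geographic", "ecological_frost", "ecological_moisture"):
            M = getattr(self, name)
            if list(M.index) != self.populations or list(M.columns) != self.populations:
                raise ValueError(f"{name} matrix is not aligned to the population order")
            arr = M.to_numpy()
            if not np.allclose(arr, arr.T, atol=1e-9, equal_nan=True):
                raise ValueError(f"{name} matrix is not symmetric")


@dataclass
class MantelResult:
    matrix_a: str
    matrix_b: str
    r: float
    p: float
    n_perm: int
    seed: int


def geographic_distances(S: SampleTable) -> pd.DataFrame:
    """Great-circle distances (km) between population coordinate centroids."""
    if S.frame[["latitude", "longitude"]].isna().any().any():
        bad = S.frame.loc[S.frame[["latitude", "longitude"]].isna().any(axis=1), "sample_id"]
        raise ValueError(f"missing coordinates for samples: {list(bad)[:5]}")
    info = S.population_info()
    lat = np.radians(info["latitude"].to_numpy())
    lon = np.radians(info["longitude"].to_numpy())
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=info.index, columns=info.index)


def ecological_distances(S: SampleTable, ranking: HabitatRanking) -> pd.DataFrame:
    """Absolute habitat-rank differences between populations (scalar Euclidean)."""
    info = S.population_info()
    unknown = sorted(set(info["habitat"]) - set(ranking.rank_of))
    if unknown:
        raise ValueError(f"habitats not covered by ranking '{ranking.axis_name}': {unknown}")
    ranks = ranking.ranks_for(info["habitat"])
    d = np.abs(ranks[:, None] - ranks[None, :])
    return pd.DataFrame(d, index=info.index, columns=info.index)


def _upper(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def mantel(
    A: pd.DataFrame | np.ndarray,
    B: pd.DataFrame | np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    name_a: str = "A",
    name_b: str = "B",
) -> MantelResult:
    """One-sided permutation Mantel test between two aligned distance matrices.

    r is the Pearson correlation over strict upper-triangle entries; the null
    distribution jointly permutes rows and columns of B;
    p = (#{r_perm >= r_obs} + 1) / (n_perm + 1).
    """
    Aa = A.to_numpy(dtype=float) if isinstance(A, pd.DataFrame) else np.asarray(A, dtype=float)
    Bb = B.to_numpy(dtype=float) if isinstance(B, pd.DataFrame) else np.asarray(B, dtype=float)
    if Aa.shape != Bb.shape or Aa.ndim != 2 or Aa.shape[0] != Aa.shape[1]:
        raise ValueError("matrices must be square and aligned")
    n = Aa.shape[0]
    if n < 4:
        raise ValueError("Mantel test requires at least 4 populations")
    if not (np.isfinite(Aa).all() and np.isfinite(Bb).all()):
        raise ValueError("distance matrices contain non-finite entries")
    iu = np.triu_indices(n, k=1)
    x = Aa[iu]
    if x.std() == 0:
        raise ValueError("matrix A has zero off-diagonal variance; r undefined")
    if _upper(Bb).std() == 0:
        raise ValueError("matrix B has zero off-diagonal variance; r undefined")

    xc = x - x.mean()
    xn = xc / np.sqrt((xc**2).sum())

    def corr_with(yv: np.ndarray) -> np.ndarray:
        yc = yv - yv.mean(axis=-1, keepdims=True)
        denom = np.sqrt((yc**2).sum(axis=-1))
        return (yc @ xn) / denom

    r_obs = float(corr_with(Bb[iu][None, :])[0])

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    y_perm = Bb[perms[:, iu[0]], perms[:, iu[1]]]  # (n_perm, n_pairs)
    r_perm = corr_with(y_perm)
    p = (np.count_nonzero(r_perm >= r_obs - 1e-12) + 1) / (n_perm + 1)
    return MantelResult(name_a, name_b, r_obs, float(p), n_perm, seed)


def build_distance_bundle(
    G: GenotypeMatrix,
    S: SampleTable,
    frost: HabitatRanking,
    moisture: HabitatRanking,
) -> DistanceBundle:
    """Aligned genetic (linearized F_ST), geographic and ecological matrices."""
    theta, _ = divergence.fst_matrix(G, S)
    lin = theta.map(lambda t: divergence.linearized_fst(t) if np.isfinite(t) else np.nan)
    np.fill_diagonal(lin.values, 0.0)
    pops = list(theta.index)
    geo = geographic_distances(S).loc[pops, pops]
    eco_f = ecological_distances(S, frost).loc[pops, pops]
    eco_m = ecological_distances(S, moisture).loc[pops, pops]
    return DistanceBundle(pops, lin, geo, eco_f, eco_m)


def _derived_seed(master_seed: int, dataset: str, distance: str) -> int:
    h = hashlib.sha256(f"{master_seed}|{dataset}|{distance}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def ibd_ibe_table(
    partitions,
    S: SampleTable,
    frost: HabitatRanking,
    moisture: HabitatRanking,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[MantelResult]]:
    """Mantel correlations of genetic vs geographic/frost/moisture distance per partition.

    For each dataset partition, pairwise F_ST is recomputed on that
    partition's loci and populations, linearized, and tested against the
    three distance matrices.  The Bonferroni threshold is alpha / N_PW where
    N_PW is the partition's population-pair count.  Per-test permutation seeds
    are derived deterministically from (seed, dataset name, distance name).
    Partitions failing the preconditions (< 4 populations or < 2 loci) are
    omitted with a diagnostic.
    """
    rows = []
    details: list[MantelResult] = []
    for part in partitions:
        Ssub = part.samples
        pops = Ssub.populations
        n_pw = len(pops) * (len(pops) - 1) // 2
        if len(pops) < 4 or part.genotypes.n_loci < 2:
            logger.warning(
                "partition %s omitted (%d populations, %d loci)",
                part.name, len(pops), part.genotypes.n_loci,
            )
            continue
        bundle = build_distance_bundle(part.genotypes, Ssub, frost, moisture)
        threshold = alpha / n_pw
        floor = 1.0 / (n_perm + 1)
        eff_threshold = max(threshold, floor)
        row = {
            "population_dataset": part.population_subset,
            "marker_dataset": part.marker_subset,
            "n_pw": n_pw,
            "n_snps": part.genotypes.n_loci,
            "bonferroni_threshold": threshold,
        }
        for dist_name, M in (
            ("geographic", bundle.geographic),
            ("frost", bundle.ecological_frost),
            ("moisture", bundle.ecological_moisture),
        ):
            s = _derived_seed(seed, part.name, dist_name)
            try:
                res = mantel(bundle.genetic, M, n_perm=n_perm, seed=s,
                             name_a=f"{part.name}:genetic", name_b=dist_name)
                row[f"r_{dist_name}"] = res.r
                row[f"p_{dist_name}"] = res.p
                row[f"sig_{dist_name}"] = res.p <= eff_threshold
            except ValueError as exc:
                logger.warning("Mantel undefined for %s vs %s: %s", part.name, dist_name, exc)
                res = MantelResult(f"{part.name}:genetic", dist_name, np.nan, np.nan, n_perm, s)
                row[f"r_{dist_name}"] = np.nan
                row[f"p_{dist_name}"] = np.nan
                row[f"sig_{dist_name}"] = False
            details.append(res)
        rows.append(row)
    return pd.DataFrame(rows), details
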