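"""Genome-environment association scans and the dataset-partition driver.

Each SNP's minor-allele dosage is regressed on a fixed factor (categorical
locality, or an ordinal habitat rank for the frost / moisture axes) together
with a phylogenetic covariate; the factor is tested by a partial F-test.  Two
model families are available:

* GLM: ordinary least squares per locus on samples with non-missing dosage.
* MLM: a single-random-effect mixed model, dosage = X beta + u + e with
  u ~ N(0, sigma2_g K) for an identity-by-state kinship K.  Variance
  components are profiled by REML over delta = sigma2_e / sigma2_g after an
  eigendecomposition of K ("EMMA").  ``emma_full`` re-estimates delta at
  every locus; ``p3d`` estimates delta once under the factor-free null model
  and reuses it for every locus test.

Genomic-control inflation (lambda_GC) and QQ quantile pairs are returned as
scan diagnostics.  Bonferroni thresholds divide alpha by the number of
markers tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import (
    FilterSpec,
    GenotypeMatrix,
    HabitatRanking,
    KinshipMatrix,
    SampleTable,
    apply_filters,
)
from .popstruct import pcoa

logger = logging.getLogger(__name__)

__all__ = [
    "DesignSpec",
    "ScanDiagnostics",
    "MixedModelFit",
    "DatasetPartition",
    "BonferroniThreshold",
    "phylo_covariate",
    "glm_scan",
    "mlm_scan",
    "bonferroni_threshold",
    "select_associated",
    "partition_datasets",
]

#: Smallest reportable p-value (avoids log-of-zero in reports).
P_FLOOR = 1e-300

FACTORS = ("locality", "frost", "moisture")


@dataclass(frozen=True)
class DesignSpec:
    fixed_factor: str  # "locality" | "frost" | "moisture"
    covariate: pd.Series | None = None  # per-sample phylogenetic covariate
    model_family: str = "glm"

    def __post_init__(self) -> None:
        if self.fixed_factor not in FACTORS:
            raise ValueError(f"fixed_factor must be one of {FACTORS}")
        if self.covariate is not None and not np.isfinite(self.covariate).all():
            raise ValueError("covariate contains non-finite values")


@dataclass
class ScanDiagnostics:
    lambda_gc: float
    qq: pd.DataFrame  # columns: expected_neglog10p, observed_neglog10p


@dataclass
class MixedModelFit:
    sigma2_g: float
    sigma2_e: float
    delta: float
    reml_loglik: float
    kinship_eigenvalues: np.ndarray = field(repr=False, default=None)


@dataclass
class DatasetPartition:
    name: str
    population_subset: str  # "entire" | "locality-contrast" | "habitat-contrast"
    marker_subset: str  # "all" | "locality-associated" | "frost-associated" | "moisture-associated"
    genotypes: GenotypeMatrix
    samples: SampleTable
    n_polymorphic: int


class BonferroniThreshold(NamedTuple):
    threshold: float
    neglog10: float


# ---------------------------------------------------------------------------
# Phylogenetic covariate
# ---------------------------------------------------------------------------


def _patristic_from_newick(path_or_str: str, taxa: list[str]) -> pd.DataFrame:
    import dendropy

    src = str(path_or_str)
    if src.strip().startswith("("):
        tree = dendropy.Tree.get(data=src, schema="newick")
    else:
        tree = dendropy.Tree.get(path=src, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    labels = {t.label: t for t in tree.taxon_namespace}
    missing = [t for t in taxa if t not in labels]
    if missing:
        raise ValueError(f"populations missing from tree tips: {missing}")
    M = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            d = pdm.patristic_distance(labels[a], labels[b])
            M.loc[a, b] = M.loc[b, a] = d
    return M


def phylo_covariate(
    pop_distances: pd.DataFrame | str,
    S: SampleTable,
    n_axes: int = 1,
) -> pd.Series:
    """Per-sample phylogenetic covariate from a population distance matrix or tree.

    A newick tree is first reduced to patristic distances between population
    tips.  The population distance matrix is summarized by its first principal
    coordinate (``n_axes`` > 1 returns extra columns); each sample receives its
    population's score, centered over samples.  A degenerate first axis (all
    populations equidistant) is flagged with a warning.
    """
    pops = S.populations
    if isinstance(pop_distances, (str,)):
        M = _patristic_from_newick(pop_distances, pops)
    else:
        missing = [p for p in pops if p not in pop_distances.index]
        if missing:
            raise ValueError(f"populations missing from distance matrix: {missing}")
        M = pop_distances.loc[pops, pops]
    res = pcoa(M, n_axes=n_axes)
    coords = res.coordinates
    if res.eigenvalues[0] <= 1e-12 or (
        len(res.eigenvalues) > 1 and np.isclose(res.eigenvalues[0], res.eigenvalues[1])
    ):
        logger.warning("first principal coordinate of the phylogenetic distances is degenerate")
    pop_of = S.population_of()
    if n_axes == 1:
        score = coords.iloc[:, 0] if coords.shape[1] else pd.Series(0.0, index=pops)
        vals = pd.Series([score[pop_of[s]] for s in S.sample_ids], index=S.sample_ids)
        return vals - vals.mean()
    out = pd.DataFrame(
        [coords.loc[pop_of[s]].to_numpy() for s in S.sample_ids],
        index=S.sample_ids,
        columns=coords.columns,
    )
    return out - out.mean()


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


def _design_matrices(
    G: GenotypeMatrix,
    S: SampleTable,
    design: DesignSpec,
    ranking: HabitatRanking | None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Full design [intercept, covariate, factor block] and the null part.

    Returns (X_full, X_null, q) where q is the number of factor columns.
    """
    meta = S.frame.set_index("sample_id").loc[G.sample_ids]
    cols = [np.ones(G.n_samples)]
    if design.covariate is not None:
        cov = design.covariate.reindex(G.sample_ids)
        if cov.isna().any():
            raise ValueError("covariate missing for some samples")
        cols.append(cov.to_numpy(dtype=float))
    X_null = np.column_stack(cols)
    if design.fixed_factor == "locality":
        levels = sorted(meta["locality"].unique())
        if len(levels) < 2:
            raise ValueError("locality factor needs >= 2 observed levels")
        fac = np.column_stack(
            [(meta["locality"] == lv).to_numpy(dtype=float) for lv in levels[1:]]
        )
    else:
        if ranking is None:
            raise ValueError(f"factor '{design.fixed_factor}' requires a HabitatRanking")
        ranks = ranking.ranks_for(meta["habitat"])
        if np.unique(ranks).size < 2:
            raise ValueError("habitat rank factor has a single observed level")
        fac = ranks[:, None]
    X_full = np.column_stack([X_null, fac])
    return X_full, X_null, fac.shape[1]


def _partial_f(
    y: np.ndarray, X_full: np.ndarray, X_null: np.ndarray, q: int
) -> tuple[float, int, int, float, np.ndarray | None]:
    """Partial F-test of the factor block by comparing nested OLS fits.

    Returns (F, df1, df2, p, beta) or flags collinearity with p = NaN.
    """
    n = y.size
    p_full = X_full.shape[1]
    df2 = n - p_full
    if df2 <= 0:
        return np.nan, q, df2, np.nan, None
    if np.linalg.matrix_rank(X_full) < p_full:
        return np.nan, q, df2, np.nan, None
    beta_f, rss_f = _ols_rss(y, X_full)
    _, rss_0 = _ols_rss(y, X_null)
    if y.std() == 0:
        return 0.0, q, df2, 1.0, beta_f
    if rss_f <= max(1e-12 * rss_0, 1e-30):
        # perfect fit: p underflows to the configured floor
        return np.inf, q, df2, P_FLOOR, beta_f
    F = ((rss_0 - rss_f) / q) / (rss_f / df2)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, q, df2))
    return float(F), q, df2, max(p, P_FLOOR), beta_f


def _ols_rss(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        rss = float(res[0])
    else:
        r = y - X @ beta
        rss = float(r @ r)
    return beta, rss


def _diagnostics(pvals: np.ndarray) -> ScanDiagnostics:
    p = pvals[np.isfinite(pvals)]
    p = np.clip(p, P_FLOOR, 1.0)
    if p.size == 0:
        return ScanDiagnostics(float("nan"), pd.DataFrame())
    chi2 = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
    obs = np.sort(-np.log10(p))[::-1]
    exp = -np.log10((np.arange(1, p.size + 1) - 0.5) / p.size)
    qq = pd.DataFrame({"expected_neglog10p": exp, "observed_neglog10p": obs})
    return ScanDiagnostics(lam, qq)


# ---------------------------------------------------------------------------
# GLM scan
# ---------------------------------------------------------------------------


def glm_scan(
    G: GenotypeMatrix,
    S: SampleTable,
    design: DesignSpec,
    ranking: HabitatRanking | None = None,
) -> tuple[pd.DataFrame, ScanDiagnostics]:
    """Per-locus least-squares association scan with a partial F-test.

    Samples with missing dosage are dropped per locus.  Returns the
    association table (locus_id, F, df1, df2, p, neglog10p, model_family) and
    scan diagnostics.
    """
    X_full, X_null, q = _design_matrices(G, S, design, ranking)
    records = []
    for j, locus in enumerate(G.locus_ids):
        y = G.dosage[:, j]
        m = ~np.isnan(y)
        F, df1, df2, p, _ = _partial_f(y[m], X_full[m], X_null[m], q)
        records.append((locus, design.fixed_factor, "glm", F, df1, df2, p))
    table = pd.DataFrame(
        records, columns=["locus_id", "factor", "model_family", "F", "df1", "df2", "p"]
    )
    table["neglog10p"] = -np.log10(table["p"].clip(lower=P_FLOOR))
    return table, _diagnostics(table["p"].to_numpy())


# ---------------------------------------------------------------------------
# Mixed model (EMMA / P3D)
# ---------------------------------------------------------------------------

REML_GRID_POINTS = 61
REML_LOG_DELTA_RANGE = (-5.0, 5.0)
REML_TOL = 1e-6


def _reml_loglik(log_delta: float, s: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> float:
    """REML log-likelihood of the rotated model at delta = exp(log_delta).

    s are kinship eigenvalues; yr, Xr the rotated response and design.
    """
    delta = np.exp(log_delta)
    n, p = Xr.shape
    w = 1.0 / (s + delta)
    XtW = Xr.T * w
    XtWX = XtW @ Xr
    XtWy = XtW @ yr
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return -np.inf
    r = yr - Xr @ beta
    rss = float((r * r * w).sum())
    if rss <= 0:
        return np.inf
    sigma2 = rss / (n - p)
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    _, logdet_XtX = np.linalg.slogdet(Xr.T @ Xr)
    ll = -0.5 * (
        (n - p) * (np.log(2 * np.pi * sigma2) + 1)
        + np.log(s + delta).sum()
        + logdet_XtWX
        - logdet_XtX
    )
    return float(ll)


def _profile_delta(s: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> tuple[float, float]:
    """Grid search plus golden-section refinement of the REML profile in log delta."""
    lo, hi = REML_LOG_DELTA_RANGE
    grid = np.linspace(lo, hi, REML_GRID_POINTS)
    vals = np.array([_reml_loglik(g, s, yr, Xr) for g in grid])
    k = int(np.nanargmax(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    if a == b:
        best = grid[k]
    else:
        res = optimize.minimize_scalar(
            lambda g: -_reml_loglik(g, s, yr, Xr),
            bounds=(a, b),
            method="bounded",
            options={"xatol": REML_TOL},
        )
        best = float(res.x)
        if _reml_loglik(best, s, yr, Xr) < vals[k]:
            best = grid[k]
    return float(np.exp(best)), _reml_loglik(best, s, yr, Xr)


def _validate_kinship(K: np.ndarray, tol: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose K, clip small negative eigenvalues, reject pathological input.

    Pairwise-complete IBS estimation with missing calls routinely yields
    slightly indefinite matrices; eigenvalues above ``-tol`` times the leading
    eigenvalue are clipped to zero, anything worse is an error.
    """
    evals, evecs = np.linalg.eigh((K + K.T) / 2)
    if evals.min() < -tol * max(1.0, evals.max()):
        raise ValueError(
            f"kinship matrix is not positive semi-definite (min eigenvalue {evals.min():.3g})"
        )
    clipped = np.clip(evals, 0.0, None)
    K_psd = (evecs * clipped) @ evecs.T
    return evals, (K_psd + K_psd.T) / 2


def _whitened_f(
    y: np.ndarray, X_full: np.ndarray, X_null: np.ndarray, q: int,
    K: np.ndarray, delta: float,
) -> tuple[float, int, int, float]:
    """Partial F at fixed delta via Cholesky whitening of V = K + delta I."""
    from scipy.linalg import solve_triangular

    V = K + delta * np.eye(K.shape[0])
    L = np.linalg.cholesky(V)
    yw = solve_triangular(L, y, lower=True)
    Xfw = solve_triangular(L, X_full, lower=True)
    Xnw = solve_triangular(L, X_null, lower=True)
    F, df1, df2, p, _ = _partial_f(yw, Xfw, Xnw, q)
    return F, df1, df2, p


def mlm_scan(
    G: GenotypeMatrix,
    S: SampleTable,
    design: DesignSpec,
    K: KinshipMatrix,
    mode: str = "p3d",
    ranking: HabitatRanking | None = None,
    p3d_max_loci: int = 500,
) -> tuple[pd.DataFrame, ScanDiagnostics, MixedModelFit]:
    """Mixed-model association scan with an IBS kinship random effect.

    ``emma_full`` re-estimates delta = sigma2_e / sigma2_g by REML at every
    locus (eigendecomposition of the kinship submatrix for that locus's
    non-missing samples); ``p3d`` profiles delta once under the factor-free
    null model (intercept + covariate, REML objective summed over up to
    ``p3d_max_loci`` evenly spaced loci with mean-imputed missing dosages) and
    reuses it for every locus.  Per-locus tests drop samples with missing
    dosage, exactly as the GLM scan does, so with an identity kinship the MLM
    p-values reduce to the GLM ones.
    """
    if mode not in ("emma_full", "p3d"):
        raise ValueError("mode must be 'emma_full' or 'p3d'")
    if list(K.sample_ids) != list(G.sample_ids):
        K = KinshipMatrix(G.sample_ids, K.to_frame().loc[G.sample_ids, G.sample_ids].to_numpy())
    evals_all, Kmat = _validate_kinship((K.K + K.K.T) / 2)

    X_full, X_null, q = _design_matrices(G, S, design, ranking)

    delta_shared = None
    reml_ll = np.nan
    if mode == "p3d":
        s_all, U = np.linalg.eigh(Kmat)
        s_all = np.clip(s_all, 0.0, None)
        Xr_null = U.T @ X_null
        idx = np.unique(np.linspace(0, G.n_loci - 1, min(p3d_max_loci, G.n_loci)).astype(int))
        col_means = np.nanmean(G.dosage, axis=0)
        lls = []

        def summed_ll(log_delta: float) -> float:
            return sum(
                _reml_loglik(log_delta, s_all, U.T @ _impute(G.dosage[:, j], col_means[j]), Xr_null)
                for j in idx
            )

        lo, hi = REML_LOG_DELTA_RANGE
        grid = np.linspace(lo, hi, REML_GRID_POINTS)
        vals = np.array([summed_ll(g) for g in grid])
        k = int(np.nanargmax(vals))
        res = optimize.minimize_scalar(
            lambda g: -summed_ll(g),
            bounds=(grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]),
            method="bounded",
            options={"xatol": REML_TOL},
        )
        delta_shared = float(np.exp(res.x))
        reml_ll = float(-res.fun)
        logger.info("p3d: shared delta = %.4g (REML over %d loci)", delta_shared, len(idx))

    records = []
    deltas = []
    for j, locus in enumerate(G.locus_ids):
        y = G.dosage[:, j]
        m = ~np.isnan(y)
        ym = y[m]
        Xf, Xn = X_full[m], X_null[m]
        Km = Kmat[np.ix_(m, m)]
        if ym.std() == 0:
            records.append((locus, design.fixed_factor, f"mlm_{mode}", 0.0, q, ym.size - Xf.shape[1], 1.0, np.nan))
            continue
        try:
            if mode == "emma_full":
                s, U = np.linalg.eigh(Km)
                s = np.clip(s, 0.0, None)
                yr, Xfr, Xnr = U.T @ ym, U.T @ Xf, U.T @ Xn
                delta_j, _ = _profile_delta(s, yr, Xfr)
                w = 1.0 / np.sqrt(s + delta_j)
                F, df1, df2, p, _ = _partial_f(yr * w, Xfr * w[:, None], Xnr * w[:, None], q)
            else:
                delta_j = delta_shared
                F, df1, df2, p = _whitened_f(ym, Xf, Xn, q, Km, delta_j)
        except np.linalg.LinAlgError:
            logger.warning("REML failed to converge at locus %s; flagged", locus)
            F, df1, df2, p, delta_j = np.nan, q, np.nan, np.nan, np.nan
        records.append((locus, design.fixed_factor, f"mlm_{mode}", F, df1, df2, p, delta_j))
        deltas.append(delta_j)

    table = pd.DataFrame(
        records,
        columns=["locus_id", "factor", "model_family", "F", "df1", "df2", "p", "delta"],
    )
    table["neglog10p"] = -np.log10(table["p"].clip(lower=P_FLOOR))
    delta_rep = delta_shared if mode == "p3d" else (float(np.nanmedian(deltas)) if deltas else np.nan)
    # representative variance components on the unit-variance dosage scale
    sigma2_g = 1.0 / (1.0 + delta_rep) if np.isfinite(delta_rep) else np.nan
    sigma2_e = delta_rep * sigma2_g if np.isfinite(delta_rep) else np.nan
    fit = MixedModelFit(
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        delta=delta_rep,
        reml_loglik=reml_ll,
        kinship_eigenvalues=evals_all,
    )
    return table, _diagnostics(table["p"].to_numpy()), fit


def _impute(y: np.ndarray, mean: float) -> np.ndarray:
    out = y.copy()
    out[np.isnan(out)] = mean
    return out


# ---------------------------------------------------------------------------
# Thresholds and partitioning
# ---------------------------------------------------------------------------


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> BonferroniThreshold:
    """Strict Bonferroni threshold alpha / n_tests and its -log10."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    t = alpha / n_tests
    return BonferroniThreshold(t, float(-np.log10(t)))


def select_associated(table: pd.DataFrame, threshold: float) -> list[str]:
    """Locus ids with p <= threshold, in stable (input) order."""
    if table.empty:
        raise ValueError("association table is empty")
    mask = table["p"].to_numpy() <= threshold
    return list(table.loc[mask, "locus_id"])


MARKER_SUBSET_NAMES = {
    "locality": "locality-associated",
    "frost": "frost-associated",
    "moisture": "moisture-associated",
}


def partition_datasets(
    G: GenotypeMatrix,
    S: SampleTable,
    assoc: dict,
    subset_rules: dict[str, list[str]],
    filter_spec: FilterSpec | None = None,
) -> list[DatasetPartition]:
    """Cross population subsets with marker subsets into dataset partitions.

    ``subset_rules`` maps population-subset names ("locality-contrast",
    "habitat-contrast") to locality lists; "entire" is always included.
    ``assoc`` maps factor -> associated locus ids, either flat (applied to all
    population subsets) or nested per subset name.  Each population subset is
    re-filtered with the same MAF and call-rate rules as the full dataset
    (depth rule not reapplied); marker subsets are intersected with the
    re-filtered loci.  Partitions with fewer than 2 polymorphic loci are
    dropped (logged), mirroring the exclusion of monomorphic subsets.
    """
    filter_spec = filter_spec or FilterSpec()
    refilter = FilterSpec(
        min_locus_depth=0.0,
        min_maf=filter_spec.min_maf,
        min_call_rate=filter_spec.min_call_rate,
    )
    pop_subsets: dict[str, SampleTable] = {"entire": S}
    for name, localities in subset_rules.items():
        sub = S.subset_localities(localities)
        if sub.frame.empty:
            raise ValueError(f"population subset rule {name!r} selects no samples")
        pop_subsets[name] = sub

    nested = assoc and all(isinstance(v, dict) for v in assoc.values())
    partitions: list[DatasetPartition] = []
    for subset_name, Ssub in pop_subsets.items():
        Gsub = G.take_samples([s for s in G.sample_ids if s in set(Ssub.sample_ids)])
        # depth rule intentionally skipped on re-filtering; silence the warning
        if Gsub.depth is None:
            Gsub = GenotypeMatrix(Gsub.sample_ids, Gsub.locus_ids, Gsub.dosage,
                                  np.full_like(Gsub.dosage, np.inf))
        Gf = apply_filters(Gsub, refilter)
        Gf = GenotypeMatrix(Gf.sample_ids, Gf.locus_ids, Gf.dosage, None)
        assoc_here = assoc.get(subset_name, {}) if nested else (assoc or {})
        marker_subsets: dict[str, list[str]] = {"all": Gf.locus_ids}
        for factor, loci in assoc_here.items():
            name = MARKER_SUBSET_NAMES.get(factor, f"{factor}-associated")
            marker_subsets[name] = [l for l in Gf.locus_ids if l in set(loci)]
        for marker_name, loci in marker_subsets.items():
            Gm = Gf.take_loci(loci)
            n_poly = _n_polymorphic(Gm)
            pname = f"{subset_name}/{marker_name}"
            if n_poly < 2:
                logger.info("partition %s dropped (%d polymorphic loci)", pname, n_poly)
                continue
            partitions.append(
                DatasetPartition(
                    name=pname,
                    population_subset=subset_name,
                    marker_subset=marker_name,
                    genotypes=Gm,
                    samples=Ssub,
                    n_polymorphic=n_poly,
                )
            )
            logger.info("partition %s: %d loci (%d polymorphic)", pname, Gm.n_loci, n_poly)
    return partitions


def _n_polymorphic(G: GenotypeMatrix) -> int:
    with np.errstate(invalid="ignore"):
        p = np.nanmean(G.dosage, axis=0) / 2.0
    return int(np.count_nonzero((p > 0) & (p < 1)))
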