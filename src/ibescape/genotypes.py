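"""Genotype containers, GBS-style variant filtering, and per-locus summaries.

The central object is :class:`GenotypeMatrix`: a samples x loci table of
minor-allele dosages (0, 1, 2, or missing) with an optional aligned read-depth
matrix.  Missing genotypes are a first-class state (``NaN``) and are never
imputed here; every downstream operation declares its own missing-data
contract.

Filtering follows the GBS rule set used for reduced-representation SNP panels:
mean read count per locus strictly above a floor, minor allele frequency (MAF)
strictly above a floor, and genotype call rate at or above a floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HABITATS = ("F", "W", "D")

__all__ = [
    "GenotypeMatrix",
    "SampleTable",
    "HabitatRanking",
    "FilterSpec",
    "LocusStats",
    "KinshipMatrix",
    "LDStats",
    "load_genotypes",
    "load_sample_table",
    "load_habitat_ranking",
    "apply_filters",
    "allele_frequencies",
    "ibs_kinship",
    "ld_prune",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Samples x loci minor-allele dosage matrix with optional read depths.

    ``dosage`` is float64 with values in {0, 1, 2} and ``NaN`` for missing
    calls.  ``depth`` (if present) has the same shape; entries at missing
    dosages may be anything and are ignored.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    dosage: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.locus_ids = list(self.locus_ids)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("locus_ids are not unique")
        obs = self.dosage[~np.isnan(self.dosage)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=float)
            if self.depth.shape != self.dosage.shape:
                raise ValueError("depth shape does not match dosage shape")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def take_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            locus_ids=list(self.locus_ids),
            dosage=self.dosage[idx, :],
            depth=None if self.depth is None else self.depth[idx, :],
        )

    def take_loci(self, locus_ids: list[str]) -> "GenotypeMatrix":
        pos = {l: j for j, l in enumerate(self.locus_ids)}
        idx = [pos[l] for l in locus_ids]
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            locus_ids=[self.locus_ids[j] for j in idx],
            dosage=self.dosage[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.sample_ids, columns=self.locus_ids)


@dataclass
class SampleTable:
    """Sample metadata: locality, habitat, coordinates and derived population key.

    A population is a locality-habitat combination.  When one locality-habitat
    cell contains more than one taxon, the taxon label is appended to the key so
    that co-occurring taxa form distinct populations (this is how a 6 x 3
    design can yield 19 rather than 18 populations).
    """

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "locality", "habitat", "latitude", "longitude")

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"sample table is missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id entries")
        if not df["latitude"].between(-90, 90).all():
            raise ValueError("latitude out of [-90, 90]")
        if not df["longitude"].between(-180, 180).all():
            raise ValueError("longitude out of [-180, 180]")
        if "taxon" not in df.columns:
            df["taxon"] = ""
        df["taxon"] = df["taxon"].fillna("")

        keys = []
        multi_taxon = {
            (loc, hab)
            for (loc, hab), grp in df.groupby(["locality", "habitat"])
            if grp["taxon"].nunique() > 1
        }
        for _, row in df.iterrows():
            base = f"{row.locality}-{row.habitat}"
            if (row.locality, row.habitat) in multi_taxon and row.taxon:
                keys.append(f"{base}-{row.taxon}")
            else:
                keys.append(base)
        df["population_key"] = keys
        self.frame = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def populations(self) -> list[str]:
        return sorted(self.frame["population_key"].unique())

    def population_of(self) -> pd.Series:
        return self.frame.set_index("sample_id")["population_key"]

    def population_info(self) -> pd.DataFrame:
        """One row per population: locality, habitat and centroid coordinates."""
        g = self.frame.groupby("population_key")
        out = g.agg(
            locality=("locality", "first"),
            habitat=("habitat", "first"),
            latitude=("latitude", "mean"),
            longitude=("longitude", "mean"),
            n_samples=("sample_id", "size"),
        )
        return out.sort_index()

    def subset_samples(self, sample_ids: list[str]) -> "SampleTable":
        df = self.frame[self.frame["sample_id"].isin(set(sample_ids))]
        return SampleTable(df.drop(columns=["population_key"]))

    def subset_localities(self, localities: list[str]) -> "SampleTable":
        df = self.frame[self.frame["locality"].isin(set(localities))]
        if df.empty:
            raise ValueError(f"no samples in localities {localities}")
        return SampleTable(df.drop(columns=["population_key"]))


@dataclass(frozen=True)
class HabitatRanking:
    """Ordinal ranks for one ecological axis over the three habitat codes.

    The default axes are theoretical exposure to frost (most severe on the dry
    exposed slopes) and theoretical soil moisture content (highest in the
    wind-sheltered wet depressions); both are configurable.
    """

    axis_name: str
    rank_of: dict[str, float]

    def __post_init__(self) -> None:
        missing = [h for h in HABITATS if h not in self.rank_of]
        if missing:
            raise ValueError(f"ranking '{self.axis_name}' missing habitats: {missing}")
        if not all(np.isfinite(v) for v in self.rank_of.values()):
            raise ValueError("ranks must be finite")

    def ranks_for(self, habitats) -> np.ndarray:
        return np.array([self.rank_of[h] for h in habitats], dtype=float)


#: Defaults: frost exposure increases from cloud forest to wet depressions to
#: dry exposed slopes; soil moisture is lowest on the dry slopes.
DEFAULT_FROST_RANKING = HabitatRanking("frost", {"F": 1.0, "W": 2.0, "D": 3.0})
DEFAULT_MOISTURE_RANKING = HabitatRanking("moisture", {"D": 1.0, "F": 2.0, "W": 3.0})


@dataclass(frozen=True)
class FilterSpec:
    """GBS filtering rules.

    min_locus_depth : mean reads per locus, exclusive (default 5)
    min_maf         : overall minor allele frequency, exclusive (default 0.05)
    min_call_rate   : genotype call rate, inclusive (default 0.72)
    excluded_samples: explicit sample exclusion list, removed before any rule
    per_call_depth  : if True, additionally mask individual calls whose depth
                      is <= min_locus_depth before applying the locus rules
    """

    min_locus_depth: float = 5.0
    min_maf: float = 0.05
    min_call_rate: float = 0.72
    excluded_samples: tuple[str, ...] = ()
    per_call_depth: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.min_maf < 0.5):
            raise ValueError("min_maf must be in [0, 0.5)")
        if not (0 < self.min_call_rate <= 1):
            raise ValueError("min_call_rate must be in (0, 1]")


@dataclass
class LocusStats:
    """Per-locus summaries: per-population frequencies and overall MAF/call rate."""

    per_population: pd.DataFrame  # loci x populations, frequency of the minor-coded allele
    overall: pd.DataFrame  # columns: p_all, maf, call_rate, mean_depth


@dataclass
class KinshipMatrix:
    """Pairwise identity-by-state allele-sharing proportions."""

    sample_ids: list[str]
    K: np.ndarray
    missing_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.K, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class LDStats:
    """Squared-correlation summaries over evaluated locus pairs."""

    pairs: pd.DataFrame  # columns: locus_a, locus_b, r2
    mean: float
    se: float
    ci_low: float
    ci_high: float
    n_pairs: int


# ---------------------------------------------------------------------------
# Input
# ---------------------------------------------------------------------------


def _orient_minor(
    dosage: np.ndarray, alleles: list[tuple[str, str]] | None = None
) -> np.ndarray:
    """Recode dosage columns so they count the minor allele.

    The minor allele is determined once over all samples.  An exact 50/50 tie
    is broken toward the alphabetically smaller allele when allele labels are
    available, otherwise the coding is left as is.
    """
    dosage = dosage.copy()
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosage, axis=0) / 2.0
    for j in range(dosage.shape[1]):
        f = freq[j]
        if np.isnan(f):
            continue
        flip = f > 0.5
        if f == 0.5 and alleles is not None:
            ref, alt = alleles[j]
            # column currently counts `alt`; count the alphabetically smaller
            flip = ref < alt
        if flip:
            dosage[:, j] = 2.0 - dosage[:, j]
    return dosage


def _load_vcf(path: str | Path):
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    dosages, depths, locus_ids, alleles = [], [], [], []
    n_skipped = 0
    any_depth = False
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        gt = var.gt_types.astype(float)  # 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        gt[gt == 3] = np.nan
        dosages.append(gt)
        locus_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        alleles.append((var.REF, var.ALT[0]))
        raw_dp = var.format("DP")
        if raw_dp is not None:
            dp = raw_dp.reshape(-1).astype(float)
        else:
            dp = var.gt_depths.astype(float)
        dp[dp < 0] = np.nan
        if np.isfinite(dp).any():
            any_depth = True
        depths.append(dp)
    if n_skipped:
        logger.warning("skipped %d multi-allelic records in %s", n_skipped, path)
    if not dosages:
        return sample_ids, [], np.empty((len(sample_ids), 0)), None, []
    dosage = np.column_stack(dosages)
    depth = np.column_stack(depths) if any_depth else None
    return sample_ids, locus_ids, dosage, depth, alleles


def _load_tsv(path: str | Path, depth_path: str | Path | None):
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA"])
    first = df.columns[0]
    if first != "sample_id":
        raise ValueError(f"{path}: first TSV column must be 'sample_id', got '{first}'")
    df = df.set_index("sample_id")
    dosage = df.to_numpy(dtype=float)
    depth = None
    if depth_path is not None:
        dd = pd.read_csv(depth_path, sep="\t", dtype={0: str}).set_index("sample_id")
        if list(dd.index) != list(df.index) or list(dd.columns) != list(df.columns):
            raise ValueError("depth TSV does not align with the dosage TSV")
        depth = dd.to_numpy(dtype=float)
    return list(df.index), list(df.columns), dosage, depth, None


def load_genotypes(
    path: str | Path,
    format: str | None = None,
    depth_path: str | Path | None = None,
) -> GenotypeMatrix:
    """Read genotypes from a VCF (GT, optional DP) or a dosage TSV.

    Dosages are recoded as minor-allele counts, the minor allele being defined
    over all samples in the file (ties broken toward the alphabetically
    smaller allele for VCF input).  Multi-allelic VCF records are skipped with
    a logged count.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if ".vcf" in path.suffixes or path.suffix in (".vcf", ".gz") else "tsv"
    if format == "vcf":
        sample_ids, locus_ids, dosage, depth, alleles = _load_vcf(path)
    elif format == "tsv":
        sample_ids, locus_ids, dosage, depth, alleles = _load_tsv(path, depth_path)
    else:
        raise ValueError(f"unknown genotype format: {format!r}")
    if dosage.shape[1]:
        dosage = _orient_minor(dosage, alleles)
    return GenotypeMatrix(sample_ids, locus_ids, dosage, depth)


def load_sample_table(path: str | Path) -> SampleTable:
    """Read the metadata TSV (sample_id, locality, habitat, latitude, longitude[, taxon])."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "taxon": str})
    return SampleTable(df)


def load_habitat_ranking(path: str | Path, axis_name: str) -> HabitatRanking:
    """Read a two-column habitat -> rank TSV for one ecological axis."""
    df = pd.read_csv(path, sep="\t", header=None, names=["habitat", "rank"], comment="#")
    return HabitatRanking(axis_name, dict(zip(df["habitat"], df["rank"].astype(float))))


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def apply_filters(G: GenotypeMatrix, spec: FilterSpec) -> GenotypeMatrix:
    """Apply the GBS rule set; keeps loci passing depth, MAF and call-rate rules.

    Excluded samples are removed first.  A locus is kept iff

    * mean depth over non-missing calls > ``min_locus_depth`` (skipped with a
      warning when no depth matrix is present),
    * overall MAF > ``min_maf`` (strict), and
    * call rate >= ``min_call_rate``.

    Locus order is preserved; per-rule removal counts are logged.
    """
    if spec.excluded_samples:
        keep = [s for s in G.sample_ids if s not in set(spec.excluded_samples)]
        G = G.take_samples(keep)

    dosage = G.dosage
    depth = G.depth
    if spec.per_call_depth and depth is not None:
        low = np.nan_to_num(depth, nan=np.inf) <= spec.min_locus_depth
        if low.any():
            dosage = dosage.copy()
            dosage[low] = np.nan
            logger.info("per-call depth rule masked %d calls", int(low.sum()))

    n_loci = G.n_loci
    observed = ~np.isnan(dosage)
    n_obs = observed.sum(axis=0)
    call_rate = n_obs / max(G.n_samples, 1)

    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0, np.nansum(dosage, axis=0) / (2.0 * np.maximum(n_obs, 1)), np.nan)
    maf = np.minimum(p, 1.0 - p)

    if depth is not None:
        d = np.where(observed, depth, np.nan)
        with np.errstate(invalid="ignore"):
            mean_depth = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
        pass_depth = mean_depth > spec.min_locus_depth
        pass_depth &= ~np.isnan(mean_depth)
    else:
        logger.warning("no depth matrix: depth rule skipped")
        pass_depth = np.ones(n_loci, dtype=bool)

    pass_maf = np.nan_to_num(maf, nan=-1.0) > spec.min_maf
    pass_call = call_rate >= spec.min_call_rate

    keep = pass_depth & pass_maf & pass_call
    logger.info(
        "filters: %d loci in; failed depth %d, MAF %d, call rate %d; %d kept",
        n_loci,
        int((~pass_depth).sum()),
        int((~pass_maf).sum()),
        int((~pass_call).sum()),
        int(keep.sum()),
    )
    if not keep.any():
        logger.warning("all loci removed by filters")
    kept_ids = [l for l, k in zip(G.locus_ids, keep) if k]
    out = GenotypeMatrix(
        sample_ids=list(G.sample_ids),
        locus_ids=kept_ids,
        dosage=dosage[:, keep],
        depth=None if depth is None else depth[:, keep],
    )
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def allele_frequencies(G: GenotypeMatrix, S: SampleTable) -> LocusStats:
    """Minor-coded allele frequencies per population plus overall MAF/call rate.

    A population with zero non-missing calls at a locus gets a missing
    frequency (``NaN``), not zero.
    """
    pop_of = S.population_of()
    missing = [s for s in G.sample_ids if s not in pop_of.index]
    if missing:
        raise ValueError(f"samples absent from the sample table: {missing[:5]}")
    pops = S.populations
    per_pop = np.full((G.n_loci, len(pops)), np.nan)
    obs = ~np.isnan(G.dosage)
    sample_pop = np.array([pop_of[s] for s in G.sample_ids])
    for k, pop in enumerate(pops):
        rows = sample_pop == pop
        if not rows.any():
            continue
        n = obs[rows].sum(axis=0)
        with np.errstate(invalid="ignore"):
            per_pop[:, k] = np.where(
                n > 0, np.nansum(G.dosage[rows], axis=0) / (2.0 * np.maximum(n, 1)), np.nan
            )
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p_all = np.where(n_obs > 0, np.nansum(G.dosage, axis=0) / (2.0 * np.maximum(n_obs, 1)), np.nan)
    overall = pd.DataFrame(
        {
            "p_all": p_all,
            "maf": np.minimum(p_all, 1 - p_all),
            "call_rate": n_obs / max(G.n_samples, 1),
            "mean_depth": (
                np.nanmean(np.where(obs, G.depth, np.nan), axis=0)
                if G.depth is not None
                else np.nan
            ),
        },
        index=G.locus_ids,
    )
    return LocusStats(
        per_population=pd.DataFrame(per_pop, index=G.locus_ids, columns=pops),
        overall=overall,
    )


def ibs_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """Identity-by-state kinship: mean allele-sharing proportion over shared loci.

    ``K[i, j]`` is the mean over loci non-missing in both samples of
    ``1 - |d_i - d_j| / 2``; the diagonal is 1.  Pairs with no shared loci get
    a missing entry and are reported in ``missing_pairs``.
    """
    if G.n_loci < 1:
        raise ValueError("kinship requires at least one locus")
    D = G.dosage
    obs = ~np.isnan(D)
    Df = np.nan_to_num(D, nan=0.0)
    # sum over shared loci of |d_i - d_j| via the identity
    # |a-b| decomposition is not bilinear, so loop over samples (n is small).
    n = G.n_samples
    K = np.full((n, n), np.nan)
    missing_pairs: list[tuple[str, str]] = []
    for i in range(n):
        shared = obs[i] & obs
        diff = np.abs(Df[i] - Df)
        diff[~shared] = 0.0
        cnt = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            K[i] = np.where(cnt > 0, 1.0 - diff.sum(axis=1) / (2.0 * np.maximum(cnt, 1)), np.nan)
    for i in range(n):
        K[i, i] = 1.0
        for j in range(i + 1, n):
            if np.isnan(K[i, j]):
                missing_pairs.append((G.sample_ids[i], G.sample_ids[j]))
    if missing_pairs:
        logger.warning("%d sample pairs share no non-missing loci", len(missing_pairs))
    return KinshipMatrix(list(G.sample_ids), K, missing_pairs)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation on pairwise-complete entries; NaN if undefined."""
    m = ~np.isnan(x) & ~np.isnan(y)
    if m.sum() < 2:
        return np.nan
    xv, yv = x[m], y[m]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_prune(
    G: GenotypeMatrix, r2_threshold: float, window: int = 50
) -> tuple[list[str], LDStats]:
    """Greedy left-to-right linkage-disequilibrium pruning in a sliding window.

    A locus is dropped when its squared Pearson correlation (on
    pairwise-complete samples) with any previously kept locus within the last
    ``window`` kept loci exceeds ``r2_threshold``.  Returns the kept locus ids
    and summary statistics of the R2 values among the kept pairs evaluated.
    Monomorphic members of a pair give an undefined R2 and the pair is skipped.
    """
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must be in (0, 1]")
    kept: list[int] = []
    kept_r2: list[tuple[str, str, float]] = []
    D = G.dosage
    for j in range(G.n_loci):
        prune = False
        r2_with_kept = []
        for i in kept[-window:]:
            r2 = _pairwise_r2(D[:, i], D[:, j])
            if np.isnan(r2):
                continue
            r2_with_kept.append((G.locus_ids[i], G.locus_ids[j], r2))
            if r2 > r2_threshold:
                prune = True
                break
        if not prune:
            kept.append(j)
            kept_r2.extend(r2_with_kept)
    pairs = pd.DataFrame(kept_r2, columns=["locus_a", "locus_b", "r2"])
    vals = pairs["r2"].to_numpy()
    if vals.size:
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        lo, hi = (float(v) for v in np.percentile(vals, [2.5, 97.5]))
    else:
        mean = se = lo = hi = float("nan")
    logger.info("LD pruning kept %d of %d loci (mean kept-pair R2 %.4f)", len(kept), G.n_loci, mean)
    return [G.locus_ids[j] for j in kept], LDStats(pairs, mean, se, lo, hi, int(vals.size))
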