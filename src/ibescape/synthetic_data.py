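"""Synthetic genotype datasets with planted IBD and IBE structure, plus a
two-deme Wright-Fisher simulator for validating migration-rate estimation.

``simulate_dataset`` emulates the study design the pipeline targets: six
Andean localities holding three habitat ecotypes each (one dry-slope cell
split into two co-occurring taxa, giving 19 locality-habitat populations and
162 samples), ~1,273 biallelic GBS SNPs with missing calls and per-call read
depths.  Isolation-by-distance arises from Balding-Nichols drift applied
sequentially along a nearest-neighbour chain of localities, with the
differentiation parameter growing with geographic distance,
F_pair(d) = d / (d + d0).  Isolation-by-environment is planted in a subset of
loci whose population frequencies are shifted on the logit scale in
proportion to the habitat's frost rank.  A further small subset of loci is
private to the habitat-contrast localities, mirroring datasets in which a
marker class loses all polymorphism outside those localities.

``simulate_island_model`` is a discrete-generation Wright-Fisher model of two
demes.  By default migrants are drawn from the across-deme mean allele
frequency (Wright's migrant-pool convention), under which the equilibrium
differentiation obeys F_ST = 1 / (1 + 4 N m); direct exchange with the other
deme (``migration="exchange"``) is also available and equilibrates at
roughly F_ST = 1 / (1 + 8 N m) because the source deme itself drifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import (
    DEFAULT_FROST_RANKING,
    GenotypeMatrix,
    HabitatRanking,
    SampleTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ESPELETIA_LOCALITIES",
    "SimConfig",
    "SimTruth",
    "WfConfig",
    "simulate_dataset",
    "simulate_island_model",
    "espeletia_config",
    "espeletia_design_fixture",
    "write_vcf",
    "write_sample_table",
    "write_truth",
]

#: Approximate centroids (latitude, longitude) of the six sampled localities.
ESPELETIA_LOCALITIES = (
    ("SA", 7.30, -72.98),
    ("CO", 6.41, -72.33),
    ("GU", 6.05, -72.85),
    ("CH", 4.52, -73.75),
    ("SU", 4.03, -74.33),
    ("RU", 4.89, -75.32),
)

HABITATS = ("F", "W", "D")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the planted-structure genotype simulation.

    d0 (km) sets how fast drift accumulates with distance via
    F_pair(d) = d / (d + d0).  delta_hab is the logit-scale allele-frequency
    shift per frost-rank unit planted at habitat loci.  f_within is a small
    Balding-Nichols differentiation among populations within a locality.
    """

    localities: tuple = ESPELETIA_LOCALITIES
    n_neutral_loci: int = 1185
    n_habitat_loci: int = 60
    n_private_loci: int = 28
    private_localities: tuple[str, ...] = ("CO", "GU")
    samples_per_population: int | None = None  # None: espeletia allocation (162 total)
    ancestral_low: float = 0.1
    ancestral_high: float = 0.9
    d0: float = 300.0
    delta_hab: float = 1.2
    f_within: float = 0.02
    missing_rate: float = 0.15
    depth_mean: float = 12.0
    depth_dispersion: float = 3.0
    site_spread_km: float = 3.0  # populations occupy distinct sites within a locality
    frost_ranking: HabitatRanking = DEFAULT_FROST_RANKING
    split_population: tuple[str, str] = ("GU", "D")  # cell split into two taxa
    split_taxa: tuple[str, str] = ("argentea", "boyacensis")
    seed: int = 0

    @property
    def n_loci(self) -> int:
        return self.n_neutral_loci + self.n_habitat_loci + self.n_private_loci

    def __post_init__(self) -> None:
        if min(self.n_neutral_loci, 1) < 1 or self.n_habitat_loci < 0 or self.n_private_loci < 0:
            raise ValueError("locus counts must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")


@dataclass
class SimTruth:
    """Ground truth emitted with each simulated dataset."""

    habitat_locus_ids: list[str]
    private_locus_ids: list[str]
    expected_freqs: pd.DataFrame  # loci x populations, the p each genotype was drawn from
    n_clamped: int
    config: SimConfig


@dataclass(frozen=True)
class WfConfig:
    """Two-deme Wright-Fisher configuration (diploid deme size N)."""

    N: int = 200
    m: float = 0.005
    n_loci: int = 500
    generations: int | None = None  # default 4N
    initial_freq: float = 0.5
    samples_per_deme: int = 20
    migration: str = "pool"  # "pool" (island-model convention) | "exchange"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.m <= 0.5):
            raise ValueError("m must be in [0, 0.5]")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.migration not in ("pool", "exchange"):
            raise ValueError("migration must be 'pool' or 'exchange'")
        if self.samples_per_deme > self.N:
            raise ValueError("cannot sample more individuals than the deme holds")


# ---------------------------------------------------------------------------
# Planted-structure dataset
# ---------------------------------------------------------------------------


def _haversine_km(lat1, lon1, lat2, lon2) -> float:
    r = 6371.0087714
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    return float(2 * r * np.arcsin(np.sqrt(h)))


def _nearest_neighbor_chain(localities) -> list[int]:
    """Greedy nearest-neighbour ordering starting from the northernmost locality."""
    n = len(localities)
    start = max(range(n), key=lambda i: localities[i][1])
    order = [start]
    remaining = set(range(n)) - {start}
    while remaining:
        last = localities[order[-1]]
        nxt = min(
            remaining,
            key=lambda i: _haversine_km(last[1], last[2], localities[i][1], localities[i][2]),
        )
        order.append(nxt)
        remaining.remove(nxt)
    return order


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Population frequencies around p with differentiation F (beta-distributed)."""
    if F < 1e-9:
        return p.copy()
    scale = (1.0 - F) / F
    a = np.clip(p * scale, 1e-6, None)
    b = np.clip((1.0 - p) * scale, 1e-6, None)
    return rng.beta(a, b)


def _population_layout(config: SimConfig) -> pd.DataFrame:
    rows = []
    for name, lat, lon in config.localities:
        for hab in HABITATS:
            if (name, hab) == config.split_population:
                for taxon in config.split_taxa:
                    rows.append((f"{name}-{hab}-{taxon}", name, hab, lat, lon, taxon))
            else:
                rows.append((f"{name}-{hab}", name, hab, lat, lon, ""))
    df = pd.DataFrame(
        rows, columns=["population_key", "locality", "habitat", "latitude", "longitude", "taxon"]
    )
    return df.sort_values("population_key").reset_index(drop=True)


def _samples_per_population(config: SimConfig, n_pops: int) -> list[int]:
    if config.samples_per_population is not None:
        return [int(config.samples_per_population)] * n_pops
    # espeletia allocation: 162 samples over 19 populations (10 x 9 + 9 x 8)
    base, extra = divmod(162, n_pops)
    return [base + 1 if i < extra else base for i in range(n_pops)]


def simulate_dataset(config: SimConfig) -> tuple[GenotypeMatrix, SampleTable, SimTruth]:
    """Draw a genotype matrix, metadata table and ground truth from the model.

    Fully reproducible from ``config.seed``.  Frequencies pushed outside (0, 1)
    by the habitat shift are clamped to [0.001, 0.999] and counted in the
    returned :class:`SimTruth`.
    """
    rng = np.random.default_rng(config.seed)
    layout = _population_layout(config)
    n_pops = len(layout)
    if config.site_spread_km > 0:
        # distinct sampling sites a few km apart within each locality; the
        # direction is random per population so habitat and geography stay
        # unconfounded across localities
        deg = config.site_spread_km / 111.0
        layout["latitude"] += rng.normal(0.0, deg, size=n_pops)
        layout["longitude"] += rng.normal(0.0, deg, size=n_pops)
    loc_names = [l[0] for l in config.localities]
    chain = _nearest_neighbor_chain(config.localities)

    n_loci = config.n_loci
    locus_ids = [f"snp{j + 1:05d}" for j in range(n_loci)]
    # deterministic locus classes: habitat loci spread through the panel,
    # private loci at the tail
    habitat_idx = np.array([], dtype=int)
    if config.n_habitat_loci:
        habitat_idx = np.linspace(
            0, config.n_neutral_loci + config.n_habitat_loci - 1, config.n_habitat_loci
        ).astype(int)
    private_idx = np.arange(n_loci - config.n_private_loci, n_loci)

    p0 = rng.uniform(config.ancestral_low, config.ancestral_high, size=n_loci)

    # locality frequencies along the geographic chain
    p_loc = np.empty((len(loc_names), n_loci))
    p_loc[chain[0]] = p0
    for prev, cur in zip(chain, chain[1:]):
        a, b = config.localities[prev], config.localities[cur]
        d = _haversine_km(a[1], a[2], b[1], b[2])
        F = d / (d + config.d0)
        p_loc[cur] = _balding_nichols(rng, p_loc[prev], F)

    loc_index = {name: i for i, name in enumerate(loc_names)}
    frost = config.frost_ranking
    mean_rank = np.mean([frost.rank_of[h] for h in HABITATS])

    p_pop = np.empty((n_pops, n_loci))
    for k, row in layout.iterrows():
        p = _balding_nichols(rng, p_loc[loc_index[row.locality]], config.f_within)
        p_pop[k] = p
    # habitat loci: logit shift proportional to the centered frost rank
    n_clamped = 0
    if len(habitat_idx):
        for k, row in layout.iterrows():
            shift = config.delta_hab * (frost.rank_of[row.habitat] - mean_rank)
            p = np.clip(p_pop[k, habitat_idx], 1e-6, 1 - 1e-6)
            logit = np.log(p / (1 - p)) + shift
            shifted = 1.0 / (1.0 + np.exp(-logit))
            clamped = np.clip(shifted, 0.001, 0.999)
            n_clamped += int(np.count_nonzero(clamped != shifted))
            p_pop[k, habitat_idx] = clamped
    # private loci: monomorphic (absent allele) outside the private localities
    if len(private_idx):
        outside = ~layout["locality"].isin(config.private_localities).to_numpy()
        p_pop[np.ix_(outside, private_idx)] = 0.0

    sizes = _samples_per_population(config, n_pops)
    sample_rows, dosage_rows = [], []
    counter = 1
    for k, row in layout.iterrows():
        for _ in range(sizes[k]):
            sample_rows.append(
                (f"s{counter:03d}", row.locality, row.habitat, row.latitude, row.longitude, row.taxon)
            )
            dosage_rows.append(rng.binomial(2, p_pop[k]))
            counter += 1
    dosage = np.array(dosage_rows, dtype=float)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan
    nb_n = config.depth_dispersion
    nb_p = nb_n / (nb_n + config.depth_mean)
    depth = rng.negative_binomial(nb_n, nb_p, size=dosage.shape).astype(float)

    samples = SampleTable(
        pd.DataFrame(
            sample_rows,
            columns=["sample_id", "locality", "habitat", "latitude", "longitude", "taxon"],
        )
    )
    G = GenotypeMatrix([r[0] for r in sample_rows], locus_ids, dosage, depth)
    truth = SimTruth(
        habitat_locus_ids=[locus_ids[j] for j in habitat_idx],
        private_locus_ids=[locus_ids[j] for j in private_idx],
        expected_freqs=pd.DataFrame(
            p_pop.T, index=locus_ids, columns=layout["population_key"]
        ),
        n_clamped=n_clamped,
        config=config,
    )
    logger.info(
        "simulated %d samples x %d loci (%d habitat, %d private; %d clamped frequencies)",
        G.n_samples, G.n_loci, len(habitat_idx), len(private_idx), n_clamped,
    )
    return G, samples, truth


def espeletia_config(seed: int = 0, **overrides) -> SimConfig:
    """The default study-design preset (19 populations, 162 samples, 1,273 loci)."""
    return replace(SimConfig(seed=seed), **overrides)


def espeletia_design_fixture(seed: int = 0):
    """Simulated dataset plus prescribed marker-association sets replicating
    the study's partition design.

    The marker sets are defined from the generator's ground truth rather than
    from a scan, so the partition arithmetic is deterministic: 172 loci stand
    in for the locality-associated set, the planted habitat loci for the
    frost-associated set, and the loci private to the habitat-contrast
    localities for the moisture-associated set.  Because the private loci are
    monomorphic outside those localities, the locality-contrast x
    moisture-associated combination loses all polymorphism and is excluded,
    yielding eleven dataset partitions (and 33 Mantel tests).

    Returns (genotypes, samples, truth, assoc) where ``assoc`` maps factor ->
    locus ids and is accepted by :func:`ibescape.gea.partition_datasets`.
    """
    config = espeletia_config(seed=seed)
    G, S, truth = simulate_dataset(config)
    neutral = [
        l for l in G.locus_ids
        if l not in set(truth.habitat_locus_ids) and l not in set(truth.private_locus_ids)
    ]
    assoc = {
        "locality": neutral[:172],
        "frost": list(truth.habitat_locus_ids),
        "moisture": list(truth.private_locus_ids),
    }
    return G, S, truth, assoc


# ---------------------------------------------------------------------------
# Two-deme Wright-Fisher island model
# ---------------------------------------------------------------------------


def simulate_island_model(
    config: WfConfig, return_frequencies: bool = False
):
    """Forward Wright-Fisher simulation of two demes with symmetric migration.

    Each generation, a fraction ``m`` of each deme's allele copies is replaced
    by migrants (from the across-deme mean pool by default, or from the other
    deme under ``migration="exchange"``), then 2N copies are binomially
    resampled.  After the configured number of generations (default 4N),
    ``samples_per_deme`` diploid genotypes are drawn per deme without
    replacement.  Loci are independent.  Loci fixed in both demes trigger a
    warning (their F_ST components are undefined downstream).
    """
    rng = np.random.default_rng(config.seed)
    gens = config.generations if config.generations is not None else 4 * config.N
    two_n = 2 * config.N
    p = np.full((2, config.n_loci), config.initial_freq)
    for _ in range(gens):
        if config.migration == "pool":
            pool = p.mean(axis=0)
            pm = (1 - config.m) * p + config.m * pool
        else:
            pm = np.empty_like(p)
            pm[0] = (1 - config.m) * p[0] + config.m * p[1]
            pm[1] = (1 - config.m) * p[1] + config.m * p[0]
        p = rng.binomial(two_n, pm) / two_n

    fixed = ((p == 0).all(axis=0)) | ((p == 1).all(axis=0))
    if fixed.all():
        logger.warning("all loci fixed across both demes; F_ST undefined everywhere")
    elif fixed.any():
        logger.info("%d loci fixed in both demes", int(fixed.sum()))

    # sample diploids without replacement: draw allele counts per deme from the
    # hypergeometric law of the 2N copies
    dosages = []
    for deme in range(2):
        good = (p[deme] * two_n).round().astype(int)
        geno = np.zeros((config.samples_per_deme, config.n_loci), dtype=float)
        remaining_good = good.copy()
        remaining_total = np.full(config.n_loci, two_n)
        for i in range(config.samples_per_deme):
            g = rng.hypergeometric(remaining_good, remaining_total - remaining_good, 2)
            geno[i] = g
            remaining_good -= g
            remaining_total -= 2
        dosages.append(geno)
    dosage = np.vstack(dosages)

    sample_rows = []
    for deme, (lat, lon) in enumerate(((0.0, 0.0), (0.0, 1.0))):
        for i in range(config.samples_per_deme):
            sample_rows.append(
                (f"d{deme + 1}_{i + 1:03d}", f"deme{deme + 1}", "W", lat, lon, "")
            )
    samples = SampleTable(
        pd.DataFrame(
            sample_rows,
            columns=["sample_id", "locality", "habitat", "latitude", "longitude", "taxon"],
        )
    )
    G = GenotypeMatrix(
        [r[0] for r in sample_rows],
        [f"wf{j + 1:05d}" for j in range(config.n_loci)],
        dosage,
    )
    if return_frequencies:
        return G, samples, p
    return G, samples


# ---------------------------------------------------------------------------
# Writers (plain-text VCF / TSV)
# ---------------------------------------------------------------------------


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Serialize the genotype matrix as a minimal VCF 4.2 file (GT:DP)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids) + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, locus in enumerate(G.locus_ids):
            fields = ["1", str(j + 1), locus, "A", "T", ".", "PASS", ".", "GT:DP"]
            for i in range(G.n_samples):
                d = G.dosage[i, j]
                gt = "./." if np.isnan(d) else gt_map[d]
                dp = "." if G.depth is None or not np.isfinite(G.depth[i, j]) else str(int(G.depth[i, j]))
                fields.append(f"{gt}:{dp}")
            fh.write("\t".join(fields) + "\n")


def write_sample_table(S: SampleTable, path: str | Path) -> None:
    cols = ["sample_id", "locality", "habitat", "latitude", "longitude", "taxon"]
    S.frame[cols].to_csv(path, sep="\t", index=False)


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Write the planted-locus table (locus_id, class) as TSV."""
    rows = [(l, "habitat") for l in truth.habitat_locus_ids]
    rows += [(l, "private") for l in truth.private_locus_ids]
    pd.DataFrame(rows, columns=["locus_id", "locus_class"]).to_csv(path, sep="\t", index=False)
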