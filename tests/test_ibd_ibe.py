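"""Distance matrices, permutation Mantel tests and the IBD/IBE report table."""

import itertools

import numpy as np
import pandas as pd
import pytest

import ibescape as ib
from ibescape import gea, ibd_ibe
from ibescape.genotypes import (
    DEFAULT_FROST_RANKING,
    DEFAULT_MOISTURE_RANKING,
    FilterSpec,
    HabitatRanking,
)

from conftest import make_samples


class TestGeographicDistances:
    def test_identical_coordinates_zero(self):
        S = make_samples([("s1", "A", "F", 4.5, -73.0), ("s2", "B", "F", 4.5, -73.0)])
        D = ibd_ibe.geographic_distances(S)
        assert D.loc["A-F", "B-F"] == pytest.approx(0.0)

    def test_one_degree_latitude_arc(self):
        S = make_samples([("s1", "A", "F", 0.0, 0.0), ("s2", "B", "F", 1.0, 0.0)])
        D = ibd_ibe.geographic_distances(S)
        expected = np.pi * ibd_ibe.EARTH_RADIUS_KM / 180.0
        assert D.loc["A-F", "B-F"] == pytest.approx(expected, abs=1e-3)
        assert D.loc["A-F", "B-F"] == pytest.approx(111.195, abs=1e-3)

    def test_quarter_great_circle(self):
        S = make_samples([("s1", "A", "F", 0.0, 0.0), ("s2", "B", "F", 0.0, 90.0)])
        D = ibd_ibe.geographic_distances(S)
        assert D.loc["A-F", "B-F"] == pytest.approx(np.pi * ibd_ibe.EARTH_RADIUS_KM / 2, abs=1e-2)

    def test_agrees_with_sklearn_haversine(self):
        sklearn_pairwise = pytest.importorskip("sklearn.metrics.pairwise")
        rng = np.random.default_rng(0)
        rows = [
            (f"s{i}", f"L{i}", "F", rng.uniform(-60, 60), rng.uniform(-150, 150))
            for i in range(6)
        ]
        S = make_samples(rows)
        D = ibd_ibe.geographic_distances(S)
        info = S.population_info()
        rad = np.radians(info[["latitude", "longitude"]].to_numpy())
        expected = sklearn_pairwise.haversine_distances(rad) * ibd_ibe.EARTH_RADIUS_KM
        np.testing.assert_allclose(D.to_numpy(), expected, atol=1e-6)

    def test_population_centroid_of_member_samples(self):
        S = make_samples(
            [("s1", "A", "F", 0.0, 0.0), ("s2", "A", "F", 2.0, 0.0),
             ("s3", "B", "F", 1.0, 1.0)]
        )
        info = S.population_info()
        assert info.loc["A-F", "latitude"] == pytest.approx(1.0)

    def test_missing_coordinates_rejected(self):
        S = make_samples([("s1", "A", "F", 0.0, 0.0), ("s2", "B", "F", 0.0, 1.0)])
        S.frame.loc[1, "latitude"] = np.nan
        with pytest.raises(ValueError, match="s2"):
            ibd_ibe.geographic_distances(S)


class TestEcologicalDistances:
    def test_default_frost_rank_matrix(self):
        S = make_samples([("s1", "A", "F"), ("s2", "A", "W"), ("s3", "A", "D")])
        D = ibd_ibe.ecological_distances(S, DEFAULT_FROST_RANKING)
        assert D.loc["A-F", "A-W"] == 1.0
        assert D.loc["A-W", "A-D"] == 1.0
        assert D.loc["A-F", "A-D"] == 2.0
        assert D.loc["A-F", "A-F"] == 0.0

    def test_unknown_habitat_rejected(self):
        S = make_samples([("s1", "A", "F"), ("s2", "A", "X")])
        with pytest.raises(ValueError, match="X"):
            ibd_ibe.ecological_distances(S, DEFAULT_FROST_RANKING)


def random_distance_matrix(rng, n):
    pts = rng.normal(size=(n, 2))
    D = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    return D


class TestMantel:
    def test_self_comparison_r_one_minimal_p(self):
        rng = np.random.default_rng(2)
        A = random_distance_matrix(rng, 8)
        res = ibd_ibe.mantel(A, A.copy(), n_perm=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 1000)

    def test_anticorrelation(self):
        rng = np.random.default_rng(3)
        A = random_distance_matrix(rng, 6)
        B = A.max() + 1.0 - A
        np.fill_diagonal(B, 0.0)
        res = ibd_ibe.mantel(A, B, n_perm=99, seed=0)
        assert res.r == pytest.approx(-1.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        A = random_distance_matrix(rng, 7)
        B = random_distance_matrix(rng, 7)
        r_ab = ibd_ibe.mantel(A, B, n_perm=49, seed=1).r
        r_ba = ibd_ibe.mantel(B, A, n_perm=49, seed=1).r
        assert r_ab == pytest.approx(r_ba, abs=1e-12)

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(5)
        A = random_distance_matrix(rng, 8)
        B = random_distance_matrix(rng, 8)
        r1 = ibd_ibe.mantel(A, B, n_perm=200, seed=42)
        r2 = ibd_ibe.mantel(A, B, n_perm=200, seed=42)
        assert (r1.r, r1.p) == (r2.r, r2.p)

    def test_exhaustive_enumeration_oracle_four_populations(self):
        rng = np.random.default_rng(6)
        A = random_distance_matrix(rng, 4)
        B = random_distance_matrix(rng, 4)
        iu = np.triu_indices(4, k=1)
        x = A[iu]

        def corr(perm):
            Bp = B[np.ix_(perm, perm)]
            return np.corrcoef(x, Bp[iu])[0, 1]

        r_obs = corr((0, 1, 2, 3))
        exceed = sum(
            corr(p) >= r_obs - 1e-12 for p in itertools.permutations(range(4))
        )
        exact_p = exceed / 24  # includes the identity permutation
        res = ibd_ibe.mantel(A, B, n_perm=10000, seed=0)
        assert res.r == pytest.approx(r_obs)
        # sampled add-one p within binomial error of the exact enumeration
        se = np.sqrt(exact_p * (1 - exact_p) / 10000)
        assert res.p == pytest.approx(exact_p, abs=4 * se + 2e-4)

    def test_agrees_with_skbio_r(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(8)
        A = random_distance_matrix(rng, 9)
        B = random_distance_matrix(rng, 9)
        r_ours = ibd_ibe.mantel(A, B, n_perm=9, seed=0).r
        r_skbio, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(A), skbio_distance.DistanceMatrix(B),
            method="pearson", permutations=0,
        )
        assert r_ours == pytest.approx(float(r_skbio), abs=1e-10)

    def test_degenerate_matrix_rejected(self):
        A = np.zeros((5, 5))
        B = random_distance_matrix(np.random.default_rng(0), 5)
        with pytest.raises(ValueError, match="zero off-diagonal variance"):
            ibd_ibe.mantel(A, B, n_perm=9, seed=0)

    def test_fewer_than_four_populations_rejected(self):
        A = random_distance_matrix(np.random.default_rng(0), 3)
        with pytest.raises(ValueError, match="at least 4"):
            ibd_ibe.mantel(A, A, n_perm=9, seed=0)


class TestIbdIbeTable:
    def test_pair_counts_and_thresholds_for_study_design(self, small_sim):
        G, S, _ = small_sim
        Gf = ib.apply_filters(G, FilterSpec())
        Sf = S.subset_samples(Gf.sample_ids)
        rules = {"locality-contrast": ["CH", "SA", "SU", "RU"],
                 "habitat-contrast": ["CO", "GU"]}
        parts = gea.partition_datasets(Gf, Sf, {}, rules)
        tab, details = ibd_ibe.ibd_ibe_table(
            parts, Sf, DEFAULT_FROST_RANKING, DEFAULT_MOISTURE_RANKING,
            n_perm=99, seed=0,
        )
        byname = tab.set_index("population_dataset")
        assert byname.loc["entire", "n_pw"] == 171
        assert byname.loc["locality-contrast", "n_pw"] == 66
        assert byname.loc["habitat-contrast", "n_pw"] == 21
        assert byname.loc["entire", "bonferroni_threshold"] == pytest.approx(0.05 / 171)
        # printed to four decimals these are 0.0003 / 0.0008 / 0.0024
        assert round(byname.loc["entire", "bonferroni_threshold"], 4) == 0.0003
        assert round(byname.loc["locality-contrast", "bonferroni_threshold"], 4) == 0.0008
        assert round(byname.loc["habitat-contrast", "bonferroni_threshold"], 4) == 0.0024
        assert len(details) == 3 * len(parts)

    def test_four_population_partition_arithmetic(self, small_sim):
        G, S, _ = small_sim
        Gf = ib.apply_filters(G, FilterSpec())
        Sf = S.subset_samples(Gf.sample_ids)
        rules = {"locality-contrast": ["CH", "RU"]}  # 2 localities x 3 habitats... 6 pops
        parts = [p for p in gea.partition_datasets(Gf, Sf, {}, rules)
                 if p.population_subset == "locality-contrast"]
        Ssub = parts[0].samples
        # reduce to exactly 4 populations
        keep_pops = Ssub.populations[:4]
        keep_samples = [
            s for s in parts[0].genotypes.sample_ids
            if Ssub.population_of()[s] in keep_pops
        ]
        part = gea.DatasetPartition(
            name="toy", population_subset="toy", marker_subset="all",
            genotypes=parts[0].genotypes.take_samples(keep_samples),
            samples=Ssub.subset_samples(keep_samples),
            n_polymorphic=parts[0].n_polymorphic,
        )
        tab, _ = ibd_ibe.ibd_ibe_table(
            [part], Sf, DEFAULT_FROST_RANKING, DEFAULT_MOISTURE_RANKING,
            n_perm=99, seed=0,
        )
        assert tab.loc[0, "n_pw"] == 6
        assert tab.loc[0, "bonferroni_threshold"] == pytest.approx(0.05 / 6)

    def test_undersized_partition_omitted_with_diagnostic(self, small_sim, caplog):
        G, S, _ = small_sim
        Gf = ib.apply_filters(G, FilterSpec())
        Sf = S.subset_samples(Gf.sample_ids)
        part = gea.DatasetPartition(
            name="tiny", population_subset="tiny", marker_subset="all",
            genotypes=Gf, samples=Sf.subset_localities(["CH"]), n_polymorphic=10,
        )
        with caplog.at_level("WARNING", logger="ibescape.ibd_ibe"):
            tab, details = ibd_ibe.ibd_ibe_table(
                [part], Sf, DEFAULT_FROST_RANKING, DEFAULT_MOISTURE_RANKING,
                n_perm=9, seed=0,
            )
        assert tab.empty and not details
        assert any("omitted" in r.message for r in caplog.records)
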