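"""Association scans (GLM and mixed models), thresholds and dataset partitioning."""

import numpy as np
import pandas as pd
import pytest

import ibescape as ib
from ibescape import gea
from ibescape.genotypes import DEFAULT_FROST_RANKING, FilterSpec, ibs_kinship

from conftest import make_genotypes, make_samples


def twelve_sample_design():
    """Two localities x two habitats, three samples each."""
    rows = []
    for i in range(12):
        loc = "AB"[i // 6]
        hab = ["F", "W"][(i // 3) % 2]
        rows.append((f"s{i+1}", loc, hab))
    return make_samples(rows)


class TestPhyloCovariate:
    def test_two_equidistant_populations_symmetric(self):
        S = make_samples(
            [("s1", "A", "F"), ("s2", "A", "F"), ("s3", "B", "F"), ("s4", "B", "F")]
        )
        D = pd.DataFrame([[0.0, 2.0], [2.0, 0.0]], index=["A-F", "B-F"], columns=["A-F", "B-F"])
        cov = gea.phylo_covariate(D, S)
        assert cov.mean() == pytest.approx(0.0, abs=1e-12)
        assert abs(cov["s1"]) == pytest.approx(abs(cov["s3"]))
        assert cov["s1"] == -cov["s3"]

    def test_three_populations_on_a_line_collinear(self):
        pops = ["A-F", "B-F", "C-F"]
        D = pd.DataFrame(
            [[0, 1, 3], [1, 0, 2], [3, 2, 0]], index=pops, columns=pops, dtype=float
        )
        S = make_samples([("s1", "A", "F"), ("s2", "B", "F"), ("s3", "C", "F")])
        cov = gea.phylo_covariate(D, S)
        # scores reproduce the 1-D positions 0, 1, 3 up to sign and shift
        gaps = np.diff(np.sort(cov.to_numpy()))
        np.testing.assert_allclose(np.sort(gaps), [1.0, 2.0], atol=1e-8)

    def test_star_tree_degenerate_axis_flagged(self, caplog):
        newick = "(A-F:1,B-F:1,C-F:1,D-F:1);"
        S = make_samples(
            [("s1", "A", "F"), ("s2", "B", "F"), ("s3", "C", "F"), ("s4", "D", "F")]
        )
        with caplog.at_level("WARNING", logger="ibescape.gea"):
            gea.phylo_covariate(newick, S)
        assert any("degenerate" in r.message for r in caplog.records)

    def test_missing_population_raises(self):
        D = pd.DataFrame([[0.0]], index=["A-F"], columns=["A-F"])
        S = make_samples([("s1", "A", "F"), ("s2", "B", "W")])
        with pytest.raises(ValueError, match="missing"):
            gea.phylo_covariate(D, S)


class TestGlmScan:
    def test_constant_dosage_gives_f_zero_p_one(self):
        S = twelve_sample_design()
        G = make_genotypes([[1.0]] * 12)
        tab, _ = gea.glm_scan(G, S, gea.DesignSpec("locality"))
        assert tab.loc[0, "F"] == 0.0 and tab.loc[0, "p"] == 1.0

    def test_perfect_fit_floors_p(self):
        S = twelve_sample_design()
        ranks = DEFAULT_FROST_RANKING.ranks_for(S.frame["habitat"])
        G = make_genotypes([[r - 1.0] for r in ranks])  # dosage equals rank signal
        tab, _ = gea.glm_scan(G, S, gea.DesignSpec("frost"), DEFAULT_FROST_RANKING)
        assert tab.loc[0, "p"] == gea.P_FLOOR

    def test_matches_statsmodels_partial_f(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        S = twelve_sample_design()
        cov = pd.Series(rng.normal(size=12), index=S.sample_ids)
        dosage = rng.integers(0, 3, size=(12, 5)).astype(float)
        dosage[2, 1] = np.nan
        G = make_genotypes(dosage.tolist())
        tab, _ = gea.glm_scan(G, S, gea.DesignSpec("locality", cov))

        meta = S.frame.set_index("sample_id")
        for j in range(5):
            y = dosage[:, j]
            m = ~np.isnan(y)
            X = pd.DataFrame(
                {
                    "const": 1.0,
                    "cov": cov.to_numpy(),
                    "locB": (meta["locality"] == "B").astype(float).to_numpy(),
                }
            )[m]
            fit = sm.OLS(y[m], X).fit()
            ft = fit.f_test("locB = 0")
            assert tab.loc[j, "F"] == pytest.approx(float(ft.fvalue), rel=1e-8)
            assert tab.loc[j, "p"] == pytest.approx(float(ft.pvalue), rel=1e-8)

    def test_collinear_factor_flagged(self):
        S = twelve_sample_design()
        # covariate identical to the locality indicator -> singular design
        cov = pd.Series(
            (S.frame["locality"] == "B").astype(float).to_numpy(), index=S.sample_ids
        )
        G = make_genotypes([[float(v % 3)] for v in range(12)])
        tab, _ = gea.glm_scan(G, S, gea.DesignSpec("locality", cov))
        assert np.isnan(tab.loc[0, "p"])


def gls_partial_f(y, X_full, X_null, K, delta):
    """Generalized-least-squares oracle at fixed variance-component ratio."""
    V = K + delta * np.eye(len(y))
    Vi = np.linalg.inv(V)

    def rss(X):
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        r = y - X @ beta
        return float(r @ Vi @ r)

    q = X_full.shape[1] - X_null.shape[1]
    df2 = len(y) - X_full.shape[1]
    F = ((rss(X_null) - rss(X_full)) / q) / (rss(X_full) / df2)
    return F, q, df2


class TestMlmScan:
    def test_identity_kinship_reproduces_glm(self):
        rng = np.random.default_rng(1)
        S = twelve_sample_design()
        dosage = rng.integers(0, 3, size=(12, 8)).astype(float)
        dosage[rng.random(dosage.shape) < 0.1] = np.nan
        G = make_genotypes(dosage.tolist())
        K = ib.KinshipMatrix(G.sample_ids, np.eye(12))
        design = gea.DesignSpec("locality")
        glm_tab, _ = gea.glm_scan(G, S, design)
        for mode in ("p3d", "emma_full"):
            mlm_tab, _, _ = gea.mlm_scan(G, S, design, K, mode=mode)
            np.testing.assert_allclose(
                mlm_tab["p"].to_numpy(), glm_tab["p"].to_numpy(), rtol=1e-6
            )

    def test_emma_f_matches_gls_oracle_at_same_delta(self):
        rng = np.random.default_rng(2)
        n = 8
        S = make_samples(
            [(f"s{i+1}", "AB"[i // 4], ["F", "W"][i % 2]) for i in range(n)]
        )
        # block-diagonal kinship: two related quartets
        K = np.kron(np.eye(2), np.full((4, 4), 0.5)) + 0.5 * np.eye(n)
        dosage = rng.integers(0, 3, size=(n, 4)).astype(float)
        G = make_genotypes(dosage.tolist())
        design = gea.DesignSpec("locality")
        tab, _, _ = gea.mlm_scan(G, S, design, ib.KinshipMatrix(G.sample_ids, K), mode="emma_full")
        X_full, X_null, q = gea._design_matrices(G, S, design, None)
        for j in range(4):
            if not np.isfinite(tab.loc[j, "F"]) or tab.loc[j, "F"] == 0.0:
                continue
            F, _, _ = gls_partial_f(dosage[:, j], X_full, X_null, K, tab.loc[j, "delta"])
            assert tab.loc[j, "F"] == pytest.approx(F, rel=1e-5)

    def test_p3d_and_emma_full_agree_on_structured_data(self):
        # complete genotypes isolate the shared-delta approximation itself;
        # with missing calls the two modes legitimately fit different
        # per-locus sample subsets during REML
        cfg = ib.espeletia_config(
            seed=11, n_neutral_loci=110, n_habitat_loci=10, n_private_loci=0,
            missing_rate=0.0,
        )
        G, S, _ = ib.simulate_dataset(cfg)
        Gf = ib.apply_filters(G, FilterSpec())
        Sf = S.subset_samples(Gf.sample_ids)
        K = ibs_kinship(Gf)
        design = gea.DesignSpec("frost")
        t1, _, _ = gea.mlm_scan(Gf, Sf, design, K, mode="p3d", ranking=DEFAULT_FROST_RANKING)
        t2, _, _ = gea.mlm_scan(Gf, Sf, design, K, mode="emma_full", ranking=DEFAULT_FROST_RANKING)
        ok = np.isfinite(t1["p"]) & np.isfinite(t2["p"])
        rho = pd.Series(t1.loc[ok, "p"].to_numpy()).corr(
            pd.Series(t2.loc[ok, "p"].to_numpy()), method="spearman"
        )
        assert rho >= 0.99

    def test_non_psd_kinship_rejected(self):
        S = twelve_sample_design()
        G = make_genotypes([[float(v % 3)] for v in range(12)])
        bad = np.eye(12)
        bad[0, 1] = bad[1, 0] = 2.0  # eigenvalue -1
        with pytest.raises(ValueError, match="positive semi-definite"):
            gea.mlm_scan(G, S, gea.DesignSpec("locality"), ib.KinshipMatrix(G.sample_ids, bad))


class TestThresholds:
    @pytest.mark.parametrize(
        "n,expected_2sf",
        [(1273, 3.9e-5), (812, 6.2e-5), (897, 5.6e-5), (1, 5.0e-2)],
    )
    def test_bonferroni_matches_printed_values(self, n, expected_2sf):
        thr = gea.bonferroni_threshold(n, 0.05)
        assert float(f"{thr.threshold:.1e}") == pytest.approx(expected_2sf)
        assert thr.threshold * n == pytest.approx(0.05, rel=1e-14)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            gea.bonferroni_threshold(0, 0.05)
        with pytest.raises(ValueError):
            gea.bonferroni_threshold(10, 1.5)

    def test_select_associated_straddling_threshold(self):
        ps = [1e-6, 2e-5, 3.9e-5, 4.0e-5, 1e-3, 0.02, 0.5, 0.9, 1.0, 5e-7]
        tab = pd.DataFrame({"locus_id": [f"L{i}" for i in range(10)], "p": ps})
        sel = gea.select_associated(tab, 3.9e-5)
        assert sel == ["L0", "L1", "L2", "L9"]
        assert gea.select_associated(tab, 1.0) == list(tab["locus_id"])
        assert gea.select_associated(tab.assign(p=1.0), 0.5) == []


class TestPartitionDatasets:
    RULES = {"locality-contrast": ["CH", "SA", "SU", "RU"], "habitat-contrast": ["CO", "GU"]}

    def test_design_fixture_yields_eleven_partitions(self):
        G, S, truth, assoc = ib.espeletia_design_fixture(seed=2)
        Gf = ib.apply_filters(G, FilterSpec())
        Sf = S.subset_samples(Gf.sample_ids)
        parts = gea.partition_datasets(Gf, Sf, assoc, self.RULES)
        assert len(parts) == 11
        names = {(p.population_subset, p.marker_subset) for p in parts}
        # the locality-contrast x moisture combination loses polymorphism
        assert ("locality-contrast", "moisture-associated") not in names
        assert ("habitat-contrast", "moisture-associated") in names

    def test_no_association_sets_give_all_markers_only(self, small_sim):
        G, S, _ = small_sim
        Gf = ib.apply_filters(G, FilterSpec())
        Sf = S.subset_samples(Gf.sample_ids)
        parts = gea.partition_datasets(Gf, Sf, {}, self.RULES)
        assert len(parts) == 3
        assert {p.marker_subset for p in parts} == {"all"}

    def test_all_polymorphic_combinations_emitted(self, small_sim):
        G, S, _ = small_sim
        Gf = ib.apply_filters(G, FilterSpec())
        Sf = S.subset_samples(Gf.sample_ids)
        # choose marker sets from loci that stay polymorphic in every
        # population subset, so no combination loses polymorphism
        survive = set(Gf.locus_ids)
        refilter = FilterSpec(min_locus_depth=0.0)
        for localities in self.RULES.values():
            Ssub = Sf.subset_localities(localities)
            Gsub = Gf.take_samples([s for s in Gf.sample_ids if s in set(Ssub.sample_ids)])
            Gsub = ib.GenotypeMatrix(Gsub.sample_ids, Gsub.locus_ids, Gsub.dosage,
                                     np.full_like(Gsub.dosage, np.inf))
            survive &= set(ib.apply_filters(Gsub, refilter).locus_ids)
        everywhere = [l for l in Gf.locus_ids if l in survive]
        assert len(everywhere) >= 30
        assoc = {
            "locality": everywhere[:10],
            "frost": everywhere[10:20],
            "moisture": everywhere[20:30],
        }
        parts = gea.partition_datasets(Gf, Sf, assoc, self.RULES)
        assert len(parts) == 12

    def test_empty_population_subset_rejected(self, small_sim):
        G, S, _ = small_sim
        with pytest.raises(ValueError, match="no samples"):
            gea.partition_datasets(G, S, {}, {"bad": ["XX"]})
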