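import numpy as np
import pandas as pd
import pytest

from ithkit import dna_ith
from ithkit.dna_ith import (DnaDiversityModel, DnaIthParams,
                            GenotypeMatrix, ado_rate,
                            bootstrap_diversity, build_genotype_matrix,
                            classical_mds, dna_diversity, filter_matrix,
                            p_distance)


def brute_force_p_distance(values):
    n = values.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diff = comp = 0
            for k in range(values.shape[1]):
                a, b = values[i, k], values[j, k]
                if np.isnan(a) or np.isnan(b):
                    continue
                comp += 1
                diff += a != b
            d[i, j] = diff / comp
    return d


class TestPDistance:
    def test_hand_counted_example(self):
        data = pd.DataFrame([[1, 0, np.nan, 1], [1, 1, np.nan, 0]],
                            index=["a", "b"], dtype=float)
        d = p_distance(data)
        assert d.loc["a", "b"] == pytest.approx(2 / 3)

    def test_identical_cells_distance_zero(self, toy_genotypes):
        dup = pd.concat([toy_genotypes, toy_genotypes.iloc[[0]]
                         .rename(index={"c1": "c1b"})])
        d = p_distance(dup)
        assert d.loc["c1", "c1b"] == 0.0

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(100):
            n, m = rng.integers(2, 8), rng.integers(3, 12)
            values = rng.integers(0, 2, size=(n, m)).astype(float)
            mask = rng.random((n, m)) < 0.2
            values[mask] = np.nan
            frame = pd.DataFrame(values)
            try:
                d = p_distance(frame).to_numpy()
            except ValueError:
                continue  # incomparable pair; rejection is the contract
            assert np.allclose(d, brute_force_p_distance(values))

    def test_symmetry_and_range(self, rng):
        values = rng.integers(0, 2, size=(10, 30)).astype(float)
        d = p_distance(pd.DataFrame(values)).to_numpy()
        assert np.allclose(d, d.T)
        assert (d >= 0).all() and (d <= 1).all()
        assert np.allclose(np.diag(d), 0)

    def test_incomparable_pair_rejected(self):
        data = pd.DataFrame([[1, np.nan], [np.nan, 0]], dtype=float)
        with pytest.raises(ValueError, match="no comparable sites"):
            p_distance(data)


class TestClassicalMds:
    def test_equilateral_triangle_reembeds_exactly(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords, _ = classical_mds(d, dims=2)
        x = coords.to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(x[i] - x[j]) == pytest.approx(
                    1.0, abs=1e-9)

    def test_planar_points_recovered_up_to_rigid_motion(self, rng):
        pts = rng.normal(size=(12, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords, evals = classical_mds(d, dims=2)
        x = coords.to_numpy()
        d2 = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        assert np.allclose(d, d2, atol=1e-8)
        assert (evals[2:] < 1e-8).all()

    def test_eigenvalues_match_dense_eigensolver(self, rng):
        pts = rng.normal(size=(9, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        _, evals = classical_mds(d, dims=4)
        n = d.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        oracle = np.sort(np.linalg.eigvalsh(-0.5 * j @ (d * d) @ j))[::-1]
        assert np.allclose(evals, oracle, atol=1e-9)

    def test_agrees_with_skbio_pcoa(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa

        pts = rng.normal(size=(10, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords, evals = classical_mds(d, dims=3)
        res = pcoa(d, number_of_dimensions=3)
        assert np.allclose(np.abs(coords.to_numpy()),
                           np.abs(res.samples.to_numpy()), atol=1e-6)

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            classical_mds(d)


class TestBuildGenotypeMatrix:
    params = DnaIthParams()

    def make_inputs(self):
        calls = {
            "c1": pd.DataFrame({"chrom": ["chr1"], "pos": [100],
                                "ref": ["A"], "alt": ["G"],
                                "vaf": [0.5]}),
            "c2": pd.DataFrame(columns=["chrom", "pos", "ref", "alt",
                                        "vaf"]),
        }
        bulk = pd.DataFrame({
            "chrom": ["chr1", "chr1", "chr1"],
            "pos": [100, 200, 300],
            "ref": ["A", "C", "G"], "alt": ["G", "T", "A"],
            "vaf_t1": [0.10, 0.05, 0.20], "vaf_t2": [0.30, 0.09, 0.25],
            "vaf_t3": [0.20, 0.08, 0.22]})
        depths = pd.DataFrame(
            {"chr1:100:G": [50, 29], "chr1:200:T": [40, 40],
             "chr1:300:A": [30, 29]},
            index=["c1", "c2"])
        return calls, depths, bulk

    def test_never_polymorphic_site_excluded(self):
        calls, depths, bulk = self.make_inputs()
        gm = build_genotype_matrix(calls, depths, bulk, self.params)
        assert "chr1:200:T" not in gm.data.columns

    def test_boundary_vaf_site_included_when_called(self):
        calls, depths, bulk = self.make_inputs()
        gm = build_genotype_matrix(calls, depths, bulk, self.params)
        assert "chr1:100:G" in gm.data.columns

    def test_uncalled_site_never_in_universe(self):
        # polymorphic but called in no cell -> excluded
        calls, depths, bulk = self.make_inputs()
        gm = build_genotype_matrix(calls, depths, bulk, self.params)
        assert "chr1:300:A" not in gm.data.columns

    def test_depth_floor_splits_zero_and_na(self):
        calls, depths, bulk = self.make_inputs()
        gm = build_genotype_matrix(calls, depths, bulk, self.params)
        assert gm.data.loc["c1", "chr1:100:G"] == 1.0
        assert np.isnan(gm.data.loc["c2", "chr1:100:G"])  # depth 29
        depths.loc["c2", "chr1:100:G"] = 30
        gm = build_genotype_matrix(calls, depths, bulk, self.params)
        assert gm.data.loc["c2", "chr1:100:G"] == 0.0

    def test_missing_depths_rejected(self):
        calls, depths, bulk = self.make_inputs()
        with pytest.raises(ValueError, match="no depth data"):
            build_genotype_matrix(calls, depths.drop(index="c2"), bulk,
                                  self.params)


class TestFilterMatrix:
    def test_all_na_site_removed(self):
        data = pd.DataFrame({"s1": [1.0, 0.0], "s2": [np.nan, np.nan]},
                            index=["c1", "c2"])
        gm, report = filter_matrix(GenotypeMatrix(data))
        assert list(gm.data.columns) == ["s1"]
        assert ("site", "s2") in set(zip(report["kind"], report["id"]))

    def test_clean_matrix_unchanged(self, toy_genotypes):
        full = toy_genotypes.fillna(1.0)
        gm, report = filter_matrix(GenotypeMatrix(full))
        assert gm.data.equals(full)
        assert report.empty

    def test_high_na_cell_removed_others_kept(self, rng):
        values = rng.integers(0, 2, size=(5, 10)).astype(float)
        values[0, :9] = np.nan  # 90% NA cell
        data = pd.DataFrame(values,
                            index=[f"c{i}" for i in range(5)])
        gm, report = filter_matrix(GenotypeMatrix(data))
        assert "c0" not in gm.data.index
        assert len(gm.data) == 4


class TestAdoRate:
    def het_inputs(self, cell_calls):
        depths = pd.DataFrame({f"chr1:{100 + i}:G": [50] for i in range(4)},
                              index=["c1"])
        vafs = pd.Series(0.5, index=depths.columns)
        return {"c1": cell_calls}, depths, vafs

    def test_all_homozygous_is_one_and_flagged(self):
        calls, depths, vafs = self.het_inputs(
            pd.DataFrame(columns=["chrom", "pos", "alt", "vaf"]))
        out = ado_rate(calls, depths, vafs)
        assert out.loc["c1", "ado"] == 1.0
        assert bool(out.loc["c1", "outlier"])

    def test_all_heterozygous_is_zero(self):
        cell_calls = pd.DataFrame({
            "chrom": ["chr1"] * 4, "pos": [100, 101, 102, 103],
            "alt": ["G"] * 4, "vaf": [0.5, 0.4, 0.55, 0.6]})
        calls, depths, vafs = self.het_inputs(cell_calls)
        out = ado_rate(calls, depths, vafs)
        assert out.loc["c1", "ado"] == 0.0

    def test_homozygous_variant_counts_as_dropout(self):
        # VAF ~1 means the reference allele dropped: still homozygous
        cell_calls = pd.DataFrame({
            "chrom": ["chr1"] * 4, "pos": [100, 101, 102, 103],
            "alt": ["G"] * 4, "vaf": [0.5, 0.5, 0.95, 1.0]})
        calls, depths, vafs = self.het_inputs(cell_calls)
        out = ado_rate(calls, depths, vafs)
        assert out.loc["c1", "ado"] == pytest.approx(0.5)

    def test_shallow_sites_not_assessed(self):
        cell_calls = pd.DataFrame(columns=["chrom", "pos", "alt", "vaf"])
        calls, depths, vafs = self.het_inputs(cell_calls)
        depths.loc["c1"] = 10  # all below the depth floor
        with pytest.warns(UserWarning, match="no assessable"):
            out = ado_rate(calls, depths, vafs)
        assert np.isnan(out.loc["c1", "ado"])


class TestDiversity:
    def test_identical_cells_zero_index(self):
        data = pd.DataFrame(np.ones((4, 6)),
                            index=[f"c{i}" for i in range(4)])
        d = p_distance(data)
        emb, ev = classical_mds(d)
        idx = dna_diversity(emb, ev, pd.Series("g", index=data.index))
        assert idx.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_homogeneity_doubling_coordinates(self, rng):
        coords = pd.DataFrame(rng.normal(size=(8, 3)),
                              index=[f"c{i}" for i in range(8)])
        ev = np.array([3.0, 2.0, 1.0])
        groups = pd.Series("g", index=coords.index)
        a = dna_diversity(coords, ev, groups)
        b = dna_diversity(coords * 2, ev, groups)
        assert b.iloc[0] == pytest.approx(2 * a.iloc[0])

    def test_rotation_invariance(self, rng):
        coords = rng.normal(size=(10, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        groups = pd.Series("g", index=range(10))
        ev = np.array([3.0, 2.0, 1.0])
        a = dna_diversity(pd.DataFrame(coords), ev, groups)
        b = dna_diversity(pd.DataFrame(coords @ q), ev, groups)
        assert a.iloc[0] == pytest.approx(b.iloc[0], abs=1e-9)

    def test_small_group_rejected(self, rng):
        coords = pd.DataFrame(rng.normal(size=(4, 2)))
        groups = pd.Series(["a", "a", "a", "b"], index=coords.index)
        with pytest.raises(ValueError, match="fewer than 3"):
            dna_diversity(coords, np.array([2.0, 1.0]), groups)


class TestBootstrapDiversity:
    def small_matrix(self, rng, n=8):
        values = rng.integers(0, 2, size=(2 * n, 40)).astype(float)
        return pd.DataFrame(values,
                            index=[f"c{i}" for i in range(2 * n)])

    def test_identical_groups_p_near_one(self, rng):
        data = self.small_matrix(rng)
        half = len(data) // 2
        # group B duplicates group A exactly
        data.iloc[half:] = data.iloc[:half].to_numpy()
        groups = pd.Series(["A"] * half + ["B"] * half, index=data.index)
        out = bootstrap_diversity(data, groups, seed=3, n_boot=1000)
        assert out["pairwise"].loc["A", "B"] > 0.5

    def test_ci_contains_observed_for_duplicated_group(self, rng):
        data = self.small_matrix(rng)
        groups = pd.Series(["A"] * 8 + ["B"] * 8, index=data.index)
        out = bootstrap_diversity(data, groups, seed=5, n_boot=500)
        for g in ["A", "B"]:
            assert (out["ci"].loc[g, "ci_low"]
                    <= out["observed"][g]
                    <= out["ci"].loc[g, "ci_high"])

    def test_seed_reproducibility(self, rng):
        data = self.small_matrix(rng)
        groups = pd.Series(["A"] * 8 + ["B"] * 8, index=data.index)
        a = bootstrap_diversity(data, groups, seed=11, n_boot=200)
        b = bootstrap_diversity(data, groups, seed=11, n_boot=200)
        assert np.array_equal(a["replicates"], b["replicates"])


class TestModelApi:
    def test_model_fit_summary(self, rng):
        values = rng.integers(0, 2, size=(12, 30)).astype(float)
        data = pd.DataFrame(values, index=[f"c{i}" for i in range(12)])
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=data.index)
        res = DnaDiversityModel(data, groups).fit(n_boot=100, seed=2)
        text = res.summary()
        assert "diversity" in text.lower()
        assert res.ci is not None
        assert set(res.diversity.index) == {"A", "B"}

    def test_end_to_end_truth_recovery(self, clean_dna_sim,
                                       clean_dna_calls):
        """Noise-free pipeline: genotype matrix equals truth restricted
        to polymorphic sites."""
        sim = clean_dna_sim
        gm = build_genotype_matrix(clean_dna_calls, sim.depths,
                                   sim.bulk_sites)
        truth = sim.truth_genotypes[gm.data.columns]
        assert gm.data.loc[truth.index].equals(truth)
        # and the selected universe is exactly the truth-polymorphic,
        # observed sites
        p = DnaIthParams()
        expect = sim.sites.index[
            (sim.sites["vaf"] >= p.vaf_lo) & (sim.sites["vaf"] <= p.vaf_hi)
            & (sim.truth_genotypes.sum(axis=0) > 0)]
        assert set(gm.data.columns) == set(expect)
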