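"""Filters, LD pruning, PCA, IBS/NJ, Hudson F_ST, Wilcoxon, and D-statistics
checked against brute-force oracles and known-tree constructions."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import wilcoxon as scipy_wilcoxon

import popkit as pk
from popkit.datatypes import GenotypeMatrix
from conftest import brute_force_hudson, random_matrix


def make_gm(geno, localities=None, pos=None, chrom=None, outgroup=True):
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    return GenotypeMatrix(
        individuals=[f"i{k}" for k in range(n)],
        localities=localities or ["x"] * n,
        chrom=np.array(chrom if chrom is not None else ["c1"] * m, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, m + 1)),
        geno=geno,
        outgroup=np.zeros(m, dtype=np.int8) if outgroup else None,
    )


class TestFilterSites:
    def test_maf_and_coverage_rules(self):
        # 22 individuals; site0: MAF 1/44 ~ 0.023 -> dropped; site1: MAF 3/44 ~0.068 kept
        # site2: genotyped in 10 of 22 -> dropped; site3: monomorphic -> dropped
        geno = np.zeros((22, 4), dtype=np.int8)
        geno[0, 0] = 1
        geno[0:3, 1] = 1
        geno[:, 2] = -1
        geno[:10, 2] = 1
        gm = make_gm(geno)
        out, report = pk.filter_sites(gm, pk.SiteFilterParams(0.05, 0.5))
        assert out.n_sites == 1
        assert list(out.pos) == [2]
        assert report["n_dropped_coverage"] == 1
        assert report["n_dropped_maf"] == 2

    def test_all_dropped_returns_empty(self):
        gm = make_gm(np.zeros((4, 3), dtype=np.int8))
        out, report = pk.filter_sites(gm)
        assert out.n_sites == 0
        assert report["n_kept"] == 0


class TestLdPrune:
    def test_perfect_pair_within_window_keeps_one(self):
        col = np.array([0, 0, 1, 1, 2, 2], dtype=np.int8)
        gm = make_gm(np.column_stack([col, col]), pos=[1000, 6000])
        out, report = pk.ld_prune(gm, max_kb=20, min_weight=0.5)
        assert out.n_sites == 1

    def test_distance_bound_respected(self):
        col = np.array([0, 0, 1, 1, 2, 2], dtype=np.int8)
        gm = make_gm(np.column_stack([col, col]), pos=[1000, 26_000])
        out, _ = pk.ld_prune(gm, max_kb=20, min_weight=0.5)
        assert out.n_sites == 2

    def test_independent_sites_mostly_retained(self):
        rng = np.random.default_rng(8)
        geno = rng.binomial(2, 0.4, size=(22, 200)).astype(np.int8)
        gm = make_gm(geno, pos=np.arange(1, 201) * 500)
        out, _ = pk.ld_prune(gm, max_kb=20, min_weight=0.5)
        assert out.n_sites >= 0.95 * 200


class TestPca:
    def test_duplicated_individual_identical_coordinates(self):
        rng = np.random.default_rng(9)
        geno = rng.integers(0, 3, size=(6, 50)).astype(np.int8)
        geno[5] = geno[0]
        res = pk.pca(make_gm(geno), k=3)
        assert np.allclose(res.coords[0], res.coords[5])

    def test_covariance_reconstruction(self):
        rng = np.random.default_rng(10)
        geno = rng.integers(0, 3, size=(8, 120)).astype(np.int8)
        gm = make_gm(geno)
        res = pk.pca(gm, k=8)
        vals, vecs = np.linalg.eigh(res.covariance)
        recon = (vecs * vals) @ vecs.T
        assert np.allclose(recon, res.covariance, atol=1e-10)

    def test_two_demes_separate_on_pc1(self):
        from sklearn.metrics import silhouette_score
        hits = 0
        reps = 20
        for s in range(reps):
            gm = pk.simulate_island_genotypes(pk.CoalescentParams(
                n_demes=2, samples_per_deme=8, theta=5, migration_rate=0.1,
                n_blocks=30, seed=400 + s))
            res = pk.pca(gm, k=2)
            labels = [0] * 4 + [1] * 4
            hits += silhouette_score(res.coords[:, :1], labels) > 0
        assert hits >= 0.95 * reps

    def test_panmictic_pc1_within_permutation_band(self):
        rng = np.random.default_rng(11)
        hits = 0
        reps = 20
        for s in range(reps):
            gm = pk.simulate_island_genotypes(pk.CoalescentParams(
                n_demes=1, samples_per_deme=16, theta=5, n_blocks=30,
                seed=500 + s))
            pc1 = pk.pca(gm, k=1).coords[:, 0]
            labels = np.array([0] * 4 + [1] * 4)
            stat = abs(pc1[labels == 0].mean() - pc1[labels == 1].mean())
            null = []
            for _ in range(199):
                perm = rng.permutation(labels)
                null.append(abs(pc1[perm == 0].mean() - pc1[perm == 1].mean()))
            hits += stat <= np.quantile(null, 0.95)
        assert hits >= 0.7 * reps  # ~5% exceedance expected per replicate


class TestIbs:
    def test_self_distance_zero_consensus(self, toy_matrix):
        d = pk.ibs_distance_matrix(toy_matrix, mode="consensus")
        assert np.all(np.diag(d) == 0)

    def test_opposite_homozygotes_distance_one(self):
        geno = np.array([[0, 0, 0], [2, 2, 2]], dtype=np.int8)
        d = pk.ibs_distance_matrix(make_gm(geno), mode="consensus")
        assert d[0, 1] == 1.0

    def test_random_mode_het_expectation(self):
        # genotypes 0/2 vs 1 at a single site: sampled alleles differ w.p. 1/2
        geno = np.array([[0], [1]], dtype=np.int8)
        gm = make_gm(geno)
        vals = [pk.ibs_distance_matrix(gm, mode="random", seed=s)[0, 1]
                for s in range(1000)]
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_zero_overlap_errors(self):
        geno = np.array([[0, -1], [-1, 2]], dtype=np.int8)
        with pytest.raises(ValueError, match="share no called sites"):
            pk.ibs_distance_matrix(make_gm(geno))

    def test_matches_brute_force_consensus(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            gm = random_matrix(rng, n_ind=6, n_sites=40)
            d = pk.ibs_distance_matrix(gm, mode="consensus")
            for i, j in combinations(range(6), 2):
                num = den = 0
                for s in range(gm.n_sites):
                    gi, gj = gm.geno[i, s], gm.geno[j, s]
                    if gi < 0 or gj < 0:
                        continue
                    den += 1
                    num += (1 if gi >= 1 else 0) != (1 if gj >= 1 else 0)
                assert d[i, j] == pytest.approx(num / den)


def _tree_distances(newick_free=False):
    """A fixed 4-taxon additive tree: ((A:2,B:3):1,(C:4,D:5))."""
    return np.array([
        [0, 5, 7, 8],
        [5, 0, 8, 9],
        [7, 8, 0, 9],
        [8, 9, 9, 0],
    ], dtype=float)


class TestNjTree:
    def test_exact_recovery_of_additive_tree(self):
        from Bio import Phylo
        import io as _io
        newick = pk.nj_tree(_tree_distances(), list("ABCD"))
        tree = Phylo.read(_io.StringIO(newick), "newick")
        # additive distances are reproduced exactly by path lengths
        for x, y, expected in [("A", "B", 5), ("A", "C", 7), ("A", "D", 8),
                               ("B", "C", 8), ("B", "D", 9), ("C", "D", 9)]:
            assert tree.distance(x, y) == pytest.approx(expected)

    def test_star_tree_equal_branches(self):
        d = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float)
        newick = pk.nj_tree(d, list("ABC"))
        assert newick.count(":1") == 3

    def test_input_order_invariance(self):
        import dendropy
        d = _tree_distances()
        names = list("ABCD")
        perm = [2, 0, 3, 1]
        n1 = pk.nj_tree(d, names)
        n2 = pk.nj_tree(d[np.ix_(perm, perm)], [names[i] for i in perm])
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=n1, schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=n2, schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        assert rf == 0

    def test_matches_scikit_bio_topology(self):
        skbio = pytest.importorskip("skbio")
        import dendropy
        rng = np.random.default_rng(13)
        for _ in range(10):
            n = 6
            x = rng.random((n, 3)) * 5
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            np.fill_diagonal(d, 0)
            names = [f"t{i}" for i in range(n)]
            mine = pk.nj_tree(d, names)
            theirs = str(skbio.tree.nj(
                skbio.DistanceMatrix(d, ids=names)))
            tns = dendropy.TaxonNamespace()
            t1 = dendropy.Tree.get(data=mine, schema="newick", taxon_namespace=tns)
            t2 = dendropy.Tree.get(data=theirs, schema="newick", taxon_namespace=tns)
            t1.encode_bipartitions()
            t2.encode_bipartitions()
            assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            pk.nj_tree(np.zeros((2, 2)), ["a", "b"])


class TestWindowedFst:
    def test_fixed_difference_gives_one(self):
        geno = np.array([[2, 2], [2, 2], [0, 0], [0, 0]], dtype=np.int8)
        gm = make_gm(geno, localities=["p1", "p1", "p2", "p2"])
        res = pk.windowed_fst(gm, window_bp=100, min_sites=1)
        assert res[("p1", "p2")]["windows"][0].fst == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(14)
        geno = rng.binomial(2, 0.3, size=(20, 400)).astype(np.int8)
        gm = make_gm(geno, localities=["p1"] * 10 + ["p2"] * 10,
                     pos=np.arange(1, 401) * 10)
        res = pk.windowed_fst(gm, window_bp=5000, min_sites=10)
        assert abs(res[("p1", "p2")]["median_fst"]) < 0.02

    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(15)
        for _ in range(25):
            gm = random_matrix(rng, n_ind=10, n_sites=80)
            idx1 = [i for i, l in enumerate(gm.localities) if l == "loc0"]
            idx2 = [i for i, l in enumerate(gm.localities) if l == "loc1"]
            num, den = pk.hudson_components(gm, idx1, idx2)
            bnum, bden = brute_force_hudson(gm.geno, idx1, idx2)
            ok = ~np.isnan(bden)
            assert np.allclose(num[ok], bnum[ok], atol=1e-12)
            assert np.allclose(den[ok], bden[ok], atol=1e-12)
            assert np.array_equal(np.isnan(num), np.isnan(bnum))
            # window ratio-of-sums equals explicit sum of the same components
            res = pk.windowed_fst(gm, window_bp=10_000, min_sites=1)
            usable = ok & (bden > 0)
            if usable.sum():
                expected = np.nansum(bnum[usable]) / np.nansum(bden[usable])
                got = res[("loc0", "loc1")]["windows"][0].fst
                assert got == pytest.approx(expected, abs=1e-12)

    def test_window_boundaries_half_open(self):
        geno = np.array([[2, 2], [2, 2], [0, 0], [0, 0]], dtype=np.int8)
        gm = make_gm(geno, localities=["p1", "p1", "p2", "p2"],
                     pos=[99_999, 100_000])
        res = pk.windowed_fst(gm, window_bp=100_000, min_sites=1)
        wins = res[("p1", "p2")]["windows"]
        assert [(w.start, w.end, w.n_sites) for w in wins] == [
            (0, 100_000, 1), (100_000, 200_000, 1)]


class TestWilcoxon:
    def test_all_positive_n5_exact(self):
        assert pk.wilcoxon_signed_rank([1, 2, 3, 4, 5]) == pytest.approx(2 / 32)

    def test_symmetric_values_p_one(self):
        assert pk.wilcoxon_signed_rank([-2, -1, 1, 2]) == pytest.approx(1.0)

    def test_all_zero_differences(self):
        assert pk.wilcoxon_signed_rank([3.0, 3.0], mu=3.0) == 1.0

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(16)
        for _ in range(20):
            x = rng.normal(0.3, 1, size=rng.integers(5, 13))
            p_mine = pk.wilcoxon_signed_rank(x)
            p_scipy = scipy_wilcoxon(x, alternative="two-sided",
                                     mode="exact").pvalue
            assert p_mine == pytest.approx(p_scipy, abs=1e-12)

    def test_approximation_close_to_exact_at_n12(self):
        rng = np.random.default_rng(17)
        for _ in range(12):
            x = rng.normal(0.4, 1, size=12)
            exact = pk.wilcoxon_signed_rank(x, method="exact")
            approx = pk.wilcoxon_signed_rank(x, method="approx")
            assert abs(exact - approx) < 0.01

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=11))
    def test_p_in_unit_interval(self, values):
        p = pk.wilcoxon_signed_rank(values)
        assert 0 <= p <= 1


class TestDstat:
    def test_hand_built_counts(self):
        # three ABBA sites, one BABA, two uninformative
        geno = np.array([
            [0, 0, 0, 2, 0, 0],
            [2, 2, 2, 0, 0, 0],
            [2, 2, 2, 2, 0, 0],
        ], dtype=np.int8)
        gm = make_gm(geno)
        r = pk.dstat(gm, "i0", "i1", "i2", block_bp=2)
        assert (r.n_abba, r.n_baba) == (3.0, 1.0)
        assert r.d == pytest.approx(0.5)

    def test_identical_h1_h2_pattern_symmetry(self):
        """Genotypically identical H1/H2: ABBA and BABA arise only from
        opposite heterozygote draws, so they are exchangeable and E[D] = 0;
        when the sampled alleles coincide everywhere D is 0/0 and flagged."""
        rng = np.random.default_rng(18)
        geno = rng.integers(0, 3, size=(3, 300)).astype(np.int8)
        geno[1] = geno[0]
        gm = make_gm(geno)
        ds = [pk.dstat(gm, "i0", "i1", "i2", block_bp=50, seed=s).d
              for s in range(200)]
        se = np.std(ds) / np.sqrt(len(ds))
        assert abs(np.mean(ds)) < 3 * se
        # all-homozygous identical pair: no informative site can exist
        hom = (2 * rng.integers(0, 2, size=(3, 100))).astype(np.int8)
        hom[1] = hom[0]
        r = pk.dstat(make_gm(hom), "i0", "i1", "i2", block_bp=50, seed=1)
        assert np.isnan(r.d) and r.n_abba == r.n_baba == 0

    def test_antisymmetry_under_h1_h2_swap(self, toy_matrix):
        a = pk.sample_alleles(toy_matrix, seed=3)
        r1 = pk.dstat(toy_matrix, "ind0", "ind1", "ind2", block_bp=50_000,
                      _alleles=a)
        r2 = pk.dstat(toy_matrix, "ind1", "ind0", "ind2", block_bp=50_000,
                      _alleles=a)
        assert r1.d == pytest.approx(-r2.d)
        assert (r1.n_abba, r1.n_baba) == (r2.n_baba, r2.n_abba)

    def test_matches_brute_force_pattern_count(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            gm = random_matrix(rng, n_ind=5, n_sites=120)
            alle = pk.sample_alleles(gm, seed=77)
            r = pk.dstat(gm, "i0", "i1", "i2", block_bp=1000, _alleles=alle)
            abba = baba = 0
            for s in range(gm.n_sites):
                a1, a2, a3 = alle[0, s], alle[1, s], alle[2, s]
                o = gm.outgroup[s]
                if min(a1, a2, a3) < 0:
                    continue
                if a1 == o and a2 != o and a3 != o:
                    abba += 1
                if a1 != o and a2 == o and a3 != o:
                    baba += 1
            assert (r.n_abba, r.n_baba) == (abba, baba)

    def test_jackknife_se_close_to_bootstrap(self):
        rng = np.random.default_rng(20)
        gm = pk.simulate_island_genotypes(pk.CoalescentParams(
            n_demes=1, samples_per_deme=8, theta=8, n_blocks=100, seed=21))
        alle = pk.sample_alleles(gm, seed=22)
        r = pk.dstat(gm, gm.individuals[0], gm.individuals[1],
                     gm.individuals[2], block_bp=2_000_000, _alleles=alle)
        from popkit.structure import _block_ids, _dstat_from_alleles
        blocks = _block_ids(gm, 2_000_000)
        nb = blocks.max() + 1
        abba_b, baba_b = _dstat_from_alleles(
            alle[0], alle[1], alle[2], gm.outgroup, blocks, nb)
        boot = []
        for _ in range(500):
            idx = rng.integers(0, nb, size=nb)
            A, B = abba_b[idx].sum(), baba_b[idx].sum()
            if A + B:
                boot.append((A - B) / (A + B))
        assert r.se == pytest.approx(np.std(boot), rel=0.2)

    def test_quartet_classification(self):
        assert pk.classify_quartet("a", "a", "a") == "within_locality"
        assert pk.classify_quartet("a", "a", "b") == "correct"
        assert pk.classify_quartet("b", "a", "a") == "incorrect"
        assert pk.classify_quartet("a", "b", "c") is None

    def test_topology_classes_present(self):
        gm = pk.simulate_island_genotypes(pk.CoalescentParams(
            n_demes=2, samples_per_deme=6, theta=4, migration_rate=1.0,
            n_blocks=50, seed=30))
        res = pk.topology_test(gm, block_bp=2_000_000, seed=31)
        classes = {r.topology_class for r in res}
        assert {"correct", "incorrect", "within_locality"} <= classes
        for r in res:
            assert 0 <= r.wilcoxon_p_d <= 1
            assert 0 <= r.wilcoxon_p_structure <= 1
            assert r.n_quartets == len(r.d_values)
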