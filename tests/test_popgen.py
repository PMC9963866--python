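import math

import numpy as np
import pytest

from conftest import make_matrix
from isocross import popgen
from isocross.errors import AnalysisError, ValidationError
from isocross.popgen import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    DistanceMatrix,
    bootstrap_tree,
    filter_sites,
    nei_distance,
    nj_tree,
    read_genotypes,
    sample_heterozygosity,
    write_vcf,
)


class TestReadGenotypes:
    def test_toy_vcf(self, toy_vcf):
        gm = read_genotypes(toy_vcf, pseudodiploid=["TET"])
        assert gm.samples == ["S1", "S2", "TET"]
        assert gm.n_loci == 3  # indel and multiallelic record skipped
        assert gm.meta["skipped_multiallelic"] == 1
        assert gm.meta["skipped_non_snp"] == 1
        assert list(gm.pos) == [100, 150, 160]

    def test_ad_summed_for_depth(self, toy_vcf):
        gm = read_genotypes(toy_vcf, pseudodiploid=["TET"])
        j = list(gm.pos).index(150)
        i = gm.samples.index("S1")
        assert gm.calls[i, j] == HET
        assert gm.depth[i, j] == 13  # AD 7,6

    def test_tetraploid_het_scored_pseudodiploid(self, toy_vcf):
        gm = read_genotypes(toy_vcf, pseudodiploid=["TET"])
        i = gm.samples.index("TET")
        assert gm.calls[i, list(gm.pos).index(100)] == HET  # 0/0/0/1
        assert gm.calls[i, list(gm.pos).index(150)] == HOM_ALT  # 1/1/1/1

    def test_unflagged_tetraploid_rejected(self, toy_vcf):
        with pytest.raises(ValidationError, match="pseudodiploid"):
            read_genotypes(toy_vcf)

    def test_missing_call(self, toy_vcf):
        gm = read_genotypes(toy_vcf, pseudodiploid=["TET"])
        assert gm.calls[gm.samples.index("S1"), list(gm.pos).index(160)] == MISSING

    def test_missing_file(self, tmp_path):
        with pytest.raises(ValidationError):
            read_genotypes(tmp_path / "nope.vcf")

    def test_vcf_roundtrip(self, toy_vcf, tmp_path):
        gm = read_genotypes(toy_vcf, pseudodiploid=["TET"])
        write_vcf(gm, tmp_path / "rt.vcf")
        gm2 = read_genotypes(tmp_path / "rt.vcf")
        assert np.array_equal(gm.calls, gm2.calls)
        assert np.array_equal(gm.depth, gm2.depth)
        assert list(gm.pos) == list(gm2.pos)


class TestFilterSites:
    def base_matrix(self):
        # 4 sites x 3 samples: all polymorphic, depth 30
        calls = np.array([
            [0, 1, 0, 2],
            [2, 0, 1, 0],
            [1, 2, 2, 1],
        ], dtype=np.int8)
        return make_matrix(calls, pos=[100, 200, 300, 400])

    def test_low_depth_genotype_removes_site(self):
        gm = self.base_matrix()
        depth = gm.depth.copy()
        depth[1, 2] = 9
        gm.depth = depth
        out = filter_sites(gm)
        assert 300 not in out.pos
        assert out.meta["filter_stats"]["genotypes_set_missing_low_depth"] == 1
        assert out.meta["filter_stats"]["removed_missing"] == 1

    def test_monomorphic_removed(self):
        calls = np.array([[0, 0], [0, 1], [0, 2]], dtype=np.int8)
        out = filter_sites(make_matrix(calls, pos=[100, 200]))
        assert list(out.pos) == [200]
        assert out.meta["filter_stats"]["removed_monomorphic"] == 1

    def test_all_het_site_removed(self):
        calls = np.array([[1, 0], [1, 1], [1, 2]], dtype=np.int8)
        out = filter_sites(make_matrix(calls, pos=[100, 200]), max_het=0.80)
        assert list(out.pos) == [200]
        assert out.meta["filter_stats"]["removed_heterozygous"] == 1

    def test_greedy_thinning(self):
        calls = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2]], dtype=np.int8)
        out = filter_sites(make_matrix(calls, pos=[100, 110, 130]), thin_bp=20)
        assert list(out.pos) == [100, 130]
        assert out.meta["filter_stats"]["removed_thinning"] == 1

    def test_thinning_is_per_chromosome(self):
        calls = np.tile(np.array([[0], [1], [2]], dtype=np.int8), (1, 2))
        gm1 = make_matrix(calls[:, :1], pos=[100], chrom="chr1")
        gm2 = make_matrix(calls[:, :1], pos=[105], chrom="chr2")
        merged = popgen.GenotypeMatrix(
            samples=gm1.samples,
            chrom=np.concatenate([gm1.chrom, gm2.chrom]),
            pos=np.concatenate([gm1.pos, gm2.pos]),
            ref=np.concatenate([gm1.ref, gm2.ref]),
            alt=np.concatenate([gm1.alt, gm2.alt]),
            calls=np.hstack([gm1.calls, gm2.calls]),
            depth=np.hstack([gm1.depth, gm2.depth]),
        )
        out = filter_sites(merged)
        assert out.n_loci == 2  # different chromosomes never thin each other

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(4, 60)).astype(np.int8)
        depth = rng.integers(5, 40, size=(4, 60)).astype(np.int32)
        gm = make_matrix(calls, pos=np.cumsum(rng.integers(5, 40, size=60)),
                         depth=depth)
        once = filter_sites(gm)
        twice = filter_sites(once)
        assert np.array_equal(once.calls, twice.calls)
        assert list(once.pos) == list(twice.pos)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 3, size=(4, 40)).astype(np.int8)
        gm = make_matrix(calls, pos=np.cumsum(rng.integers(5, 40, size=40)))
        perm = [2, 0, 3, 1]
        gm_perm = make_matrix(calls[perm], pos=gm.pos,
                              samples=[gm.samples[i] for i in perm])
        assert list(filter_sites(gm).pos) == list(filter_sites(gm_perm).pos)

    def test_empty_result_warns(self):
        calls = np.zeros((3, 2), dtype=np.int8)  # all monomorphic
        with pytest.warns(UserWarning, match="all sites removed"):
            out = filter_sites(make_matrix(calls, pos=[100, 200]))
        assert out.n_loci == 0


class TestHeterozygosity:
    def test_all_hom_zero(self):
        calls = np.array([[0, 2, 0, 2]], dtype=np.int8)
        assert sample_heterozygosity(make_matrix(calls))["S1"] == 0.0

    def test_counting(self):
        calls = np.full((1, 250), HOM_REF, dtype=np.int8)
        calls[0, :25] = HET
        assert sample_heterozygosity(make_matrix(calls))["S1"] == pytest.approx(0.1)

    def test_f1_identity(self):
        # F1 of homozygous parents differing at k of L loci is het at k/L
        L, k = 200, 37
        p1 = np.full(L, HOM_REF, dtype=np.int8)
        p2 = np.full(L, HOM_REF, dtype=np.int8)
        p2[:k] = HOM_ALT
        f1 = np.where(p1 == p2, p1, HET).astype(np.int8)
        gm = make_matrix(np.vstack([p1, p2, f1]), samples=["P1", "P2", "F1"])
        assert sample_heterozygosity(gm)["F1"] == pytest.approx(k / L)

    def test_uncalled_sample_nan(self):
        calls = np.array([[0, 0], [MISSING, MISSING]], dtype=np.int8)
        with pytest.warns(UserWarning, match="no called"):
            het = sample_heterozygosity(make_matrix(calls))
        assert math.isnan(het["S2"])


class TestNeiDistance:
    def test_identical_samples_zero(self):
        calls = np.array([[0, 1, 2], [0, 1, 2]], dtype=np.int8)
        dm = nei_distance(make_matrix(calls))
        assert dm.values[0, 1] == 0.0

    def test_fixed_difference_ln2(self):
        # locus 1: X ref / Y alt; locus 2: both ref -> D = ln 2
        calls = np.array([[0, 0], [2, 0]], dtype=np.int8)
        dm = nei_distance(make_matrix(calls))
        assert dm.values[0, 1] == pytest.approx(math.log(2), abs=1e-10)

    def test_het_vs_hom_single_locus(self):
        calls = np.array([[1], [0]], dtype=np.int8)
        dm = nei_distance(make_matrix(calls))
        assert dm.values[0, 1] == pytest.approx(0.5 * math.log(2), abs=1e-10)
        assert dm.values[0, 1] == pytest.approx(0.3466, abs=5e-5)

    def test_duplicated_sample_zero_and_nonnegative(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(3, 80)).astype(np.int8)
        calls = np.vstack([calls, calls[0]])
        dm = nei_distance(make_matrix(calls, samples=["A", "B", "C", "A2"]))
        assert dm.get("A", "A2") == 0.0
        assert (dm.values >= 0).all()

    def test_no_shared_alleles_sentinel(self):
        calls = np.array([[0], [2]], dtype=np.int8)
        with pytest.warns(UserWarning, match="sentinel"):
            dm = nei_distance(make_matrix(calls))
        assert dm.values[0, 1] == popgen.NEI_INF_SENTINEL

    def test_missing_excluded_pairwise(self):
        # locus 2 missing in Y: distance computed from locus 1 only
        calls = np.array([[0, 0], [0, MISSING]], dtype=np.int8)
        dm = nei_distance(make_matrix(calls))
        assert dm.values[0, 1] == 0.0

    def test_too_small(self):
        calls = np.array([[0, 1]], dtype=np.int8)
        with pytest.raises(AnalysisError):
            nei_distance(make_matrix(calls))


def tree_distances_from(tree):
    return tree.leaf_distances()


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        tree = nj_tree(dm)
        lengths = {node.name: length for node, length in tree.root.children}
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    @pytest.mark.parametrize("n", [4, 5, 6, 8])
    def test_additive_matrix_recovery(self, n):
        from isocross import synthdata

        cfg = synthdata.SynthConfig(n_taxa=n, tree_shape="random", seed=n)
        true_tree = synthdata.build_tree(cfg, np.random.default_rng(n))
        true_d = true_tree.leaf_distances()
        labels = sorted(true_tree.labels)
        values = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j in range(i + 1, n):
                b = labels[j]
                values[i, j] = values[j, i] = true_d[(min(a, b), max(a, b))]
        est = nj_tree(DistanceMatrix(labels, values))
        est_d = est.leaf_distances()
        for key, value in true_d.items():
            assert est_d[key] == pytest.approx(value, abs=1e-10)
        assert est.bipartitions() == true_tree.bipartitions()

    def test_label_order_invariance(self):
        rng = np.random.default_rng(9)
        n = 6
        a = rng.random((n, n)) + 1
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        labels = [f"L{i}" for i in range(n)]
        dm = DistanceMatrix(labels, a)
        tree1 = nj_tree(dm)
        perm = [3, 1, 5, 0, 2, 4]
        dm2 = DistanceMatrix([labels[i] for i in perm], a[np.ix_(perm, perm)])
        tree2 = nj_tree(dm2)
        assert tree1.bipartitions() == tree2.bipartitions()
        d1, d2 = tree1.leaf_distances(), tree2.leaf_distances()
        for key in d1:
            assert d1[key] == pytest.approx(d2[key], abs=1e-10)

    def test_too_few_taxa(self):
        with pytest.raises(AnalysisError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0.0]])))

    def test_nan_rejected(self):
        values = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0.0]])
        with pytest.raises(AnalysisError):
            nj_tree(DistanceMatrix(["A", "B", "C"], values))

    def test_newick_parses_with_dendropy(self):
        import dendropy

        dm = DistanceMatrix(["A", "B", "C", "D"],
                            np.array([[0, 2, 4, 4], [2, 0, 4, 4],
                                      [4, 4, 0, 2], [4, 4, 2, 0]], float))
        newick = nj_tree(dm).to_newick()
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == {
            "A", "B", "C", "D"
        }


class TestBootstrap:
    def test_strong_clades_high_support(self, two_clade_matrix):
        tree = bootstrap_tree(two_clade_matrix, n_reps=200, seed=11)
        clade = frozenset({"A1", "A2", "A3"})
        supports = {}

        def walk(node):
            for child, _ in node.children:
                if not child.is_leaf:
                    supports[frozenset(child.leaves())] = child.support
                    walk(child)

        walk(tree.root)
        found = [s for side, s in supports.items()
                 if side == clade or side == frozenset(tree.labels) - clade]
        assert found and all(s >= 95.0 for s in found)

    def test_no_bootstrap_no_supports(self, two_clade_matrix):
        tree = bootstrap_tree(two_clade_matrix, n_reps=0)
        def all_supports(node):
            out = []
            for child, _ in node.children:
                if not child.is_leaf:
                    out.append(child.support)
                    out.extend(all_supports(child))
            return out
        assert all(s is None for s in all_supports(tree.root))

    def test_seed_reproducibility(self, two_clade_matrix):
        t1 = bootstrap_tree(two_clade_matrix, n_reps=50, seed=5)
        t2 = bootstrap_tree(two_clade_matrix, n_reps=50, seed=5)
        assert t1.to_newick() == t2.to_newick()

    def test_locus_order_invariance(self, two_clade_matrix):
        gm = two_clade_matrix
        perm = np.random.default_rng(2).permutation(gm.n_loci)
        shuffled = gm.take_loci(perm)  # construction re-sorts by position
        t1 = bootstrap_tree(gm, n_reps=30, seed=5)
        t2 = bootstrap_tree(shuffled, n_reps=30, seed=5)
        assert t1.to_newick() == t2.to_newick()

    def test_seed_required(self, two_clade_matrix):
        with pytest.raises(ValidationError, match="seed"):
            bootstrap_tree(two_clade_matrix, n_reps=10)


def test_distance_matrix_tsv_roundtrip(tmp_path):
    dm = DistanceMatrix(["A", "B", "C"],
                        np.array([[0, 0.5, 1.25], [0.5, 0, 2], [1.25, 2, 0.0]]))
    dm.to_tsv(tmp_path / "d.tsv")
    back = DistanceMatrix.from_tsv(tmp_path / "d.tsv")
    assert back.labels == dm.labels
    assert np.allclose(back.values, dm.values)
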