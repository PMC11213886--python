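import numpy as np
import pandas as pd
import pytest

from capriscan import structure
from capriscan.popio import PopulationMap

from conftest import make_panel, random_panel


def wc_fst_oracle(counts_a, counts_b):
    """Scalar Weir-Cockerham ratio-of-sums for two populations.

    ``counts_x``: list of (n_diploids, n_alt_alleles, n_het_genotypes).
    Written independently from the vectorised implementation.
    """
    num = den = 0.0
    r = 2
    for (na, alt_a, het_a), (nb, alt_b, het_b) in zip(counts_a, counts_b):
        pa, pb = alt_a / (2 * na), alt_b / (2 * nb)
        ha, hb = het_a / na, het_b / nb
        nbar = (na + nb) / 2
        nc = (r * nbar - (na ** 2 + nb ** 2) / (r * nbar)) / (r - 1)
        pbar = (na * pa + nb * pb) / (r * nbar)
        s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (na * ha + nb * hb) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


def two_pop_panel(G_a, G_b):
    G = np.vstack([G_a, G_b])
    samples = [f"a{i}" for i in range(len(G_a))] + [f"b{i}" for i in range(len(G_b))]
    panel = make_panel(G, samples=samples)
    pm = PopulationMap({s: ("A" if s.startswith("a") else "B") for s in samples})
    return panel, pm


class TestPca:
    def test_two_groups_rank_one(self):
        G = np.array([[0, 2, 0, 2]] * 4 + [[2, 0, 2, 0]] * 4)
        res = structure.pca(make_panel(G), k=3)
        assert res.explained_pct[0] == pytest.approx(100.0)
        assert np.sign(res.coords[0, 0]) != np.sign(res.coords[-1, 0])

    def test_sample_permutation_invariance(self, rng):
        panel = random_panel(rng, n_samples=8, n_snps=40)
        res = structure.pca(panel, k=2)
        perm = rng.permutation(8)
        panel2 = make_panel(panel.genotypes[perm],
                            positions=panel.variants["pos"],
                            samples=[panel.samples[i] for i in perm])
        res2 = structure.pca(panel2, k=2)
        inv = np.argsort(perm)
        for comp in range(2):
            a, b = res.coords[:, comp], res2.coords[inv, comp]
            assert (np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8))

    def test_null_panel_has_no_dominant_axis(self, rng):
        vals = []
        for _ in range(5):
            freqs = rng.uniform(0.2, 0.8, 200)
            G = rng.binomial(2, freqs[None, :], size=(20, 200)).astype(np.int8)
            res = structure.pca(make_panel(G), k=5)
            nonzero = res.eigenvalues[res.eigenvalues > 1e-10]
            vals.append(res.eigenvalues[0] / nonzero.mean())
        assert max(vals) < 5.0

    def test_percents_sum_to_100(self, rng):
        panel = random_panel(rng, n_samples=6, n_snps=30)
        res = structure.pca(panel, k=5)
        assert res.eigenvalues.sum() > 0
        assert 100 * res.eigenvalues / res.eigenvalues.sum() == pytest.approx(
            np.concatenate([res.explained_pct,
                            100 * res.eigenvalues[5:] / res.eigenvalues.sum()]))


class TestFst:
    def test_fixed_difference_is_one(self):
        panel, pm = two_pop_panel([[0, 0]] * 3, [[2, 2]] * 3)
        assert structure.pairwise_fst(panel, pm, "A", "B") == pytest.approx(1.0)

    def test_identical_pops_non_positive(self):
        G = [[0, 1], [1, 2], [2, 0]]
        panel, pm = two_pop_panel(G, G)
        assert structure.pairwise_fst(panel, pm, "A", "B") <= 0

    def test_matrix_symmetric_zero_diagonal(self, rng):
        panel = random_panel(rng, n_samples=9, n_snps=30)
        pm = PopulationMap({f"s{i + 1}": f"P{i % 3}" for i in range(9)})
        M = structure.fst_matrix(panel, pm)
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 0)

    def test_small_population_raises(self):
        panel, pm = two_pop_panel([[0, 1]], [[1, 2], [2, 0]])
        with pytest.raises(ValueError, match=">= 2 samples"):
            structure.pairwise_fst(panel, pm, "A", "B")

    def test_matches_scalar_oracle(self, rng):
        """Ratio-of-sums equals a hand-summed per-site implementation."""
        for seed in range(30):
            r = np.random.default_rng(seed)
            m = int(r.integers(2, 10))
            Ga = r.binomial(2, r.uniform(0.1, 0.9, m)[None, :], (4, m))
            Gb = r.binomial(2, r.uniform(0.1, 0.9, m)[None, :], (5, m))
            # keep only sites polymorphic overall so the oracle denominator
            # is never empty
            keep = ((np.vstack([Ga, Gb]).sum(0) > 0)
                    & (np.vstack([Ga, Gb]).sum(0) < 18))
            if keep.sum() == 0:
                continue
            Ga, Gb = Ga[:, keep], Gb[:, keep]
            panel, pm = two_pop_panel(Ga, Gb)
            got = structure.pairwise_fst(panel, pm, "A", "B")
            counts_a = [(4, Ga[:, j].sum(), (Ga[:, j] == 1).sum())
                        for j in range(Ga.shape[1])]
            counts_b = [(5, Gb[:, j].sum(), (Gb[:, j] == 1).sum())
                        for j in range(Gb.shape[1])]
            assert got == pytest.approx(wc_fst_oracle(counts_a, counts_b),
                                        rel=1e-10), f"seed {seed}"


class TestNjTree:
    def test_three_taxon_algebra(self):
        M = pd.DataFrame([[0, 2, 4], [2, 0, 4], [4, 4, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        nwk = structure.nj_tree(M)
        import dendropy
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        lengths = {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(1.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):0.5,C:3,D:4) -> additive distances
        labels = list("ABCD")
        M = pd.DataFrame(
            [[0, 3, 4.5, 5.5], [3, 0, 5.5, 6.5], [4.5, 5.5, 0, 7], [5.5, 6.5, 7, 0]],
            index=labels, columns=labels, dtype=float)
        nwk = structure.nj_tree(M)
        import dendropy
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i in labels:
            for j in labels:
                if i < j:
                    assert pdm.patristic_distance(taxa[i], taxa[j]) == pytest.approx(
                        M.loc[i, j], abs=1e-9)

    def test_star_topology_zero_internal(self):
        labels = list("ABCD")
        M = pd.DataFrame(2.0, index=labels, columns=labels)
        np.fill_diagonal(M.values, 0.0)
        nwk = structure.nj_tree(M)
        import dendropy
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        internal = [e.length for e in tree.preorder_edge_iter()
                    if e.head_node.is_internal() and e.length is not None]
        assert all(abs(x) < 1e-9 for x in internal)

    def test_asymmetric_matrix_raises(self):
        M = pd.DataFrame([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            structure.nj_tree(M)


class TestQMatrix:
    def test_read_with_ids(self, tmp_path):
        p = tmp_path / "q.tsv"
        p.write_text("s1 0.8 0.2\ns2 0.3 0.7\n")
        Q = structure.read_qmatrix(p)
        assert Q.loc["s1", "Q1"] == pytest.approx(0.8)

    def test_bad_row_sum_raises(self, tmp_path):
        p = tmp_path / "q.tsv"
        p.write_text("0.8 0.5\n")
        with pytest.raises(ValueError, match="sum to 1"):
            structure.read_qmatrix(p)
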