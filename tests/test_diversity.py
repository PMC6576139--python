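"""Distances, neighbor joining, PCA and the misassignment screen."""

import io

import numpy as np
import pandas as pd
import pytest
import skbio

from nampop import SimConfig, simulate_founders, simulate_nam
from nampop.diversity import (DistanceMatrix, allele_sharing_distance,
                              flag_misassigned, nj_tree, pca)

from conftest import genotypes_from_codes


def dm_from(ids, values):
    values = np.asarray(values, float)
    n = len(ids)
    return DistanceMatrix(np.asarray(ids, object), values,
                          np.full((n, n), 1000), np.zeros((n, n), bool))


def random_additive_tree(n_taxa, rng):
    """Random binary tree with positive branch lengths and its leaf-to-leaf
    distance matrix (independent oracle for NJ recovery)."""
    labels = [f"t{i:02d}" for i in range(n_taxa)]
    nodes = [(skbio.TreeNode(name=l), l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        (a, _), (b, _) = nodes[i], nodes[j]
        a.length = float(rng.uniform(0.1, 1.0))
        b.length = float(rng.uniform(0.1, 1.0))
        parent = skbio.TreeNode(children=[a, b])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append((parent, ""))
    tree = nodes[0][0]
    d = np.zeros((n_taxa, n_taxa))
    tip = {t.name: t for t in tree.tips()}
    for x in range(n_taxa):
        for y in range(x + 1, n_taxa):
            d[x, y] = d[y, x] = tip[labels[x]].distance(tip[labels[y]])
    return tree, labels, d


class TestDistance:
    def test_identity_opposite_and_half(self):
        codes = np.array([[0, 0, 0], [0, 0, 0], [2, 2, 2], [1, 1, 1]], np.int8)
        D = allele_sharing_distance(genotypes_from_codes(codes), min_shared=1)
        assert D.values[0, 1] == pytest.approx(0.0)
        assert D.values[0, 2] == pytest.approx(1.0)
        assert D.values[0, 3] == pytest.approx(0.5)
        np.testing.assert_allclose(D.values, D.values.T)
        assert (np.diag(D.values) == 0).all()

    def test_low_confidence_flag_and_missing_pairs(self):
        codes = np.array([[0, -1], [-1, 2]], np.int8)
        D = allele_sharing_distance(genotypes_from_codes(codes), min_shared=1)
        assert np.isnan(D.values[0, 1])  # zero shared calls
        assert not D.is_complete()

    def test_invariance_marker_order_and_allele_swap(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 3, (20, 50)).astype(np.int8)
        G = genotypes_from_codes(codes)
        base = allele_sharing_distance(G).values
        perm = rng.permutation(50)
        a = allele_sharing_distance(G.take_markers(perm)).values
        b = allele_sharing_distance(
            genotypes_from_codes((2 - codes).astype(np.int8))).values
        np.testing.assert_allclose(base, a, atol=1e-12)
        np.testing.assert_allclose(base, b, atol=1e-12)


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # distances from ((A:1,B:2):1,(C:3,D:4)): additive, so NJ recovers
        # the generating tree with exact branch lengths
        d = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], float)
        t = nj_tree(dm_from(list("ABCD"), d))
        tips = {x.name: x for x in t.tips()}
        assert set(tips) == set("ABCD")
        assert tips["A"].length == pytest.approx(1.0)
        assert tips["B"].length == pytest.approx(2.0)
        # additivity round-trip: tree distances reproduce the input matrix
        for i, x in enumerate("ABCD"):
            for j, y in enumerate("ABCD"):
                if i < j:
                    assert tips[x].distance(tips[y]) == pytest.approx(d[i, j])

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
        t = nj_tree(dm_from(list("XYZ"), d))
        tips = {x.name: x for x in t.tips()}
        assert tips["X"].length == pytest.approx(0.5 * (4 + 6 - 8))
        assert tips["Y"].length == pytest.approx(0.5 * (4 + 8 - 6))
        assert tips["Z"].length == pytest.approx(0.5 * (6 + 8 - 4))

    def test_matches_reference_implementation_on_additive_matrices(self):
        rng = np.random.default_rng(31)
        for rep in range(20):
            n = int(rng.integers(4, 13))
            truth, labels, d = random_additive_tree(n, rng)
            ours = nj_tree(dm_from(labels, d))
            ref = skbio.tree.nj(skbio.DistanceMatrix(d, labels))
            assert ours.compare_rfd(ref) == 0.0
            assert ours.compare_rfd(truth) == 0.0

    def test_incomplete_matrix_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            nj_tree(dm_from(list("ABC"), d))

    def test_family_monophyly_on_simulated_rils(self):
        # a wheat-like karyotype: many chromosomes give enough independent
        # loci for family clades to resolve
        from nampop import GenomeModel
        genome = GenomeModel.regular(n_chromosomes=14,
                                     chrom_length_bp=100_000_000,
                                     chrom_length_cm=100.0,
                                     markers_per_chromosome=40)
        hits = 0
        reps = 20
        for rep in range(reps):
            panel = simulate_founders(genome, 5, 0.5, seed=500 + rep)
            sim = SimConfig(n_families=4, rils_per_family=6, seed=500 + rep)
            G, _ = simulate_nam(panel, genome, sim)
            tree = nj_tree(allele_sharing_distance(G))
            fam = dict(zip(G.sample_ids, G.families))
            clades = {frozenset(t.name for t in node.tips())
                      for node in tree.non_tips()} | {
                      frozenset([t.name]) for t in tree.tips()}
            # an unrooted split is a clade on either side
            all_leaves = frozenset(G.sample_ids)
            ok = True
            for f in set(G.families):
                members = frozenset(s for s in G.sample_ids if fam[s] == f)
                if members not in clades and (all_leaves - members) not in clades:
                    ok = False
            hits += ok
        assert hits >= 0.95 * reps


class TestPca:
    def test_identical_rows_zero_variance(self):
        codes = np.tile(np.array([0, 1, 2, 0], np.int8), (5, 1))
        with pytest.warns(UserWarning, match="constant"):
            scores, explained = pca(genotypes_from_codes(codes))
        assert scores.empty and explained.size == 0

    def test_two_divergent_families_separate_on_pc1(self):
        from nampop import GenomeModel
        genome = GenomeModel.regular(n_chromosomes=14,
                                     chrom_length_bp=100_000_000,
                                     chrom_length_cm=100.0,
                                     markers_per_chromosome=40)
        panel = simulate_founders(genome, 3, 0.5, seed=9)
        sim = SimConfig(n_families=2, rils_per_family=30, seed=9)
        G, _ = simulate_nam(panel, genome, sim)
        scores, _ = pca(G, n_components=2)
        pc1 = scores["PC1"]
        f1 = pc1[G.families == "fam01"]
        f2 = pc1[G.families == "fam02"]
        assert (f1.max() < f2.min()) or (f2.max() < f1.min())

    def test_explained_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(14)
        codes = rng.integers(0, 3, (40, 25)).astype(np.int8)
        G = genotypes_from_codes(codes)
        scores, explained = pca(G, n_components=5)
        # eigendecomposition oracle: fractions are eigenvalue ratios of the
        # marker cross-product matrix
        x = codes - codes.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(x.T @ x))[::-1]
        expect = evals[:5] / np.sum(x ** 2)
        np.testing.assert_allclose(explained, expect, atol=1e-8)
        assert np.all(np.diff(explained) <= 1e-12)
        assert explained.sum() <= 1.0 + 1e-9

    def test_scores_sample_order_invariant_up_to_sign(self):
        rng = np.random.default_rng(15)
        codes = rng.integers(0, 3, (30, 20)).astype(np.int8)
        G = genotypes_from_codes(codes)
        perm = rng.permutation(30)
        s1, _ = pca(G, 3)
        s2, _ = pca(G.take_samples(perm), 3)
        for c in s1.columns:
            a = s1[c].loc[s2.index]
            agree = np.allclose(a, s2[c], atol=1e-8)
            flipped = np.allclose(a, -s2[c], atol=1e-8)
            assert agree or flipped


@pytest.fixture(scope="module")
def nam():
    from nampop import GenomeModel
    genome = GenomeModel.regular(n_chromosomes=14, chrom_length_bp=100_000_000,
                                 chrom_length_cm=100.0, markers_per_chromosome=40)
    panel = simulate_founders(genome, 5, 0.5, seed=123)
    sim = SimConfig(n_families=3, rils_per_family=15, seed=123)
    return simulate_nam(panel, genome, sim)


class TestMisassignment:

    def test_relabeled_sample_flagged(self, nam):
        G, _ = nam
        fams = G.families.copy()
        victim = np.flatnonzero(fams == "fam01")[0]
        fams[victim] = "fam02"
        G2 = type(G)(G.calls, G.sample_ids, G.marker_ids, fams, G.is_founder)
        flags = flag_misassigned(G2)
        assert G.sample_ids[victim] in set(flags["sample"])

    def test_clean_labels_no_flags(self, nam):
        G, _ = nam
        assert flag_misassigned(G).empty

    def test_margin_one_disables_flagging(self, nam):
        G, _ = nam
        fams = G.families.copy()
        fams[0] = "fam02"
        G2 = type(G)(G.calls, G.sample_ids, G.marker_ids, fams, G.is_founder)
        assert flag_misassigned(G2, margin=1.0).empty
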