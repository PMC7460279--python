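import io as _io

import numpy as np
import pytest
from helpers import build_ds
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from oracles import naive_ibs, random_tree_distances
from skbio import TreeNode as SkbioTree
from skbio.tree import nj as skbio_nj
from skbio import DistanceMatrix as SkbioDM

from galdiv import (
    MISSING,
    BreedConfig,
    DistanceMatrix,
    GaldivError,
    SimConfig,
    breed_average_mds,
    classical_mds,
    ibs_distance,
    neighbor_joining,
    reynolds_distance,
    simulate_dataset,
    write_newick,
)

M = MISSING


def tip_distance_matrix(tree, labels):
    out = np.zeros((len(labels), len(labels)))
    tips = {t.name: t for t in tree.tips()}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                out[i, j] = out[j, i] = tips[a].distance(tips[b])
    return out


class TestIBS:
    def test_identical_individuals_have_zero_distance(self):
        calls = np.array([[0, 1, 2, 1], [0, 1, 2, 1]], dtype=np.int8)
        d = ibs_distance(build_ds(calls)).d
        assert d[0, 1] == 0.0

    def test_opposite_homozygotes_have_distance_one(self):
        calls = np.array([[0, 0, 0], [2, 2, 2]], dtype=np.int8)
        assert ibs_distance(build_ds(calls)).d[0, 1] == 1.0

    def test_hand_arithmetic_half_distance(self):
        # a = {0,1}, b = {2,1}: similarities {0,1} -> distance 0.5
        calls = np.array([[0, 1], [2, 1]], dtype=np.int8)
        assert ibs_distance(build_ds(calls)).d[0, 1] == pytest.approx(0.5)

    def test_missing_pair_requires_flag(self):
        calls = np.array([[0, M], [M, 2]], dtype=np.int8)
        with pytest.raises(GaldivError, match="share no typed markers"):
            ibs_distance(build_ds(calls))
        d = ibs_distance(build_ds(calls), allow_missing_pairs=True).d
        assert np.isnan(d[0, 1])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        hnp.arrays(np.int8, (5, 15), elements=st.sampled_from([-1, 0, 1, 2]))
    )
    def test_metric_axioms_hold_on_arbitrary_datasets(self, calls):
        calls = calls.copy()
        calls[:, 0] = 0  # every pair shares a typed marker
        d = ibs_distance(build_ds(calls)).d
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 1).all()

    def test_matches_naive_double_loop_with_missing(self, rng):
        calls = rng.integers(-1, 3, size=(12, 80)).astype(np.int8)
        calls[:, 0] = 0  # guarantee every pair shares a marker
        d = ibs_distance(build_ds(calls)).d
        assert np.allclose(d, naive_ibs(calls), atol=1e-12)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)


class TestClassicalMDS:
    def test_collinear_points_embed_exactly_in_one_dimension(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        res = classical_mds(DistanceMatrix(["a", "b", "c"], d), k=1)
        y = res.coordinates.to_numpy().ravel()
        got = np.abs(y[:, None] - y[None, :])
        assert np.allclose(got, d, atol=1e-9)

    def test_zero_matrix_embeds_at_origin(self):
        d = np.zeros((4, 4))
        res = classical_mds(DistanceMatrix(list("abcd"), d), k=2)
        assert np.allclose(res.coordinates.to_numpy(), 0.0)

    def test_euclidean_config_reproduced_to_1e9(self, rng):
        X = rng.normal(size=(6, 3))
        d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        res = classical_mds(DistanceMatrix([f"p{i}" for i in range(6)], d), k=5)
        Y = res.coordinates.to_numpy()
        d2 = np.sqrt(((Y[:, None, :] - Y[None, :, :]) ** 2).sum(-1))
        assert np.allclose(d, d2, atol=1e-9)

    def test_k_reduced_with_warning_when_rank_is_low(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        with pytest.warns(UserWarning, match="positive eigenvalue"):
            res = classical_mds(DistanceMatrix(["a", "b", "c"], d), k=3)
        assert res.coordinates.shape[1] < 3


class TestReynolds:
    def two_breed_ds(self, calls_x, calls_y):
        calls = np.vstack([calls_x, calls_y]).astype(np.int8)
        return build_ds(calls, breeds=["X"] * len(calls_x) + ["Y"] * len(calls_y))

    def test_identical_frequencies_give_zero(self):
        block = np.array([[0, 1], [2, 1]])
        d = reynolds_distance(self.two_breed_ds(block, block)).d
        assert d[0, 1] == pytest.approx(0.0)

    def test_fixed_opposite_locus_gives_one(self):
        # one locus, p_x = 1, p_y = 0 -> theta = 2/2 = 1
        x = np.array([[2], [2]])
        y = np.array([[0], [0]])
        d = reynolds_distance(self.two_breed_ds(x, y)).d
        assert d[0, 1] == pytest.approx(1.0)

    def test_symmetry_on_random_frequency_pairs(self, rng):
        calls = rng.integers(0, 3, size=(20, 100)).astype(np.int8)
        ds = build_ds(calls, breeds=["X"] * 7 + ["Y"] * 6 + ["Z"] * 7)
        d = reynolds_distance(ds).d
        assert np.allclose(d, d.T)
        assert (d >= 0).all()

    def test_linearized_exceeds_theta(self, rng):
        calls = rng.integers(0, 3, size=(12, 200)).astype(np.int8)
        ds = build_ds(calls, breeds=["X"] * 6 + ["Y"] * 6)
        theta = reynolds_distance(ds).d[0, 1]
        lin = reynolds_distance(ds, linearized=True).d[0, 1]
        assert lin >= theta > 0


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert np.allclose(tip_distance_matrix(tree, labels), d, atol=1e-9)

    def test_permuting_labels_gives_isomorphic_tree(self, rng):
        labels, d = random_tree_distances(6, rng)
        perm = rng.permutation(6)
        t1 = neighbor_joining(DistanceMatrix(labels, d))
        t2 = neighbor_joining(
            DistanceMatrix([labels[i] for i in perm], d[np.ix_(perm, perm)])
        )
        assert np.allclose(
            tip_distance_matrix(t1, labels), tip_distance_matrix(t2, labels), atol=1e-9
        )

    def test_agrees_with_skbio_nj_oracle(self, rng):
        labels, d = random_tree_distances(7, rng)
        mine = neighbor_joining(DistanceMatrix(labels, d))
        theirs = skbio_nj(SkbioDM(d, ids=labels))
        assert np.allclose(
            tip_distance_matrix(mine, labels),
            tip_distance_matrix(theirs, labels),
            atol=1e-9,
        )

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(GaldivError, match="symmetric"):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], d))


class TestNewick:
    def test_three_leaf_star_shape(self):
        d = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float)
        nwk = write_newick(neighbor_joining(DistanceMatrix(["A", "B", "C"], d)))
        assert nwk == "(A:1,B:1,C:1);"

    def test_round_trip_parse_is_isomorphic(self, rng):
        labels, d = random_tree_distances(6, rng)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        parsed = SkbioTree.read(_io.StringIO(write_newick(tree)))
        assert np.allclose(
            tip_distance_matrix(tree, labels),
            tip_distance_matrix(parsed, labels),
            atol=1e-5,  # 6 significant digits in serialization
        )

    def test_metacharacter_label_is_quoted(self):
        d = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float)
        nwk = write_newick(
            neighbor_joining(DistanceMatrix(["Hy-line(w)", "B", "C"], d))
        )
        assert "'Hy-line(w)'" in nwk
        parsed = SkbioTree.read(_io.StringIO(nwk))
        assert {t.name for t in parsed.tips()} == {"Hy-line(w)", "B", "C"}


class TestStructureOnSimulatedBreeds:
    def test_mds_separates_diverged_pools_and_nj_pairs_clades(self):
        """Three diverged pools separate in C1/C2; clade mates are NJ neighbors."""
        cfg = SimConfig(
            n_chrom=2,
            snps_per_chrom=600,
            chrom_length_bp=12_000_000,
            breeds=[
                BreedConfig("PAD1", 10, divergence=0.04, clade="PAD"),
                BreedConfig("PAD2", 10, divergence=0.04, clade="PAD"),
                BreedConfig("FAR1", 10, divergence=0.35),
                BreedConfig("FAR2", 10, divergence=0.35),
            ],
            clade_divergence=0.3,
            seed=17,
        )
        ds, _ = simulate_dataset(cfg)
        res = breed_average_mds(ds, k=2)
        coords = res.coordinates
        # breed centroids must be mutually distinct in the C1/C2 plane
        pts = coords.to_numpy()
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                assert np.linalg.norm(pts[i] - pts[j]) > 1e-3
        # clade members are each other's nearest centroid
        dists = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        idx = {b: k for k, b in enumerate(coords.index)}
        assert dists[idx["PAD1"]].argmin() == idx["PAD2"]

        tree = neighbor_joining(reynolds_distance(ds))
        pad1 = tree.find("PAD1")
        siblings = {t.name for t in pad1.parent.children if t.is_tip()}
        assert "PAD2" in siblings
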