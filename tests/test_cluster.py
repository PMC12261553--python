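"""Distance transform, agglomerative clustering, bootstrap stability, k selection."""

import numpy as np
import pandas as pd
import pytest

from palliseq import (
    adjusted_rand_index,
    agglomerative_cluster,
    archetype_config,
    bootstrap_stability,
    dendrogram_newick,
    encode_cohort,
    generate_claims,
    pairwise_similarity_matrix,
    select_als_cohort,
    select_num_clusters,
    similarity_to_distance,
)


def two_block_distance(sizes=(5, 5), within=0.0, between=0.9):
    n = sum(sizes)
    D = np.full((n, n), between)
    start = 0
    for size in sizes:
        D[start:start + size, start:start + size] = within
        start += size
    np.fill_diagonal(D, 0.0)
    return D


@pytest.fixture(scope="module")
def archetype_distance():
    """Distance matrix and planted labels for 60 three-archetype pathways."""
    claims = generate_claims(archetype_config(n=60, seed=5))
    cohort = select_als_cohort(claims)
    sequences = encode_cohort(cohort)
    S = pairwise_similarity_matrix(sequences)
    truth = dict(zip(claims.truth.individual_id, claims.truth.template_name))
    return similarity_to_distance(S), truth


@pytest.fixture(scope="module")
def sharp_archetype_distance():
    """Archetype distances with wider timing dispersion: the 3-way partition
    stays perfectly stable while neighboring k become genuinely ambiguous."""
    claims = generate_claims(archetype_config(n=30, seed=5, sigma=0.6))
    sequences = encode_cohort(select_als_cohort(claims))
    return similarity_to_distance(pairwise_similarity_matrix(sequences))


class TestDistanceTransform:
    def test_unit_similarity_maps_to_zero_distance(self):
        S = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]])
        D = similarity_to_distance(S)
        assert (D.values == 0).all()

    def test_complement_arithmetic(self):
        S = pd.DataFrame([[1.0, 0.1225], [0.1225, 1.0]])
        assert similarity_to_distance(S).iloc[0, 1] == pytest.approx(0.8775)

    def test_diagonal_zero_for_any_valid_similarity(self):
        S = pd.DataFrame([[1.0, 0.4, 0.2], [0.4, 1.0, 0.7], [0.2, 0.7, 1.0]])
        assert (np.diag(similarity_to_distance(S)) == 0).all()

    def test_asymmetry_rejected(self):
        S = pd.DataFrame([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(ValueError, match="asymmetric"):
            similarity_to_distance(S)

    def test_out_of_range_entries_rejected(self):
        S = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="0, 1"):
            similarity_to_distance(S)


class TestAgglomerative:
    def test_two_tight_groups_recovered(self):
        D = two_block_distance()
        labels = agglomerative_cluster(D, 2)
        assert list(labels[:5]) == [1] * 5
        assert list(labels[5:]) == [2] * 5

    def test_k_equals_n_minus_one_merges_closest_pair(self):
        D = np.array(
            [
                [0.0, 0.1, 0.8, 0.9],
                [0.1, 0.0, 0.7, 0.85],
                [0.8, 0.7, 0.0, 0.95],
                [0.9, 0.85, 0.95, 0.0],
            ]
        )
        labels = agglomerative_cluster(D, 3)
        assert labels[0] == labels[1]  # global minimum pair merged
        assert len(set(labels)) == 3

    def test_labels_canonical_by_size_then_position(self):
        D = two_block_distance(sizes=(3, 7))
        labels = agglomerative_cluster(D, 2)
        assert list(labels[3:]) == [1] * 7  # larger cluster gets id 1
        assert list(labels[:3]) == [2] * 3

    def test_out_of_range_k_rejected(self):
        D = two_block_distance()
        with pytest.raises(ValueError, match="k="):
            agglomerative_cluster(D, 1)
        with pytest.raises(ValueError, match="k="):
            agglomerative_cluster(D, 10)

    def test_archetype_recovery_at_true_k(self, archetype_distance):
        D, truth = archetype_distance
        labels = agglomerative_cluster(D.values, 3)
        by_id = dict(zip(D.index, (int(c) for c in labels)))
        assert adjusted_rand_index(by_id, {i: truth[i] for i in D.index}) >= 0.9


class TestAdjustedRand:
    def test_identical_partitions(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_hand_computed_negative_case(self):
        assert adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)

    def test_singletons_vs_single_cluster(self):
        assert adjusted_rand_index([1, 2, 3, 4], [1, 1, 1, 1]) == pytest.approx(0.0)

    def test_invariant_under_label_permutation(self):
        a = [1, 1, 2, 2, 3]
        b = [3, 3, 1, 1, 2]
        assert adjusted_rand_index(a, b) == 1.0

    def test_mismatched_id_sets_rejected(self):
        with pytest.raises(ValueError, match="id sets"):
            adjusted_rand_index({"a": 1, "b": 2}, {"a": 1, "c": 2})


class TestBootstrapStability:
    def test_zero_resamples_rejected(self):
        with pytest.raises(ValueError, match="B"):
            bootstrap_stability(two_block_distance(), 2, B=0)

    def test_separated_blocks_perfectly_stable(self):
        D = two_block_distance(sizes=(8, 8), within=0.05, between=0.95)
        rng = np.random.default_rng(3)
        D += rng.uniform(0, 0.01, D.shape)
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        assert bootstrap_stability(D, 2, B=30, seed=1) == 1.0

    def test_stability_peaks_at_planted_k(self, sharp_archetype_distance):
        D = sharp_archetype_distance
        scores = {k: bootstrap_stability(D.values, k, B=30, seed=2) for k in (2, 3, 4)}
        assert scores[3] == max(scores.values())
        assert scores[3] - scores[2] >= 0.05
        assert scores[3] - scores[4] >= 0.05


class TestSelection:
    def test_degenerate_range_returns_kmin(self):
        D = two_block_distance()
        solution = select_num_clusters(pd.DataFrame(D), 2, 2, B=5, seed=0)
        assert solution.k == 2

    def test_archetype_range_selects_three(self, archetype_distance):
        D, truth = archetype_distance
        solution = select_num_clusters(D, 2, 6, B=30, seed=4)
        assert solution.k == 3
        ari = adjusted_rand_index(
            solution.labels, {i: truth[i] for i in solution.labels}
        )
        assert ari >= 0.9
        assert set(solution.stability) == {2, 3, 4, 5, 6}

    def test_selection_deterministic_given_seed(self, archetype_distance):
        D, _ = archetype_distance
        a = select_num_clusters(D, 2, 4, B=10, seed=7)
        b = select_num_clusters(D, 2, 4, B=10, seed=7)
        assert a.k == b.k
        assert a.labels == b.labels
        assert a.stability == b.stability
        assert a.newick == b.newick


class TestNewick:
    def test_leaf_names_round_trip(self):
        from skbio import TreeNode
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        D = two_block_distance(sizes=(2, 3))
        ids = [f"P{i}" for i in range(5)]
        Z = linkage(squareform(D, checks=False), method="average")
        newick = dendrogram_newick(Z, ids)
        tree = TreeNode.read([newick])
        assert {t.name for t in tree.tips()} == set(ids)
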