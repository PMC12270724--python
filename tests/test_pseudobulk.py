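"""KNN graph, neighborhood sampling and the VDJ usage feature space."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from vdjtraj.pseudobulk import (
    NeighborhoodSet,
    exact_knn,
    knn_graph,
    make_neighborhoods,
    vdj_feature_space,
)


def _space(coords):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[1] == 1:
        coords = np.hstack([coords, np.zeros_like(coords)])
    return pd.DataFrame(
        coords, index=[f"c{i}" for i in range(len(coords))]
    )


class TestKnnGraph:
    def test_collinear_points_hand_geometry(self):
        g = knn_graph(_space([[0.0], [1.0], [10.0]]), k=1)
        adj = g.adjacency.toarray()
        assert adj[0, 1] and adj[1, 0]
        assert adj[1, 2] and adj[2, 1]
        assert not adj[0, 2]

    def test_k_equals_n_minus_one_gives_complete_graph(self):
        g = knn_graph(_space([[0.0], [1.0], [2.0], [5.0]]), k=3)
        adj = g.adjacency.toarray()
        assert (adj.sum(axis=1) == 3).all()

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError, match="k"):
            knn_graph(_space([[0.0], [1.0]]), k=2)

    def test_distance_ties_broken_by_lower_index(self):
        # three coincident points: each picks the lowest other index
        _, idx = exact_knn(np.zeros((3, 2)), k=1)
        assert idx.ravel().tolist() == [1, 0, 0]


class TestMakeNeighborhoods:
    def test_full_proportion_without_refinement(self):
        g = knn_graph(_space([[0.0], [1.0], [2.0], [3.0], [4.0]]), k=2)
        nh = make_neighborhoods(g, proportion=1.0, seed=0, refined=False)
        assert nh.n_nhoods == 5
        assert (nh.sizes() == 3).all()

    def test_each_neighborhood_contains_its_index_cell(self):
        rng = np.random.default_rng(0)
        g = knn_graph(_space(rng.normal(size=(40, 3))), k=5)
        nh = make_neighborhoods(g, proportion=0.5, seed=3, refined=True)
        M = nh.membership.toarray()
        assert all(M[c, j] for j, c in enumerate(nh.index_cells))

    def test_seeded_determinism_and_seed_sensitivity(self):
        rng = np.random.default_rng(1)
        g = knn_graph(_space(rng.normal(size=(60, 3))), k=6)
        a1 = make_neighborhoods(g, proportion=0.2, seed=11, refined=False)
        a2 = make_neighborhoods(g, proportion=0.2, seed=11, refined=False)
        b = make_neighborhoods(g, proportion=0.2, seed=12, refined=False)
        assert (a1.membership != a2.membership).nnz == 0
        assert set(a1.index_cells) != set(b.index_cells)

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_invalid_proportion_raises(self, bad):
        g = knn_graph(_space([[0.0], [1.0], [2.0]]), k=1)
        with pytest.raises(ValueError, match="proportion"):
            make_neighborhoods(g, proportion=bad)


def _cells_table(records):
    """records: cell_id -> dict of chain-call columns (+ cell_type)."""
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = "cell_id"
    for col in ("TRA_v", "TRA_j", "TRA_c", "TRB_v", "TRB_d", "TRB_j", "TRB_c"):
        if col not in df.columns:
            df[col] = None
    if "cell_type" not in df.columns:
        df["cell_type"] = "T"
    return df


def _manual_nhoods(cell_ids, memberships, k=1):
    M = np.zeros((len(cell_ids), len(memberships)), dtype=bool)
    for j, members in enumerate(memberships):
        M[members, j] = True
    return NeighborhoodSet(
        membership=sp.csr_matrix(M),
        cell_ids=np.array(cell_ids, dtype=object),
        index_cells=np.array([m[0] for m in memberships]),
        k=k,
    )


class TestVdjFeatureSpace:
    def test_unanimous_gene_gets_fraction_one(self):
        cells = _cells_table(
            {"a": {"TRA_v": "TRAV1"}, "b": {"TRA_v": "TRAV1"}}
        )
        nh = _manual_nhoods(["a", "b"], [[0, 1]])
        fs = vdj_feature_space(cells, nh)
        assert fs.features.loc[:, "TRA_v:TRAV1"].iloc[0] == 1.0

    def test_split_usage_sums_to_one(self):
        cells = _cells_table(
            {"a": {"TRA_v": "TRAV1"}, "b": {"TRA_v": "TRAV2"}}
        )
        nh = _manual_nhoods(["a", "b"], [[0, 1]])
        fs = vdj_feature_space(cells, nh)
        assert fs.features.iloc[0]["TRA_v:TRAV1"] == 0.5
        assert fs.features.iloc[0]["TRA_v:TRAV2"] == 0.5

    def test_missing_calls_renormalised_out_of_denominator(self):
        cells = _cells_table(
            {
                "a": {"TRB_d": "TRBD1"},
                "b": {"TRB_d": None},  # missing D call
                "c": {"TRB_d": "TRBD1"},
            }
        )
        nh = _manual_nhoods(["a", "b", "c"], [[0, 1, 2]])
        fs = vdj_feature_space(cells, nh, renormalize_missing=True)
        assert fs.features.iloc[0]["TRB_d:TRBD1"] == 1.0
        fs2 = vdj_feature_space(cells, nh, renormalize_missing=False)
        assert fs2.features.iloc[0]["TRB_d:TRBD1"] == pytest.approx(2 / 3)

    def test_category_simplex_on_random_fixture(self):
        rng = np.random.default_rng(42)
        n = 60
        records = {
            f"c{i}": {
                "TRA_v": f"TRAV{rng.integers(5)+1}",
                "TRA_j": f"TRAJ{rng.integers(8)+1}",
                "TRB_v": f"TRBV{rng.integers(6)+1}",
                "TRB_d": None if rng.random() < 0.4 else f"TRBD{rng.integers(2)+1}",
                "TRB_j": f"TRBJ{rng.integers(4)+1}",
            }
            for i in range(n)
        }
        cells = _cells_table(records)
        memberships = [
            sorted(rng.choice(n, size=rng.integers(2, 8), replace=False).tolist())
            for _ in range(15)
        ]
        nh = _manual_nhoods(list(cells.index), memberships)
        fs = vdj_feature_space(cells, nh)
        for (locus, seg), cols in fs.category_columns().items():
            sums = fs.features[cols].sum(axis=1).to_numpy()
            counted = sums > 0  # categories with at least one counted cell
            assert np.allclose(sums[counted], 1.0, atol=1e-9)

    def test_feature_count_is_number_of_distinct_observed_genes(self):
        cells = _cells_table(
            {
                "a": {"TRA_v": "TRAV1", "TRA_j": "TRAJ1"},
                "b": {"TRA_v": "TRAV2", "TRA_j": "TRAJ1"},
            }
        )
        nh = _manual_nhoods(["a", "b"], [[0, 1]])
        fs = vdj_feature_space(cells, nh)
        assert fs.features.shape[1] == 3  # TRAV1, TRAV2, TRAJ1
        # adding a cell reusing observed genes adds no feature
        cells2 = pd.concat(
            [cells, _cells_table({"c": {"TRA_v": "TRAV1", "TRA_j": "TRAJ1"}})]
        )
        nh2 = _manual_nhoods(["a", "b", "c"], [[0, 1, 2]])
        assert vdj_feature_space(cells2, nh2).features.shape[1] == 3

    def test_cell_order_permutation_invariance(self):
        rng = np.random.default_rng(3)
        records = {
            f"c{i}": {"TRA_v": f"TRAV{rng.integers(3)+1}"} for i in range(10)
        }
        cells = _cells_table(records)
        nh = _manual_nhoods(list(cells.index), [[0, 1, 2], [3, 4, 5, 6]])
        fs1 = vdj_feature_space(cells, nh)
        fs2 = vdj_feature_space(cells.sample(frac=1.0, random_state=1), nh)
        pd.testing.assert_frame_equal(fs1.features, fs2.features)

    def test_majority_label_and_fraction(self):
        cells = _cells_table(
            {
                "a": {"TRA_v": "TRAV1", "cell_type": "DP"},
                "b": {"TRA_v": "TRAV1", "cell_type": "DP"},
                "c": {"TRA_v": "TRAV1", "cell_type": "SP"},
            }
        )
        nh = _manual_nhoods(["a", "b", "c"], [[0, 1, 2]])
        fs = vdj_feature_space(cells, nh)
        assert fs.nhood_labels.iloc[0] == "DP"
        assert fs.label_fractions.iloc[0] == pytest.approx(2 / 3)
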