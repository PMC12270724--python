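"""KNN neighborhoods over a reduced expression space and the VDJ feature space.

Cells are grouped into overlapping neighborhoods (an index cell plus its k
exact nearest neighbours in, say, PCA space) and each neighborhood is
treated as a pseudobulk. Within each pseudobulk the usage of every V/D/J
gene is tabulated into usage fractions, turning categorical receptor gene
calls into a continuous neighborhoods x genes feature matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from .io import VDJ_LOCI

logger = logging.getLogger(__name__)


def exact_knn(coords: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact Euclidean k-nearest neighbours with deterministic tie-breaking.

    Returns ``(dist, idx)`` of shape (n, k); ties in distance are broken by
    the lower cell index, self is excluded.
    """
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of points ({n})")
    dist = cdist(coords, coords)
    np.fill_diagonal(dist, np.inf)
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), dist), axis=1)
    idx = order[:, :k]
    rows = np.arange(n)[:, None]
    return dist[rows, idx], idx


@dataclass
class KnnGraph:
    """Undirected union-of-KNN graph plus the directed neighbour lists."""

    cell_ids: np.ndarray
    coords: np.ndarray
    k: int
    knn_idx: np.ndarray  # (n, k) directed nearest-neighbour indices
    knn_dist: np.ndarray
    adjacency: sp.csr_matrix  # symmetric boolean union of directed edges

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def knn_graph(space: pd.DataFrame, k: int = 30) -> KnnGraph:
    """Build the exact KNN graph over a cells x dims coordinate frame."""
    coords = np.asarray(space.to_numpy(dtype=float))
    n = coords.shape[0]
    dist, idx = exact_knn(coords, k)
    rows = np.repeat(np.arange(n), k)
    adj = sp.coo_matrix(
        (np.ones(n * k, dtype=bool), (rows, idx.ravel())), shape=(n, n)
    ).tocsr()
    adj = (adj + adj.T).astype(bool).tocsr()
    return KnnGraph(
        cell_ids=space.index.to_numpy(dtype=object),
        coords=coords,
        k=k,
        knn_idx=idx,
        knn_dist=dist,
        adjacency=adj,
    )


@dataclass
class NeighborhoodSet:
    """Overlapping pseudobulks: binary cells x neighborhoods membership."""

    membership: sp.csr_matrix  # cells x n_nhoods, boolean
    cell_ids: np.ndarray
    index_cells: np.ndarray  # index-cell position per neighborhood
    k: int

    @property
    def n_nhoods(self) -> int:
        return self.membership.shape[1]

    @property
    def nhood_ids(self) -> np.ndarray:
        """Neighborhoods are named after their index cell."""
        return self.cell_ids[self.index_cells]

    def sizes(self) -> np.ndarray:
        return np.asarray(self.membership.sum(axis=0)).ravel()


def make_neighborhoods(
    graph: KnnGraph,
    proportion: float = 0.1,
    seed: int = 0,
    refined: bool = True,
) -> NeighborhoodSet:
    """Sample index cells and form their (k+1)-neighborhoods.

    A fraction ``proportion`` of cells is sampled as candidate index cells;
    with ``refined`` each candidate is replaced by the member of its own
    (k+1)-neighborhood closest to that neighborhood's coordinate mean,
    which stabilises the sampling. Identical index cells are deduplicated.
    """
    if not 0 < proportion <= 1:
        raise ValueError(f"proportion must be in (0, 1], got {proportion}")
    n = graph.n_cells
    rng = np.random.default_rng(seed)
    n_candidates = int(np.ceil(proportion * n))
    candidates = rng.choice(n, size=n_candidates, replace=False)
    if refined:
        refined_idx = np.empty(n_candidates, dtype=int)
        for i, c in enumerate(candidates):
            members = np.concatenate(([c], graph.knn_idx[c]))
            centre = graph.coords[members].mean(axis=0)
            d = np.linalg.norm(graph.coords[members] - centre, axis=1)
            # ties -> lower cell index wins
            best = members[np.lexsort((members, d))[0]]
            refined_idx[i] = best
        candidates = refined_idx
    index_cells = np.unique(candidates)
    n_nhoods = len(index_cells)
    rows, cols = [], []
    for j, c in enumerate(index_cells):
        members = np.concatenate(([c], graph.knn_idx[c]))
        rows.append(np.unique(members))
        cols.append(np.full(len(rows[-1]), j))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    membership = sp.coo_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)), shape=(n, n_nhoods)
    ).tocsr()
    logger.info(
        "make_neighborhoods: %d neighborhood(s) of target size %d over %d cell(s)",
        n_nhoods,
        graph.k + 1,
        n,
    )
    return NeighborhoodSet(
        membership=membership,
        cell_ids=graph.cell_ids,
        index_cells=index_cells,
        k=graph.k,
    )


@dataclass
class VdjFeatureSpace:
    """Neighborhoods x V/D/J-gene matrix of usage fractions.

    Feature names are ``<locus>_<segment>:<gene>`` and ``categories`` maps
    each feature to its (locus, segment) group. ``nhood_labels`` holds the
    majority cell-type label of each pseudobulk and ``label_fractions`` the
    fraction of member cells carrying it.
    """

    features: pd.DataFrame  # n_nhoods x n_features
    categories: dict[str, tuple[str, str]]
    nhood_labels: pd.Series
    label_fractions: pd.Series
    renormalize_missing: bool = True

    @property
    def n_nhoods(self) -> int:
        return self.features.shape[0]

    def category_columns(self) -> dict[tuple[str, str], list[str]]:
        groups: dict[tuple[str, str], list[str]] = {}
        for name, cat in self.categories.items():
            groups.setdefault(cat, []).append(name)
        return groups


def _segments_for(locus: str) -> tuple[str, ...]:
    return ("v", "d", "j") if locus in VDJ_LOCI else ("v", "j")


def vdj_feature_space(
    cells: pd.DataFrame,
    nhoods: NeighborhoodSet,
    renormalize_missing: bool = True,
    loci: tuple[str, ...] = ("TRA", "TRB"),
    label_column: str = "cell_type",
) -> VdjFeatureSpace:
    """Tabulate per-neighborhood V/D/J gene usage into usage fractions.

    For each neighborhood and each (locus, segment) category the value of
    feature ``locus_seg:gene`` is the number of member cells whose main
    chain carries that gene, divided by — with ``renormalize_missing`` —
    the number of member cells with any call in that category (so each
    populated category lies on the probability simplex), otherwise by the
    neighborhood size.
    """
    nhood_cells = pd.Index(nhoods.cell_ids)
    missing = nhood_cells.difference(cells.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} neighborhood cell(s) absent from the cell table"
        )
    table = cells.reindex(nhood_cells)
    M = nhoods.membership.T.astype(float).tocsr()  # nhoods x cells
    sizes = np.asarray(M.sum(axis=1)).ravel()

    blocks: list[pd.DataFrame] = []
    categories: dict[str, tuple[str, str]] = {}
    for locus in loci:
        for seg in _segments_for(locus):
            col = f"{locus}_{seg}"
            calls = table[col]
            genes = sorted(calls.dropna().unique())
            if not genes:
                continue
            # cells x genes indicator, then aggregate over members
            indicator = pd.get_dummies(calls).reindex(columns=genes, fill_value=0)
            counts = M @ indicator.to_numpy(dtype=float)
            if renormalize_missing:
                denom = M @ calls.notna().to_numpy(dtype=float)
            else:
                denom = sizes
            empty = denom == 0
            if np.any(empty & (counts.sum(axis=1) == 0)) and renormalize_missing:
                logger.info(
                    "vdj_feature_space: %d neighborhood(s) have no %s call",
                    int(empty.sum()),
                    col,
                )
            safe = np.where(denom == 0, 1.0, denom)
            frac = counts / safe[:, None]
            names = [f"{col}:{g}" for g in genes]
            categories.update({name: (locus, seg) for name in names})
            blocks.append(pd.DataFrame(frac, columns=names))
    features = pd.concat(blocks, axis=1)
    features.index = pd.Index(nhoods.nhood_ids, name="nhood_id")

    labels = []
    fractions = []
    label_values = table[label_column].to_numpy(dtype=object)
    for j in range(nhoods.n_nhoods):
        members = nhoods.membership.getcol(j).tocoo().row
        vals, counts_ = np.unique(label_values[members].astype(str), return_counts=True)
        top = int(np.argmax(counts_))
        labels.append(vals[top])
        fractions.append(counts_[top] / counts_.sum())
    return VdjFeatureSpace(
        features=features,
        categories=categories,
        nhood_labels=pd.Series(labels, index=features.index, name="majority_label"),
        label_fractions=pd.Series(
            fractions, index=features.index, name="label_fraction"
        ),
        renormalize_missing=renormalize_missing,
    )
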