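"""Pseudotime and branch probabilities via an absorbing Markov chain.

The trajectory stage works on the multiscale diffusion embedding of the
VDJ feature space. Waypoints are spread over the embedding by per-dimension
max-min sampling; pseudotime is initialised as shortest-path distance from
the root and refined iteratively by averaging waypoint perspectives with
Gaussian weights. A directed KNN graph, pruned of backward edges beyond a
local pseudotime scale, defines a Markov chain whose terminal (absorbing)
states are either supplied or detected unsupervised; the fundamental matrix
N = (I-Q)^-1 then yields, for every state, the probability of ultimately
absorbing in each terminal fate.

The public surface follows the model/results convention:
:class:`MarkovTrajectory` is constructed from a feature space (or any
states x features frame) and ``fit()`` returns a
:class:`TrajectoryResults` carrying pseudotime, terminal states and the
branch-probability matrix, with ``summary()`` and ``project()`` helpers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
import scipy.stats
from scipy.sparse.csgraph import connected_components, dijkstra

from .diffusion import DiffusionMap, MultiscaleSpace, diffusion_map, multiscale_space
from .pseudobulk import NeighborhoodSet, VdjFeatureSpace, exact_knn

logger = logging.getLogger(__name__)


class TrajectoryError(RuntimeError):
    """A trajectory stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# waypoints


def select_waypoints(
    coords: np.ndarray, n_waypoints: int, root: int, seed: int = 0
) -> np.ndarray:
    """Per-dimension max-min waypoint sampling, root always included.

    Cycling over coordinate dimensions, greedily add the state whose 1-D
    distance to the nearest already-chosen state (in that dimension) is
    maximal, until ``n_waypoints`` unique states are collected.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n, d = coords.shape
    if n_waypoints < 2:
        raise ValueError("n_waypoints must be at least 2")
    n_waypoints = min(n_waypoints, n)
    chosen = [int(root)]
    chosen_mask = np.zeros(n, dtype=bool)
    chosen_mask[root] = True
    # min 1-D distance to the chosen set, maintained per dimension
    min_dist = np.abs(coords - coords[root][None, :])
    dim = 0
    while len(chosen) < n_waypoints:
        scores = min_dist[:, dim].copy()
        scores[chosen_mask] = -np.inf
        new = int(np.argmax(scores))  # argmax ties -> lowest index
        chosen.append(new)
        chosen_mask[new] = True
        min_dist = np.minimum(min_dist, np.abs(coords - coords[new][None, :]))
        dim = (dim + 1) % d
    return np.array(chosen, dtype=int)


# ---------------------------------------------------------------------------
# pseudotime


def _knn_graph_matrix(coords: np.ndarray, k: int) -> sp.csr_matrix:
    """Symmetric (union) KNN graph with Euclidean edge weights."""
    n = coords.shape[0]
    k = min(k, n - 1)
    dist, idx = exact_knn(coords, k)
    rows = np.repeat(np.arange(n), k)
    g = sp.coo_matrix((dist.ravel(), (rows, idx.ravel())), shape=(n, n)).tocsr()
    return g.maximum(g.T)


def _check_connected(graph: sp.csr_matrix) -> None:
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise TrajectoryError(
            f"pseudotime: multiscale KNN graph is disconnected "
            f"(component sizes {sizes}); increase k_traj"
        )


def compute_pseudotime(
    coords: np.ndarray,
    root: int,
    waypoints: np.ndarray,
    k_traj: int = 30,
    tol: float = 1e-3,
    max_iter: int = 25,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative waypoint-refined pseudotime over the multiscale space.

    Returns ``(pseudotime, weights)`` where ``weights`` is the
    waypoints x states Gaussian weight matrix (columns normalised) reused
    downstream to smooth waypoint-level quantities onto all states.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    waypoints = np.asarray(waypoints, dtype=int)
    if root not in waypoints:
        raise ValueError("root must be among the waypoints")
    graph = _knn_graph_matrix(coords, k_traj)
    _check_connected(graph)
    D = dijkstra(graph, directed=False, indices=waypoints)
    root_row = int(np.flatnonzero(waypoints == root)[0])
    pseudotime = D[root_row].copy()

    # Silverman-style global bandwidth over all waypoint-state distances
    flat = D.ravel()
    sdv = np.std(flat) * 1.06 * len(flat) ** (-1 / 5)
    if sdv == 0:
        sdv = 1.0
    W = np.exp(-0.5 * (D / sdv) ** 2)
    W = W / W.sum(axis=0, keepdims=True)

    converged = False
    for it in range(max_iter):
        # perspective of waypoint w on state s: its own pseudotime plus the
        # graph distance, signed by whether s currently lies before or after w
        before = pseudotime[None, :] < pseudotime[waypoints][:, None]
        P = np.where(before, -D, D) + pseudotime[waypoints][:, None]
        new = (W * P).sum(axis=0)
        new = new - new.min()
        # damped update: the before/after masks make the raw map
        # discontinuous and it can enter a limit cycle; averaging with the
        # previous iterate keeps the same fixed point and converges
        if it > 0:
            new = 0.5 * (new + pseudotime)
            new = new - new.min()
        delta = float(np.max(np.abs(new - pseudotime)))
        pseudotime = new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("compute_pseudotime: stopped at max_iter without convergence")
    return pseudotime, W


# ---------------------------------------------------------------------------
# Markov chain


def default_k_mc(n_states: int, cap: int = 30) -> int:
    """Scale-aware Markov-chain neighbour count: min(cap, ceil(sqrt(n))).

    With few states a fixed k spans too much of the trajectory and the
    backward-edge pruning can never isolate the tips; a sqrt rule keeps
    the neighbourhood local at small n and saturates at the conventional
    30 for large state counts.
    """
    return int(max(3, min(cap, np.ceil(np.sqrt(n_states)))))


def build_markov_chain(
    coords: np.ndarray,
    pseudotime: np.ndarray,
    k_mc: int | None = None,
) -> np.ndarray:
    """Directed transition matrix oriented by pseudotime.

    Edges of the directed KNN graph that run backward in pseudotime by more
    than the state's local pseudotime scale (SD of pseudotime differences
    to its neighbours) are pruned; surviving edges get Gaussian weights at
    a spatial adaptive width (the distance to the state's k/3-th
    neighbour, so the two scales stay in their own units). A state left
    with no outgoing edge becomes a self-loop; with a constant pseudotime
    nothing is pruned and the chain is a plain normalised KNN kernel.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = coords.shape[0]
    if k_mc is None:
        k_mc = default_k_mc(n)
    k_mc = min(k_mc, n - 1)
    dist, idx = exact_knn(coords, k_mc)
    pt = np.asarray(pseudotime, dtype=float)
    dpt = pt[idx] - pt[:, None]  # pseudotime difference to each neighbour
    # spread of the neighbourhood's pseudotime offsets; |dpt| so that a
    # state whose neighbours sit at uniform offsets (e.g. a regular line)
    # prunes its backward edges instead of keeping them all
    pt_scale = np.abs(dpt).std(axis=1)
    keep = pt[idx] >= (pt[:, None] - pt_scale[:, None])
    # spatial Gaussian width: distance to the k/3-th neighbour
    adaptive = dist[:, max(0, int(np.floor(k_mc / 3)) - 1)].copy()
    positive = adaptive > 0
    adaptive[~positive] = adaptive[positive].mean() if positive.any() else 1.0
    weights = np.exp(-(dist**2) / (adaptive[:, None] ** 2)) * keep
    # guard against underflow: a row with kept edges but zero weight mass
    # falls back to uniform weights over its kept edges
    kept_mass = weights.sum(axis=1)
    underflow = (kept_mass == 0) & keep.any(axis=1)
    if underflow.any():
        weights[underflow] = keep[underflow].astype(float)
    T = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k_mc)
    T[rows, idx.ravel()] = weights.ravel()
    row_sums = T.sum(axis=1)
    dead = row_sums == 0
    if dead.any():
        T[np.flatnonzero(dead), np.flatnonzero(dead)] = 1.0
        row_sums[dead] = 1.0
    return T / row_sums[:, None]


def identify_terminal_states(
    T: np.ndarray,
    pseudotime: np.ndarray,
    n_expected: int | None = None,
    late_fraction: float = 0.5,
) -> np.ndarray:
    """Unsupervised terminal-state detection on the oriented chain.

    Candidate states are the union of pure self-loop states (no forward
    edges) and outliers of the chain's stationary-like mass (left
    eigenvectors at eigenvalue 1, one per recurrent class, thresholded at
    a median/MAD-based normal quantile). Candidates are grouped into
    connected components of the chain's undirected support and each
    component contributes its maximum-pseudotime state, so one terminal is
    reported per absorbing region rather than one per high-mass state.
    Representatives that are not local pseudotime maxima of the chain's
    undirected support (some neighbour lies later), or that fall earlier
    than ``late_fraction`` of the pseudotime range, are discarded — both
    are signatures of mid-trajectory clumps isolated by the pruning rather
    than genuine fates. The result is ranked by pseudotime descending;
    ``n_expected=None`` returns all.
    """
    T = np.asarray(T, dtype=float)
    pt = np.asarray(pseudotime, dtype=float)
    n = T.shape[0]
    self_loop = np.flatnonzero(np.isclose(np.diag(T), 1.0, atol=1e-9))
    vals, vecs = scipy.linalg.eig(T.T)
    at_one = np.flatnonzero(np.abs(vals - 1.0) < 1e-6)
    mass = np.zeros(n)
    for j in at_one:
        v = np.abs(np.real(vecs[:, j]))
        total = v.sum()
        if total > 0:
            mass += v / total
    med = float(np.median(mass))
    mad = float(np.median(np.abs(mass - med)))
    scale = mad if mad > 0 else float(mass.std())
    if scale > 0:
        cutoff = float(scipy.stats.norm.ppf(0.9999, loc=med, scale=scale))
        high_mass = np.flatnonzero(mass > max(cutoff, 1e-8))
    else:
        high_mass = np.array([], dtype=int)
    candidates = np.union1d(self_loop, high_mass)
    if len(candidates) == 0:
        raise TrajectoryError(
            "terminal-state detection found no candidates; supply terminal "
            "states explicitly"
        )
    undirected = (T + T.T) > 0
    support = sp.csr_matrix(undirected[np.ix_(candidates, candidates)])
    n_comp, comp = connected_components(support, directed=False)
    reps = np.array(
        [
            candidates[comp == c][np.argmax(pt[candidates[comp == c]])]
            for c in range(n_comp)
        ]
    )
    np.fill_diagonal(undirected, False)
    local_max = np.array(
        [not np.any(pt[undirected[r]] > pt[r]) for r in reps]
    )
    late = pt[reps] >= pt.min() + late_fraction * (pt.max() - pt.min())
    good = local_max & late
    if good.any():
        reps = reps[good]
    else:
        # fall back to the latest representative so at least one fate exists
        reps = reps[[int(np.argmax(pt[reps]))]]
    ranked = reps[np.argsort(-pt[reps], kind="stable")]
    if n_expected is not None:
        ranked = ranked[:n_expected]
    return ranked


def rescue_dead_ends(
    T: np.ndarray,
    coords: np.ndarray,
    pseudotime: np.ndarray,
    terminal: np.ndarray,
) -> np.ndarray:
    """Reconnect non-terminal closed classes of the chain.

    Backward-edge pruning can leave closed recurrent classes in the middle
    of the trajectory (a spatially isolated clump whose outside neighbours
    all lie earlier in pseudotime). Such dead ends are artifacts of the
    pruning, not fates: each one is given an escape edge from its member
    closest to an outside, later-pseudotime state (falling back to the
    nearest outside state when none is later), and the row renormalised.
    Repeats until every state can reach a terminal.
    """
    T = np.asarray(T, dtype=float).copy()
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    pt = np.asarray(pseudotime, dtype=float)
    terminal = np.asarray(terminal, dtype=int)
    n = T.shape[0]
    is_terminal = np.zeros(n, dtype=bool)
    is_terminal[terminal] = True
    for _ in range(n):
        support = sp.csr_matrix(T > 0)
        n_comp, comp = connected_components(support, directed=True, connection="strong")
        rewired = False
        for c in range(n_comp):
            members = np.flatnonzero(comp == c)
            if is_terminal[members].any():
                continue
            outside = np.flatnonzero(comp != c)
            if len(outside) == 0 or T[np.ix_(members, outside)].any():
                continue  # not closed
            later = outside[pt[outside] > pt[members].max()]
            targets = later if len(later) else outside
            d = np.linalg.norm(
                coords[members][:, None, :] - coords[targets][None, :, :], axis=2
            )
            mi, tj = np.unravel_index(np.argmin(d), d.shape)
            i, j = members[mi], targets[tj]
            T[i, i] = 0.0  # drop a pure self-loop if that is all the row has
            T[i, j] += max(T[i].max(), 1.0)
            T[i] /= T[i].sum()
            logger.info(
                "rescue_dead_ends: reconnected closed class of %d state(s) "
                "via edge %d->%d",
                len(members),
                i,
                j,
            )
            rewired = True
        if not rewired:
            break
    return T


def absorption_probabilities(
    T: np.ndarray, terminal: np.ndarray, labels: np.ndarray | None = None
) -> pd.DataFrame:
    """Fate-absorption probabilities from the fundamental matrix.

    Terminal rows are rewritten as unit self-loops; with the transient
    block Q and transient-to-absorbing block R, B = (I-Q)^-1 R gives each
    transient state's probability of absorbing in each terminal state.
    Terminals sharing a label are summed into one fate column.
    """
    T = np.asarray(T, dtype=float).copy()
    terminal = np.asarray(terminal, dtype=int)
    if len(terminal) == 0:
        raise ValueError("terminal set must be non-empty")
    n = T.shape[0]
    T[terminal, :] = 0.0
    T[terminal, terminal] = 1.0
    is_terminal = np.zeros(n, dtype=bool)
    is_terminal[terminal] = True
    transient = np.flatnonzero(~is_terminal)

    # reachability check gives a better error than a raw singular solve
    reachable = np.zeros(n, dtype=bool)
    for t in terminal:
        order = sp.csgraph.breadth_first_order(
            sp.csr_matrix((T > 0).T), i_start=int(t), return_predecessors=False
        )
        reachable[order] = True
    unreachable = np.flatnonzero(~reachable)
    if len(unreachable):
        raise TrajectoryError(
            f"absorption: state(s) {unreachable.tolist()} cannot reach any "
            "terminal state"
        )

    Q = T[np.ix_(transient, transient)]
    R = T[np.ix_(transient, terminal)]
    try:
        B_trans = scipy.linalg.solve(np.eye(len(transient)) - Q, R)
    except scipy.linalg.LinAlgError as err:  # pragma: no cover - guarded above
        raise TrajectoryError("absorption: (I - Q) is singular") from err
    B = np.zeros((n, len(terminal)))
    B[transient] = B_trans
    B[terminal, np.arange(len(terminal))] = 1.0

    if labels is None:
        fate_labels = [str(t) for t in terminal]
    else:
        fate_labels = [str(labels[t]) for t in terminal]
    out = pd.DataFrame(B, columns=fate_labels)
    # fates sharing a label collapse into one column
    out = out.T.groupby(level=0, sort=True).sum().T
    return out


def monte_carlo_absorption(
    T: np.ndarray,
    terminal: np.ndarray,
    n_walks: int = 100_000,
    seed: int = 0,
    max_steps: int = 10_000,
) -> np.ndarray:
    """Absorption frequencies from simulated random walks.

    Independent validation route for :func:`absorption_probabilities`:
    ``n_walks`` walkers start in every state and step by the transition
    matrix until they hit a terminal state. Returns the states x terminals
    frequency matrix (terminal columns in the order given).
    """
    T = np.asarray(T, dtype=float).copy()
    terminal = np.asarray(terminal, dtype=int)
    n = T.shape[0]
    T[terminal, :] = 0.0
    T[terminal, terminal] = 1.0
    cum = np.cumsum(T, axis=1)
    term_col = np.full(n, -1, dtype=int)
    term_col[terminal] = np.arange(len(terminal))
    rng = np.random.default_rng(seed)
    # all walkers in one vectorised batch: n_walks per start state
    start = np.repeat(np.arange(n), n_walks)
    pos = start.copy()
    active = np.flatnonzero(term_col[pos] < 0)
    for _ in range(max_steps):
        if len(active) == 0:
            break
        r = rng.random(len(active))
        pos[active] = (cum[pos[active]] < r[:, None]).sum(axis=1)
        active = active[term_col[pos[active]] < 0]
    out = np.zeros((n, len(terminal)))
    landed = term_col[pos] >= 0
    np.add.at(out, (start[landed], term_col[pos[landed]]), 1.0)
    return out / n_walks


# ---------------------------------------------------------------------------
# model / results


@dataclass
class TrajectoryParams:
    """Tunable parameters of the trajectory model (recorded in results)."""

    n_comps: int = 10
    k_dm: int = 30
    ka: int = 10
    n_eigs: int | str = "auto"
    n_waypoints: int = 500
    k_traj: int = 30
    k_mc: int | None = None  # None -> min(30, ceil(sqrt(n_states)))
    tol: float = 1e-3
    max_iter: int = 25
    seed: int = 0


class TrajectoryResults:
    """Fitted pseudotime, terminal fates and branch probabilities.

    Attributes
    ----------
    pseudotime : pd.Series
        Per-state pseudotime, min 0, indexed by state id.
    terminal_states : list
        State ids detected (or supplied) as absorbing fates.
    branch_probs : pd.DataFrame
        States x fates absorption probabilities; rows sum to 1.
    """

    def __init__(
        self,
        model: "MarkovTrajectory",
        pseudotime: pd.Series,
        terminal_states: list,
        branch_probs: pd.DataFrame,
        dm: DiffusionMap,
        ms: MultiscaleSpace,
        waypoints: np.ndarray,
    ):
        self.model = model
        self.pseudotime = pseudotime
        self.terminal_states = terminal_states
        self.branch_probs = branch_probs
        self.diffusion = dm
        self.multiscale = ms
        self.waypoints = waypoints

    @property
    def fates(self) -> list[str]:
        return list(self.branch_probs.columns)

    def to_frame(self) -> pd.DataFrame:
        """One row per state: pseudotime plus prob_<fate> columns."""
        out = pd.DataFrame({"pseudotime": self.pseudotime})
        for fate in self.fates:
            out[f"prob_{fate}"] = self.branch_probs[fate]
        return out

    def project(self, nhoods: NeighborhoodSet, cells: pd.DataFrame | None = None):
        """Project state-level results onto cells (see projection module)."""
        from .projection import project_to_cells

        return project_to_cells(self, nhoods, cells=cells)

    def summary(self) -> str:
        p = self.model.params
        lines = [
            "Absorbing Markov chain trajectory results",
            "=" * 45,
            f"states:            {len(self.pseudotime)}",
            f"root:              {self.model.root}",
            f"terminal states:   {', '.join(map(str, self.terminal_states))}",
            f"fates:             {', '.join(self.fates)}",
            f"diffusion comps:   {p.n_comps} (k_dm={self.diffusion.k_dm}, "
            f"ka={self.diffusion.ka})",
            f"multiscale eigs:   {self.multiscale.n_eigs}",
            f"waypoints:         {len(self.waypoints)}",
            f"pseudotime range:  [0, {self.pseudotime.max():.4g}]",
            "",
            "mean branch probability by fate:",
        ]
        for fate in self.fates:
            lines.append(f"  {fate:<20s} {self.branch_probs[fate].mean():.4f}")
        return "\n".join(lines)


class MarkovTrajectory:
    """Trajectory model over a (pseudobulked) VDJ feature space.

    Parameters
    ----------
    features : pd.DataFrame
        States x features matrix (e.g. the VDJ usage fractions).
    root : hashable
        State id of the trajectory origin.
    terminal_states : list or None
        State ids of the absorbing fates; ``None`` detects them
        unsupervised from the chain.
    labels : pd.Series or None
        Per-state fate label (e.g. majority cell type); terminals sharing
        a label are merged into one fate.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        root,
        terminal_states: list | None = None,
        labels: pd.Series | None = None,
        params: TrajectoryParams | None = None,
    ):
        if features.empty:
            raise ValueError("feature space is empty")
        self.features = features
        self.root = root
        self.terminal_states = terminal_states
        self.labels = labels
        self.params = params or TrajectoryParams()
        if root not in features.index:
            raise ValueError(f"root state {root!r} not in the feature space")

    @classmethod
    def from_feature_space(
        cls,
        fs: VdjFeatureSpace,
        root=None,
        root_label: str | None = None,
        terminal_states: list | None = None,
        params: TrajectoryParams | None = None,
    ) -> "MarkovTrajectory":
        """Build the model from a :class:`VdjFeatureSpace`.

        ``root`` may be a neighborhood id; alternatively ``root_label``
        selects, among neighborhoods with that majority cell-type label,
        the most extreme one — the candidate with the largest mean
        feature-space distance to all other neighborhoods, i.e. the far
        end of the earliest stage rather than its middle.
        """
        if root is None:
            if root_label is None:
                raise ValueError("provide either root or root_label")
            mask = (fs.nhood_labels == root_label).to_numpy()
            if not mask.any():
                raise ValueError(f"no neighborhood has majority label {root_label!r}")
            X = fs.features.to_numpy(dtype=float)
            from scipy.spatial.distance import cdist

            mean_dist = cdist(X[mask], X).mean(axis=1)
            root = fs.features.index[np.flatnonzero(mask)[np.argmax(mean_dist)]]
        return cls(
            features=fs.features,
            root=root,
            terminal_states=terminal_states,
            labels=fs.nhood_labels,
            params=params,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, root, **kwargs) -> "MarkovTrajectory":
        return cls(features=df, root=root, **kwargs)

    def fit(self) -> TrajectoryResults:
        """Run the full trajectory inference and return the results."""
        p = self.params
        n = len(self.features)
        state_index = self.features.index

        def _stage(name, fn, *args, **kw):
            try:
                return fn(*args, **kw)
            except TrajectoryError:
                raise
            except Exception as err:
                raise TrajectoryError(f"{name}: {err}") from err

        dm = _stage(
            "diffusion_map",
            diffusion_map,
            self.features,
            n_comps=min(p.n_comps, n - 1),
            k_dm=p.k_dm,
            ka=p.ka,
            seed=p.seed,
        )
        ms = _stage("multiscale_space", multiscale_space, dm, p.n_eigs)
        root_idx = int(state_index.get_indexer([self.root])[0])
        coords = ms.coords

        n_waypoints = min(p.n_waypoints, n)
        waypoints = _stage(
            "select_waypoints", select_waypoints, coords, n_waypoints, root_idx, p.seed
        )
        # user-supplied terminals must take part in the chain
        if self.terminal_states is not None:
            term_idx = state_index.get_indexer(self.terminal_states)
            if (term_idx < 0).any():
                raise TrajectoryError("terminal states not found in the feature space")
            waypoints = np.concatenate(
                [waypoints, np.setdiff1d(term_idx, waypoints)]
            ).astype(int)

        pseudotime, W = _stage(
            "compute_pseudotime",
            compute_pseudotime,
            coords,
            root_idx,
            waypoints,
            k_traj=p.k_traj,
            tol=p.tol,
            max_iter=p.max_iter,
        )

        wp_coords = coords[waypoints]
        wp_pt = pseudotime[waypoints]
        T = _stage("build_markov_chain", build_markov_chain, wp_coords, wp_pt, p.k_mc)

        if self.terminal_states is None:
            term_wp = _stage("identify_terminal_states", identify_terminal_states, T, wp_pt)
        else:
            term_idx = state_index.get_indexer(self.terminal_states)
            term_wp = np.array(
                [int(np.flatnonzero(waypoints == t)[0]) for t in term_idx]
            )

        if self.labels is not None:
            labels_arr = self.labels.reindex(state_index).to_numpy(dtype=object)[
                waypoints
            ]
        else:
            # fall back to state ids so fate columns are always nameable
            labels_arr = np.array(
                [str(state_index[w]) for w in waypoints], dtype=object
            )
        T = _stage("rescue_dead_ends", rescue_dead_ends, T, wp_coords, wp_pt, term_wp)
        B_wp = _stage("absorption_probabilities", absorption_probabilities, T, term_wp, labels_arr)

        # smooth waypoint-level fate probabilities onto all states with the
        # same Gaussian waypoint weights used for pseudotime, then renormalise
        B_states = W.T @ B_wp.to_numpy()
        row_sums = B_states.sum(axis=1, keepdims=True)
        row_sums[row_sums == 0] = 1.0
        B_states = B_states / row_sums
        branch_probs = pd.DataFrame(
            B_states, index=state_index, columns=B_wp.columns
        )
        # terminal states are certain of their own fate
        terminal_state_ids = [state_index[waypoints[t]] for t in term_wp]
        fate_of_terminal = {
            state_index[waypoints[t]]: str(labels_arr[t]) for t in term_wp
        }
        for sid, fate in fate_of_terminal.items():
            branch_probs.loc[sid] = 0.0
            branch_probs.loc[sid, fate] = 1.0

        result = TrajectoryResults(
            model=self,
            pseudotime=pd.Series(pseudotime, index=state_index, name="pseudotime"),
            terminal_states=terminal_state_ids,
            branch_probs=branch_probs,
            dm=dm,
            ms=ms,
            waypoints=waypoints,
        )
        return result


def markov_probability(
    fs: VdjFeatureSpace,
    root=None,
    root_label: str | None = None,
    terminal_states: list | None = None,
    params: TrajectoryParams | None = None,
) -> TrajectoryResults:
    """Functional wrapper: fit the trajectory model on a feature space."""
    model = MarkovTrajectory.from_feature_space(
        fs,
        root=root,
        root_label=root_label,
        terminal_states=terminal_states,
        params=params,
    )
    return model.fit()
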