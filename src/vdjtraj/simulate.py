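"""Synthetic paired GEX + TCR datasets with known ground truth.

Emulates a bifurcating alpha/beta T-cell development dataset
(DP(P) -> DP(Q) -> ABT(ENTRY) -> {CD4+T, CD8+T}): each cell carries a
latent developmental time in [0,1], a branch assignment past the branch
point, smooth branch-dependent coordinates in a reduced expression space,
and TCR contigs whose V/J usage is trajectory-informative. TRAV/TRAJ gene
indices are drawn from a window that slides with latent time, mimicking the
proximal-to-distal progression of recombination during development, and
TRBJ usage acquires an opposite bias on the two branches past the branch
point, so the feature space carries both time and fate signal. Realistic
artifacts (non-productive chains, orphan cells, extra receptor pairs) are
injected at configurable rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ChainCalls, combined_receptor_string

#: Human-like gene-inventory magnitudes.
GENE_INVENTORY = {"TRAV": 40, "TRAJ": 50, "TRBV": 40, "TRBD": 2, "TRBJ": 13}

STAGE_THRESHOLDS = (0.25, 0.5, 0.75)
STAGES = ("DP_P", "DP_Q", "ABT_ENTRY")
FATE_LABELS = {"fateA": "CD4_T", "fateB": "CD8_T"}

#: Half-width of the sliding TRAV/TRAJ usage window (gene-index units).
WINDOW_HALF_WIDTH = 3
#: Strength of the branch-dependent TRBJ bias at the trajectory tips.
TRBJ_BIAS = 6.0
#: Branch-dependent TRBD preference at the trajectory tips:
#: p(TRBD1) = 0.5 +/- TRBD_BIAS * ramp (fateA high, fateB low).
TRBD_BIAS = 0.45


@dataclass
class SimulatedDataset:
    """A simulated paired dataset plus its generating truth."""

    space: pd.DataFrame  # cells x dims reduced expression coordinates
    contigs: pd.DataFrame  # standardised contig table
    metadata: pd.DataFrame  # cell_id, cell_type
    truth: pd.DataFrame  # cell_id, latent_time, branch, stage


def _stage_label(t: float, branch: str) -> str:
    for threshold, stage in zip(STAGE_THRESHOLDS, STAGES):
        if t < threshold:
            return stage
    return FATE_LABELS.get(branch, "MATURE_T")


def _window_gene(rng, prefix: str, t: float) -> str:
    """Draw a gene from the latent-time-sliding window of the inventory."""
    n = GENE_INVENTORY[prefix]
    centre = t * (n - 1)
    lo = int(np.floor(centre - WINDOW_HALF_WIDTH))
    hi = int(np.ceil(centre + WINDOW_HALF_WIDTH))
    idx = int(np.clip(rng.integers(lo, hi + 1), 0, n - 1))
    return f"{prefix}{idx + 1}"


#: Fraction of the full branch signal present immediately at commitment:
#: lineage choice is a bistable regulatory switch, so committed cells carry
#: a discrete jump of fate signal that then matures toward the tips.
COMMITMENT_FLOOR = 0.3


def _ramp(t, branch, branch_point: float):
    """Branch-signal strength: 0 on the trunk, COMMITMENT_FLOOR at the
    branch point, rising (square-root shaped) to 1 at the tips."""
    frac = np.clip((np.asarray(t) - branch_point) / (1 - branch_point), 0.0, None)
    on_branch = np.isin(np.asarray(branch), list(FATE_LABELS)) & (frac > 0)
    return (COMMITMENT_FLOOR + (1 - COMMITMENT_FLOOR) * np.sqrt(frac)) * on_branch


def _trbd_gene(rng, t: float, branch: str, branch_point: float) -> str:
    """Branch-biased TRBD choice (fateA prefers TRBD1, fateB TRBD2)."""
    ramp = _ramp(t, branch, branch_point)
    sign = 1.0 if branch == "fateA" else -1.0
    p1 = 0.5 + sign * TRBD_BIAS * ramp
    return "TRBD1" if rng.random() < p1 else "TRBD2"


def _trbj_gene(rng, t: float, branch: str, branch_point: float) -> str:
    n = GENE_INVENTORY["TRBJ"]
    idx = np.arange(n)
    ramp = _ramp(t, branch, branch_point)
    if ramp > 0:
        sign = -1.0 if branch == "fateA" else 1.0
        logits = sign * TRBJ_BIAS * ramp * (idx / (n - 1) - 0.5)
        weights = np.exp(logits)
        weights /= weights.sum()
    else:
        weights = np.full(n, 1.0 / n)
    return f"TRBJ{rng.choice(n, p=weights) + 1}"


def _coordinates(t: np.ndarray, branch: np.ndarray, n_dims: int, branch_point: float,
                 noise_sd: float, rng) -> np.ndarray:
    coords = np.empty((len(t), n_dims))
    for d in range(n_dims):
        coords[:, d] = np.cos((d + 1) * np.pi * t) / (1.0 + d / 2.0)
    divergence = _ramp(t, branch, branch_point) * (1 - branch_point)
    sign = np.where(branch == "fateA", 1.0, np.where(branch == "fateB", -1.0, 0.0))
    for d in range(min(n_dims, 4)):
        coords[:, d] += sign * divergence * 0.9 / (1.0 + d)
    coords += rng.normal(0.0, noise_sd, size=coords.shape)
    return coords


def _make_chain_contigs(rng, cell_id, t, branch, branch_point, start=0):
    """One productive TRA + TRB pair for a cell; returns contig row dicts."""
    tra = {
        "cell_id": cell_id,
        "contig_id": f"{cell_id}_c{start}",
        "locus": "TRA",
        "v_call": _window_gene(rng, "TRAV", t),
        "d_call": None,
        "j_call": _window_gene(rng, "TRAJ", t),
        "c_call": "TRAC",
        "productive": True,
        "umi_count": 1 + int(rng.poisson(3)),
    }
    trb = {
        "cell_id": cell_id,
        "contig_id": f"{cell_id}_c{start + 1}",
        "locus": "TRB",
        "v_call": f"TRBV{rng.integers(GENE_INVENTORY['TRBV']) + 1}",
        "d_call": _trbd_gene(rng, t, branch, branch_point),
        "j_call": _trbj_gene(rng, t, branch, branch_point),
        "c_call": f"TRBC{rng.integers(2) + 1}",
        "productive": True,
        "umi_count": 1 + int(rng.poisson(3)),
    }
    return [tra, trb]


def _simulate(
    n_cells: int,
    n_dims: int,
    branch_point: float,
    seed: int,
    noise_sd: float,
    p_nonproductive: float,
    p_orphan: float,
    p_extra_pair: float,
    bifurcating: bool,
) -> SimulatedDataset:
    if n_cells < 100:
        raise ValueError("n_cells must be at least 100")
    if not 0 < branch_point < 1:
        raise ValueError("branch_point must lie in (0, 1)")
    for name, rate in (
        ("p_nonproductive", p_nonproductive),
        ("p_orphan", p_orphan),
        ("p_extra_pair", p_extra_pair),
    ):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {rate}")
    if p_nonproductive + p_orphan + p_extra_pair > 1:
        raise ValueError("artifact rates must sum to at most 1")

    rng = np.random.default_rng(seed)
    t = rng.uniform(0.0, 1.0, size=n_cells)
    if bifurcating:
        branch = np.where(
            t <= branch_point,
            "trunk",
            np.where(rng.random(n_cells) < 0.5, "fateA", "fateB"),
        )
        signal_branch = branch
    else:
        # single lineage: late cells are labelled as the (only) fate for
        # staging purposes but carry no commitment signal
        branch = np.where(t <= branch_point, "trunk", "fateA")
        signal_branch = np.full(n_cells, "trunk", dtype=object)
    cell_ids = np.array([f"cell{i:05d}" for i in range(n_cells)], dtype=object)

    coords = _coordinates(t, signal_branch, n_dims, branch_point, noise_sd, rng)
    space = pd.DataFrame(
        coords,
        index=pd.Index(cell_ids, name="cell_id"),
        columns=[f"dim{d}" for d in range(n_dims)],
    )

    # one artifact class at most per cell, drawn from a single uniform
    u = rng.random(n_cells)
    artifact = np.where(
        u < p_nonproductive,
        "nonproductive",
        np.where(
            u < p_nonproductive + p_orphan,
            "orphan",
            np.where(u < p_nonproductive + p_orphan + p_extra_pair, "extra_pair", "none"),
        ),
    )

    rows: list[dict] = []
    for i, cid in enumerate(cell_ids):
        pair = _make_chain_contigs(rng, cid, t[i], signal_branch[i], branch_point)
        kind = artifact[i]
        if kind == "nonproductive":
            pair[1]["productive"] = False
        elif kind == "orphan":
            pair = [pair[int(rng.integers(2))]]
        elif kind == "extra_pair":
            pair += _make_chain_contigs(
                rng, cid, t[i], signal_branch[i], branch_point, start=2
            )
        rows.extend(pair)
    contigs = pd.DataFrame(rows)

    stage = np.array(
        [_stage_label(t[i], branch[i]) for i in range(n_cells)], dtype=object
    )
    metadata = pd.DataFrame({"cell_id": cell_ids, "cell_type": stage})
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "latent_time": t,
            "branch": branch,
            "stage": stage,
            "artifact": artifact,
        }
    )
    return SimulatedDataset(space=space, contigs=contigs, metadata=metadata, truth=truth)


def simulate_bifurcating_repertoire(
    n_cells: int = 2000,
    n_dims: int = 10,
    branch_point: float = 0.5,
    seed: int = 0,
    noise_sd: float = 0.05,
    p_nonproductive: float = 0.05,
    p_orphan: float = 0.05,
    p_extra_pair: float = 0.05,
) -> SimulatedDataset:
    """Bifurcating T-cell development dataset with two terminal fates."""
    return _simulate(
        n_cells,
        n_dims,
        branch_point,
        seed,
        noise_sd,
        p_nonproductive,
        p_orphan,
        p_extra_pair,
        bifurcating=True,
    )


def simulate_linear_repertoire(
    n_cells: int = 2000,
    n_dims: int = 10,
    seed: int = 0,
    noise_sd: float = 0.05,
    p_nonproductive: float = 0.05,
    p_orphan: float = 0.05,
    p_extra_pair: float = 0.05,
) -> SimulatedDataset:
    """Linear (single-fate) variant of the development dataset."""
    return _simulate(
        n_cells,
        n_dims,
        0.5,
        seed,
        noise_sd,
        p_nonproductive,
        p_orphan,
        p_extra_pair,
        bifurcating=False,
    )


def write_fixture(dataset: SimulatedDataset, directory, dialect: str = "airr") -> dict:
    """Serialise a simulated dataset in one of the supported dialects.

    Emits the contigs in the chosen dialect (``airr`` TSV, ``10x`` CSV, or
    the ``combined_string`` column appended to the metadata), plus the
    metadata CSV and the coordinates CSV. Returns the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "metadata": directory / "metadata.csv",
        "coords": directory / "coords.csv",
    }
    dataset.space.to_csv(paths["coords"], float_format="%.17g")

    contigs = dataset.contigs
    if dialect == "airr":
        paths["contigs"] = directory / "contigs.tsv"
        airr = pd.DataFrame(
            {
                "sequence_id": contigs["contig_id"],
                "cell_id": contigs["cell_id"],
                "locus": contigs["locus"],
                "v_call": contigs["v_call"].fillna(""),
                "d_call": contigs["d_call"].fillna(""),
                "j_call": contigs["j_call"].fillna(""),
                "c_call": contigs["c_call"].fillna(""),
                "productive": np.where(contigs["productive"], "T", "F"),
                "duplicate_count": contigs["umi_count"],
            }
        )
        airr.to_csv(paths["contigs"], sep="\t", index=False)
        dataset.metadata.to_csv(paths["metadata"], index=False)
    elif dialect == "10x":
        paths["contigs"] = directory / "filtered_contig_annotations.csv"
        tenx = pd.DataFrame(
            {
                "barcode": contigs["cell_id"],
                "contig_id": contigs["contig_id"],
                "chain": contigs["locus"],
                "v_gene": contigs["v_call"].fillna("None"),
                "d_gene": contigs["d_call"].fillna("None"),
                "j_gene": contigs["j_call"].fillna("None"),
                "c_gene": contigs["c_call"].fillna("None"),
                "productive": np.where(contigs["productive"], "true", "false"),
                "umis": contigs["umi_count"],
            }
        )
        tenx.to_csv(paths["contigs"], index=False)
        dataset.metadata.to_csv(paths["metadata"], index=False)
    elif dialect == "combined_string":
        # the string format holds one (productive) chain per locus, as after
        # upstream filtering: reduce each cell to its max-UMI productive chain
        productive = contigs.loc[contigs["productive"]]
        strings = {}
        for cell_id, group in productive.groupby("cell_id"):
            chains = {}
            for locus in ("TRA", "TRB"):
                sub = group.loc[group["locus"] == locus]
                if sub.empty:
                    chains[locus] = ChainCalls()
                    continue
                best = sub.sort_values(
                    ["umi_count", "contig_id"], ascending=[False, True]
                ).iloc[0]
                chains[locus] = ChainCalls(
                    v=best["v_call"] if pd.notna(best["v_call"]) else None,
                    d=best["d_call"] if pd.notna(best["d_call"]) else None,
                    j=best["j_call"] if pd.notna(best["j_call"]) else None,
                    c=best["c_call"] if pd.notna(best["c_call"]) else None,
                )
            strings[cell_id] = combined_receptor_string(chains)
        meta = dataset.metadata.copy()
        meta["CTgene"] = meta["cell_id"].map(strings).fillna("NA_NA")
        meta.to_csv(paths["metadata"], index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return paths
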