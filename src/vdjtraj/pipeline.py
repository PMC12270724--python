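"""End-to-end pipeline with file-based stage composition.

Each stage reads the serialized outputs of the previous stage from the run
directory and writes its own, so running the monolithic pipeline and
chaining the per-stage CLI subcommands produce identical files. A single
run seed fans out into per-stage seeds by stable hashing of the stage
name, so adding a stage never perturbs earlier stages' randomness.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import __version__
from .io import (
    read_10x_contigs,
    read_airr,
    read_cell_metadata,
    read_reduced_space,
    write_cell_trajectory,
)
from .markov import MarkovTrajectory, TrajectoryParams
from .preprocess import (
    PreprocessParams,
    cells_from_combined_strings,
    setup_vdj_cells,
)
from .pseudobulk import (
    NeighborhoodSet,
    VdjFeatureSpace,
    knn_graph,
    make_neighborhoods,
    vdj_feature_space,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, object] = {
    "seed": 0,
    "input.contigs": "",
    "input.dialect": "airr",
    "input.metadata": "",
    "input.coords": "",
    "preprocess.already_productive": False,
    "preprocess.allowed_chain_status": "single_pair,extra_pair",
    "preprocess.loci": "TRA,TRB",
    "pseudobulk.k": 30,
    "pseudobulk.proportion": 0.1,
    "pseudobulk.refined": True,
    "pseudobulk.renormalize_missing": True,
    "trajectory.root": "",
    "trajectory.root_label": "",
    "trajectory.terminals": "auto",
    "trajectory.n_comps": 10,
    "trajectory.k_dm": 30,
    "trajectory.ka": 10,
    "trajectory.n_eigs": "auto",
    "trajectory.n_waypoints": 500,
    "trajectory.k_traj": 30,
    "trajectory.k_mc": "auto",
    "trajectory.tol": 1e-3,
    "trajectory.max_iter": 25,
}

_BOOL_KEYS = {
    "preprocess.already_productive",
    "pseudobulk.refined",
    "pseudobulk.renormalize_missing",
}
_INT_KEYS = {
    "seed",
    "pseudobulk.k",
    "trajectory.n_comps",
    "trajectory.k_dm",
    "trajectory.ka",
    "trajectory.n_waypoints",
    "trajectory.k_traj",
    "trajectory.max_iter",
}
_FLOAT_KEYS = {"pseudobulk.proportion", "trajectory.tol"}


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return (int(seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


def _coerce(key: str, value):
    if key in _BOOL_KEYS:
        if isinstance(value, bool):
            return value
        return str(value).strip().lower() in {"1", "true", "yes", "on"}
    if key in _INT_KEYS:
        return int(value)
    if key in _FLOAT_KEYS:
        return float(value)
    return value


def parse_config_file(path) -> dict:
    """Parse a flat ``key = value`` config file with dotted stage prefixes."""
    cfg = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        cfg[key] = value
    return cfg


def resolve_config(overrides: dict | None = None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    for key, value in (overrides or {}).items():
        if key not in DEFAULT_CONFIG:
            raise ValueError(f"unknown config key {key!r}")
        cfg[key] = value
    return {k: _coerce(k, v) for k, v in cfg.items()}


def write_config(cfg: dict, path) -> None:
    lines = [f"{k} = {cfg[k]}" for k in sorted(cfg)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# neighborhood serialization (text formats: MTX + CSV)


def save_neighborhoods(nhoods: NeighborhoodSet, outdir: Path) -> None:
    scipy.io.mmwrite(outdir / "nhood_membership.mtx", nhoods.membership.astype(int))
    pd.DataFrame({"cell_id": nhoods.cell_ids.astype(str)}).to_csv(
        outdir / "nhood_cells.csv", index=False
    )
    pd.DataFrame(
        {
            "nhood_id": nhoods.nhood_ids.astype(str),
            "index_cell_position": nhoods.index_cells,
            "k": nhoods.k,
        }
    ).to_csv(outdir / "nhood_index.csv", index=False)


def load_neighborhoods(outdir: Path) -> NeighborhoodSet:
    membership = sp.csr_matrix(
        scipy.io.mmread(outdir / "nhood_membership.mtx").astype(bool)
    )
    cells = pd.read_csv(outdir / "nhood_cells.csv", dtype=str)
    info = pd.read_csv(outdir / "nhood_index.csv")
    return NeighborhoodSet(
        membership=membership,
        cell_ids=cells["cell_id"].to_numpy(dtype=object),
        index_cells=info["index_cell_position"].to_numpy(dtype=int),
        k=int(info["k"].iloc[0]),
    )


def save_feature_space(fs: VdjFeatureSpace, outdir: Path) -> None:
    fs.features.to_csv(outdir / "feature_space.csv", float_format="%.17g")
    pd.DataFrame(
        {
            "nhood_id": fs.features.index,
            "majority_label": fs.nhood_labels.to_numpy(),
            "label_fraction": fs.label_fractions.to_numpy(),
        }
    ).to_csv(outdir / "nhood_labels.csv", index=False, float_format="%.17g")


def load_feature_space(outdir: Path) -> VdjFeatureSpace:
    features = pd.read_csv(outdir / "feature_space.csv", index_col=0)
    features.index = features.index.astype(str)
    labels = pd.read_csv(outdir / "nhood_labels.csv", dtype={"nhood_id": str})
    labels = labels.set_index("nhood_id").reindex(features.index)
    categories = {}
    for name in features.columns:
        prefix = name.split(":", 1)[0]
        locus, seg = prefix.split("_", 1)
        categories[name] = (locus, seg)
    return VdjFeatureSpace(
        features=features,
        categories=categories,
        nhood_labels=labels["majority_label"],
        label_fractions=labels["label_fraction"],
    )


# ---------------------------------------------------------------------------
# stages


def stage_preprocess(cfg: dict, outdir: Path) -> dict:
    dialect = cfg["input.dialect"]
    loci = tuple(str(cfg["preprocess.loci"]).split(","))
    allowed_raw = str(cfg["preprocess.allowed_chain_status"]).strip().lower()
    allowed = (
        None
        if allowed_raw in {"none", "null", ""}
        else frozenset(str(cfg["preprocess.allowed_chain_status"]).split(","))
    )
    params = PreprocessParams(
        already_productive=bool(cfg["preprocess.already_productive"]),
        allowed_chain_status=allowed,
        loci=loci,
    )
    metadata = read_cell_metadata(cfg["input.metadata"])
    if dialect == "combined_string":
        cells = cells_from_combined_strings(metadata, params=params)
        n_contigs = len(metadata)
    else:
        reader = {"airr": read_airr, "10x": read_10x_contigs}.get(dialect)
        if reader is None:
            raise ValueError(f"unknown input dialect {dialect!r}")
        contigs = reader(cfg["input.contigs"])
        n_contigs = len(contigs)
        cells = setup_vdj_cells(contigs, metadata, params)
    cells.to_csv(outdir / "cells.csv")
    return {"n_contigs_in": int(n_contigs), "n_cells_retained": int(len(cells))}


def stage_pseudobulk(cfg: dict, outdir: Path) -> dict:
    cells = pd.read_csv(outdir / "cells.csv", index_col=0)
    cells.index = cells.index.astype(str)
    space = read_reduced_space(cfg["input.coords"])
    shared = space.index.intersection(cells.index)
    space = space.loc[shared]
    cells = cells.loc[shared]
    graph = knn_graph(space, k=int(cfg["pseudobulk.k"]))
    nhoods = make_neighborhoods(
        graph,
        proportion=float(cfg["pseudobulk.proportion"]),
        seed=stage_seed(cfg["seed"], "pseudobulk"),
        refined=bool(cfg["pseudobulk.refined"]),
    )
    loci = tuple(str(cfg["preprocess.loci"]).split(","))
    fs = vdj_feature_space(
        cells,
        nhoods,
        renormalize_missing=bool(cfg["pseudobulk.renormalize_missing"]),
        loci=loci,
    )
    save_neighborhoods(nhoods, outdir)
    save_feature_space(fs, outdir)
    return {
        "n_cells": int(len(cells)),
        "n_neighborhoods": int(nhoods.n_nhoods),
        "n_features": int(fs.features.shape[1]),
    }


def stage_trajectory(cfg: dict, outdir: Path) -> dict:
    fs = load_feature_space(outdir)
    terminals_raw = str(cfg["trajectory.terminals"]).strip()
    terminals = (
        None
        if terminals_raw.lower() in {"auto", ""}
        else [t.strip() for t in terminals_raw.split(",")]
    )
    params = TrajectoryParams(
        n_comps=int(cfg["trajectory.n_comps"]),
        k_dm=int(cfg["trajectory.k_dm"]),
        ka=int(cfg["trajectory.ka"]),
        n_eigs=(
            "auto"
            if str(cfg["trajectory.n_eigs"]).lower() == "auto"
            else int(cfg["trajectory.n_eigs"])
        ),
        n_waypoints=int(cfg["trajectory.n_waypoints"]),
        k_traj=int(cfg["trajectory.k_traj"]),
        k_mc=(
            None
            if str(cfg["trajectory.k_mc"]).lower() == "auto"
            else int(cfg["trajectory.k_mc"])
        ),
        tol=float(cfg["trajectory.tol"]),
        max_iter=int(cfg["trajectory.max_iter"]),
        seed=stage_seed(cfg["seed"], "trajectory"),
    )
    root = str(cfg["trajectory.root"]).strip() or None
    root_label = str(cfg["trajectory.root_label"]).strip() or None
    model = MarkovTrajectory.from_feature_space(
        fs, root=root, root_label=root_label, terminal_states=terminals, params=params
    )
    result = model.fit()
    frame = result.to_frame()
    frame.index.name = "nhood_id"
    frame.to_csv(outdir / "pseudobulk_trajectory.csv", float_format="%.17g")
    (outdir / "trajectory_summary.txt").write_text(result.summary() + "\n")
    return {
        "n_states": int(len(frame)),
        "terminal_states": [str(t) for t in result.terminal_states],
        "fates": result.fates,
    }


def stage_project(cfg: dict, outdir: Path) -> dict:
    from types import SimpleNamespace

    frame = pd.read_csv(outdir / "pseudobulk_trajectory.csv", index_col=0)
    frame.index = frame.index.astype(str)
    prob_cols = [c for c in frame.columns if c.startswith("prob_")]
    result = SimpleNamespace(
        pseudotime=frame["pseudotime"],
        branch_probs=frame[prob_cols].rename(
            columns={c: c[len("prob_"):] for c in prob_cols}
        ),
    )
    nhoods = load_neighborhoods(outdir)
    cells = pd.read_csv(outdir / "cells.csv", index_col=0)
    cells.index = cells.index.astype(str)
    from .projection import project_to_cells

    table = project_to_cells(result, nhoods, cells=cells)
    write_cell_trajectory(table, outdir / "cell_trajectory.csv")
    return {
        "n_cells_projected": int(len(table)),
        "n_cells_dropped": int(table.attrs["n_dropped"]),
    }


STAGES = [
    ("preprocess", stage_preprocess),
    ("pseudobulk", stage_pseudobulk),
    ("trajectory", stage_trajectory),
    ("project", stage_project),
]


def run_pipeline(config: dict, outdir) -> Path:
    """Run every stage in order, writing outputs and a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = resolve_config(config)
    write_config(cfg, outdir / "config.txt")
    manifest: dict = {
        "package": {"name": "vdjtraj", "version": __version__},
        "libraries": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "config": {k: str(v) for k, v in cfg.items()},
        "stage_seeds": {
            name: stage_seed(cfg["seed"], name) for name, _ in STAGES
        },
        "stages": {},
    }
    for name, fn in STAGES:
        try:
            manifest["stages"][name] = fn(cfg, outdir)
        except Exception as err:
            (outdir / "FAILED").write_text(f"stage {name}: {err}\n")
            manifest["stages"][name] = {"error": str(err)}
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline failed at stage {name!r}: {err}") from err
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
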