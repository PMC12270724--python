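"""Shared fixtures: the 10-cell hand-built contig table and a full
pipeline run on the standard bifurcating simulation, computed once per
session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vdjtraj.markov import MarkovTrajectory
from vdjtraj.preprocess import setup_vdj_cells
from vdjtraj.pseudobulk import knn_graph, make_neighborhoods, vdj_feature_space
from vdjtraj.simulate import simulate_bifurcating_repertoire


def _contig(cell, cid, locus, v, d, j, c, productive=True, umi=5):
    return {
        "cell_id": cell,
        "contig_id": cid,
        "locus": locus,
        "v_call": v,
        "d_call": d,
        "j_call": j,
        "c_call": c,
        "productive": productive,
        "umi_count": umi,
    }


@pytest.fixture(scope="session")
def hand_contigs() -> pd.DataFrame:
    """10 cells: 6 productive single pairs, 2 TRA-only orphans, 2 cells
    whose TRB chain is non-productive."""
    rows = []
    # 6 complete productive alpha/beta pairs
    for i in range(6):
        cell = f"pair{i}"
        rows.append(
            _contig(cell, f"{cell}_a", "TRA", f"TRAV{i+1}", None, f"TRAJ{i+1}", "TRAC")
        )
        rows.append(
            _contig(
                cell, f"{cell}_b", "TRB", f"TRBV{i+1}", "TRBD1", f"TRBJ{i+1}", "TRBC1"
            )
        )
    # 2 orphan cells carrying only a TRA chain
    for i in range(2):
        cell = f"orphan{i}"
        rows.append(
            _contig(cell, f"{cell}_a", "TRA", "TRAV9", None, "TRAJ9", "TRAC")
        )
    # 2 cells whose TRB contig is non-productive
    for i in range(2):
        cell = f"nonprod{i}"
        rows.append(
            _contig(cell, f"{cell}_a", "TRA", "TRAV8", None, "TRAJ8", "TRAC")
        )
        rows.append(
            _contig(
                cell,
                f"{cell}_b",
                "TRB",
                "TRBV8",
                "TRBD2",
                "TRBJ8",
                "TRBC2",
                productive=False,
            )
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def hand_metadata(hand_contigs) -> pd.DataFrame:
    cells = sorted(hand_contigs["cell_id"].unique())
    return pd.DataFrame({"cell_id": cells, "cell_type": ["T"] * len(cells)})


@pytest.fixture(scope="session")
def bifurcating_run():
    """Full pipeline on the standard bifurcating dataset (n=2000, seed 7).

    Pseudobulk sampling uses proportion 0.25, the Milo-style setting for a
    dataset of this size.
    """
    sim = simulate_bifurcating_repertoire(n_cells=2000, seed=7)
    cells = setup_vdj_cells(sim.contigs, sim.metadata)
    graph = knn_graph(sim.space.loc[cells.index], k=30)
    nhoods = make_neighborhoods(graph, proportion=0.25, seed=1, refined=True)
    fs = vdj_feature_space(cells, nhoods)
    result = MarkovTrajectory.from_feature_space(fs, root_label="DP_P").fit()
    projected = result.project(nhoods, cells=cells)
    merged = projected.set_index("cell_id").join(sim.truth.set_index("cell_id"))
    return {
        "sim": sim,
        "cells": cells,
        "nhoods": nhoods,
        "fs": fs,
        "result": result,
        "projected": projected,
        "merged": merged,
    }
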