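"""Project pseudobulk-level trajectory results back onto single cells.

Each cell inherits the unweighted mean of the pseudotime and fate
probabilities of the neighborhoods that contain it; cells belonging to no
neighborhood are dropped (their count is reported on the output frame).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .pseudobulk import NeighborhoodSet

logger = logging.getLogger(__name__)


def project_to_cells(
    result,
    nhoods: NeighborhoodSet,
    cells: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cell-level pseudotime and fate probabilities from state-level results.

    Parameters
    ----------
    result : TrajectoryResults
        Fitted trajectory whose states are the neighborhood ids of
        ``nhoods``.
    nhoods : NeighborhoodSet
        The pseudobulk membership used to build the feature space.
    cells : pd.DataFrame, optional
        Cell table indexed by cell id; if given, its ``cell_type`` column is
        carried into the output.

    Returns
    -------
    pd.DataFrame
        Columns ``cell_id``, optional ``cell_type``, ``pseudotime`` and one
        ``prob_<fate>`` per fate; ``.attrs["n_dropped"]`` holds the number
        of cells in no neighborhood. Probabilities are renormalised to sum
        to one exactly.
    """
    state_ids = pd.Index(nhoods.nhood_ids)
    if not state_ids.equals(pd.Index(result.pseudotime.index)):
        if set(state_ids) != set(result.pseudotime.index):
            raise ValueError(
                "trajectory states do not match the neighborhood ids"
            )
    pt = result.pseudotime.reindex(state_ids).to_numpy()
    B = result.branch_probs.reindex(state_ids).to_numpy()
    fates = list(result.branch_probs.columns)

    M = nhoods.membership.astype(float)  # cells x nhoods
    counts = np.asarray(M.sum(axis=1)).ravel()
    keep = counts > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "project_to_cells: removed %d cell(s) not belonging to any "
            "neighborhood",
            n_dropped,
        )
    cell_pt = np.asarray(M @ pt).ravel()[keep] / counts[keep]
    cell_B = np.asarray(M @ B)[keep] / counts[keep, None]
    row_sums = cell_B.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    cell_B = cell_B / row_sums

    out = pd.DataFrame({"cell_id": nhoods.cell_ids[keep].astype(str)})
    if cells is not None and "cell_type" in cells.columns:
        out["cell_type"] = cells["cell_type"].reindex(out["cell_id"]).to_numpy()
    out["pseudotime"] = cell_pt
    for j, fate in enumerate(fates):
        out[f"prob_{fate}"] = cell_B[:, j]
    out.attrs["n_dropped"] = n_dropped
    return out
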