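"""Cell-level VDJ filtering and main-chain extraction.

Reproduces the repertoire preprocessing stage: keep productive contigs,
classify each cell's chain status from how many VDJ-class (e.g. TRB) and
VJ-class (e.g. TRA) chains were recovered, drop cells whose status is not
allowed, and collapse each cell's contigs per locus to the single chain
with the highest UMI count (the "main" chain).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io import VDJ_LOCI, ChainCalls, parse_combined_receptor

logger = logging.getLogger(__name__)

CHAIN_STATUSES = (
    "single_pair",
    "orphan_vdj",
    "orphan_vj",
    "extra_vdj",
    "extra_vj",
    "extra_pair",
    "ambiguous",
    "none",
)

#: (n VDJ-class contigs, n VJ-class contigs) -> status; counts above 2 are
#: ambiguous. (2,0)/(0,2) are classed on the "extra" axis.
_STATUS_MAP = {
    (1, 1): "single_pair",
    (1, 0): "orphan_vdj",
    (0, 1): "orphan_vj",
    (2, 1): "extra_vdj",
    (1, 2): "extra_vj",
    (2, 2): "extra_pair",
    (0, 0): "none",
    (2, 0): "extra_vdj",
    (0, 2): "extra_vj",
}

DEFAULT_ALLOWED_STATUS = frozenset({"single_pair", "extra_pair"})


@dataclass
class PreprocessParams:
    """Knobs of :func:`setup_vdj_cells`.

    already_productive
        Skip the productive filter (data pre-filtered upstream).
    allowed_chain_status
        Statuses to retain; ``None`` disables status screening entirely.
    loci
        Ordered loci to resolve (default alpha/beta TCR).
    umi_tie_break
        Tie rule for equal-UMI contigs; only the deterministic
        ``lexicographic_contig_id`` rule is defined.
    """

    already_productive: bool = False
    allowed_chain_status: frozenset[str] | None = DEFAULT_ALLOWED_STATUS
    loci: tuple[str, ...] = ("TRA", "TRB")
    umi_tie_break: str = "lexicographic_contig_id"

    def __post_init__(self):
        if not self.loci:
            raise ValueError("loci must be non-empty")
        if self.allowed_chain_status is not None:
            self.allowed_chain_status = frozenset(self.allowed_chain_status)


class EmptyResultError(ValueError):
    """Every cell was filtered out."""


def filter_productive(contigs: pd.DataFrame) -> pd.DataFrame:
    """Keep only productive contigs; logs the number removed."""
    keep = contigs["productive"].astype(bool)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_productive: removed %d non-productive contig(s)", n_removed)
    out = contigs.loc[keep].reset_index(drop=True)
    if out.empty and not contigs.empty:
        logger.warning("filter_productive: no productive contigs remain")
    return out


def assign_chain_status(cell_contigs: pd.DataFrame, loci=("TRA", "TRB")) -> str:
    """Classify one cell by its (VDJ-class, VJ-class) contig counts."""
    loci = set(loci)
    in_scope = cell_contigs.loc[cell_contigs["locus"].isin(loci)]
    n_vdj = int(in_scope["locus"].isin(VDJ_LOCI).sum())
    n_vj = len(in_scope) - n_vdj
    if n_vdj > 2 or n_vj > 2:
        return "ambiguous"
    return _STATUS_MAP[(n_vdj, n_vj)]


def extract_main_chains(
    cell_contigs: pd.DataFrame,
    loci=("TRA", "TRB"),
    tie_break: str = "lexicographic_contig_id",
) -> dict[str, ChainCalls]:
    """Resolve one cell's main chain per locus (max UMI, ties by contig id)."""
    if tie_break != "lexicographic_contig_id":
        raise ValueError(f"unknown tie_break {tie_break!r}")
    out: dict[str, ChainCalls] = {}
    for locus in loci:
        sub = cell_contigs.loc[cell_contigs["locus"] == locus]
        if sub.empty:
            out[locus] = ChainCalls()
            continue
        # sort: UMI descending, contig_id ascending -> deterministic argmax
        best = sub.sort_values(
            ["umi_count", "contig_id"], ascending=[False, True]
        ).iloc[0]
        out[locus] = ChainCalls(
            v=best["v_call"] if pd.notna(best["v_call"]) else None,
            d=best["d_call"] if pd.notna(best["d_call"]) else None,
            j=best["j_call"] if pd.notna(best["j_call"]) else None,
            c=best["c_call"] if pd.notna(best["c_call"]) else None,
        )
    return out


def _chain_columns(loci) -> list[str]:
    cols = []
    for locus in loci:
        segs = ("v", "d", "j", "c") if locus in VDJ_LOCI else ("v", "j", "c")
        cols += [f"{locus}_{s}" for s in segs]
    return cols


def setup_vdj_cells(
    contigs: pd.DataFrame,
    metadata: pd.DataFrame,
    params: PreprocessParams | None = None,
) -> pd.DataFrame:
    """Run the full cell-level preprocessing pipeline.

    Returns one row per retained cell, indexed by ``cell_id``, with the
    metadata columns, a ``chain_status`` column, and per-locus main-chain
    call columns (``TRA_v``, ``TRB_d``, ...). Cells without metadata are
    dropped with a logged count.
    """
    params = params or PreprocessParams()
    loci = params.loci

    contigs = contigs.loc[contigs["locus"].isin(loci)].reset_index(drop=True)
    known_cells = set(metadata["cell_id"])
    has_meta = contigs["cell_id"].isin(known_cells)
    n_orphan_cells = contigs.loc[~has_meta, "cell_id"].nunique()
    if n_orphan_cells:
        logger.info(
            "setup_vdj_cells: dropped %d cell(s) absent from metadata", n_orphan_cells
        )
    contigs = contigs.loc[has_meta]

    n_cells_in = contigs["cell_id"].nunique()
    if not params.already_productive:
        contigs = filter_productive(contigs)

    rows = []
    for cell_id, group in contigs.groupby("cell_id", sort=True):
        status = assign_chain_status(group, loci)
        if (
            params.allowed_chain_status is not None
            and status not in params.allowed_chain_status
        ):
            continue
        chains = extract_main_chains(group, loci, params.umi_tie_break)
        row: dict[str, object] = {"cell_id": cell_id, "chain_status": status}
        for locus in loci:
            ch = chains[locus]
            row[f"{locus}_v"] = ch.v
            row[f"{locus}_j"] = ch.j
            row[f"{locus}_c"] = ch.c
            if locus in VDJ_LOCI:
                row[f"{locus}_d"] = ch.d
        rows.append(row)

    if not rows:
        raise EmptyResultError(
            "no cells retained; relax allowed_chain_status or check the "
            "productive filter settings"
        )
    table = pd.DataFrame(rows)
    table = metadata.merge(table, on="cell_id", how="inner")
    table = table.set_index("cell_id", verify_integrity=True).sort_index()
    # stable column order: metadata, status, chain calls
    meta_cols = [c for c in metadata.columns if c != "cell_id"]
    table = table[meta_cols + ["chain_status"] + _chain_columns(loci)]
    logger.info(
        "setup_vdj_cells: retained %d of %d cell(s)", len(table), n_cells_in
    )
    return table


def cells_from_combined_strings(
    metadata: pd.DataFrame,
    column: str = "CTgene",
    params: PreprocessParams | None = None,
) -> pd.DataFrame:
    """Build the cell table from a combined-receptor string column.

    This path assumes upstream tooling already kept one (productive) chain
    per locus, so chain status is derived from chain presence alone:
    both chains -> single_pair, one -> orphan, none -> none.
    """
    params = params or PreprocessParams(already_productive=True)
    vj_locus, vdj_locus = params.loci[0], params.loci[1]
    rows = []
    for _, rec in metadata.iterrows():
        chains = parse_combined_receptor(str(rec[column]), (vj_locus, vdj_locus))
        has_vj = not chains[vj_locus].absent
        has_vdj = not chains[vdj_locus].absent
        status = _STATUS_MAP[(int(has_vdj), int(has_vj))]
        if (
            params.allowed_chain_status is not None
            and status not in params.allowed_chain_status
        ):
            continue
        row: dict[str, object] = {"cell_id": rec["cell_id"], "chain_status": status}
        for locus in params.loci:
            ch = chains[locus]
            row[f"{locus}_v"] = ch.v
            row[f"{locus}_j"] = ch.j
            row[f"{locus}_c"] = ch.c
            if locus in VDJ_LOCI:
                row[f"{locus}_d"] = ch.d
        rows.append(row)
    if not rows:
        raise EmptyResultError("no cells retained from combined-receptor strings")
    table = pd.DataFrame(rows)
    meta = metadata.drop(columns=[column])
    table = meta.merge(table, on="cell_id", how="inner")
    table = table.set_index("cell_id", verify_integrity=True).sort_index()
    meta_cols = [c for c in meta.columns if c != "cell_id"]
    return table[meta_cols + ["chain_status"] + _chain_columns(params.loci)]
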