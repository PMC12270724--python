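"""Readers and writers for repertoire and trajectory tables.

Supports the AIRR Rearrangement TSV dialect, the 10x Genomics
``filtered_contig_annotations.csv`` dialect, and the combined-receptor
string dialect in which the VJ-class chain (e.g. TRA) and the VDJ-class
chain (e.g. TRB) of a cell are packed into a single string: genes are
separated by periods, chains by an underscore, and ``NA`` marks a missing
gene or an absent chain (``TRAV23.TRAJ21.TRAC_TRBV5-1.NA.TRBJ2-1.TRBC2``).

All readers return a contig table — one row per sequenced receptor chain —
with the standardised columns in :data:`CONTIG_COLUMNS`. Missing gene calls
are ``NaN``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Standardised contig-table columns produced by every reader.
CONTIG_COLUMNS = [
    "cell_id",
    "contig_id",
    "locus",
    "v_call",
    "d_call",
    "j_call",
    "c_call",
    "productive",
    "umi_count",
]

#: Loci whose chains carry a D segment.
VDJ_LOCI = frozenset({"TRB", "TRD", "IGH"})
#: Loci whose chains recombine V to J directly (no D segment).
VJ_LOCI = frozenset({"TRA", "TRG", "IGK", "IGL"})
KNOWN_LOCI = VDJ_LOCI | VJ_LOCI

_TRUE_TOKENS = {"T", "TRUE", "true", "True"}
_FALSE_TOKENS = {"F", "FALSE", "false", "False"}
_MISSING_TOKENS = {"", "None", "NA", "nan", "NaN"}


class RepertoireFormatError(ValueError):
    """A repertoire file violates its dialect's contract."""


@dataclass(frozen=True)
class ChainCalls:
    """The V/(D)/J/C gene calls of one receptor chain.

    A chain with every field ``None`` represents an absent chain.
    """

    v: str | None = None
    d: str | None = None
    j: str | None = None
    c: str | None = None

    @property
    def absent(self) -> bool:
        return self.v is None and self.d is None and self.j is None and self.c is None


def _clean_gene(value) -> str | None:
    """Normalise a gene-call token; en-dashes become ASCII hyphens."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    token = str(value).strip().replace("–", "-").replace("—", "-")
    if token in _MISSING_TOKENS:
        return None
    return token


def _parse_productive(value, row_index: int) -> bool:
    token = str(value).strip()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise RepertoireFormatError(
        f"row {row_index}: unparsable productive value {value!r}"
    )


def _finalise_contigs(df: pd.DataFrame, source: str) -> pd.DataFrame:
    """Drop contigs on unknown loci (logged) and enforce the D-segment rule."""
    known = df["locus"].isin(KNOWN_LOCI)
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.info("%s: dropped %d contig(s) with unmappable locus", source, n_dropped)
    df = df.loc[known].reset_index(drop=True)
    # VJ-class chains recombine without a D segment; scrub stray calls.
    df.loc[df["locus"].isin(list(VJ_LOCI)), "d_call"] = None
    return df[CONTIG_COLUMNS]


def read_airr(path) -> pd.DataFrame:
    """Read an AIRR Rearrangement TSV into a standardised contig table.

    ``sequence_id`` (or ``contig_id``) supplies the contig id and
    ``duplicate_count``/``umi_count``/``umis`` the UMI count (default 0).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("cell_id", "locus", "v_call", "j_call", "productive"):
        if col not in raw.columns:
            raise RepertoireFormatError(f"AIRR file missing mandatory column {col!r}")
    umi_col = next(
        (c for c in ("duplicate_count", "umi_count", "umis") if c in raw.columns), None
    )
    contig_col = next(
        (c for c in ("sequence_id", "contig_id") if c in raw.columns), None
    )
    out = pd.DataFrame(
        {
            "cell_id": raw["cell_id"].astype(str),
            "contig_id": (
                raw[contig_col].astype(str)
                if contig_col
                else [f"contig_{i}" for i in range(len(raw))]
            ),
            "locus": raw["locus"].str.strip(),
            "v_call": raw["v_call"].map(_clean_gene),
            "d_call": raw["d_call"].map(_clean_gene) if "d_call" in raw else None,
            "j_call": raw["j_call"].map(_clean_gene),
            "c_call": raw["c_call"].map(_clean_gene) if "c_call" in raw else None,
            "productive": [
                _parse_productive(v, i) for i, v in enumerate(raw["productive"])
            ],
            "umi_count": (
                pd.to_numeric(raw[umi_col].replace("", "0")).astype(int)
                if umi_col
                else 0
            ),
        }
    )
    return _finalise_contigs(out, "read_airr")


def read_10x_contigs(path) -> pd.DataFrame:
    """Read a 10x ``filtered_contig_annotations.csv`` into a contig table.

    ``chain="Multi"`` rows (and any chain outside the supported loci) are
    dropped with a logged count rather than raising.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("barcode", "chain", "v_gene", "j_gene", "productive"):
        if col not in raw.columns:
            raise RepertoireFormatError(f"10x file missing mandatory column {col!r}")
    out = pd.DataFrame(
        {
            "cell_id": raw["barcode"].astype(str),
            "contig_id": (
                raw["contig_id"].astype(str)
                if "contig_id" in raw
                else [f"contig_{i}" for i in range(len(raw))]
            ),
            "locus": raw["chain"].str.strip(),
            "v_call": raw["v_gene"].map(_clean_gene),
            "d_call": raw["d_gene"].map(_clean_gene) if "d_gene" in raw else None,
            "j_call": raw["j_gene"].map(_clean_gene),
            "c_call": raw["c_gene"].map(_clean_gene) if "c_gene" in raw else None,
            "productive": [
                _parse_productive(v, i) for i, v in enumerate(raw["productive"])
            ],
            "umi_count": (
                pd.to_numeric(raw["umis"].replace("", "0")).astype(int)
                if "umis" in raw
                else 0
            ),
        }
    )
    return _finalise_contigs(out, "read_10x_contigs")


def parse_combined_receptor(
    s: str, loci: tuple[str, str] = ("TRA", "TRB")
) -> dict[str, ChainCalls]:
    """Parse a combined-receptor string into per-locus :class:`ChainCalls`.

    The string holds the VJ-class chain first (``V.J.C``) and the VDJ-class
    chain second (``V.D.J.C``), joined by a single underscore. ``NA`` in a
    field means the gene call is missing; a whole segment equal to ``NA``
    means the chain is absent.
    """
    if not s:
        raise RepertoireFormatError("empty combined-receptor string")
    s = s.replace("–", "-").replace("—", "-")
    parts = s.split("_")
    if len(parts) != 2:
        raise RepertoireFormatError(
            f"expected exactly one underscore in combined-receptor string: {s!r}"
        )
    vj_locus, vdj_locus = loci

    def _segment(segment: str, n_fields: int) -> ChainCalls:
        if segment == "NA":
            return ChainCalls()
        fields = segment.split(".")
        if len(fields) != n_fields:
            raise RepertoireFormatError(
                f"segment {segment!r}: expected {n_fields} period-separated fields, "
                f"got {len(fields)}"
            )
        calls = [None if f == "NA" else f for f in fields]
        if n_fields == 3:
            return ChainCalls(v=calls[0], d=None, j=calls[1], c=calls[2])
        return ChainCalls(v=calls[0], d=calls[1], j=calls[2], c=calls[3])

    return {vj_locus: _segment(parts[0], 3), vdj_locus: _segment(parts[1], 4)}


def combined_receptor_string(
    chains: dict[str, ChainCalls], loci: tuple[str, str] = ("TRA", "TRB")
) -> str:
    """Serialise per-locus chain calls into the combined-receptor dialect.

    Inverse of :func:`parse_combined_receptor` on its output language.
    """
    vj_locus, vdj_locus = loci

    def _fmt(call: str | None) -> str:
        return "NA" if call is None else call

    def _segment(chain: ChainCalls | None, with_d: bool) -> str:
        if chain is None or chain.absent:
            return "NA"
        fields = (
            [chain.v, chain.d, chain.j, chain.c] if with_d else [chain.v, chain.j, chain.c]
        )
        return ".".join(_fmt(f) for f in fields)

    return "_".join(
        [_segment(chains.get(vj_locus), False), _segment(chains.get(vdj_locus), True)]
    )


def read_cell_metadata(path) -> pd.DataFrame:
    """Read the cell metadata CSV (``cell_id``, ``cell_type``, extras)."""
    meta = pd.read_csv(path, dtype={"cell_id": str})
    if "cell_id" not in meta.columns:
        raise RepertoireFormatError("metadata missing mandatory column 'cell_id'")
    if meta["cell_id"].duplicated().any() or (meta["cell_id"] == "").any():
        raise RepertoireFormatError("metadata cell_id must be unique and non-empty")
    return meta


def read_reduced_space(path) -> pd.DataFrame:
    """Read a cells x dims coordinate CSV (first column = cell id)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    coords = df.to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        raise RepertoireFormatError("reduced space contains non-finite entries")
    if coords.shape[1] < 2:
        raise RepertoireFormatError("reduced space needs at least 2 dimensions")
    return df


def write_cell_trajectory(table: pd.DataFrame, path) -> None:
    """Write the per-cell trajectory table as CSV.

    Column order is fixed (cell_id, [cell_type], pseudotime, prob_*) and
    floats are printed at 17 significant digits so the matching reader
    round-trips bit-identically.
    """
    if "cell_id" not in table.columns or "pseudotime" not in table.columns:
        raise RepertoireFormatError(
            "cell trajectory table requires cell_id and pseudotime columns"
        )
    if table["cell_id"].duplicated().any():
        raise RepertoireFormatError("duplicate cell_id in trajectory table")
    prob_cols = sorted(c for c in table.columns if c.startswith("prob_"))
    cols = ["cell_id"]
    if "cell_type" in table.columns:
        cols.append("cell_type")
    cols += ["pseudotime"] + prob_cols
    table[cols].to_csv(path, index=False, float_format="%.17g")


def read_cell_trajectory(path) -> pd.DataFrame:
    """Read a table written by :func:`write_cell_trajectory`."""
    df = pd.read_csv(path, dtype={"cell_id": str}, float_precision="round_trip")
    if "pseudotime" not in df.columns:
        raise RepertoireFormatError("trajectory file missing 'pseudotime' column")
    return df
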