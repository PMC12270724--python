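"""Agreement statistics for comparing two trajectory outputs.

Pearson correlation, Lin's concordance correlation coefficient (CCC),
Kendall's tau-b, mean absolute error, and a Bland-Altman summary. Tau-b is
tie-corrected, which matters here because projected pseudotime contains
ties by construction (cells sharing identical neighborhood sets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats


def _pair(x, y, min_len: int = 2) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < min_len:
        raise ValueError(f"need at least {min_len} observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    return x, y


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x, y = _pair(x, y)
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("pearson undefined for a zero-variance vector")
    return float(scipy.stats.pearsonr(x, y).statistic)


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments).

    2 cov(x,y) / (var(x) + var(y) + (mean(x) - mean(y))^2) with
    n-denominator moments. Two equal constant vectors give 1, unequal
    constants give 0.
    """
    x, y = _pair(x, y)
    vx, vy = np.var(x), np.var(y)
    dmean = x.mean() - y.mean()
    denom = vx + vy + dmean**2
    if denom == 0:
        return 1.0  # both constant and equal
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2 * cov / denom)


def _tau_b_enumerate(x: np.ndarray, y: np.ndarray) -> float:
    """Tau-b by explicit pair enumeration (vectorised O(n^2))."""
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(len(x), k=1)
    sx, sy = dx[iu], dy[iu]
    concordant_minus_discordant = float(np.sum(sx * sy))
    n0 = len(sx)
    tied_x = float(np.sum(sx == 0))
    tied_y = float(np.sum(sy == 0))
    denom = np.sqrt((n0 - tied_x) * (n0 - tied_y))
    if denom == 0:
        raise ValueError("kendall tau undefined: a vector is entirely tied")
    return concordant_minus_discordant / denom


def kendall_tau(x, y) -> float:
    """Kendall's tau-b; exact pair enumeration up to n=2000, O(n log n) above."""
    x, y = _pair(x, y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("kendall tau undefined: a vector is entirely tied")
    if len(x) <= 2000:
        return _tau_b_enumerate(x, y)
    return float(scipy.stats.kendalltau(x, y).statistic)


def mae(x, y) -> float:
    """Mean absolute error."""
    x, y = _pair(x, y, min_len=1)
    return float(np.mean(np.abs(x - y)))


@dataclass
class BlandAltman:
    """Bland-Altman summary: bias, 1.96-SD limits and the per-point table."""

    bias: float
    lower_limit: float
    upper_limit: float
    table: pd.DataFrame  # columns: mean, difference

    def as_dict(self) -> dict[str, float]:
        return {
            "bias": self.bias,
            "lower_limit": self.lower_limit,
            "upper_limit": self.upper_limit,
        }


def bland_altman_summary(x, y) -> BlandAltman:
    """Bias and limits of agreement for x - y, plus the plot table."""
    x, y = _pair(x, y, min_len=3)
    diff = x - y
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    table = pd.DataFrame({"mean": (x + y) / 2.0, "difference": diff})
    return BlandAltman(
        bias=bias,
        lower_limit=bias - 1.96 * sd,
        upper_limit=bias + 1.96 * sd,
        table=table,
    )


def compare_trajectories(a: pd.DataFrame, b: pd.DataFrame) -> dict[str, dict]:
    """All agreement metrics between two cell-trajectory tables.

    Tables are joined on ``cell_id``; metrics are computed for pseudotime
    and for every shared ``prob_<fate>`` column.
    """
    merged = a.merge(b, on="cell_id", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("no shared cells between the two trajectory tables")
    shared = [
        c
        for c in a.columns
        if c in b.columns and (c == "pseudotime" or c.startswith("prob_"))
    ]
    def _safe(fn, *args):
        # correlation metrics are undefined on constant columns (e.g. the
        # probability column of a single-fate trajectory); report null
        try:
            return fn(*args)
        except ValueError:
            return None

    out: dict[str, dict] = {}
    for col in shared:
        xa = merged[f"{col}_a"].to_numpy(dtype=float)
        xb = merged[f"{col}_b"].to_numpy(dtype=float)
        ba = bland_altman_summary(xa, xb)
        out[col] = {
            "pearson": _safe(pearson, xa, xb),
            "lin_ccc": lin_ccc(xa, xb),
            "kendall_tau": _safe(kendall_tau, xa, xb),
            "mae": mae(xa, xb),
            "bland_altman": ba.as_dict(),
            "n": int(len(merged)),
        }
    return out
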