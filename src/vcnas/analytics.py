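"""Summaries of a trial ledger: error histograms and box-whisker statistics.

These reproduce the two analytic views used to study how structure drives
performance: the frequency distribution of validation error over all
trained networks (2%-wide bins), and five-number summaries of the error
against each structural attribute (VC-dimension on log-spaced bins, depth,
and per-type layer counts).  Both are pure functions of the ledger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "error_histogram",
    "attribute_boxstats",
    "AttributeBinning",
    "ATTRIBUTES",
]

ATTRIBUTES = ("vc_dimension", "depth", "n_conv", "n_dense", "n_maxpool")


def error_histogram(errors, bin_width: float = 2.0) -> pd.DataFrame:
    """Histogram of classification error percentages in fixed-width bins.

    ``errors`` are fractions in [0, 1]; bins are left-closed right-open
    over [0, 100] except the last, which includes 100.  Returns a frame
    with ``bin_left``, ``bin_right`` and ``count`` whose counts sum to
    ``len(errors)``.
    """
    errors = np.asarray(list(errors), dtype=float)
    if errors.size == 0:
        raise ValueError("ledger holds no trial errors")
    pct = errors * 100.0
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    if edges[-1] < 100.0:
        edges = np.append(edges, 100.0)
    counts, _ = np.histogram(pct, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


@dataclass
class AttributeBinning:
    """Per-bin five-number summaries of error against one attribute."""

    attribute: str
    bin_edges: np.ndarray
    table: pd.DataFrame  # columns: bin_left, bin_right, count, min, q1, median, q3, max, whisker_lo, whisker_hi
    global_min_bin: int  # index of the bin containing the overall best error

    def __post_init__(self) -> None:
        if self.attribute not in ATTRIBUTES:
            raise ValueError(f"unknown attribute {self.attribute!r}")


def _five_numbers(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(values.max()),
        "whisker_lo": float(inside.min()),
        "whisker_hi": float(inside.max()),
    }


def _default_edges(attribute: str, values: np.ndarray, n_bins: int) -> np.ndarray:
    if attribute == "vc_dimension":
        lo, hi = values.min(), values.max()
        if lo <= 0:
            lo = min(v for v in values if v > 0) if (values > 0).any() else 1.0
        if lo == hi:
            hi = lo * 1.0001
        return np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    # small integer attributes: one bin per observed value
    vmax = int(values.max())
    return np.arange(-0.5, vmax + 1.5, 1.0)


def attribute_boxstats(
    ledger_frame: pd.DataFrame,
    attribute: str,
    bin_edges=None,
    n_bins: int = 10,
) -> AttributeBinning:
    """Box-whisker statistics of error (%) binned by a structural attribute.

    ``ledger_frame`` needs an ``error`` column (fraction) and a column for
    the attribute.  Quartiles use linear interpolation between order
    statistics; whiskers follow the Tukey rule (most extreme points within
    1.5·IQR of the quartiles).  VC-dimension defaults to ``n_bins``
    log-spaced bins between the observed extremes; integer attributes get
    one bin per value.  Empty bins report count 0 and no summary.
    """
    if attribute not in ATTRIBUTES:
        raise ValueError(f"unknown attribute {attribute!r}")
    if attribute not in ledger_frame or "error" not in ledger_frame:
        raise ValueError("ledger frame must have 'error' and attribute columns")
    values = ledger_frame[attribute].to_numpy(dtype=float)
    errors = ledger_frame["error"].to_numpy(dtype=float) * 100.0
    edges = (
        np.asarray(bin_edges, dtype=float)
        if bin_edges is not None
        else _default_edges(attribute, values, n_bins)
    )
    idx = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = errors[idx == b]
        row = {"bin_left": edges[b], "bin_right": edges[b + 1], "count": len(sel)}
        if len(sel):
            row.update(_five_numbers(sel))
        rows.append(row)
    table = pd.DataFrame(rows)
    best = int(idx[np.argmin(errors)])
    return AttributeBinning(attribute, edges, table, best)
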