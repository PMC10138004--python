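"""Cross-recurrence quantification: RR, DET, LAM and MDL.

All four indices are deterministic functions of the binary matrix and
derive from run-length histograms:

* ``RR``  — density of recurrent cells, ``sum / (N * M)``;
* ``DET`` — share of recurrent cells lying on diagonal runs of length
  at least ``lmin`` (co-evolving episodes);
* ``LAM`` — share lying on vertical runs of length at least ``vmin``
  (one system dwelling while the other moves);
* ``MDL`` — mean length of the diagonal runs of length >= ``lmin``.

Runs are *maximal*: cells beyond the matrix border count as zeros, so a
run touching the border is still a single maximal run.  Only the
direction parallel to the main diagonal (i -> i+1, j -> j+1) is counted
for diagonals; vertical runs vary the second index at fixed first index
(a vertical line in the plot, whose x axis is the first series' sample
index).  Empty sums follow the 0/0 -> 0 convention so degenerate
matrices never raise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LineHistograms",
    "CRQAMetrics",
    "line_histograms",
    "recurrence_rate",
    "determinism",
    "laminarity",
    "mean_diagonal_length",
    "crqa",
]


def _cells(matrix) -> np.ndarray:
    c = getattr(matrix, "cells", matrix)
    c = np.asarray(c)
    if c.ndim != 2 or c.size == 0:
        raise ValueError("expected a nonempty 2-D binary matrix")
    return c.astype(bool)


def _run_lengths(flat: np.ndarray) -> np.ndarray:
    """Lengths of maximal 1-runs in a flat boolean array."""
    padded = np.zeros(flat.size + 2, dtype=np.int8)
    padded[1:-1] = flat
    step = np.diff(padded)
    return np.flatnonzero(step == -1) - np.flatnonzero(step == 1)


def _histogram(lengths: np.ndarray) -> dict[int, int]:
    if lengths.size == 0:
        return {}
    counts = np.bincount(lengths)
    return {int(l): int(c) for l, c in enumerate(counts) if l > 0 and c > 0}


@dataclass(frozen=True)
class LineHistograms:
    """Counts of maximal diagonal and vertical 1-runs, keyed by length."""

    diagonal: dict[int, int]
    vertical: dict[int, int]

    def diagonal_points(self) -> int:
        """Total recurrent cells counted through diagonal runs."""
        return sum(l * c for l, c in self.diagonal.items())

    def vertical_points(self) -> int:
        return sum(l * c for l, c in self.vertical.items())


@dataclass(frozen=True)
class CRQAMetrics:
    rr: float
    det: float
    lam: float
    mdl: float
    lmin: int = 2
    vmin: int = 2


def line_histograms(matrix) -> LineHistograms:
    """Histogram every maximal diagonal and vertical run of 1s."""
    cells = _cells(matrix)
    n, m = cells.shape

    # Vertical runs: fixed first index, varying second.  A zero column
    # appended to each row separates the rows after raveling.
    vflat = np.hstack([cells, np.zeros((n, 1), dtype=bool)]).ravel()
    vertical = _histogram(_run_lengths(vflat))

    # Diagonal runs: concatenate every diagonal with zero separators.
    buf = np.zeros(cells.size + n + m - 1, dtype=bool)
    pos = 0
    for offset in range(-(n - 1), m):
        diag = np.diagonal(cells, offset=offset)
        buf[pos : pos + diag.size] = diag
        pos += diag.size + 1
    diagonal = _histogram(_run_lengths(buf))

    return LineHistograms(diagonal, vertical)


def recurrence_rate(matrix) -> float:
    """Density of recurrent cells: sum over N*M."""
    return float(_cells(matrix).mean())


def determinism(hist: LineHistograms, lmin: int = 2) -> float:
    """Fraction of recurrence mass on diagonal runs of length >= lmin."""
    total = hist.diagonal_points()
    if total == 0:
        return 0.0
    kept = sum(l * c for l, c in hist.diagonal.items() if l >= lmin)
    return kept / total


def laminarity(hist: LineHistograms, vmin: int = 2) -> float:
    """Fraction of recurrence mass on vertical runs of length >= vmin."""
    total = hist.vertical_points()
    if total == 0:
        return 0.0
    kept = sum(v * c for v, c in hist.vertical.items() if v >= vmin)
    return kept / total


def mean_diagonal_length(hist: LineHistograms, lmin: int = 2) -> float:
    """Average length of diagonal runs of length >= lmin (0 if none)."""
    count = sum(c for l, c in hist.diagonal.items() if l >= lmin)
    if count == 0:
        return 0.0
    mass = sum(l * c for l, c in hist.diagonal.items() if l >= lmin)
    return mass / count


def crqa(matrix, lmin: int = 2, vmin: int = 2) -> CRQAMetrics:
    """All four indices of one cross-recurrence matrix."""
    hist = line_histograms(matrix)
    return CRQAMetrics(
        rr=recurrence_rate(matrix),
        det=determinism(hist, lmin),
        lam=laminarity(hist, vmin),
        mdl=mean_diagonal_length(hist, lmin),
        lmin=lmin,
        vmin=vmin,
    )
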