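"""Cross-recurrence matrices between two trajectories in one phase space.

The cross-recurrence matrix of two embedded trajectories ``a`` (N
points) and ``b`` (M points) is the binary N x M matrix

    CR[i, j] = 1   iff   dist(a_i, b_j) <= epsilon,

with the threshold ``epsilon`` a fixed fraction of the diameter of the
*joint* point cloud, so that both series are judged in one shared phase
space with a single distance scale.  Boundary ties count as recurrent
(the Heaviside convention Theta(0) = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "VALID_NORMS",
    "CrossRecurrenceMatrix",
    "phase_space_diameter",
    "cross_recurrence_matrix",
    "render_crp",
    "write_matrix_text",
    "read_matrix_text",
]

VALID_NORMS = ("euclidean", "maximum")
_CHUNK = 2048  # rows per cdist block; bounds peak memory on long records

_METRIC = {"euclidean": "euclidean", "maximum": "chebyshev"}


def _points(obj) -> np.ndarray:
    pts = getattr(obj, "points", obj)
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2:
        raise ValueError("expected a Trajectory or an (N, n) point matrix")
    return pts


def _check_norm(norm: str) -> str:
    if norm not in VALID_NORMS:
        raise ValueError(f"norm must be one of {VALID_NORMS}, got {norm!r}")
    return _METRIC[norm]


@dataclass(frozen=True, eq=False)
class CrossRecurrenceMatrix:
    """Binary recurrence cells plus the threshold metadata behind them."""

    cells: np.ndarray  # bool, shape (N, M); rows index trajectory a
    epsilon: float
    epsilon_fraction: float
    norm: str
    labels: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        c = np.asarray(self.cells)
        if c.ndim != 2:
            raise ValueError("cells must be a 2-D matrix")
        object.__setattr__(self, "cells", c.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    @property
    def n_recurrent(self) -> int:
        return int(self.cells.sum())


def phase_space_diameter(a, b, norm: str = "euclidean") -> float:
    """Maximum pairwise distance over the union of both point clouds."""
    metric = _check_norm(norm)
    pa, pb = _points(a), _points(b)
    if pa.shape[1] != pb.shape[1]:
        raise ValueError(
            f"embedding dimension mismatch: {pa.shape[1]} vs {pb.shape[1]}; "
            "resolve shared embedding parameters before comparing"
        )
    union = np.vstack([pa, pb])
    if norm == "maximum":
        # Chebyshev diameter reduces to the largest per-coordinate range.
        return float(np.max(union.max(axis=0) - union.min(axis=0)))
    best = 0.0
    for start in range(0, union.shape[0], _CHUNK):
        block = cdist(union[start : start + _CHUNK], union, metric=metric)
        best = max(best, float(block.max()))
    return best


def cross_recurrence_matrix(
    a,
    b,
    epsilon_fraction: float = 0.006,
    norm: str = "euclidean",
    labels: tuple[str, str] | None = None,
) -> CrossRecurrenceMatrix:
    """Threshold the cross-distance matrix at a fraction of the joint diameter.

    Parameters
    ----------
    a, b
        Trajectories (or raw point matrices) of equal embedding dimension.
    epsilon_fraction
        epsilon as a fraction of the joint phase-space diameter, in (0, 1).
        The default is the conventional 0.6%; sparse matrices at that
        setting are expected on well-spread clouds, so the fraction is a
        first-class analysis parameter.
    norm
        ``"euclidean"`` or ``"maximum"``.
    """
    if not 0 < epsilon_fraction < 1:
        raise ValueError(f"epsilon_fraction must lie in (0, 1), got {epsilon_fraction}")
    metric = _check_norm(norm)
    pa, pb = _points(a), _points(b)
    diameter = phase_space_diameter(pa, pb, norm)
    if diameter == 0:
        raise ValueError(
            "zero phase-space diameter (all points coincide): the recurrence "
            "threshold is undefined"
        )
    epsilon = epsilon_fraction * diameter
    cells = np.empty((pa.shape[0], pb.shape[0]), dtype=bool)
    for start in range(0, pa.shape[0], _CHUNK):
        stop = start + _CHUNK
        cells[start:stop] = cdist(pa[start:stop], pb, metric=metric) <= epsilon
    if labels is None:
        labels = (getattr(a, "label", ""), getattr(b, "label", ""))
    return CrossRecurrenceMatrix(cells, float(epsilon), float(epsilon_fraction), norm, labels)


def render_crp(matrix: CrossRecurrenceMatrix, path) -> None:
    """Write the CRP as an exact 1-pixel-per-cell raster (PNG).

    Recurrent cells are black, non-recurrent white.  The x axis runs
    over the sample index of the first trajectory, the y axis (bottom
    up) over the second.
    """
    from PIL import Image

    img = np.where(matrix.cells.T[::-1], 0, 255).astype(np.uint8)
    Image.fromarray(img, mode="L").save(path)


def write_matrix_text(matrix: CrossRecurrenceMatrix, path) -> None:
    """Export cells as compact 0/1 rows with a metadata header line."""
    with open(path, "w") as fh:
        fh.write(
            f"# epsilon={matrix.epsilon!r} epsilon_fraction={matrix.epsilon_fraction!r} "
            f"norm={matrix.norm} labels={matrix.labels[0]}|{matrix.labels[1]}\n"
        )
        for row in matrix.cells:
            fh.write("".join("1" if c else "0" for c in row) + "\n")


def read_matrix_text(path) -> CrossRecurrenceMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("missing metadata header line")
        meta = dict(tok.split("=", 1) for tok in header[1:].split())
        rows = [line.strip() for line in fh if line.strip()]
    cells = np.array([[ch == "1" for ch in row] for row in rows], dtype=bool)
    la, _, lb = meta.get("labels", "|").partition("|")
    return CrossRecurrenceMatrix(
        cells,
        float(meta["epsilon"]),
        float(meta["epsilon_fraction"]),
        meta["norm"],
        (la, lb),
    )
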