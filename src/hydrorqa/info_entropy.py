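"""Discrete entropy and mutual information between two factor records.

Records are discretized into equal-width bins over their own range (a
value on an interior edge belongs to the upper bin; the maximum goes to
the top bin).  Entropies are reported in bits.  Mutual information is
computed through the entropy identity I(X;Y) = H(X) + H(Y) - H(X,Y)
and clipped at zero against rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiscretizedSeries",
    "InfoMetrics",
    "discretize",
    "entropy",
    "joint_entropy",
    "mutual_information",
    "info_metrics",
    "series_mutual_information",
]


@dataclass(frozen=True, eq=False)
class DiscretizedSeries:
    symbols: np.ndarray  # integers in [0, n_bins)
    n_bins: int
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.symbols, dtype=np.int64).ravel()
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if s.size == 0:
            raise ValueError("empty symbol vector")
        if s.min() < 0 or s.max() >= self.n_bins:
            raise ValueError("symbols out of range [0, n_bins)")
        object.__setattr__(self, "symbols", s)
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))

    def __len__(self) -> int:
        return self.symbols.size


@dataclass(frozen=True)
class InfoMetrics:
    h_x: float
    h_y: float
    h_xy: float
    mi: float


def discretize(series, n_bins: int = 16) -> DiscretizedSeries:
    """Equal-width binning of a series (or raw vector) over [min, max]."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    v = np.asarray(getattr(series, "values", series), dtype=float).ravel()
    lo, hi = v.min(), v.max()
    if lo == hi:
        raise ValueError("cannot discretize a constant series")
    edges = np.linspace(lo, hi, n_bins + 1)
    symbols = np.minimum(
        np.floor((v - lo) / (hi - lo) * n_bins).astype(np.int64), n_bins - 1
    )
    return DiscretizedSeries(symbols, n_bins, edges)


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def entropy(d: DiscretizedSeries) -> float:
    """Shannon entropy of the empirical symbol distribution, in bits."""
    return _entropy_from_counts(np.bincount(d.symbols, minlength=d.n_bins))


def joint_entropy(dx: DiscretizedSeries, dy: DiscretizedSeries) -> float:
    """Entropy of the empirical joint distribution, in bits."""
    if len(dx) != len(dy):
        raise ValueError(f"length mismatch: {len(dx)} vs {len(dy)}")
    joint = dx.symbols * dy.n_bins + dy.symbols
    return _entropy_from_counts(np.bincount(joint, minlength=dx.n_bins * dy.n_bins))


def mutual_information(dx: DiscretizedSeries, dy: DiscretizedSeries) -> float:
    """I(X;Y) = H(X) + H(Y) - H(X,Y), in bits, floored at zero."""
    return max(0.0, entropy(dx) + entropy(dy) - joint_entropy(dx, dy))


def info_metrics(dx: DiscretizedSeries, dy: DiscretizedSeries) -> InfoMetrics:
    h_x, h_y, h_xy = entropy(dx), entropy(dy), joint_entropy(dx, dy)
    return InfoMetrics(h_x, h_y, h_xy, max(0.0, h_x + h_y - h_xy))


def series_mutual_information(x, y, n_bins: int = 16) -> float:
    """Convenience: discretize two aligned raw series and return MI in bits."""
    return mutual_information(discretize(x, n_bins), discretize(y, n_bins))
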