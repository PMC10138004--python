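"""Phase-space reconstruction of scalar water-quality records.

A uniformly sampled scalar record :math:`w_1, w_2, \\dots, w_i` is
unfolded into an ``n``-dimensional trajectory by the method of delays
(Takens embedding)::

    x_k = (w_k, w_{k+t}, ..., w_{k+(n-1)t}),   k = 1 .. N,
    N   = i - (n-1) t

where ``t`` is the embedding delay (in samples) and ``n`` the embedding
dimension.  The delay is selected at the first local minimum of the
average mutual information (AMI) between the record and its lagged
copy; the dimension by the false-nearest-neighbour (FNN) criterion of
Kennel, Brown & Abarbanel (1992).

Two records that must be compared in a *shared* phase space are given a
single parameter pair by :func:`resolve_best_match`, which keeps the
larger of the two dimensions and the smaller of the two delays — a
higher dimension never loses information, and the smaller delay keeps
the finer temporal resolution of the pair.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeries",
    "EmbeddingParams",
    "Trajectory",
    "embed",
    "ami_curve",
    "ami_delay",
    "fnn_fractions",
    "fnn_dimension",
    "select_embedding_params",
    "resolve_best_match",
]


@dataclass(frozen=True, eq=False)
class TimeSeries:
    """One factor's uniformly sampled record at one station.

    Parameters
    ----------
    values
        The sample values, coerced to a 1-D float array.  Gaps must be
        filled before construction (see :func:`hydrorqa.io.read_dataset`).
    station, factor
        Identifiers, e.g. ``"ST1"`` and ``"pH"``.
    sampling_interval
        Minutes between consecutive samples (default 30).
    """

    values: np.ndarray
    station: str = ""
    factor: str = ""
    sampling_interval: float = 30.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size < 2:
            raise ValueError("a time series needs at least 2 samples")
        if not np.all(np.isfinite(v)):
            raise ValueError(
                f"series {self.label!r} contains missing/non-finite values; "
                "interpolate gaps before analysis"
            )
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def label(self) -> str:
        return f"{self.station}:{self.factor}"

    @property
    def is_constant(self) -> bool:
        return bool(np.ptp(self.values) == 0)

    def standardized(self) -> "TimeSeries":
        """Return a z-scored copy (zero mean, unit standard deviation)."""
        if self.is_constant:
            raise ValueError(f"cannot standardize constant series {self.label!r}")
        v = self.values
        return dataclasses.replace(self, values=(v - v.mean()) / v.std())

    def truncated(self, length: int) -> "TimeSeries":
        """Return the first ``length`` samples as a new series."""
        if not 2 <= length <= len(self):
            raise ValueError(
                f"truncation length {length} outside [2, {len(self)}]"
            )
        return dataclasses.replace(self, values=self.values[:length].copy())


@dataclass(frozen=True)
class EmbeddingParams:
    """An (embedding dimension, delay) pair, both in samples, both >= 1."""

    dimension: int
    delay: int

    def __post_init__(self) -> None:
        if int(self.dimension) != self.dimension or self.dimension < 1:
            raise ValueError(f"dimension must be an integer >= 1, got {self.dimension}")
        if int(self.delay) != self.delay or self.delay < 1:
            raise ValueError(f"delay must be an integer >= 1, got {self.delay}")
        object.__setattr__(self, "dimension", int(self.dimension))
        object.__setattr__(self, "delay", int(self.delay))

    @property
    def span(self) -> int:
        """Number of samples consumed by the delayed copies: (n-1)*t."""
        return (self.dimension - 1) * self.delay

    def __str__(self) -> str:  # the conventional "n/t" notation
        return f"{self.dimension}/{self.delay}"


@dataclass(frozen=True, eq=False)
class Trajectory:
    """An embedded point cloud: N x n matrix of delay vectors."""

    points: np.ndarray
    params: EmbeddingParams
    source: TimeSeries | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float)
        if p.ndim != 2:
            raise ValueError("trajectory points must form a 2-D matrix")
        object.__setattr__(self, "points", p)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def dimension(self) -> int:
        return self.points.shape[1]

    @property
    def label(self) -> str:
        return self.source.label if self.source is not None else ""


def embed(series: TimeSeries, params: EmbeddingParams) -> Trajectory:
    """Delay-embed ``series`` with the given parameters.

    The result has ``N = len(series) - (n-1)*t`` rows; row ``k`` (0-based)
    equals ``(w_k, w_{k+t}, ..., w_{k+(n-1)t})``.
    """
    v = series.values
    i = v.size
    if params.span >= i:
        n_max = (i - 1) // params.delay + 1
        raise ValueError(
            f"cannot embed length-{i} series with dimension {params.dimension} "
            f"and delay {params.delay}: (n-1)*t = {params.span} >= {i}; the "
            f"maximal feasible dimension at this delay is {n_max}"
        )
    n_rows = i - params.span
    cols = [v[m * params.delay : m * params.delay + n_rows] for m in range(params.dimension)]
    return Trajectory(np.column_stack(cols), params, series)


def ami_curve(series: TimeSeries, max_delay: int, n_bins: int = 16) -> np.ndarray:
    """Average mutual information I(w_k; w_{k+tau}) for tau = 1..max_delay.

    Estimated from an equal-width 2-D histogram with ``n_bins`` bins per
    axis spanning the series range; returned in nats (the location of
    the minimum is independent of the log base).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if max_delay < 1:
        raise ValueError("max_delay must be >= 1")
    v = series.values
    if series.is_constant:
        raise ValueError(
            f"constant series {series.label!r}: mutual information is "
            "degenerate (zero entropy at every lag)"
        )
    if max_delay >= v.size / 2:
        raise ValueError(
            f"max_delay={max_delay} requires at least {2 * max_delay + 1} "
            f"samples; series has {v.size}"
        )
    edges = np.linspace(v.min(), v.max(), n_bins + 1)
    out = np.empty(max_delay)
    for lag in range(1, max_delay + 1):
        h, _, _ = np.histogram2d(v[:-lag], v[lag:], bins=[edges, edges])
        pxy = h / h.sum()
        px = pxy.sum(axis=1)
        py = pxy.sum(axis=0)
        nz = pxy > 0
        out[lag - 1] = float(np.sum(pxy[nz] * np.log(pxy[nz] / np.outer(px, py)[nz])))
    return out


def ami_delay(
    series: TimeSeries,
    max_delay: int = 60,
    n_bins: int = 16,
    smooth: int = 3,
    order: int = 5,
) -> int:
    """Embedding delay: lag of the first local minimum of the AMI curve.

    Histogram AMI curves of strongly periodic signals carry binning
    ripple, so the raw curve is smoothed with a centred moving average
    of width ``smooth`` and a minimum only counts when it is the lowest
    value within ``order`` lags on either side.  Falls back to
    ``max_delay`` (with a logged warning) when no such minimum exists.
    """
    curve = ami_curve(series, max_delay, n_bins)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        smoothed = np.convolve(curve, kernel, mode="valid")
        offset = smooth // 2
    else:
        smoothed, offset = curve, 0
    n = smoothed.size
    for k in range(1, n - 1):
        window = smoothed[max(0, k - order) : min(n, k + order + 1)]
        if (
            smoothed[k] <= window.min()
            and smoothed[k] < smoothed[k - 1]
            and smoothed[k] <= smoothed[k + 1]
        ):
            return k + 1 + offset
    logger.warning(
        "no local AMI minimum up to lag %d for series %r; using max_delay",
        max_delay,
        series.label,
    )
    return max_delay


def fnn_fractions(
    series: TimeSeries,
    delay: int,
    max_dim: int,
    rtol: float = 15.0,
    atol: float = 2.0,
    max_points: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """False-nearest-neighbour fractions for dimensions 1..max_dim.

    For each candidate dimension ``n`` the series is embedded at ``n+1``;
    the nearest neighbour of every point (in the first ``n`` coordinates)
    is flagged false when the extra coordinate either stretches the
    neighbour distance by more than ``rtol`` or pushes the pair beyond
    ``atol`` attractor sizes apart (Kennel's two criteria).  With
    ``max_points`` set, a reproducible subsample of the embedded points
    is used for the neighbour statistics.
    """
    if delay < 1:
        raise ValueError("delay must be >= 1")
    if max_dim < 1:
        raise ValueError("max_dim must be >= 1")
    if series.is_constant:
        raise ValueError(f"constant series {series.label!r}: FNN undefined")
    v = series.values
    if max_dim * delay >= v.size:
        raise ValueError(
            f"series of length {v.size} too short to test dimension "
            f"{max_dim} at delay {delay} (needs > {max_dim * delay} samples)"
        )
    attractor_size = float(v.std())
    fractions = np.empty(max_dim)
    for n in range(1, max_dim + 1):
        emb = embed(series, EmbeddingParams(n + 1, delay)).points
        pts, extra = emb[:, :n], emb[:, n]
        if max_points is not None and pts.shape[0] > max_points:
            idx = np.sort(
                np.random.default_rng(seed).choice(pts.shape[0], max_points, replace=False)
            )
            pts, extra = pts[idx], extra[idx]
        tree = cKDTree(pts)
        dist, nb = tree.query(pts, k=2)
        r_n = dist[:, 1]
        d_extra = np.abs(extra - extra[nb[:, 1]])
        with np.errstate(divide="ignore", invalid="ignore"):
            stretch = np.where(r_n > 0, d_extra / r_n, np.inf)
        stretch[(r_n == 0) & (d_extra == 0)] = 0.0
        false = (stretch > rtol) | (np.hypot(r_n, d_extra) / attractor_size > atol)
        fractions[n - 1] = float(false.mean())
    return fractions


def fnn_dimension(
    series: TimeSeries,
    delay: int,
    max_dim: int = 10,
    rtol: float = 15.0,
    atol: float = 2.0,
    threshold: float = 0.01,
    max_points: int | None = None,
    seed: int = 0,
) -> int:
    """Smallest dimension whose FNN fraction drops below ``threshold``.

    Returns ``max_dim`` with a logged warning when no dimension
    qualifies (the signature of an effectively stochastic series).
    """
    fractions = fnn_fractions(series, delay, max_dim, rtol, atol, max_points, seed)
    below = np.flatnonzero(fractions < threshold)
    if below.size:
        return int(below[0]) + 1
    logger.warning(
        "FNN fraction never fell below %.3g up to dimension %d for series %r "
        "(min %.3g); using max_dim",
        threshold,
        max_dim,
        series.label,
        fractions.min(),
    )
    return max_dim


def select_embedding_params(
    series: TimeSeries,
    max_delay: int = 60,
    ami_bins: int = 16,
    max_dim: int = 10,
    rtol: float = 15.0,
    atol: float = 2.0,
    threshold: float = 0.01,
    max_points: int | None = None,
) -> EmbeddingParams:
    """AMI delay followed by FNN dimension for one series.

    ``max_dim`` is reduced when the series is too short to probe it at
    the selected delay.
    """
    delay = ami_delay(series, max_delay, ami_bins)
    feasible = (len(series) - 1) // delay  # largest n with n*t < length
    if feasible < 1:
        raise ValueError(
            f"series {series.label!r} too short to embed at delay {delay}"
        )
    if feasible < max_dim:
        logger.warning(
            "reducing FNN search from %d to %d dimensions for series %r "
            "(length %d, delay %d)",
            max_dim,
            feasible,
            series.label,
            len(series),
            delay,
        )
        max_dim = feasible
    dim = fnn_dimension(series, delay, max_dim, rtol, atol, threshold, max_points)
    return EmbeddingParams(dim, delay)


def resolve_best_match(a: EmbeddingParams, b: EmbeddingParams) -> EmbeddingParams:
    """Shared parameters for a pair: the larger dimension, smaller delay."""
    return EmbeddingParams(
        max(a.dimension, b.dimension), min(a.delay, b.delay)
    )
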