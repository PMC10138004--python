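"""Long-format CSV I/O and the multi-station dataset container.

The interchange schema is a long CSV with columns
``timestamp,station,factor,value`` — one row per sample.  Short gaps
(missing timestamps or NaN values, up to ``max_gap`` consecutive
samples) are linearly interpolated on read; longer gaps abort with an
error naming the offending series.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .phase_space import TimeSeries

__all__ = ["COLUMNS", "StationDataset", "read_dataset", "write_dataset"]

COLUMNS = ["timestamp", "station", "factor", "value"]

DEFAULT_START = pd.Timestamp("2021-07-22 00:00")


@dataclass
class StationDataset:
    """All (station, factor) records of one synchronized deployment."""

    series: dict[tuple[str, str], TimeSeries]
    start_time: pd.Timestamp = DEFAULT_START
    truth: object | None = None  # generator config when synthetic

    def __post_init__(self) -> None:
        if self.series:
            lengths = {len(s) for s in self.series.values()}
            intervals = {s.sampling_interval for s in self.series.values()}
            if len(lengths) != 1 or len(intervals) != 1:
                raise ValueError(
                    "all series must share one length and sampling interval; "
                    f"got lengths {sorted(lengths)} and intervals {sorted(intervals)}"
                )

    @property
    def stations(self) -> list[str]:
        out: list[str] = []
        for station, _ in self.series:
            if station not in out:
                out.append(station)
        return out

    @property
    def factors(self) -> list[str]:
        out: list[str] = []
        for _, factor in self.series:
            if factor not in out:
                out.append(factor)
        return out

    @property
    def n_samples(self) -> int:
        if not self.series:
            return 0
        return len(next(iter(self.series.values())))

    @property
    def sampling_interval(self) -> float:
        return next(iter(self.series.values())).sampling_interval

    def get(self, station: str, factor: str) -> TimeSeries:
        try:
            return self.series[(station, factor)]
        except KeyError:
            raise KeyError(
                f"no series {station}:{factor}; available stations "
                f"{self.stations}, factors {self.factors}"
            ) from None

    def truncated(self, length: int) -> "StationDataset":
        return StationDataset(
            {k: s.truncated(length) for k, s in self.series.items()},
            start_time=self.start_time,
            truth=self.truth,
        )

    def to_long_frame(self) -> pd.DataFrame:
        if not self.series:
            raise ValueError("empty dataset")
        idx = pd.date_range(
            self.start_time,
            periods=self.n_samples,
            freq=pd.Timedelta(minutes=self.sampling_interval),
        )
        frames = [
            pd.DataFrame(
                {
                    "timestamp": idx,
                    "station": station,
                    "factor": factor,
                    "value": ts.values,
                }
            )
            for (station, factor), ts in self.series.items()
        ]
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, max_gap: int = 3) -> "StationDataset":
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"long-format CSV is missing columns {missing}")
        df = df.copy()
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        series: dict[tuple[str, str], TimeSeries] = {}
        starts = set()
        for (station, factor), group in df.groupby(["station", "factor"], sort=False):
            group = group.sort_values("timestamp")
            stamps = group["timestamp"]
            if len(stamps) < 2:
                raise ValueError(f"series {station}:{factor} has fewer than 2 samples")
            step = stamps.diff().dropna().min()
            if step <= pd.Timedelta(0):
                raise ValueError(f"duplicate timestamps in series {station}:{factor}")
            full = pd.date_range(stamps.iloc[0], stamps.iloc[-1], freq=step)
            values = group.set_index("timestamp")["value"].reindex(full)
            gaps = values.isna().to_numpy()
            if gaps.any():
                run = _longest_run(gaps)
                if run > max_gap:
                    raise ValueError(
                        f"series {station}:{factor} has a gap of {run} samples "
                        f"(> max_gap={max_gap}); refusing to interpolate"
                    )
                values = values.interpolate(method="linear", limit_area="inside")
            series[(station, factor)] = TimeSeries(
                values.to_numpy(),
                station=str(station),
                factor=str(factor),
                sampling_interval=step / pd.Timedelta(minutes=1),
            )
            starts.add(full[0])
        if len(starts) > 1:
            raise ValueError("series are not aligned to one common start time")
        return cls(series, start_time=starts.pop())


def _longest_run(mask: np.ndarray) -> int:
    padded = np.zeros(mask.size + 2, dtype=np.int8)
    padded[1:-1] = mask
    step = np.diff(padded)
    lengths = np.flatnonzero(step == -1) - np.flatnonzero(step == 1)
    return int(lengths.max()) if lengths.size else 0


def write_dataset(dataset: StationDataset, path) -> None:
    """Write the dataset as a long-format CSV (round-trip exact)."""
    dataset.to_long_frame().to_csv(path, index=False)


def read_dataset(path, max_gap: int = 3) -> StationDataset:
    """Read a long-format CSV, interpolating gaps up to ``max_gap`` samples."""
    df = pd.read_csv(Path(path), float_precision="round_trip")
    if df.empty:
        raise ValueError(f"no data rows in {path}")
    return StationDataset.from_long_frame(df, max_gap=max_gap)
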