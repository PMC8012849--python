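"""Window-level descriptive features of hemodynamic signals.

Six statistics are available — mean, variance (and its square root, the
standard deviation), slope, kurtosis and skewness — computed per channel on
short moving windows (default 2 s, 1 s step) tiling each task epoch.  Mean
and slope form the default set used for classification; the remaining
moments are kept for ablation studies.

Conventions follow the printed formulas: variance uses the sample (n-1)
denominator, while kurtosis and skewness normalize by the population
standard deviation with an n denominator (so a standard normal sample has
kurtosis about 3 and skewness about 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .optics import HemodynamicSeries
from .paradigm import ParadigmSchedule, TASK_LABELS

__all__ = [
    "mean",
    "variance",
    "stdev",
    "slope",
    "kurtosis",
    "skewness",
    "FEATURES",
    "FeatureMatrix",
    "extract_features",
]


def _vec(x, min_n: int = 1) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_n:
        raise ValueError(f"need at least {min_n} samples, got {arr.size}")
    return arr


def mean(x) -> float:
    """Arithmetic mean, sum(x) / n."""
    return float(np.mean(_vec(x, 1)))


def variance(x) -> float:
    """Sample variance with the (n - 1) denominator."""
    return float(np.var(_vec(x, 2), ddof=1))


def stdev(x) -> float:
    """Sample standard deviation, the square root of :func:`variance`."""
    return float(np.sqrt(variance(x)))


def slope(x, dt: float = 1.0) -> float:
    """Least-squares slope of x against time, in units per second.

    For two points this reduces to the two-point rise over run dy/dx.
    """
    arr = _vec(x, 2)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = np.arange(arr.size) * dt
    return float(np.polyfit(t, arr, 1)[0])


def _standardized_moment(x, power: int) -> float:
    arr = _vec(x, 2)
    mu = arr.mean()
    sigma = arr.std()  # population (n denominator)
    if sigma == 0:
        raise ValueError("degenerate data: zero variance")
    return float(np.mean(((arr - mu) / sigma) ** power))


def kurtosis(x) -> float:
    """Fourth standardized moment (non-excess), population sigma."""
    return _standardized_moment(x, 4)


def skewness(x) -> float:
    """Third standardized moment, population sigma."""
    return _standardized_moment(x, 3)


#: Name -> callable(window, dt) for every supported feature.
FEATURES = {
    "mean": lambda w, dt: mean(w),
    "variance": lambda w, dt: variance(w),
    "stdev": lambda w, dt: stdev(w),
    "slope": lambda w, dt: slope(w, dt),
    "kurtosis": lambda w, dt: kurtosis(w),
    "skewness": lambda w, dt: skewness(w),
}


@dataclass
class FeatureMatrix:
    """Windowed feature vectors with workload labels for one chromophore."""

    X: pd.DataFrame  # rows = windows, columns = "feature:channel"
    y: np.ndarray  # per-row label, "mwl1" / "mwl2"
    chromophore: str
    epoch_id: np.ndarray  # per-row task-epoch index
    window_start: np.ndarray  # per-row window onset, seconds

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if len(self.X) != self.y.size:
            raise ValueError("label count must match the row count")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_rows(self) -> int:
        return len(self.X)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    def to_frame(self) -> pd.DataFrame:
        out = self.X.copy()
        out.insert(0, "label", self.y)
        out.insert(1, "epoch_id", self.epoch_id)
        out.insert(2, "window_start", self.window_start)
        return out


def extract_features(
    series: HemodynamicSeries,
    schedule: ParadigmSchedule,
    window_s: float = 2.0,
    step_s: float = 1.0,
    feature_set: tuple[str, ...] = ("mean", "slope"),
    channels=None,
    chromophore: str = "hbo",
    channel_average: bool = False,
) -> FeatureMatrix:
    """Assemble the labeled feature matrix for one chromophore.

    Overlapping windows of ``window_s`` seconds, advanced by ``step_s``,
    tile every task epoch; each row holds the requested features for every
    retained channel (or for the spatial channel mean when
    ``channel_average`` is set) and is labeled with the epoch's workload
    level.
    """
    for f in feature_set:
        if f not in FEATURES:
            raise ValueError(f"unknown feature {f!r}; choose from {sorted(FEATURES)}")
    if not feature_set:
        raise ValueError("feature_set must not be empty")
    if channels is None:
        channels = np.arange(series.n_channels)
    channels = np.asarray(channels, dtype=int)
    if channels.size == 0:
        raise ValueError("channel set must not be empty")
    if window_s <= 0 or step_s <= 0:
        raise ValueError("window_s and step_s must be > 0")

    fs = series.sampling_rate
    dt = 1.0 / fs
    data = series.chromophore(chromophore)[channels]
    if channel_average:
        data = data.mean(axis=0, keepdims=True)
        col_channels = ["avg"]
    else:
        col_channels = [series.channels[i] for i in channels]

    win = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if win < 2:
        raise ValueError("window too short for the sampling rate")

    rows, labels, epoch_ids, starts = [], [], [], []
    epoch = 0
    for block in schedule.blocks:
        if block.label not in TASK_LABELS:
            continue
        sl = schedule.sample_slice(block)
        n_block = sl.stop - sl.start
        if win > n_block:
            raise ValueError(
                f"window of {window_s} s exceeds the {block.duration} s task epoch"
            )
        for off in range(0, n_block - win + 1, step):
            seg = data[:, sl.start + off : sl.start + off + win]
            row = [FEATURES[f](seg[c], dt) for c in range(seg.shape[0]) for f in feature_set]
            rows.append(row)
            labels.append(block.label.value)
            epoch_ids.append(epoch)
            starts.append(block.onset + off / fs)
        epoch += 1
    if not rows:
        raise ValueError("no task windows found in the schedule")

    columns = [f"{f}:{ch}" for ch in col_channels for f in feature_set]
    return FeatureMatrix(
        X=pd.DataFrame(rows, columns=columns),
        y=np.array(labels),
        chromophore=chromophore.lower(),
        epoch_id=np.array(epoch_ids),
        window_start=np.array(starts),
    )
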