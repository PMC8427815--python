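"""Higuchi fractal dimension (HFD) estimation and windowed feature extraction.

For a timeseries S(t), t = 0..N-1, Higuchi's method reconstructs k decimated
curves, one per phase offset m = 0..k-1, and measures the normalised curve
length

    L_m(k) = (sum_{i=1}^{n_m} |S(m + i k) - S(m + (i-1) k)|) * (N - 1) / (n_m k^2)

with n_m = floor((N - 1 - m) / k), and averages them, L(k) = mean_m L_m(k).
For a fractal signal L(k) is proportional to k^(-D); the fractal dimension D
is minus the slope of the least-squares fit of log L(k) on log k.  For a
timeseries D lies in [1, 2]: a straight line gives exactly 1 (L(k) =
(N-1)/k), uncorrelated noise approaches 2, and fractional Brownian motion
with Hurst exponent H sits near 2 - H.

The estimate is invariant under affine transforms a*S + b (a != 0) of the
signal, so amplitude units never matter.  Constant windows have zero curve
length at every k and are treated as degenerate: the estimator raises, and
the table extractor records the cell as missing.

Feature extraction follows the windowing scheme used for cue-based
motor-imagery epochs: 2-s windows at 0, 1, 2, 3 s offsets (50% overlap)
within each 5-s trial, one HFD value per (participant, trial, task, channel,
window offset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import EpochsDataset

__all__ = [
    "HfdConfig",
    "curve_length",
    "higuchi_fd",
    "higuchi_fd_batch",
    "extract_windows",
    "extract_features",
    "write_features",
    "read_features",
    "DegenerateSignalError",
    "WindowError",
    "FEATURE_COLUMNS",
]

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "group",
    "participant",
    "trial",
    "task",
    "channel",
    "window_offset",
    "hfd",
]


class DegenerateSignalError(ValueError):
    """Signal has zero curve length (constant window)."""


class WindowError(ValueError):
    """Requested window does not fit inside the trial."""


@dataclass(frozen=True)
class HfdConfig:
    """Estimator and windowing parameters.

    ``k_grid`` defaults to every integer 2..k_max; with the default
    k_max = 7 this is the full usable grid (estimation of EEG fractal
    dimension is most accurate for k_max near 6-7).  ``window_length`` and
    ``window_offsets`` are in seconds.
    """

    k_max: int = 7
    k_grid: tuple[int, ...] | None = None
    window_length: float = 2.0
    window_offsets: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)

    def __post_init__(self) -> None:
        grid = self.k_grid
        if grid is None:
            grid = tuple(range(2, self.k_max + 1))
            object.__setattr__(self, "k_grid", grid)
        else:
            object.__setattr__(self, "k_grid", tuple(int(k) for k in grid))
            grid = self.k_grid
        if len(grid) < 2:
            raise ValueError("k_grid needs at least two values for a slope fit")
        if min(grid) < 2:
            raise ValueError("k values must be >= 2")
        if max(grid) > self.k_max:
            raise ValueError("k_grid exceeds k_max")
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        if any(o < 0 for o in self.window_offsets):
            raise ValueError("window offsets must be non-negative")


def _curve_lengths_batch(x: np.ndarray, k: int) -> np.ndarray:
    """L(k) for every row of ``x`` (shape (B, N)); vectorised over phases."""
    n = x.shape[1]
    total = np.zeros(x.shape[0])
    for m in range(k):
        n_m = (n - 1 - m) // k
        sub = x[:, m : m + (n_m + 1) * k : k]
        inc = np.abs(np.diff(sub, axis=1)).sum(axis=1)
        total += inc * (n - 1) / (n_m * k * k)
    return total / k


def curve_length(signal: np.ndarray, k: int) -> float:
    """Normalised Higuchi curve length L(k) of a 1-D signal.

    Requires k >= 2 and len(signal) >= 2k (so every phase offset yields at
    least one increment).  A constant signal returns 0.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if signal.size < 2 * k:
        raise WindowError(
            f"signal of length {signal.size} too short for k={k} (need >= {2 * k})"
        )
    return float(_curve_lengths_batch(signal[np.newaxis, :], k)[0])


def higuchi_fd(signal: np.ndarray, config: HfdConfig | None = None) -> float:
    """Higuchi fractal dimension of a 1-D signal.

    Minus the slope of the least-squares fit of log L(k) on log k over
    ``config.k_grid``.  Raises :class:`DegenerateSignalError` when any L(k)
    is zero (constant signal).
    """
    config = config or HfdConfig()
    signal = np.asarray(signal, dtype=float)
    d = higuchi_fd_batch(signal[np.newaxis, :], config)[0]
    if np.isnan(d):
        raise DegenerateSignalError("constant signal has no fractal dimension")
    return float(d)


def higuchi_fd_batch(x: np.ndarray, config: HfdConfig | None = None) -> np.ndarray:
    """HFD of every row of ``x`` (shape (B, N)); degenerate rows give NaN."""
    config = config or HfdConfig()
    x = np.asarray(x, dtype=float)
    k_grid = np.asarray(config.k_grid)
    if x.shape[1] < 2 * k_grid.max():
        raise WindowError(
            f"signals of length {x.shape[1]} too short for k_max={k_grid.max()}"
        )
    lengths = np.column_stack([_curve_lengths_batch(x, int(k)) for k in k_grid])
    ok = np.all(lengths > 0.0, axis=1)
    log_k = np.log(k_grid.astype(float))
    xc = log_k - log_k.mean()
    denom = (xc**2).sum()
    out = np.full(x.shape[0], np.nan)
    if np.any(ok):
        log_l = np.log(lengths[ok])
        slope = (log_l - log_l.mean(axis=1, keepdims=True)) @ xc / denom
        out[ok] = -slope
    return out


def extract_windows(
    trial_signal: np.ndarray, sampling_rate: float, config: HfdConfig | None = None
) -> list[np.ndarray]:
    """Cut a trial into the configured analysis windows.

    Window start is ``round(offset * rate)`` and length ``round(length *
    rate)``, which is exact at both 250 and 256 Hz.  Raises
    :class:`WindowError` naming the first offset that does not fit.
    """
    config = config or HfdConfig()
    trial_signal = np.asarray(trial_signal, dtype=float)
    n = trial_signal.shape[-1]
    n_win = round(config.window_length * sampling_rate)
    windows = []
    for offset in config.window_offsets:
        start = round(offset * sampling_rate)
        if start + n_win > n:
            raise WindowError(
                f"window at offset {offset} s ({start}..{start + n_win}) "
                f"exceeds trial length {n}"
            )
        windows.append(trial_signal[..., start : start + n_win])
    return windows


def extract_features(
    dataset: EpochsDataset, config: HfdConfig | None = None
) -> pd.DataFrame:
    """One HFD value per (participant, trial, task, channel, window offset).

    Returns a tidy frame with columns ``group, participant, trial, task,
    channel, window_offset, hfd``.  Degenerate (constant) windows appear as
    NaN; their count is logged.
    """
    config = config or HfdConfig()
    n_part, n_trials, n_tasks, n_chan, _ = dataset.data.shape
    offsets = config.window_offsets
    values = np.empty((n_part, n_trials, n_tasks, n_chan, len(offsets)))
    windows = extract_windows(dataset.data, dataset.sampling_rate, config)
    for w_idx, win in enumerate(windows):
        flat = win.reshape(-1, win.shape[-1])
        values[..., w_idx] = higuchi_fd_batch(flat, config).reshape(
            n_part, n_trials, n_tasks, n_chan
        )
    n_bad = int(np.isnan(values).sum())
    if n_bad:
        logger.warning("extract_features: %d degenerate windows recorded as NaN",
                       n_bad)
    index = pd.MultiIndex.from_product(
        [
            dataset.participants,
            range(n_trials),
            dataset.tasks,
            dataset.montage.names,
            offsets,
        ],
        names=["participant", "trial", "task", "channel", "window_offset"],
    )
    table = pd.DataFrame({"hfd": values.ravel()}, index=index).reset_index()
    table.insert(0, "group", table["participant"].map(dataset.group_of))
    return table[FEATURE_COLUMNS]


def write_features(table: pd.DataFrame, path) -> None:
    """Write a feature table as tidy CSV in the canonical column order."""
    table[FEATURE_COLUMNS].to_csv(path, index=False)


def read_features(path) -> pd.DataFrame:
    """Read a feature table CSV, validating the canonical columns."""
    table = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature CSV missing columns: {missing}")
    return table[FEATURE_COLUMNS]
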