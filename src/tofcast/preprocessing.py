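"""Series preprocessing: half split, gap filling, supervised windows, scaling.

The forecasting protocol trains on the first half of each patient's TOFR
sequence and evaluates one-step-ahead predictions on the second half.
Missing samples in the training half are filled by linear interpolation on
the sample-index grid; the test half is left raw so that evaluation can make
causal (real-time) decisions about missing data.  Supervised patterns use
four consecutive samples as input and the next sample as target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import EmptySeriesError, InsufficientDataError, SeriesTooShortError
from .synthetic_cohort import TOFRSeries

__all__ = [
    "SplitSeries",
    "WindowSet",
    "split_half",
    "interpolate_missing",
    "make_windows",
    "scale_series",
    "scale_values",
    "unscale_values",
]

#: Fixed scale divisor: TOFR percent -> ~[0, 1.1] for training stability.
#: A constant (rather than per-patient min-max) keeps transferred models on a
#: common input scale across patients.
TOFR_SCALE = 100.0

#: Number of lagged samples per supervised input pattern.
DEFAULT_WINDOW_SIZE = 4

MIN_SPLIT_LENGTH = 10


@dataclass(frozen=True)
class SplitSeries:
    """A series split into a gap-filled training half and a raw test half.

    ``train`` holds the first ceil(n/2) samples with missing values filled;
    ``test`` holds the remaining samples untouched.  ``split_index`` is the
    sample index at which the test half begins (== len(train)).
    """

    train: TOFRSeries
    test: TOFRSeries
    split_index: int


@dataclass(frozen=True)
class WindowSet:
    """One-step supervised patterns: ``inputs[k]`` are ``window_size``
    consecutive samples, ``targets[k]`` the next sample."""

    inputs: np.ndarray  # shape (n_patterns, window_size)
    targets: np.ndarray  # shape (n_patterns,)
    window_size: int = DEFAULT_WINDOW_SIZE

    def __len__(self) -> int:
        return int(self.targets.shape[0])


def split_half(series: TOFRSeries) -> SplitSeries:
    """Split a series into first-half training and second-half test data.

    The training half receives ceil(n/2) samples (ties favour training data
    on the shortest sequences) and is gap-filled by
    :func:`interpolate_missing`; the test half keeps its missingness mask.
    Concatenating the two halves reproduces the original sample order.
    """
    n = len(series)
    if n < MIN_SPLIT_LENGTH:
        raise SeriesTooShortError(f"need at least {MIN_SPLIT_LENGTH} samples to split, got {n}")
    k = math.ceil(n / 2)
    train_raw = TOFRSeries(values=series.values[:k], observed=series.observed[:k])
    test = TOFRSeries(values=series.values[k:], observed=series.observed[k:])
    return SplitSeries(train=interpolate_missing(train_raw), test=test, split_index=k)


def interpolate_missing(series: TOFRSeries) -> TOFRSeries:
    """Fill missing samples by linear interpolation on the index grid.

    Interior gaps are interpolated between their flanking observed values;
    leading/trailing gaps are filled by constant extension of the nearest
    observed value.  Observed values pass through unchanged, so the
    operation is idempotent.
    """
    obs = series.observed
    if not obs.any():
        raise EmptySeriesError("cannot interpolate a series with no observed values")
    if obs.all():
        return series
    idx = np.arange(len(series), dtype=float)
    filled = np.interp(idx, idx[obs], series.values[obs])
    return TOFRSeries(values=filled, observed=np.ones(len(series), dtype=bool))


def make_windows(series: TOFRSeries, window_size: int = DEFAULT_WINDOW_SIZE) -> WindowSet:
    """Slice a fully observed series into one-step supervised patterns.

    Produces exactly ``n - window_size`` patterns in temporal order (no
    shuffling here; the trainer owns randomisation).
    """
    if window_size < 1:
        raise InsufficientDataError(f"window_size must be >= 1, got {window_size}")
    if not series.observed.all():
        raise InsufficientDataError("make_windows requires a fully observed series; fill gaps first")
    n = len(series)
    if n <= window_size:
        raise InsufficientDataError(
            f"need more than window_size={window_size} samples for one pattern, got {n}"
        )
    v = series.values
    n_patterns = n - window_size
    inputs = np.lib.stride_tricks.sliding_window_view(v, window_size)[:n_patterns].copy()
    targets = v[window_size:].copy()
    return WindowSet(inputs=inputs, targets=targets, window_size=window_size)


def scale_values(values: np.ndarray) -> np.ndarray:
    """TOFR percent -> model scale (divide by 100)."""
    return np.asarray(values, dtype=float) / TOFR_SCALE


def unscale_values(values: np.ndarray) -> np.ndarray:
    """Model scale -> TOFR percent (multiply by 100)."""
    return np.asarray(values, dtype=float) * TOFR_SCALE


def scale_series(series: TOFRSeries) -> TOFRSeries:
    """Return the series with values divided by 100; the mask is preserved.

    RMSE is always reported on the unscaled 0-100 percent scale; scaling
    exists only for training stability.
    """
    return TOFRSeries(values=series.values / TOFR_SCALE, observed=series.observed)
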