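"""Center-of-pressure (CoP) streams and postural-instability metrics.

A force platform such as the Wii Balance Board reports the body's center of
pressure as a 2-D position sampled at roughly 50 Hz.  The within-trial
dispersion of those samples — ``CoP_MAD``, the median radial distance of the
samples from their coordinate-wise median — serves as a per-trial index of
postural instability ("fidgeting").  Coordinates are treated as abstract
device length units: the board's raw output is uncalibrated when sat upon,
so a units label is carried as metadata rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

DEFAULT_SAMPLE_RATE_HZ = 50.0

#: canonical column name -> default CSV column name
DEFAULT_DIALECT: dict[str, str] = {
    "trial_id": "trial_id",
    "t": "t",
    "x": "x",
    "y": "y",
}


class CoPSample(NamedTuple):
    """One CoP sample: time from trial onset (s) and 2-D position."""

    t: float
    x: float
    y: float


@dataclass
class CoPTrace:
    """Timestamped CoP samples for a single trial.

    Parameters
    ----------
    trial_id
        Identifier of the trial the samples belong to.
    t, x, y
        Equal-length arrays: seconds from trial onset (strictly
        increasing), lateral position, anterior–posterior position.
    nominal_rate
        Nominal sampling rate in Hz (default 50).
    units
        Label for the coordinate units; purely metadata.
    """

    trial_id: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    nominal_rate: float = DEFAULT_SAMPLE_RATE_HZ
    units: str = "device"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValidationError("t, x, y must have identical shapes")
        if self.t.ndim != 1 or self.t.size < 1:
            raise ValidationError("a CoP trace needs at least one sample")
        if not np.all(np.isfinite(self.t)) or np.any(self.t < 0):
            raise ValidationError("timestamps must be finite and >= 0")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError("CoP coordinates must be finite")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValidationError(
                f"timestamps must be strictly increasing (trial {self.trial_id})"
            )
        if not self.nominal_rate > 0:
            raise ValidationError("nominal_rate must be > 0")

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def samples(self) -> Iterator[CoPSample]:
        """Iterate over samples as (t, x, y) tuples."""
        for ti, xi, yi in zip(self.t, self.x, self.y):
            yield CoPSample(float(ti), float(xi), float(yi))


def read_cop_table(path, dialect: Mapping[str, str] | None = None) -> list[CoPTrace]:
    """Read a per-sample CoP table (CSV) into one trace per trial.

    The file must have a header row with columns resolvable to
    ``trial_id``, ``t``, ``x`` and ``y`` through *dialect* (a mapping from
    canonical names to the file's column names).  Rows are grouped by
    trial id and sorted by time; the total row count is conserved.
    """
    names = dict(DEFAULT_DIALECT)
    if dialect:
        names.update(dialect)
    df = pd.read_csv(path)
    missing = [c for key, c in names.items() if c not in df.columns]
    if missing:
        raise FormatError(
            f"missing required column(s) {missing!r} in {path}"
        )
    df = df.rename(columns={v: k for k, v in names.items()})

    traces: list[CoPTrace] = []
    bad_trials: list[int] = []
    for trial_id, grp in df.groupby("trial_id", sort=True):
        grp = grp.sort_values("t", kind="stable")
        t = grp["t"].to_numpy(dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            bad_trials.append(int(trial_id))
            continue
        traces.append(
            CoPTrace(
                trial_id=int(trial_id),
                t=t,
                x=grp["x"].to_numpy(dtype=float),
                y=grp["y"].to_numpy(dtype=float),
            )
        )
    if bad_trials:
        raise ValidationError(
            f"duplicate or non-increasing timestamps in trial(s) {bad_trials}"
        )
    return traces


def write_cop_table(traces: Sequence[CoPTrace], path,
                    dialect: Mapping[str, str] | None = None) -> None:
    """Write traces back to the CSV layout accepted by :func:`read_cop_table`."""
    names = dict(DEFAULT_DIALECT)
    if dialect:
        names.update(dialect)
    frames = [
        pd.DataFrame(
            {
                names["trial_id"]: tr.trial_id,
                names["t"]: tr.t,
                names["x"]: tr.x,
                names["y"]: tr.y,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def compute_cop_mad(trace: CoPTrace) -> float:
    """Median radial deviation of CoP samples from their per-axis median.

    Computes ``median(sqrt((x - median(x))^2 + (y - median(y))^2))``, a
    robust dispersion statistic for within-trial postural instability.
    Even-length medians use the midpoint of the two central order
    statistics.  Returns 0 iff every sample sits at the coordinate-wise
    median point.
    """
    if trace.n_samples < 1:  # unreachable through the constructor; defensive
        raise ValidationError("cannot compute CoP_MAD of an empty trace")
    dx = trace.x - np.median(trace.x)
    dy = trace.y - np.median(trace.y)
    return float(np.median(np.hypot(dx, dy)))


def smooth_sma(values, window_n: int) -> np.ndarray:
    """Simple moving average of a per-trial series over the preceding trials.

    Element ``i`` of the result is the mean of ``values[max(0, i - window_n)
    .. i]``: the current value averaged with up to ``window_n`` predecessors,
    truncating the window at the start of the series so the output has one
    value per input.  ``window_n = 0`` is the identity.
    """
    if not isinstance(window_n, (int, np.integer)):
        raise ValidationError("window_n must be an integer")
    if window_n < 0:
        raise ValidationError("window_n must be >= 0")
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("values must be one-dimensional")
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValidationError("values must be finite")
    if arr.size == 0:
        return arr.copy()
    return (
        pd.Series(arr)
        .rolling(window=window_n + 1, min_periods=1)
        .mean()
        .to_numpy()
    )
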