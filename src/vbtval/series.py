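"""Uniformly sampled time series — the backbone container for all signal processing.

Everything downstream (filtering, differentiation, integration, segmentation)
assumes an even time grid in seconds and SI-unit values, either scalar per
sample or a 3-vector per sample (world frame: x along the barbell axis,
z vertical, up positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class UniformSeries:
    """Evenly sampled signal.

    Parameters
    ----------
    t0 : float
        Time of the first sample, seconds.
    dt : float
        Sample interval, seconds (> 0).
    values : ndarray
        Shape ``(n,)`` for scalar signals or ``(n, 3)`` for 3-D signals.
    """

    t0: float
    dt: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"sample interval must be positive, got {self.dt}")
        if self.values.ndim not in (1, 2):
            raise ValueError("values must be 1-D (scalar) or 2-D (vector) per sample")
        if self.values.ndim == 2 and self.values.shape[1] != 3:
            raise ValueError("vector series must have 3 components per sample")
        if len(self.values) < 1:
            raise ValueError("series must contain at least one sample")

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def rate(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    @property
    def t_end(self) -> float:
        return self.t0 + (self.n - 1) * self.dt

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (clipped to range)."""
        i = int(round((t - self.t0) / self.dt))
        return min(max(i, 0), self.n - 1)

    def slice_time(self, ta: float, tb: float) -> "UniformSeries":
        """Sub-series covering [ta, tb] (nearest-sample bounds, inclusive)."""
        ia, ib = self.index_at(ta), self.index_at(tb)
        if ib < ia:
            ia, ib = ib, ia
        return UniformSeries(self.t0 + ia * self.dt, self.dt, self.values[ia : ib + 1])

    def with_values(self, values: np.ndarray) -> "UniformSeries":
        """Same time base, new values."""
        return UniformSeries(self.t0, self.dt, values)

    def component(self, axis: int) -> "UniformSeries":
        if self.values.ndim != 2:
            raise ValueError("component() requires a vector series")
        return UniformSeries(self.t0, self.dt, self.values[:, axis])


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter specification.

    ``order`` is the order of the underlying Butterworth design; with
    ``zero_phase`` the filter is applied forward and backward, which squares
    the magnitude response (and removes phase lag).
    """

    cutoff_hz: float
    order: int = 4
    zero_phase: bool = True
    kind: str = "lowpass"

    def __post_init__(self) -> None:
        if self.kind != "lowpass":
            raise ValueError("only low-pass filtering is supported")
        if self.order < 2 or self.order % 2:
            raise ValueError("filter order must be an even integer >= 2")
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff must be positive")

    def validate_for_rate(self, rate_hz: float) -> None:
        if self.cutoff_hz >= rate_hz / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz is at or above the Nyquist "
                f"frequency {rate_hz / 2:g} Hz"
            )
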