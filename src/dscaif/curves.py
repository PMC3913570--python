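"""Uniformly sampled time series — the universal unit for signals, concentrations and AIFs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SampledCurve", "make_grid"]


def make_grid(duration: float, dt: float, start: float = 0.0) -> np.ndarray:
    """Uniform time grid of ``duration/dt`` samples starting at ``start``.

    ``duration/dt`` must be (numerically) an integer; sample ``i`` sits at
    ``start + i*dt``, so the grid covers ``[start, start + duration - dt]``.
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("duration and dt must be positive")
    n_float = duration / dt
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9:
        raise ValueError(f"duration/dt = {n_float} is not an integer number of samples")
    return start + dt * np.arange(n)


@dataclass(frozen=True)
class SampledCurve:
    """A time series sampled on a uniform grid.

    Attributes
    ----------
    times : ndarray
        Sample times in seconds, uniformly spaced, increasing.
    values : ndarray
        Sample values (signal intensity, concentration, ...), same length.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("a sampled curve needs at least two samples")
        if not np.all(np.isfinite(t)):
            raise ValueError("non-finite sample times")
        steps = np.diff(t)
        if steps[0] <= 0 or not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("times must be uniformly spaced and increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n(self) -> int:
        return int(self.times.size)

    def integral(self) -> float:
        """Rectangle-rule integral: sum of values times dt."""
        return float(self.values.sum() * self.dt)

    def with_values(self, values: np.ndarray) -> "SampledCurve":
        return SampledCurve(self.times, np.asarray(values, dtype=float))

    def same_grid(self, other: "SampledCurve", rtol: float = 1e-9) -> bool:
        return self.n == other.n and bool(np.allclose(self.times, other.times, rtol=rtol))
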