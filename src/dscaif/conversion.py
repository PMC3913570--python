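"""Signal-to-concentration conversion (inverse of the exponential T2* signal model)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import SampledCurve
from .phantom import AcquisitionParams

__all__ = [
    "BaselineEstimate",
    "estimate_baseline",
    "signal_to_concentration",
    "signal_matrix_to_concentration",
]

#: Signals at or below this fraction of baseline are clipped before the log.
SIGNAL_CLIP_FRACTION = 1e-6

#: Default number of pre-contrast frames for baseline estimation: the bolus is
#: injected at the seventh acquired frame and the first two frames are
#: discarded, leaving five pre-bolus frames.
DEFAULT_N_PRE = 5


@dataclass(frozen=True)
class BaselineEstimate:
    """Per-curve baseline signal estimated from pre-contrast frames."""

    s0_hat: float
    n_pre: int

    def __post_init__(self) -> None:
        if self.n_pre < 1:
            raise ValueError("n_pre must be at least 1")
        if not self.s0_hat > 0:
            raise ValueError("baseline estimate must be positive")


def estimate_baseline(signal: SampledCurve, n_pre: int = DEFAULT_N_PRE) -> BaselineEstimate:
    """Mean of the first ``n_pre`` samples as the pre-contrast baseline."""
    if n_pre < 1:
        raise ValueError("n_pre must be at least 1")
    if n_pre > signal.n:
        raise ValueError(f"n_pre={n_pre} exceeds series length {signal.n}")
    s0_hat = float(np.mean(signal.values[:n_pre]))
    return BaselineEstimate(s0_hat=s0_hat, n_pre=n_pre)


def _k_te(acq: AcquisitionParams) -> float:
    # Unknown k_signal (clinical mode): use 1 — downstream statistics are
    # scale-invariant or comparative, so only relative concentration matters.
    k = acq.k_signal if acq.k_signal is not None else 1.0
    return k * acq.te


def signal_to_concentration(
    signal: SampledCurve, s0: float, acq: AcquisitionParams
) -> SampledCurve:
    """Invert the signal model: ``C = -ln(S/s0) / (k_signal * te)``.

    Signals at or below ``1e-6 * s0`` are clipped to that floor before the
    logarithm so the map stays total on noisy input.
    """
    if s0 <= 0:
        raise ValueError("baseline s0 must be positive")
    values = np.asarray(signal.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite signal values")
    clipped = np.clip(values, SIGNAL_CLIP_FRACTION * s0, None)
    return SampledCurve(signal.times, -np.log(clipped / s0) / _k_te(acq))


def signal_matrix_to_concentration(
    signals: np.ndarray, s0, acq: AcquisitionParams
) -> np.ndarray:
    """Row-wise conversion of a (n_curves, n_timepoints) signal matrix.

    ``s0`` is a scalar common baseline or a per-row vector.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2:
        raise ValueError("expected a 2-D (curves x time) matrix")
    if not np.all(np.isfinite(signals)):
        raise ValueError("non-finite signal values")
    s0_arr = np.asarray(s0, dtype=float)
    if s0_arr.ndim == 1:
        if s0_arr.size != signals.shape[0]:
            raise ValueError("per-row s0 length mismatch")
        s0_arr = s0_arr[:, None]
    if np.any(s0_arr <= 0):
        raise ValueError("baseline s0 must be positive")
    clipped = np.clip(signals, SIGNAL_CLIP_FRACTION * s0_arr, None)
    return -np.log(clipped / s0_arr) / _k_te(acq)
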