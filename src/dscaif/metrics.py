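"""Curve-shape statistics, the M selection rule, and evaluation metrics.

The detection pipeline picks, among the five per-cluster mean concentration
curves, the one maximizing M = PV/(TTP*FWHM) — tall, early, narrow curves are
arterial-like. Evaluation against the ground truth uses the partial-volume
fraction of the selected cluster, the shape statistics, AUC, the RMSE against
the true AIF, and (for repeated runs) a mean per-timepoint variance
"robustness" score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import SampledCurve

__all__ = [
    "FwhmUndefinedError",
    "DetectionFailure",
    "CurveShape",
    "AifSelection",
    "curve_shape",
    "m_measure",
    "select_aif",
    "rmse",
    "pve_fraction",
    "robustness",
]


class FwhmUndefinedError(ValueError):
    """The curve never drops below half its maximum on one side of the peak."""


class DetectionFailure(RuntimeError):
    """No cluster produced an eligible (finite-FWHM) mean curve."""


@dataclass(frozen=True)
class CurveShape:
    """Shape statistics of a single curve.

    ``pv``: peak value; ``ttp``: time of the first maximal sample (s);
    ``fwhm``: width between the half-maximum crossings (s); ``auc``:
    rectangle-rule area; ``m_value``: PV/(TTP*FWHM), NaN when TTP is zero.
    """

    pv: float
    ttp: float
    fwhm: float
    auc: float
    m_value: float


def curve_shape(curve: SampledCurve) -> CurveShape:
    """PV, TTP, FWHM, AUC and M of a sampled curve.

    TTP is the time of the first maximal sample (no sub-sample
    interpolation). FWHM uses linear interpolation between the bracketing
    samples of the first left and last right half-maximum crossings.

    Raises
    ------
    FwhmUndefinedError
        If the curve never drops below half its maximum before the peak or
        after it (e.g. a constant curve).
    """
    v = curve.values
    pv = float(np.max(v))
    if pv <= 0:
        raise FwhmUndefinedError("curve has no positive peak")
    ip = int(np.argmax(v))
    ttp = float(curve.times[ip])
    half = pv / 2.0

    above = np.flatnonzero(v >= half)
    il, ir = int(above[0]), int(above[-1])
    if il == 0:
        raise FwhmUndefinedError("curve never drops below half maximum left of the peak")
    if ir == curve.n - 1:
        raise FwhmUndefinedError("curve never drops below half maximum right of the peak")
    t_left = _interp_crossing(curve.times, v, il - 1, il, half)
    t_right = _interp_crossing(curve.times, v, ir, ir + 1, half)
    fwhm = float(t_right - t_left)

    auc = curve.integral()
    m_value = m_measure(pv, ttp, fwhm) if ttp > 0 and fwhm > 0 else float("nan")
    return CurveShape(pv=pv, ttp=ttp, fwhm=fwhm, auc=auc, m_value=m_value)


def _interp_crossing(t: np.ndarray, v: np.ndarray, i: int, j: int, level: float) -> float:
    """Linear-interpolated time where the segment (i, j) crosses ``level``."""
    vi, vj = v[i], v[j]
    if vj == vi:
        return float(t[i])
    return float(t[i] + (t[j] - t[i]) * (level - vi) / (vj - vi))


def m_measure(pv: float, ttp: float, fwhm: float) -> float:
    """Selection statistic M = PV / (TTP * FWHM)."""
    if ttp * fwhm == 0:
        raise ValueError("TTP and FWHM must be nonzero")
    return pv / (ttp * fwhm)


@dataclass(frozen=True)
class AifSelection:
    """Result of the M-based cluster selection."""

    index: int
    curve: SampledCurve
    m_values: tuple[float, ...]


def select_aif(mean_curves, times: np.ndarray) -> AifSelection:
    """Pick the cluster mean curve with the highest M value.

    ``mean_curves`` is a sequence of per-cluster value arrays (or ``None``
    for empty clusters). Clusters whose mean curve has no defined FWHM are
    ineligible and carry an M of NaN. Ties go to the lowest cluster index.

    Raises
    ------
    DetectionFailure
        If no cluster is eligible.
    """
    m_values: list[float] = []
    for values in mean_curves:
        if values is None:
            m_values.append(float("nan"))
            continue
        try:
            shape = curve_shape(SampledCurve(times, values))
            m_values.append(shape.m_value)
        except FwhmUndefinedError:
            m_values.append(float("nan"))
    arr = np.asarray(m_values)
    if not np.any(np.isfinite(arr)):
        raise DetectionFailure("no cluster yields an eligible AIF candidate")
    best = int(np.nanargmax(arr))
    return AifSelection(index=best, curve=SampledCurve(times, mean_curves[best]), m_values=tuple(m_values))


def rmse(est: SampledCurve, truth: SampledCurve) -> float:
    """Root mean square error between two curves on the same grid."""
    if not est.same_grid(truth):
        raise ValueError("curves are not on the same time grid")
    return float(np.sqrt(np.mean((est.values - truth.values) ** 2)))


def pve_fraction(assignments: np.ndarray, voxel_labels: np.ndarray, selected: int) -> float:
    """Fraction of non-arterial voxels in the selected cluster.

    ``voxel_labels`` holds class labels for the clustered voxels; voxels not
    labelled ``'true_arterial'`` count as partial-volume contamination.
    """
    assignments = np.asarray(assignments)
    voxel_labels = np.asarray(voxel_labels)
    members = assignments == selected
    total = int(members.sum())
    if total == 0:
        raise ValueError("selected cluster is empty")
    non_arterial = int(np.sum(voxel_labels[members] != "true_arterial"))
    return non_arterial / total


def robustness(aif_stack: np.ndarray) -> float:
    """Mean per-timepoint variance of repeated AIF detections.

    ``aif_stack`` has shape (n_runs, n_timepoints); the score is
    ``(1/(M*N)) * sum_t sum_r (x_rt - mean_t)^2`` — zero iff all runs are
    identical, and scaling every run by c scales the score by c^2.
    """
    stack = np.asarray(aif_stack, dtype=float)
    if stack.ndim != 2:
        raise ValueError("expected a (runs x timepoints) matrix")
    n_runs, n_time = stack.shape
    if n_runs < 2:
        raise ValueError("robustness needs at least two runs")
    if np.all(stack == stack[0]):
        return 0.0  # exact zero for bit-identical runs (no floating-mean residue)
    dev = stack - stack.mean(axis=0, keepdims=True)
    return float((dev**2).sum() / (n_runs * n_time))
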