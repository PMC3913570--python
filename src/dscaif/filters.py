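"""Pre-clustering curve filters: drop weak (low-area) and irregular (rough) curves."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .curves import SampledCurve

__all__ = ["FilterConfig", "curve_auc", "curve_roughness", "apply_prefilters"]


@dataclass(frozen=True)
class FilterConfig:
    """Fractions of curves excluded by the two filter stages.

    ``p_auc_low``: fraction of lowest-area curves dropped first.
    ``p_rough``: fraction of the survivors with the largest roughness
    integral dropped second.
    """

    p_auc_low: float = 0.90
    p_rough: float = 0.25

    def __post_init__(self) -> None:
        if not (0 <= self.p_auc_low < 1 and 0 <= self.p_rough < 1):
            raise ValueError("filter fractions must lie in [0, 1)")


def curve_auc(curve: SampledCurve) -> float:
    """Area under the curve, rectangle rule (sum of samples times dt)."""
    return curve.integral()


def curve_roughness(curve: SampledCurve) -> float:
    """Discrete roughness: integral of the squared second derivative.

    Sum of squared second differences divided by dt^3; zero for affine
    curves, nonnegative always.
    """
    if curve.n < 3:
        raise ValueError("roughness needs at least three samples")
    d2 = np.diff(curve.values, n=2)
    return float(np.sum(d2**2) / curve.dt**3)


def _matrix_aucs(curves: np.ndarray, dt: float) -> np.ndarray:
    return curves.sum(axis=1) * dt


def _matrix_roughness(curves: np.ndarray, dt: float) -> np.ndarray:
    d2 = np.diff(curves, n=2, axis=1)
    return (d2**2).sum(axis=1) / dt**3


def apply_prefilters(curves: np.ndarray, dt: float, cfg: FilterConfig | None = None) -> np.ndarray:
    """Indices of curves surviving the area filter then the roughness filter.

    Stage 1 excludes ``floor(p_auc_low * n)`` curves with the smallest areas;
    stage 2 excludes ``floor(p_rough * m)`` of the ``m`` survivors with the
    largest roughness. Ties are broken by original index, lower index
    retained first. Returned indices refer to the input matrix and preserve
    its order.
    """
    if cfg is None:
        cfg = FilterConfig()
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two curves")
    if curves.shape[1] < 3:
        raise ValueError("curves must have at least three samples for the roughness stage")
    n = curves.shape[0]

    aucs = _matrix_aucs(curves, dt)
    k1 = math.floor(cfg.p_auc_low * n)
    # ascending AUC; among ties the higher index is removed first, so lower
    # indices are retained preferentially
    order = np.lexsort((-np.arange(n), aucs))
    survivors = np.sort(order[k1:])
    if survivors.size == 0:
        raise ValueError("area filter excluded every curve")

    rough = _matrix_roughness(curves[survivors], dt)
    m = survivors.size
    k2 = math.floor(cfg.p_rough * m)
    order2 = np.lexsort((-survivors, -rough))  # descending roughness; ties: higher index first
    retained = np.sort(survivors[order2[k2:]])
    if retained.size == 0:
        raise ValueError("roughness filter excluded every curve")
    return retained
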