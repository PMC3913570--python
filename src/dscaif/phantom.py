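"""Synthetic DSC-MRI perfusion phantom.

Generates a labelled population of voxel time-signal curves: a handful of true
arterial voxels (gamma-variate bolus with a delayed, dispersed recirculation
peak), slightly delayed "false" arterial voxels, three tissue classes (normal
grey matter, pathological grey matter, normal white matter) obtained by
indicator-dilution convolution of the arterial concentration with a dispersed
residue function, and partial-volume voxels formed as random convex mixtures of
arterial and tissue signal. Concentration is mapped to T2*-weighted signal
through an exponential model whose proportionality constant is calibrated so
the normal-grey-matter signal dips 40% below baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .curves import SampledCurve, make_grid

__all__ = [
    "AifModelParams",
    "AcquisitionParams",
    "TissueClassParams",
    "PhantomDataset",
    "DEFAULT_TISSUE_CLASSES",
    "DEFAULT_COMPOSITION",
    "gamma_variate",
    "recirculation_scale",
    "recirculation_component",
    "true_aif_curve",
    "residue_function",
    "tissue_concentration",
    "calibrate_signal_constant",
    "concentration_to_signal",
    "pseudo_aif_grid",
    "build_phantom",
]

#: Fractional peak signal drop from baseline that the calibration enforces for
#: the normal-grey-matter curve.
GM_PEAK_SIGNAL_DROP = 0.40

#: Recirculation peak height as a fraction of the main-peak height.
RECIRCULATION_PEAK_RATIO = 1.0 / 3.0

#: Lower truncation bound for per-voxel mean-transit-time draws (s).
MTT_LOWER_BOUND = 0.1


@dataclass(frozen=True)
class AifModelParams:
    """Parameters of the arterial input model.

    The main bolus peak is the gamma variate
    ``amplitude * (t - t0)^alpha * exp(-(t - t0)/beta)`` for ``t > t0``,
    zero otherwise. Recirculation is the main peak delayed by ``td`` and
    convolved with an exponential dispersion kernel ``exp(-t/tau)``, rescaled
    so its peak is one third of the main peak's.

    Parameters
    ----------
    alpha : float
        Inflow steepness exponent (dimensionless).
    beta : float
        Inflow/washout time constant (s).
    t0 : float
        Contrast arrival time (s).
    td : float
        Delay between the main peak and recirculation (s).
    tau : float
        Recirculation dispersion time constant (s).
    amplitude : float
        Multiplicative constant of the main peak (concentration units).
    """

    alpha: float = 3.0
    beta: float = 1.5
    t0: float = 26.0
    td: float = 8.0
    tau: float = 30.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0 and self.tau > 0):
            raise ValueError("alpha, beta and tau must be positive")
        if self.t0 < 0 or self.td < 0:
            raise ValueError("t0 and td must be nonnegative")
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition / signal-model parameters.

    ``k_signal`` is the proportionality constant of the exponential signal
    model ``S = s0 * exp(-k_signal * te * C)``; it is ``None`` until set by
    :func:`calibrate_signal_constant`. ``rho`` is brain tissue density
    (g/ml) and ``k_h`` the large-vessel/capillary hematocrit correction.
    """

    te: float = 0.03
    s0: float = 100.0
    duration: float = 90.0
    dt: float = 1.0
    k_signal: float | None = None
    rho: float = 1.04
    k_h: float = 0.73

    def __post_init__(self) -> None:
        if not (self.te > 0 and self.s0 > 0 and self.dt > 0 and self.duration > 0):
            raise ValueError("te, s0, dt and duration must be positive")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration/dt must be an integer number of samples")
        if self.k_signal is not None and not self.k_signal > 0:
            raise ValueError("k_signal must be positive when set")

    def grid(self) -> np.ndarray:
        return make_grid(self.duration, self.dt)


@dataclass(frozen=True)
class TissueClassParams:
    """One simulated voxel class: perfusion parameters and population count.

    ``cbv`` is cerebral blood volume in ml/100 g; per-voxel mean transit time
    is drawn from a normal with mean ``mtt_mean`` and sd ``mtt_sd`` truncated
    below at 0.1 s. CBF follows from the central volume theorem CBF = CBV/MTT.
    """

    label: str
    cbv: float
    mtt_mean: float
    mtt_sd: float
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be nonnegative")
        if self.cbv is not None and self.cbv <= 0:
            raise ValueError("cbv must be positive")
        if self.mtt_mean is not None and self.mtt_mean <= 0:
            raise ValueError("mtt_mean must be positive")


DEFAULT_TISSUE_CLASSES: tuple[TissueClassParams, ...] = (
    TissueClassParams("gm_normal", cbv=4.0, mtt_mean=4.0, mtt_sd=0.33, count=440),
    TissueClassParams("gm_pathological", cbv=3.3, mtt_mean=10.0, mtt_sd=0.7, count=440),
    TissueClassParams("wm_normal", cbv=2.0, mtt_mean=5.45, mtt_sd=0.33, count=600),
)

#: Default voxel population: label -> count.
DEFAULT_COMPOSITION: Mapping[str, int] = {
    "true_arterial": 6,
    "false_arterial": 16,
    "gm_normal": 440,
    "gm_pathological": 440,
    "wm_normal": 600,
    "pve": 400,
}


def gamma_variate(t, params: AifModelParams):
    """Gamma-variate main bolus peak evaluated at time(s) ``t``.

    Zero for ``t <= t0``; ``amplitude*(t-t0)^alpha*exp(-(t-t0)/beta)`` after.
    The continuous maximum sits at ``t0 + alpha*beta``.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("non-finite time values")
    x = t_arr - params.t0
    with np.errstate(invalid="ignore"):
        out = np.where(
            x > 0,
            params.amplitude * np.power(np.clip(x, 0, None), params.alpha) * np.exp(-np.clip(x, 0, None) / params.beta),
            0.0,
        )
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def _dispersed_delayed_peak(times: np.ndarray, params: AifModelParams) -> np.ndarray:
    """Unscaled recirculation shape: delayed main peak (x) exp(-t/tau), rectangle rule."""
    if times.size == 0:
        raise ValueError("empty time grid")
    dt = float(times[1] - times[0]) if times.size > 1 else None
    if dt is None or dt <= 0:
        raise ValueError("grid must have at least two increasing samples")
    delayed = gamma_variate(times - params.td, params)
    kernel = np.exp(-(times - times[0]) / params.tau)
    return np.convolve(delayed, kernel)[: times.size] * dt


def recirculation_scale(times: np.ndarray, params: AifModelParams) -> float:
    """Scale factor making the recirculation peak one third of the main peak on this grid."""
    times = np.asarray(times, dtype=float)
    main_peak = float(np.max(gamma_variate(times, params)))
    raw = _dispersed_delayed_peak(times, params)
    raw_peak = float(np.max(raw))
    if raw_peak <= 0 or main_peak <= 0:
        raise ValueError("grid does not resolve the bolus peaks; cannot fix the recirculation scale")
    return RECIRCULATION_PEAK_RATIO * main_peak / raw_peak


def recirculation_component(times: np.ndarray, params: AifModelParams) -> SampledCurve:
    """Recirculation peak on ``times``: delayed, dispersed copy of the main peak.

    Zero for ``t <= t0 + td``; peak equals one third of the main-peak maximum
    sampled on the same grid.
    """
    times = np.asarray(times, dtype=float)
    scale = recirculation_scale(times, params)
    return SampledCurve(times, scale * _dispersed_delayed_peak(times, params))


def true_aif_curve(times: np.ndarray, params: AifModelParams | None = None) -> SampledCurve:
    """True arterial concentration: main gamma-variate peak plus recirculation."""
    if params is None:
        params = AifModelParams()
    times = np.asarray(times, dtype=float)
    main = gamma_variate(times, params)
    rec = recirculation_component(times, params)
    return SampledCurve(times, main + rec.values)


def residue_function(times: np.ndarray, mtt: float) -> SampledCurve:
    """Dispersed-exponential residue kernel on the grid's elapsed-time axis.

    ``r(t) = (t/b^2) exp(-t/b)`` with ``b = mtt/2``, rescaled so the
    rectangle-rule integral equals ``mtt`` (so that CBF times the kernel
    integral recovers CBV — the central volume theorem by construction).
    """
    if mtt <= 0:
        raise ValueError("mtt must be positive")
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("grid must have at least two samples")
    dt = float(times[1] - times[0])
    t = times - times[0]
    b = mtt / 2.0
    r = (t / b**2) * np.exp(-t / b)
    total = r.sum() * dt
    if total <= 0:
        raise ValueError("grid too coarse to resolve the residue function")
    return SampledCurve(times, r * (mtt / total))


def tissue_concentration(
    aif: SampledCurve,
    tissue: TissueClassParams,
    acq: AcquisitionParams,
    mtt_draw: float,
) -> SampledCurve:
    """Tissue concentration: CBF-scaled convolution of the AIF with the residue kernel.

    ``C_t = (rho/k_h) * CBF * (C_a (x) r) * dt`` with
    ``CBF = (cbv/100)/mtt_draw`` in ml g^-1 s^-1.
    """
    if mtt_draw <= 0:
        raise ValueError("mtt_draw must be positive")
    r = residue_function(aif.times, mtt_draw)
    cbf = (tissue.cbv / 100.0) / mtt_draw
    conv = np.convolve(aif.values, r.values)[: aif.n] * aif.dt
    return SampledCurve(aif.times, (acq.rho / acq.k_h) * cbf * conv)


def calibrate_signal_constant(gm_conc: SampledCurve, acq: AcquisitionParams) -> float:
    """Signal constant giving a 40% peak signal drop for the normal-GM curve.

    Closed form: ``k = -ln(1 - 0.40) / (te * max(gm_conc))``.
    """
    peak = float(np.max(gm_conc.values))
    if peak <= 0:
        raise ValueError("cannot calibrate from an all-zero concentration curve")
    return float(-np.log(1.0 - GM_PEAK_SIGNAL_DROP) / (acq.te * peak))


def concentration_to_signal(conc: SampledCurve, acq: AcquisitionParams) -> SampledCurve:
    """Exponential T2* signal model ``S = s0 exp(-k_signal te C)``."""
    if acq.k_signal is None:
        raise ValueError("k_signal is unset; run calibrate_signal_constant first")
    values = np.asarray(conc.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite concentration values")
    return SampledCurve(conc.times, acq.s0 * np.exp(-acq.k_signal * acq.te * values))


def pseudo_aif_grid(base: AifModelParams) -> list[AifModelParams]:
    """The sixteen false-arterial parameter sets.

    Cartesian grid of arrival times ``t0 + {1,2,3,4}`` s and recirculation
    delays ``td + {1,2,3,4}`` s; all other fields copied from ``base``.
    """
    out = []
    for dt0 in (1.0, 2.0, 3.0, 4.0):
        for dtd in (1.0, 2.0, 3.0, 4.0):
            out.append(replace(base, t0=base.t0 + dt0, td=base.td + dtd))
    return out


@dataclass(frozen=True)
class PhantomDataset:
    """A generated voxel population.

    Attributes
    ----------
    times : ndarray
        Common time grid (s).
    curves : ndarray, shape (n_voxels, n_timepoints)
        Signal-intensity curves, strictly positive.
    labels : ndarray of str
        Per-voxel class label.
    true_aif : SampledCurve
        Ground-truth arterial concentration on the same grid.
    seed : int
        Seed that produced the dataset.
    aif_params, acq, tissue_classes
        The exact parameters used (``acq.k_signal`` holds the calibrated value).
    """

    times: np.ndarray
    curves: np.ndarray
    labels: np.ndarray
    true_aif: SampledCurve
    seed: int
    aif_params: AifModelParams
    acq: AcquisitionParams
    tissue_classes: tuple[TissueClassParams, ...]

    def __post_init__(self) -> None:
        if self.curves.shape != (self.labels.size, self.times.size):
            raise ValueError("curves shape inconsistent with labels/times")
        if not np.all(self.curves > 0):
            raise ValueError("phantom signal values must be strictly positive")

    @property
    def n_voxels(self) -> int:
        return int(self.curves.shape[0])

    def label_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def _draw_mtt(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Truncated-normal MTT draws, lower bound 0.1 s."""
    if sd == 0:
        return np.full(size, mean)
    a = (MTT_LOWER_BOUND - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def build_phantom(
    seed: int,
    composition: Mapping[str, int] | None = None,
    aif_params: AifModelParams | None = None,
    acq: AcquisitionParams | None = None,
    tissue_classes: Sequence[TissueClassParams] | None = None,
) -> PhantomDataset:
    """Generate the labelled voxel population.

    The population comprises, in row order: copies of the true arterial
    signal; false-arterial signals from the delayed pseudo-AIF grid; the three
    tissue classes with per-voxel MTT drawn from a truncated normal; and
    partial-volume voxels mixing arterial and tissue signal with a uniform
    random weight. Identical seeds give bit-identical datasets.
    """
    if aif_params is None:
        aif_params = AifModelParams()
    if acq is None:
        acq = AcquisitionParams()
    classes = tuple(tissue_classes) if tissue_classes is not None else DEFAULT_TISSUE_CLASSES
    comp = dict(DEFAULT_COMPOSITION if composition is None else composition)
    known = {"true_arterial", "false_arterial", "pve"} | {c.label for c in classes}
    unknown = set(comp) - known
    if unknown:
        raise ValueError(f"unknown composition labels: {sorted(unknown)}")
    if any(v < 0 for v in comp.values()):
        raise ValueError("composition counts must be nonnegative")

    rng = np.random.default_rng(seed)
    times = acq.grid()
    aif = true_aif_curve(times, aif_params)

    # Calibrate k_signal once, from the mean-MTT normal-GM curve.
    gm = next((c for c in classes if c.label == "gm_normal"), classes[0])
    gm_conc = tissue_concentration(aif, gm, acq, gm.mtt_mean)
    acq = replace(acq, k_signal=calibrate_signal_constant(gm_conc, acq))

    arterial_signal = concentration_to_signal(aif, acq).values

    rows: list[np.ndarray] = []
    labels: list[str] = []

    n_true = comp.get("true_arterial", 0)
    rows.extend([arterial_signal.copy() for _ in range(n_true)])
    labels.extend(["true_arterial"] * n_true)

    n_false = comp.get("false_arterial", 0)
    pseudo = pseudo_aif_grid(aif_params)
    for i in range(n_false):
        p = pseudo[i % len(pseudo)]
        sig = concentration_to_signal(true_aif_curve(times, p), acq).values
        rows.append(sig)
        labels.append("false_arterial")

    def _tissue_signal(cls: TissueClassParams, mtt: float) -> np.ndarray:
        conc = tissue_concentration(aif, cls, acq, mtt)
        return concentration_to_signal(conc, acq).values

    for cls in classes:
        n = comp.get(cls.label, 0)
        mtts = _draw_mtt(rng, cls.mtt_mean, cls.mtt_sd, n)
        for mtt in mtts:
            rows.append(_tissue_signal(cls, float(mtt)))
            labels.append(cls.label)

    n_pve = comp.get("pve", 0)
    for _ in range(n_pve):
        cls = classes[rng.integers(len(classes))]
        mtt = float(_draw_mtt(rng, cls.mtt_mean, cls.mtt_sd, 1)[0])
        w = rng.uniform()
        rows.append(w * arterial_signal + (1.0 - w) * _tissue_signal(cls, mtt))
        labels.append("pve")

    curves = np.vstack(rows) if rows else np.empty((0, times.size))
    return PhantomDataset(
        times=times,
        curves=curves,
        labels=np.asarray(labels, dtype=object),
        true_aif=aif,
        seed=int(seed),
        aif_params=aif_params,
        acq=acq,
        tissue_classes=classes,
    )
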