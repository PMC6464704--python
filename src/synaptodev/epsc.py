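"""Biexponential decay analysis of evoked NMDAR-mediated EPSCs.

GluN2A- and GluN2B-containing NMDA receptors close with distinct kinetics
(fast, ~50 ms, vs slow, ~300 ms), so the decay phase of a pharmacologically
isolated NMDAR-EPSC recorded at +50 mV is well described by

    Y(t) = A_f * exp(-t / tau_fast) + A_s * exp(-t / tau_slow)

and the relative subunit contribution is read out from the fractional
amplitudes A_f/(A_f+A_s), A_s/(A_f+A_s) and the amplitude-weighted decay
time constant

    tau_w = tau_fast * A_f/(A_f+A_s) + tau_slow * A_s/(A_f+A_s).

This module fits that model to averaged sweeps, and derives rise time
(time from stimulus onset to peak) and per-cell percent change in tau_w
under pharmacology (e.g. the GluN2B antagonist Ro 25-6981).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import DegenerateInputError, FitError, ParameterError

__all__ = [
    "EPSCTrace",
    "BiexpFit",
    "average_sweeps",
    "normalize_to_peak",
    "fit_biexp_decay",
    "weighted_tau",
    "rise_time",
    "percent_change_tau",
]

#: Bounds on either decay time constant during fitting, ms.
TAU_BOUNDS_MS = (1.0, 5000.0)

#: Below this tau_slow/tau_fast ratio the fit is flagged quasi-single-exponential.
QUASI_SINGLE_RATIO = 1.2


@dataclass
class EPSCTrace:
    """A single (or averaged) evoked current sweep.

    Attributes
    ----------
    time : ndarray
        Sample times in ms, strictly increasing with a uniform step.
    current : ndarray
        Membrane current in pA (outward positive at +50 mV holding).
    stim_onset : float
        Time of the evoked stimulus, ms.
    holding_label : str
        Annotation of the holding potential.
    """

    time: np.ndarray
    current: np.ndarray
    stim_onset: float
    holding_label: str = "+50 mV"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.current.shape:
            raise ParameterError("time and current must be 1-D arrays of equal length")
        if len(self.time) < 2:
            raise ParameterError("time: need at least two samples")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise ParameterError("time: must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ParameterError("time: sampling must be uniform")

    @property
    def dt(self) -> float:
        """Sample interval, ms."""
        return float(self.time[1] - self.time[0])


@dataclass
class BiexpFit:
    """Result of a biexponential decay fit.

    ``amp_fast``/``amp_slow`` are in the units of the fitted trace (typically
    normalized units after :func:`normalize_to_peak`); time constants in ms.
    """

    amp_fast: float
    amp_slow: float
    tau_fast: float
    tau_slow: float
    frac_fast: float
    frac_slow: float
    tau_w: float
    rise_time: float
    gof: float
    fit_window: tuple[float, float]
    quasi_single: bool = False
    diagnostics: dict = field(default_factory=dict)


def average_sweeps(sweeps: list[EPSCTrace]) -> EPSCTrace:
    """Pointwise mean of aligned sweeps (the per-cell averaging step before fitting).

    All sweeps must share the same time base and stimulus onset.
    """
    if not sweeps:
        raise ParameterError("sweeps: empty list")
    ref = sweeps[0]
    for s in sweeps[1:]:
        if s.time.shape != ref.time.shape or not np.allclose(s.time, ref.time):
            raise ParameterError("sweeps: time bases differ; align before averaging")
        if s.stim_onset != ref.stim_onset:
            raise ParameterError("sweeps: stim_onset differs across sweeps")
    mean_current = np.mean([s.current for s in sweeps], axis=0)
    return EPSCTrace(ref.time.copy(), mean_current, ref.stim_onset, ref.holding_label)


def _peak_index(trace: EPSCTrace) -> int:
    """Index of the absolute post-stimulus extremum."""
    post = trace.time >= trace.stim_onset
    if not np.any(post):
        raise ParameterError("stim_onset: beyond end of trace")
    idx_post = np.argmax(np.abs(trace.current[post]))
    return int(np.nonzero(post)[0][0] + idx_post)


def normalize_to_peak(trace: EPSCTrace) -> EPSCTrace:
    """Scale the trace so the post-stimulus peak has magnitude 1 (peak positive).

    Sign convention is outward-positive: if the extremum is negative the trace
    is sign-flipped so the normalized peak is +1.  Shape (ratios between
    samples) is preserved.
    """
    ipk = _peak_index(trace)
    peak = trace.current[ipk]
    if peak == 0.0:
        raise DegenerateInputError("trace has zero post-stimulus peak")
    return replace(trace, current=trace.current / peak)


def _biexp(t: np.ndarray, a_f: float, a_s: float, tau_f: float, tau_s: float) -> np.ndarray:
    return a_f * np.exp(-t / tau_f) + a_s * np.exp(-t / tau_s)


def rise_time(trace: EPSCTrace) -> float:
    """Time to peak amplitude, ms, measured from stimulus onset."""
    ipk = _peak_index(trace)
    if ipk == len(trace.time) - 1:
        warnings.warn("peak at trace end; rise time may be truncated", stacklevel=2)
    return float(trace.time[ipk] - trace.stim_onset)


def weighted_tau(fit: BiexpFit | tuple[float, float, float, float]) -> float:
    """Amplitude-weighted decay time constant.

    tau_w = tau_f * A_f/(A_f+A_s) + tau_s * A_s/(A_f+A_s)

    Accepts a :class:`BiexpFit` or a bare ``(A_f, A_s, tau_f, tau_s)`` tuple.
    """
    if isinstance(fit, BiexpFit):
        a_f, a_s, tau_f, tau_s = fit.amp_fast, fit.amp_slow, fit.tau_fast, fit.tau_slow
    else:
        a_f, a_s, tau_f, tau_s = fit
    total = a_f + a_s
    if total <= 0:
        raise DegenerateInputError("A_f + A_s must be positive")
    return tau_f * (a_f / total) + tau_s * (a_s / total)


def fit_biexp_decay(
    trace: EPSCTrace,
    window: tuple[float, float] | None = None,
) -> BiexpFit:
    """Least-squares biexponential fit of the decay phase.

    The pre-stimulus mean is subtracted first; the fit window defaults to
    [post-stimulus peak, end of sweep].  Components are ordered so
    ``tau_fast < tau_slow`` regardless of the optimizer's labeling, and all
    derived read-outs (fractional amplitudes, tau_w, rise time, R²) are
    filled in.

    Parameters
    ----------
    trace : EPSCTrace
    window : (start_ms, end_ms), optional
        Fit window; must start at or after the peak and contain >= 20 samples.

    Raises
    ------
    ParameterError
        Window before the peak or too few samples.
    FitError
        Optimizer failure, with diagnostics in the message.
    """
    # Baseline subtraction from the pre-stimulus segment.
    pre = trace.time < trace.stim_onset
    baseline = float(np.mean(trace.current[pre])) if np.any(pre) else 0.0
    current = trace.current - baseline

    work = replace(trace, current=current)
    ipk = _peak_index(work)
    sign = 1.0 if current[ipk] >= 0 else -1.0
    current = current * sign

    t_peak = float(trace.time[ipk])
    if window is None:
        window = (t_peak, float(trace.time[-1]))
    if window[0] < t_peak - 0.5 * trace.dt:
        raise ParameterError("window: must start at or after the post-stimulus peak")

    sel = (trace.time >= window[0]) & (trace.time <= window[1])
    if int(sel.sum()) < 20:
        raise ParameterError("window: need at least 20 samples in the fit window")

    t = trace.time[sel] - trace.time[sel][0]
    y = current[sel]
    y0 = y[0]

    # Initialization: tau_f0 from the 1/e crossing of the windowed decay,
    # tau_s0 = 6 * tau_f0, amplitudes split evenly.
    below = np.nonzero(y <= y0 / np.e)[0]
    tau_f0 = float(t[below[0]]) if len(below) else float(t[-1] / 3.0)
    tau_f0 = float(np.clip(tau_f0, TAU_BOUNDS_MS[0], TAU_BOUNDS_MS[1] / 6.0))
    p0 = (y0 / 2.0, y0 / 2.0, tau_f0, 6.0 * tau_f0)
    lo = (0.0, 0.0, TAU_BOUNDS_MS[0], TAU_BOUNDS_MS[0])
    hi = (np.inf, np.inf, TAU_BOUNDS_MS[1], TAU_BOUNDS_MS[1])

    try:
        popt, _ = curve_fit(_biexp, t, y, p0=p0, bounds=(lo, hi), maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - rare solver failure
        raise FitError(
            f"biexponential fit did not converge (p0={p0}, window={window}): {exc}"
        ) from exc

    a1, a2, tau1, tau2 = popt
    if tau1 <= tau2:
        a_f, a_s, tau_f, tau_s = a1, a2, tau1, tau2
    else:
        a_f, a_s, tau_f, tau_s = a2, a1, tau2, tau1

    resid = y - _biexp(t, a_f, a_s, tau_f, tau_s)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    gof = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    total = a_f + a_s
    if total <= 0:
        raise FitError("fit collapsed to zero amplitude")
    quasi = (tau_s / tau_f) < QUASI_SINGLE_RATIO
    if quasi:
        warnings.warn(
            "tau_slow/tau_fast < 1.2: decay is quasi-single-exponential", stacklevel=2
        )

    return BiexpFit(
        amp_fast=float(a_f),
        amp_slow=float(a_s),
        tau_fast=float(tau_f),
        tau_slow=float(tau_s),
        frac_fast=float(a_f / total),
        frac_slow=float(a_s / total),
        tau_w=float(weighted_tau((a_f, a_s, tau_f, tau_s))),
        rise_time=float(t_peak - trace.stim_onset),
        gof=float(gof),
        fit_window=(float(window[0]), float(window[1])),
        quasi_single=bool(quasi),
        diagnostics={"baseline_pa": baseline, "sign": sign, "rmse": float(np.sqrt(ss_res / len(y)))},
    )


def percent_change_tau(
    baseline: list[BiexpFit | float],
    treated: list[BiexpFit | float],
    paired_by_cell: bool = True,
) -> dict:
    """Per-cell percent change in tau_w after drug application.

    For each cell: 100 * (tau_w_treated - tau_w_baseline) / tau_w_baseline.
    Returns the per-cell vector plus mean ± s.e.m. summary.
    """

    def _tw(x):
        return x.tau_w if isinstance(x, BiexpFit) else float(x)

    if paired_by_cell and len(baseline) != len(treated):
        raise ParameterError("paired comparison requires equal-length, aligned lists")
    base = np.array([_tw(x) for x in baseline], dtype=float)
    trea = np.array([_tw(x) for x in treated], dtype=float)
    if np.any(base <= 0):
        raise DegenerateInputError("baseline tau_w must be positive")
    pct = 100.0 * (trea - base) / base
    sem = float(np.std(pct, ddof=1) / np.sqrt(len(pct))) if len(pct) > 1 else float("nan")
    return {"per_cell_pct": pct, "mean_pct": float(np.mean(pct)), "sem_pct": sem}
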