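"""Photocurrent and current-clamp trace metrics.

Quantities mirror standard whole-cell pump characterization: peak and
steady-state photocurrent with the inactivation ratio, light-off relaxation
constant, current–voltage slope, action-spectrum peak, light-saturation
parameters, pulse-train adaptation, and spike metrics for optogenetic
silencing experiments.  Outward (pump) current is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .kinetics import fit_trace_multiexp
from .synth import PhotocurrentTrace

__all__ = [
    "PhotocurrentMetrics",
    "IVSeries",
    "ActionSpectrum",
    "SpikeMetrics",
    "photocurrent_metrics",
    "iv_fit",
    "action_spectrum_peak",
    "saturation_fit",
    "pulse_adaptation",
    "spike_metrics",
    "silencing_compare",
]

#: |slope| (pA/mV) below which an I–V relation is flagged voltage-insensitive;
#: roughly 5% of a typical fitted pump slope. Override via iv_fit argument.
VOLTAGE_INSENSITIVE_SLOPE = 0.02


@dataclass(frozen=True)
class PhotocurrentMetrics:
    i_peak: float  # pA, baseline-subtracted maximum during light
    i_ss: float  # pA, mean over the last 20% of the light epoch
    inactivation_ratio: float  # i_ss / i_peak
    tau_off: float  # ms, mono-exponential light-off relaxation


@dataclass(frozen=True)
class IVSeries:
    voltages: np.ndarray  # mV
    currents: np.ndarray  # pA
    slope: float  # pA/mV
    intercept: float  # pA
    r_squared: float
    slope_stderr: float
    voltage_insensitive: bool


@dataclass(frozen=True)
class ActionSpectrum:
    wavelengths: np.ndarray  # nm
    normalized_current: np.ndarray  # max = 1
    peak_nm: float
    irradiance_mW_mm2: float = 0.2
    edge_peak: bool = False


@dataclass(frozen=True)
class SpikeMetrics:
    spike_times: np.ndarray  # ms
    latency_first_spike: float  # ms; nan when no spike fired
    n_spikes: int


def photocurrent_metrics(trace: PhotocurrentTrace, epoch_index: int = 0, tail_fraction: float = 0.2) -> PhotocurrentMetrics:
    """Peak, steady-state, inactivation ratio and τ_off of one light epoch.

    The pre-light mean is subtracted as baseline; i_peak is the maximum
    during the epoch, i_ss the mean over its last ``tail_fraction``; τ_off
    comes from a mono-exponential fit to the post-light relaxation.
    """
    if not trace.light_epochs:
        raise ValueError("trace has no light epoch")
    on, off = trace.light_epochs[epoch_index]
    t, i = trace.time, trace.current
    lit = (t >= on) & (t < off)
    if lit.sum() < 5:
        raise ValueError(f"light epoch ({on}, {off}) ms spans fewer than 5 samples")
    pre = t < on
    baseline = float(i[pre].mean()) if pre.any() else 0.0
    y = i - baseline
    i_peak = float(y[lit].max())
    tail = (t >= off - tail_fraction * (off - on)) & (t < off)
    i_ss = float(y[tail].mean())
    next_on = min((o for o, _ in trace.light_epochs if o > off), default=t[-1] + trace.dt)
    post = (t >= off) & (t < next_on)
    tau_fit = fit_trace_multiexp(t[post] - off, y[post], n=1, fit_offset=True)
    return PhotocurrentMetrics(
        i_peak=i_peak,
        i_ss=i_ss,
        inactivation_ratio=i_ss / i_peak if i_peak != 0 else float("nan"),
        tau_off=float(tau_fit.taus[0]),
    )


def iv_fit(voltages, currents, insensitive_slope: float = VOLTAGE_INSENSITIVE_SLOPE) -> IVSeries:
    """Ordinary least-squares line through an I–V relation.

    Flags the relation voltage-insensitive when |slope| falls below
    ``insensitive_slope`` (pA/mV).
    """
    v = np.asarray(voltages, dtype=float)
    i = np.asarray(currents, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 voltage points")
    if np.unique(v).size != v.size:
        raise ValueError("voltages must be distinct")
    res = stats.linregress(v, i)
    return IVSeries(
        voltages=v,
        currents=i,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_stderr=float(res.stderr),
        voltage_insensitive=abs(res.slope) < insensitive_slope,
    )


def action_spectrum_peak(wavelengths, currents, irradiance_mW_mm2: float = 0.2) -> ActionSpectrum:
    """Normalized action spectrum and its peak wavelength.

    The peak is refined by a quadratic through the maximum sample and its
    two neighbours; a maximum at the grid edge is returned as-is with a
    warning (the true peak may lie outside the measured range).
    """
    wl = np.asarray(wavelengths, dtype=float)
    cur = np.asarray(currents, dtype=float)
    if wl.size < 3:
        raise ValueError("need at least 3 wavelengths")
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    norm = cur / cur.max()
    j = int(np.argmax(cur))
    edge = j in (0, wl.size - 1)
    if edge:
        warnings.warn("action-spectrum maximum at grid edge; peak may lie outside the measured range", stacklevel=2)
        peak = float(wl[j])
    else:
        x, y = wl[j - 1 : j + 2], cur[j - 1 : j + 2]
        denom = (y[0] - 2 * y[1] + y[2])
        if denom == 0:
            peak = float(wl[j])
        else:
            # vertex of the parabola through the three points (uniform or not)
            a, b, c = np.polyfit(x, y, 2)
            peak = float(-b / (2 * a))
    return ActionSpectrum(wl, norm, peak, irradiance_mW_mm2, edge_peak=edge)


def saturation_fit(irradiances, currents, ):
    """Fit the light-saturation hyperbola I = i_max·P/(P + p_half).

    Returns (i_max, p_half) with p_half in the irradiance units supplied
    (I reaches half of i_max at P = p_half).
    """
    p = np.asarray(irradiances, dtype=float)
    i = np.asarray(currents, dtype=float)
    if p.size < 3:
        raise ValueError("need at least 3 irradiance points")

    def hyperbola(P, i_max, p_half):
        return i_max * P / (P + p_half)

    p0 = (float(i.max()) * 1.2, float(np.median(p)))
    popt, _ = optimize.curve_fit(hyperbola, p, i, p0=p0, maxfev=10000)
    return float(popt[0]), float(popt[1])


def pulse_adaptation(trace: PhotocurrentTrace, pulse_times) -> tuple[np.ndarray, float]:
    """Per-pulse peak currents and the adaptation ratio (last/first).

    Each pulse window extends from its onset to the next onset (or trace
    end); peaks are baseline-subtracted against the pre-first-pulse mean.
    """
    pulses = np.sort(np.asarray(pulse_times, dtype=float))
    if pulses.size < 2:
        raise ValueError("need at least 2 pulses")
    if np.any(np.diff(pulses) < trace.dt):
        raise ValueError("pulses are closer than the trace sampling interval")
    t, i = trace.time, trace.current
    pre = t < pulses[0]
    baseline = float(i[pre].mean()) if pre.any() else 0.0
    edges = np.append(pulses, t[-1] + trace.dt)
    peaks = np.array(
        [float((i[(t >= a) & (t < b)] - baseline).max()) for a, b in zip(edges[:-1], edges[1:])]
    )
    return peaks, float(peaks[-1] / peaks[0])


def spike_metrics(time_ms, voltage_mV, threshold_mV: float = -20.0, refractory_ms: float = 2.0) -> SpikeMetrics:
    """Detect action potentials as upward threshold crossings.

    A crossing within ``refractory_ms`` of the previous spike is ignored
    (lockout), so a noisy plateau is not double-counted.  Latency is the
    time of the first spike relative to trace start (nan if none).
    """
    t = np.asarray(time_ms, dtype=float)
    v = np.asarray(voltage_mV, dtype=float)
    above = v >= threshold_mV
    crossings = t[1:][~above[:-1] & above[1:]]
    spikes: list[float] = []
    for c in crossings:
        if not spikes or c - spikes[-1] >= refractory_ms:
            spikes.append(float(c))
    arr = np.array(spikes)
    return SpikeMetrics(
        spike_times=arr,
        latency_first_spike=float(arr[0] - t[0]) if arr.size else float("nan"),
        n_spikes=int(arr.size),
    )


def silencing_compare(lit: SpikeMetrics, unlit: SpikeMetrics) -> tuple[float, int]:
    """Optical-silencing efficacy: (latency shift T, change in spike count).

    T = latency(lit) − latency(unlit) in ms; a positive T and a negative
    count change indicate effective silencing.
    """
    return (
        float(lit.latency_first_spike - unlit.latency_first_spike),
        int(lit.n_spikes - unlit.n_spikes),
    )
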