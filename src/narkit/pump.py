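"""Pump-assay (pH electrode) trace quantification.

A light-driven outward H⁺ pump acidifies the external medium during
illumination; a Na⁺ pump alkalinizes it (secondary proton uptake follows
Na⁺ extrusion), and the protonophore CCCP — which collapses the H⁺
gradient — suppresses the former but enhances the latter.  Classification
is from the sign and significance of the initial illumination slope.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass
from scipy import stats

from .synth import PumpTrace

__all__ = ["PumpMetrics", "pump_metrics"]

#: seconds of illumination over which the initial slope is measured
SLOPE_WINDOW_S = 30.0

#: slope significance multiple (in standard errors) for classification
SIGMA_RULE = 3.0


@dataclass(frozen=True)
class PumpMetrics:
    initial_slope: float  # pH/s over the first 30 s of illumination, drift-corrected
    slope_stderr: float  # OLS standard error of that slope
    net_delta_pH: float  # pH change over the whole illumination window
    classification: str  # H_export | Na_export_alkalinization | none
    cccp_ratio: float | None  # slope(CCCP)/slope(no CCCP) when a pair is given


def _window_slope(trace: PumpTrace, start: float, stop: float) -> tuple[float, float]:
    sel = (trace.time >= start) & (trace.time <= stop)
    if sel.sum() < 2:
        return 0.0, float("inf")
    res = stats.linregress(trace.time[sel], trace.pH[sel])
    return float(res.slope), float(res.stderr) if np.isfinite(res.stderr) else 0.0


def pump_metrics(
    trace: PumpTrace,
    paired_cccp_trace: PumpTrace | None = None,
    slope_window_s: float = SLOPE_WINDOW_S,
    sigma_rule: float = SIGMA_RULE,
) -> PumpMetrics:
    """Initial illumination slope, net ΔpH and transport-mode classification.

    The slope is OLS over the first ``slope_window_s`` seconds of
    illumination, after subtracting the pre-illumination drift slope (so a
    linear dark drift cancels by construction).  Classification: slope
    < −``sigma_rule``·SE → H_export; > +``sigma_rule``·SE →
    Na_export_alkalinization; otherwise none.  If a paired trace recorded
    with CCCP is supplied, the ratio of (drift-corrected) slopes is added.
    """
    on, off = trace.illumination_window
    t = trace.time
    if not (t[0] <= on < off <= t[-1]):
        raise ValueError(f"illumination window ({on}, {off}) s outside trace span [{t[0]}, {t[-1]}] s")
    in_window = (t >= on) & (t <= off)
    if in_window.sum() < 10:
        raise ValueError("fewer than 10 samples inside the illumination window")
    if paired_cccp_trace is not None and paired_cccp_trace.illumination_window != trace.illumination_window:
        raise ValueError("paired CCCP trace has a different illumination window")

    drift, _ = _window_slope(trace, t[0], on) if np.any(t < on) else (0.0, 0.0)
    raw_slope, stderr = _window_slope(trace, on, min(on + slope_window_s, off))
    slope = raw_slope - drift

    first = trace.pH[in_window][0]
    last = trace.pH[in_window][-1]
    net = float(last - first - drift * (off - on))

    if slope < -sigma_rule * stderr:
        cls = "H_export"
    elif slope > sigma_rule * stderr:
        cls = "Na_export_alkalinization"
    else:
        cls = "none"

    ratio = None
    if paired_cccp_trace is not None:
        pt = paired_cccp_trace.time
        pdrift, _ = _window_slope(paired_cccp_trace, pt[0], on) if np.any(pt < on) else (0.0, 0.0)
        praw, _ = _window_slope(paired_cccp_trace, on, min(on + slope_window_s, off))
        pslope = praw - pdrift
        ratio = float(pslope / slope) if slope != 0 else float("nan")

    return PumpMetrics(
        initial_slope=float(slope),
        slope_stderr=float(stderr),
        net_delta_pH=net,
        classification=cls,
        cccp_ratio=ratio,
    )
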