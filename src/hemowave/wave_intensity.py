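"""Wave intensity analysis of the ensemble-averaged beat.

Wave intensity is the product of the local pressure and velocity changes per
unit time:

    WI(t) = (dP/dt) (dU/dt)

computed from crude sample-to-sample differences at the native sampling rate
(1 kHz -> increments per 0.001 s), with no smoothing by default.  With P in
mmHg and U in m/s this yields WI in mmHg.m/s3.  Positive excursions mark
net forward-travelling wave energy, negative excursions backward-travelling
(reflected) waves:

* W1 — first positive peak in early systole (ventricular contraction);
* NW — mid-systolic negative trough (peripheral reflection returning to the
  heart; larger magnitude = stronger reflection);
* W2 — second positive peak near end-ejection (active flow deceleration).

Peak windows are phase-based fractions of the ejection interval (W1 within
the first 40 %, W2 from 60 % to 50 ms past end-ejection, NW between the W1
and W2 peak times); the fractions are overridable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import LandmarkError, SchemaError
from .preprocessing import EnsembleBeat

logger = logging.getLogger(__name__)


@dataclass
class WaveIntensityResult:
    """WI trace (length N-1 for an N-sample beat) and its three peaks."""

    fs_hz: float
    wi_trace: np.ndarray = field(repr=False)       # mmHg.m/s3 (default mode)
    dpdt_trace: np.ndarray = field(repr=False)     # mmHg/s
    dudt_trace: np.ndarray = field(repr=False)     # m/s2
    w1: float = float("nan")
    w1_time_s: float = float("nan")
    w2: float = float("nan")
    w2_time_s: float = float("nan")
    nw: float = float("nan")
    nw_time_s: float = float("nan")


def wave_intensity(
    beat: EnsembleBeat,
    probe_area_cm2: float | None = None,
    smooth_ms: float = 0.0,
    time_normalized: bool = True,
    w1_window_frac: float = 0.4,
    w2_window_frac: float = 0.6,
) -> WaveIntensityResult:
    """Compute the WI trace of an ensemble beat and extract W1/NW/W2.

    Velocity is taken from the beat, or derived from flow via
    ``probe_area_cm2`` (U = Q/A).  ``time_normalized=False`` reproduces the
    raw-increment convention dP*dU (values scale down by fs^2).  Optional
    moving-average smoothing of width ``smooth_ms`` is applied to P and U
    before differencing (logged).
    """
    p = np.asarray(beat.p_mmhg, dtype=float)
    u = beat.u_m_s
    if u is None:
        if beat.q_ml_s is None or not probe_area_cm2:
            raise SchemaError("no velocity trace and no probe area to derive one")
        u = beat.q_ml_s / probe_area_cm2 / 100.0
    u = np.asarray(u, dtype=float)

    if smooth_ms > 0:
        width = max(int(round(smooth_ms * 1e-3 * beat.fs_hz)) | 1, 1)
        kernel = np.ones(width) / width
        p = np.convolve(p, kernel, mode="same")
        u = np.convolve(u, kernel, mode="same")
        logger.info("smoothed P and U with a %d-sample moving average", width)

    scale = beat.fs_hz if time_normalized else 1.0
    dpdt = np.diff(p) * scale
    dudt = np.diff(u) * scale
    wi = dpdt * dudt

    result = WaveIntensityResult(
        fs_hz=beat.fs_hz, wi_trace=wi, dpdt_trace=dpdt, dudt_trace=dudt
    )
    peaks = extract_wi_peaks(
        wi,
        beat.fs_hz,
        beat.ejection_onset_s,
        beat.ejection_end_s,
        w1_window_frac=w1_window_frac,
        w2_window_frac=w2_window_frac,
    )
    (result.w1, result.w1_time_s, result.nw, result.nw_time_s,
     result.w2, result.w2_time_s) = peaks
    return result


def extract_wi_peaks(
    wi_trace: np.ndarray,
    fs_hz: float,
    ejection_onset_s: float,
    ejection_end_s: float,
    w1_window_frac: float = 0.4,
    w2_window_frac: float = 0.6,
    w2_post_s: float = 0.05,
) -> tuple[float, float, float, float, float, float]:
    """Extract (w1, w1_time, nw, nw_time, w2, w2_time) from a WI trace.

    W1 is the maximum over [onset, onset + w1_frac * E], W2 the maximum over
    [onset + w2_frac * E, end + 50 ms] with E the ejection duration, and NW
    the minimum strictly between the W1 and W2 peak times.
    """
    wi = np.asarray(wi_trace, dtype=float)
    n = len(wi)
    duration = n / fs_hz
    if not (0 <= ejection_onset_s < ejection_end_s <= duration + 1.0 / fs_hz):
        raise LandmarkError(
            f"landmarks [{ejection_onset_s}, {ejection_end_s}] s outside the "
            f"{duration:.3f} s trace"
        )
    eject = ejection_end_s - ejection_onset_s
    i_on = int(round(ejection_onset_s * fs_hz))
    i_w1_hi = min(int(round((ejection_onset_s + w1_window_frac * eject) * fs_hz)), n - 1)
    i_w2_lo = min(int(round((ejection_onset_s + w2_window_frac * eject) * fs_hz)), n - 1)
    i_w2_hi = min(int(round((ejection_end_s + w2_post_s) * fs_hz)), n - 1)

    w1_slice = wi[i_on : i_w1_hi + 1]
    i_w1 = i_on + int(np.argmax(w1_slice))
    w2_slice = wi[i_w2_lo : i_w2_hi + 1]
    i_w2 = i_w2_lo + int(np.argmax(w2_slice))

    lo, hi = i_w1 + 1, i_w2  # strictly between the two positive peaks
    if hi > lo:
        mid = wi[lo:hi]
        i_nw = lo + int(np.argmin(mid))
        nw, nw_time = float(mid.min()), i_nw / fs_hz
    else:
        nw, nw_time = 0.0, (i_w1 + 1) / fs_hz
    return (
        float(wi[i_w1]),
        i_w1 / fs_hz,
        nw,
        nw_time,
        float(wi[i_w2]),
        i_w2 / fs_hz,
    )
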