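"""Beat segmentation, ECG-gated ensemble averaging and beat summaries.

Beat-to-beat fluctuation from catheter motion and respiration is suppressed
by aligning successive beats at the ECG R apex and averaging pointwise over
eight beats (the count is configurable).  Beats of unequal length are
harmonized by linear resampling to the median RR interval before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import InsufficientDataError, LandmarkError, SegmentationError
from .waveform_io import WaveformRecord

#: minimum separation of R peaks (physiologic refractory period), seconds
_REFRACTORY_S = 0.2


@dataclass
class BeatSegmentation:
    """R-peak sample indices and the derived RR intervals."""

    r_peak_indices: np.ndarray
    rr_s: np.ndarray
    fs_hz: float

    @property
    def n_beats(self) -> int:
        return len(self.rr_s)


@dataclass
class EnsembleBeat:
    """One R-aligned averaged beat with ejection landmarks.

    All traces share the same length; ``lvp_mmhg``, ``q_ml_s`` or ``u_m_s``
    may be None when the source recording lacks them.
    """

    fs_hz: float
    p_mmhg: np.ndarray
    u_m_s: np.ndarray | None = None
    q_ml_s: np.ndarray | None = None
    lvp_mmhg: np.ndarray | None = None
    n_beats_averaged: int = 0
    ejection_onset_s: float = float("nan")
    ejection_end_s: float = float("nan")

    @property
    def duration_s(self) -> float:
        return len(self.p_mmhg) / self.fs_hz

    def time(self) -> np.ndarray:
        return np.arange(len(self.p_mmhg)) / self.fs_hz


@dataclass
class BeatSummary:
    """Scalar hemodynamics of an ensemble beat (pressures in mmHg)."""

    hr_bpm: float
    sbp_mmhg: float
    dbp_mmhg: float
    map_mmhg: float
    pp_mmhg: float
    co_l_min: float | None = None
    lv_dpdt_max_mmhg_s: float | None = None
    lv_dpdt_min_mmhg_s: float | None = None
    dqdt_max_ml_s2: float | None = None
    dqdt_min_ml_s2: float | None = None


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    width = max(width | 1, 1)  # odd, >= 1
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_r_peaks(ecg: np.ndarray, fs_hz: float) -> BeatSegmentation:
    """Locate R apexes with a band-limited derivative-energy threshold.

    The ECG is low-pass smoothed (8 ms moving average), differentiated and
    squared; the smoothed energy envelope is thresholded adaptively with a
    200 ms refractory period, and each detection is refined to the apex of
    the smoothed ECG within +-20 ms.  Adequate for clean laboratory signals;
    this is not a clinical QRS detector.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.ndim != 1 or len(ecg) < 3:
        raise SegmentationError("ECG must be a 1-D array with >= 3 samples")
    smooth = _moving_average(ecg, int(round(0.008 * fs_hz)))
    energy = np.gradient(smooth) ** 2
    envelope = _moving_average(energy, int(round(0.015 * fs_hz)))
    peak = envelope.max()
    if peak <= 0 or np.ptp(ecg) == 0:
        raise SegmentationError("flat-line ECG: no QRS energy found")
    candidates, _ = find_peaks(
        envelope, height=0.3 * peak, distance=max(int(_REFRACTORY_S * fs_hz), 1)
    )
    half_win = max(int(round(0.020 * fs_hz)), 1)
    apexes = []
    for c in candidates:
        lo, hi = max(c - half_win, 0), min(c + half_win + 1, len(ecg))
        apexes.append(lo + int(np.argmax(smooth[lo:hi])))
    apexes = np.unique(apexes)
    # enforce refractory after refinement
    kept: list[int] = []
    for a in apexes:
        if not kept or (a - kept[-1]) >= _REFRACTORY_S * fs_hz:
            kept.append(int(a))
    if len(kept) < 2:
        raise SegmentationError(f"found {len(kept)} R peak(s); need at least 2")
    idx = np.asarray(kept)
    return BeatSegmentation(r_peak_indices=idx, rr_s=np.diff(idx) / fs_hz, fs_hz=fs_hz)


def ensemble_average(
    record: WaveformRecord,
    segmentation: BeatSegmentation,
    n_beats: int = 8,
    probe_area_cm2: float | None = None,
) -> EnsembleBeat:
    """Average the first ``n_beats`` R-aligned beats of a recording.

    Each beat spans one R apex to the next; beats are linearly resampled to
    the median RR length and averaged pointwise.  If the recording has only
    one of flow/velocity the other is derived when ``probe_area_cm2`` is
    given (U = Q / A).
    """
    peaks = segmentation.r_peak_indices
    available = len(peaks) - 1
    if available < n_beats:
        raise InsufficientDataError(
            f"need {n_beats} complete beats, only {available} available"
        )
    starts, stops = peaks[:n_beats], peaks[1 : n_beats + 1]
    target = int(round(np.median(stops - starts)))

    def average(channel: str) -> np.ndarray | None:
        if channel not in record.channels:
            return None
        x = record.channels[channel]
        grid = np.arange(target)
        acc = np.zeros(target)
        for i0, i1 in zip(starts, stops):
            beat = x[i0:i1]
            src = np.linspace(0, target - 1, num=len(beat))
            acc += np.interp(grid, src, beat)
        return acc / n_beats

    p = average("aop")
    q = average("flow")
    u = average("velocity")
    if q is None and u is not None and probe_area_cm2:
        q = u * 100.0 * probe_area_cm2
    if u is None and q is not None and probe_area_cm2:
        u = q / probe_area_cm2 / 100.0
    beat = EnsembleBeat(
        fs_hz=record.fs_hz,
        p_mmhg=p,
        u_m_s=u,
        q_ml_s=q,
        lvp_mmhg=average("lvp"),
        n_beats_averaged=n_beats,
    )
    beat.ejection_onset_s, beat.ejection_end_s = locate_ejection(beat)
    return beat


def locate_ejection(
    beat: EnsembleBeat, onset_frac: float = 0.05, end_frac: float = 0.02
) -> tuple[float, float]:
    """Find ejection onset/end from the flow (or velocity) trace.

    Onset: first sample rising above ``onset_frac`` of the beat maximum.
    End: first sample at/below max(0, ``end_frac`` * maximum) after the peak
    (i.e. a downward zero-crossing, or the fall below the end threshold).
    """
    q = beat.q_ml_s if beat.q_ml_s is not None else beat.u_m_s
    if q is None:
        raise LandmarkError("no flow or velocity trace to locate ejection")
    qmax = float(np.max(q))
    if qmax <= 0:
        raise LandmarkError("flow is non-positive throughout the beat")
    above = np.nonzero(q > onset_frac * qmax)[0]
    onset = int(above[0])
    peak = int(np.argmax(q))
    after = np.nonzero(q[peak:] <= max(0.0, end_frac * qmax))[0]
    end = peak + int(after[0]) if after.size else len(q) - 1
    return onset / beat.fs_hz, end / beat.fs_hz


def summarize_beat(
    beat: EnsembleBeat, segmentation: BeatSegmentation | None = None
) -> BeatSummary:
    """Scalar summary: SBP/DBP/MAP/PP, HR, CO and dP/dt / dQ/dt extremes.

    MAP is the time average of the pressure trace.  CO is the time-mean flow
    over the beat.  Derivatives use central differences at the native rate
    with no smoothing.  HR comes from the mean RR when a segmentation is
    given, else from the ensemble-beat duration.
    """
    p = beat.p_mmhg
    sbp, dbp = float(np.max(p)), float(np.min(p))
    if segmentation is not None:
        hr = 60.0 / float(np.mean(segmentation.rr_s))
    else:
        hr = 60.0 / beat.duration_s
    co = None
    dqdt_max = dqdt_min = None
    if beat.q_ml_s is not None:
        co = float(np.mean(beat.q_ml_s)) * 60.0 / 1000.0  # mL/s -> L/min
        dq = np.gradient(beat.q_ml_s) * beat.fs_hz
        dqdt_max, dqdt_min = float(np.max(dq)), float(np.min(dq))
    dpdt_max = dpdt_min = None
    if beat.lvp_mmhg is not None:
        dp = np.gradient(beat.lvp_mmhg) * beat.fs_hz
        dpdt_max, dpdt_min = float(np.max(dp)), float(np.min(dp))
    return BeatSummary(
        hr_bpm=hr,
        sbp_mmhg=sbp,
        dbp_mmhg=dbp,
        map_mmhg=float(np.mean(p)),
        pp_mmhg=sbp - dbp,
        co_l_min=co,
        lv_dpdt_max_mmhg_s=dpdt_max,
        lv_dpdt_min_mmhg_s=dpdt_min,
        dqdt_max_ml_s2=dqdt_max,
        dqdt_min_ml_s2=dqdt_min,
    )
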