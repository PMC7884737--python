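"""End-to-end analysis of one recording: the full measurement chain.

Ties together R-peak detection, eight-beat ensemble averaging, input
impedance (Z0, Zc), wave separation (RM, RI), wave intensity (W1, W2, NW)
and — when diameters are supplied — stiffness beta, percent diameter change
and Bramwell-Hill PWV.  Returns a flat dict of unit-suffixed metrics, the
shape the report builder and CLI consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import impedance as imp
from . import preprocessing as pre
from . import stiffness as stiff
from . import wave_intensity as wi
from . import wave_separation as ws
from .waveform_io import DiameterMeasurement, WaveformRecord

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with the package's standard defaults."""

    n_beats_ensemble: int = 8
    zc_band_hz: tuple[float, float] = (1.0, 10.0)
    probe_area_cm2: float | None = None
    w1_window_frac: float = 0.4
    w2_window_frac: float = 0.6
    smooth_ms: float = 0.0
    ejection_onset_frac: float = 0.05
    ejection_end_frac: float = 0.02


def analyze_recording(
    record: WaveformRecord,
    diameters: DiameterMeasurement | None = None,
    config: AnalysisConfig | None = None,
) -> dict[str, float]:
    """Run the full pipeline on one recording; returns unit-suffixed metrics."""
    config = config or AnalysisConfig()
    record.validate()

    segmentation = pre.detect_r_peaks(record.channels["ecg"], record.fs_hz)
    beat = pre.ensemble_average(
        record,
        segmentation,
        n_beats=config.n_beats_ensemble,
        probe_area_cm2=config.probe_area_cm2,
    )
    summary = pre.summarize_beat(beat, segmentation)

    metrics: dict[str, float] = {
        "hr_bpm": summary.hr_bpm,
        "sbp_mmhg": summary.sbp_mmhg,
        "dbp_mmhg": summary.dbp_mmhg,
        "map_mmhg": summary.map_mmhg,
        "pp_mmhg": summary.pp_mmhg,
    }
    for key, value in (
        ("co_l_min", summary.co_l_min),
        ("lv_dpdt_max_mmhg_s", summary.lv_dpdt_max_mmhg_s),
        ("lv_dpdt_min_mmhg_s", summary.lv_dpdt_min_mmhg_s),
        ("dqdt_max_ml_s2", summary.dqdt_max_ml_s2),
        ("dqdt_min_ml_s2", summary.dqdt_min_ml_s2),
    ):
        if value is not None:
            metrics[key] = value

    if beat.q_ml_s is not None:
        spectrum = imp.input_impedance(beat, zc_band_hz=config.zc_band_hz)
        metrics["z0_dyn_s_cm5"] = spectrum.z0_dyn_s_cm5
        metrics["zc_dyn_s_cm5"] = spectrum.zc_dyn_s_cm5
        separation = ws.separate_waves(beat, spectrum.zc_dyn_s_cm5)
        metrics["pf_amp_mmhg"] = separation.pf_amp_mmhg
        metrics["pb_amp_mmhg"] = separation.pb_amp_mmhg
        metrics["rm"] = separation.rm
        metrics["ri"] = separation.ri

    intensity = wi.wave_intensity(
        beat,
        probe_area_cm2=config.probe_area_cm2,
        smooth_ms=config.smooth_ms,
        w1_window_frac=config.w1_window_frac,
        w2_window_frac=config.w2_window_frac,
    )
    metrics["w1_mmhg_m_s3"] = intensity.w1
    metrics["w2_mmhg_m_s3"] = intensity.w2
    metrics["nw_mmhg_m_s3"] = intensity.nw
    metrics["w1_time_s"] = intensity.w1_time_s
    metrics["w2_time_s"] = intensity.w2_time_s
    metrics["nw_time_s"] = intensity.nw_time_s

    if diameters is not None:
        indices = stiff.compute_stiffness_indices(
            summary.sbp_mmhg, summary.dbp_mmhg, diameters
        )
        metrics["beta"] = indices.beta
        metrics["diameter_change_pct"] = indices.diameter_change_pct
        metrics["pwv_m_s"] = indices.pwv_m_s
    else:
        logger.info("no diameter measurement: beta/diameter change/PWV omitted")

    return metrics
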