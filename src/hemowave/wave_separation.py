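"""Linear forward/backward pressure wave separation.

With the characteristic impedance Zc known, the measured pulsatile pressure
(above its diastolic offset) and flow split uniquely into a forward-running
and a backward-running (reflected) component:

    Pf = (p + Zc Q) / 2,   Pb = (p - Zc Q) / 2,   p = P - min(P)

Reflection magnitude and index follow from the peak-trough amplitudes:

    RM = |Pb| / |Pf|,   RI = |Pb| / (|Pf| + |Pb|) = RM / (1 + RM)

The diastolic offset is removed before separation so that the constant
baseline is not attributed to the forward wave; both the per-sample traces
and the amplitudes are reported, since absolute-referenced and
amplitude-referenced conventions coexist in the literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ImpedanceError, ParameterError
from .preprocessing import EnsembleBeat
from .waveform_io import MMHG_TO_DYN_CM2


@dataclass
class WaveSeparationResult:
    """Forward/backward traces (mmHg above the diastolic offset) + scalars."""

    pf_trace_mmhg: np.ndarray = field(repr=False)
    pb_trace_mmhg: np.ndarray = field(repr=False)
    pf_amp_mmhg: float = float("nan")
    pb_amp_mmhg: float = float("nan")
    rm: float = float("nan")
    ri: float = float("nan")
    offset_mmhg: float = float("nan")
    zc_dyn_s_cm5: float = float("nan")


def reflection_index_from_magnitude(rm: float) -> float:
    """RI = RM / (1 + RM); the algebraic link between the two indices."""
    if rm < 0:
        raise ParameterError(f"reflection magnitude must be >= 0, got {rm}")
    return rm / (1.0 + rm)


def separate_waves(beat: EnsembleBeat, zc_dyn_s_cm5: float) -> WaveSeparationResult:
    """Split an ensemble beat into forward and backward pressure waves.

    Requires the flow trace and a positive Zc.  The emitted result satisfies
    ``pf + pb + offset == P`` and ``(pf - pb)/Zc == Q`` sample-by-sample to
    numerical precision.
    """
    if not (zc_dyn_s_cm5 > 0):
        raise ParameterError(f"zc must be > 0, got {zc_dyn_s_cm5}")
    if beat.q_ml_s is None:
        raise ImpedanceError("ensemble beat has no flow trace")
    p = np.asarray(beat.p_mmhg, dtype=float)
    q = np.asarray(beat.q_ml_s, dtype=float)
    offset = float(np.min(p))
    p_pulsatile = p - offset
    zcq_mmhg = zc_dyn_s_cm5 * q / MMHG_TO_DYN_CM2
    pf = 0.5 * (p_pulsatile + zcq_mmhg)
    pb = 0.5 * (p_pulsatile - zcq_mmhg)
    pf_amp = float(np.ptp(pf))
    pb_amp = float(np.ptp(pb))
    rm = pb_amp / pf_amp if pf_amp > 0 else float("nan")
    return WaveSeparationResult(
        pf_trace_mmhg=pf,
        pb_trace_mmhg=pb,
        pf_amp_mmhg=pf_amp,
        pb_amp_mmhg=pb_amp,
        rm=rm,
        ri=reflection_index_from_magnitude(rm) if np.isfinite(rm) else float("nan"),
        offset_mmhg=offset,
        zc_dyn_s_cm5=zc_dyn_s_cm5,
    )
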