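"""Synthetic pressure/flow/ECG recordings from a single-tube reflection model.

The generator emulates an ascending-aortic measurement site on a uniform
transmission line with characteristic impedance ``Zc`` and a single distal
reflection site of coefficient ``gamma`` at one-way distance ``tau`` (the
round trip takes ``2*tau`` seconds):

* forward flow is a half-sine ejection pulse, zero in diastole;
* forward pressure is ``Pf = Zc * Qf`` (converted to mmHg);
* the backward wave is ``Pb(t) = gamma * Pf(t - 2*tau)`` ("single" mode), or
  the full re-reflection train for a flow-source proximal boundary
  ("reverberant" mode): ``Pf = sum_k gamma^k Pf0(t - 2 k tau)`` for k >= 0 and
  ``Pb`` the same sum for k >= 1, truncated once ``gamma^k < 1e-6``;
* measured pressure is ``DBP + Pf + Pb`` plus Gaussian noise, measured flow
  is ``(Pf - Pb)/Zc`` plus noise, velocity is flow over the probe area;
* the ECG channel carries a 20 ms triangular R complex whose apex marks each
  beat onset.

Beat-to-beat jitter perturbs the beat *periods* only; the within-beat shape
is fixed, so ensemble averaging is exercised realistically.  Noise-free
outputs satisfy the conservation identities ``P - DBP = Pf + Pb`` and
``Q = (Pf - Pb)/Zc`` at every sample to machine precision, and the returned
:class:`SyntheticTruth` carries the exact per-sample forward/backward traces
for recovery tests.

Default parameter values portray an anesthetized large-animal preparation:
HR 120 bpm, DBP 90 mmHg, Zc ~63 dyn.s.cm-5, peak ejection flow 410 mL/s over
30 % of the cycle (cardiac output ~4.7 L/min), aortic cross-section 3 cm2.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .waveform_io import MMHG_TO_DYN_CM2, WaveformRecord

#: silence before the first beat so the first R apex is an interior sample
_LEAD_IN_S = 0.1
#: total width of the triangular R complex (s)
_R_WIDTH_S = 0.020
#: relative amplitude below which the reverberant train is truncated
_REVERB_TOL = 1e-6


@dataclass
class SyntheticConfig:
    """Parameters of the single-tube generator (see module docstring)."""

    heart_rate_bpm: float = 120.0
    n_beats: int = 12
    fs_hz: float = 1000.0
    zc_true: float = 62.8              # dyn.s.cm-5
    gamma: float = 0.4                 # distal reflection coefficient
    round_trip_delay_s: float = 0.05   # 2*tau
    ejection_fraction_of_cycle: float = 0.3
    peak_flow_ml_s: float = 410.0
    diastolic_pressure_mmhg: float = 90.0
    probe_area_cm2: float = 3.0
    rr_jitter_sd_s: float = 0.005
    noise_sd_pressure_mmhg: float = 0.5
    noise_sd_flow_ml_s: float = 5.0
    seed: int = 12345
    reflection_mode: str = "single"    # "single" | "reverberant"

    def validate(self) -> None:
        checks = [
            (self.heart_rate_bpm > 0, "heart_rate_bpm must be > 0"),
            (self.n_beats >= 1, "n_beats must be >= 1"),
            (self.fs_hz > 0, "fs_hz must be > 0"),
            (self.zc_true > 0, "zc_true must be > 0"),
            (0.0 <= self.gamma < 1.0, "gamma must lie in [0, 1)"),
            (self.round_trip_delay_s >= 0, "round_trip_delay_s must be >= 0"),
            (
                self.round_trip_delay_s < 60.0 / self.heart_rate_bpm,
                "round_trip_delay_s must be shorter than the cycle length",
            ),
            (
                0.0 < self.ejection_fraction_of_cycle < 1.0,
                "ejection_fraction_of_cycle must lie in (0, 1)",
            ),
            (self.peak_flow_ml_s > 0, "peak_flow_ml_s must be > 0"),
            (self.probe_area_cm2 > 0, "probe_area_cm2 must be > 0"),
            (self.rr_jitter_sd_s >= 0, "rr_jitter_sd_s must be >= 0"),
            (self.noise_sd_pressure_mmhg >= 0, "noise_sd_pressure_mmhg must be >= 0"),
            (self.noise_sd_flow_ml_s >= 0, "noise_sd_flow_ml_s must be >= 0"),
            (
                self.reflection_mode in ("single", "reverberant"),
                "reflection_mode must be 'single' or 'reverberant'",
            ),
        ]
        for ok, message in checks:
            if not ok:
                raise ConfigurationError(message)


@dataclass
class SyntheticTruth:
    """Ground truth returned alongside a generated recording."""

    zc_true: float
    gamma: float
    round_trip_delay_s: float
    pf_trace: np.ndarray = field(repr=False)   # mmHg above diastolic
    pb_trace: np.ndarray = field(repr=False)   # mmHg above diastolic
    onset_indices: np.ndarray = field(repr=False)
    ejection_duration_s: float = 0.0
    seed: int = 0


def _shift(x: np.ndarray, by: int) -> np.ndarray:
    """Right-shift with zero fill; samples pushed past the end are dropped."""
    if by <= 0:
        return x.copy()
    out = np.zeros_like(x)
    out[by:] = x[:-by]
    return out


def generate_recording(config: SyntheticConfig) -> tuple[WaveformRecord, SyntheticTruth]:
    """Generate one recording plus its ground truth. Deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs_hz
    t_cycle = 60.0 / config.heart_rate_bpm
    t_eject = config.ejection_fraction_of_cycle * t_cycle

    # beat periods: jitter on the period only, shape fixed; clip guards
    # against pathological draws shortening a beat below the ejection window
    rr = t_cycle + rng.normal(0.0, config.rr_jitter_sd_s, size=config.n_beats)
    rr = np.clip(rr, t_eject + config.round_trip_delay_s + 1e-3, None)

    onsets_s = _LEAD_IN_S + np.concatenate([[0.0], np.cumsum(rr[:-1])])
    n = int(round((_LEAD_IN_S + rr.sum()) * fs)) + 1
    onset_idx = np.round(onsets_s * fs).astype(int)

    n_eject = max(int(round(t_eject * fs)), 2)
    pulse = config.peak_flow_ml_s * np.sin(np.pi * np.arange(n_eject) / n_eject)

    qf = np.zeros(n)
    for i0 in onset_idx:
        stop = min(i0 + n_eject, n)
        qf[i0:stop] += pulse[: stop - i0]

    # forward pressure in mmHg: Zc [dyn.s.cm-5] * Q [cm3/s] -> dyn/cm2
    pf0 = config.zc_true * qf / MMHG_TO_DYN_CM2
    d = int(round(config.round_trip_delay_s * fs))
    if config.gamma == 0.0:
        pf, pb = pf0.copy(), np.zeros(n)
    elif config.reflection_mode == "single":
        pf, pb = pf0.copy(), config.gamma * _shift(pf0, d)
    else:  # reverberant: geometric re-reflection train off a flow source
        k_max = int(math.ceil(math.log(_REVERB_TOL) / math.log(config.gamma)))
        pf, pb = pf0.copy(), np.zeros(n)
        for k in range(1, k_max + 1):
            term = config.gamma**k * _shift(pf0, k * d)
            pf += term
            pb += term

    p_clean = config.diastolic_pressure_mmhg + pf + pb
    q_clean = (pf - pb) * MMHG_TO_DYN_CM2 / config.zc_true

    ecg = np.zeros(n)
    half = int(round(_R_WIDTH_S / 2 * fs))
    tri = 1.0 - np.abs(np.arange(-half, half + 1)) / half
    for i0 in onset_idx:
        lo, hi = i0 - half, i0 + half + 1
        ecg[max(lo, 0) : min(hi, n)] += tri[max(lo, 0) - lo : tri.size - (hi - min(hi, n))]

    lvp = _left_ventricular_pressure(p_clean, onset_idx, n_eject, fs, n)

    aop = p_clean + rng.normal(0.0, config.noise_sd_pressure_mmhg, n)
    flow = q_clean + rng.normal(0.0, config.noise_sd_flow_ml_s, n)
    velocity = flow / config.probe_area_cm2 / 100.0  # cm/s -> m/s
    lvp = lvp + rng.normal(0.0, config.noise_sd_pressure_mmhg, n)

    record = WaveformRecord(
        fs_hz=fs,
        channels={"ecg": ecg, "aop": aop, "lvp": lvp, "flow": flow, "velocity": velocity},
        subject_id="synthetic",
        condition=f"gamma={config.gamma:g}",
    )
    truth = SyntheticTruth(
        zc_true=config.zc_true,
        gamma=config.gamma,
        round_trip_delay_s=config.round_trip_delay_s,
        pf_trace=pf,
        pb_trace=pb,
        onset_indices=onset_idx,
        ejection_duration_s=n_eject / fs,
        seed=config.seed,
    )
    return record, truth


def _left_ventricular_pressure(p_clean, onset_idx, n_eject, fs, n):
    """Crude LV pressure: tracks aortic pressure during ejection, with a
    40 ms isovolumic rise before and a 40 ms relaxation after; 8 mmHg floor."""
    base = 8.0
    ramp = max(int(round(0.040 * fs)), 1)
    lvp = np.full(n, base)
    for i0 in onset_idx:
        stop = min(i0 + n_eject, n)
        lvp[i0:stop] = p_clean[i0:stop] + 2.0
        rise = np.arange(max(i0 - ramp, 0), i0)
        if rise.size:
            frac = 0.5 * (1 - np.cos(np.pi * (rise - rise[0]) / max(rise.size, 1)))
            lvp[rise] = base + frac * (p_clean[i0] + 2.0 - base)
        fall = np.arange(stop, min(stop + ramp, n))
        if fall.size and stop > 0:
            frac = 0.5 * (1 + np.cos(np.pi * (fall - stop) / ramp))
            lvp[fall] = base + frac * (lvp[stop - 1] - base)
    return lvp


def load_config(path) -> SyntheticConfig:
    """Load a config from JSON or flat ``key: value`` lines."""
    text = Path(path).read_text(encoding="utf-8").strip()
    if text.startswith("{"):
        raw = json.loads(text)
    else:
        raw = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition(":")
            raw[key.strip()] = value.strip()
    fields = SyntheticConfig.__dataclass_fields__
    unknown = set(raw) - set(fields)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    coerced = {}
    for key, value in raw.items():
        typ = fields[key].type
        if typ == "int":
            coerced[key] = int(value)
        elif typ == "float":
            coerced[key] = float(value)
        else:
            coerced[key] = str(value)
    config = SyntheticConfig(**coerced)
    config.validate()
    return config


def write_truth(truth: SyntheticTruth, path) -> None:
    """Write the truth sidecar as flat JSON (traces as lists)."""
    payload = asdict(truth)
    for key in ("pf_trace", "pb_trace", "onset_indices"):
        payload[key] = np.asarray(payload[key]).tolist()
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def read_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    payload["pf_trace"] = np.asarray(payload["pf_trace"], dtype=float)
    payload["pb_trace"] = np.asarray(payload["pb_trace"], dtype=float)
    payload["onset_indices"] = np.asarray(payload["onset_indices"], dtype=int)
    return SyntheticTruth(**payload)
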