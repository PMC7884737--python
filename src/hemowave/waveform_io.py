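"""Read/write multichannel waveform recordings and unit conversion.

The on-disk container is deliberately plain: delimited text (comma or tab,
autodetected), UTF-8, with ``#``-prefixed metadata lines before a header row
of channel names.  Metadata keys: ``fs_hz``, ``subject_id``, ``condition``
and ``unit.<channel>`` per channel, e.g.::

    # fs_hz=1000
    # subject_id=goat1
    # condition=baseline
    # unit.aop=mmHg
    ecg,aop,flow
    0.0,90.2,0.0
    ...

A ``time_s`` column, if present, must be uniform to 1 ppm and is used to
derive (or cross-check) the sampling rate.  Scalar tables (diameters) are
ordinary CSV with a header row.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, PolicyError, SchemaError, UnitError

logger = logging.getLogger(__name__)

#: 1 mmHg in dyn/cm^2 (CGS pressure), the conventional hemodynamics factor.
MMHG_TO_DYN_CM2 = 1333.22

# Each physical dimension maps unit -> factor to an arbitrary base unit of
# that dimension.  Conversion between any two units of one dimension is the
# ratio of factors, which keeps the conversion graph trivially consistent.
_UNIT_TABLE: dict[str, dict[str, float]] = {
    "pressure": {"mmHg": MMHG_TO_DYN_CM2, "dyn/cm2": 1.0, "Pa": 10.0},
    "flow": {"L/min": 1000.0 / 60.0, "mL/s": 1.0, "cm3/s": 1.0},
    "velocity": {"m/s": 100.0, "cm/s": 1.0},
    "length": {"mm": 0.1, "cm": 1.0, "m": 100.0},
}

#: Channels every recording must provide (plus one of flow/velocity).
MANDATORY_CHANNELS = ("ecg", "aop")

DEFAULT_UNITS = {
    "ecg": "a.u.",
    "aop": "mmHg",
    "lvp": "mmHg",
    "flow": "mL/s",
    "velocity": "m/s",
}


def convert_units(value, from_unit: str, to_unit: str):
    """Convert ``value`` between two units of the same physical dimension.

    Supported: mmHg/dyn-cm2/Pa, L-min/mL-s/cm3-s, m-s/cm-s, mm/cm/m.
    Raises :class:`UnitError` for unknown units or mixed dimensions.
    """
    if from_unit == to_unit:
        return value
    for table in _UNIT_TABLE.values():
        if from_unit in table and to_unit in table:
            return value * (table[from_unit] / table[to_unit])
    raise UnitError(f"unsupported unit pair: {from_unit!r} -> {to_unit!r}")


@dataclass
class WaveformRecord:
    """A uniformly sampled multichannel recording with unit metadata.

    channels holds named 1-D arrays; ``ecg`` and ``aop`` are mandatory and at
    least one of ``flow``/``velocity`` must be present for downstream
    analysis. ``lvp`` (left-ventricular pressure) is optional.
    """

    fs_hz: float
    channels: dict[str, np.ndarray]
    units: dict[str, str] = field(default_factory=dict)
    subject_id: str = ""
    condition: str = ""
    t0_s: float = 0.0

    def __post_init__(self):
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name in self.channels:
            self.units.setdefault(name, DEFAULT_UNITS.get(name, ""))

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def time(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.fs_hz

    def validate(self) -> None:
        if not self.channels:
            raise SchemaError("record has no channels")
        if not (self.fs_hz > 0):
            raise FormatError(f"fs_hz must be positive, got {self.fs_hz}")
        lengths = {name: len(x) for name, x in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise FormatError(f"channels differ in length: {lengths}")
        for name in MANDATORY_CHANNELS:
            if name not in self.channels:
                raise SchemaError(f"missing mandatory channel {name!r}")
        if "flow" not in self.channels and "velocity" not in self.channels:
            raise SchemaError("missing mandatory channel: one of 'flow'/'velocity'")
        for name, x in self.channels.items():
            if not np.all(np.isfinite(x)):
                raise PolicyError(f"channel {name!r} contains non-finite samples")


@dataclass
class DiameterMeasurement:
    """B-mode internal aortic diameters (mm) for one subject/condition."""

    dmax_mm: float
    dmin_mm: float
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self):
        if not (self.dmax_mm >= self.dmin_mm > 0):
            raise ParameterError(
                f"require dmax_mm >= dmin_mm > 0, got dmax={self.dmax_mm}, dmin={self.dmin_mm}"
            )


def _parse_metadata(lines: list[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for raw in lines:
        body = raw.lstrip("#").strip()
        if not body or "=" not in body:
            continue
        key, _, value = body.partition("=")
        meta[key.strip()] = value.strip()
    return meta


def read_recording(path, interpolate_nonfinite: bool = False) -> WaveformRecord:
    """Read a delimited-text recording.

    Non-finite samples raise :class:`PolicyError` unless
    ``interpolate_nonfinite`` is set, in which case they are filled by linear
    interpolation and the count is logged.
    """
    text = Path(path).read_text(encoding="utf-8")
    meta_lines = [ln for ln in text.splitlines() if ln.startswith("#")]
    body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("#"))
    meta = _parse_metadata(meta_lines)

    header = body.splitlines()[0] if body.strip() else ""
    sep = "\t" if header.count("\t") > header.count(",") else ","
    try:
        df = pd.read_csv(io.StringIO(body), sep=sep)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"{path}: no data rows")

    fs_hz = float(meta["fs_hz"]) if "fs_hz" in meta else None
    t0_s = 0.0
    if "time_s" in df.columns:
        t = df.pop("time_s").to_numpy(dtype=float)
        dt = np.diff(t)
        if len(dt) == 0:
            raise FormatError(f"{path}: time column has a single row")
        if np.max(np.abs(dt - dt[0])) > 1e-6 * abs(dt[0]):
            raise FormatError(f"{path}: time_s column is not uniform within 1 ppm")
        fs_from_t = 1.0 / dt[0]
        if fs_hz is not None and not math.isclose(fs_hz, fs_from_t, rel_tol=1e-6):
            raise FormatError(
                f"{path}: declared fs_hz={fs_hz} disagrees with time column ({fs_from_t:g})"
            )
        fs_hz = fs_from_t
        t0_s = float(t[0])
    if fs_hz is None:
        raise FormatError(f"{path}: no '# fs_hz=' header and no time_s column")

    channels: dict[str, np.ndarray] = {}
    for name in df.columns:
        x = df[name].to_numpy(dtype=float)
        bad = ~np.isfinite(x)
        if bad.any():
            if not interpolate_nonfinite:
                raise PolicyError(
                    f"{path}: channel {name!r} has {int(bad.sum())} non-finite samples "
                    "(pass interpolate_nonfinite=True to fill linearly)"
                )
            if bad.all():
                raise PolicyError(f"{path}: channel {name!r} has no finite samples")
            idx = np.arange(len(x))
            x = x.copy()
            x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
            logger.info("interpolated %d non-finite samples in channel %s", bad.sum(), name)
        channels[name] = x

    units = {k.split(".", 1)[1]: v for k, v in meta.items() if k.startswith("unit.")}
    record = WaveformRecord(
        fs_hz=fs_hz,
        channels=channels,
        units=units,
        subject_id=meta.get("subject_id", ""),
        condition=meta.get("condition", ""),
        t0_s=t0_s,
    )
    record.validate()
    return record


def write_recording(record: WaveformRecord, path) -> None:
    """Write a record to the text container; lossless to ~1e-16 relative."""
    record.validate()
    lines = [f"# fs_hz={record.fs_hz:.17g}"]
    if record.subject_id:
        lines.append(f"# subject_id={record.subject_id}")
    if record.condition:
        lines.append(f"# condition={record.condition}")
    for name, unit in record.units.items():
        lines.append(f"# unit.{name}={unit}")
    names = list(record.channels)
    lines.append(",".join(names))
    data = np.column_stack([record.channels[n] for n in names])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, data, delimiter=",", fmt="%.17g")


def read_diameters(path) -> list[DiameterMeasurement]:
    """Read a diameter table (CSV with subject_id, condition, dmax_mm, dmin_mm)."""
    df = pd.read_csv(path)
    required = {"subject_id", "condition", "dmax_mm", "dmin_mm"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: diameter table missing columns {sorted(missing)}")
    return [
        DiameterMeasurement(
            dmax_mm=float(row.dmax_mm),
            dmin_mm=float(row.dmin_mm),
            subject_id=str(row.subject_id),
            condition=str(row.condition),
        )
        for row in df.itertuples()
    ]
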