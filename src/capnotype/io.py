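"""Reading and writing multi-channel ventilation waveform recordings.

A recording is stored as a pair of files sharing a base name: ``<base>.csv``
holding a ``time_s`` column plus one column per channel, and ``<base>.json``
(the sidecar) holding sampling rate, units, the ventilation interface and
subject metadata.  The CSV stays purely numeric; all semantics live in the
sidecar.

Channel roles and canonical units
---------------------------------
======== =========================================== ========
role     meaning                                     unit
======== =========================================== ========
P_pat    airway pressure, patient side of leak port  cmH2O
Q_pat    airflow, patient side (inspiration > 0)     ml/s
CO2_pat  CO2 fraction, patient side                  %
Q_vent   airflow, ventilator side (toward patient>0) ml/s
CO2_vent CO2 fraction, ventilator side               %
O2_pat   O2 fraction, patient side (optional)        %
======== =========================================== ========
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError

MANDATORY_CHANNELS = ("P_pat", "Q_pat", "CO2_pat", "Q_vent", "CO2_vent")
OPTIONAL_CHANNELS = ("O2_pat",)

CANONICAL_UNITS = {
    "P_pat": "cmH2O",
    "Q_pat": "ml/s",
    "CO2_pat": "%",
    "Q_vent": "ml/s",
    "CO2_vent": "%",
    "O2_pat": "%",
}

#: accepted unit spellings → multiplicative factor to the canonical unit
_UNIT_FACTORS = {
    "ml/s": {"ml/s": 1.0, "mL/s": 1.0, "l/s": 1000.0, "L/s": 1000.0,
             "l/min": 1000.0 / 60.0, "L/min": 1000.0 / 60.0},
    "cmH2O": {"cmH2O": 1.0, "cmh2o": 1.0},
    "%": {"%": 1.0, "percent": 1.0},
}

#: physiologically admissible CO2 fraction range, percent
CO2_RANGE = (0.0, 15.0)

_TIME_TOLERANCE_PPM = 1.0


@dataclass
class Recording:
    """Synchronized multi-channel waveforms sampled at a fixed rate.

    Samples are treated as uniformly spaced at ``sampling_rate``; the
    on-disk ``time_s`` column is used only to validate regularity.
    """

    sampling_rate: float
    channels: dict[str, np.ndarray]
    interface: str = "invasive"
    subject_id: str = ""
    time_origin: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise SchemaError("sampling_rate must be positive")
        if self.interface not in ("invasive", "noninvasive"):
            raise SchemaError(
                f"interface must be 'invasive' or 'noninvasive', got {self.interface!r}")
        if not self.channels:
            raise SchemaError("recording has no channels")
        lengths = {role: len(s) for role, s in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise SchemaError(f"channel lengths differ: {lengths}")
        for role in MANDATORY_CHANNELS:
            if role not in self.channels:
                raise SchemaError(f"missing mandatory channel {role!r}")
        self.channels = {r: np.asarray(s, dtype=float) for r, s in self.channels.items()}
        for role in ("CO2_pat", "CO2_vent"):
            lo, hi = CO2_RANGE
            series = self.channels[role]
            if series.size and (series.min() < lo - 1e-9 or series.max() > hi + 1e-9):
                raise SchemaError(
                    f"{role} outside [{lo}, {hi}] %: "
                    f"range [{series.min():.4g}, {series.max():.4g}]")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        """Recorded span in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.time_origin + np.arange(self.n_samples) / self.sampling_rate

    def copy(self) -> "Recording":
        return Recording(
            sampling_rate=self.sampling_rate,
            channels={r: s.copy() for r, s in self.channels.items()},
            interface=self.interface,
            subject_id=self.subject_id,
            time_origin=self.time_origin,
            metadata=dict(self.metadata),
        )


def _base_path(path: str | Path) -> Path:
    p = Path(path)
    if p.suffix in (".csv", ".json"):
        p = p.with_suffix("")
    return p


def _convert_unit(role: str, unit: str, series: np.ndarray) -> np.ndarray:
    canonical = CANONICAL_UNITS[role]
    factors = _UNIT_FACTORS[canonical]
    if unit not in factors:
        raise SchemaError(
            f"channel {role!r}: unit {unit!r} is not {canonical!r} or a "
            f"declared conversion ({sorted(factors)})")
    factor = factors[unit]
    return series if factor == 1.0 else series * factor


def read_recording(path: str | Path) -> Recording:
    """Load and validate a recording from ``<base>.csv`` + ``<base>.json``."""
    base = _base_path(path)
    csv_path, sidecar_path = base.with_suffix(".csv"), base.with_suffix(".json")
    if not csv_path.exists():
        raise SchemaError(f"recording CSV not found: {csv_path}")
    if not sidecar_path.exists():
        raise SchemaError(f"sidecar JSON not found: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("sampling_rate", "units", "interface"):
        if key not in meta:
            raise SchemaError(f"sidecar missing {key!r}")
    fs = float(meta["sampling_rate"])
    if fs <= 0:
        raise SchemaError("sampling_rate must be positive")
    table = pd.read_csv(csv_path)
    if "time_s" not in table.columns:
        raise SchemaError("CSV missing 'time_s' column")
    for role in MANDATORY_CHANNELS:
        if role not in table.columns:
            raise SchemaError(f"missing mandatory channel {role!r}")

    times = table["time_s"].to_numpy(dtype=float)
    _validate_time_base(times, fs)

    units = meta["units"]
    channels: dict[str, np.ndarray] = {}
    for role in MANDATORY_CHANNELS + OPTIONAL_CHANNELS:
        if role not in table.columns:
            continue
        unit = units.get(role, CANONICAL_UNITS[role])
        channels[role] = _convert_unit(role, unit, table[role].to_numpy(dtype=float))

    return Recording(
        sampling_rate=fs,
        channels=channels,
        interface=meta["interface"],
        subject_id=str(meta.get("subject_id", "")),
        time_origin=float(times[0]) if len(times) else 0.0,
        metadata=dict(meta.get("metadata", {})),
    )


def _validate_time_base(times: np.ndarray, fs: float) -> None:
    """The time column must be a uniform grid at 1/fs within 1 ppm."""
    if len(times) < 2:
        return
    dt = 1.0 / fs
    ideal = times[0] + np.arange(len(times)) * dt
    span = max(times[-1] - times[0], dt)
    tol = span * _TIME_TOLERANCE_PPM * 1e-6
    worst = np.max(np.abs(times - ideal))
    if worst > tol:
        raise FormatError(
            f"irregular time base: max deviation {worst:.3g} s from a uniform "
            f"{fs} Hz grid exceeds {tol:.3g} s ({_TIME_TOLERANCE_PPM} ppm of span)")


def write_recording(recording: Recording, path: str | Path) -> tuple[Path, Path]:
    """Write ``<base>.csv`` + ``<base>.json``; returns the two paths.

    Floats are written with ``%.9g`` so that a read-back reproduces the
    channels to float32-level text round-trip precision.
    """
    base = _base_path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    csv_path, sidecar_path = base.with_suffix(".csv"), base.with_suffix(".json")

    columns = {"time_s": recording.times}
    for role in MANDATORY_CHANNELS + OPTIONAL_CHANNELS:
        if role in recording.channels:
            columns[role] = recording.channels[role]
    pd.DataFrame(columns).to_csv(csv_path, index=False, float_format="%.9g")

    sidecar = {
        "sampling_rate": recording.sampling_rate,
        "time_origin": recording.time_origin,
        "interface": recording.interface,
        "subject_id": recording.subject_id,
        "units": {r: CANONICAL_UNITS[r] for r in recording.channels},
        "metadata": recording.metadata,
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return csv_path, sidecar_path


def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    """Write a per-cycle table (features, labels, boundaries) as CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.9g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
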