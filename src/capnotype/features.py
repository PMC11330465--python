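"""The 17 per-cycle respiratory parameters.

All integrals are trapezoidal over the phase windows of a cycle
(expiration ``[exp_start, insp_start]``, inspiration
``[insp_start, insp_end]``; consecutive phases share their boundary
sample).  Patient-side tidal volumes are magnitudes of the flow integral;
ventilator-side tidal volumes are signed with flow toward the patient
positive, so the expiratory ventilator-side tidal volume — the net volume
moving *away* from the patient during expiration — is genuinely negative
for cycles whose ventilator-side flow never reverses (type I).

The pressure "surface" parameters are time integrals in cmH2O*s (chart
area on a strip recorder is device-dependent; the time integral is the
underlying quantity).  PEEP is the mean patient-side pressure over the
final 50 ms of expiration.  Breathing frequency is the instantaneous
per-cycle value 60/(Ti+Te).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .errors import DegenerateDataError
from .io import Recording
from .segment import BreathCycle

#: end-expiratory window over which PEEP is averaged, seconds
PEEP_WINDOW = 0.05

#: the 16 numeric feature columns + the interface flag; this column set is
#: the contract with the stats and classifier modules
FEATURE_COLUMNS = [
    "insp_co2_volume",
    "insp_max_pressure_pat",
    "insp_time",
    "exp_time",
    "insp_pressure_integral_pat",
    "exp_pressure_integral_pat",
    "insp_vt_pat",
    "exp_vt_pat",
    "insp_vt_vent",
    "exp_vt_vent",
    "insp_max_flow_pat",
    "exp_max_flow_pat",
    "insp_max_flow_vent",
    "exp_max_flow_vent",
    "breath_frequency",
    "peep",
    "invasive",
]


@dataclass
class CycleFeatures:
    """The 17 parameters of one expiration→inspiration cycle."""

    insp_co2_volume: float        # ml
    insp_max_pressure_pat: float  # cmH2O
    insp_time: float              # s
    exp_time: float               # s
    insp_pressure_integral_pat: float  # cmH2O*s
    exp_pressure_integral_pat: float   # cmH2O*s
    insp_vt_pat: float            # ml
    exp_vt_pat: float             # ml
    insp_vt_vent: float           # ml, signed (toward patient positive)
    exp_vt_vent: float            # ml, signed (away from patient positive)
    insp_max_flow_pat: float      # ml/s
    exp_max_flow_pat: float       # ml/s
    insp_max_flow_vent: float     # ml/s
    exp_max_flow_vent: float      # ml/s
    breath_frequency: float       # breaths/min
    peep: float                   # cmH2O
    invasive: bool

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _trapz(y: np.ndarray, dt: float) -> float:
    return float(np.trapezoid(y, dx=dt))


def insp_co2_volume(flow: np.ndarray, co2_fraction: np.ndarray,
                    cycle: BreathCycle, fs: float) -> float:
    """Inspired CO2 volume (ml) of one cycle.

    Trapezoidal integral of the CO2 flow curve — inspiratory airflow times
    CO2 concentration — over the inspiration window:
    ``∫ max(Q, 0) * (FCO2/100) dt``.
    """
    window = slice(cycle.insp_start, cycle.insp_end + 1)
    q = np.maximum(np.asarray(flow, dtype=float)[window], 0.0)
    c = np.asarray(co2_fraction, dtype=float)[window] / 100.0
    return _trapz(q * c, 1.0 / fs)


def extract_features(recording: Recording, cycle: BreathCycle) -> CycleFeatures:
    """Compute the 17 parameters for one cycle of a recording."""
    n = recording.n_samples
    if not (0 <= cycle.exp_start and cycle.insp_end < n):
        raise DegenerateDataError(
            f"cycle ({cycle.exp_start}, {cycle.insp_start}, {cycle.insp_end}) "
            f"outside recording of {n} samples")
    if cycle.insp_start - cycle.exp_start < 2 or cycle.insp_end - cycle.insp_start < 2:
        raise DegenerateDataError("degenerate phase (< 2 samples)")

    fs = recording.sampling_rate
    dt = 1.0 / fs
    exp_w = slice(cycle.exp_start, cycle.insp_start + 1)
    insp_w = slice(cycle.insp_start, cycle.insp_end + 1)

    p_pat = recording.channels["P_pat"]
    q_pat = recording.channels["Q_pat"]
    q_vent = recording.channels["Q_vent"]
    co2_pat = recording.channels["CO2_pat"]

    ti = (cycle.insp_end - cycle.insp_start) * dt
    te = (cycle.insp_start - cycle.exp_start) * dt

    peep_n = max(1, int(round(PEEP_WINDOW * fs)))
    peep_w = slice(max(cycle.exp_start, cycle.insp_start - peep_n + 1),
                   cycle.insp_start + 1)

    return CycleFeatures(
        insp_co2_volume=insp_co2_volume(q_pat, co2_pat, cycle, fs),
        insp_max_pressure_pat=float(p_pat[insp_w].max()),
        insp_time=ti,
        exp_time=te,
        insp_pressure_integral_pat=_trapz(p_pat[insp_w], dt),
        exp_pressure_integral_pat=_trapz(p_pat[exp_w], dt),
        insp_vt_pat=abs(_trapz(q_pat[insp_w], dt)),
        exp_vt_pat=abs(_trapz(q_pat[exp_w], dt)),
        insp_vt_vent=_trapz(q_vent[insp_w], dt),
        exp_vt_vent=_trapz(-q_vent[exp_w], dt),
        insp_max_flow_pat=float(np.abs(q_pat[insp_w]).max()),
        exp_max_flow_pat=float(np.abs(q_pat[exp_w]).max()),
        insp_max_flow_vent=float(np.abs(q_vent[insp_w]).max()),
        exp_max_flow_vent=float(np.abs(q_vent[exp_w]).max()),
        breath_frequency=60.0 / (ti + te),
        peep=float(p_pat[peep_w].mean()),
        invasive=recording.interface == "invasive",
    )


def extract_feature_table(recording: Recording,
                          cycles: list[BreathCycle]) -> pd.DataFrame:
    """Feature table with one row per analyzable cycle.

    Cycles with degenerate phases are skipped; ``cycle_id`` indexes into
    the input cycle list so features, labels and ground truth stay joinable.
    """
    rows = []
    for cid, cycle in enumerate(cycles):
        try:
            feats = extract_features(recording, cycle)
        except DegenerateDataError:
            continue
        row = {"cycle_id": cid}
        row.update(feats.as_dict())
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["cycle_id"] + FEATURE_COLUMNS)
    frame["invasive"] = frame["invasive"].astype(int)
    return frame
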