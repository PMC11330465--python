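"""Reference (CO2-based) classification of breath cycles.

The ventilator-side CO2 trace of a delay-compensated recording decides the
cycle type:

* **type I** — CO2 never appears on the ventilator side during expiration;
* **type II** — CO2 appears but is fully flushed out of the leak port
  before the next inspiration starts;
* **type III** — CO2 is still present at inspiration onset and is
  re-inhaled (rebreathing).

"Zero" and "positive" are operationalized by two thresholds:
``zero_epsilon`` (below which a measured CO2 value counts as zero) and
``borderline_band``.  Onset values between the two are *borderline* and
excluded from analysis, mirroring a visual-classification protocol that
only keeps cycles attributable to one type beyond dispute; the type III
boundary coincides with the 0.1 % inspired-CO2 level conventionally taken
as significant rebreathing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InvalidParameterError
from .features import insp_co2_volume
from .io import Recording
from .segment import BreathCycle


@dataclass
class LabelerConfig:
    """Thresholds (in %CO2) of the rule labeler.

    ``fico2_threshold`` is the mean inspired CO2 fraction above which a
    cycle is flagged as significant rebreathing.
    """

    zero_epsilon: float = 0.05
    borderline_band: float = 0.10
    fico2_threshold: float = 0.10

    def __post_init__(self) -> None:
        if not 0 <= self.zero_epsilon < self.borderline_band:
            raise InvalidParameterError(
                "require 0 <= zero_epsilon < borderline_band")
        if self.fico2_threshold <= 0:
            raise InvalidParameterError("fico2_threshold must be positive")


@dataclass
class CycleLabel:
    """Rule-labeler verdict for one cycle."""

    cycle_id: int
    type: str  # "I" | "II" | "III" | "borderline" | "excluded"
    vent_co2_at_insp_onset: float
    max_vent_co2_during_exp: float
    flow_reversal_detected: bool
    significant_rebreathing: bool
    excluded_reason: str = ""


def detect_flow_reversal(recording: Recording, cycle: BreathCycle,
                         hysteresis: float = 10.0) -> tuple[bool, int | None]:
    """Mid-expiration sign change of the ventilator-side flow.

    The type II/III signature: early in expiration the patient's
    expiratory flow exceeds the EPAP bias flow and the ventilator-side
    flow points away from the patient; as the expiratory flow decays below
    the bias flow the direction reverses.  Returns ``(flag, sample)`` with
    the first sign-change sample, judged on excursions beyond
    ``hysteresis`` (ml/s) to ignore noise around zero.
    """
    window = recording.channels["Q_vent"][cycle.exp_start:cycle.insp_start]
    signs = np.sign(window) * (np.abs(window) > hysteresis)
    nonzero = np.flatnonzero(signs)
    if nonzero.size == 0:
        return False, None
    s = signs[nonzero]
    change = np.flatnonzero(s[1:] != s[:-1])
    if change.size == 0:
        return False, None
    return True, int(cycle.exp_start + nonzero[change[0] + 1])


def classify_cycle(recording: Recording, cycle: BreathCycle,
                   config: LabelerConfig | None = None,
                   cycle_id: int = 0) -> CycleLabel:
    """Assign type I/II/III (or borderline) from ventilator-side CO2.

    The recording must already be delay-compensated
    (:func:`capnotype.preprocess.align_capnogram`).  The inspiration-onset
    value is read at the single boundary sample.
    """
    config = config or LabelerConfig()
    n = recording.n_samples
    if not (0 <= cycle.exp_start and cycle.insp_end < n):
        raise DegenerateDataError("cycle outside recording")
    co2_vent = recording.channels["CO2_vent"]
    max_exp = float(co2_vent[cycle.exp_start:cycle.insp_start].max())
    onset = float(co2_vent[cycle.insp_start])

    if onset > config.borderline_band:
        cycle_type = "III"
    elif onset > config.zero_epsilon:
        cycle_type = "borderline"
    elif max_exp > config.zero_epsilon:
        cycle_type = "II"
    else:
        cycle_type = "I"

    reversal, _ = detect_flow_reversal(recording, cycle)

    fs = recording.sampling_rate
    insp_vol = abs(np.trapezoid(
        recording.channels["Q_pat"][cycle.insp_start:cycle.insp_end + 1],
        dx=1.0 / fs))
    co2_vol = insp_co2_volume(recording.channels["Q_pat"],
                              recording.channels["CO2_pat"], cycle, fs)
    mean_fico2 = 100.0 * co2_vol / insp_vol if insp_vol > 0 else 0.0

    return CycleLabel(
        cycle_id=cycle_id,
        type=cycle_type,
        vent_co2_at_insp_onset=onset,
        max_vent_co2_during_exp=max_exp,
        flow_reversal_detected=reversal,
        significant_rebreathing=bool(mean_fico2 > config.fico2_threshold),
        excluded_reason="borderline onset CO2" if cycle_type == "borderline" else "",
    )


def label_recording(recording: Recording, cycles: list[BreathCycle],
                    config: LabelerConfig | None = None) -> pd.DataFrame:
    """Labels CSV table: one row per cycle."""
    rows = []
    for cid, cycle in enumerate(cycles):
        lab = classify_cycle(recording, cycle, config, cycle_id=cid)
        rows.append({
            "cycle_id": lab.cycle_id,
            "type": lab.type,
            "onset_co2": lab.vent_co2_at_insp_onset,
            "max_exp_co2": lab.max_vent_co2_during_exp,
            "flow_reversal": int(lab.flow_reversal_detected),
            "significant_rebreathing": int(lab.significant_rebreathing),
            "excluded_reason": lab.excluded_reason,
        })
    return pd.DataFrame(rows)


def summarize_labels(labels) -> pd.DataFrame:
    """Counts and percentages per type over analyzable cycles.

    ``labels`` is a sequence of type strings, a labels DataFrame (with a
    ``type`` column), or a mapping type → count.  Borderline and excluded
    cycles are reported separately and excluded from the percentages.
    Percentages are truncated (not rounded) to one decimal so the shares
    never sum above 100 %.
    """
    if isinstance(labels, pd.DataFrame):
        counts = labels["type"].value_counts().to_dict()
    elif isinstance(labels, dict):
        counts = dict(labels)
    else:
        counts = pd.Series(list(labels)).value_counts().to_dict()

    kept = {t: int(counts.get(t, 0)) for t in ("I", "II", "III")}
    total = sum(kept.values())
    if total == 0:
        raise DegenerateDataError("no analyzable (non-borderline) cycles")
    excluded = sum(int(v) for t, v in counts.items() if t not in ("I", "II", "III"))
    rows = []
    for t in ("I", "II", "III"):
        pct = np.floor(1000.0 * kept[t] / total + 1e-9) / 10.0
        rows.append({"type": t, "count": kept[t], "percent": pct})
    rows.append({"type": "excluded", "count": excluded, "percent": np.nan})
    return pd.DataFrame(rows)
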