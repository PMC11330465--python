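"""Breath segmentation from patient-side flow zero-crossings.

Inspiration and expiration boundaries are the points where patient-side
flow crosses zero (inspiratory flow positive, expiratory negative).  The
analysis unit is an expiration followed by the next inspiration, because
rebreathing during an inspiration is determined by the CO2 left in the
ventilator limb by the preceding expiration.

A hysteresis band and a minimum phase duration make the crossing detector
robust to sensor noise near zero flow: a crossing is only accepted once
the flow has moved beyond ``hysteresis`` in the new direction, and
crossings closer than ``min_phase_duration`` to the previously accepted
one are suppressed (short blips never split a phase).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError


@dataclass
class SegmentationConfig:
    """Noise-robustness knobs for the zero-crossing detector.

    Defaults (10 ml/s band, 0.2 s minimum phase) never clip adult
    breathing at rates up to 60/min while rejecting baseline flow noise of
    a few ml/s.
    """

    hysteresis: float = 10.0
    min_phase_duration: float = 0.2

    def __post_init__(self) -> None:
        if self.hysteresis < 0:
            raise InvalidParameterError("hysteresis must be >= 0")
        if self.min_phase_duration <= 0:
            raise InvalidParameterError("min_phase_duration must be positive")


@dataclass
class BreathCycle:
    """One expiration→inspiration cycle delimited by flow zero-crossings.

    Half-open phases: expiration occupies ``[exp_start, insp_start)`` and
    inspiration ``[insp_start, insp_end)``; the crossing sample is the
    first sample past zero in the new direction.
    """

    exp_start: int
    insp_start: int
    insp_end: int
    complete: bool = True

    def __post_init__(self) -> None:
        if not self.exp_start < self.insp_start < self.insp_end:
            raise InvalidParameterError(
                f"cycle indices must be increasing: "
                f"({self.exp_start}, {self.insp_start}, {self.insp_end})")


def detect_crossings(flow: np.ndarray, fs: float,
                     config: SegmentationConfig | None = None
                     ) -> list[tuple[int, int]]:
    """Zero-crossings of a flow series as ``(sample, direction)`` pairs.

    ``direction`` is +1 for an upward crossing (inspiration start) and -1
    for a downward crossing (expiration start).  Directions alternate.  A
    series that starts inside a phase sets the initial sign without
    emitting a crossing; a series that starts at (or below the hysteresis
    band around) zero emits its first crossing at the first sample past
    zero in the emerging direction.  All-zero or never-crossing flow
    returns an empty list.
    """
    config = config or SegmentationConfig()
    flow = np.asarray(flow, dtype=float)
    if flow.size < 2:
        return []
    hyst = config.hysteresis
    min_gap = int(round(config.min_phase_duration * fs))

    crossings: list[tuple[int, int]] = []
    phase_sign = 0
    candidate: tuple[int, int] | None = None  # (index, sign) pending confirmation

    for i, v in enumerate(flow):
        if phase_sign == 0 and candidate is None:
            if v > 0:
                candidate = (i, 1)
            elif v < 0:
                candidate = (i, -1)
            continue
        if candidate is not None:
            ci, cs = candidate
            if v * cs > hyst:
                # confirmed beyond the hysteresis band
                if phase_sign == 0:
                    # initial emergence: a crossing only if the series
                    # started at zero (i.e. the run began after sample 0)
                    if ci > 0:
                        crossings.append((ci, cs))
                    phase_sign = cs
                elif crossings and ci - crossings[-1][0] < min_gap:
                    pass  # too close to the previous accepted crossing: suppressed
                else:
                    crossings.append((ci, cs))
                    phase_sign = cs
                candidate = None
            elif v * cs <= 0 and phase_sign != 0:
                candidate = None  # fell back before confirmation
            elif v * cs <= 0 and phase_sign == 0:
                candidate = (i, -cs) if v * cs < 0 else None
        else:
            if v * phase_sign < 0:
                candidate = (i, -phase_sign)
    return crossings


def build_cycles(crossings: list[tuple[int, int]],
                 series_length: int) -> list[BreathCycle]:
    """Pair alternating crossings into expiration→inspiration cycles.

    Each downward crossing (expiration start) is paired with the next
    upward crossing (inspiration start) and the following downward
    crossing (inspiration end).  Leading and trailing partial phases are
    dropped; consecutive cycles share their boundary sample.
    """
    if len(crossings) < 3:
        return []
    for (a, da), (b, db) in zip(crossings, crossings[1:]):
        if da == db or not a < b:
            raise InvalidParameterError("crossings must alternate and increase")
    cycles = []
    for j in range(len(crossings) - 2):
        idx, direction = crossings[j]
        if direction == -1:
            cycles.append(BreathCycle(
                exp_start=idx,
                insp_start=crossings[j + 1][0],
                insp_end=crossings[j + 2][0],
            ))
    return cycles


def segment_recording(recording, config: SegmentationConfig | None = None
                      ) -> list[BreathCycle]:
    """Convenience: detect crossings on Q_pat and assemble cycles."""
    crossings = detect_crossings(recording.channels["Q_pat"],
                                 recording.sampling_rate, config)
    return build_cycles(crossings, recording.n_samples)


def cycles_frame(cycles: list[BreathCycle], fs: float):
    """Per-cycle boundary table (cycle_id, exp_start_s, insp_start_s, insp_end_s)."""
    import pandas as pd

    return pd.DataFrame({
        "cycle_id": np.arange(len(cycles)),
        "exp_start_s": [c.exp_start / fs for c in cycles],
        "insp_start_s": [c.insp_start / fs for c in cycles],
        "insp_end_s": [c.insp_end / fs for c in cycles],
        "exp_start": [c.exp_start for c in cycles],
        "insp_start": [c.insp_start for c in cycles],
        "insp_end": [c.insp_end for c in cycles],
    })
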