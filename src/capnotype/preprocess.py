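"""Phasing of sidestream CO2 channels with the pressure/flow channels.

A sidestream capnometer aspirates gas through a sampling line, so both CO2
channels lag pressure and flow by ``60 * line_volume / pump_flow`` seconds.
:func:`align_capnogram` advances the CO2 channels by that delay, quantized
to whole samples (block shift, no sub-sample interpolation: the delay
uncertainty of a real sampling line exceeds one sample at typical rates,
and a block shift is exactly invertible).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import InvalidParameterError
from .io import Recording
from .simulate import compute_sampling_delay


@dataclass
class AlignmentConfig:
    """How to undo the sidestream transport delay.

    Either give ``delay`` (s) explicitly, or give the sampling-line
    ``sample_line_volume`` (ml) and ``pump_flow`` (ml/min) and the delay is
    computed as ``60 * volume / flow``.  ``smoothing_window`` (s) applies a
    centered moving average to the CO2 channels after shifting (0 = off).
    """

    delay: float | None = None
    sample_line_volume: float | None = None
    pump_flow: float | None = None
    smoothing_window: float = 0.0

    def __post_init__(self) -> None:
        if self.smoothing_window < 0:
            raise InvalidParameterError("smoothing_window must be >= 0")
        if self.delay is not None and self.delay < 0:
            raise InvalidParameterError("delay must be >= 0")

    def resolve_delay(self) -> float:
        if self.delay is not None:
            return self.delay
        if self.sample_line_volume is None or self.pump_flow is None:
            raise InvalidParameterError(
                "give either delay or (sample_line_volume, pump_flow)")
        return compute_sampling_delay(self.sample_line_volume, self.pump_flow)


def align_capnogram(recording: Recording, config: AlignmentConfig) -> Recording:
    """Advance both CO2 channels by the sidestream delay.

    The shift is ``round(delay * fs)`` samples earlier in time; the
    trailing gap is padded with the last value (edge cycles are discarded
    downstream anyway).  A provenance note is recorded in the metadata.
    """
    delay = config.resolve_delay()
    if delay >= recording.duration:
        raise InvalidParameterError(
            f"delay {delay} s is not smaller than the recording duration "
            f"{recording.duration:.3g} s")
    fs = recording.sampling_rate
    shift = int(round(delay * fs))
    out = recording.copy()
    for role in ("CO2_pat", "CO2_vent"):
        if role not in out.channels:
            continue
        x = out.channels[role]
        if shift > 0:
            x = np.concatenate([x[shift:], np.full(shift, x[-1])])
        if config.smoothing_window > 0:
            x = smooth(x, config.smoothing_window, fs)
        out.channels[role] = x
    out.metadata["capnogram_alignment"] = {
        "delay_s": delay, "shift_samples": shift,
        "smoothing_window_s": config.smoothing_window,
    }
    return out


def smooth(series: np.ndarray, window: float, fs: float) -> np.ndarray:
    """Centered moving average over ``window`` seconds; 0 is the identity.

    Edges are handled by nearest-value padding so the output length equals
    the input length.
    """
    if window < 0:
        raise InvalidParameterError("window must be >= 0")
    series = np.asarray(series, dtype=float)
    n = int(round(window * fs))
    if n <= 1:
        return series.copy()
    return uniform_filter1d(series, size=n, mode="nearest")
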