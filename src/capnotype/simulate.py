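"""Physical simulator of CO2 movement in a single-limb BiPAP leak circuit.

The model reproduces the three CO2-movement regimes seen at the intentional
leak port of a single-limb bilevel circuit:

* **type I** — peak patient expiratory flow never exceeds the EPAP bias flow
  through the leak, so exhaled CO2 is flushed straight out of the port and
  never enters the ventilator limb;
* **type II** — early-expiratory flow exceeds the bias flow, ventilator-side
  flow reverses and a CO2 bolus is pushed into the ventilator limb, but the
  bias flow washes it back out of the port before the next inspiration;
* **type III** — the bolus is not fully washed out before inspiration starts
  and part of it is advected back to the patient: CO2 rebreathing.

Circuit model
-------------
The leak port is a volumeless junction (node).  Signed flows (positive
toward the patient): patient flow ``Q_pat``, ventilator-limb flow
``Q_vent``, and leak flow ``Q_leak = k * P`` out of the port, with ``k`` a
linear leak conductance.  Mass balance at the node each step:
``Q_vent = Q_pat + Q_leak``.  The ventilator is an ideal pressure source
alternating IPAP/EPAP with fixed timing plus per-cycle log-normal jitter;
patient inspiratory and expiratory flows are decaying exponentials scaled
to the tidal volume.  The ventilator limb is discretized into N well-mixed
cells in series with upwind advective exchange only (no diffusion term;
the scheme's numerical diffusion stands in for the small physical mixing).
The patient-side CO2 sensor is modelled as a small well-mixed volume at
the port (the patient-limb apparatus dead space) flushed by ``Q_pat``,
which is what gives type I/II cycles their small but nonzero inspired-CO2
volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InvalidParameterError
from .io import Recording

#: time constant of the rising-exponential expiratory capnogram, seconds
CAPNOGRAM_TAU = 0.15

#: default sampling rate of simulated recordings, Hz
DEFAULT_SAMPLING_RATE = 200.0

#: internal volumes (ml) of a typical sidestream gas-sampling interface kit:
#: the sample line itself, the membrane dryer, and miscellaneous
#: tubing/junctions.  They sum to the 4.0 ml used as the default
#: sample-line volume.
SAMPLING_KIT_VOLUMES_ML = {
    "sample_line": 3.336,
    "dryer": 0.386,
    "tubing_junctions": 0.278,
}

DEFAULT_NOISE_SD = {
    "P_pat": 0.2,     # cmH2O
    "Q_pat": 5.0,     # ml/s
    "Q_vent": 5.0,    # ml/s
    "CO2_pat": 0.02,  # %CO2
    "CO2_vent": 0.02, # %CO2
}


def compute_sampling_delay(line_volume: float, pump_flow: float) -> float:
    """Transport delay of a sidestream sampling line, in seconds.

    ``delay = 60 s/min * line_volume [ml] / pump_flow [ml/min]`` — the time
    the aspirated gas needs to travel the internal volume of the line at
    the pump's flow rate.

    Parameters
    ----------
    line_volume : internal volume of the sampling line, ml (>= 0).
    pump_flow : aspiration pump flow, ml/min (> 0).
    """
    if pump_flow <= 0:
        raise InvalidParameterError(f"pump_flow must be positive, got {pump_flow}")
    if line_volume < 0:
        raise InvalidParameterError(f"line_volume must be >= 0, got {line_volume}")
    return 60.0 * line_volume / pump_flow


@dataclass
class CircuitConfig:
    """Geometry and pneumatics of the leak circuit and capnometer.

    Parameters
    ----------
    epap, ipap : expiratory / inspiratory positive airway pressure, cmH2O.
    leak_conductance : linear leak-port conductance k in Q = k*P, ml/s per
        cmH2O.  100 gives ~24 L/min bias flow at EPAP 4 cmH2O, in the range
        of a typical intentional exhalation port.
    vent_limb_volume : internal volume of the ventilator-side limb, ml.
    vent_limb_cells : number of well-mixed cells discretizing the limb.
    pat_limb_volume : apparatus dead space between the CO2 sensor and the
        patient connector, ml.
    sample_line_volume, pump_flow : sidestream capnometer sampling line
        volume (ml) and pump flow (ml/min); together they set the
        capnometer transport delay.
    capnometer_smoothing_tau : first-order response time of the capnometer
        cell, s (0 disables smoothing).
    pressure_tau : rise/fall time constant of the pressure source, s.
    """

    epap: float = 4.0
    ipap: float = 15.0
    leak_conductance: float = 100.0
    vent_limb_volume: float = 500.0
    vent_limb_cells: int = 20
    pat_limb_volume: float = 10.0
    sample_line_volume: float = 4.0
    pump_flow: float = 150.0
    capnometer_smoothing_tau: float = 0.0
    pressure_tau: float = 0.05

    def __post_init__(self) -> None:
        if not self.ipap > self.epap > 0:
            raise InvalidParameterError(
                f"require ipap > epap > 0, got ipap={self.ipap}, epap={self.epap}")
        if self.leak_conductance <= 0:
            raise InvalidParameterError("leak_conductance must be positive")
        if self.vent_limb_cells < 1:
            raise InvalidParameterError("vent_limb_cells must be >= 1")
        for name in ("vent_limb_volume", "pat_limb_volume", "sample_line_volume"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.pump_flow <= 0:
            raise InvalidParameterError("pump_flow must be positive")
        if self.leak_conductance * self.epap <= 0:
            raise InvalidParameterError(
                "leak flow at EPAP is zero: the circuit cannot vent")


@dataclass
class PatientConfig:
    """Breathing pattern of the simulated patient.

    ``exp_flow_tau`` is the decay constant of the exponential expiratory
    flow; together with the tidal volume it sets the peak expiratory flow
    whose relation to the EPAP bias flow decides whether CO2 enters the
    ventilator limb.  ``transition_time`` is the raised-cosine ramp at each
    phase boundary that keeps flow continuous (zero at every boundary), as
    in real breathing.  ``cycle_jitter_cv`` is the coefficient of variation
    of the per-cycle log-normal duration jitter.
    """

    respiratory_rate: float = 20.0
    ti_fraction: float = 0.4
    tidal_volume: float = 500.0
    fetco2: float = 5.0
    exp_flow_tau: float = 0.4
    transition_time: float = 0.05
    cycle_jitter_cv: float = 0.05
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.respiratory_rate <= 0:
            raise InvalidParameterError("respiratory_rate must be positive")
        if not 0 < self.ti_fraction < 1:
            raise InvalidParameterError("ti_fraction must be in (0, 1)")
        if not 0 <= self.fetco2 <= 15:
            raise InvalidParameterError("fetco2 must be in [0, 15] %")
        if self.tidal_volume < 0:
            raise InvalidParameterError("tidal_volume must be >= 0")
        if self.exp_flow_tau <= 0:
            raise InvalidParameterError("exp_flow_tau must be positive")
        if self.transition_time < 0:
            raise InvalidParameterError("transition_time must be >= 0")
        if self.cycle_jitter_cv < 0:
            raise InvalidParameterError("cycle_jitter_cv must be >= 0")


@dataclass
class SimulatedRecording:
    """A simulated recording plus the simulator's per-cycle ground truth.

    ``truth_labels`` holds one ``(cycle_index, type)`` pair per complete
    expiration→inspiration cycle; ``true_rebreathed_co2`` is the CO2 volume
    (ml) advected from the ventilator limb to the patient during the
    inspiration of each cycle — exactly 0 for types I and II in the truth
    model, positive for type III.  ``true_boundaries`` are the sample
    indices of every phase transition.  ``mass_balance`` carries per-cycle
    exhaled / vented / re-inhaled CO2 volumes and circuit content for
    conservation checks.
    """

    recording: Recording
    truth_labels: list[tuple[int, str]]
    true_rebreathed_co2: np.ndarray
    true_boundaries: np.ndarray
    mass_balance: pd.DataFrame

    def truth_frame(self) -> pd.DataFrame:
        """Ground truth as a table (cycle_id, type, rebreathed_ml, boundaries)."""
        rows = []
        for (idx, label), reb in zip(self.truth_labels, self.true_rebreathed_co2):
            mb = self.mass_balance.iloc[idx]
            rows.append({
                "cycle_id": idx,
                "type": label,
                "rebreathed_ml": reb,
                "exp_start": int(mb["exp_start"]),
                "insp_start": int(mb["insp_start"]),
                "insp_end": int(mb["insp_end"]),
            })
        return pd.DataFrame(rows)


def _phase_schedule(patient: PatientConfig, duration: float,
                    rng: np.random.Generator) -> list[tuple[float, float, str]]:
    """Alternating (start, end, kind) phases covering ``duration``.

    The train starts with an inspiration so the first analyzable
    expiration→inspiration cycle begins at the first expiration.
    """
    mean_period = 60.0 / patient.respiratory_rate
    cv = patient.cycle_jitter_cv
    sigma = math.sqrt(math.log1p(cv * cv)) if cv > 0 else 0.0
    phases: list[tuple[float, float, str]] = []
    t = 0.0
    while t < duration:
        jitter = math.exp(rng.normal(-0.5 * sigma * sigma, sigma)) if sigma else 1.0
        period = mean_period * jitter
        ti = patient.ti_fraction * period
        te = period - ti
        phases.append((t, t + ti, "insp"))
        phases.append((t + ti, t + ti + te, "exp"))
        t += period
    return phases


def _flow_envelope(tau_phase: np.ndarray, span: float, tr: float) -> np.ndarray:
    """Raised-cosine ramp from/to zero over ``tr`` s at both phase ends."""
    env = np.ones_like(tau_phase)
    if tr <= 0:
        return env
    rise = tau_phase < tr
    env[rise] = np.sin(0.5 * np.pi * tau_phase[rise] / tr) ** 2
    fall = tau_phase > span - tr
    env[fall] *= np.sin(0.5 * np.pi * (span - tau_phase[fall]) / tr) ** 2
    return env


def _phase_flow(tau_phase: np.ndarray, span: float, tau_decay: float,
                volume: float, tr: float) -> np.ndarray:
    """Flow magnitude A * env(t) * exp(-t/tau) integrating to ``volume``.

    The amplitude is fixed by sampling-rate-independent quadrature so the
    waveform (and the delivered tidal volume) does not depend on the
    discretization.
    """
    from scipy.integrate import quad

    def shape(t):
        e = math.exp(-t / tau_decay)
        if tr > 0:
            if t < tr:
                e *= math.sin(0.5 * math.pi * t / tr) ** 2
            if t > span - tr:
                e *= math.sin(0.5 * math.pi * (span - t) / tr) ** 2
        return e

    pts = sorted({0.0, min(tr, span), max(span - tr, 0.0), span})
    integral = 0.0
    for a, b in zip(pts, pts[1:]):
        integral += quad(shape, a, b, limit=100)[0]
    amp = volume / integral if integral > 0 else 0.0
    return amp * _flow_envelope(tau_phase, span, tr) * np.exp(-tau_phase / tau_decay)


def simulate_recording(
    patient: PatientConfig,
    circuit: CircuitConfig,
    duration: float = 60.0,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    interface: str = "invasive",
    truth_epsilon: float = 0.05,
    subject_id: str = "sim",
) -> SimulatedRecording:
    """Simulate a BiPAP leak-circuit recording with per-cycle ground truth.

    Parameters
    ----------
    duration : recorded span, s; must cover at least two full breaths.
    truth_epsilon : %CO2 below which the ventilator-limb CO2 state counts
        as zero when deriving ground-truth labels (the same operational
        threshold the rule labeler applies to measured signals).

    Returns
    -------
    SimulatedRecording with noiseless dynamics, per-cycle truth labels
    derived from the noiseless ventilator-limb state, and channel noise
    added per ``patient.noise_sd``.
    """
    if duration < 2 * 60.0 / patient.respiratory_rate:
        raise InvalidParameterError(
            "duration must cover at least two full breathing cycles")
    rng = np.random.default_rng(patient.seed)
    fs = float(sampling_rate)
    dt = 1.0 / fs
    n = int(round(duration * fs))

    phases = _phase_schedule(patient, duration, rng)
    starts = np.array([p[0] for p in phases])
    boundary_idx = np.minimum(np.ceil(starts * fs - 1e-9).astype(int), n)
    phase_of_sample = np.searchsorted(starts, np.arange(n) / fs, side="right") - 1

    # --- pressure and flow waveforms -------------------------------------
    p_target = np.where([phases[k][2] == "insp" for k in phase_of_sample],
                        circuit.ipap, circuit.epap)
    pressure = np.empty(n)
    decay_p = math.exp(-dt / circuit.pressure_tau)
    prev = circuit.epap
    for i in range(n):
        prev = p_target[i] + (prev - p_target[i]) * decay_p
        pressure[i] = prev

    q_pat = np.empty(n)
    for k, (t0, t1, kind) in enumerate(phases):
        sel = phase_of_sample == k
        if not sel.any():
            continue
        tau_phase = (np.arange(n)[sel] / fs) - t0
        span = t1 - t0
        tr = min(patient.transition_time, 0.25 * span)
        if kind == "insp":
            q_pat[sel] = _phase_flow(tau_phase, span, span / 3.0,
                                     patient.tidal_volume, tr)
        else:
            q_pat[sel] = -_phase_flow(tau_phase, span, patient.exp_flow_tau,
                                      patient.tidal_volume, tr)

    q_leak = circuit.leak_conductance * pressure
    q_vent = q_pat + q_leak

    # --- CO2 transport ---------------------------------------------------
    n_cells = circuit.vent_limb_cells
    v_cell = circuit.vent_limb_volume / n_cells
    cells = np.zeros(n_cells)
    co2_vent = np.empty(n)
    co2_pat = np.empty(n)
    sensor = 0.0  # patient-side sensor mixing volume concentration, %
    v_mix = circuit.pat_limb_volume

    exhaled = np.zeros(n)    # cumulative CO2 ml past the patient sensor plane
    vented = np.zeros(n)     # cumulative CO2 ml out of the leak port
    reinhaled = np.zeros(n)  # cumulative CO2 ml advected back to the patient
    limb_content = np.empty(n)  # instantaneous CO2 ml held in the circuit
    to_patient_step = np.zeros(n)

    acc_exh = acc_vent = acc_reinh = acc_beyond = 0.0
    for i in range(n):
        k = phase_of_sample[i]
        t0, t1, kind = phases[k]
        tau_phase = i / fs - t0
        qv = q_vent[i]
        moved = abs(qv) * dt

        if kind == "exp":
            c_expired = patient.fetco2 * -math.expm1(-tau_phase / CAPNOGRAM_TAU)
            inflow_pat = -q_pat[i] * dt  # gas volume from patient into node
            acc_exh += inflow_pat * c_expired / 100.0
            if qv >= 0:
                # limb feeds the node; everything exits through the leak
                out_co2 = _advect(cells, v_cell, moved, toward_node=True,
                                  boundary=0.0)
                acc_vent += inflow_pat * c_expired / 100.0 + out_co2
            else:
                # node feeds the limb at the expired concentration
                acc_beyond += _advect(cells, v_cell, moved, toward_node=False,
                                      boundary=c_expired)
                acc_vent += q_leak[i] * dt * c_expired / 100.0
            c_sensor_in = c_expired
            flush = inflow_pat
        else:  # inspiration: qv = q_pat + q_leak > 0, limb feeds the node
            out_co2 = _advect(cells, v_cell, moved, toward_node=True,
                              boundary=0.0)
            c_node = out_co2 * 100.0 / moved if moved > 0 else 0.0
            to_pat = out_co2 * (q_pat[i] / qv) if qv > 0 else 0.0
            acc_reinh += to_pat
            acc_vent += out_co2 - to_pat
            to_patient_step[i] = to_pat
            c_sensor_in = c_node
            flush = q_pat[i] * dt

        if v_mix > 0:
            sensor = c_sensor_in + (sensor - c_sensor_in) * math.exp(-flush / v_mix)
        else:
            sensor = c_sensor_in

        co2_vent[i] = cells[0]
        co2_pat[i] = sensor
        exhaled[i], vented[i], reinhaled[i] = acc_exh, acc_vent, acc_reinh
        # circuit CO2 content: the modeled limb cells plus gas displaced
        # beyond the limb into the ventilator-side tubing
        limb_content[i] = cells.sum() * v_cell / 100.0 + acc_beyond

    # --- ground truth per expiration→inspiration cycle -------------------
    labels: list[tuple[int, str]] = []
    rebreathed: list[float] = []
    mb_rows = []
    cycle_idx = 0
    for k, (t0, t1, kind) in enumerate(phases):
        if kind != "exp" or k + 1 >= len(phases):
            continue
        if phases[k + 1][1] > duration + 1e-9:
            continue  # following inspiration not fully recorded
        exp_start = int(boundary_idx[k])
        insp_start = int(boundary_idx[k + 1])
        insp_end = int(boundary_idx[k + 2]) if k + 2 < len(phases) else n
        if insp_start >= n or insp_end <= insp_start:
            continue
        exp_sl = slice(exp_start, insp_start)
        insp_sl = slice(insp_start, insp_end)
        max_c1 = co2_vent[exp_sl].max() if insp_start > exp_start else 0.0
        onset = co2_vent[insp_start - 1] if insp_start > 0 else 0.0
        if onset > truth_epsilon:
            label = "III"
            reb = float(to_patient_step[insp_sl].sum())
        elif max_c1 > truth_epsilon:
            label, reb = "II", 0.0
        else:
            label, reb = "I", 0.0
        labels.append((cycle_idx, label))
        rebreathed.append(reb)
        start0 = max(exp_start - 1, 0)
        mb_rows.append({
            "cycle_id": cycle_idx,
            "exp_start": exp_start, "insp_start": insp_start, "insp_end": insp_end,
            "exhaled_ml": exhaled[insp_end - 1] - exhaled[start0],
            "vented_ml": vented[insp_end - 1] - vented[start0],
            "reinhaled_ml": reinhaled[insp_end - 1] - reinhaled[start0],
            "content_start_ml": limb_content[start0],
            "content_end_ml": limb_content[insp_end - 1],
            "onset_co2": onset,
            "max_exp_co2": max_c1,
        })
        cycle_idx += 1

    # --- assemble channels, add measurement noise ------------------------
    channels = {
        "P_pat": pressure, "Q_pat": q_pat, "CO2_pat": co2_pat,
        "Q_vent": q_vent, "CO2_vent": co2_vent,
    }
    noisy = {}
    for role, series in channels.items():
        sd = float(patient.noise_sd.get(role, 0.0)) if patient.noise_sd else 0.0
        out = series + rng.normal(0.0, sd, size=n) if sd > 0 else series.copy()
        if role.startswith("CO2"):
            np.clip(out, 0.0, 15.0, out=out)
        noisy[role] = out

    recording = Recording(
        sampling_rate=fs, channels=noisy, interface=interface,
        subject_id=subject_id,
        metadata={"seed": patient.seed, "simulated": True,
                  "truth_epsilon": truth_epsilon},
    )
    boundaries = boundary_idx[(boundary_idx > 0) & (boundary_idx < n)]
    return SimulatedRecording(
        recording=recording,
        truth_labels=labels,
        true_rebreathed_co2=np.asarray(rebreathed),
        true_boundaries=np.asarray(boundaries, dtype=int),
        mass_balance=pd.DataFrame(mb_rows),
    )


def _advect(cells: np.ndarray, v_cell: float, volume: float,
            toward_node: bool, boundary: float) -> float:
    """Upwind plug-flow advection of ``volume`` ml through the cell chain.

    ``toward_node=True`` moves gas from the ventilator end toward the leak
    port (cell 0) with fresh gas entering the far end, and returns the CO2
    volume (ml) delivered to the node.  ``toward_node=False`` pushes node
    gas at concentration ``boundary`` (%) into cell 0 and returns the CO2
    volume displaced past the ventilator end of the modeled limb (it stays
    in the circuit tubing beyond the limb and is not assumed to return).
    Sub-steps keep each fractional exchange below one cell volume so the
    scheme is conservative and stable.
    """
    if volume <= 0 or v_cell <= 0:
        return 0.0
    n_sub = max(1, int(math.ceil(volume / (0.9 * v_cell))))
    q = volume / n_sub
    frac = q / v_cell
    displaced = 0.0
    for _ in range(n_sub):
        if toward_node:
            displaced += q * cells[0] / 100.0
            cells[:-1] += frac * (cells[1:] - cells[:-1])
            cells[-1] *= 1.0 - frac
        else:
            displaced += q * cells[-1] / 100.0
            cells[1:] += frac * (cells[:-1] - cells[1:])
            cells[0] += frac * (boundary - cells[0])
    return displaced


def apply_capnometer(recording: Recording, circuit: CircuitConfig) -> Recording:
    """Forward model of the sidestream capnometer.

    Delays both CO2 channels by the sampling-line transport delay
    (``compute_sampling_delay``) and, if ``capnometer_smoothing_tau`` > 0,
    applies a first-order low-pass.  All other channels are untouched.
    This is the distortion that :func:`capnotype.preprocess.align_capnogram`
    undoes.
    """
    out = recording.copy()
    delay = compute_sampling_delay(circuit.sample_line_volume, circuit.pump_flow)
    shift = int(round(delay * recording.sampling_rate))
    dt = 1.0 / recording.sampling_rate
    for role in ("CO2_pat", "CO2_vent"):
        if role not in out.channels:
            continue
        x = out.channels[role]
        if shift > 0 and len(x):
            if shift >= len(x):
                x = np.full_like(x, x[0])
            else:
                x = np.concatenate([np.full(shift, x[0]), x[:-shift]])
        tau = circuit.capnometer_smoothing_tau
        if tau > 0:
            alpha = -math.expm1(-dt / tau)
            y = np.empty_like(x)
            acc = x[0]
            for i, xi in enumerate(x):
                acc += alpha * (xi - acc)
                y[i] = acc
            x = y
        out.channels[role] = x
    out.metadata = dict(out.metadata)
    out.metadata["capnometer_delay_s"] = delay
    return out


# ---------------------------------------------------------------------------
# Feature-table sampler


@dataclass
class ClassStats:
    """Per-type means and SDs of the 17 per-cycle respiratory parameters.

    ``means``/``sds`` map cycle type ("I", "II", "III") to arrays aligned
    with ``features``; ``invasive_p`` gives the per-type probability that a
    cycle comes from an invasively ventilated patient.  An optional
    ``correlation`` matrix (shared across types) induces correlated draws.
    """

    features: Sequence[str]
    means: Mapping[str, np.ndarray]
    sds: Mapping[str, np.ndarray]
    invasive_p: Mapping[str, float]
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = len(self.features)
        self.means = {k: np.asarray(v, dtype=float) for k, v in self.means.items()}
        self.sds = {k: np.asarray(v, dtype=float) for k, v in self.sds.items()}
        for k, v in self.sds.items():
            if v.shape != (p,) or (v < 0).any():
                raise InvalidParameterError(f"SDs for type {k} invalid")
        for k, v in self.means.items():
            if v.shape != (p,):
                raise InvalidParameterError(f"means for type {k} have wrong length")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            if c.shape != (p, p) or not np.allclose(c, c.T):
                raise InvalidParameterError("correlation matrix must be symmetric p x p")
            if np.linalg.eigvalsh(c).min() < -1e-8:
                raise InvalidParameterError("correlation matrix not positive semi-definite")
            self.correlation = c

    @property
    def types(self) -> list[str]:
        return list(self.means)


#: feature names whose values cannot physically be negative; draws below
#: zero are truncated at zero.  Expiratory ventilator-side tidal volume is
#: excluded: it is signed (net flow away from the patient) and genuinely
#: negative for type I cycles.
NONNEGATIVE_FEATURES = frozenset({
    "insp_co2_volume", "insp_max_pressure_pat", "peep", "insp_time",
    "exp_time", "breath_frequency", "insp_pressure_integral_pat",
    "exp_pressure_integral_pat", "insp_vt_pat", "exp_vt_pat",
    "insp_vt_vent", "insp_max_flow_pat", "exp_max_flow_pat",
    "insp_max_flow_vent", "exp_max_flow_vent",
})


def sample_feature_table(stats: ClassStats, n_per_class: int | Mapping[str, int],
                         seed: int) -> pd.DataFrame:
    """Draw a labeled synthetic per-cycle feature table.

    Each class is sampled from a multivariate normal with the class means
    and SDs (independent coordinates unless ``stats.correlation`` is set);
    nonnegative-by-definition features are truncated at 0 and the
    invasive flag is Bernoulli with the per-class probability.  Returns a
    DataFrame with the feature columns plus ``cycle_type``.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for cls in stats.types:
        n = n_per_class[cls] if isinstance(n_per_class, Mapping) else int(n_per_class)
        if n < 1:
            raise InvalidParameterError("n_per_class must be >= 1")
        mu, sd = stats.means[cls], stats.sds[cls]
        if stats.correlation is not None:
            cov = stats.correlation * np.outer(sd, sd)
            draws = rng.multivariate_normal(mu, cov, size=n, method="svd")
        else:
            draws = mu + sd * rng.standard_normal((n, len(mu)))
        frame = pd.DataFrame(draws, columns=list(stats.features))
        for name in frame.columns:
            if name in NONNEGATIVE_FEATURES:
                frame[name] = frame[name].clip(lower=0.0)
        frame["invasive"] = (rng.random(n) < stats.invasive_p.get(cls, 1.0)).astype(int)
        frame["cycle_type"] = cls
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
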