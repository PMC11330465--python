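"""Per-cycle parameter extraction: closed forms and refined-grid oracles."""

import numpy as np
import pytest

from capnotype import pipeline as pl
from capnotype.errors import DegenerateDataError
from capnotype.features import (
    FEATURE_COLUMNS,
    extract_feature_table,
    extract_features,
    insp_co2_volume,
)
from capnotype.io import Recording
from capnotype.segment import BreathCycle, segment_recording
from capnotype.simulate import simulate_recording


def _recording_from(channels, fs=200.0, interface="invasive"):
    n = len(next(iter(channels.values())))
    full = {r: np.zeros(n) for r in ("P_pat", "Q_pat", "CO2_pat", "Q_vent", "CO2_vent")}
    full.update(channels)
    return Recording(sampling_rate=fs, channels=full, interface=interface)


class TestClosedForms:
    def test_rectangular_inspiratory_flow(self):
        """500 ml/s over the whole 1 s inspiration window -> V_T 500 ml."""
        fs = 200.0
        n_half = int(fs)  # 1 s phases
        # constant +500 across the inclusive inspiration window [200, 400]
        q = np.concatenate([np.full(n_half, -500.0), np.full(n_half + 1, 500.0),
                            np.full(9, -500.0)])
        rec = _recording_from({"Q_pat": q}, fs)
        cycle = BreathCycle(0, n_half, 2 * n_half)
        feats = extract_features(rec, cycle)
        assert feats.insp_vt_pat == pytest.approx(500.0, rel=1e-9)
        assert feats.insp_max_flow_pat == pytest.approx(500.0, rel=1e-12)
        assert feats.insp_time == pytest.approx(1.0)
        assert feats.breath_frequency == pytest.approx(30.0)

    def test_triangular_pressure_ramp(self):
        """0 -> 20 cmH2O ramp over the 1 s inspiration integrates to 10."""
        fs = 200.0
        n_half = int(fs)
        p = np.concatenate([np.zeros(n_half),
                            np.linspace(0, 20, n_half + 1),
                            np.zeros(9)])
        q = np.concatenate([np.full(n_half, -100.0), np.full(n_half + 1, 100.0),
                            np.full(9, -100.0)])
        rec = _recording_from({"P_pat": p, "Q_pat": q}, fs)
        feats = extract_features(rec, BreathCycle(0, n_half, 2 * n_half))
        assert feats.insp_pressure_integral_pat == pytest.approx(10.0, rel=1e-9)
        assert feats.insp_max_pressure_pat == pytest.approx(20.0, rel=1e-12)

    def test_constant_co2_flow_product(self):
        """600 ml/s at 1% CO2 for a 1 s inspiration -> 6.0 ml."""
        fs = 200.0
        n_half = int(fs)
        q = np.concatenate([np.full(n_half, -600.0), np.full(n_half + 1, 600.0),
                            np.full(9, -600.0)])
        co2 = np.full(q.size, 1.0)
        rec = _recording_from({"Q_pat": q, "CO2_pat": co2}, fs)
        cycle = BreathCycle(0, n_half, 2 * n_half)
        vol = insp_co2_volume(rec.channels["Q_pat"], rec.channels["CO2_pat"],
                              cycle, fs)
        assert vol == pytest.approx(6.0, rel=1e-9)

    def test_zero_co2_gives_zero_volume(self, clean_sims):
        rec = clean_sims["I"].recording.copy()
        rec.channels["CO2_pat"][:] = 0.0
        cycles = segment_recording(rec)
        for c in cycles[:3]:
            assert insp_co2_volume(rec.channels["Q_pat"], rec.channels["CO2_pat"],
                                   c, rec.sampling_rate) == 0.0


class TestRefinedGridOracle:
    def test_integrals_match_spline_refined_quadrature(self, clean_sims):
        """Trapezoidal phase integrals agree with an independent quadrature
        of a 10x-refined cubic-spline interpolant of the same channels."""
        from scipy.interpolate import CubicSpline

        sim = clean_sims["III"]
        rec = sim.recording
        fs = rec.sampling_rate
        cycles = segment_recording(rec)
        table = extract_feature_table(rec, cycles)

        def refined(series, start, end):
            idx = np.arange(start, end + 1)
            dense = np.linspace(start, end, (end - start) * 10 + 1)
            return np.trapezoid(CubicSpline(idx, series[idx])(dense),
                                dx=0.1 / fs)

        for _, row in table.iloc[1:-1].iterrows():
            c = cycles[int(row.cycle_id)]
            checks = {
                "insp_vt_pat": abs(refined(rec.channels["Q_pat"],
                                           c.insp_start, c.insp_end)),
                "exp_vt_pat": abs(refined(rec.channels["Q_pat"],
                                          c.exp_start, c.insp_start)),
                "insp_pressure_integral_pat": refined(
                    rec.channels["P_pat"], c.insp_start, c.insp_end),
                "exp_pressure_integral_pat": refined(
                    rec.channels["P_pat"], c.exp_start, c.insp_start),
                "insp_co2_volume": refined(
                    np.maximum(rec.channels["Q_pat"], 0)
                    * rec.channels["CO2_pat"] / 100.0,
                    c.insp_start, c.insp_end),
            }
            for col, oracle in checks.items():
                assert abs(row[col] - oracle) / max(abs(oracle), 1e-9) < 0.01, col

    def test_integral_features_stable_under_doubled_sampling(self):
        """Doubling the sampling rate moves flow/pressure integrals < 0.5%."""
        scenario = pl.demo_scenarios(0)[1]
        scenario.patient.noise_sd = {}
        scenario.patient.cycle_jitter_cv = 0.0
        coarse = simulate_recording(scenario.patient, scenario.circuit, 30.0,
                                    sampling_rate=200.0)
        fine = simulate_recording(scenario.patient, scenario.circuit, 30.0,
                                  sampling_rate=400.0)
        fc = extract_feature_table(coarse.recording,
                                   segment_recording(coarse.recording))
        ff = extract_feature_table(fine.recording,
                                   segment_recording(fine.recording))
        n = min(len(fc), len(ff))
        for col in ("insp_vt_pat", "exp_vt_pat", "insp_vt_vent",
                    "insp_pressure_integral_pat", "exp_pressure_integral_pat"):
            a = fc[col].to_numpy()[1:n - 1]
            b = ff[col].to_numpy()[1:n - 1]
            rel = np.abs(a - b) / np.maximum(np.abs(b), 1e-9)
            assert rel.max() < 0.005, col

    def test_patient_side_volume_balance_without_leak_asymmetry(self, clean_sims):
        """Inhaled and exhaled patient-side volumes agree per cycle."""
        sim = clean_sims["II"]
        table = extract_feature_table(sim.recording,
                                      segment_recording(sim.recording))
        diff = (table.insp_vt_pat - table.exp_vt_pat).abs()
        assert (diff / table.insp_vt_pat).max() < 0.01

    def test_type3_co2_volume_matches_simulator_truth(self, clean_sims):
        """Measured inspired CO2 = rebreathed + patient-limb dead-space CO2."""
        sim = clean_sims["III"]
        cycles = segment_recording(sim.recording)
        table = extract_feature_table(sim.recording, cycles)
        truth = sim.truth_frame()
        merged = 0
        for _, row in table.iterrows():
            c = cycles[int(row.cycle_id)]
            match = truth[(truth.exp_start - c.exp_start).abs() <= 5]
            if match.empty:
                continue
            merged += 1
            reb = float(match.iloc[0].rebreathed_ml)
            dead_space = sim.recording.channels["CO2_pat"][c.insp_start] / 100.0 \
                * 10.0  # sensor mixing volume at onset concentration
            expected = reb + dead_space
            assert abs(row.insp_co2_volume - expected) / expected < 0.10
        assert merged >= 5


class TestContracts:
    def test_degenerate_phase_flagged(self, clean_sims):
        rec = clean_sims["I"].recording
        with pytest.raises(DegenerateDataError):
            extract_features(rec, BreathCycle(0, 1, 2))

    def test_cycle_outside_recording_rejected(self, clean_sims):
        rec = clean_sims["I"].recording
        n = rec.n_samples
        with pytest.raises(DegenerateDataError):
            extract_features(rec, BreathCycle(n - 100, n - 50, n + 10))

    def test_table_has_contract_columns(self, clean_sims):
        sim = clean_sims["II"]
        table = extract_feature_table(sim.recording,
                                      segment_recording(sim.recording))
        assert list(table.columns) == ["cycle_id"] + FEATURE_COLUMNS
        assert (table.insp_time > 0).all() and (table.exp_time > 0).all()
        np.testing.assert_allclose(
            table.breath_frequency, 60 / (table.insp_time + table.exp_time))
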