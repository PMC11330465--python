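"""Circuit simulator: delay formula, CO2 regimes, conservation, sampler."""

import numpy as np
import pandas as pd
import pytest

from capnotype import pipeline as pl
from capnotype.errors import InvalidParameterError
from capnotype.label import label_recording
from capnotype.refdata import REFERENCE_FEATURES, reference_class_stats
from capnotype.segment import segment_recording
from capnotype.simulate import (
    SAMPLING_KIT_VOLUMES_ML,
    CircuitConfig,
    ClassStats,
    PatientConfig,
    apply_capnometer,
    compute_sampling_delay,
    sample_feature_table,
    simulate_recording,
)


class TestSamplingDelay:
    @pytest.mark.parametrize("volume, flow, expected", [
        (4.0, 150.0, 1.6),   # increased pump speed
        (4.0, 100.0, 2.4),   # factory-preset pump speed
        (0.0, 100.0, 0.0),   # empty line has no transport delay
    ])
    def test_delay_formula(self, volume, flow, expected):
        assert compute_sampling_delay(volume, flow) == pytest.approx(expected, abs=1e-12)

    def test_kit_component_volumes_sum(self):
        assert sum(SAMPLING_KIT_VOLUMES_ML.values()) == pytest.approx(4.0)

    def test_nonpositive_pump_flow_rejected(self):
        with pytest.raises(InvalidParameterError):
            compute_sampling_delay(4.0, 0.0)


class TestConfigValidation:
    def test_ipap_must_exceed_epap(self):
        with pytest.raises(InvalidParameterError):
            CircuitConfig(epap=10.0, ipap=8.0)

    def test_ti_fraction_bounds(self):
        with pytest.raises(InvalidParameterError):
            PatientConfig(ti_fraction=1.2)

    def test_duration_must_cover_two_cycles(self):
        with pytest.raises(InvalidParameterError):
            simulate_recording(PatientConfig(respiratory_rate=10),
                               CircuitConfig(), duration=8.0)


class TestRegimes:
    def test_zero_fetco2_gives_all_type_one(self):
        patient = PatientConfig(fetco2=0.0, noise_sd={}, seed=3)
        sim = simulate_recording(patient, CircuitConfig(), 30.0)
        assert {t for _, t in sim.truth_labels} == {"I"}
        assert np.all(sim.recording.channels["CO2_pat"] == 0)
        assert np.all(sim.recording.channels["CO2_vent"] == 0)
        assert np.all(sim.true_rebreathed_co2 == 0)

    def test_gentle_breathing_high_leak_is_type_one(self, clean_sims):
        sim = clean_sims["I"]
        assert {t for _, t in sim.truth_labels} == {"I"}
        # the labeler rules on the noiseless channels agree with the truth
        cycles = segment_recording(sim.recording)
        labels = label_recording(sim.recording, cycles)
        assert set(labels["type"]) == {"I"}

    def test_fast_large_breathing_low_leak_rebreathes(self, clean_sims):
        sim = clean_sims["III"]
        types = [t for _, t in sim.truth_labels]
        assert "III" in types
        reb = sim.true_rebreathed_co2[[i for i, t in enumerate(types) if t == "III"]]
        assert (reb > 0).all()
        # vent-side CO2 is positive at inspiration onset for type III cycles
        assert (sim.mass_balance.loc[[t == "III" for t in types], "onset_co2"] > 0.05).all()

    def test_rebreathed_zero_for_types_one_and_two(self, clean_sims):
        for sim in clean_sims.values():
            for (idx, t), reb in zip(sim.truth_labels, sim.true_rebreathed_co2):
                if t in ("I", "II"):
                    assert reb == 0.0
                else:
                    assert reb > 0.0

    def test_type_two_has_vent_side_co2_during_expiration(self, clean_sims):
        sim = clean_sims["II"]
        assert {t for _, t in sim.truth_labels} == {"II"}
        assert (sim.mass_balance["max_exp_co2"] > 0.05).all()
        assert (sim.mass_balance["onset_co2"] <= 0.05).all()


class TestConservationAndDeterminism:
    def test_per_cycle_co2_mass_balance(self, clean_sims):
        for sim in clean_sims.values():
            mb = sim.mass_balance
            residual = mb.exhaled_ml - (mb.vented_ml + mb.reinhaled_ml
                                        + mb.content_end_ml - mb.content_start_ml)
            assert (residual.abs() / mb.exhaled_ml).max() < 0.01

    def test_same_seed_bit_identical(self):
        patient = PatientConfig(seed=11)
        a = simulate_recording(patient, CircuitConfig(), 20.0)
        b = simulate_recording(PatientConfig(seed=11), CircuitConfig(), 20.0)
        for role in a.recording.channels:
            assert np.array_equal(a.recording.channels[role],
                                  b.recording.channels[role])
        assert a.truth_labels == b.truth_labels

    def test_severity_monotone_in_tidal_volume_and_leak(self):
        """More expired volume or less leak washout never makes a regime milder."""
        rank = {"I": 0, "II": 1, "III": 2}

        def worst(vt, leak):
            patient = PatientConfig(tidal_volume=vt, respiratory_rate=24,
                                    cycle_jitter_cv=0.0, noise_sd={}, seed=5)
            sim = simulate_recording(patient, CircuitConfig(leak_conductance=leak), 30.0)
            return max(rank[t] for _, t in sim.truth_labels)

        by_vt = [worst(vt, 100.0) for vt in (250, 450, 700)]
        assert by_vt == sorted(by_vt)
        by_leak = [worst(500, leak) for leak in (250.0, 100.0, 50.0)]
        assert by_leak == sorted(by_leak)


class TestCapnometer:
    def test_zero_delay_zero_tau_is_identity(self, clean_sims):
        rec = clean_sims["II"].recording
        circuit = CircuitConfig(sample_line_volume=0.0, capnometer_smoothing_tau=0.0)
        out = apply_capnometer(rec, circuit)
        for role in ("CO2_pat", "CO2_vent"):
            assert np.array_equal(out.channels[role], rec.channels[role])

    def test_delay_is_an_index_shift(self, clean_sims):
        rec = clean_sims["II"].recording  # 200 Hz
        out = apply_capnometer(rec, CircuitConfig())  # 4.0 ml at 150 ml/min -> 1.6 s
        shift = 320
        x = rec.channels["CO2_vent"]
        assert np.array_equal(out.channels["CO2_vent"][shift:], x[:-shift])
        assert np.all(out.channels["CO2_vent"][:shift] == x[0])
        assert np.array_equal(out.channels["Q_pat"], rec.channels["Q_pat"])

    def test_smoothing_bounded_by_input_extrema(self, clean_sims):
        rec = clean_sims["II"].recording
        circuit = CircuitConfig(sample_line_volume=0.0, capnometer_smoothing_tau=0.2)
        out = apply_capnometer(rec, circuit)
        x, y = rec.channels["CO2_vent"], out.channels["CO2_vent"]
        assert y.max() <= x.max() + 1e-12
        assert y.min() >= x.min() - 1e-12


class TestFeatureSampler:
    def test_zero_sd_reproduces_class_means(self):
        stats = reference_class_stats()
        degenerate = ClassStats(
            features=stats.features,
            means=stats.means,
            sds={t: np.zeros(len(stats.features)) for t in stats.types},
            invasive_p={t: 1.0 for t in stats.types},
        )
        table = sample_feature_table(degenerate, n_per_class=5, seed=0)
        for t in stats.types:
            rows = table[table.cycle_type == t]
            mu = np.clip(stats.means[t], 0.0, None)
            mu[REFERENCE_FEATURES.index("exp_vt_vent")] = stats.means[t][
                REFERENCE_FEATURES.index("exp_vt_vent")]
            assert np.allclose(rows[list(stats.features)].to_numpy(), mu)

    def test_sample_mean_matches_reference_type3_co2(self):
        stats = reference_class_stats()
        table = sample_feature_table(stats, n_per_class=10_000, seed=42)
        vals = table.loc[table.cycle_type == "III", "insp_co2_volume"]
        # draws are clipped at 0, so the expected mean is the closed-form
        # mean of a normal N(4.92, 4.88) rectified at zero:
        # E[max(X,0)] = mu*Phi(mu/sigma) + sigma*phi(mu/sigma)
        from scipy.stats import norm
        mu, sigma = 4.92, 4.88
        expected = mu * norm.cdf(mu / sigma) + sigma * norm.pdf(mu / sigma)
        se = sigma / np.sqrt(len(vals))
        assert abs(vals.mean() - expected) < 3 * se

    def test_fixed_seed_is_reproducible(self):
        stats = reference_class_stats()
        a = sample_feature_table(stats, 50, seed=7)
        b = sample_feature_table(stats, 50, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_non_psd_correlation_rejected(self):
        stats = reference_class_stats()
        bad = np.eye(len(stats.features))
        bad[0, 1] = bad[1, 0] = 2.0
        with pytest.raises(InvalidParameterError):
            ClassStats(features=stats.features, means=stats.means,
                       sds=stats.sds, invasive_p=stats.invasive_p,
                       correlation=bad)
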