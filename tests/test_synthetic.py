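"""The generators must match their own ground truth: exact threshold
crossings for vGRF, closed-form rectified amplitudes for EMG, known ramp
slopes for IMTP, and requested correlation structure for cohorts."""

import math

import numpy as np
import pytest

from runcna.errors import InvalidSpecError
from runcna.gait import detect_contacts
from runcna.synthetic import (
    CONTACT_THRESHOLD_N,
    SyntheticCohortSpec,
    SyntheticRunSpec,
    gen_cohort,
    gen_emg,
    gen_imtp,
    gen_vgrf,
    planted_cohort,
    run_spec_for_speed,
)


def make_spec(**overrides):
    defaults = dict(speed_kmh=12.0, contact_time_s=0.22, flight_time_s=0.12,
                    n_strides=5, noise_sd=0.0, seed=0)
    defaults.update(overrides)
    return SyntheticRunSpec(**defaults)


class TestGenVgrf:
    def test_ground_truth_stride_frequency_is_60_over_cycle(self):
        spec = make_spec()
        _, gt = gen_vgrf(spec, 72.0)
        assert gt.true_stride_frequency == pytest.approx(60.0 / 0.34)

    def test_zero_strides_gives_empty_trace_and_events(self):
        trace, gt = gen_vgrf(make_spec(n_strides=0), 72.0)
        assert trace.n == 0
        assert gt.contact_onsets.size == 0

    def test_detector_recovers_ground_truth_within_one_sample(self):
        spec = make_spec(n_strides=8)
        trace, gt = gen_vgrf(spec, 72.0)
        events = detect_contacts(trace, CONTACT_THRESHOLD_N)
        assert events.n_contacts == 8
        onsets = np.array([on for on, _ in events.contacts])
        offsets = np.array([off for _, off in events.contacts])
        assert np.max(np.abs(onsets - gt.contact_onsets)) <= 1
        assert np.max(np.abs(offsets - gt.contact_offsets)) <= 1

    def test_stance_peaks_at_requested_body_weight_multiple(self):
        spec = make_spec(peak_force_bw=2.5)
        trace, _ = gen_vgrf(spec, 70.0)
        assert trace.samples.max() == pytest.approx(2.5 * 70.0 * 9.81, rel=1e-3)

    def test_flight_phase_is_zero_force_when_noise_free(self):
        spec = make_spec()
        trace, gt = gen_vgrf(spec, 72.0)
        flight = trace.samples[gt.contact_offsets[0] + 1: gt.contact_onsets[1] - 1]
        assert np.all(flight == 0.0)

    def test_same_seed_is_bit_identical(self):
        a, _ = gen_vgrf(make_spec(noise_sd=8.0, seed=3), 72.0)
        b, _ = gen_vgrf(make_spec(noise_sd=8.0, seed=3), 72.0)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_events_alternate_and_increase(self):
        _, gt = gen_vgrf(make_spec(n_strides=6), 72.0)
        assert np.all(np.diff(gt.contact_onsets) > 0)
        assert np.all(gt.contact_offsets > gt.contact_onsets)
        assert np.all(gt.contact_onsets[1:] > gt.contact_offsets[:-1])

    @pytest.mark.parametrize("bad", [
        dict(contact_time_s=-0.1), dict(flight_time_s=-0.1),
        dict(grf_rate=0.0), dict(peak_force_bw=0.0), dict(noise_sd=-1.0),
    ])
    def test_invalid_spec_raises(self, bad):
        with pytest.raises(InvalidSpecError):
            make_spec(**bad)


class TestGenEmg:
    def test_zero_amplitude_gives_zero_signal(self, clean_run):
        spec, _, gt = clean_run
        env = {m: dict(v) for m, v in spec.envelope_spec.items()}
        env["BF"]["amplitude_uV"] = 0.0
        zspec = run_spec_for_speed(12.0, n_strides=15, seed=7, envelope_spec=env)
        traces, _ = gen_emg(zspec, gt, muscles=("BF",))
        assert np.all(traces["BF"].samples == 0.0)

    def test_constant_envelope_mean_rectified_matches_gaussian_closed_form(self):
        # long cycles and a constant envelope: E|X| = a * sqrt(2/pi)
        amp = 40.0
        env = {"VL": {"phase_center": 0.0, "phase_width": 2.0, "amplitude_uV": amp}}
        spec = make_spec(n_strides=6, contact_time_s=0.6, flight_time_s=0.4,
                         envelope_spec=env)
        _, gt = gen_vgrf(spec, 72.0)
        traces, _ = gen_emg(spec, gt)
        x = traces["VL"].samples
        x = x[np.abs(x) > 0]  # inside cycles
        expected = amp * math.sqrt(2.0 / math.pi)
        assert np.mean(np.abs(x)) == pytest.approx(expected, rel=0.02)

    def test_doubling_amplitude_doubles_signal_and_expected_iemg(self):
        spec1 = make_spec(n_strides=4)
        _, gt1 = gen_vgrf(spec1, 72.0)
        env2 = {m: dict(v) for m, v in spec1.envelope_spec.items()}
        for v in env2.values():
            v["amplitude_uV"] *= 2.0
        spec2 = make_spec(n_strides=4, envelope_spec=env2)
        _, gt2 = gen_vgrf(spec2, 72.0)
        t1, gt1 = gen_emg(spec1, gt1)
        t2, gt2 = gen_emg(spec2, gt2)
        np.testing.assert_allclose(2.0 * t1["GM"].samples, t2["GM"].samples, rtol=1e-12)
        np.testing.assert_allclose(2.0 * gt1.true_iemg_per_cycle["GM"],
                                   gt2.true_iemg_per_cycle["GM"], rtol=1e-12)

    def test_phase_center_outside_unit_interval_rejected(self):
        env = {"VL": {"phase_center": 1.2, "phase_width": 0.3, "amplitude_uV": 10.0}}
        with pytest.raises(InvalidSpecError):
            make_spec(envelope_spec=env)

    def test_empty_events_rejected(self):
        spec = make_spec(n_strides=0)
        _, gt = gen_vgrf(spec, 72.0)
        with pytest.raises(InvalidSpecError):
            gen_emg(make_spec(), gt)


class TestGenImtp:
    def test_noise_free_linear_ramp_has_constant_rfd_truth(self):
        _, gt = gen_imtp(72.0, rise_rate=3000.0, noise_sd=0.0, shape="linear")
        assert set(gt.true_rfd_per_window) == {50, 100, 150, 200, 250}
        for v in gt.true_rfd_per_window.values():
            assert v == pytest.approx(3000.0, rel=1e-9)

    def test_noise_free_onset_is_first_sample_above_baseline(self):
        trace, gt = gen_imtp(72.0, rise_rate=3000.0, noise_sd=0.0, shape="linear")
        bw = 72.0 * 9.81
        first_above = int(np.flatnonzero(trace.samples > bw)[0])
        assert gt.true_onset_index == first_above

    def test_short_baseline_rejected(self):
        with pytest.raises(InvalidSpecError):
            gen_imtp(72.0, baseline_s=0.3)

    def test_plateau_must_exceed_body_weight(self):
        with pytest.raises(InvalidSpecError):
            gen_imtp(72.0, plateau_force=100.0)

    def test_same_seed_is_bit_identical(self):
        a, _ = gen_imtp(72.0, noise_sd=6.0, seed=11)
        b, _ = gen_imtp(72.0, noise_sd=6.0, seed=11)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestGenCohort:
    @staticmethod
    def spec_for(rho, n=23, seed=0):
        r = np.array([[1.0, rho], [rho, 1.0]])
        return SyntheticCohortSpec(n, ("a", "b"), r, np.zeros(2), np.ones(2), seed=seed)

    def test_perfect_correlation_reproduced_exactly(self):
        table, _ = gen_cohort(self.spec_for(1.0))
        r = np.corrcoef(table["a"], table["b"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_null_correlation_vanishes_for_large_n(self):
        n = 4000
        table, _ = gen_cohort(self.spec_for(0.0, n=n, seed=5))
        r = np.corrcoef(table["a"], table["b"])[0, 1]
        assert abs(r) < 3.0 / math.sqrt(n)

    def test_non_psd_matrix_rejected(self):
        r = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(InvalidSpecError):
            SyntheticCohortSpec(10, ("a", "b", "c"), r, np.zeros(3), np.ones(3))

    def test_planted_rho_recorded(self):
        _, gt = gen_cohort(self.spec_for(-0.6))
        assert gt.planted_rho == {("a", "b"): -0.6}

    def test_planted_mean_r_close_to_target_over_replicates(self):
        rs = []
        for seed in range(300):
            table, _ = gen_cohort(self.spec_for(-0.6, seed=seed))
            rs.append(np.corrcoef(table["a"], table["b"])[0, 1])
        # E[r] is mildly attenuated toward zero at n=23
        assert np.mean(rs) == pytest.approx(-0.59, abs=0.03)

    def test_study_shaped_cohort_has_iemg_consistent_with_cna(self):
        table, gt = planted_cohort(n=23, rho=-0.6, seed=1)
        np.testing.assert_allclose(
            table["BF_iemg_12"] * table["stride_freq_spm"],
            table["BF_cna_12"], rtol=1e-12,
        )
        assert ("Kflex_ecc", "BF_cna_12") in gt.planted_rho
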