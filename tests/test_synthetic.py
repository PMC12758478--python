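"""Synthetic Holter generator: mechanisms, determinism, rate recovery."""

import numpy as np
import pytest

from pvchr import (
    CircadianProfile,
    LinearRampProfile,
    MechanismConfig,
    MechanismKind,
    Methodology,
    SimulationSpec,
    classify_points,
    cohort_preset,
    mechanism_expected_rate,
    segment_record,
    simulate_cohort,
    simulate_record,
    spec_from_dict,
    spec_to_dict,
    write_beat_record,
)
from pvchr.synthetic import ConfigurationError


def constant_hr_spec(mechanism, hr=80.0, duration=600.0, seed=1, **kw):
    return SimulationSpec(
        record_id="C",
        mechanism=mechanism,
        hr_profile=LinearRampProfile(hr, hr, duration, jitter_sd=0.0),
        duration_s=duration,
        seed=seed,
        **kw,
    )


class TestConfigValidation:
    def test_circadian_floor(self):
        with pytest.raises(ConfigurationError, match="floor"):
            CircadianProfile(base_hr=50, amplitude=25)

    def test_negative_jitter(self):
        with pytest.raises(ConfigurationError, match="jitter"):
            CircadianProfile(jitter_sd=-1)

    def test_ectopic_period_exceeds_refractory(self):
        mech = MechanismConfig(
            kind=MechanismKind.PURE_PARASYSTOLE, ectopic_period=0.3, refractory=0.4
        )
        with pytest.raises(ConfigurationError, match="refractory"):
            simulate_record(constant_hr_spec(mech))

    def test_coupling_must_fit_in_sinus_period(self):
        mech = MechanismConfig(
            kind=MechanismKind.FIXED_NIB, nib=1, coupling_interval=0.9
        )
        with pytest.raises(ConfigurationError, match="coupling"):
            simulate_record(constant_hr_spec(mech, hr=80))  # period 0.75 s


class TestMechanisms:
    def test_fixed_nib_bigeminy_rate(self):
        """NIB=1 at a constant 80 bpm gives 40 PVCs per minute (HR/2)."""
        mech = MechanismConfig(kind=MechanismKind.FIXED_NIB, nib=1)
        rec = simulate_record(constant_hr_spec(mech, hr=80.0, duration=600.0))
        per_min = [iv.pvc_count for iv in segment_record(rec, 60.0)]
        assert all(abs(c - 40) <= 1 for c in per_min)

    def test_no_mechanism_clock_arithmetic(self):
        """60 bpm for one hour yields 3600 +- 1 sinus beats and no PVCs."""
        rec = simulate_record(
            constant_hr_spec(MechanismConfig(), hr=60.0, duration=3600.0)
        )
        assert abs(rec.n_beats - 3600) <= 1
        assert rec.n_pvc == 0

    def test_blocked_compensatory_pause(self, bigeminy_record):
        """After every PVC the next scheduled sinus beat is absent.

        In bigeminy at 80 bpm (period 0.75 s) the gap from each PVC to the
        next expressed beat spans the blocked slot: about 2T - coupling.
        """
        t = bigeminy_record.times
        gaps_after_pvc = np.diff(t)[bigeminy_record.is_pvc[:-1]]
        assert gaps_after_pvc.min() > 0.75  # always longer than one period

    def test_fixed_nib_empirical_matches_expected(self):
        for nib in (1, 2, 4):
            mech = MechanismConfig(kind=MechanismKind.FIXED_NIB, nib=nib)
            rec = simulate_record(constant_hr_spec(mech, hr=90.0, duration=600.0))
            expected = mechanism_expected_rate(mech, 90.0).pvc_per_min
            per_min = [iv.pvc_count for iv in segment_record(rec, 60.0)]
            assert all(abs(c - expected) <= 1 for c in per_min)

    def test_parasystole_rate_decreases_with_hr(self):
        """Protected-pacemaker PVC counts fall as heart rate rises."""
        mech = MechanismConfig(
            kind=MechanismKind.PURE_PARASYSTOLE, ectopic_period=1.3, refractory=0.4
        )
        n_neg = 0
        for seed in range(5):
            spec = SimulationSpec(
                record_id="P",
                mechanism=mech,
                hr_profile=LinearRampProfile(50, 110, 4 * 3600.0, jitter_sd=0.0),
                duration_s=4 * 3600.0,
                seed=seed,
            )
            rec = simulate_record(spec)
            ivs = [iv for iv in segment_record(rec, 60.0) if iv.valid]
            pts = np.array([[iv.mean_hr, iv.pvc_count] for iv in ivs])
            res = classify_points(pts, Methodology(60.0))
            n_neg += res.r < 0
        assert n_neg == 5


class TestExpectedRate:
    def test_fixed_nib_closed_form(self):
        mech = MechanismConfig(kind=MechanismKind.FIXED_NIB, nib=2)
        assert mechanism_expected_rate(mech, 90.0) == (30.0, False)

    def test_bigeminy_slope_is_half(self):
        """d(rate)/d(HR) for NIB=1 is 0.5 at any heart rate."""
        mech = MechanismConfig(kind=MechanismKind.FIXED_NIB, nib=1)
        rates = [mechanism_expected_rate(mech, hr).pvc_per_min for hr in (60, 100)]
        assert (rates[1] - rates[0]) / 40.0 == pytest.approx(0.5)

    def test_logistic_accounts_for_blocked_beats(self):
        """With per-beat probability p, a fraction p/(1+p) of slots are PVCs."""
        mech = MechanismConfig(
            kind=MechanismKind.LOGISTIC_HR,
            logistic_slope=0.0,
            logistic_intercept=float(np.log(0.1 / 0.9)),  # p = 0.1 at any HR
        )
        got = mechanism_expected_rate(mech, 70.0)
        assert got.pvc_per_min == pytest.approx(70.0 * 0.1 / 1.1, rel=1e-9)
        assert not got.simulated
        # empirical cross-check
        rec = simulate_record(constant_hr_spec(mech, hr=70.0, duration=3600.0))
        assert rec.n_pvc / 60.0 == pytest.approx(got.pvc_per_min, rel=0.1)

    def test_parasystole_rate_is_simulated(self):
        mech = MechanismConfig(
            kind=MechanismKind.PURE_PARASYSTOLE, ectopic_period=1.3, refractory=0.4
        )
        got = mechanism_expected_rate(mech, 60.0)
        assert got.simulated
        assert got.pvc_per_min > 0


class TestDeterminism:
    def test_same_seed_same_record(self, tmp_path):
        mech = MechanismConfig(
            kind=MechanismKind.LOGISTIC_HR, logistic_slope=0.05, logistic_intercept=-5
        )
        spec = SimulationSpec(
            record_id="D",
            mechanism=mech,
            hr_profile=CircadianProfile(75, 15),
            duration_s=6 * 3600.0,
            noise_segment_prob=0.02,
            seed=123,
        )
        a, b = simulate_record(spec), simulate_record(spec)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.is_pvc, b.is_pvc)
        assert a.noise.segments == b.noise.segments
        # byte-identical on disk
        write_beat_record(a, tmp_path / "a.csv")
        write_beat_record(b, tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_different_seed_differs(self):
        mech = MechanismConfig(
            kind=MechanismKind.LOGISTIC_HR, logistic_slope=0.05, logistic_intercept=-5
        )
        a = simulate_record(constant_hr_spec(mech, seed=1, duration=3600.0))
        b = simulate_record(constant_hr_spec(mech, seed=2, duration=3600.0))
        assert a.n_pvc != b.n_pvc or not np.array_equal(a.times, b.times)


class TestCohort:
    def test_duplicate_ids_rejected(self):
        spec = SimulationSpec(record_id="X", duration_s=60.0)
        with pytest.raises(ValueError, match="duplicate"):
            simulate_cohort([spec, spec])

    def test_ids_match(self):
        specs = [
            SimulationSpec(record_id=f"R{i}", duration_s=120.0, seed=i)
            for i in range(3)
        ]
        recs = simulate_cohort(specs)
        assert [r.record_id for r in recs] == ["R0", "R1", "R2"]

    def test_preset_burden_range(self):
        """The mixed-mechanism preset spans burdens of roughly 1%-44%."""
        recs = simulate_cohort(cohort_preset(n_records=48, days=1, seed=0))
        burdens = np.array([r.pvc_burden for r in recs])
        assert burdens.min() <= 0.02
        assert burdens.max() >= 0.40
        assert burdens.max() <= 0.50


class TestSpecSerialisation:
    def test_yaml_dict_round_trip(self):
        spec = SimulationSpec(
            record_id="S",
            days=2,
            mechanism=MechanismConfig(kind=MechanismKind.HUMP_HR, hump_peak_hr=85),
            hr_profile=(
                CircadianProfile(70, 10),
                LinearRampProfile(60, 90, 3600.0),
            ),
            noise_segment_prob=0.01,
            seed=9,
        )
        back = spec_from_dict(spec_to_dict(spec))
        assert back == spec
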