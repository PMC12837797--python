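"""Gravity correction, moment-balance solvers and force-to-sEMG fitting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import lumbarload as ll
from lumbarload._exceptions import ConfigurationError, FitError, GeometryError, InputError
from lumbarload.calibration import (
    EXTENSION,
    FLEXION,
    ForceEmgSamples,
    extract_calibration_samples,
    label_phases,
)
from lumbarload.synthetic import generate_vct, gravity_sweep


def geom(arm, angle_deg, csa=10.0, muscle="RES"):
    return ll.MuscleGeometry(muscle=muscle, csa=csa, moment_arm=arm, inclination_deg=angle_deg)


class TestGravityCalibration:
    def test_measured_angles_reproduced_exactly(self):
        curve = ll.fit_gravity_calibration([0.0, 30.0, 60.0], [1.0, 5.0, 12.0])
        assert curve(30.0) == pytest.approx(5.0)
        assert curve(0.0) == pytest.approx(1.0)

    def test_extrapolation_clamps_to_endpoints(self):
        curve = ll.fit_gravity_calibration([10.0, 20.0], [2.0, 4.0])
        assert curve(-5.0) == pytest.approx(2.0)
        assert curve(90.0) == pytest.approx(4.0)

    def test_duplicate_angles_averaged(self):
        curve = ll.fit_gravity_calibration([0.0, 0.0, 10.0], [1.0, 3.0, 5.0])
        assert curve(0.0) == pytest.approx(2.0)

    def test_fewer_than_two_distinct_angles_rejected(self):
        with pytest.raises(InputError):
            ll.fit_gravity_calibration([5.0, 5.0], [1.0, 1.0])

    def test_recovers_generating_cubic_between_nodes(self, clean_config, clean_dataset):
        truth = clean_dataset.truth
        angles = np.arange(0.0, 90.0, 5.0)
        curve = ll.fit_gravity_calibration(angles, truth.gravity(angles))
        query = angles[:-1] + 2.5
        # piecewise-linear interpolation of a smooth function: |error| <= max|g''| h^2 / 8
        g = truth.gravity
        u = np.linspace(0.0, 1.0, 200)
        second_deriv = g.scale * np.abs(2.0 * g.c2 + 6.0 * g.c3 * u) / 90.0**2
        bound = second_deriv.max() * 5.0**2 / 8.0
        assert np.max(np.abs(curve(query) - g(query))) <= bound

    def test_zero_rest_torque_curve_leaves_moment_unchanged(self):
        curve = ll.fit_gravity_calibration([0.0, 90.0], [0.0, 0.0])
        raw = np.array([3.0, -1.0, 7.0])
        assert np.array_equal(ll.correct_moment(raw, np.array([10.0, 40.0, 80.0]), curve), raw)

    def test_zero_effort_trial_corrects_to_zero(self, clean_config, clean_dataset):
        trial = generate_vct(clean_config, 0, clean_dataset.truth, 60.0, effort_profile=0.0)
        curve = ll.fit_gravity_calibration(*trial.rest_sweep)
        corrected = ll.correct_moment(trial.torque_nm, trial.lever_angle_deg, curve)
        assert np.allclose(corrected, 0.0, atol=1e-8)


class TestMomentBalanceSolvers:
    def test_extension_hand_value(self):
        force = ll.solve_extension_force(10.0, 0.5, geom(0.05, 0.0))
        assert force == pytest.approx(100.0)

    def test_zero_moment_gives_zero_force(self):
        assert ll.solve_extension_force(0.0, 0.5, geom(0.05, 0.0)) == 0.0
        f_ra, f_eo = ll.solve_flexion_forces(0.0, 0.5, geom(0.1, 0.0), geom(0.08, 45.0), 1.0)
        assert f_ra == 0.0 and f_eo == 0.0

    def test_sixty_degree_inclination_doubles_force(self):
        at_zero = ll.solve_extension_force(10.0, 0.5, geom(0.05, 0.0))
        at_sixty = ll.solve_extension_force(10.0, 0.5, geom(0.05, 60.0))
        assert at_sixty == pytest.approx(2.0 * at_zero)

    def test_flexion_hand_value(self):
        # M_B* * d_L = 10 N*m split between RA and EO with r = 1
        f_ra, f_eo = ll.solve_flexion_forces(20.0, 0.5, geom(0.10, 0.0), geom(0.08, 45.0), 1.0)
        expected = 10.0 / (0.10 + 0.08 * math.cos(math.radians(45.0)))
        assert expected == pytest.approx(63.87, abs=0.01)
        assert f_ra == pytest.approx(expected)
        assert f_eo == pytest.approx(expected)

    def test_zero_csa_ratio_attributes_all_moment_to_ra(self):
        f_ra, f_eo = ll.solve_flexion_forces(20.0, 0.5, geom(0.10, 0.0), geom(0.08, 45.0), 0.0)
        assert f_ra == pytest.approx(10.0 / 0.10)
        assert f_eo == 0.0

    def test_negative_inputs_clamped_and_bad_geometry_rejected(self):
        assert ll.solve_extension_force(-5.0, 0.5, geom(0.05, 0.0)) == 0.0
        with pytest.raises(GeometryError):
            ll.solve_extension_force(1.0, 0.5, geom(0.05, 90.0))
        with pytest.raises(ll.ParameterError):
            ll.solve_flexion_forces(1.0, 0.5, geom(0.1, 0.0), geom(0.08, 45.0), -0.5)

    @given(
        force=st.floats(1.0, 5000.0),
        arm=st.floats(0.01, 0.2),
        angle=st.floats(0.0, 80.0),
        d_l=st.floats(0.25, 0.8),
    )
    def test_extension_round_trip(self, force, arm, angle, d_l):
        """Forward moment then solver recovers the prescribed force exactly."""
        g = geom(arm, angle)
        mbstar = force * arm * math.cos(math.radians(angle)) / d_l
        recovered = ll.solve_extension_force(mbstar, d_l, g)
        assert recovered == pytest.approx(force, rel=1e-9)

    @given(
        f_ra=st.floats(1.0, 3000.0),
        arm_ra=st.floats(0.02, 0.15),
        arm_eo=st.floats(0.02, 0.15),
        angle_ra=st.floats(0.0, 80.0),
        ratio=st.floats(0.1, 5.0),
        d_l=st.floats(0.25, 0.8),
    )
    def test_flexion_round_trip_and_balance_residual(
        self, f_ra, arm_ra, arm_eo, angle_ra, ratio, d_l
    ):
        g_ra, g_eo = geom(arm_ra, angle_ra), geom(arm_eo, 45.0)
        f_eo = ratio * f_ra
        moment = f_ra * arm_ra * math.cos(math.radians(angle_ra)) + f_eo * arm_eo * math.cos(
            math.radians(45.0)
        )
        rec_ra, rec_eo = ll.solve_flexion_forces(moment / d_l, d_l, g_ra, g_eo, ratio)
        assert rec_ra == pytest.approx(f_ra, rel=1e-9)
        assert rec_eo == pytest.approx(f_eo, rel=1e-9)
        balanced = rec_ra * arm_ra * math.cos(math.radians(angle_ra)) + rec_eo * arm_eo * math.cos(
            math.radians(45.0)
        )
        assert balanced == pytest.approx(moment, rel=1e-9)


class TestPhaseRouting:
    def test_phase_labels_follow_velocity_sign_with_deadband(self):
        rate = 100.0
        angle = np.concatenate([np.linspace(0, 30, 50), np.linspace(30, 0, 50)])
        phases = label_phases(angle, rate)
        assert phases[10] == FLEXION
        assert phases[80] == EXTENSION

    def test_extension_only_trial_contributes_no_flexor_samples(self):
        rate = 100.0
        n = 100
        angle = np.linspace(60, 0, n)
        phases = label_phases(angle, rate)
        forces = {ch: np.full(n, 10.0) for ch in ll.CHANNELS}
        envelopes = {ch: np.full(n, 0.5) for ch in ll.CHANNELS}
        pairs = ll.pair_force_emg(forces, envelopes, phases, speed=60.0)
        assert pairs["RRA"].n == 0 and pairs["REO"].n == 0
        assert pairs["RES"].n > 0

    def test_fully_rest_masked_channel_refuses_to_fit(self):
        samples = ForceEmgSamples(muscle="RES", force=np.array([]), envelope=np.array([]),
                                  speed=60.0)
        with pytest.raises(FitError):
            ll.fit_relationship(samples, "linear")

    def test_noise_free_pairs_lie_on_ground_truth_curve(self, clean_config, clean_dataset):
        truth = clean_dataset.truth
        trial = clean_dataset.vcts[3]  # max-effort 60 deg/s
        curve = ll.fit_gravity_calibration(*trial.rest_sweep)
        pairs = extract_calibration_samples(trial, truth.geometry, curve)
        for channel in ("RES", "RRA", "REO"):
            samples = pairs[channel]
            predicted = truth.relationships[channel].force(samples.envelope)
            assert np.allclose(predicted, samples.force, rtol=1e-9, atol=1e-6)


class TestFitRelationship:
    def test_exact_linear_fit(self):
        s = np.linspace(0.1, 2.0, 30)
        samples = ForceEmgSamples(muscle="RES", force=2.0 + 3.0 * s, envelope=s, speed=60.0)
        rel = ll.fit_relationship(samples, "linear")
        assert rel.a == pytest.approx(2.0, abs=1e-10)
        assert rel.b == pytest.approx(3.0, abs=1e-10)
        assert rel.rss == pytest.approx(0.0, abs=1e-16)

    def test_exact_logarithmic_fit(self):
        s = np.linspace(0.2, 3.0, 30)
        samples = ForceEmgSamples(
            muscle="RRA", force=1.0 + 2.0 * np.log(s), envelope=s, speed=60.0
        )
        rel = ll.fit_relationship(samples, "logarithmic")
        assert rel.a == pytest.approx(1.0, abs=1e-10)
        assert rel.b == pytest.approx(2.0, abs=1e-10)

    def test_noisy_recovery_within_three_standard_errors(self):
        rng = np.random.default_rng(4)
        s = rng.uniform(0.2, 2.0, 500)
        force = 10.0 + 40.0 * np.log(s) + rng.normal(0.0, 3.0, 500)
        samples = ForceEmgSamples(muscle="RRA", force=force, envelope=s, speed=60.0)
        rel = ll.fit_relationship(samples, "logarithmic")
        assert abs(rel.a - 10.0) < 3.0 * rel.se_a
        assert abs(rel.b - 40.0) < 3.0 * rel.se_b

    def test_degenerate_samples_rejected(self):
        flat = ForceEmgSamples(
            muscle="RES", force=np.array([1.0, 2.0, 3.0]), envelope=np.full(3, 0.5), speed=60.0
        )
        with pytest.raises(FitError):
            ll.fit_relationship(flat, "linear")
        nonpositive = ForceEmgSamples(
            muscle="RRA", force=np.array([1.0, 2.0, 3.0]),
            envelope=np.array([0.0, 0.5, 1.0]), speed=60.0,
        )
        with pytest.raises(FitError):
            ll.fit_relationship(nonpositive, "logarithmic")

    def test_prediction_clamped_at_zero(self):
        rel = ll.ForceEmgRelationship(
            muscle="RES", form="linear", specificity="specific", speed=60.0, a=-5.0, b=10.0
        )
        assert np.all(rel.predict(np.array([0.0, 0.1, 1.0])) >= 0.0)


class TestGeneralRelationship:
    @staticmethod
    def make_samples(gain, n=50, form="linear"):
        s = np.linspace(0.1, 1.0, n)
        force = gain * (4.0 * s) if form == "linear" else gain * (2.0 + np.log(s))
        return ForceEmgSamples(muscle="RES", force=force, envelope=s, speed=60.0)

    def test_duplicated_subject_matches_specific_fit_on_normalized_axes(self):
        samples = self.make_samples(1.0)
        normalized = ForceEmgSamples(
            muscle="RES",
            force=samples.force / samples.force.max(),
            envelope=samples.envelope / samples.envelope.max(),
            speed=60.0,
        )
        specific = ll.fit_relationship(normalized, "linear")
        general = ll.build_general_relationship([samples, samples], "linear")
        assert general.a == pytest.approx(specific.a, abs=1e-12)
        assert general.b == pytest.approx(specific.b, abs=1e-12)

    def test_gain_differences_vanish_under_normalization(self):
        # identical shape, 5x gain: the pooled normalized fit is exact
        general = ll.build_general_relationship(
            [self.make_samples(1.0), self.make_samples(5.0)], "linear"
        )
        assert general.rss == pytest.approx(0.0, abs=1e-16)

    def test_shape_heterogeneity_penalizes_the_general_fit(self, clean_config):
        datasets = [
            ll.generate_subject_dataset(clean_config, i, speeds=[60.0], include_slss=False)
            for i in range(clean_config.n_subjects)
        ]
        calibrations = []
        for ds in datasets:
            baselines = {ch: ll.compute_rest_baseline(tr) for ch, tr in ds.rest.items()}
            calibrations.append(
                (ds.subject.subject_id, ll.calibrate_subject(ds.subject, ds.vcts, baselines))
            )
        _, records = ll.population_error_records(calibrations, speeds=[60.0])
        import pandas as pd

        means = pd.DataFrame(records).groupby("specificity")["percent_error"].mean()
        assert means["specific"] < means["general"]

    def test_zero_maximum_subject_excluded_with_warning(self):
        good = self.make_samples(1.0)
        dead = ForceEmgSamples(
            muscle="RES", force=np.zeros(10), envelope=np.linspace(0.1, 1, 10), speed=60.0
        )
        with pytest.warns(UserWarning):
            general = ll.build_general_relationship([good, good, dead], "linear")
        assert general.n == 2 * good.n


class TestScoring:
    def test_perfect_predictions_score_zero(self):
        s = np.linspace(0.1, 1.0, 20)
        samples = ForceEmgSamples(muscle="RES", force=3.0 * s, envelope=s, speed=60.0)
        rel = ll.fit_relationship(samples, "linear")
        assert ll.percent_error(rel, samples) == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_percent_error(self):
        rel = ll.ForceEmgRelationship(
            muscle="RES", form="linear", specificity="specific", speed=60.0, a=0.0, b=1.0
        )
        samples = ForceEmgSamples(
            muscle="RES", force=np.array([10.0, 20.0]), envelope=np.array([11.0, 18.0]),
            speed=60.0,
        )
        # predictions are the envelopes themselves: errors 1 and 2 over max 20
        assert ll.percent_error(rel, samples) == pytest.approx(7.5)

    def test_scale_invariance(self):
        rel = ll.ForceEmgRelationship(
            muscle="RES", form="linear", specificity="specific", speed=60.0, a=0.0, b=2.0
        )
        s = np.array([1.0, 2.0, 3.0])
        small = ForceEmgSamples(muscle="RES", force=2.2 * s, envelope=s, speed=60.0)
        # forces and predictions both scaled 10x leave the score unchanged
        big = ForceEmgSamples(muscle="RES", force=22.0 * s, envelope=s, speed=60.0)
        big_rel = ll.ForceEmgRelationship(
            muscle="RES", form="linear", specificity="specific", speed=60.0, a=0.0, b=20.0
        )
        assert ll.percent_error(rel, small) == pytest.approx(ll.percent_error(big_rel, big))

    def test_all_zero_forces_rejected(self):
        rel = ll.ForceEmgRelationship(
            muscle="RES", form="linear", specificity="specific", speed=60.0, a=0.0, b=1.0
        )
        samples = ForceEmgSamples(
            muscle="RES", force=np.zeros(5), envelope=np.linspace(0.1, 1, 5), speed=60.0
        )
        with pytest.raises(InputError):
            ll.percent_error(rel, samples)

    @pytest.mark.parametrize(
        "errors,expected",
        [
            ({"linear": 17.0, "logarithmic": 22.0}, "linear"),
            ({"linear": 18.0, "logarithmic": 13.0}, "logarithmic"),
            ({"linear": 15.0, "logarithmic": 15.0}, "linear"),
        ],
    )
    def test_lowest_error_form_selected_with_linear_tiebreak(self, errors, expected):
        assert ll.select_best_relationship(errors) == expected

    def test_incomplete_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            ll.select_best_relationship({"linear": 10.0})
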