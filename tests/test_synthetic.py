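"""Generator: waveform template, sensor projection, cohort statistics."""

import math

import numpy as np
import pytest

import solegrf.preprocessing as pp
import solegrf.synthetic as sy
from solegrf.evaluation import variability_summary
from solegrf.synthetic import (CROSS_STEP, MOVEMENTS, SIDE_STEP, STRAIGHT,
                               DomainError, GeneratorConfig, WaveformParams,
                               activation_windows, generate_dataset,
                               generate_trial, grf_template,
                               sensor_projection, x_additive_sds)


class TestTemplate:
    @pytest.mark.parametrize("movement", list(MOVEMENTS.values()),
                             ids=lambda m: m.label)
    @pytest.mark.parametrize("s", [0.0, 1.0])
    def test_zero_at_stance_endpoints(self, movement, s):
        assert np.allclose(grf_template(movement, s, 70.0), 0.0)

    def test_midstance_vertical_value_frozen(self):
        # direct evaluation of the two-peak-minus-valley expression
        expected = 58 * 9.81 * (1.1 * math.exp(-0.5 * ((0.5 - 0.25) / 0.18) ** 2)
                                + 1.1 * math.exp(-0.5 * ((0.5 - 0.75) / 0.18) ** 2)
                                - 0.4)
        got = grf_template(STRAIGHT, 0.5, 58.0)
        assert got[2] == pytest.approx(expected, rel=1e-12)
        assert got[2] == pytest.approx(249.5415695201, rel=1e-9)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            grf_template(STRAIGHT, -0.01, 58.0)
        with pytest.raises(DomainError):
            grf_template(STRAIGHT, 1.01, 58.0)
        with pytest.raises(DomainError):
            grf_template(STRAIGHT, 0.5, -3.0)

    def test_vertical_force_nonnegative_and_double_peaked(self):
        s = np.linspace(0, 1, 501)
        fz = grf_template(STRAIGHT, s, 58.0)[:, 2]
        assert np.all(fz >= 0)
        mid = fz[240:260].min()
        peak1, peak2 = fz[:250].max(), fz[250:].max()
        assert mid < 0.6 * min(peak1, peak2)  # loading/push-off peaks with valley

    def test_turn_offset_flips_sign_only(self):
        s = np.linspace(0, 1, 101)
        fx_side = grf_template(SIDE_STEP, s, 58.0)[:, 0]
        fx_cross = grf_template(CROSS_STEP, s, 58.0)[:, 0]
        fx_straight = grf_template(STRAIGHT, s, 58.0)[:, 0]
        # side + cross = 2 × straight base; the turn bumps cancel exactly
        assert np.allclose(fx_side + fx_cross, 2 * fx_straight, atol=1e-9)
        assert not np.allclose(fx_side, fx_cross)


class TestSensorProjection:
    def test_windows_partition_unity(self):
        s = np.linspace(0, 1, 300)
        w = activation_windows(s)
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(w >= 0)

    def test_vertical_channels_conserve_force(self):
        s = np.linspace(0, 1, 200)
        grf = grf_template(SIDE_STEP, s, 65.0)
        ch = sensor_projection(grf, s)
        assert np.allclose(ch[:, 8:12].sum(axis=1), grf[:, 2], atol=1e-9)

    def test_zero_vertical_force_zero_vertical_channels(self):
        grf = np.array([[5.0, -3.0, 0.0]])
        ch = sensor_projection(grf, np.array([0.4]))
        assert np.allclose(ch[0, 8:12], 0.0)

    def test_noise_level_matches_analytic_prediction(self, rng):
        """Monte-Carlo SD of the summed-vertical deviation vs closed form."""
        s = np.linspace(0, 1, 200)
        grf = grf_template(STRAIGHT, s, 58.0)
        clean = sensor_projection(grf, s)
        ranges = clean.max(axis=0) - clean.min(axis=0)
        predicted = 0.02 * np.sqrt(np.sum(ranges[8:12] ** 2))
        devs = []
        for _ in range(50):  # 50×200 = 10^4 draws
            noisy = sensor_projection(grf, s, rng, 0.02)
            devs.append(noisy[:, 8:12].sum(axis=1) - grf[:, 2])
        observed = np.std(np.concatenate(devs))
        assert observed == pytest.approx(predicted, rel=0.20)

    def test_grf_recoverable_from_channels(self):
        """The 12→3 projection is full-rank (least-squares invertible) at
        every stance fraction in the interior — the premise that makes the
        regression stages meaningful."""
        for s in np.linspace(0.05, 0.95, 31):
            M = np.column_stack([
                sensor_projection(np.eye(3)[d][None, :], np.array([s]))[0]
                for d in range(3)])
            sv = np.linalg.svd(M, compute_uv=False)
            assert sv[-1] > 1e-3 * sv[0]


class TestCohort:
    def test_trial_counts(self):
        cfg = GeneratorConfig(n_participants=2, steps_per_movement=3)
        assert len(generate_dataset(cfg)) == 2 * 3 * 3

    def test_determinism(self):
        cfg = GeneratorConfig(n_participants=1, steps_per_movement=2,
                              master_seed=9)
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.sensor, tb.sensor)
            assert np.array_equal(ta.forceplate, tb.forceplate)
            assert np.array_equal(ta.markers, tb.markers)
            assert ta.truth_heading_deg == tb.truth_heading_deg

    def test_disjoint_master_seeds_give_disjoint_trial_seeds(self):
        cfg1 = GeneratorConfig(n_participants=2, steps_per_movement=2,
                               master_seed=1)
        cfg2 = GeneratorConfig(n_participants=2, steps_per_movement=2,
                               master_seed=2)
        seeds1 = {t.seed for t in generate_dataset(cfg1)}
        seeds2 = {t.seed for t in generate_dataset(cfg2)}
        assert not (seeds1 & seeds2)

    def test_stream_invariants(self):
        cfg = GeneratorConfig(n_participants=1, steps_per_movement=1,
                              master_seed=4)
        trial = generate_dataset(cfg)[0]
        assert np.all(trial.forceplate[:, 2] >= 0)
        # padding stays strictly sub-threshold on both streams
        t_s = np.arange(trial.sensor.shape[0]) / trial.sensor_fs
        pad_s = (t_s < trial.truth_stance_start - 0.01) | \
                (t_s > trial.truth_stance_start + trial.truth_stance_duration + 0.01)
        assert np.all(np.abs(trial.sensor[pad_s, 8:12].sum(axis=1)) < 15.0)
        t_p = np.arange(trial.forceplate.shape[0]) / trial.plate_fs
        pad_p = (t_p < trial.truth_stance_start - 0.01) | \
                (t_p > trial.truth_stance_start + trial.truth_stance_duration + 0.01)
        assert np.all(trial.forceplate[pad_p, 2] < 50.0)

    def test_mass_within_bounds(self):
        cfg = GeneratorConfig(n_participants=12, steps_per_movement=1,
                              master_seed=11)
        for t in generate_dataset(cfg):
            lo, hi = cfg.mass_bounds
            assert lo <= t.participant.body_mass <= hi

    def test_straight_trial_lab_equals_shoe_frame(self):
        """With zero heading the plate stream is the shoe-frame template."""
        cfg = GeneratorConfig(n_participants=1, steps_per_movement=1,
                              movements=("straight",), heading_noise_sd=0.0,
                              sensor_noise_sd=0.0, master_seed=5)
        trial = generate_dataset(cfg)[0]
        t_p = np.arange(trial.forceplate.shape[0]) / trial.plate_fs
        mask = (t_p >= trial.truth_stance_start) & \
               (t_p <= trial.truth_stance_start + trial.truth_stance_duration)
        s = (t_p[mask] - trial.truth_stance_start) / trial.truth_stance_duration
        tmpl = grf_template(trial.movement, s, trial.participant.body_mass,
                            trial.truth_scale, cfg.waveform,
                            trial.truth_x_additive)
        assert np.allclose(trial.forceplate[mask], tmpl, atol=1e-9)


class TestVariabilityCalibration:
    def test_x_variability_matches_targets_and_ordering(self):
        """Cohort-level mediolateral variability reproduces the calibration
        targets (±30%, averaged over 3 cohorts of 8×10) and the ordering
        cross-step > side-step ≈ straight."""
        acc_b = {m: [] for m in MOVEMENTS}
        acc_w = {m: [] for m in MOVEMENTS}
        for seed in (1, 2, 3):
            cfg = GeneratorConfig(n_participants=8, steps_per_movement=10,
                                  master_seed=seed)
            steps = pp.preprocess_trials(generate_dataset(cfg))
            v = variability_summary(steps)
            for _, r in v[v.direction == "x"].iterrows():
                acc_b[r.movement].append(r.between_sd)
                acc_w[r.movement].append(r.within_sd)
        between = {m: np.mean(acc_b[m]) for m in acc_b}
        within = {m: np.mean(acc_w[m]) for m in acc_w}
        for mov, target in sy.X_BETWEEN_SD_TARGET.items():
            assert between[mov] == pytest.approx(target, rel=0.30)
        for mov, target in sy.X_WITHIN_SD_TARGET.items():
            assert within[mov] == pytest.approx(target, rel=0.30)
        assert between["cross_step"] > max(between["side_step"],
                                           between["straight"])
        assert within["cross_step"] > within["side_step"] > within["straight"]

    def test_additive_sd_solves_calibration_identity(self):
        """The additive-coefficient SDs invert the mean-over-stance map."""
        between, within = x_additive_sds()
        p = WaveformParams()
        s = np.linspace(0, 1, 2001)
        shape_b = np.exp(-0.5 * ((s - sy.X_BETWEEN_SHAPE[0])
                                 / sy.X_BETWEEN_SHAPE[1]) ** 2)
        taper = sy._taper(s, p.taper_frac)
        for mov, sd in between.items():
            implied = 9.81 * sd * np.mean(shape_b * taper)
            assert implied == pytest.approx(sy.X_BETWEEN_SD_TARGET[mov], rel=1e-6)
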