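"""Synthetic cohort generator: schedule, input function, kinetics, noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from renalpet import (
    CONTROL_INPUT,
    DEFAULT_PRESETS,
    FrameSchedule,
    GroupPreset,
    InputFunctionModel,
    TimeActivityCurve,
    add_noise,
    export_cohort,
    make_input_function,
    read_tac,
    simulate_bladder_tac,
    simulate_cohort,
    simulate_tissue_tac,
    write_tac,
)
from renalpet.cohort import ValidationError


class TestFrameSchedule:
    def test_default_schedule_has_33_contiguous_frames_over_90_min(self, schedule):
        assert schedule.count == 33
        assert schedule.span_s == 5400.0
        np.testing.assert_allclose(
            schedule.frame_start_s[1:],
            schedule.frame_start_s[:-1] + schedule.frame_duration_s[:-1],
        )

    def test_rejects_overlapping_or_nonpositive_frames(self):
        with pytest.raises(ValidationError):
            FrameSchedule(np.array([0.0, 5.0]), np.array([6.0, 6.0]))
        with pytest.raises(ValidationError):
            FrameSchedule(np.array([0.0, 6.0]), np.array([6.0, 0.0]))

    def test_file_roundtrip(self, schedule, tmp_path):
        schedule.to_file(tmp_path / "frames.csv")
        back = FrameSchedule.from_file(tmp_path / "frames.csv")
        np.testing.assert_allclose(back.frame_start_s, schedule.frame_start_s)


class TestInputFunction:
    def test_zero_before_delay_and_nonnegative(self, control_input):
        t = np.linspace(0.0, 90.0, 5001)
        vals = control_input(t)
        assert np.all(vals[t < control_input.delay_min] == 0)
        assert np.all(vals >= 0)

    def test_rate_constants_must_be_positive(self):
        with pytest.raises(ValidationError):
            InputFunctionModel((1.0, 1.0, 1.0), (1.0, -0.5, 0.1))

    def test_curve_negativity_is_rejected(self):
        # dominant negative slow term drives the curve below zero
        with pytest.raises(ValidationError):
            InputFunctionModel((1.0, -5.0, 0.0), (5.0, 0.1, 1.0))

    def test_analytic_auc_matches_quadrature(self, control_input):
        oracle, _ = integrate.quad(control_input, 0.0, 90.0, limit=500)
        assert control_input.auc(0.0, 90.0) == pytest.approx(oracle, rel=1e-8)

    def test_frame_average_matches_quadrature(self, control_input, schedule):
        means = control_input.frame_average(schedule)
        for i in [0, 1, 5, 12, 20, 32]:
            a = schedule.frame_start_s[i] / 60.0
            b = schedule.frame_end_s[i] / 60.0
            oracle, _ = integrate.quad(control_input, a, b, limit=200)
            assert means[i] == pytest.approx(oracle / (b - a), abs=1e-9, rel=1e-8)


class TestMakeInputFunction:
    def test_identity_for_unit_plasma_scale(self, control_input):
        model = make_input_function(DEFAULT_PRESETS["control"])
        assert model.amplitudes == control_input.amplitudes

    @pytest.mark.parametrize("preset_name,scale", [("tg", 1.8), ("pyrimethamine", 1 / 1.1)])
    def test_auc_scales_with_plasma_scale(self, control_input, preset_name, scale):
        scaled = make_input_function(DEFAULT_PRESETS[preset_name])
        num = integrate.quad(scaled, 0.0, 90.0, limit=500)[0]
        den = integrate.quad(control_input, 0.0, 90.0, limit=500)[0]
        assert num / den == pytest.approx(scale, rel=1e-8)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValidationError):
            GroupPreset("bad", 1, 0.8, 0.15, plasma_scale=0.0)


class TestSimulateTissueTac:
    def test_zero_input_gives_zero_tac(self, schedule):
        zero = InputFunctionModel((0.0, 0.0, 0.0), (1.0, 2.0, 3.0))
        tac = simulate_tissue_tac(zero, 0.8, 0.15, schedule)
        assert np.all(tac.values == 0)

    def test_constant_input_plateau_closed_form(self, schedule):
        # lambda -> 0 makes the input effectively constant at C0
        c0 = 3.0
        const = InputFunctionModel((c0, 0.0, 0.0), (1e-9, 1.0, 1.0), delay_min=0.0)
        tac = simulate_tissue_tac(const, 0.8, 0.15, schedule)
        t = schedule.mid_min

        def closed(t):
            return (0.8 * c0 / 0.15) * (1 - np.exp(-0.15 * t))

        # frame means of the closed form, analytic
        a, b = schedule.frame_start_s / 60, schedule.frame_end_s / 60
        mean_cf = (0.8 * c0 / 0.15) * (
            (b - a) + (np.exp(-0.15 * b) - np.exp(-0.15 * a)) / 0.15
        ) / (b - a)
        np.testing.assert_allclose(tac.values, mean_cf, rtol=1e-6)
        assert tac.values[-1] == pytest.approx(0.8 * c0 / 0.15, rel=1e-4)  # plateau 5.333*C0

    def test_irreversible_trapping_limit_matches_quadrature(self, control_input, schedule):
        tac = simulate_tissue_tac(control_input, 0.5, 0.0, schedule)
        for i in [3, 10, 25, 32]:
            a = schedule.frame_start_s[i] / 60.0
            b = schedule.frame_end_s[i] / 60.0
            oracle = integrate.quad(lambda t: control_input.integral(t), a, b, limit=200)[0]
            assert tac.values[i] == pytest.approx(0.5 * oracle / (b - a), rel=1e-7)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(c=st.floats(min_value=0.1, max_value=10.0))
    def test_scaling_input_scales_tissue_linearly(self, c):
        sched = FrameSchedule.default()
        base = simulate_tissue_tac(CONTROL_INPUT, 0.8, 0.15, sched)
        scaled = simulate_tissue_tac(CONTROL_INPUT.scaled(c), 0.8, 0.15, sched)
        np.testing.assert_allclose(scaled.values, c * base.values, rtol=1e-9)


class TestAddNoise:
    def test_zero_noise_is_identity(self, constant_tac):
        out = add_noise(constant_tac, 0.0, seed=1)
        assert out is constant_tac

    def test_same_seed_is_bitwise_identical(self, constant_tac):
        a = add_noise(constant_tac, 1.0, seed=42)
        b = add_noise(constant_tac, 1.0, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_empirical_sd_matches_model(self, schedule):
        # one frame examined over 1000 replicates against sigma = ns*sqrt(v/dur)
        v, frame = 10.0, 20  # 60-s frame
        tac = TimeActivityCurve(schedule, np.full(schedule.count, v))
        draws = np.array([add_noise(tac, 1.0, seed=s).values[frame] for s in range(1000)])
        sigma = np.sqrt(v / schedule.frame_duration_s[frame])
        assert draws.std(ddof=1) == pytest.approx(sigma, rel=0.05)


class TestSimulateCohort:
    def test_empty_cohort(self):
        assert simulate_cohort(DEFAULT_PRESETS["wt"], 0, seed=1) == []

    def test_negative_n_rejected(self):
        with pytest.raises(ValidationError):
            simulate_cohort(DEFAULT_PRESETS["wt"], -1, seed=1)

    def test_fixed_seed_reproduces_cohort(self):
        a = simulate_cohort(DEFAULT_PRESETS["tg"], 3, seed=9)
        b = simulate_cohort(DEFAULT_PRESETS["tg"], 3, seed=9)
        for sa, sb in zip(a, b):
            assert sa.record == sb.record
            assert np.array_equal(sa.idif.values, sb.idif.values)
            assert np.array_equal(sa.cortex_left.values, sb.cortex_left.values)

    def test_adding_subjects_never_perturbs_existing_ones(self):
        small = simulate_cohort(DEFAULT_PRESETS["wt"], 2, seed=5)
        large = simulate_cohort(DEFAULT_PRESETS["wt"], 4, seed=5)
        for s, l in zip(small, large):
            assert np.array_equal(s.idif.values, l.idif.values)

    def test_noiseless_cortex_reproduces_forward_model(self):
        p = DEFAULT_PRESETS["wt"]
        quiet = GroupPreset(p.name, 1, p.true_K1, p.true_k2, p.plasma_scale, 0.0)
        subj = simulate_cohort(quiet, 1, seed=2)[0]
        oracle = simulate_tissue_tac(subj.input_model, p.true_K1, p.true_k2, subj.idif.schedule)
        np.testing.assert_allclose(subj.cortex_left.values, oracle.values, rtol=1e-12)

    def test_body_weight_and_dose_within_truncation(self):
        cohort = simulate_cohort(DEFAULT_PRESETS["tg"], 8, seed=11)
        for s in cohort:
            assert s.record.body_weight_g > 15.0
            assert s.record.injected_dose_kBq > 1000.0


class TestBladder:
    def test_bladder_accumulates_monotonically(self, control_input, schedule):
        tac = simulate_bladder_tac(control_input, schedule)
        assert np.all(np.diff(tac.values) >= -1e-12)


class TestTacIO:
    def test_tac_file_roundtrip(self, tmp_path, schedule):
        tac = TimeActivityCurve(schedule, np.linspace(0, 5, schedule.count), "idif")
        write_tac(tac, tmp_path / "t.csv")
        back = read_tac(tmp_path / "t.csv")
        np.testing.assert_array_equal(back.values, tac.values)
        np.testing.assert_array_equal(back.schedule.frame_start_s, schedule.frame_start_s)

    def test_export_cohort_writes_manifest_truth_and_tacs(self, tmp_path):
        cohort = simulate_cohort(DEFAULT_PRESETS["wt"], 2, seed=3)
        out = export_cohort(cohort, tmp_path / "wt", seed=3)
        assert (out / "manifest.csv").exists()
        assert (out / "ground_truth.csv").exists()
        assert (out / "presets.json").exists()
        assert (out / "wt-01_idif.csv").exists()
        assert (out / "wt-02_kidney_cortex_r.csv").exists()
        back = read_tac(out / "wt-01_idif.csv")
        np.testing.assert_array_equal(back.values, cohort[0].idif.values)
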