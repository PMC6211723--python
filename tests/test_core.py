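import numpy as np
import pytest

from covertest import (
    GazeRecording,
    ParameterError,
    Phase,
    PipelineConfig,
    ScheduleError,
    SimulationConfig,
    TestSchedule,
    aggregate,
    classify_direction,
    default_schedule,
    deg_to_pd,
    occlusion_phoria,
    pd_to_deg,
    phase_position,
    run_covertest,
    simulate_recording,
)
from covertest.core import OcclusionMeasurement, PhaseEstimate

from conftest import make_recording, piecewise_trace


def estimate(posL, posR, phase=None, q=1.0):
    phase = phase or Phase("binocular", 0.0, 5.0)
    return PhaseEstimate(phase=phase, posL=posL, posR=posR, qualityL=q, qualityR=q)


class TestDefaultSchedule:
    def test_three_cycles_give_twelve_phases_sixty_seconds(self):
        sched = default_schedule()
        assert len(sched.phases) == 12
        assert len(sched.occlusions) == 6
        assert sum(p.kind == "occlude_left" for p in sched.phases) == 3
        assert sum(p.kind == "occlude_right" for p in sched.phases) == 3
        assert sched.duration == pytest.approx(60.0)

    def test_cycle_order(self):
        sched = default_schedule(cycles=1)
        assert [p.kind for p in sched.phases] == [
            "binocular", "occlude_left", "binocular", "occlude_right",
        ]

    def test_zero_cycles_rejected(self):
        with pytest.raises(ParameterError):
            default_schedule(cycles=0)

    def test_phases_contiguous(self):
        sched = default_schedule()
        for a, b in zip(sched.phases, sched.phases[1:]):
            assert a.end == pytest.approx(b.onset)

    def test_non_contiguous_schedule_rejected(self):
        with pytest.raises(ScheduleError):
            TestSchedule(
                phases=(Phase("binocular", 0, 5), Phase("occlude_left", 6, 5)),
                cycles=1,
            )


class TestPhasePosition:
    def test_constant_window(self):
        x = np.full(2500, 1.5)
        rec = make_recording(x, -x)
        est = phase_position(rec, Phase("binocular", 0.0, 10.0))
        assert est.posL == pytest.approx(1.5)
        assert est.posR == pytest.approx(-1.5)
        assert est.quality == 1.0

    def test_even_count_median_is_mean_of_central_pair(self):
        # 8 Hz recording: the 0.5 s window holds exactly 4 samples
        vals = [0.9, 1.0, 1.1, 5.0]
        x = np.array([0.0] * 4 + vals)
        rec = make_recording(x, x.copy(), rate=8.0)
        est = phase_position(rec, Phase("binocular", 0.0, 1.0), window=0.5)
        oracle = np.sort(vals)
        assert est.posL == pytest.approx((oracle[1] + oracle[2]) / 2.0)  # 1.05

    def test_interpolated_samples_lower_quality_below_threshold(self):
        x = np.zeros(2500)
        rec = make_recording(x, x.copy())
        n = rec.n
        interp = np.zeros(n, dtype=bool)
        interp[-75:] = True  # 60% of the 125-sample window
        rec = GazeRecording(
            t=rec.t, xL=rec.xL, xR=rec.xR, validL=rec.validL, validR=rec.validR,
            rate=rec.rate, interpL=interp, interpR=np.zeros(n, dtype=bool),
        )
        est = phase_position(rec, Phase("binocular", 0.0, 10.0), min_quality=0.5)
        assert est.posL is None and est.qualityL == pytest.approx(0.4)
        assert est.posR is not None

    def test_phase_outside_recording_is_error(self):
        rec = make_recording(np.zeros(250), np.zeros(250))
        with pytest.raises(ScheduleError):
            phase_position(rec, Phase("binocular", 0.0, 5.0))


class TestOcclusionPhoria:
    def test_left_occlusion_esophoria_positive(self):
        occ = estimate(1.146, 0.0, Phase("occlude_left", 5.0, 5.0))
        m = occlusion_phoria(estimate(0.0, 0.0), occ, "left")
        oracle = 100.0 * np.tan(np.radians(1.146))
        assert m.het_1eye == pytest.approx(oracle)  # ~2.00 PD eso
        assert m.het_2eyes == pytest.approx(oracle)
        assert m.valid

    def test_right_occlusion_temporal_movement_is_exophoria(self):
        occ = estimate(0.0, 1.146, Phase("occlude_right", 5.0, 5.0))
        m = occlusion_phoria(estimate(0.0, 0.0), occ, "right")
        assert m.het_1eye == pytest.approx(-100.0 * np.tan(np.radians(1.146)))
        assert m.het_1eye < 0  # exo

    def test_conjugate_movement_is_invalid(self):
        occ = estimate(1.0, 1.0, Phase("occlude_left", 5.0, 5.0))
        m = occlusion_phoria(estimate(0.0, 0.0), occ, "left")
        assert not m.valid
        assert m.reason is not None

    def test_same_direction_fixation_disparity_adds(self):
        occ = estimate(1.0, 0.1, Phase("occlude_left", 5.0, 5.0))
        m = occlusion_phoria(estimate(0.0, 0.0), occ, "left")
        assert abs(m.het_2eyes) > abs(m.het_1eye)
        assert m.het_2eyes == pytest.approx(deg_to_pd(1.1))

    def test_opposite_direction_fixation_disparity_subtracts(self):
        occ = estimate(1.0, -0.1, Phase("occlude_left", 5.0, 5.0))
        m = occlusion_phoria(estimate(0.0, 0.0), occ, "left")
        assert abs(m.het_2eyes) < abs(m.het_1eye)

    def test_missing_phase_gives_invalid_with_reason(self):
        occ = estimate(None, 0.0, Phase("occlude_left", 5.0, 5.0))
        m = occlusion_phoria(estimate(0.0, 0.0), occ, "left")
        assert not m.valid and m.reason == "missing phase"
        assert m.het_1eye is None

    def test_angles_summed_before_tangent(self):
        occ = estimate(3.0, 2.0, Phase("occlude_left", 5.0, 5.0))
        m = occlusion_phoria(estimate(0.0, 0.0), occ, "left")
        assert m.het_2eyes == pytest.approx(100.0 * np.tan(np.radians(5.0)))
        assert m.het_2eyes != pytest.approx(deg_to_pd(3.0) + deg_to_pd(2.0), abs=1e-6)

    def test_large_fixating_displacement_sets_tropia_flag(self):
        occ = estimate(3.0, 1.0, Phase("occlude_left", 5.0, 5.0))
        m = occlusion_phoria(estimate(0.0, 0.0), occ, "left")
        assert m.valid and m.tropia_flag


class TestAggregate:
    def _measurement(self, value, eye="left", valid=True):
        return OcclusionMeasurement(
            occluded_eye=eye, het_1eye=value, het_2eyes=value,
            disp_occluded=pd_to_deg(value), disp_fixating=0.0, valid=valid,
        )

    def test_median_of_six(self):
        vals = [-2.1, -1.9, -2.0, -2.3, -1.8, -2.2]
        ms = [
            self._measurement(v, eye=("left" if i % 2 else "right"))
            for i, v in enumerate(vals)
        ]
        res = aggregate(ms)
        assert res.het_2eyes == pytest.approx(-2.05)
        assert res.het_1eye == pytest.approx(-2.05)
        assert res.n_valid == 6
        assert res.direction == "exo"

    def test_per_eye_medians_split_by_occluded_eye(self):
        ms = [self._measurement(v, eye="left") for v in (-2.0, -2.1, -2.2)]
        ms += [self._measurement(v, eye="right") for v in (-1.0, -1.1, -1.2)]
        res = aggregate(ms)
        assert res.het_LE == pytest.approx(-2.1)
        assert res.het_RE == pytest.approx(-1.1)

    def test_invalid_measurements_excluded(self):
        ms = [self._measurement(v) for v in (-2.1, -1.9, -2.0, -2.3, -1.8)]
        ms.append(self._measurement(50.0, valid=False))
        res = aggregate(ms)
        assert res.het_2eyes == pytest.approx(-2.0)
        assert res.n_valid == 5

    def test_zero_valid_is_no_measurement(self):
        res = aggregate([self._measurement(1.0, valid=False)])
        assert res.status == "no_measurement"
        assert res.het_2eyes is None and res.direction is None

    def test_empty_list_rejected(self):
        with pytest.raises(ParameterError):
            aggregate([])

    def test_sign_disagreement_above_threshold_is_inconsistent(self):
        ms = [self._measurement(v) for v in (3.0, -3.0, 2.0, -2.0)]
        assert aggregate(ms).direction == "inconsistent"

    def test_sign_disagreement_below_threshold_is_not_inconsistent(self):
        ms = [self._measurement(v) for v in (0.5, -0.4, 0.3, -0.2)]
        assert aggregate(ms).direction == "ortho"

    def test_median_robust_to_one_corrupted_value(self):
        vals = [-2.1, -1.9, -2.0, -2.3, -1.8, -2.2]
        ms = [self._measurement(v) for v in vals]
        corrupted = ms[:5] + [self._measurement(40.0)]
        res = aggregate(corrupted)
        assert min(vals[:5]) <= res.het_2eyes <= max(vals[:5])


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "het,expected",
        [(0.99, "ortho"), (-0.99, "ortho"), (1.0, "eso"), (-1.0, "exo"),
         (14.0, "eso"), (-14.0, "exo"), (0.0, "ortho")],
    )
    def test_threshold_boundaries(self, het, expected):
        assert classify_direction(het) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ParameterError):
            classify_direction(float("nan"))


class TestRunCovertest:
    def test_noiseless_simulation_recovers_truth(self, schedule):
        cfg = SimulationConfig(
            true_phoria=-4.0, noise_sd=0.0, hering_gain=0.0, blink_rate=0.0, seed=7
        )
        rec, _ = simulate_recording(schedule, cfg)
        res = run_covertest(rec, schedule)
        # residual of the exponential approach over the last-0.5-s window
        assert res.het_2eyes == pytest.approx(-4.0, abs=0.05)
        assert res.direction == "exo"
        assert res.n_valid == 6

    def test_recording_shorter_than_schedule_is_error(self, schedule):
        rec = make_recording(np.zeros(2500), np.zeros(2500))
        with pytest.raises(ScheduleError):
            run_covertest(rec, schedule)

    def test_conjugate_saccades_without_phoria_give_no_measurement(self, schedule):
        def fn(phase, tl):
            if phase.kind == "binocular":
                return np.zeros_like(tl)
            return np.where(tl >= 2.0, 2.0, 0.0)  # 2 deg conjugate jump

        rec = piecewise_trace(schedule, 250.0, fn, fn)
        res = run_covertest(rec, schedule)
        assert res.status == "no_measurement" or abs(res.het_2eyes) < 0.1

    def test_method_equivalence_when_fixating_eye_static(self, schedule):
        def left(phase, tl):
            return np.full_like(tl, 1.5) if phase.kind == "occlude_left" else np.zeros_like(tl)

        def right(phase, tl):
            return np.full_like(tl, -1.5) if phase.kind == "occlude_right" else np.zeros_like(tl)

        rec = piecewise_trace(schedule, 250.0, left, right)
        res = run_covertest(rec, schedule)
        for m in res.per_occlusion:
            assert m.het_1eye == pytest.approx(m.het_2eyes, abs=1e-9)
        assert res.het_1eye == pytest.approx(res.het_2eyes, abs=1e-9)

    def test_eye_swap_antisymmetry(self, schedule):
        cfg = SimulationConfig(
            true_phoria=-6.0, phoria_asymmetry=1.0, fixation_disparity_L=0.1,
            fixation_disparity_R=-0.08, noise_sd=0.05, hering_gain=0.05,
            blink_rate=0.0, seed=11,
        )
        rec, _ = simulate_recording(schedule, cfg)
        res = run_covertest(rec, schedule)
        mirrored = make_recording(-rec.xR, -rec.xL, rate=rec.rate)
        swap = {"occlude_left": "occlude_right", "occlude_right": "occlude_left",
                "binocular": "binocular"}
        msched = TestSchedule(
            phases=tuple(
                Phase(swap[p.kind], p.onset, p.duration) for p in schedule.phases
            ),
            cycles=schedule.cycles,
        )
        mres = run_covertest(mirrored, msched)
        assert mres.het_1eye == pytest.approx(res.het_1eye, abs=1e-9)
        assert mres.het_2eyes == pytest.approx(res.het_2eyes, abs=1e-9)

    def test_min_valid_config_controls_no_measurement(self, schedule):
        cfg = SimulationConfig(true_phoria=0.0, noise_sd=0.0, hering_gain=0.0,
                               blink_rate=0.0, seed=5)
        rec, _ = simulate_recording(schedule, cfg)
        # zero phoria, zero noise: |d_occ| > |d_fix| is never strict
        res = run_covertest(rec, schedule, PipelineConfig(min_valid=1))
        assert res.status == "no_measurement"
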