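import numpy as np
import pytest

from neckservo import (
    HeadGeometry,
    PlantParams,
    RotationProfile,
    SlowRotationSpec,
    SuppressionParams,
    SwitchConfig,
    damping_ratio,
    eccentric_inertia,
    gain_scheduling_prediction,
    make_slow_rotation,
    simulate,
    torque_integrals,
)
from neckservo.model import DEG

from conftest import SIM_RATE, zero_profile

LOOPS_OFF = SwitchConfig(prop_loop_on=False, force_loop_on=False, reflex_gain=1.0)


def sinusoid(freq, amp=2.0, duration=2.0, rate=SIM_RATE):
    t = np.arange(int(round(duration * rate)) + 1) / rate
    w = 2 * np.pi * freq
    return RotationProfile(
        t, amp * np.sin(w * t), amp * w * np.cos(w * t), -amp * w**2 * np.sin(w * t), rate
    )


class TestSimulate:
    def test_rest_equilibrium(self):
        trace = simulate(zero_profile())
        assert np.all(trace.torque_net == 0.0)

    def test_component_decomposition(self, static_traces):
        for trace in static_traces.values():
            assert np.max(np.abs(trace.component_sum() - trace.torque_net)) <= 1e-9

    def test_linearity_with_loops_off(self, static_profiles):
        prof = static_profiles["fast"]
        base = simulate(prof, switches=LOOPS_OFF)
        scaled_prof = RotationProfile(
            prof.t, 3.0 * prof.angle, 3.0 * prof.velocity, 3.0 * prof.acceleration,
            prof.sample_rate,
        )
        scaled = simulate(scaled_prof, switches=LOOPS_OFF)
        assert np.allclose(scaled.torque_net, 3.0 * base.torque_net, atol=1e-12)

    def test_time_invariance(self, static_profiles):
        prof = static_profiles["standard"]
        k = 200  # 100 ms at the 2 kHz grid
        shifted_prof = RotationProfile(
            np.arange(len(prof.t) + k) * prof.dt,
            np.concatenate([np.zeros(k), prof.angle]),
            np.concatenate([np.zeros(k), prof.velocity]),
            np.concatenate([np.zeros(k), prof.acceleration]),
            prof.sample_rate,
        )
        base = simulate(prof)
        shifted = simulate(shifted_prof)
        assert np.allclose(shifted.torque_net[k:], base.torque_net, atol=1e-12)
        assert np.allclose(shifted.torque_net[:k], 0.0)

    @pytest.mark.parametrize("freq", [0.1, 0.5, 1.0, 2.0, 5.0])
    def test_oracle_second_order_response(self, freq):
        """Delays off, loops off: output equals -J s^2 - (B+D)s - (K+P)
        acting on the displacement (resistive orientation), to <1% RMS."""
        plant = PlantParams(tau_c=0.0)
        prof = sinusoid(freq, duration=max(2.0, 2.0 / freq))
        trace = simulate(prof, plant, switches=LOOPS_OFF)
        oracle = (
            plant.J_total * prof.acceleration * DEG
            + (plant.K + plant.P) * prof.angle
            + (plant.B + plant.D) * prof.velocity
        )
        rel_rms = np.sqrt(np.mean((trace.torque_net - oracle) ** 2)) / np.sqrt(
            np.mean(oracle**2)
        )
        assert rel_rms < 0.01

    def test_grid_convergence(self, static_profiles):
        """Halving dt from 1 ms to 0.5 ms moves t1/t2 by <1%."""
        for prof in static_profiles.values():
            coarse = torque_integrals(simulate(prof, dt=1e-3))
            fine = torque_integrals(simulate(prof, dt=5e-4))
            assert coarse.t1 == pytest.approx(fine.t1, rel=0.01)
            assert coarse.t2 == pytest.approx(fine.t2, rel=0.01)

    def test_deceleration_dip_all_static_perturbations(self, static_profiles, static_traces):
        """An oppositely directed fast torque variation accompanies every
        deceleration phase: the net torque drops by at least the inertial
        step while the stimulus decelerates."""
        from neckservo import PERTURBATION_METRICS

        plant = PlantParams()
        for name, trace in static_traces.items():
            spec = PERTURBATION_METRICS[name]
            decel = (trace.t >= spec.decel_onset) & (trace.t <= spec.total_duration + 0.05)
            pre = trace.torque_net[np.argmin(np.abs(trace.t - (spec.decel_onset - 0.005)))]
            dip = pre - trace.torque_net[decel].min()
            inertial_step = (
                plant.J_total
                * spec.plateau_velocity
                / (spec.total_duration - spec.decel_onset)
                * DEG
            )
            assert dip > 0.8 * inertial_step

    def test_validation(self, static_profiles):
        prof = static_profiles["fast"]
        with pytest.raises(ValueError):
            simulate(prof, dt=2e-3)
        bad = RotationProfile(
            prof.t, prof.angle.copy(), prof.velocity, prof.acceleration, prof.sample_rate
        )
        bad.angle[5] = np.nan
        with pytest.raises(ValueError):
            simulate(bad)


class TestEccentricInertia:
    def test_centered_sphere(self):
        geom = HeadGeometry(m=4.5, r0=0.0894, r=0.0)
        assert eccentric_inertia(geom) == pytest.approx(0.0144, abs=2e-4)

    def test_offset_term_quadratic(self):
        base = HeadGeometry(m=4.5, r0=0.0894, r=0.05)
        double = HeadGeometry(m=4.5, r0=0.0894, r=0.10)
        sphere = eccentric_inertia(HeadGeometry(m=4.5, r0=0.0894, r=1e-12))
        assert eccentric_inertia(double) - sphere == pytest.approx(
            4 * (eccentric_inertia(base) - sphere), rel=1e-6
        )

    def test_validation(self):
        with pytest.raises(ValueError):
            HeadGeometry(m=-1.0, r0=0.1, r=0.0)


class TestDampingRatio:
    def test_undamped_limit(self):
        assert damping_ratio(PlantParams(B=0.0, D=0.0)) == 0.0

    def test_unit_rescale_invariance(self):
        base = PlantParams()
        scaled = PlantParams(
            P=base.P * 4, D=base.D * 4, K=base.K * 4, B=base.B * 4,
            J_head=base.J_head * 4, J_ecc=base.J_ecc * 4,
        )
        assert damping_ratio(scaled) == pytest.approx(damping_ratio(base), rel=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            damping_ratio(PlantParams(K=0.0, P=0.0))


class TestGainScheduling:
    def test_unit_gain_matches_suppression_off(self, static_profiles):
        prof = static_profiles["standard"]
        a = gain_scheduling_prediction(prof, reflex_gain=1.0)
        b = simulate(prof, switches=LOOPS_OFF)
        assert np.array_equal(a.torque_net, b.torque_net)

    def test_zero_stiffness_limit(self):
        """With zero passive elements and zero reflex gain, the constant
        velocity mid-course of the slow rotation produces ~no torque."""
        prof = make_slow_rotation(SlowRotationSpec(), SIM_RATE)
        plant = PlantParams(K=0.0, B=0.0)
        trace = gain_scheduling_prediction(prof, plant, reflex_gain=0.0)
        mid = np.abs(trace.t - 2.5) < 0.05
        # only the inertial term survives; near t=2.5 s acceleration ~ 0
        assert np.max(np.abs(trace.torque_net[mid])) < 1e-3

    def test_passive_residual_is_nonzero(self):
        prof = make_slow_rotation(SlowRotationSpec(), SIM_RATE)
        trace = gain_scheduling_prediction(prof, reflex_gain=0.0)
        mid = np.abs(trace.t - 2.5) < 0.05
        assert np.min(np.abs(trace.torque_net[mid])) > 0.01
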