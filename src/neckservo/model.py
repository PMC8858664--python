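"""Open-loop neuromechanical plant of the head-neck system.

The head is fixed to a servo-driven holder, so the imposed head-on-trunk
kinematics theta(t) are an *input*, never a state (the voluntary-movement
switch stays open).  Net resistive torque measured at the holder shaft is the
sum of

* an inertial component  J_tot * theta_dd        (theta_dd in rad/s^2),
* a passive viscoelastic component  K*theta + B*theta_d  (deg units),
* a reflexive component from a transport-delayed PD controller standing in
  for the motoneuronal pool driven by the neck-proprioceptive loop, and
* minus the output of a voluntary force-feedback integrator.

Voluntary suppression ("neutralization") enters through two loops:

* a length loop (prop'): the delayed, dead-zoned displacement is subtracted
  from the controller input, cancelling most of the stretch-reflex drive;
* a force loop (force'): the delayed, dead-zoned *measured* net torque drives
  a pure integrator (gain / s) whose state is subtracted from the net torque.

All torques are reported in the resistive-positive orientation (torque
opposing the imposed displacement is positive), matching the convention in
which early/late response integrals are tabulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .stimuli import RotationProfile

__all__ = [
    "PlantParams",
    "SuppressionParams",
    "SwitchConfig",
    "HeadGeometry",
    "TorqueTrace",
    "deadzone",
    "simulate",
    "eccentric_inertia",
    "damping_ratio",
    "gain_scheduling_prediction",
    "DYNAMIC_OVERRIDE",
    "TANGORRA_PLANT",
]

DEG = math.pi / 180.0


def deadzone(x, threshold):
    """Signed dead-zone: sign(x) * max(|x| - threshold, 0)."""
    return np.sign(x) * np.maximum(np.abs(x) - threshold, 0.0)


@dataclass(frozen=True)
class PlantParams:
    """Reflexive + passive + inertial constants of the stretch-reflex loop.

    Defaults are the fitted values: PD controller P = 0.09 Nm/deg,
    D = 0.007 Nm*s/deg with a lumped loop delay of 50 ms; passive stiffness
    0.008 Nm/deg and damping 0.002 Nm*s/deg; head inertia 0.018 kg m^2 plus a
    0.030 kg m^2 eccentricity surplus (cantilevered carriage of the head mass
    off the rotation axis).
    """

    P: float = 0.09
    D: float = 0.007
    tau_c: float = 0.050
    K: float = 0.008
    B: float = 0.002
    J_head: float = 0.018
    J_ecc: float = 0.030

    def __post_init__(self) -> None:
        for name in ("P", "D", "tau_c", "K", "B", "J_head", "J_ecc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def J_total(self) -> float:
        return self.J_head + self.J_ecc


@dataclass(frozen=True)
class SuppressionParams:
    """Thresholds, delays and gains of the voluntary neutralization loops.

    Length loop (prop'): displacement threshold 0.6 deg, delay 70 ms,
    dimensionless gain 0.9.  Force loop (force'): torque threshold 0.02 Nm,
    delay 90 ms, integrator gain 4 /s.
    """

    prop_threshold: float = 0.6
    prop_delay: float = 0.070
    prop_gain: float = 0.9
    force_threshold: float = 0.02
    force_delay: float = 0.090
    force_gain: float = 4.0

    def __post_init__(self) -> None:
        for name in (
            "prop_threshold", "prop_delay", "prop_gain",
            "force_threshold", "force_delay", "force_gain",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: Length-loop adjustment the dynamic (mid-rotation) context calls for:
#: delay reduced to 50 ms, gain raised to 1.1.
DYNAMIC_OVERRIDE = {"prop_delay": 0.050, "prop_gain": 1.1}


def dynamic_suppression(base: SuppressionParams) -> SuppressionParams:
    """Suppression parameters with the dynamic-context length-loop override."""
    return replace(base, **DYNAMIC_OVERRIDE)


#: Alternative passive parametrization (torque-perturbation study): overall
#: stiffness 0.12 Nm/deg, damping 0.006 Nm*s/deg, inertia 0.018 kg m^2.
TANGORRA_PLANT = PlantParams(
    P=0.0, D=0.0, tau_c=0.0, K=0.12, B=0.006, J_head=0.018, J_ecc=0.0
)


@dataclass(frozen=True)
class SwitchConfig:
    """Voluntary-loop switches and the reflex gain-scheduling factor.

    ``reflex_gain`` scales the stretch-reflex (PROP) pathway: 1 is the normal
    reflex, 0 is full gain scheduling.  The two suppression switches engage
    the length (prop') and force (force') neutralization loops.
    """

    prop_loop_on: bool = True
    force_loop_on: bool = True
    reflex_gain: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.reflex_gain <= 1.0:
            raise ValueError("reflex_gain must lie in [0, 1]")


#: Named model variants used in counterfactual comparisons.
VARIANTS = {
    "full": SwitchConfig(True, True, 1.0),
    "force-only": SwitchConfig(False, True, 1.0),
    "length-only": SwitchConfig(True, False, 1.0),
    "gain0": SwitchConfig(False, False, 0.0),
    "reflex": SwitchConfig(False, False, 1.0),
    "passive": SwitchConfig(False, False, 0.0),  # with reflex_gain 0 = passive+inertial
}


@dataclass(frozen=True)
class HeadGeometry:
    """Eccentric-sphere head geometry: mass m, sphere radius r0, axis offset r."""

    m: float
    r0: float
    r: float

    def __post_init__(self) -> None:
        if self.m <= 0 or self.r0 <= 0:
            raise ValueError("mass and radius must be > 0")
        if self.r < 0:
            raise ValueError("axis offset must be >= 0")


def eccentric_inertia(geom: HeadGeometry) -> float:
    """Moment of inertia of a sphere about an axis offset r from its centre.

    J = (2/5) m r0^2 + m r^2.
    """
    return 0.4 * geom.m * geom.r0**2 + geom.m * geom.r**2


def damping_ratio(plant: PlantParams) -> float:
    """Damping ratio of the lumped second-order system, delays neglected.

    zeta = B_tot / (2 sqrt(K_tot J_tot)) with K_tot = (K+P) and B_tot = (B+D)
    converted to per-radian units and J_tot = J_head + J_ecc.
    """
    K_tot = (plant.K + plant.P) / DEG
    B_tot = (plant.B + plant.D) / DEG
    J_tot = plant.J_total
    if K_tot <= 0 or J_tot <= 0:
        raise ValueError("stiffness and inertia must be positive")
    return B_tot / (2.0 * math.sqrt(K_tot * J_tot))


@dataclass(frozen=True)
class TorqueTrace:
    """Net resistive torque with its signed component breakdown (Nm)."""

    t: np.ndarray
    torque_net: np.ndarray
    torque_inertial: np.ndarray
    torque_passive: np.ndarray
    torque_reflex: np.ndarray
    torque_suppression: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in (
            "torque_net", "torque_inertial", "torque_passive",
            "torque_reflex", "torque_suppression",
        ):
            if len(getattr(self, name)) != n:
                raise ValueError("trace channels must share one grid")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    def component_sum(self) -> np.ndarray:
        return (
            self.torque_inertial
            + self.torque_passive
            + self.torque_reflex
            + self.torque_suppression
        )


def _force_loop_py(T_raw, df, frac, dt, gain, threshold):
    n = T_raw.shape[0]
    T_net = np.empty(n)
    x_hist = np.empty(n)
    x = 0.0
    for i in range(n):
        T_net[i] = T_raw[i] - x
        x_hist[i] = x
        # fractional-sample transport delay, linearly interpolated
        a = T_net[i - df] if i >= df else 0.0
        b = T_net[i - df - 1] if i >= df + 1 else 0.0
        src = (1.0 - frac) * a + frac * b
        mag = abs(src) - threshold
        if mag > 0.0:
            x += dt * gain * (mag if src > 0.0 else -mag)
    return T_net, x_hist


try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    _force_loop = njit(cache=True)(_force_loop_py)
except Exception:  # pragma: no cover
    _force_loop = _force_loop_py


def _shift(x: np.ndarray, k: int) -> np.ndarray:
    if k == 0:
        return x
    out = np.zeros_like(x)
    out[k:] = x[:-k]
    return out


def _delayed(x: np.ndarray, delay: float, dt: float) -> np.ndarray:
    """Transport-delay x by `delay` seconds, zero-padded (rest before t=0).

    Fractional-sample delays are linearly interpolated between adjacent grid
    shifts so the response is continuous in the delay value (sub-sample
    accuracy matters when delays of 50-90 ms are fitted).
    """
    k, frac = _split_delay(delay, dt)
    if frac == 0.0:
        return _shift(x, k)
    return (1.0 - frac) * _shift(x, k) + frac * _shift(x, k + 1)


def _split_delay(delay: float, dt: float) -> tuple[int, float]:
    k = delay / dt
    ki = int(np.floor(k + 1e-12))
    frac = k - ki
    if frac < 1e-9:
        frac = 0.0
    return ki, frac


def _resample_profile(profile: RotationProfile, dt: float) -> RotationProfile:
    if abs(profile.dt - dt) < 1e-12:
        return profile
    t = np.arange(int(round(profile.duration / dt)) + 1) * dt
    return RotationProfile(
        t,
        np.interp(t, profile.t, profile.angle),
        np.interp(t, profile.t, profile.velocity),
        np.interp(t, profile.t, profile.acceleration),
        1.0 / dt,
    )


def simulate(
    profile: RotationProfile,
    plant: PlantParams = PlantParams(),
    suppr: SuppressionParams = SuppressionParams(),
    switches: SwitchConfig = SwitchConfig(),
    dt: float = 5e-4,
    output_rate: float | None = None,
) -> TorqueTrace:
    """Simulate the open-loop plant driven by prescribed kinematics.

    Fixed-step (forward-Euler) evaluation at step `dt` (<= 1 ms so that the
    50-90 ms transport delays are well resolved; fractional-sample delays are
    linearly interpolated).  The inertial,
    passive and reflexive pathways are feed-forward in the kinematics and are
    evaluated vectorized; only the force-feedback integrator is stateful.  The
    controller's derivative input is formed analytically from the velocity
    channel, not by differencing.

    Parameters
    ----------
    output_rate : float, optional
        If given, the returned trace is decimated to this rate (must divide
        1/dt), mirroring e.g. a 200 Hz acquisition system.
    """
    if dt > 1e-3:
        raise ValueError("dt must be <= 1 ms to resolve the loop delays")
    if np.any(~np.isfinite(profile.angle)):
        raise ValueError("NaN/inf in profile")
    max_delay = max(plant.tau_c, suppr.prop_delay, suppr.force_delay)
    if profile.duration <= max_delay:
        raise ValueError("profile must outlast the longest loop delay")

    prof = _resample_profile(profile, dt)
    th, v, a = prof.angle, prof.velocity, prof.acceleration
    n = len(th)

    torque_inertial = plant.J_total * a * DEG
    torque_passive = plant.K * th + plant.B * v

    # controller input u = reflex_gain*theta - prop'(t); resistive orientation
    g = switches.reflex_gain
    if switches.prop_loop_on:
        th_d = _delayed(th, suppr.prop_delay, dt)
        prop = suppr.prop_gain * deadzone(th_d, suppr.prop_threshold)
        prop_dot = np.where(
            np.abs(th_d) > suppr.prop_threshold,
            suppr.prop_gain * _delayed(v, suppr.prop_delay, dt),
            0.0,
        )
    else:
        prop = prop_dot = 0.0
    u = g * th - prop
    u_dot = g * v - prop_dot
    torque_reflex = plant.P * _delayed(u, plant.tau_c, dt) + plant.D * _delayed(
        u_dot, plant.tau_c, dt
    )

    T_raw = torque_inertial + torque_passive + torque_reflex
    if switches.force_loop_on:
        df, frac = _split_delay(suppr.force_delay, dt)
        torque_net, x = _force_loop(
            T_raw, df, frac, dt, suppr.force_gain, suppr.force_threshold
        )
        torque_suppression = -x
    else:
        torque_net = T_raw
        torque_suppression = np.zeros(n)

    trace = TorqueTrace(
        prof.t, torque_net, torque_inertial, torque_passive,
        torque_reflex, torque_suppression, 1.0 / dt,
    )
    if output_rate is not None:
        trace = decimate_trace(trace, output_rate)
    return trace


def decimate_trace(trace: TorqueTrace, rate: float) -> TorqueTrace:
    """Down-sample a trace to `rate` by strided selection (rate must divide)."""
    stride = trace.sample_rate / rate
    k = int(round(stride))
    if abs(stride - k) > 1e-9 or k < 1:
        raise ValueError("output rate must divide the simulation rate")
    if k == 1:
        return trace
    sl = slice(None, None, k)
    return TorqueTrace(
        trace.t[sl], trace.torque_net[sl], trace.torque_inertial[sl],
        trace.torque_passive[sl], trace.torque_reflex[sl],
        trace.torque_suppression[sl], rate,
    )


def gain_scheduling_prediction(
    profile: RotationProfile,
    plant: PlantParams = PlantParams(),
    reflex_gain: float = 0.0,
    dt: float = 5e-4,
    output_rate: float | None = None,
) -> TorqueTrace:
    """Counterfactual: suppression loops open, reflex gain scaled (0 = full
    gain scheduling).  The residual torque is the passive + inertial response
    plus the scaled reflex."""
    switches = SwitchConfig(prop_loop_on=False, force_loop_on=False, reflex_gain=reflex_gain)
    return simulate(profile, plant, SuppressionParams(), switches, dt=dt, output_rate=output_rate)
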