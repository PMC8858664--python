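"""Stimulus kinematics for passive head-on-trunk rotation experiments.

Two stimulus families are generated analytically on a uniform time grid:

* slow raised-cosine head-on-trunk rotations (default 16 deg over 5 s,
  peak angular velocity A*pi/(2T) ~ 5 deg/s), and
* brief ramp-and-hold perturbations realised as trapezoidal velocity
  pulses (linear rise to a plateau, linear fall), whose plateau velocity
  is solved so that the integrated displacement equals the requested
  amplitude.

Velocity and acceleration channels are the exact analytic derivatives of
the angle channel, never numeric differences, so that transport-delayed
derivative terms in the plant simulation stay noise-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RotationProfile",
    "SlowRotationSpec",
    "PerturbationSpec",
    "STANDARD",
    "FAST",
    "LONG",
    "make_slow_rotation",
    "make_perturbation",
    "superimpose",
]


@dataclass(frozen=True)
class RotationProfile:
    """Sampled angular kinematics of an imposed head-on-trunk movement.

    Attributes
    ----------
    t : ndarray
        Uniform time grid in seconds, starting at 0.
    angle, velocity, acceleration : ndarray
        Head-on-trunk angle (deg), angular velocity (deg/s) and angular
        acceleration (deg/s^2) on the grid.
    sample_rate : float
        Samples per second (1/step).
    """

    t: np.ndarray
    angle: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.angle) == len(self.velocity) == len(self.acceleration) == n):
            raise ValueError("profile channels must share one grid")
        if n >= 2:
            steps = np.diff(self.t)
            if not np.allclose(steps, 1.0 / self.sample_rate, rtol=0, atol=1e-9):
                raise ValueError("time grid is not uniform at sample_rate")
        for name in ("angle", "velocity", "acceleration"):
            if np.any(~np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        return float(self.t[-1])

    def flipped(self) -> "RotationProfile":
        """Mirror the profile (direction flip negates all channels)."""
        return RotationProfile(
            self.t, -self.angle, -self.velocity, -self.acceleration, self.sample_rate
        )


@dataclass(frozen=True)
class SlowRotationSpec:
    """Raised-cosine slow rotation: amplitude deg over `duration` s."""

    amplitude: float = 16.0
    duration: float = 5.0
    direction: int = +1

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")


@dataclass(frozen=True)
class PerturbationSpec:
    """Ramp-and-hold perturbation (trapezoidal velocity pulse).

    amplitude : net displacement in deg (> 0)
    total_duration : s, end of the velocity pulse
    accel_time : s, linear velocity rise 0 -> plateau
    decel_onset : s, start of the linear fall plateau -> 0
    direction : +1 / -1
    """

    amplitude: float
    total_duration: float
    accel_time: float = 0.09
    decel_onset: float = 0.30
    direction: int = +1

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if not (0 < self.accel_time < self.decel_onset < self.total_duration):
            raise ValueError(
                "timing must satisfy 0 < accel_time < decel_onset < total_duration"
            )
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")

    @property
    def plateau_velocity(self) -> float:
        """Plateau velocity (deg/s) solving integral(velocity) = amplitude."""
        decel_time = self.total_duration - self.decel_onset
        eff = 0.5 * self.accel_time + (self.decel_onset - self.accel_time) + 0.5 * decel_time
        return self.amplitude / eff


#: The three perturbation metrics used in the study: standard (0.9 deg / 0.4 s),
#: fast (1.8 deg / 0.4 s) and long (1.8 deg / 0.65 s), all with ~90 ms rise and
#: deceleration starting at ~0.3 / 0.3 / 0.6 s, giving plateaus ~3 / 6 / 3 deg/s.
STANDARD = PerturbationSpec(amplitude=0.9, total_duration=0.40, accel_time=0.09, decel_onset=0.30)
FAST = PerturbationSpec(amplitude=1.8, total_duration=0.40, accel_time=0.09, decel_onset=0.30)
LONG = PerturbationSpec(amplitude=1.8, total_duration=0.65, accel_time=0.09, decel_onset=0.60)

PERTURBATION_METRICS = {"standard": STANDARD, "fast": FAST, "long": LONG}


def _grid(total: float, sample_rate: float) -> np.ndarray:
    n = int(round(total * sample_rate))
    return np.arange(n + 1) / sample_rate


def make_slow_rotation(
    spec: SlowRotationSpec,
    sample_rate: float = 1000.0,
    tail: float = 0.0,
) -> RotationProfile:
    """Generate the raised-cosine slow rotation.

    angle(t) = direction * (A/2) * (1 - cos(pi t / T)) on [0, T]; the angle is
    held at its final value for `tail` extra seconds.  Peak velocity is
    A*pi/(2T) at t = T/2 and angle(T/2) = A/2 exactly.
    """
    if sample_rate < 200.0:
        raise ValueError("sample_rate must be >= 200 Hz")
    A, T, s = spec.amplitude, spec.duration, spec.direction
    t = _grid(T + tail, sample_rate)
    inside = t <= T
    phase = np.pi * np.minimum(t, T) / T
    angle = s * (A / 2.0) * (1.0 - np.cos(phase))
    velocity = np.where(inside, s * (A * np.pi / (2.0 * T)) * np.sin(phase), 0.0)
    acceleration = np.where(inside, s * (A * np.pi**2 / (2.0 * T**2)) * np.cos(phase), 0.0)
    return RotationProfile(t, angle, velocity, acceleration, float(sample_rate))


def make_perturbation(
    spec: PerturbationSpec,
    sample_rate: float = 1000.0,
    tail: float = 0.4,
) -> RotationProfile:
    """Generate a ramp-and-hold perturbation profile.

    The velocity is a trapezoid (linear rise over `accel_time`, plateau,
    linear fall from `decel_onset` to `total_duration`); the angle is its
    exact running integral and is held constant for `tail` seconds after the
    pulse so that post-stimulus relaxation windows are covered.
    """
    if sample_rate < 200.0:
        raise ValueError("sample_rate must be >= 200 Hz")
    v_pl = spec.plateau_velocity * spec.direction
    ta, td, te = spec.accel_time, spec.decel_onset, spec.total_duration
    t = _grid(te + tail, sample_rate)

    velocity = np.zeros_like(t)
    acceleration = np.zeros_like(t)
    rise = t < ta
    velocity[rise] = v_pl * t[rise] / ta
    acceleration[rise] = v_pl / ta
    plat = (t >= ta) & (t < td)
    velocity[plat] = v_pl
    fall = (t >= td) & (t < te)
    velocity[fall] = v_pl * (te - t[fall]) / (te - td)
    acceleration[fall] = -v_pl / (te - td)

    # exact piecewise-quadratic integral of the trapezoid
    angle = np.zeros_like(t)
    angle[rise] = 0.5 * v_pl * t[rise] ** 2 / ta
    a_ta = 0.5 * v_pl * ta
    angle[plat] = a_ta + v_pl * (t[plat] - ta)
    a_td = a_ta + v_pl * (td - ta)
    angle[fall] = a_td + v_pl * (t[fall] - td) - 0.5 * v_pl * (t[fall] - td) ** 2 / (te - td)
    angle[t >= te] = spec.amplitude * spec.direction
    return RotationProfile(t, angle, velocity, acceleration, float(sample_rate))


def superimpose(
    slow: RotationProfile,
    pert: RotationProfile,
    onset: float = 2.5,
    direction: int = +1,
) -> RotationProfile:
    """Superimpose a perturbation onto an ongoing slow rotation.

    The perturbation's kinematics are added to the slow profile starting at
    `onset` (rounded to the shared grid).  ``direction=+1`` delivers the
    perturbation as given ("ipsilateral" when its sign matches the slow
    rotation), ``direction=-1`` flips it ("contralateral").
    """
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    if abs(slow.sample_rate - pert.sample_rate) > 1e-9:
        raise ValueError("grid mismatch: profiles must share sample_rate")
    i0 = int(round(onset * slow.sample_rate))
    if abs(i0 / slow.sample_rate - onset) > 1e-9:
        raise ValueError("onset must fall on the shared grid")
    if onset + pert.duration > slow.duration + 1e-9:
        raise ValueError("perturbation extends beyond the slow rotation")

    n = len(slow.t)
    angle = slow.angle.copy()
    velocity = slow.velocity.copy()
    acceleration = slow.acceleration.copy()
    m = min(len(pert.t), n - i0)
    sl = slice(i0, i0 + m)
    angle[sl] += direction * pert.angle[:m]
    velocity[sl] += direction * pert.velocity[:m]
    acceleration[sl] += direction * pert.acceleration[:m]
    # hold the perturbation's final displacement if the slow profile outlasts it
    if i0 + m < n:
        angle[i0 + m:] += direction * pert.angle[-1]
    return RotationProfile(slow.t, angle, velocity, acceleration, slow.sample_rate)
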