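"""Synthetic cohort generator standing in for the human torque recordings.

Emulates a cohort of subjects (default 6) measured at 200 Hz under the full
condition grid: three perturbation metrics (standard / fast / long), three
contexts (static, dynamic ipsilateral, dynamic contralateral) and two
directions.  Inter-subject variability is modelled as lognormal jitter
(default coefficient of variation 0.15) on every plant and suppression
parameter, and measurement noise as band-limited (30 Hz) additive Gaussian
noise on the torque channel, calibrated so that the dispersion of the static
early/late response integrals across subjects resembles the tabulated
between-subject SDs.

Dynamic contexts are simulated with the dynamic-context length-loop override
(delay 50 ms, gain 1.1) applied on top of each subject's jittered parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .fitting import ALL_NAMES, ReferenceCurve, _apply, _param_value
from .model import (
    DYNAMIC_OVERRIDE,
    PlantParams,
    SuppressionParams,
    SwitchConfig,
    TorqueTrace,
    simulate,
)
from .stimuli import (
    PERTURBATION_METRICS,
    SlowRotationSpec,
    make_perturbation,
    make_slow_rotation,
    superimpose,
)

__all__ = ["CohortSpec", "SyntheticDataset", "generate_cohort", "average_traces"]

METRICS = ("standard", "fast", "long")
CONTEXTS = ("static", "ipsi", "contra")
DIRECTIONS = (+1, -1)

#: Onset (s) of the dynamic perturbations within the slow rotation.
DYNAMIC_ONSET = 2.5


@dataclass(frozen=True)
class CohortSpec:
    """Stated world of the synthetic cohort.

    n_subjects : cohort size (6, as in the study)
    plant / suppr : base (literature-fit) parameter values
    variability : lognormal coefficient of variation applied per parameter
        and subject (0.15)
    noise_sd : Nm, standard deviation of the band-limited torque noise
    noise_bandwidth : Hz, low-pass corner of the noise (30 Hz on a 200 Hz
        acquisition channel)
    trials_per_cell : noisy trials generated per condition cell before
        averaging (the study averaged two trials per direction)
    discard_outliers : apply the trial-discard rule (fluctuations beyond
        mean + 1.5 SD) before averaging, when more than two trials exist
    """

    n_subjects: int = 6
    plant: PlantParams = PlantParams()
    suppr: SuppressionParams = SuppressionParams()
    variability: float = 0.15
    noise_sd: float = 0.10
    noise_bandwidth: float = 30.0
    sample_rate: float = 200.0
    trials_per_cell: int = 2
    discard_outliers: bool = False
    seed: int = 0
    dt: float = 5e-4

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.variability < 0 or self.noise_sd < 0:
            raise ValueError("variability and noise_sd must be >= 0")
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")


@dataclass(frozen=True)
class SyntheticDataset:
    """Per-subject traces keyed by (metric, context, direction), their
    cohort averages, and the stimulus profiles used to generate them."""

    spec: CohortSpec
    profiles: dict
    traces: dict
    subjects: tuple[dict, ...]

    def average(self, metric: str, context: str) -> TorqueTrace:
        return average_traces(self, (metric, context))

    def static_references(self) -> list[ReferenceCurve]:
        """Cohort-average static responses packaged for fitting."""
        refs = []
        for name in METRICS:
            spec = PERTURBATION_METRICS[name]
            refs.append(
                ReferenceCurve(
                    label=name,
                    profile=self.profiles[(name, "static", +1)],
                    trace=self.average(name, "static"),
                    pert_end=spec.total_duration,
                )
            )
        return refs


def _subject_params(spec: CohortSpec, rng: np.random.Generator):
    """Lognormal multipliers (unit mean) on every parameter."""
    if spec.variability == 0:
        return spec.plant, spec.suppr, {n: 1.0 for n in ALL_NAMES}
    sigma = np.sqrt(np.log1p(spec.variability**2))
    mult = {n: float(np.exp(rng.normal(-0.5 * sigma**2, sigma))) for n in ALL_NAMES}
    values = [mult[n] * _param_value(spec.plant, spec.suppr, n) for n in ALL_NAMES]
    # snap jittered transport delays onto the integration grid
    for i, n in enumerate(ALL_NAMES):
        if n in ("tau_c", "prop_delay", "force_delay"):
            values[i] = round(values[i] / spec.dt) * spec.dt
    plant, suppr = _apply(spec.plant, spec.suppr, ALL_NAMES, values)
    return plant, suppr, mult


def _dynamic_suppr(suppr: SuppressionParams, mult: dict, dt: float) -> SuppressionParams:
    """Dynamic-context override, retaining the subject's multipliers."""
    delay = DYNAMIC_OVERRIDE["prop_delay"] * mult["prop_delay"]
    return replace(
        suppr,
        prop_delay=round(delay / dt) * dt,
        prop_gain=DYNAMIC_OVERRIDE["prop_gain"] * mult["prop_gain"],
    )


def _noise(rng: np.random.Generator, n: int, spec: CohortSpec) -> np.ndarray:
    if spec.noise_sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    sos = signal.butter(4, spec.noise_bandwidth, fs=spec.sample_rate, output="sos")
    filt = signal.sosfilt(sos, white)
    sd = float(np.std(filt))
    return spec.noise_sd * filt / sd if sd > 0 else filt


def _average_trials(trials: list[np.ndarray], discard: bool) -> np.ndarray:
    arr = np.stack(trials)
    if discard and len(trials) > 2:
        centre = arr.mean(axis=0)
        dev = np.max(np.abs(arr - centre), axis=1)
        keep = dev <= dev.mean() + 1.5 * dev.std()
        if keep.any():
            arr = arr[keep]
    return arr.mean(axis=0)


def _make_profiles(spec: CohortSpec) -> dict:
    rate = 1.0 / spec.dt
    profiles = {}
    for name in METRICS:
        pspec = PERTURBATION_METRICS[name]
        for d in DIRECTIONS:
            pert = make_perturbation(replace(pspec, direction=d), rate, tail=0.4)
            profiles[(name, "static", d)] = pert
            slow = make_slow_rotation(SlowRotationSpec(direction=d), rate, tail=0.4)
            pos_pert = make_perturbation(pspec, rate, tail=0.4)
            profiles[(name, "ipsi", d)] = superimpose(slow, pos_pert, DYNAMIC_ONSET, d)
            profiles[(name, "contra", d)] = superimpose(slow, pos_pert, DYNAMIC_ONSET, -d)
    return profiles


def generate_cohort(spec: CohortSpec = CohortSpec()) -> SyntheticDataset:
    """Generate the full synthetic dataset (deterministic for a fixed seed).

    For every subject a parameter set is drawn, all 18 condition cells are
    simulated, band-limited noise is added per trial, trials are (optionally
    filtered and) averaged, and traces are recorded at the acquisition rate.
    """
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)
    profiles = _make_profiles(spec)
    switches = SwitchConfig(True, True, 1.0)

    traces: dict = {key: [] for key in profiles}
    subjects = []
    for seq in subject_seeds:
        rng = np.random.default_rng(seq)
        plant, suppr, mult = _subject_params(spec, rng)
        suppr_dyn = _dynamic_suppr(suppr, mult, spec.dt)
        subjects.append({"plant": plant, "suppr": suppr, "multipliers": mult})
        for (name, context, d), profile in profiles.items():
            sp = suppr if context == "static" else suppr_dyn
            clean = simulate(
                profile, plant, sp, switches, dt=spec.dt, output_rate=spec.sample_rate
            )
            n = len(clean.t)
            trials = [
                clean.torque_net + _noise(rng, n, spec)
                for _ in range(spec.trials_per_cell)
            ]
            net = _average_trials(trials, spec.discard_outliers)
            noise_avg = net - clean.torque_net
            traces[(name, context, d)].append(
                TorqueTrace(
                    clean.t, net, clean.torque_inertial, clean.torque_passive,
                    clean.torque_reflex, clean.torque_suppression + noise_avg,
                    clean.sample_rate,
                )
            )

    traces = {k: tuple(v) for k, v in traces.items()}
    return SyntheticDataset(spec=spec, profiles=profiles, traces=traces, subjects=tuple(subjects))


def average_traces(dataset: SyntheticDataset, condition: tuple[str, str]) -> TorqueTrace:
    """Cohort-average trace for (metric, context), mirroring the leftward
    (direction -1) responses before pointwise averaging."""
    name, context = condition
    members = []
    for d in DIRECTIONS:
        key = (name, context, d)
        if key not in dataset.traces or not dataset.traces[key]:
            raise ValueError(f"empty condition cell {key}")
        members.extend([(tr, d) for tr in dataset.traces[key]])
    first = members[0][0]
    fields = (
        "torque_net", "torque_inertial", "torque_passive",
        "torque_reflex", "torque_suppression",
    )
    means = {
        f: np.mean([d * getattr(tr, f) for tr, d in members], axis=0) for f in fields
    }
    return TorqueTrace(first.t, means["torque_net"], means["torque_inertial"],
                       means["torque_passive"], means["torque_reflex"],
                       means["torque_suppression"], first.sample_rate)
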