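"""Columnar-text / JSON serialization and the end-to-end pipeline.

All data products are plain text: stimulus profiles and torque traces as
whitespace-separated columns with a one-line header, parameter sets and
reports as JSON.  Every pipeline output embeds the run seed and a hash of the
generating configuration so a run can be regenerated bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from .fitting import FitSpec, FitResult, compare_variants, cross_validate, fit
from .model import (
    VARIANTS,
    PlantParams,
    SuppressionParams,
    SwitchConfig,
    TorqueTrace,
    gain_scheduling_prediction,
)
from .stimuli import RotationProfile
from .synth import CohortSpec, DYNAMIC_ONSET, METRICS, CONTEXTS, generate_cohort

__all__ = [
    "read_trace",
    "write_trace",
    "read_profile",
    "write_profile",
    "read_params",
    "write_params",
    "RunConfig",
    "run_pipeline",
]

_FMT = "%.17g"  # lossless float round-trip

TRACE_COLUMNS = (
    "t_s", "torque_Nm", "torque_inertial_Nm", "torque_passive_Nm",
    "torque_reflex_Nm", "torque_suppression_Nm",
)
PROFILE_COLUMNS = ("t_s", "angle_deg", "vel_degs", "acc_degs2")


class ParseError(ValueError):
    pass


def _write_columns(path, header, columns) -> None:
    arr = np.column_stack(columns)
    np.savetxt(path, arr, fmt=_FMT, header=" ".join(header), comments="")


def _read_columns(path, required) -> dict[str, np.ndarray]:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
    if not header or any(ch.isdigit() for ch in header[0][:1]):
        raise ParseError(f"{path}:1: missing header line")
    missing = [c for c in required if c not in header]
    if missing:
        raise ParseError(f"{path}:1: missing column: {missing[0]}")
    try:
        data = np.loadtxt(path, skiprows=1, ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: malformed numeric data ({exc})") from exc
    if data.shape[1] != len(header):
        raise ParseError(f"{path}: {data.shape[1]} columns but {len(header)} header names")
    cols = {name: data[:, i] for i, name in enumerate(header)}
    t = cols["t_s"]
    if len(t) >= 2:
        steps = np.diff(t)
        bad = np.nonzero(np.abs(steps - steps[0]) > 1e-9)[0]
        if bad.size:
            raise ParseError(f"{path}:{bad[0] + 3}: non-uniform time grid")
    return cols


def write_trace(trace: TorqueTrace, path) -> None:
    _write_columns(
        path,
        TRACE_COLUMNS,
        (trace.t, trace.torque_net, trace.torque_inertial, trace.torque_passive,
         trace.torque_reflex, trace.torque_suppression),
    )


def read_trace(path) -> TorqueTrace:
    cols = _read_columns(path, TRACE_COLUMNS)
    t = cols["t_s"]
    rate = 1.0 / (t[1] - t[0]) if len(t) >= 2 else 1.0
    return TorqueTrace(
        t, cols["torque_Nm"], cols["torque_inertial_Nm"], cols["torque_passive_Nm"],
        cols["torque_reflex_Nm"], cols["torque_suppression_Nm"], rate,
    )


def write_profile(profile: RotationProfile, path) -> None:
    _write_columns(
        path, PROFILE_COLUMNS,
        (profile.t, profile.angle, profile.velocity, profile.acceleration),
    )


def read_profile(path) -> RotationProfile:
    cols = _read_columns(path, PROFILE_COLUMNS)
    t = cols["t_s"]
    rate = 1.0 / (t[1] - t[0]) if len(t) >= 2 else 1.0
    return RotationProfile(t, cols["angle_deg"], cols["vel_degs"], cols["acc_degs2"], rate)


def write_params(plant: PlantParams, suppr: SuppressionParams, path) -> None:
    payload = {"plant": asdict(plant), "suppression": asdict(suppr)}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_params(path) -> tuple[PlantParams, SuppressionParams]:
    payload = json.loads(Path(path).read_text())
    return PlantParams(**payload["plant"]), SuppressionParams(**payload["suppression"])


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration (all randomness flows from `seed`)."""

    outdir: str = "neckservo_run"
    seed: int = 0
    n_subjects: int = 6
    variant: str = "full"
    noise_sd: float = 0.10
    variability: float = 0.15
    multistart: int = 2
    maxiter: int = 12
    free_parameters: tuple[str, ...] | None = None
    make_plots: bool = True

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded so
        reruns into different directories stay byte-identical)."""
        payload = asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _fit_result_payload(result: FitResult) -> dict:
    return {
        "plant": asdict(result.plant),
        "suppression": asdict(result.suppr),
        "objective_Nms": result.objective,
        "per_curve_Nms": list(result.per_curve),
        "converged": result.converged,
        "n_evals": result.n_evals,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic analysis: cohort generation, condition averages,
    response metrics, constrained fit, 3-fold cross-validation and variant
    comparison; writes traces, a tidy metrics CSV, JSON reports and figures.

    Returns the report dictionary that is also written to ``report.json``.
    """
    out = Path(config.outdir)
    (out / "traces").mkdir(parents=True, exist_ok=True)

    cohort_spec = CohortSpec(
        n_subjects=config.n_subjects,
        variability=config.variability,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    dataset = generate_cohort(cohort_spec)

    # condition averages + tidy metrics table
    rows = []
    integrals = {}
    for name in METRICS:
        for context in CONTEXTS:
            avg = dataset.average(name, context)
            write_trace(avg, out / "traces" / f"{name}_{context}.txt")
            if context == "static":
                ri = metrics_mod.torque_integrals(avg, onset=0.0)
            else:
                # dynamic: subtract the mid-rotation baseline; express the
                # contralateral response in the perturbation's direction
                ri = metrics_mod.torque_integrals(
                    avg, onset=DYNAMIC_ONSET, baseline_window=0.05
                )
                if context == "contra":
                    ri = metrics_mod.ResponseIntegrals(-ri.t1, -ri.t2, ri.onset)
            integrals[(name, context)] = ri
            t1_disp, t2_disp = ri.scaled()
            rows.append({"condition": context, "metric": name, "window": "t1",
                         "value_Nms_e3": t1_disp})
            rows.append({"condition": context, "metric": name, "window": "t2",
                         "value_Nms_e3": t2_disp})
    for name in METRICS:
        for context in ("ipsi", "contra"):
            p1, p2 = metrics_mod.percent_of_static(
                integrals[(name, context)], integrals[(name, "static")]
            )
            rows.append({"condition": context, "metric": name,
                         "window": "t1_pct_static", "value_Nms_e3": p1})
            rows.append({"condition": context, "metric": name,
                         "window": "t2_pct_static", "value_Nms_e3": p2})
    frame = pd.DataFrame(rows)
    frame.insert(0, "config_hash", config.digest())
    frame.to_csv(out / "metrics.csv", index=False, float_format="%.6g")

    refs = dataset.static_references()
    free = config.free_parameters or FitSpec().free_parameters
    fit_spec = FitSpec(
        free_parameters=tuple(free),
        multistart=config.multistart,
        maxiter=config.maxiter,
        seed=config.seed,
    )
    switches = VARIANTS[config.variant]
    fit_result = fit(refs, fit_spec, switches)
    cv = cross_validate(refs, fit_spec, switches)
    variants = {k: VARIANTS[k] for k in ("full", "force-only", "gain0")}
    ranking = compare_variants(refs, variants, fit_spec)

    # gain-scheduling residual during the slow rotation (counterfactual check)
    slow = dataset.profiles[("standard", "ipsi", +1)]
    gs = gain_scheduling_prediction(slow, reflex_gain=0.0)
    gs_residual = float(np.max(np.abs(gs.torque_net[: int(2.5 / gs.dt)])))

    report = {
        "seed": config.seed,
        "config_hash": config.digest(),
        "fit": _fit_result_payload(fit_result),
        "cross_validation": [
            {
                "training": list(f.training),
                "training_error_pct": f.training_percent,
                "held_out": f.held_out,
                "prediction_error_pct": f.prediction_percent,
            }
            for f in cv.folds
        ],
        "variant_ranking": [
            {"variant": name, "objective_Nms": res.objective}
            for name, res in ranking
        ],
        "gain_scheduling_residual_Nm": gs_residual,
        "gain_scheduling_residual_nonzero": gs_residual > 1e-3,
    }
    report = _round_floats(report)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    (out / "crossval.csv").write_text(_cv_csv(report))

    if config.make_plots:
        _plots(dataset, out)
    return report


def _cv_csv(report: dict) -> str:
    lines = ["training,held_out,training_error_pct,prediction_error_pct"]
    for fold in report["cross_validation"]:
        lines.append(
            f"{'+'.join(fold['training'])},{fold['held_out']},"
            f"{fold['training_error_pct']:.4g},{fold['prediction_error_pct']:.4g}"
        )
    return "\n".join(lines) + "\n"


def _plots(dataset, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    colors = {"standard": "tab:blue", "fast": "tab:red", "long": "tab:green"}
    for name in METRICS:
        avg = dataset.average(name, "static")
        axes[0].plot(avg.t, avg.torque_net, color=colors[name], label=name)
        profile = dataset.profiles[(name, "static", +1)]
        stride = int(round(profile.sample_rate / avg.sample_rate))
        axes[1].plot(profile.angle[::stride][: len(avg.t)], avg.torque_net,
                     color=colors[name])
    axes[0].set(xlabel="time (s)", ylabel="torque (Nm)", title="static responses")
    axes[0].legend(frameon=False)
    axes[1].set(xlabel="displacement (deg)", ylabel="torque (Nm)",
                title="stiffness diagram")
    fig.tight_layout()
    fig.savefig(out / "responses.png", dpi=120)
    plt.close(fig)
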