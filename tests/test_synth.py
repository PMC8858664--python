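import numpy as np
import pytest

from neckservo import (
    CohortSpec,
    PlantParams,
    SuppressionParams,
    SwitchConfig,
    average_traces,
    generate_cohort,
    simulate,
    torque_integrals,
)
from neckservo.model import dynamic_suppression
from neckservo.synth import METRICS


SMALL = dict(n_subjects=2, trials_per_cell=1)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = generate_cohort(CohortSpec(seed=3, **SMALL))
        b = generate_cohort(CohortSpec(seed=3, **SMALL))
        for key in a.traces:
            for ta, tb in zip(a.traces[key], b.traces[key]):
                assert np.array_equal(ta.torque_net, tb.torque_net)

    def test_different_seed_differs(self):
        a = generate_cohort(CohortSpec(seed=3, **SMALL))
        b = generate_cohort(CohortSpec(seed=4, **SMALL))
        key = ("standard", "static", +1)
        assert not np.array_equal(a.traces[key][0].torque_net, b.traces[key][0].torque_net)


class TestDegenerateCohort:
    def test_zero_variability_zero_noise_equals_base(self):
        spec = CohortSpec(n_subjects=3, variability=0.0, noise_sd=0.0, trials_per_cell=1)
        ds = generate_cohort(spec)
        prof = ds.profiles[("fast", "static", +1)]
        base = simulate(prof, spec.plant, spec.suppr, SwitchConfig(),
                        dt=spec.dt, output_rate=spec.sample_rate)
        for tr in ds.traces[("fast", "static", +1)]:
            assert np.allclose(tr.torque_net, base.torque_net, atol=1e-15)
        avg = ds.average("fast", "static")
        assert np.allclose(avg.torque_net, base.torque_net, atol=1e-12)

    def test_dynamic_cells_use_override(self):
        spec = CohortSpec(n_subjects=1, variability=0.0, noise_sd=0.0, trials_per_cell=1)
        ds = generate_cohort(spec)
        prof = ds.profiles[("standard", "ipsi", +1)]
        with_override = simulate(prof, spec.plant, dynamic_suppression(spec.suppr),
                                 SwitchConfig(), dt=spec.dt, output_rate=spec.sample_rate)
        got = ds.traces[("standard", "ipsi", +1)][0]
        assert np.allclose(got.torque_net, with_override.torque_net, atol=1e-15)


class TestAverages:
    def test_average_equals_member_mean_with_mirroring(self):
        ds = generate_cohort(CohortSpec(seed=5, **SMALL))
        avg = average_traces(ds, ("long", "static"))
        members = [tr.torque_net for tr in ds.traces[("long", "static", +1)]]
        members += [-tr.torque_net for tr in ds.traces[("long", "static", -1)]]
        assert np.allclose(avg.torque_net, np.mean(members, axis=0), atol=1e-15)

    def test_mirrored_pair_average(self):
        """Without noise, leftward and rightward responses are exact mirrors
        and the sign-aligned average equals either magnitude."""
        spec = CohortSpec(n_subjects=1, variability=0.0, noise_sd=0.0, trials_per_cell=1)
        ds = generate_cohort(spec)
        right = ds.traces[("fast", "static", +1)][0].torque_net
        left = ds.traces[("fast", "static", -1)][0].torque_net
        assert np.allclose(left, -right, atol=1e-12)
        avg = ds.average("fast", "static")
        assert np.allclose(avg.torque_net, right, atol=1e-12)

    def test_cohort_average_noise_shrinks_sqrt_n(self):
        """Averaging n subjects' noise-only residuals shrinks their SD ~ 1/sqrt(n)."""
        spec = CohortSpec(n_subjects=6, variability=0.0, noise_sd=0.10,
                          trials_per_cell=1, seed=11)
        ds = generate_cohort(spec)
        base = simulate(
            ds.profiles[("standard", "static", +1)], spec.plant, spec.suppr,
            SwitchConfig(), dt=spec.dt, output_rate=spec.sample_rate,
        )
        residuals = np.stack(
            [tr.torque_net - base.torque_net for tr in ds.traces[("standard", "static", +1)]]
        )
        member_sd = residuals.std(axis=0).mean()
        avg_sd = residuals.mean(axis=0).std()
        assert avg_sd == pytest.approx(member_sd / np.sqrt(6), rel=0.4)

    def test_missing_cell_rejected(self):
        ds = generate_cohort(CohortSpec(seed=5, **SMALL))
        with pytest.raises(ValueError):
            average_traces(ds, ("nonexistent", "static"))


class TestCalibration:
    def test_static_integral_means_inside_table_envelopes(self):
        """Cohort means of the static early/late integrals fall inside the
        tabulated mean +/- SD envelopes (x1e-3 Nm s): early 3.9+/-1.5,
        7.5+/-1.5, 3.5+/-1.0; late 13.4+/-5.1, 16.4+/-7.5, 11.2+/-3.8."""
        envelopes = {
            "standard": ((3.9, 1.5), (13.4, 5.1)),
            "fast": ((7.5, 1.5), (16.4, 7.5)),
            "long": ((3.5, 1.0), (11.2, 3.8)),
        }
        ds = generate_cohort(CohortSpec(seed=0))
        for name in METRICS:
            per_subject = []
            for i in range(ds.spec.n_subjects):
                vals = []
                for d in (+1, -1):
                    ri = torque_integrals(ds.traces[(name, "static", d)][i])
                    vals.append((d * ri.t1 * 1e3, d * ri.t2 * 1e3))
                per_subject.append(np.mean(vals, axis=0))
            mean_t1, mean_t2 = np.mean(per_subject, axis=0)
            (m1, s1), (m2, s2) = envelopes[name]
            assert m1 - s1 <= mean_t1 <= m1 + s1
            assert m2 - s2 <= mean_t2 <= m2 + s2

    def test_discard_filter_runs(self):
        spec = CohortSpec(n_subjects=1, trials_per_cell=4, discard_outliers=True, seed=2)
        ds = generate_cohort(spec)
        assert len(ds.traces[("standard", "static", +1)]) == 1
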