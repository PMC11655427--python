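"""Quenching arithmetic and induction-curve handling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from npqunmix import (
    average_curves,
    compute_npq,
    compute_qp,
    difference_curve,
    extract_pulse_samples,
    generate_dataset,
    partition_recovery,
    resample_uniform,
    samples_to_curve,
    simulate_pam_trace,
    steady_state_closure,
)
from npqunmix.errors import (
    GridMismatchError,
    InvalidMeasurementError,
    PhaseError,
)
from npqunmix.pam import PHASE_LIGHT, PHASE_RECOVERY, FluorescenceTrace, InductionCurve


def light_curve(times, npq, qp=None, intensity=100.0, **kw):
    qp = np.ones_like(np.asarray(times, float)) if qp is None else qp
    return InductionCurve(times, npq, qp, intensity, **kw)


@pytest.mark.parametrize(
    "fm, fm_prime, expected",
    [(2.0, 1.0, 1.0), (1.7, 1.7, 0.0), (3.5, 1.4, 1.5)],
)
def test_npq_stern_volmer_arithmetic(fm, fm_prime, expected):
    assert compute_npq(fm, fm_prime) == pytest.approx(expected)


def test_npq_rejects_nonpositive_fm_prime():
    with pytest.raises(InvalidMeasurementError):
        compute_npq(2.0, 0.0)


@given(fm=st.floats(0.5, 10), d=st.floats(0.01, 5))
@settings(derandomize=True, max_examples=50, deadline=None)
def test_npq_decreasing_in_fm_prime(fm, d):
    """More quenching (lower Fm') always means higher NPQ."""
    assert compute_npq(fm, fm) == 0.0
    assert compute_npq(fm, fm / (1 + d)) > compute_npq(fm, fm)


@pytest.mark.parametrize(
    "fm_prime, f_prime, fo_prime, expected",
    [(1.0, 0.2, 0.2, 1.0), (1.0, 1.0, 0.2, 0.0), (1.0, 0.5, 0.2, 0.625)],
)
def test_qp_open_centre_fraction(fm_prime, f_prime, fo_prime, expected):
    assert compute_qp(fm_prime, f_prime, fo_prime) == pytest.approx(expected)


def test_qp_degenerate_denominator():
    with pytest.raises(InvalidMeasurementError):
        compute_qp(0.2, 0.2, 0.2)


@given(c=st.floats(0.01, 100), f=st.floats(0.21, 0.99))
@settings(derandomize=True, max_examples=50, deadline=None)
def test_qp_affine_invariant_under_yield_rescaling(c, f):
    """qP depends only on yield ratios, not on detector gain."""
    base = compute_qp(1.0, f, 0.2)
    assert compute_qp(c, c * f, c * 0.2) == pytest.approx(base, rel=1e-9)


class TestTraceExtraction:
    def test_forward_simulated_trace_roundtrips_exactly(self):
        dataset, _ = generate_dataset(n_curves=2, seed=5, genotype="wt")
        curve = dataset.curves[0]
        trace = simulate_pam_trace(curve)
        recovered = samples_to_curve(extract_pulse_samples(trace), trace)
        np.testing.assert_allclose(recovered.npq, curve.npq, atol=1e-6)
        np.testing.assert_allclose(recovered.qp, curve.qp, atol=1e-6)
        assert recovered.closure_ss == pytest.approx(curve.closure_ss, abs=1e-6)

    def test_constant_yield_trace_gives_zero_npq(self):
        t = np.arange(0.0, 120.0, 0.2)
        y = np.full(t.size, 0.5)
        for p in (5.0, 60.0, 90.0):
            y[np.abs(t - p) <= 0.4] = 1.0
        trace = FluorescenceTrace(t, y, [5.0, 60.0, 90.0], 25.0, 100.0, 50.0)
        samples = extract_pulse_samples(trace)
        assert all(s.npq == pytest.approx(0.0, abs=1e-12) for s in samples)

    def test_missing_dark_reference_pulse_is_an_error(self):
        t = np.arange(0.0, 100.0, 0.5)
        trace = FluorescenceTrace(t, np.ones(t.size), [50.0], 25.0, 90.0, 50.0)
        with pytest.raises(PhaseError):
            extract_pulse_samples(trace)

    def test_overlapping_pulse_windows_rejected(self):
        t = np.arange(0.0, 100.0, 0.1)
        trace = FluorescenceTrace(t, np.ones(t.size), [5.0, 30.0, 30.5], 25.0, 90.0, 50.0)
        with pytest.raises(Exception):
            extract_pulse_samples(trace, window=1.0)


class TestSteadyStateClosure:
    def test_constant_qp(self):
        c = light_curve(np.arange(10.0, 610, 10), np.zeros(60), np.full(60, 0.875))
        assert steady_state_closure(c) == pytest.approx(0.125)

    def test_mean_of_last_three(self):
        qp = np.concatenate([np.ones(57), [0.5, 0.6, 0.7]])
        c = light_curve(np.arange(10.0, 610, 10), np.zeros(60), qp)
        assert steady_state_closure(c) == pytest.approx(0.4)

    def test_too_few_points(self):
        c = light_curve([10.0, 20.0], [0, 0], [1, 1])
        with pytest.raises(PhaseError):
            steady_state_closure(c, n_last=3)

    def test_generator_roundtrip(self, wt_preset):
        dataset, truth = wt_preset
        measured = np.array([steady_state_closure(c) for c in dataset.curves])
        np.testing.assert_allclose(measured, truth.closures, atol=5e-3)


class TestResample:
    def test_identity_on_target_grid(self):
        t = np.arange(10.0, 601, 10)
        c = light_curve(t, np.sin(t / 100), np.full(t.size, 0.5))
        r = resample_uniform(c, step=10.0)
        np.testing.assert_allclose(r.times, t)
        np.testing.assert_allclose(r.npq, c.npq)

    def test_linear_two_point(self):
        c = light_curve([0.0, 600.0], [0.0, 6.0])
        r = resample_uniform(c, step=100.0)
        np.testing.assert_allclose(r.npq, [1, 2, 3, 4, 5, 6])

    def test_mixed_schedule_preserves_area(self):
        """Pulse schedule 10 s (first 2 min) then 30 s, resampled to 10 s."""
        sched = np.concatenate([np.arange(10.0, 121, 10), np.arange(150.0, 601, 30)])
        dense = np.arange(10.0, 601, 1.0)
        prof = lambda t: 1.7 * (1 - np.exp(-t / 45)) - (1 - np.exp(-t / 200))
        c = light_curve(sched, prof(sched))
        r = resample_uniform(c, step=10.0)
        area = np.trapezoid(r.npq, r.times)
        oracle = np.trapezoid(prof(dense), dense)
        assert area == pytest.approx(oracle, rel=0.02)

    def test_empty_phase_errors(self):
        c = light_curve([10.0, 20.0], [0, 0])
        with pytest.raises(PhaseError):
            resample_uniform(c, phase=PHASE_RECOVERY)


class TestAverageAndDifference:
    def test_identical_curves_have_zero_se(self):
        t = np.arange(10.0, 101, 10)
        curves = [light_curve(t, np.ones(t.size)) for _ in range(4)]
        mean, se = average_curves(curves)
        np.testing.assert_allclose(se, 0.0)
        np.testing.assert_allclose(mean.npq, 1.0)

    def test_mean_of_two(self):
        t = np.array([10.0, 20.0])
        a = light_curve(t, [0.0, 2.0])
        b = light_curve(t, [2.0, 0.0])
        mean, _ = average_curves([a, b])
        np.testing.assert_allclose(mean.npq, [1.0, 1.0])

    def test_se_matches_planted_noise(self):
        from npqunmix.synth import wt_mixing
        mix = wt_mixing(leaf_sd=0.0, point_sd=0.02)
        dataset, _ = generate_dataset(n_curves=5, intensities=np.full(5, 500.0),
                                      mixing=mix, seed=7, genotype="wt")
        _, se = average_curves([c.illumination() for c in dataset.curves])
        theory = 0.02 / np.sqrt(5)
        assert np.mean(se) < 3 * theory

    def test_grid_mismatch(self):
        a = light_curve([10.0, 20.0], [0, 0])
        b = light_curve([10.0, 30.0], [0, 0])
        with pytest.raises(GridMismatchError):
            average_curves([a, b])
        with pytest.raises(GridMismatchError):
            difference_curve(a, b)

    def test_difference_of_self_is_zero(self):
        t = np.arange(10.0, 101, 10)
        a = light_curve(t, np.linspace(0, 1, t.size))
        np.testing.assert_allclose(difference_curve(a, a).npq, 0.0)

    def test_difference_reveals_planted_component(self):
        """Untreated minus inhibitor-treated isolates the blocked component,
        mirroring chemical-difference analysis of xanthophyll quenching."""
        from npqunmix.synth import canonical_profiles
        grid = np.arange(10.0, 601, 10)
        shapes = {s.label: s.values(grid) for s in canonical_profiles(grid, "wt")}
        full = light_curve(grid, 2.0 * shapes["alpha"] + 0.7 * shapes["beta"])
        treated = light_curve(grid, 0.7 * shapes["beta"])
        diff = difference_curve(full, treated)
        np.testing.assert_allclose(diff.npq, 2.0 * shapes["alpha"], atol=1e-12)


class TestRecoveryPartition:
    def _curve(self, npq_rec):
        t_ill = np.arange(10.0, 601, 10)
        t_rec = np.arange(630.0, 901, 30)
        npq = np.concatenate([np.linspace(0, 1.0, t_ill.size), npq_rec])
        phase = np.concatenate([
            np.full(t_ill.size, PHASE_LIGHT), np.full(t_rec.size, PHASE_RECOVERY)
        ]).astype(object)
        return light_curve(np.concatenate([t_ill, t_rec]), npq,
                           np.ones(t_ill.size + t_rec.size), phase=phase)

    def test_full_relaxation(self):
        rapid, slow = partition_recovery(self._curve(np.zeros(10)))
        assert (rapid, slow) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_no_relaxation(self):
        rapid, slow = partition_recovery(self._curve(np.ones(10)))
        assert (rapid, slow) == (pytest.approx(0.0), pytest.approx(1.0))

    def test_no_recovery_phase_errors(self):
        t = np.arange(10.0, 601, 10)
        with pytest.raises(PhaseError):
            partition_recovery(light_curve(t, np.zeros(t.size)))

    def test_slowly_reversible_matches_planted_delta(self, npq1_preset):
        dataset, truth = npq1_preset
        d = truth.labels.index("delta")
        for i in (0, 40, 84):
            _, slow = partition_recovery(dataset.curves[i])
            assert slow == pytest.approx(truth.amplitudes[i, d], abs=0.06)
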