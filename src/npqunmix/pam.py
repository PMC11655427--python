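"""Saturating-pulse (PAM) fluorometry arithmetic and induction-curve handling.

Raw traces hold fluorescence yield sampled through a dark / illumination /
recovery schedule punctuated by saturating pulses.  Per pulse we read off
Fm' (maximum yield inside the pulse window) and F' (yield just before it),
and derive the two standard quenching coefficients:

* NPQ = (Fm - Fm') / Fm'      (Stern-Volmer nonphotochemical quenching)
* qP  = (Fm' - F') / (Fm' - Fo')   (photochemical quenching, fraction of
  open PSII reaction centres)

Fo' may be measured directly; when absent it is estimated from the
dark-adapted Fo, Fm and the light-adapted Fm' via the Oxborough-Baker
relation Fo' = Fo / (Fv/Fm + Fo/Fm').
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (
    GridMismatchError,
    InvalidMeasurementError,
    PhaseError,
    ValidationError,
)

PHASE_DARK = "dark"
PHASE_LIGHT = "illumination"
PHASE_RECOVERY = "recovery"

#: tolerance below zero accepted for noisy NPQ / qP values
NEG_TOL = 0.25


@dataclass
class FluorescenceTrace:
    """Raw time / fluorescence-yield samples with pulse and light annotations.

    ``time`` is strictly increasing (seconds), ``fluor`` is yield in
    arbitrary units (>= 0).  ``pulse_times`` are the centres of the
    saturating pulses; the first pulse must precede ``light_on`` so a
    dark-adapted Fm reference exists.
    """

    time: np.ndarray
    fluor: np.ndarray
    pulse_times: np.ndarray
    light_on: float
    light_off: float
    light_intensity: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluor = np.asarray(self.fluor, dtype=float)
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        if self.time.ndim != 1 or self.time.size != self.fluor.size:
            raise ValidationError("time and fluor must be 1-D and equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be strictly increasing")
        if np.any(self.fluor < 0):
            raise ValidationError("fluorescence yields must be >= 0")
        if not self.light_on < self.light_off:
            raise ValidationError("light_on must precede light_off")
        if self.pulse_times.size and (
            self.pulse_times.min() < self.time[0]
            or self.pulse_times.max() > self.time[-1]
        ):
            raise ValidationError("pulse_times must lie within the sampled range")


@dataclass
class QuenchingSample:
    """Quenching coefficients extracted at one saturating pulse.

    ``t`` is seconds since light on (negative for the dark reference).
    ``flagged`` marks small negative NPQ/qP excursions tolerated as noise.
    """

    t: float
    fm_prime: float
    f_prime: float
    fo_prime: Optional[float]
    npq: float
    qp: float
    flagged: bool = False


@dataclass
class InductionCurve:
    """NPQ(t) and qP(t) at pulse times for one leaf at one light intensity.

    ``times`` are seconds since light on; ``phase`` labels every point as
    dark / illumination / recovery.  ``closure_ss`` is the steady-state
    closed-centre fraction (1 - qP)_ss, required before decomposition.
    """

    times: np.ndarray
    npq: np.ndarray
    qp: np.ndarray
    light_intensity: float
    closure_ss: Optional[float] = None
    phase: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.npq = np.asarray(self.npq, dtype=float)
        self.qp = np.asarray(self.qp, dtype=float)
        if not (self.times.size == self.npq.size == self.qp.size):
            raise ValidationError("times, npq and qp must have equal length")
        if self.phase is None:
            self.phase = np.full(self.times.size, PHASE_LIGHT, dtype=object)
        else:
            self.phase = np.asarray(self.phase, dtype=object)
            if self.phase.size != self.times.size:
                raise ValidationError("phase mask length mismatch")
        if self.closure_ss is not None and not 0.0 <= self.closure_ss <= 1.0:
            raise ValidationError("closure_ss must lie in [0, 1]")

    def phase_mask(self, phase: str) -> np.ndarray:
        return np.asarray(self.phase == phase)

    def illumination(self) -> "InductionCurve":
        """Sub-curve restricted to the illumination phase."""
        m = self.phase_mask(PHASE_LIGHT)
        return InductionCurve(
            self.times[m], self.npq[m], self.qp[m], self.light_intensity,
            closure_ss=self.closure_ss, phase=self.phase[m], meta=dict(self.meta),
        )


@dataclass
class CurveDataset:
    """A set of induction curves sharing (or resampleable onto) one grid."""

    curves: list
    genotype: str = "wt"
    provenance: str = "measured"

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValidationError("dataset must contain at least one curve")

    def __len__(self) -> int:
        return len(self.curves)

    def closures(self) -> np.ndarray:
        cl = [c.closure_ss for c in self.curves]
        if any(c is None for c in cl):
            raise ValidationError("every curve needs closure_ss before decomposition")
        return np.asarray(cl, dtype=float)

    def intensities(self) -> np.ndarray:
        return np.asarray([c.light_intensity for c in self.curves], dtype=float)

    def to_matrix(self, step: float = 10.0):
        """Resample all curves onto a uniform illumination grid.

        Returns ``(X, grid)`` with X of shape (n_curves, n_times).
        """
        resampled = [resample_uniform(c, step=step) for c in self.curves]
        grid = resampled[0].times
        for r in resampled[1:]:
            if r.times.size != grid.size or not np.allclose(r.times, grid):
                raise GridMismatchError("curves do not cover a common illumination span")
        X = np.vstack([r.npq for r in resampled])
        return X, grid


def compute_npq(fm: float, fm_prime: float) -> float:
    """Stern-Volmer NPQ = (Fm - Fm') / Fm'."""
    if np.any(np.asarray(fm_prime) <= 0):
        raise InvalidMeasurementError("Fm' must be positive")
    return (fm - fm_prime) / fm_prime


def compute_qp(fm_prime: float, f_prime: float, fo_prime: float) -> float:
    """Photochemical quenching qP = (Fm' - F') / (Fm' - Fo')."""
    if np.any(np.asarray(fm_prime) <= np.asarray(fo_prime)):
        raise InvalidMeasurementError("Fm' must exceed Fo' (degenerate denominator)")
    return (fm_prime - f_prime) / (fm_prime - fo_prime)


def estimate_fo_prime(fo: float, fm: float, fm_prime: float) -> float:
    """Oxborough-Baker estimate Fo' = Fo / (Fv/Fm + Fo/Fm')."""
    if fo <= 0 or fm <= fo or fm_prime <= 0:
        raise InvalidMeasurementError("need 0 < Fo < Fm and Fm' > 0 to estimate Fo'")
    fv_over_fm = (fm - fo) / fm
    return fo / (fv_over_fm + fo / fm_prime)


def extract_pulse_samples(trace: FluorescenceTrace, window: float = 1.0):
    """Read Fm', F' (and Fo' via the estimator) at every saturating pulse.

    The first pulse, which must precede ``light_on``, provides the
    dark-adapted Fm (max yield in its window) and Fo (min dark-phase yield
    outside pulse windows).  For each later pulse Fm' is the max yield
    within +/- window/2 and F' the last sample before the window opens.
    """
    pulses = np.sort(trace.pulse_times)
    if pulses.size == 0:
        raise PhaseError("trace has no saturating pulses")
    if pulses[0] >= trace.light_on:
        raise PhaseError("missing dark-reference pulse before light_on")
    if pulses.size > 1 and np.any(np.diff(pulses) <= window):
        raise ValidationError("pulse windows overlap; reduce window")

    half = window / 2.0
    t, y = trace.time, trace.fluor

    def in_window(p):
        return (t >= p - half) & (t <= p + half)

    fm = float(y[in_window(pulses[0])].max())
    dark = (t < trace.light_on)
    for p in pulses[pulses < trace.light_on]:
        dark &= ~in_window(p)
    if not dark.any():
        raise PhaseError("no dark baseline samples outside pulse windows")
    fo = float(y[dark].min())

    samples = []
    for p in pulses[1:]:
        w = in_window(p)
        if not w.any():
            raise ValidationError(f"no samples inside pulse window at t={p}")
        fm_p = float(y[w].max())
        before = t < p - half
        if not before.any():
            raise ValidationError(f"no baseline sample before pulse at t={p}")
        f_p = float(y[before][-1])
        fo_p = estimate_fo_prime(fo, fm, fm_p)
        npq = compute_npq(fm, fm_p)
        qp = compute_qp(fm_p, f_p, fo_p)
        flagged = (npq < 0) or not (0.0 <= qp <= 1.0)
        if npq < -NEG_TOL or qp < -NEG_TOL or qp > 1 + NEG_TOL:
            raise InvalidMeasurementError(
                f"pulse at t={p}: NPQ={npq:.3g}, qP={qp:.3g} outside tolerated range"
            )
        samples.append(
            QuenchingSample(p - trace.light_on, fm_p, f_p, fo_p, npq, qp, flagged)
        )
    return samples


def samples_to_curve(samples: Sequence[QuenchingSample], trace: FluorescenceTrace) -> InductionCurve:
    """Assemble extracted pulse samples into an induction curve with phases."""
    times = np.array([s.t for s in samples])
    duration = trace.light_off - trace.light_on
    phase = np.where(
        times <= 0, PHASE_DARK, np.where(times <= duration, PHASE_LIGHT, PHASE_RECOVERY)
    ).astype(object)
    curve = InductionCurve(
        times,
        np.array([s.npq for s in samples]),
        np.array([s.qp for s in samples]),
        trace.light_intensity,
        phase=phase,
        meta=dict(trace.meta),
    )
    curve.closure_ss = steady_state_closure(curve)
    return curve


def steady_state_closure(curve: InductionCurve, n_last: int = 3) -> float:
    """Mean of (1 - qP) over the final ``n_last`` illumination pulses, in [0, 1]."""
    m = curve.phase_mask(PHASE_LIGHT)
    if m.sum() < n_last:
        raise PhaseError(f"need at least {n_last} illumination points")
    qp_tail = curve.qp[m][-n_last:]
    return float(np.clip(np.mean(1.0 - qp_tail), 0.0, 1.0))


def resample_uniform(curve: InductionCurve, step: float = 10.0,
                     phase: str = PHASE_LIGHT) -> InductionCurve:
    """Linear interpolation onto the grid step, 2*step, ... within one phase.

    No extrapolation: the grid stops at the last observed point of the
    selected phase.  A curve already on the target grid is returned with
    identical values.
    """
    if step <= 0:
        raise ValidationError("step must be positive")
    m = curve.phase_mask(phase)
    if m.sum() < 2:
        raise PhaseError(f"phase {phase!r} has fewer than 2 points")
    t, npq, qp = curve.times[m], curve.npq[m], curve.qp[m]
    t0 = t[0] if phase != PHASE_LIGHT else 0.0
    grid = np.arange(t0 + step, t[-1] + step / 2, step)
    grid = grid[grid >= t[0] - 1e-9]
    if grid.size == 0:
        raise PhaseError("phase span shorter than one step")
    return InductionCurve(
        grid,
        np.interp(grid, t, npq),
        np.interp(grid, t, qp),
        curve.light_intensity,
        closure_ss=curve.closure_ss,
        phase=np.full(grid.size, phase, dtype=object),
        meta=dict(curve.meta),
    )


def _require_common_grid(curves: Sequence[InductionCurve]) -> np.ndarray:
    grid = curves[0].times
    for c in curves[1:]:
        if c.times.size != grid.size or not np.allclose(c.times, grid):
            raise GridMismatchError("curves are not on a common grid")
    return grid


def average_curves(group: Sequence[InductionCurve]):
    """Pointwise mean curve and standard error SE = sd / sqrt(n)."""
    if not group:
        raise ValidationError("empty group")
    grid = _require_common_grid(group)
    npq = np.vstack([c.npq for c in group])
    qp = np.vstack([c.qp for c in group])
    n = len(group)
    se = npq.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(grid.size)
    mean = InductionCurve(
        grid, npq.mean(axis=0), qp.mean(axis=0),
        float(np.mean([c.light_intensity for c in group])),
        phase=group[0].phase.copy(),
        meta={"n_averaged": n},
    )
    return mean, se


def difference_curve(a: InductionCurve, b: InductionCurve) -> InductionCurve:
    """Pointwise NPQ difference a - b (e.g. untreated minus inhibitor-treated)."""
    grid = _require_common_grid([a, b])
    return InductionCurve(
        grid, a.npq - b.npq, a.qp, a.light_intensity,
        phase=a.phase.copy(),
        meta={"difference_of": (a.meta.get("curve_id"), b.meta.get("curve_id"))},
    )


def partition_recovery(curve: InductionCurve, n_last: int = 2):
    """Split end-of-light NPQ into rapidly and slowly reversible parts.

    slow = mean NPQ over the final ``n_last`` recovery pulses; rapid is the
    remainder of the NPQ level at the end of illumination.
    """
    rec = curve.phase_mask(PHASE_RECOVERY)
    ill = curve.phase_mask(PHASE_LIGHT)
    if rec.sum() < n_last:
        raise PhaseError("curve has no (or too few) recovery-phase points")
    if not ill.any():
        raise PhaseError("curve has no illumination phase")
    slow = float(np.mean(curve.npq[rec][-n_last:]))
    rapid = float(curve.npq[ill][-1] - slow)
    return rapid, slow
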