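"""Synthetic NPQ induction datasets with known ground truth.

The generator emulates a saturating-pulse study design: curves measured on
many leaves across a ladder of actinic light intensities, each curve a
non-negative mixture of a few kinetic components whose amplitudes follow
smooth trends of the steady-state closure x = (1-qP)_ss.

Wild-type-like datasets plant three components:

* ``alpha`` -- zeaxanthin-associated quenching, taken from the indirect
  xanthophyll-cycle model so it carries the characteristic onset lag;
  amplitude follows a sigmoid of x (turning point 0.38, amplitude 2.1).
* ``beta``  -- pH/PsbS-associated, rises to a peak near 2 min then relaxes;
  amplitude follows a sloped sigmoid (turning point 0.126, final 0.69).
* ``gamma`` -- fast pH-associated phase with a local maximum at 60 s and a
  local minimum at 200 s (3.3 min); amplitude linear (0.13 x + 0.43).

npq1-like datasets (no zeaxanthin) replace alpha by the lag-free,
monotonically rising photoinhibition-like ``delta`` and make all three
amplitude trends linear (beta 0.4x+0.15, gamma 0.12x+0.14, delta 0.8x).

Biological noise: an independent multiplicative lognormal leaf effect per
curve and per component (sd 0.3, calibrated so trend fits on the synthetic
contributions reproduce the uncertainty scale of measured-leaf datasets of
this size), plus additive Gaussian noise per point (sd 0.02 NPQ units),
clipped at zero.  All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .errors import ValidationError
from .kinetics import KineticParams, simulate_xanthophyll, trend_value
from .pam import (
    PHASE_LIGHT,
    PHASE_RECOVERY,
    CurveDataset,
    FluorescenceTrace,
    InductionCurve,
    estimate_fo_prime,
)

ILLUMINATION_S = 600.0
RECOVERY_S = 300.0

#: indirect-model rates generating the planted alpha profile (s^-1)
ALPHA_K = 0.004
ALPHA_KB = 0.008


@dataclass
class ComponentShape:
    """A named, normalised induction profile p(t) with p(0) = 0, max = 1."""

    label: str
    fn: Callable[[np.ndarray], np.ndarray]
    params: Dict[str, float] = field(default_factory=dict)

    def values(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        v = np.asarray(self.fn(grid), dtype=float)
        if abs(float(self.fn(np.array([0.0]))[0])) > 1e-9:
            raise ValidationError(f"profile {self.label} must vanish at t=0")
        peak = v.max()
        if peak <= 0:
            raise ValidationError(f"profile {self.label} is non-positive on grid")
        return v / peak


def _alpha_fn(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.max() <= 0:
        return np.zeros_like(grid)
    params = KineticParams(k=ALPHA_K, k_b=ALPHA_KB)
    traj = simulate_xanthophyll(params, "indirect", np.sort(np.unique(np.append(grid, 0.0))))
    return np.interp(grid, traj.t, traj.npq_alpha)


def _biexp(k1: float, k2: float, a1: float, a2: float, m: float = 0.0):
    def fn(t):
        t = np.asarray(t, dtype=float)
        return a1 * (1 - np.exp(-k1 * t)) - a2 * (1 - np.exp(-k2 * t)) + m * t
    return fn


def _gamma_constants(k1: float = 1 / 20, k2: float = 1 / 100, a1: float = 1.0,
                     t_max: float = 60.0, t_min: float = 200.0):
    """Solve the second-exponential weight and slope so the profile is exactly
    stationary at the planted local maximum and minimum."""
    e1, e2 = np.exp(-k1 * t_max), np.exp(-k2 * t_max)
    f1, f2 = np.exp(-k1 * t_min), np.exp(-k2 * t_min)
    c = a1 * k1 * (e1 - f1) / (e2 - f2)      # = a2 * k2
    m = c * f2 - a1 * k1 * f1
    return c / k2, m


def canonical_profiles(grid: np.ndarray, genotype: str) -> List[ComponentShape]:
    """The planted component shapes for a genotype ('wt' or 'npq1')."""
    grid = np.asarray(grid, dtype=float)
    if grid.max() < ILLUMINATION_S - 1e-9:
        raise ValidationError("grid must cover the 0-600 s illumination span")
    a2g, mg = _gamma_constants()
    beta = ComponentShape(
        "beta", _biexp(1 / 45, 1 / 200, 1.7, 1.0),
        {"k1": 1 / 45, "k2": 1 / 200, "a1": 1.7, "a2": 1.0},
    )
    gamma = ComponentShape(
        "gamma", _biexp(1 / 20, 1 / 100, 1.0, a2g, mg),
        {"k1": 1 / 20, "k2": 1 / 100, "a1": 1.0, "a2": a2g, "m": mg},
    )
    if genotype == "wt":
        alpha = ComponentShape("alpha", _alpha_fn, {"k": ALPHA_K, "k_b": ALPHA_KB})
        return [alpha, beta, gamma]
    if genotype == "npq1":
        delta = ComponentShape(
            "delta", lambda t: 1 - np.exp(-np.asarray(t, float) / 100.0), {"tau": 100.0}
        )
        return [beta, gamma, delta]
    raise ValidationError(f"unknown genotype {genotype!r}")


def component_library(grid: np.ndarray) -> List[ComponentShape]:
    """All four canonical shapes (alpha, beta, gamma, delta) for labelling."""
    wt = canonical_profiles(grid, "wt")
    npq1 = canonical_profiles(grid, "npq1")
    seen = {s.label: s for s in wt + npq1}
    return [seen[k] for k in ("alpha", "beta", "gamma", "delta")]


# ------------------------------------------------------------- mixing


@dataclass
class MixingModel:
    """Per-component amplitude trends of closure plus the noise model.

    ``trends`` maps component label -> (kind, params) evaluated through the
    trend models of :mod:`npqunmix.kinetics`.  ``leaf_sd`` is the sd of the
    multiplicative lognormal leaf effect, ``point_sd`` the additive
    per-point Gaussian sd in NPQ units.
    """

    trends: Dict[str, Tuple[str, Dict[str, float]]]
    leaf_sd: float = 0.3
    point_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.leaf_sd < 0 or self.point_sd < 0:
            raise ValidationError("noise sds must be non-negative")
        xs = np.linspace(0, 1, 201)
        for label, (kind, params) in self.trends.items():
            if np.any(trend_value(kind, params, xs) < -1e-9):
                raise ValidationError(f"trend for {label} goes negative on [0,1]")

    @property
    def labels(self) -> List[str]:
        return list(self.trends)

    def amplitudes(self, x: float) -> np.ndarray:
        return np.array(
            [max(trend_value(kind, params, x), 0.0)
             for kind, params in self.trends.values()]
        )


def wt_mixing(leaf_sd: float = 0.3, point_sd: float = 0.02) -> MixingModel:
    return MixingModel(
        {
            "alpha": ("sigmoid", {"A": 2.1, "x0": 0.38, "w": 0.07}),
            "beta": ("sloped_sigmoid", {"A": 0.82, "x0": 0.126, "w": 0.015, "B": -0.15}),
            "gamma": ("linear", {"m": 0.13, "c": 0.43}),
        },
        leaf_sd=leaf_sd,
        point_sd=point_sd,
    )


def npq1_mixing(leaf_sd: float = 0.3, point_sd: float = 0.02) -> MixingModel:
    return MixingModel(
        {
            "beta": ("linear", {"m": 0.4, "c": 0.15}),
            "gamma": ("linear", {"m": 0.12, "c": 0.14}),
            "delta": ("linear", {"m": 0.8, "c": 0.0}),
        },
        leaf_sd=leaf_sd,
        point_sd=point_sd,
    )


@dataclass
class GroundTruth:
    """Planted profiles and per-curve amplitudes behind a synthetic dataset."""

    labels: List[str]
    grid: np.ndarray
    profiles: np.ndarray        # (K, T), max-normalised
    amplitudes: np.ndarray      # (n_curves, K), NPQ units (leaf effect included)
    closures: np.ndarray        # planted (1-qP)_ss per curve
    seed: int

    def noiseless_matrix(self) -> np.ndarray:
        return self.amplitudes @ self.profiles


def closure_from_light(intensity, half_sat: float = 300.0):
    """Steady-state closure x = I / (I + half_sat), a rectangular hyperbola.

    The default half-saturation (300 umol m^-2 s^-1) maps the 26-1074
    intensity ladder onto closures of roughly 0.08-0.78.
    """
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValidationError("intensity must be >= 0")
    out = intensity / (intensity + half_sat)
    return float(out) if out.ndim == 0 else out


def default_intensities(n_levels: int = 17, n_replicates: int = 5,
                        lo: float = 26.0, hi: float = 1074.0) -> np.ndarray:
    """The study design: log-spaced intensity levels with leaf replicates."""
    return np.repeat(np.geomspace(lo, hi, n_levels), n_replicates)


def generate_dataset(
    n_curves: int = 85,
    intensities: Optional[np.ndarray] = None,
    mixing: Optional[MixingModel] = None,
    seed: int = 0,
    genotype: str = "wt",
    step: float = 10.0,
    include_recovery: bool = True,
    half_sat: float = 300.0,
):
    """Generate a synthetic induction-curve dataset plus its ground truth.

    Per curve: closure from intensity, amplitudes = trend(x) * leaf effect,
    NPQ(t) = sum_k amplitude_k * profile_k(t) + additive noise (clipped at
    zero), and a consistent planted qP(t) whose final closure equals x.
    The recovery phase decays to the slowly reversible level (the delta
    amplitude when planted, else 15% of the end-of-light NPQ).
    """
    if n_curves < 1:
        raise ValidationError("n_curves must be >= 1")
    if mixing is None:
        mixing = wt_mixing() if genotype == "wt" else npq1_mixing()
    if intensities is None:
        base = default_intensities()
        intensities = base[np.arange(n_curves) % base.size]
    intensities = np.asarray(intensities, dtype=float)
    if intensities.size != n_curves:
        raise ValidationError("need one intensity per curve")

    grid = np.arange(step, ILLUMINATION_S + step / 2, step)
    shapes = canonical_profiles(np.append(grid, ILLUMINATION_S), genotype)
    if set(mixing.labels) != {s.label for s in shapes}:
        raise ValidationError("mixing trends do not match genotype components")
    shapes = [next(s for s in shapes if s.label == lab) for lab in mixing.labels]
    P = np.vstack([s.values(grid) for s in shapes])

    rng = np.random.default_rng(seed)
    closures = closure_from_light(intensities, half_sat=half_sat)
    t_rec = np.arange(ILLUMINATION_S + 30.0, ILLUMINATION_S + RECOVERY_S + 1e-9, 30.0)

    curves, amps_all = [], []
    for i in range(n_curves):
        x = float(closures[i])
        # biological leaf effect: each component's amplitude varies
        # independently between leaves (pool sizes, PsbS level, ...); this
        # per-component variation is also what keeps datasets whose trends
        # are all linear in closure (npq1) at full rank
        n_comp = len(mixing.labels)
        leaf = (rng.lognormal(0.0, mixing.leaf_sd, n_comp)
                if mixing.leaf_sd > 0 else np.ones(n_comp))
        amps = mixing.amplitudes(x) * leaf
        npq_ill = amps @ P + rng.normal(0.0, mixing.point_sd, grid.size)
        npq_ill = np.clip(npq_ill, 0.0, None)
        qp_ill = 1.0 - x * (1.0 - np.exp(-grid / 60.0))

        times, npq, qp = grid, npq_ill, qp_ill
        phase = np.full(grid.size, PHASE_LIGHT, dtype=object)
        if include_recovery:
            npq_end = float(amps @ P[:, -1])
            slow = (amps[mixing.labels.index("delta")]
                    if "delta" in mixing.labels else 0.15 * npq_end)
            npq_rec = slow + (npq_end - slow) * np.exp(-(t_rec - ILLUMINATION_S) / 60.0)
            npq_rec = np.clip(npq_rec + rng.normal(0.0, mixing.point_sd, t_rec.size), 0.0, None)
            qp_rec = 1.0 - x * np.exp(-(t_rec - ILLUMINATION_S) / 90.0)
            times = np.concatenate([grid, t_rec])
            npq = np.concatenate([npq_ill, npq_rec])
            qp = np.concatenate([qp_ill, qp_rec])
            phase = np.concatenate([phase, np.full(t_rec.size, PHASE_RECOVERY, dtype=object)])

        closure_ss = float(np.clip(np.mean(1.0 - qp_ill[-3:]), 0.0, 1.0))
        curves.append(InductionCurve(
            times, npq, qp, float(intensities[i]),
            closure_ss=closure_ss, phase=phase,
            meta={"curve_id": f"{genotype}-{i:03d}", "genotype": genotype},
        ))
        amps_all.append(amps)

    dataset = CurveDataset(curves, genotype=genotype, provenance="synthetic")
    truth = GroundTruth(
        labels=list(mixing.labels), grid=grid, profiles=P,
        amplitudes=np.vstack(amps_all), closures=closures, seed=seed,
    )
    return dataset, truth


# ----------------------------------------------------- raw-trace forward model


def simulate_pam_trace(
    curve: InductionCurve,
    fo: float = 0.5,
    fm: float = 2.5,
    light_on: float = 25.0,
    pulse_halfwidth: float = 0.4,
) -> FluorescenceTrace:
    """Forward-simulate a raw PAM trace realising a given induction curve.

    Per pulse: Fm' = Fm / (1 + NPQ) (Stern-Volmer inversion), Fo' from the
    same Oxborough-Baker estimator used at extraction, and
    F' = Fm' - qP * (Fm' - Fo').  The continuous trace holds F' levels
    between pulses and spikes to Fm' inside each 0.8 s pulse, so a
    round trip through ``extract_pulse_samples`` returns the planted NPQ
    and qP exactly.
    """
    if not 0 < fo < fm:
        raise ValidationError("need 0 < Fo < Fm")
    if np.any(curve.npq < 0):
        raise ValidationError("cannot simulate negative NPQ")
    eps = pulse_halfwidth + 0.11   # just outside the +/-0.5 s read-out window
    light_off = light_on + ILLUMINATION_S

    pts: List[Tuple[float, float]] = [(0.0, fo)]
    pulses = [light_on - 20.0]
    p0 = pulses[0]
    pts += [(p0 - eps, fo), (p0 - pulse_halfwidth, fm), (p0, fm),
            (p0 + pulse_halfwidth, fm), (p0 + eps, fo)]
    for t_i, npq_i, qp_i in zip(curve.times, curve.npq, curve.qp):
        if t_i <= 0:
            continue
        p = light_on + t_i
        fm_p = fm / (1.0 + npq_i)
        fo_p = estimate_fo_prime(fo, fm, fm_p)
        f_p = fm_p - qp_i * (fm_p - fo_p)
        pts += [(p - eps, f_p), (p - pulse_halfwidth, fm_p), (p, fm_p),
                (p + pulse_halfwidth, fm_p), (p + eps, f_p)]
        pulses.append(p)
    pts.append((pulses[-1] + 5.0, pts[-1][1]))

    arr = np.asarray(pts)
    return FluorescenceTrace(
        arr[:, 0], arr[:, 1], np.asarray(pulses), light_on, light_off,
        curve.light_intensity, meta=dict(curve.meta),
    )
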