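"""Contribution-trend fits and xanthophyll-cycle ODE models.

Two kinds of model live here:

1. Trends of component NPQ contribution versus steady-state closure
   x = (1-qP)_ss: ``sigmoid``, ``sloped_sigmoid`` and ``linear``.
2. The simplified violaxanthin -> antheraxanthin -> zeaxanthin de-epoxidation
   cascade.  Because violaxanthin carries two identical epoxide groups acted
   on by the same enzyme (VDE), the first step runs at twice the rate of the
   second: dV/dt = -2kV, dA/dt = 2kV - kA, dZ/dt = kA.  Quenching is either
   proportional to zeaxanthin itself ("direct") or to a quencher formed by a
   subsequent binding step dQ/dt = k_b * Z * (1 - Q/Q_max) ("indirect"); the
   extra step delays the onset, giving ~t^3 instead of ~t^2 growth at small t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit, least_squares
from scipy.special import expit

from .errors import ValidationError

# ----------------------------------------------------------------- trends


def sigmoid(x, A, x0, w):
    """Logistic step A / (1 + exp(-(x - x0)/w)); x0 is the turning point."""
    return A * expit((x - x0) / w)


def sloped_sigmoid(x, A, x0, w, B):
    """Sigmoidal rise with a superimposed linear slope.

    f(x) = A * logistic((x - x0)/w) + B * (x - x0).  With B < 0 this rises
    through the turning point x0, peaks just above it, and settles toward
    the final amplitude f(1).
    """
    return A * expit((x - x0) / w) + B * (x - x0)


def linear(x, m, c):
    return m * x + c


TREND_MODELS: Dict[str, Callable] = {
    "sigmoid": sigmoid,
    "sloped_sigmoid": sloped_sigmoid,
    "linear": linear,
}

TREND_PARAM_NAMES = {
    "sigmoid": ("A", "x0", "w"),
    "sloped_sigmoid": ("A", "x0", "w", "B"),
    "linear": ("m", "c"),
}


def trend_value(kind: str, params: Dict[str, float], x):
    """Evaluate a named trend at closure value(s) x."""
    fn = TREND_MODELS[kind]
    return fn(np.asarray(x, dtype=float), *[params[p] for p in TREND_PARAM_NAMES[kind]])


@dataclass
class ContributionFit:
    """Result of fitting one contribution-vs-closure trend."""

    kind: str
    params: Dict[str, float]
    stderr: Dict[str, float]
    r2: float
    success: bool = True
    message: str = ""

    def final_amplitude(self) -> float:
        """Trend value at full closure x = 1."""
        return float(trend_value(self.kind, self.params, 1.0))


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)


def fit_contribution_trend(x, y, kind: str, n_starts: int = 5,
                           seed: int = 0) -> ContributionFit:
    """Least-squares fit of a contribution trend with multi-start restarts.

    ``x`` is the per-curve closure (1-qP)_ss in [0, 1]; ``y`` the NPQ-unit
    contribution of one component.  Nonlinear kinds restart from ``n_starts``
    seeded perturbations of a heuristic initial guess; the best sum of
    squares wins.  Non-convergence is reported via ``success=False``, never
    silently.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValidationError("need >= 5 (x, y) points")
    if np.any((x < -1e-9) | (x > 1 + 1e-9)):
        raise ValidationError("closure values must lie in [0, 1]")
    if kind not in TREND_MODELS:
        raise ValidationError(f"unknown trend kind {kind!r}")
    names = TREND_PARAM_NAMES[kind]
    fn = TREND_MODELS[kind]

    if kind == "linear":
        coeffs, cov = np.polyfit(x, y, 1, cov=True)
        params = {"m": float(coeffs[0]), "c": float(coeffs[1])}
        stderr = {"m": float(np.sqrt(cov[0, 0])), "c": float(np.sqrt(cov[1, 1]))}
        return ContributionFit(kind, params, stderr, _r2(y, np.polyval(coeffs, x)))

    span = max(y.max() - min(y.min(), 0.0), 1e-6)
    x_half = float(x[np.argmin(np.abs(y - 0.5 * y.max()))])
    if kind == "sigmoid":
        p0 = np.array([y.max(), x_half, 0.1])
        lo, hi = [0, 0, 1e-4], [np.inf, 1, 1]
    else:  # sloped_sigmoid
        p0 = np.array([y.max(), x_half, 0.05, -0.1 * span])
        lo, hi = [0, 0, 1e-4, -np.inf], [np.inf, 1, 1, np.inf]

    rng = np.random.default_rng(seed)
    best = None
    for i in range(n_starts):
        start = p0 if i == 0 else p0 * rng.lognormal(0.0, 0.3, p0.size)
        start[-1] = p0[-1] * (1 if i == 0 else rng.lognormal(0.0, 0.3))
        start = np.clip(start, np.asarray(lo) + 1e-9, np.asarray(hi))
        try:
            popt, pcov = curve_fit(fn, x, y, p0=start, bounds=(lo, hi), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum((y - fn(x, *popt)) ** 2))
        if best is None or ss < best[0]:
            best = (ss, popt, pcov)
    if best is None:
        return ContributionFit(kind, {}, {}, 0.0, success=False,
                               message="no restart converged")
    _, popt, pcov = best
    sds = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return ContributionFit(
        kind,
        dict(zip(names, map(float, popt))),
        dict(zip(names, map(float, sds))),
        _r2(y, fn(x, *popt)),
    )


# ------------------------------------------------- xanthophyll-cycle ODEs


@dataclass
class KineticParams:
    """Rates of the simplified xanthophyll cascade.

    ``k`` is the antheraxanthin->zeaxanthin de-epoxidation rate (s^-1); the
    violaxanthin->antheraxanthin rate is fixed at 2k.  ``k_b`` (s^-1 per
    unit zeaxanthin) is the quencher-binding rate of the indirect model.
    """

    k: float
    k_b: Optional[float] = None
    v0: float = 1.0
    q_max: float = 1.0
    q_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.k <= 0 or self.v0 <= 0 or self.q_max <= 0:
            raise ValidationError("rates and pools must be positive")
        if self.k_b is not None and self.k_b <= 0:
            raise ValidationError("rates and pools must be positive")


@dataclass
class KineticTrajectory:
    t: np.ndarray
    V: np.ndarray
    A: np.ndarray
    Z: np.ndarray
    Q: np.ndarray
    npq_alpha: np.ndarray


def simulate_xanthophyll(params: KineticParams, kind: str,
                         grid: np.ndarray) -> KineticTrajectory:
    """Integrate the de-epoxidation cascade on ``grid`` (seconds, from 0).

    ``kind`` selects the quenching readout: ``direct`` (npq ~ Z) or
    ``indirect`` (npq ~ Q from the binding step).  Stiff-safe integration
    (LSODA) at relative tolerance 1e-8.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] < 0 or np.any(np.diff(grid) <= 0):
        raise ValidationError("grid must be increasing and start at t >= 0")
    if kind not in ("direct", "indirect"):
        raise ValidationError(f"unknown model kind {kind!r}")
    if kind == "indirect" and params.k_b is None:
        raise ValidationError("indirect model needs k_b")
    k, kb, qmax = params.k, params.k_b, params.q_max

    def rhs(_t, y):
        V, A, Z, Q = y
        dq = kb * Z * (1.0 - Q / qmax) if kind == "indirect" else 0.0
        return [-2 * k * V, 2 * k * V - k * A, k * A, dq]

    t_eval = grid if grid[0] == 0 else np.concatenate([[0.0], grid])
    sol = solve_ivp(rhs, (0.0, float(grid[-1])), [params.v0, 0.0, 0.0, 0.0],
                    t_eval=t_eval, method="LSODA", rtol=1e-8, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    off = 0 if grid[0] == 0 else 1
    V, A, Z, Q = (sol.y[i][off:] for i in range(4))
    npq = params.q_scale * (Q if kind == "indirect" else Z)
    return KineticTrajectory(grid, V, A, Z, Q, npq)


def direct_z_closed_form(t, v0: float, k: float):
    """Analytic zeaxanthin build-up Z(t) = V0 (1 - e^{-kt})^2 of the cascade."""
    return v0 * (1.0 - np.exp(-k * np.asarray(t, dtype=float))) ** 2


def fit_alpha_kinetics(profile: np.ndarray, grid: np.ndarray, kind: str,
                       n_starts: int = 5, seed: int = 0):
    """Fit the max-normalised model output to a normalised alpha profile.

    Free parameters: log10(k) (both kinds) plus log10(k_b) (indirect).
    Returns ``(KineticParams, r2)``; comparing r2 across kinds tests whether
    the onset lag requires the binding step.
    """
    profile = np.asarray(profile, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if profile.max() <= 0:
        raise ValidationError("degenerate (all-zero) profile")
    if np.any(profile < -1e-9):
        raise ValidationError("profile must be non-negative")
    profile = profile / profile.max()

    def model(logp):
        k = 10.0 ** logp[0]
        kb = 10.0 ** logp[1] if kind == "indirect" else None
        traj = simulate_xanthophyll(KineticParams(k=k, k_b=kb), kind, grid)
        m = traj.npq_alpha
        return m / m.max() if m.max() > 0 else m

    p0 = np.array([-2.3, -2.1])[: (2 if kind == "indirect" else 1)]
    rng = np.random.default_rng(seed)
    best = None
    for i in range(n_starts):
        start = p0 if i == 0 else p0 + rng.normal(0.0, 0.5, p0.size)
        try:
            res = least_squares(lambda lp: model(lp) - profile, start,
                                method="lm", x_scale="jac", max_nfev=400)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("alpha kinetic fit did not converge from any start")
    k = 10.0 ** best.x[0]
    kb = 10.0 ** best.x[1] if kind == "indirect" else None
    params = KineticParams(k=k, k_b=kb)
    return params, _r2(profile, model(best.x))
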