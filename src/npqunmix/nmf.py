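"""Guided non-negative matrix factorisation of the curve matrix.

X (curves x time) ~ H W with H >= 0 the per-curve contributions (NPQ units)
and W >= 0 the component induction profiles.  The factorisation is guided:
H is initialised from the phasor-derived barycentric abundances scaled by
each curve's mean NPQ, W from a row-wise non-negative least-squares solve,
and both are then refined by Lee-Seung multiplicative updates on the
Frobenius objective ||X - H W||_F^2, which never increase the loss.
Profiles are normalised to unit maximum with the scale absorbed into H.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import nnls

from .errors import ValidationError
from .pam import InductionCurve
from .pca import adjusted_r2

_EPS = 1e-9


@dataclass
class ComponentSet:
    """K normalised profiles with per-curve contributions and fit scores."""

    profiles: np.ndarray            # (K, T), each row max 1
    contributions: np.ndarray       # (n_curves, K), NPQ units
    labels: List[str] = field(default_factory=list)
    adj_r2: Optional[np.ndarray] = None
    loss_trace: Optional[np.ndarray] = None

    @property
    def k(self) -> int:
        return self.profiles.shape[0]

    def reconstruction(self) -> np.ndarray:
        return self.contributions @ self.profiles


def profile_cosine(a: np.ndarray, b: np.ndarray, center: bool = True) -> float:
    """Cosine similarity between two profiles.

    By default profiles are mean-centred first: raw cosines of non-negative
    rising curves are dominated by the shared DC component and saturate near
    1, whereas the centred cosine compares line shapes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if center:
        a = a - a.mean()
        b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def init_factors(X: np.ndarray, abundances: np.ndarray):
    """Guided initial factors from per-curve abundances.

    ``abundances`` rows must sum to one (barycentric weights).  H0 scales
    each row by the curve's mean NPQ; W0 solves X ~ H0 W0 by NNLS per time
    point.  Entries are floored at 1e-9 to avoid zero locking.
    """
    X = np.asarray(X, dtype=float)
    A = np.asarray(abundances, dtype=float)
    if A.shape[0] != X.shape[0]:
        raise ValidationError("one abundance row per curve required")
    if not np.allclose(A.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("abundance rows must sum to 1")
    means = X.mean(axis=1)
    if np.any(means <= 0):
        raise ValidationError("all-zero curve cannot be factorised")
    H0 = np.maximum(A * means[:, None], _EPS)
    W0 = np.empty((A.shape[1], X.shape[1]))
    for j in range(X.shape[1]):
        W0[:, j], _ = nnls(H0, X[:, j])
    return H0, np.maximum(W0, _EPS)


def _loss(X, H, W) -> float:
    return float(np.linalg.norm(X - H @ W) ** 2)


def run_nmf(X: np.ndarray, H0: np.ndarray, W0: np.ndarray,
            tol: float = 1e-6, max_iter: int = 10000) -> ComponentSet:
    """Lee-Seung multiplicative updates from the guided initialisation.

    Stops when the relative loss change drops below ``tol`` or after
    ``max_iter`` iterations.  The loss trace is monotonically
    non-increasing (asserted); the result is normalised so every profile
    has unit maximum, with the scale absorbed into the contributions.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)) or np.any(X < 0):
        raise ValidationError("X must be finite and non-negative")
    if tol <= 0:
        raise ValidationError("tol must be positive")
    H = np.maximum(np.asarray(H0, dtype=float).copy(), _EPS)
    W = np.maximum(np.asarray(W0, dtype=float).copy(), _EPS)
    if H.shape[0] != X.shape[0] or W.shape[1] != X.shape[1] or H.shape[1] != W.shape[0]:
        raise ValidationError("factor shapes inconsistent with X")

    trace = [_loss(X, H, W)]
    # absolute slack keeps the monotonicity guard meaningful when the loss
    # approaches floating-point zero (exactly factorisable X)
    slack = 1e-14 * max(trace[0], 1.0)
    for _ in range(max_iter):
        H *= (X @ W.T) / np.maximum(H @ (W @ W.T), _EPS)
        H = np.maximum(H, _EPS)
        W *= (H.T @ X) / np.maximum((H.T @ H) @ W, _EPS)
        W = np.maximum(W, _EPS)
        loss = _loss(X, H, W)
        if loss > trace[-1] * (1 + 1e-10) + slack:
            raise RuntimeError("NMF loss increased; multiplicative update broken")
        rel = (trace[-1] - loss) / max(trace[-1], 1e-300)
        trace.append(loss)
        if rel < tol:
            break

    scale = W.max(axis=1)
    W = W / scale[:, None]
    H = H * scale[None, :]
    return ComponentSet(
        profiles=W, contributions=H,
        labels=["unassigned"] * W.shape[0],
        loss_trace=np.asarray(trace),
    )


def score_fit(X: np.ndarray, cset: ComponentSet) -> np.ndarray:
    """Per-curve adjusted r^2 of the H W reconstruction (p = K)."""
    X = np.asarray(X, dtype=float)
    rec = cset.reconstruction()
    if rec.shape != X.shape:
        raise ValidationError("component set does not match the data shape")
    scores = np.array([adjusted_r2(X[i], rec[i], cset.k) for i in range(X.shape[0])])
    cset.adj_r2 = scores
    return scores


def label_components(cset: ComponentSet, reference: Sequence, grid: np.ndarray,
                     threshold: float = 0.8) -> ComponentSet:
    """Greedy max-cosine assignment of profiles to a reference shape library.

    ``reference`` is a sequence of ComponentShape objects evaluated on
    ``grid``.  Pairs are assigned best-first; profiles whose best remaining
    cosine falls below ``threshold`` stay 'unassigned'.
    """
    if not reference:
        raise ValidationError("reference library is empty")
    ref_vals = {s.label: s.values(grid) for s in reference}
    sims = {(i, lab): profile_cosine(cset.profiles[i], v)
            for i in range(cset.k) for lab, v in ref_vals.items()}
    labels = ["unassigned"] * cset.k
    used_i, used_lab = set(), set()
    for (i, lab), c in sorted(sims.items(), key=lambda kv: -kv[1]):
        if c < threshold:
            break
        if i in used_i or lab in used_lab:
            continue
        labels[i] = lab
        used_i.add(i)
        used_lab.add(lab)
    cset.labels = labels
    return cset


def deduplicate_profiles(profiles: Sequence[np.ndarray],
                         threshold: float = 0.9) -> List[int]:
    """Indices of distinct profiles: greedy, merging pairs with cosine >= threshold."""
    reps: List[int] = []
    for i, p in enumerate(profiles):
        if all(profile_cosine(p, profiles[r]) < threshold for r in reps):
            reps.append(i)
    return reps


def nnls_project(curve, profiles: np.ndarray):
    """Non-negative least-squares weights of one curve on given profiles.

    ``curve`` may be an InductionCurve (its NPQ series is used) or a plain
    series on the profile grid.  Returns ``(weights, r2)``.
    """
    y = curve.npq if isinstance(curve, InductionCurve) else np.asarray(curve, dtype=float)
    P = np.atleast_2d(np.asarray(profiles, dtype=float))
    if P.size == 0 or P.shape[0] == 0:
        raise ValidationError("profile set is empty")
    if P.shape[1] != y.size:
        raise ValidationError("profiles are not on the curve grid")
    w, _ = nnls(P.T, y)
    yhat = w @ P
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - yhat) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return w, r2
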