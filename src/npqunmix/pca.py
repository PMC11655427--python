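"""PCA of the mean-centred curve matrix, scree-elbow counting, scoring.

The curve matrix X (curves x time points) is mean-centred and decomposed;
curves are weighted equally and not normalised per curve, because the NPQ
amplitude itself carries the light-intensity dependence being unmixed.
The number of strongly varying components is read off the scree plot as
the point of maximum curvature (second difference) of the explained-
variance sequence; the elbow index marks the first component at the noise
floor, so ``retained = elbow - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from sklearn.decomposition import PCA as _SKPCA

from .errors import ValidationError
from .pam import CurveDataset


@dataclass
class PCAResult:
    mean_curve: np.ndarray
    components: np.ndarray          # (k, T), orthonormal rows
    coefficients: np.ndarray        # (n, k) scores
    explained_fraction: np.ndarray  # (k,), non-increasing, sums to <= 1
    grid: np.ndarray


@dataclass
class ElbowResult:
    """Scree elbow (1-based component index) and the retained count.

    ``fallback`` is set when the scree curve has no convex kink and the
    90% cumulative-variance rule was used instead.
    """

    elbow_index: int
    n_retained: int
    fallback: bool = False

    def __int__(self) -> int:
        return self.elbow_index


def _as_matrix(dataset: Union[CurveDataset, np.ndarray], step: float):
    if isinstance(dataset, CurveDataset):
        return dataset.to_matrix(step=step)
    X = np.asarray(dataset, dtype=float)
    return X, np.arange(step, step * (X.shape[1] + 0.5), step)


def run_pca(dataset: Union[CurveDataset, np.ndarray], step: float = 10.0) -> PCAResult:
    """PCA of the mean-centred curve matrix.

    Sign convention: each component is oriented so that its element of
    maximum magnitude is positive, making vertex placement downstream
    reproducible.
    """
    X, grid = _as_matrix(dataset, step)
    if X.shape[0] < 2:
        raise ValidationError("PCA needs at least 2 curves")
    if not np.all(np.isfinite(X)):
        raise ValidationError("curve matrix contains NaN/inf")
    k = min(X.shape[0] - 1, X.shape[1])
    pca = _SKPCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    comps = pca.components_.copy()
    total_var = np.sum(np.var(X, axis=0, ddof=1))
    # guard against pure rounding variance in a constant dataset
    tiny = 1e-20 * max(float(np.mean(X**2)), 1e-300)
    frac = (pca.explained_variance_ / total_var if total_var > tiny
            else np.zeros(k))

    flip = np.sign(comps[np.arange(k), np.argmax(np.abs(comps), axis=1)])
    flip[flip == 0] = 1.0
    comps *= flip[:, None]
    scores = scores * flip[None, :]
    return PCAResult(X.mean(axis=0), comps, scores, frac, grid)


def scree_elbow(explained_fraction: np.ndarray, cumulative: float = 0.9) -> ElbowResult:
    """Locate the scree elbow as the maximum second difference.

    For fractions f_1 >= f_2 >= ..., the curvature c_i = f_{i-1} - 2 f_i +
    f_{i+1} is computed for i = 2..m-1; the elbow is argmax(c) + 1 (earliest
    index on ties), i.e. the first component at the noise floor.  When no
    curvature is positive the scree has no kink and the retained count
    falls back to the smallest r with cumulative variance >= ``cumulative``.
    """
    f = np.asarray(explained_fraction, dtype=float)
    if f.size < 3:
        raise ValidationError("need at least 3 explained-variance entries")
    curvature = f[:-2] - 2.0 * f[1:-1] + f[2:]   # c at components 2..m-1
    if curvature.max() > 1e-9:                   # fp-robust "positive"
        i = int(np.argmax(curvature)) + 2        # 1-based component index
        return ElbowResult(elbow_index=i + 1, n_retained=i)
    r = int(np.searchsorted(np.cumsum(f), cumulative) + 1)
    r = min(r, f.size)
    return ElbowResult(elbow_index=r + 1, n_retained=r, fallback=True)


def adjusted_r2(y: np.ndarray, yhat: np.ndarray, n_params: int) -> float:
    """Adjusted r^2 = 1 - (1 - r^2)(n - 1)/(n - p - 1)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if n_params >= n - 1:
        raise ValidationError("too many parameters for adjusted r^2")
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def reconstruct(result: PCAResult, n_components: int) -> np.ndarray:
    """Mean + truncated score * loading reconstruction of every curve."""
    if n_components > result.components.shape[0]:
        raise ValidationError("more components requested than available")
    rec = result.mean_curve[None, :]
    if n_components:
        rec = rec + result.coefficients[:, :n_components] @ result.components[:n_components]
    else:
        rec = np.repeat(rec, result.coefficients.shape[0], axis=0)
    return rec


def reconstruct_and_score(result: PCAResult, n_components: int,
                          dataset: Union[CurveDataset, np.ndarray],
                          step: float = 10.0) -> np.ndarray:
    """Per-curve adjusted r^2 of the truncated PCA reconstruction."""
    X, _ = _as_matrix(dataset, step)
    rec = reconstruct(result, n_components)
    return np.array([adjusted_r2(X[i], rec[i], n_components) for i in range(X.shape[0])])
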