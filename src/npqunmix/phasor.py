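"""Full-harmonic phasor analysis (FH-PhA) of induction curves.

Each curve y_0..y_{N-1} on a uniform grid maps to a 2-D point via its
discrete Fourier coefficients F_n: per harmonic, G_n = Re(F_n)/F_0 and
S_n = -Im(F_n)/F_0 (positive S for early-peaking curves); the full-harmonic
coordinates are the means of G_n and S_n over harmonics n = 1..H.

Because both coordinates are ratios of linear functionals sharing the
denominator F_0 (the curve area), the phasor of any non-negative mixture
y = sum a_i y_i is exactly the convex combination of the component phasors
with weights a_i * area_i / sum_j a_j * area_j.  That linearity is what
lets a triangle anchored on the principal components unmix three-component
data by barycentric coordinates: two vertices come from extreme PCA
reconstructions, and the third follows from the data-cloud centroid via
v3 = 3 * centroid - v1 - v2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import (
    DegenerateTriangleError,
    ExcessiveClippingError,
    UndefinedPhasorError,
    ValidationError,
)


@dataclass(frozen=True)
class PhasorPoint:
    g: float
    s: float

    def as_array(self) -> np.ndarray:
        return np.array([self.g, self.s])


@dataclass
class TriangleModel:
    """Three phasor vertices plus the data-cloud centroid.

    ``provenance`` records how each vertex was obtained
    (``pc1`` / ``pc2`` / ``extrapolated``).
    """

    v1: PhasorPoint
    v2: PhasorPoint
    v3: PhasorPoint
    centroid: PhasorPoint
    provenance: Tuple[str, str, str] = ("pc1", "pc2", "extrapolated")
    area_tol: float = 1e-12

    @property
    def vertices(self) -> np.ndarray:
        return np.vstack([v.as_array() for v in (self.v1, self.v2, self.v3)])

    @property
    def area(self) -> float:
        (x1, y1), (x2, y2), (x3, y3) = self.vertices
        return abs((x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)) / 2.0

    def __post_init__(self) -> None:
        if self.area <= self.area_tol:
            raise DegenerateTriangleError("triangle vertices are (near-)collinear")


def phasor_transform(values: np.ndarray, n_harmonics: Optional[int] = None) -> PhasorPoint:
    """Full-harmonic phasor of a uniformly sampled non-negative series.

    ``n_harmonics`` defaults to floor((N-1)/2), every harmonic below Nyquist.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or y.size < 4:
        raise ValidationError("need a 1-D series of length >= 4")
    if not np.all(np.isfinite(y)):
        raise ValidationError("series contains NaN/inf")
    n = y.size
    h_max = (n - 1) // 2
    h = h_max if n_harmonics is None else int(n_harmonics)
    if not 1 <= h <= h_max:
        raise ValidationError(f"n_harmonics must be in [1, {h_max}]")
    f = np.fft.rfft(y)
    f0 = f[0].real
    if abs(f0) < 1e-300:
        raise UndefinedPhasorError("zero-area curve has no phasor")
    g = float(np.mean(f[1:h + 1].real) / f0)
    s = float(-np.mean(f[1:h + 1].imag) / f0)
    return PhasorPoint(g, s)


def phasor_cloud(X: np.ndarray, n_harmonics: Optional[int] = None) -> np.ndarray:
    """Phasor coordinates (n_curves, 2) of every row of the curve matrix."""
    return np.vstack([phasor_transform(row, n_harmonics).as_array() for row in X])


def pc_vertex(mean_curve: np.ndarray, component: np.ndarray, scale: float,
              n_harmonics: Optional[int] = None,
              max_clip_fraction: float = 0.05) -> PhasorPoint:
    """Phasor of the extreme reconstruction mean + scale * component.

    Principal components are zero-mean, so their raw phasor is undefined
    (F_0 = 0); the vertex is instead placed at the phasor of the most
    extreme admissible reconstruction along the component.  Negative
    excursions are clipped at zero; if the clipped mass exceeds
    ``max_clip_fraction`` of the curve area the scale is too large and an
    error asks the user to reduce it.
    """
    curve = np.asarray(mean_curve, dtype=float) + scale * np.asarray(component, dtype=float)
    clipped = np.clip(curve, 0.0, None)
    area = float(clipped.sum())
    lost = float(np.sum(clipped - curve))
    if area <= 0 or lost > max_clip_fraction * area:
        raise ExcessiveClippingError(
            f"extreme reconstruction loses {lost:.3g} of area {area:.3g} when "
            "clipped at zero; reduce the vertex scale"
        )
    return phasor_transform(clipped, n_harmonics)


def third_vertex(v1: PhasorPoint, v2: PhasorPoint, centroid: PhasorPoint) -> PhasorPoint:
    """Extrapolate the remaining vertex from two vertices and the centroid."""
    c = 3.0 * centroid.as_array() - v1.as_array() - v2.as_array()
    return PhasorPoint(float(c[0]), float(c[1]))


def barycentric_abundances(p: PhasorPoint, triangle: TriangleModel):
    """Barycentric weights of a phasor point in the component triangle.

    Solves [v1 v2 v3; 1 1 1] w = [p; 1].  Weights sum to one; negative
    weights (points outside the triangle, e.g. from noise) are clipped to
    zero and renormalised, with ``clipped=True`` flagged.
    """
    M = np.vstack([triangle.vertices.T, np.ones(3)])
    rhs = np.array([p.g, p.s, 1.0])
    try:
        w = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateTriangleError(str(exc)) from exc
    clipped = bool(np.any(w < -1e-12))
    if clipped:
        w = np.clip(w, 0.0, None)
        total = w.sum()
        if total <= 0:
            raise DegenerateTriangleError("point projects outside a degenerate triangle")
        w = w / total
    return w, clipped


def raw_barycentric(points: np.ndarray, triangle: TriangleModel) -> np.ndarray:
    """Unclipped barycentric coordinates (rows sum to 1, may be negative)."""
    M = np.vstack([triangle.vertices.T, np.ones(3)])
    rhs = np.vstack([points.T, np.ones(points.shape[0])])
    try:
        return np.linalg.solve(M, rhs).T
    except np.linalg.LinAlgError as exc:
        raise DegenerateTriangleError(str(exc)) from exc


def inflate_triangle(points: np.ndarray, triangle: TriangleModel,
                     quantile: float = 0.8):
    """Inflate a triangle about the data centroid to enclose the phasor cloud.

    Extreme-reconstruction vertices necessarily sit inside the data cloud,
    whereas pure-component phasors lie at (or beyond) its corners.  Scaling
    each vertex v -> c + f (v - c) rescales barycentric coordinates
    affinely, so the smallest factor enclosing a point with minimum
    coordinate w_min is 1 - 3 w_min.  The factor is taken at ``quantile``
    of the per-point requirement, leaving noise-driven outliers to the
    clip-and-renormalise policy rather than letting them set the simplex.

    Returns ``(inflated_triangle, factor)``.
    """
    w = raw_barycentric(points, triangle)
    need = 1.0 - 3.0 * w.min(axis=1)
    f = max(1.0, float(np.quantile(need, quantile)))
    c = triangle.centroid.as_array()
    verts = [PhasorPoint(*(c + f * (v.as_array() - c)))
             for v in (triangle.v1, triangle.v2, triangle.v3)]
    return TriangleModel(*verts, centroid=triangle.centroid,
                         provenance=triangle.provenance), f


def fit_enclosing_simplex(points: np.ndarray, triangle: TriangleModel,
                          mu: float = 2.0) -> TriangleModel:
    """Refine a triangle to the minimum-area simplex enclosing the cloud.

    Minimises area + mu * (total out-of-triangle barycentric mass) over the
    three vertices, starting from ``triangle`` (Nelder-Mead on the
    standardised cloud).  This is the classic minimum-volume endmember
    criterion: with curves sampling the mixing simplex's edges, its
    vertices approach the pure-component phasors much more closely than
    extreme PCA reconstructions can.  ``mu`` balances shrinkage against
    enclosure; a handful of noise outliers may stay outside.
    """
    from scipy.optimize import minimize

    c, s = points.mean(axis=0), float(points.std(axis=0).mean())
    if s <= 0:
        raise DegenerateTriangleError("phasor cloud has zero spread")
    P = np.vstack([((points - c) / s).T, np.ones(points.shape[0])])

    def objective(v):
        V = v.reshape(3, 2)
        M = np.vstack([V.T, np.ones(3)])
        try:
            w = np.linalg.solve(M, P)
        except np.linalg.LinAlgError:
            return 1e6
        area = abs(np.linalg.det(np.c_[V[1] - V[0], V[2] - V[0]])) / 2.0
        return area + mu * float(np.clip(-w, 0.0, None).sum())

    v0 = ((triangle.vertices - c) / s).ravel()
    res = minimize(objective, v0, method="Nelder-Mead",
                   options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-9})
    verts = res.x.reshape(3, 2) * s + c
    return TriangleModel(*[PhasorPoint(*v) for v in verts],
                         centroid=triangle.centroid,
                         provenance=triangle.provenance)


def abundance_table(points: np.ndarray, triangle: TriangleModel):
    """Barycentric weights for a whole phasor cloud.

    Returns ``(W, clipped_flags)``; the fraction of clipped (out-of-
    triangle) curves is ``clipped_flags.mean()``.
    """
    W = np.empty((points.shape[0], 3))
    flags = np.empty(points.shape[0], dtype=bool)
    for i, (g, s) in enumerate(points):
        W[i], flags[i] = barycentric_abundances(PhasorPoint(g, s), triangle)
    return W, flags
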