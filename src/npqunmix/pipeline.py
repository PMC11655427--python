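"""End-to-end decomposition: PCA -> scree elbow -> phasor triangle -> NMF.

The component count follows the staged logic: the scree elbow counts the
strongly varying principal components (retained = elbow - 1) and the
phasor triangle contributes one weakly varying extrapolated component, so
K = retained + 1.  When retained != 2 the triangle construction does not
apply (it is inherently three-cornered) and the NMF falls back to a
uniform-abundance initialisation, which is reported in the result.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .nmf import ComponentSet, init_factors, label_components, run_nmf, score_fit
from .pam import CurveDataset
from .pca import ElbowResult, PCAResult, run_pca, scree_elbow
from .phasor import (
    TriangleModel,
    abundance_table,
    fit_enclosing_simplex,
    inflate_triangle,
    pc_vertex,
    phasor_cloud,
    phasor_transform,
    third_vertex,
)
from .synth import component_library


@dataclass
class PipelineConfig:
    """Tunable knobs of the decomposition pipeline."""

    step: float = 10.0                 # illumination resampling grid (s)
    n_harmonics: Optional[int] = 10    # harmonics averaged in the phasor
    vertex_quantile: float = 0.95      # coefficient quantile setting PC vertex scale
    nmf_tol: float = 1e-9
    nmf_max_iter: int = 300000
    enclose_quantile: float = 0.8     # triangle inflation: cloud fraction enclosed
    simplex_mu: float = 2.0            # enclosure penalty of the min-area refinement
    label_threshold: float = 0.8
    dedup_threshold: float = 0.9
    elbow_cumulative: float = 0.9      # fallback cumulative-variance rule
    n_components: Optional[int] = None # manual K override
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step <= 0 or self.nmf_tol <= 0 or self.nmf_max_iter < 1:
            raise ValueError("tolerances and iteration counts must be positive")


@dataclass
class DecompositionResult:
    pca: PCAResult
    elbow: ElbowResult
    n_components: int
    components: ComponentSet
    triangle: Optional[TriangleModel] = None
    abundances: Optional[np.ndarray] = None
    phasors: Optional[np.ndarray] = None
    inflation_factor: float = 1.0
    clipped_fraction: float = 0.0
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def provenance(self) -> dict:
        """Machine-readable record sufficient to reproduce the run."""
        return {
            "config": asdict(self.config),
            "elbow": {"index": self.elbow.elbow_index,
                      "retained": self.elbow.n_retained,
                      "fallback": self.elbow.fallback},
            "n_components": self.n_components,
            "inflation_factor": self.inflation_factor,
            "clipped_fraction": self.clipped_fraction,
            "labels": self.components.labels,
        }


def build_triangle(pca: PCAResult, config: PipelineConfig,
                   n_harmonics: Optional[int] = None) -> TriangleModel:
    """Anchor the phasor triangle on the two leading PCs and the centroid.

    Vertices 1 and 2 are phasors of the extreme reconstructions along PC1
    and PC2 (scale = the ``vertex_quantile`` quantile of |coefficients|);
    the centroid is the phasor of the mean curve and the third vertex is
    extrapolated as 3*centroid - v1 - v2.
    """
    if n_harmonics is None:
        n_harmonics = config.n_harmonics
    centroid = phasor_transform(pca.mean_curve, n_harmonics)
    verts = []
    for j in range(2):
        scale = float(np.quantile(np.abs(pca.coefficients[:, j]), config.vertex_quantile))
        verts.append(pc_vertex(pca.mean_curve, pca.components[j], scale,
                               n_harmonics))
    v3 = third_vertex(verts[0], verts[1], centroid)
    return TriangleModel(verts[0], verts[1], v3, centroid)


def decompose(dataset: CurveDataset,
              config: Optional[PipelineConfig] = None) -> DecompositionResult:
    """Run the full unmixing pipeline on an induction-curve dataset."""
    config = config or PipelineConfig()
    dataset.closures()  # enforce: closure_ss set on every curve
    X, grid = dataset.to_matrix(step=config.step)

    pca = run_pca(X, step=config.step)
    elbow = scree_elbow(pca.explained_fraction, cumulative=config.elbow_cumulative)
    k = config.n_components or elbow.n_retained + 1

    triangle = phasors = abundances = None
    inflation = 1.0
    clipped_fraction = 0.0
    if k == 3:
        n_harm = config.n_harmonics
        if n_harm is not None:
            n_harm = min(n_harm, (X.shape[1] - 1) // 2)
        anchor = build_triangle(pca, config, n_harm)
        phasors = phasor_cloud(X, n_harm)
        inflated, inflation = inflate_triangle(phasors, anchor,
                                               config.enclose_quantile)
        triangle = fit_enclosing_simplex(phasors, inflated, config.simplex_mu)
        abundances, flags = abundance_table(phasors, triangle)
        clipped_fraction = float(flags.mean())
    else:
        abundances = np.full((X.shape[0], k), 1.0 / k)

    H0, W0 = init_factors(X, abundances)
    cset = run_nmf(X, H0, W0, tol=config.nmf_tol, max_iter=config.nmf_max_iter)
    label_components(cset, component_library(grid), grid,
                     threshold=config.label_threshold)
    score_fit(X, cset)

    return DecompositionResult(
        pca=pca, elbow=elbow, n_components=k, components=cset,
        triangle=triangle, abundances=abundances, phasors=phasors,
        inflation_factor=inflation, clipped_fraction=clipped_fraction,
        config=config,
    )
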