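"""Render the (n+1)-dimensional energy landscape as a 3-D surface.

The n-gene state space is reduced to the first two principal components
(samples as observations, genes as features).  A regular grid spanning the
samples' bounding box (plus a margin) is mapped back to expression space by
the inverse PCA transform, discretised with the same ternary threshold as
the real samples, and scored with the Hopfield energy — elevation z over
the (PC1, PC2) plane.  The developmental trajectory is the polyline through
the per-stage centroids in stage order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import StageAnnotation, validate_expression
from .hopfield import sample_energies
from .preprocess import discretize

__all__ = ["PCAProjection", "LandscapeSurface", "project_samples",
           "render_surface", "trajectory"]


@dataclass
class PCAProjection:
    """Fitted 2-component linear projection with a deterministic sign.

    Each component's loading vector is oriented so that its
    largest-magnitude entry is positive, making scores reproducible across
    linear-algebra backends.
    """

    mean: np.ndarray                 # (n_genes,)
    components: np.ndarray           # (2, n_genes)
    explained_variance_ratio: np.ndarray
    gene_ids: list[str]

    def transform(self, matrix: pd.DataFrame) -> np.ndarray:
        """Project genes x samples values to (n_samples, 2) scores."""
        x = matrix.to_numpy(dtype=float).T
        return (x - self.mean) @ self.components.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        """Map (k, 2) plane coordinates back to (k, n_genes) expression."""
        return np.asarray(scores, dtype=float) @ self.components + self.mean


@dataclass
class LandscapeSurface:
    """Energy surface over the PC1/PC2 plane plus the real sample points."""

    grid_x: np.ndarray               # PC1 coordinates, length gx
    grid_y: np.ndarray               # PC2 coordinates, length gy
    grid_energy: np.ndarray          # (gx, gy); grid_energy[i, j] at (x_i, y_j)
    sample_points: pd.DataFrame      # sample_id, pc1, pc2, energy[, stage]
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (pc1, pc2, energy), one row per grid point."""
        xx, yy = np.meshgrid(self.grid_x, self.grid_y, indexing="ij")
        return pd.DataFrame({
            "pc1": xx.ravel(),
            "pc2": yy.ravel(),
            "energy": self.grid_energy.ravel(),
        })

    def to_dict(self) -> dict:
        return {
            "grid_x": self.grid_x.tolist(),
            "grid_y": self.grid_y.tolist(),
            "grid_energy": self.grid_energy.tolist(),
            "sample_points": self.sample_points.to_dict(orient="records"),
            "metadata": dict(self.metadata),
        }


def project_samples(matrix: pd.DataFrame) -> tuple[pd.DataFrame, PCAProjection]:
    """PCA of the samples onto the two major components of the genes.

    Fit on the (z-scored, feature-selected) continuous matrix with samples
    as observations.  Returns per-sample (pc1, pc2) scores and the fitted
    linear map needed for grid inversion.
    """
    matrix = validate_expression(matrix)
    n_genes, n_samples = matrix.shape
    if n_samples < 3:
        raise ValueError(f"PCA needs >= 3 samples, got {n_samples}")
    if n_genes < 2:
        raise ValueError(f"PCA needs >= 2 genes, got {n_genes}")
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(matrix.to_numpy(dtype=float).T)
    components = pca.components_.copy()
    for c in range(components.shape[0]):
        pivot = np.argmax(np.abs(components[c]))
        if components[c, pivot] < 0:
            components[c] *= -1.0
            scores[:, c] *= -1.0
    projection = PCAProjection(
        mean=pca.mean_.copy(),
        components=components,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        gene_ids=list(matrix.index),
    )
    score_frame = pd.DataFrame(scores, index=matrix.columns,
                               columns=["pc1", "pc2"])
    return score_frame, projection


def _grid_axis(lo: float, hi: float, size: int, margin: float,
               name: str) -> np.ndarray:
    extent = hi - lo
    if extent <= 1e-12 * max(abs(lo), abs(hi), 1.0):
        warnings.warn(
            f"degenerate {name} axis (zero extent); expanding by unit margin",
            UserWarning, stacklevel=3)
        lo, hi = lo - 1.0, hi + 1.0
    else:
        lo, hi = lo - margin * extent, hi + margin * extent
    return np.linspace(lo, hi, size)


def render_surface(
    matrix: pd.DataFrame,
    weights: pd.DataFrame,
    threshold: float = 0.5,
    grid_size: int = 50,
    *,
    margin: float = 0.1,
    annotation: StageAnnotation | None = None,
) -> LandscapeSurface:
    """Score a regular PC-plane grid with the Hopfield energy.

    Every grid point is inverse-mapped to n-gene expression space,
    discretised with the same threshold as the samples, and scored against
    ``weights``.  Real samples appear in ``sample_points`` with their own
    energies (computed from their actual discretised profiles, not from
    the plane approximation).
    """
    if grid_size < 2:
        raise ValueError(f"grid_size must be >= 2, got {grid_size}")
    if not matrix.index.equals(weights.index):
        raise ValueError("matrix and weight matrix gene orders differ")
    scores, projection = project_samples(matrix)

    grid_x = _grid_axis(scores["pc1"].min(), scores["pc1"].max(),
                        grid_size, margin, "PC1")
    grid_y = _grid_axis(scores["pc2"].min(), scores["pc2"].max(),
                        grid_size, margin, "PC2")
    xx, yy = np.meshgrid(grid_x, grid_y, indexing="ij")
    plane = np.column_stack([xx.ravel(), yy.ravel()])
    inverse = projection.inverse_transform(plane)        # (g^2, n_genes)
    grid_states = pd.DataFrame(
        inverse.T, index=matrix.index,
        columns=[f"_grid{i}" for i in range(plane.shape[0])])
    grid_states = discretize(grid_states, threshold)
    grid_energy = sample_energies(grid_states, weights).to_numpy()
    grid_energy = grid_energy.reshape(len(grid_x), len(grid_y))

    states = discretize(matrix, threshold)
    own_energy = sample_energies(states, weights)
    points = scores.copy()
    points.insert(0, "sample_id", scores.index)
    points["energy"] = own_energy.loc[scores.index].to_numpy()
    if annotation is not None:
        points["stage"] = [annotation.stage_of(s) for s in points["sample_id"]]
    points = points.reset_index(drop=True)

    return LandscapeSurface(
        grid_x=grid_x, grid_y=grid_y, grid_energy=grid_energy,
        sample_points=points,
        metadata={
            "threshold": float(threshold),
            "grid_size": int(grid_size),
            "margin": float(margin),
            "grid_discretized": True,
            "explained_variance_ratio":
                projection.explained_variance_ratio.tolist(),
        })


def trajectory(
    sample_points: pd.DataFrame,
    annotation: StageAnnotation,
) -> pd.DataFrame:
    """Stage-centroid polyline (mean pc1, pc2, energy) in stage order."""
    points = sample_points
    if "stage" not in points.columns:
        points = points.copy()
        points["stage"] = [annotation.stage_of(s) for s in points["sample_id"]]
    rows = []
    for stage in annotation.stage_order:
        sub = points[points["stage"] == stage]
        rows.append({"stage": stage,
                     "pc1": float(sub["pc1"].mean()),
                     "pc2": float(sub["pc2"].mean()),
                     "energy": float(sub["energy"].mean()),
                     "n_samples": int(len(sub))})
    return pd.DataFrame(rows)
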