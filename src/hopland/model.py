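"""Model / results interface over the full landscape workflow.

`HopfieldLandscape` is constructed from an expression matrix plus a stage
annotation; `fit()` runs feature selection, normalisation, discretisation,
weight-matrix construction, energy profiling and the 2-D PCA projection,
returning a `HopfieldLandscapeResults` that carries the estimates and
exposes the downstream analyses (surface rendering, trajectory,
perturbation robustness, switched-gene detection, plotting).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import hopfield, landscape, perturbation, preprocess, switching
from .containers import EnergyProfile, StageAnnotation, validate_expression

__all__ = ["HopfieldLandscape", "HopfieldLandscapeResults"]


class HopfieldLandscape:
    """Hopfield energy-landscape model of a developmental time course.

    Parameters
    ----------
    expression
        Raw (or log-scale) genes x samples expression values.
    annotation
        Sample -> stage assignment with an explicit stage order.
    threshold
        Symmetric ternary discretisation threshold on per-gene z-scores.
    feature_method, n_features
        Variance-based gene selection: ``"elbow"`` (default, parameter
        free), ``"top_k"`` (requires ``n_features``) or ``"none"`` to keep
        every gene.  Variance is ranked on the raw values, before z-scoring.
    ddof
        Degrees-of-freedom convention for SDs/variances (1 = sample).
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        annotation: StageAnnotation,
        *,
        threshold: float = 0.5,
        feature_method: str = "elbow",
        n_features: int | None = None,
        ddof: int = 1,
    ) -> None:
        if not threshold > 0:
            raise ValueError(f"threshold must be positive, got {threshold}")
        if feature_method not in ("elbow", "top_k", "none"):
            raise ValueError(f"unknown feature_method {feature_method!r}")
        self.expression = validate_expression(expression)
        annotation.validate_samples(self.expression.columns)
        self.annotation = annotation
        self.threshold = float(threshold)
        self.feature_method = feature_method
        self.n_features = n_features
        self.ddof = int(ddof)

    @classmethod
    def from_files(cls, expression_path, annotation_path,
                   stage_order=None, **kwargs) -> "HopfieldLandscape":
        from .io import read_annotation, read_expression
        matrix = read_expression(expression_path)
        annotation = read_annotation(annotation_path, stage_order=stage_order)
        return cls(matrix, annotation, **kwargs)

    def fit(self, *, aggregate: str = "mean") -> "HopfieldLandscapeResults":
        """Run the landscape workflow and return the fitted results."""
        if self.feature_method == "none":
            selected = self.expression.loc[
                preprocess.gene_variances(self.expression,
                                          ddof=self.ddof).index]
        else:
            selected = preprocess.select_features(
                self.expression, method=self.feature_method,
                k=self.n_features, ddof=self.ddof)
        normalized = preprocess.zscore_normalize(selected, ddof=self.ddof)
        states = preprocess.discretize(normalized, self.threshold)
        weights = hopfield.build_weight_matrix(normalized)
        energies = hopfield.stage_energies(states, weights, self.annotation,
                                           aggregate=aggregate)
        scores, projection = landscape.project_samples(normalized)
        return HopfieldLandscapeResults(
            model=self, normalized=normalized, states=states,
            weights=weights, energies=energies, scores=scores,
            projection=projection)


class HopfieldLandscapeResults:
    """Fitted landscape: weights, states, energies and the PCA embedding."""

    def __init__(self, model: HopfieldLandscape, normalized: pd.DataFrame,
                 states: pd.DataFrame, weights: pd.DataFrame,
                 energies: EnergyProfile, scores: pd.DataFrame,
                 projection: landscape.PCAProjection) -> None:
        self.model = model
        self.normalized = normalized
        self.states = states
        self.weights = weights
        self.energies = energies
        self.scores = scores
        self.projection = projection

    # -- descriptive -------------------------------------------------------
    @property
    def annotation(self) -> StageAnnotation:
        return self.model.annotation

    @property
    def n_genes_selected(self) -> int:
        return self.weights.shape[0]

    def stage_table(self) -> pd.DataFrame:
        """Per-stage sample counts and energy statistics."""
        per_sample = self.energies.per_sample
        rows = []
        for stage in self.annotation.stage_order:
            vals = per_sample[self.annotation.samples_of(stage)]
            rows.append({
                "stage": stage,
                "n_samples": len(vals),
                "mean_energy": float(vals.mean()),
                "sd_energy": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "min_energy": float(vals.min()),
                "max_energy": float(vals.max()),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary."""
        model = self.model
        evr = self.projection.explained_variance_ratio
        lines = [
            "Hopfield Energy Landscape Results",
            "=" * 54,
            f"Genes (input / selected):  {model.expression.shape[0]} / "
            f"{self.n_genes_selected}",
            f"Samples / stages:          {model.expression.shape[1]} / "
            f"{len(self.annotation.stage_order)}",
            f"Feature selection:         {model.feature_method}",
            f"Discretisation threshold:  {model.threshold:g} (|z|)",
            f"PC1/PC2 explained var.:    {evr[0]:.3f} / {evr[1]:.3f}",
            "-" * 54,
            f"{'stage':<10}{'n':>4}{'mean E':>14}{'sd E':>12}",
        ]
        for row in self.stage_table().itertuples():
            lines.append(f"{row.stage:<10}{row.n_samples:>4}"
                         f"{row.mean_energy:>14.3f}{row.sd_energy:>12.3f}")
        lines.append("=" * 54)
        return "\n".join(lines)

    # -- downstream analyses ----------------------------------------------
    def render_surface(self, grid_size: int = 50, *,
                       margin: float = 0.1) -> landscape.LandscapeSurface:
        return landscape.render_surface(
            self.normalized, self.weights, self.model.threshold, grid_size,
            margin=margin, annotation=self.annotation)

    def trajectory(self) -> pd.DataFrame:
        points = self.scores.copy()
        points.insert(0, "sample_id", points.index)
        points["energy"] = self.energies.per_sample.loc[points.index].to_numpy()
        points = points.reset_index(drop=True)
        return landscape.trajectory(points, self.annotation)

    def perturbation_analysis(
        self,
        fractions=perturbation.DEFAULT_FRACTIONS,
        repeats: int = 100,
        seed: int = 0,
        *,
        cellwise: bool = False,
    ) -> list[perturbation.PerturbationResult]:
        return perturbation.run_perturbation_analysis(
            self.normalized, self.annotation, self.model.threshold,
            fractions, repeats, seed, cellwise=cellwise)

    def detect_switches(self, pairs="successive", *,
                        lenient: bool = False) -> switching.SwitchReport:
        return switching.detect_switches(self.states, self.annotation, pairs,
                                         lenient=lenient)

    def recall_sample(self, sample_id: str, max_sweeps: int = 100):
        """Relax one sample's state to its attractor (exploratory only;
        energy profiling never iterates)."""
        state = self.states[sample_id]
        return hopfield.recall(state, self.weights, max_sweeps)

    # -- plotting ----------------------------------------------------------
    def plot_landscape(self, path=None, *, grid_size: int = 50,
                       view: str = "3d"):
        from .plotting import plot_landscape
        surface = self.render_surface(grid_size)
        return plot_landscape(surface, self.trajectory(), path=path, view=view)

    def plot_stage_energies(self, path=None):
        from .plotting import plot_stage_energies
        return plot_stage_energies(self.energies, self.annotation, path=path)
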