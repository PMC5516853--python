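"""Normalisation, feature selection and ternary discretisation.

The Hopfield formalism needs each gene on a common scale (z-scores), a
reduced set of informative genes (variance ranking with an elbow cut), and
ternary node states in {-1, 0, +1}.  All three steps operate on genes x
samples DataFrames and preserve identifier ordering except where a step's
contract says otherwise (feature selection returns genes ranked by
descending variance).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import validate_expression

__all__ = ["zscore_normalize", "select_features", "discretize",
           "gene_variances", "elbow_index"]


def zscore_normalize(matrix: pd.DataFrame, *, ddof: int = 1) -> pd.DataFrame:
    """Z-score each gene row to mean 0, SD 1 across samples.

    Zero-variance genes cannot be scaled; their rows are mapped to all
    zeros and a warning is issued (such genes carry no co-expression
    signal and are dropped by feature selection anyway).

    Parameters
    ----------
    matrix
        Genes x samples expression values.
    ddof
        Delta degrees of freedom for the SD (1 = sample SD, the default;
        0 = population SD).
    """
    matrix = validate_expression(matrix)
    values = matrix.to_numpy()
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    flat = sd[:, 0] == 0.0
    if flat.any():
        names = matrix.index[flat].tolist()
        warnings.warn(
            f"{flat.sum()} zero-variance gene(s) mapped to all-zero rows: "
            f"{names[:5]}{'...' if len(names) > 5 else ''}",
            UserWarning, stacklevel=2)
        sd[flat, :] = 1.0
    out = (values - mean) / sd
    out[flat, :] = 0.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def gene_variances(matrix: pd.DataFrame, *, ddof: int = 1) -> pd.Series:
    """Across-sample variance per gene, tie-broken by gene id.

    Returns variances sorted descending; equal variances are ordered by
    lexicographic gene id so the ranking is stable under row permutation.
    """
    var = matrix.astype(float).var(axis=1, ddof=ddof)
    order = sorted(var.index, key=lambda g: (-var[g], str(g)))
    return var.loc[order]


def elbow_index(sorted_values: np.ndarray) -> int:
    """Elbow of a descending curve: point farthest below the end-to-end chord.

    Returns the index of the maximum drop below the straight line joining
    the first and last points (Kneedle-style).  Returns 0 when the curve
    is flat, signalling "no elbow".
    """
    y = np.asarray(sorted_values, dtype=float)
    n = y.size
    if n < 3:
        return 0
    x = np.arange(n, dtype=float)
    chord = y[0] + (y[-1] - y[0]) * x / (n - 1)
    below = chord - y
    if np.allclose(below, 0.0, atol=1e-12 * max(1.0, abs(y[0]))):
        return 0
    return int(np.argmax(below))


def select_features(
    matrix: pd.DataFrame,
    method: str = "elbow",
    k: int | None = None,
    *,
    ddof: int = 1,
) -> pd.DataFrame:
    """Keep the most variable genes, ranked by descending variance.

    ``method="elbow"`` cuts the descending variance curve at the point of
    maximum perpendicular distance below its end-to-end chord and keeps the
    genes before that point; a flat curve (no elbow) keeps every gene with
    a warning.  ``method="top_k"`` keeps the ``k`` most variable genes.
    Fewer than 2 retained genes is an error: the weight matrix is undefined.
    """
    matrix = validate_expression(matrix)
    var = gene_variances(matrix, ddof=ddof)
    ranked = matrix.loc[var.index]

    if method == "top_k":
        if k is None:
            raise ValueError("method='top_k' requires k")
        if not 2 <= k <= len(ranked):
            raise ValueError(
                f"k must be in [2, {len(ranked)}], got {k}")
        return ranked.iloc[:k]

    if method != "elbow":
        raise ValueError(f"unknown feature-selection method {method!r}")

    cut = elbow_index(var.to_numpy())
    if cut == 0:
        warnings.warn(
            "variance curve has no elbow (flat); retaining all genes",
            UserWarning, stacklevel=2)
        return ranked
    if cut < 2:
        raise ValueError(
            f"elbow retains only {cut} gene(s); weight matrix undefined")
    return ranked.iloc[:cut]


def discretize(matrix: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Map z-scored expression to ternary node states.

    An entry becomes +1 above ``threshold``, -1 below ``-threshold`` and 0
    inside the dead zone.  The symmetric threshold (default 0.5) gives all
    three states non-zero mass under a standard normal.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    matrix = validate_expression(matrix)
    values = matrix.to_numpy()
    states = np.zeros(values.shape, dtype=np.int8)
    states[values > threshold] = 1
    states[values < -threshold] = -1
    return pd.DataFrame(states, index=matrix.index, columns=matrix.columns)
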