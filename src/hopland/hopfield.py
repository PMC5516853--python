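"""Hopfield network core: correlation weights, energy, stage profiles, recall.

The network has one node per gene; edge weights are Pearson correlations of
the two genes' expression across all samples, giving a symmetric
zero-diagonal weight matrix W with entries in [-1, 1].  A sample's ternary
state vector H is scored by the quadratic form

    E[H] = -1/2 * H W H^T

which is unitless, scales linearly with the number of concordant active
pairs, and is a Lyapunov function of the asynchronous update dynamics.
Energy profiling of biological samples deliberately skips the update
iteration: the observed (discretised) expression pattern is scored as-is,
so the energy describes the measured state, not an attractor it would
relax to.  :func:`recall` exposes the attractor dynamics separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import EnergyProfile, StageAnnotation, validate_expression

__all__ = ["build_weight_matrix", "energy", "sample_energies",
           "stage_energies", "recall"]


def build_weight_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson-correlation weight matrix over genes.

    Requires >= 2 genes, >= 3 samples and non-zero variance in every gene
    row.  The diagonal is forced to exactly zero and the matrix exactly
    symmetrised, so self-interaction never contributes to the energy.
    """
    matrix = validate_expression(matrix)
    n_genes, n_samples = matrix.shape
    if n_genes < 2:
        raise ValueError(f"need >= 2 genes, got {n_genes}")
    if n_samples < 3:
        raise ValueError(f"need >= 3 samples, got {n_samples}")
    values = matrix.to_numpy()
    flat = values.std(axis=1) == 0.0
    if flat.any():
        names = matrix.index[flat].tolist()
        raise ValueError(
            f"zero-variance gene(s) have undefined correlation: {names[:5]}")
    weights = np.corrcoef(values)
    weights = np.clip((weights + weights.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(weights, 0.0)
    return pd.DataFrame(weights, index=matrix.index, columns=matrix.index)


def _aligned(state, weights) -> tuple[np.ndarray, np.ndarray]:
    w = weights.to_numpy() if isinstance(weights, pd.DataFrame) else np.asarray(weights)
    if isinstance(state, pd.Series):
        if isinstance(weights, pd.DataFrame) and not state.index.equals(weights.index):
            raise ValueError("state and weight matrix gene orders differ")
        h = state.to_numpy()
    else:
        h = np.asarray(state)
    if w.shape[0] != w.shape[1]:
        raise ValueError(f"weight matrix not square: {w.shape}")
    if h.shape[0] != w.shape[0]:
        raise ValueError(
            f"dimension mismatch: state has {h.shape[0]} nodes, "
            f"weights are {w.shape[0]}x{w.shape[1]}")
    return h.astype(float), w.astype(float)


def energy(state, weights) -> float:
    """Hopfield energy -1/2 H W H^T of one ternary state vector."""
    h, w = _aligned(state, weights)
    return float(-0.5 * h @ w @ h)


def sample_energies(states: pd.DataFrame, weights: pd.DataFrame) -> pd.Series:
    """Energy of every sample column of a ternary state matrix."""
    if not states.index.equals(weights.index):
        raise ValueError("state matrix and weight matrix gene orders differ")
    h = states.to_numpy(dtype=float)
    w = weights.to_numpy(dtype=float)
    energies = -0.5 * np.einsum("gs,gs->s", h, w @ h)
    return pd.Series(energies, index=states.columns, name="energy")


def stage_energies(
    states: pd.DataFrame,
    weights: pd.DataFrame,
    annotation: StageAnnotation,
    *,
    aggregate: str = "mean",
) -> EnergyProfile:
    """Per-sample energies plus a per-stage summary.

    ``aggregate="mean"`` (default) averages the replicate energies of each
    stage.  ``aggregate="centroid"`` instead scores the stage's consensus
    ternary state (sign of the replicate mean), provided for comparison;
    the per-sample energies are identical either way.
    """
    annotation.validate_samples(states.columns)
    per_sample = sample_energies(states, weights)
    if aggregate == "mean":
        per_stage = pd.Series(
            {stage: float(per_sample[annotation.samples_of(stage)].mean())
             for stage in annotation.stage_order})
    elif aggregate == "centroid":
        per_stage = {}
        for stage in annotation.stage_order:
            consensus = np.sign(
                states[annotation.samples_of(stage)].mean(axis=1).to_numpy())
            per_stage[stage] = energy(consensus, weights)
        per_stage = pd.Series(per_stage)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    per_stage = per_stage.loc[annotation.stage_order]
    return EnergyProfile(per_sample=per_sample, per_stage=per_stage,
                         stage_order=list(annotation.stage_order))


def recall(
    state,
    weights,
    max_sweeps: int = 100,
    mode: str = "asynchronous",
) -> tuple[np.ndarray, list[float]]:
    """Asynchronous recall: descend the energy surface to an attractor.

    Nodes are updated one at a time in fixed index order; each update sets
    H_i to the sign of its local field sum_j w_ij H_j, with a zero field
    leaving H_i unchanged (this keeps the descent well defined for the
    ternary 0 state, which classical +/-1 Hopfield theory does not cover).
    Stops after a full sweep changes no node, or after ``max_sweeps``.

    Returns the final state (same type semantics as a NumPy vector; a
    Series input returns a Series) and the energy after each sweep, which
    is monotonically non-increasing.
    """
    if mode != "asynchronous":
        raise ValueError(f"unsupported update mode {mode!r}")
    if max_sweeps < 1:
        raise ValueError(f"max_sweeps must be >= 1, got {max_sweeps}")
    h, w = _aligned(state, weights)
    h = h.copy()
    trajectory: list[float] = []
    for _ in range(max_sweeps):
        changed = False
        for i in range(h.size):
            field = w[i] @ h
            if field > 0 and h[i] != 1:
                h[i], changed = 1.0, True
            elif field < 0 and h[i] != -1:
                h[i], changed = -1.0, True
        trajectory.append(float(-0.5 * h @ w @ h))
        if not changed:
            break
    final = h.astype(np.int8)
    if isinstance(state, pd.Series):
        return pd.Series(final, index=state.index), trajectory
    return final, trajectory
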