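"""Core data containers shared across the package.

Expression matrices, ternary state matrices and weight matrices are plain
:class:`pandas.DataFrame` objects (genes in rows, samples in columns; weight
matrices are square with identical row/column gene order).  The classes here
carry the structured metadata that a bare DataFrame cannot: the ordered
stage design of a time course and the per-sample/per-stage energy profile.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StageAnnotation", "EnergyProfile", "validate_expression"]


class StageAnnotation:
    """Ordered sample -> developmental-stage assignment.

    Parameters
    ----------
    sample_to_stage
        Mapping from sample identifier to stage label.
    stage_order
        Stage labels in developmental order.  When omitted, stages are
        ordered by first appearance in ``sample_to_stage``.
    """

    def __init__(
        self,
        sample_to_stage: Mapping[str, str],
        stage_order: Sequence[str] | None = None,
    ) -> None:
        self.sample_to_stage: dict[str, str] = dict(sample_to_stage)
        if not self.sample_to_stage:
            raise ValueError("annotation is empty")
        if stage_order is None:
            seen: dict[str, None] = {}
            for stage in self.sample_to_stage.values():
                seen.setdefault(stage, None)
            stage_order = list(seen)
        self.stage_order: list[str] = [str(s) for s in stage_order]
        if len(set(self.stage_order)) != len(self.stage_order):
            raise ValueError("stage_order contains duplicate labels")
        if len(self.stage_order) < 2:
            raise ValueError("need at least 2 stages, got "
                             f"{len(self.stage_order)}")
        known = set(self.stage_order)
        for sample, stage in self.sample_to_stage.items():
            if stage not in known:
                raise ValueError(
                    f"sample {sample!r} maps to stage {stage!r} "
                    "missing from stage_order")
        for stage in self.stage_order:
            if not any(v == stage for v in self.sample_to_stage.values()):
                raise ValueError(f"stage {stage!r} has no samples")

    # -- accessors ---------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.sample_to_stage)

    @property
    def stages(self) -> list[str]:
        return list(self.stage_order)

    def stage_of(self, sample: str) -> str:
        return self.sample_to_stage[sample]

    def samples_of(self, stage: str) -> list[str]:
        if stage not in self.stage_order:
            raise KeyError(f"unknown stage {stage!r}")
        return [s for s, t in self.sample_to_stage.items() if t == stage]

    def successive_pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.stage_order[:-1], self.stage_order[1:]))

    @property
    def endpoint_stages(self) -> tuple[str, str]:
        return self.stage_order[0], self.stage_order[-1]

    @property
    def transient_stages(self) -> list[str]:
        return self.stage_order[1:-1]

    # -- validation --------------------------------------------------------
    def validate_samples(self, sample_ids: Sequence[str]) -> None:
        """Check that ``sample_ids`` and the annotation cover each other."""
        ids = list(sample_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in matrix")
        missing = [s for s in ids if s not in self.sample_to_stage]
        if missing:
            raise ValueError(f"samples without stage annotation: {missing[:5]}")
        extra = [s for s in self.sample_to_stage if s not in set(ids)]
        if extra:
            raise ValueError(f"annotated samples absent from matrix: {extra[:5]}")

    # -- conversion --------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.samples,
             "stage": [self.sample_to_stage[s] for s in self.samples]}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   stage_order: Sequence[str] | None = None) -> "StageAnnotation":
        if frame.shape[1] < 2:
            raise ValueError("annotation table needs (sample_id, stage) columns")
        sample_col, stage_col = frame.columns[:2]
        mapping = dict(zip(frame[sample_col].astype(str),
                           frame[stage_col].astype(str)))
        if len(mapping) != len(frame):
            raise ValueError("duplicate sample ids in annotation table")
        return cls(mapping, stage_order)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, StageAnnotation)
                and self.sample_to_stage == other.sample_to_stage
                and self.stage_order == other.stage_order)

    def __repr__(self) -> str:
        return (f"StageAnnotation({len(self.sample_to_stage)} samples, "
                f"stages={self.stage_order})")


@dataclass
class EnergyProfile:
    """Hopfield energies per sample and averaged per stage.

    The energy is unitless and scales linearly with the number of active
    node pairs; lower values mean stronger agreement between a sample's
    ternary state and the co-expression structure stored in the weights.
    """

    per_sample: pd.Series          # index: sample_id
    per_stage: pd.Series           # index: stage, ordered by stage_order
    stage_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.stage_order:
            self.stage_order = list(self.per_stage.index)

    def to_frame(self, annotation: StageAnnotation | None = None) -> pd.DataFrame:
        """Long table (sample_id, stage, energy); stage blank if unknown."""
        frame = pd.DataFrame({
            "sample_id": self.per_sample.index,
            "energy": self.per_sample.to_numpy(),
        })
        if annotation is not None:
            frame.insert(1, "stage",
                         [annotation.stage_of(s) for s in frame["sample_id"]])
        return frame

    def to_dict(self) -> dict:
        return {
            "per_sample": {k: float(v) for k, v in self.per_sample.items()},
            "per_stage": {k: float(v) for k, v in self.per_stage.items()},
            "stage_order": list(self.stage_order),
        }


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Validate a genes x samples expression DataFrame.

    Rejects duplicate gene/sample identifiers, non-numeric values and
    missing entries; returns the matrix as float64.
    """
    if matrix.index.has_duplicates:
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    if matrix.columns.has_duplicates:
        dupes = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes[:5]}")
    try:
        values = matrix.astype(np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression values: {exc}") from exc
    if values.isna().any().any():
        bad = values.isna().stack()
        gene, sample = bad[bad].index[0]
        raise ValueError(
            f"missing value at gene {gene!r}, sample {sample!r} "
            "(impute or filter before loading)")
    return values
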