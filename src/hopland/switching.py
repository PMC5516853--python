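"""Switched-gene identification between developmental stages.

A gene whose discretised state flips between -1 and +1 across two stages is
a candidate driver of that cell-state transition.  Replicates within a
stage are aggregated to a consensus ternary state (sign of the replicate
mean); the strict rule reports only full -1 <-> +1 flips, while the lenient
variant also reports changes through or into the 0 state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import StageAnnotation

__all__ = ["SwitchReport", "stage_consensus", "detect_switches"]


@dataclass
class SwitchReport:
    """Switched genes per requested stage transition."""

    transitions: list[tuple[str, str]]
    tables: dict = field(default_factory=dict)   # (a, b) -> DataFrame
    strict: bool = True

    @property
    def counts(self) -> dict:
        return {pair: int(len(self.tables[pair])) for pair in self.transitions}

    def genes(self, stage_a: str, stage_b: str) -> list[str]:
        return self.tables[(stage_a, stage_b)]["gene_id"].tolist()

    def to_frame(self) -> pd.DataFrame:
        """One long table over all transitions."""
        rows = []
        for (a, b) in self.transitions:
            table = self.tables[(a, b)].copy()
            table.insert(0, "stage_a", a)
            table.insert(1, "stage_b", b)
            rows.append(table)
        if not rows:
            return pd.DataFrame(
                columns=["stage_a", "stage_b", "gene_id",
                         "state_a", "state_b", "direction"])
        return pd.concat(rows, ignore_index=True)

    def counts_dict(self) -> dict:
        return {f"{a}->{b}": n for (a, b), n in self.counts.items()}


def stage_consensus(
    states: pd.DataFrame,
    annotation: StageAnnotation,
    stage: str,
) -> pd.Series:
    """Per-gene consensus state of one stage: sign of the replicate mean."""
    samples = annotation.samples_of(stage)
    mean = states[samples].mean(axis=1).to_numpy()
    return pd.Series(np.sign(mean).astype(np.int8), index=states.index,
                     name=stage)


def _resolve_pairs(annotation: StageAnnotation, pairs) -> list[tuple[str, str]]:
    if pairs == "successive":
        return annotation.successive_pairs()
    if pairs == "all_pairs":
        return list(combinations(annotation.stage_order, 2))
    resolved = []
    known = set(annotation.stage_order)
    for a, b in pairs:
        if a not in known or b not in known:
            bad = a if a not in known else b
            raise ValueError(f"unknown stage label {bad!r} in custom pair")
        resolved.append((a, b))
    return resolved


def detect_switches(
    states: pd.DataFrame,
    annotation: StageAnnotation,
    pairs="successive",
    *,
    lenient: bool = False,
) -> SwitchReport:
    """List genes whose consensus state flips between stage pairs.

    ``pairs`` is ``"successive"`` (each stage to the next), ``"all_pairs"``
    or an explicit list of (stage_a, stage_b) tuples.  Under the strict
    rule a switch means consensus -1 in one stage and +1 in the other;
    direction "up" is -1 -> +1.  ``lenient=True`` additionally reports any
    consensus change involving 0 (not part of the strict definition).
    """
    annotation.validate_samples(states.columns)
    transitions = _resolve_pairs(annotation, pairs)
    consensus = {stage: stage_consensus(states, annotation, stage)
                 for stage in annotation.stage_order}
    tables = {}
    for a, b in transitions:
        sa, sb = consensus[a], consensus[b]
        if lenient:
            mask = (sa != sb).to_numpy()
        else:
            mask = (sa.to_numpy() * sb.to_numpy()) == -1
        sub_a, sub_b = sa[mask], sb[mask]
        tables[(a, b)] = pd.DataFrame({
            "gene_id": sub_a.index,
            "state_a": sub_a.to_numpy(),
            "state_b": sub_b.to_numpy(),
            "direction": np.where(sub_b.to_numpy() > sub_a.to_numpy(),
                                  "up", "down"),
        }).reset_index(drop=True)
    return SwitchReport(transitions=transitions, tables=tables,
                        strict=not lenient)
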