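"""Synthetic stage-structured expression time courses.

The generator emulates the statistical signature the energy model assumes:
genes organised in co-regulated modules whose within-module co-variation is
tight at the first and last (phenotypically stable) stages and loose at the
transient stages in between, with a subset of modules reversing sign over
the course — the ground-truth "switched" genes.

Each gene g in module k of a sample s at stage t is generated as

    x[g, s] = sign_k(t) * coherence(t) * f_k(s) + eps[g, s]

where f_k(s) ~ N(1, factor_sd^2) is the module latent factor shared by all
genes of the module in that sample, coherence(t) is ``endpoint_coherence``
at the first/last stage and ``transient_coherence`` in between, sign_k(t)
flips from +1 to -1 at the midpoint of the course for switched modules,
and eps is i.i.d. Gaussian noise.  The unit-mean factor makes endpoint
states ternary-coherent across replicates (so switched genes are cleanly
recoverable), while its dispersion supplies the within-module correlation
that is stronger at endpoints than at transient stages.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .containers import StageAnnotation

__all__ = ["ArcDesign", "generate_arc_dataset", "generate_null_dataset"]


@dataclass(frozen=True)
class ArcDesign:
    """Parameters of the arc-shaped synthetic time course.

    Defaults give 4 stages x 10 replicates of 200 genes in 4 modules, half
    of which switch sign between the endpoints.
    """

    n_genes: int = 200
    n_stages: int = 4
    replicates_per_stage: int = 10
    endpoint_coherence: float = 0.9
    transient_coherence: float = 0.2
    n_modules: int = 4
    switch_fraction: float = 0.5
    noise_sd: float = 0.3
    factor_sd: float = 0.2
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_stages < 3:
            raise ValueError(f"n_stages must be >= 3, got {self.n_stages}")
        if self.replicates_per_stage < 2:
            raise ValueError("replicates_per_stage must be >= 2, got "
                             f"{self.replicates_per_stage}")
        if not 0.0 < self.endpoint_coherence <= 1.0:
            raise ValueError("endpoint_coherence must be in (0, 1], got "
                             f"{self.endpoint_coherence}")
        if not 0.0 <= self.transient_coherence < self.endpoint_coherence:
            raise ValueError(
                "transient_coherence must be in [0, endpoint_coherence), got "
                f"{self.transient_coherence}")
        if not 1 <= self.n_modules <= self.n_genes:
            raise ValueError(f"n_modules must be in [1, n_genes], got "
                             f"{self.n_modules}")
        if not 0.0 <= self.switch_fraction <= 1.0:
            raise ValueError("switch_fraction must be in [0, 1], got "
                             f"{self.switch_fraction}")
        if not self.noise_sd > 0:
            raise ValueError(f"noise_sd must be positive, got {self.noise_sd}")
        if self.factor_sd < 0:
            raise ValueError(f"factor_sd must be >= 0, got {self.factor_sd}")

    def to_dict(self) -> dict:
        return asdict(self)


def _module_assignment(design: ArcDesign) -> tuple[list[np.ndarray], list[int]]:
    """Partition gene indices into modules; choose which modules flip.

    Modules are flipped greedily from the first until the flipped gene
    count reaches ``switch_fraction * n_genes`` (rounded), so the
    ground-truth switched set has a deterministic size.
    """
    modules = np.array_split(np.arange(design.n_genes), design.n_modules)
    target = round(design.switch_fraction * design.n_genes)
    flipped, covered = [], 0
    for k, module in enumerate(modules):
        if covered >= target:
            break
        flipped.append(k)
        covered += module.size
    return modules, flipped


def generate_arc_dataset(
    design: ArcDesign = ArcDesign(),
) -> tuple[pd.DataFrame, StageAnnotation, list[str]]:
    """Generate (expression matrix, stage annotation, ground-truth switches).

    Deterministic given ``design.seed``.  The returned ground truth is the
    list of gene ids belonging to sign-flipping modules — exactly the genes
    whose discretised state reverses between the first and last stage.
    """
    rng = np.random.default_rng(design.seed)
    n_samples = design.n_stages * design.replicates_per_stage
    gene_ids = [f"g{i:04d}" for i in range(design.n_genes)]
    stages = [f"S{t + 1}" for t in range(design.n_stages)]
    sample_ids, sample_stage = [], {}
    for stage in stages:
        for rep in range(design.replicates_per_stage):
            sid = f"{stage}_r{rep + 1:02d}"
            sample_ids.append(sid)
            sample_stage[sid] = stage
    annotation = StageAnnotation(sample_stage, stages)

    coherence = np.full(design.n_stages, design.transient_coherence)
    coherence[0] = coherence[-1] = design.endpoint_coherence
    flip_at = -(-design.n_stages // 2)          # ceil: second half flips
    modules, flipped = _module_assignment(design)

    stage_of_sample = np.repeat(np.arange(design.n_stages),
                                design.replicates_per_stage)
    factors = 1.0 + design.factor_sd * rng.standard_normal(
        (design.n_modules, n_samples))
    values = np.empty((design.n_genes, n_samples))
    for k, module in enumerate(modules):
        sign = np.ones(design.n_stages)
        if k in flipped:
            sign[flip_at:] = -1.0
        signal = sign[stage_of_sample] * coherence[stage_of_sample] * factors[k]
        values[module, :] = signal[None, :]
    values += rng.normal(0.0, design.noise_sd, size=values.shape)

    matrix = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    ground_truth = [gene_ids[i] for k in flipped for i in modules[k]]
    return matrix, annotation, ground_truth


def generate_null_dataset(
    n_genes: int,
    n_samples: int | None = None,
    annotation: StageAnnotation | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Structure-free control: i.i.d. uniform [-1, 1] entries.

    Matched null for perturbation baselines and false-positive checks.
    Column names follow ``annotation`` when given.
    """
    if annotation is not None:
        columns = annotation.samples
        if n_samples is not None and n_samples != len(columns):
            raise ValueError(
                f"n_samples={n_samples} conflicts with the "
                f"{len(columns)}-sample annotation")
    else:
        if n_samples is None:
            raise ValueError("need n_samples or annotation")
        columns = [f"s{i + 1:03d}" for i in range(n_samples)]
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    rng = np.random.default_rng(seed)
    values = rng.uniform(-1.0, 1.0, size=(n_genes, len(columns)))
    return pd.DataFrame(values,
                        index=[f"g{i:04d}" for i in range(n_genes)],
                        columns=columns)
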