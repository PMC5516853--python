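"""File input/output, pipeline configuration and the end-to-end run.

Matrices travel as tab- or comma-separated text with genes in rows (first
column gene id, header row of sample ids); stage annotations as two-column
(sample_id, stage) text.  The pipeline writes every artefact plus a
machine-readable manifest (parameters, seed, versions, input checksums)
that suffices to reproduce the run exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .containers import StageAnnotation, validate_expression
from .model import HopfieldLandscape
from .perturbation import DEFAULT_FRACTIONS, results_to_tidy

__all__ = ["read_expression", "write_expression", "read_annotation",
           "write_annotation", "PipelineConfig", "PipelineError",
           "run_pipeline"]

logger = logging.getLogger("hopland")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# readers / writers

def _detect_separator(path: Path) -> str:
    with open(path) as handle:
        header = handle.readline()
    return "\t" if "\t" in header else ","


def read_expression(path, sep: str | None = None) -> pd.DataFrame:
    """Load a genes x samples matrix from TSV/CSV text.

    The delimiter is auto-detected from the header unless forced.
    Duplicate gene ids, ragged rows, missing or non-numeric cells raise
    ``ValueError`` with context.
    """
    path = Path(path)
    if sep is None:
        sep = _detect_separator(path)
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed table {path}: {exc}") from exc
    if frame.empty or frame.shape[1] == 0:
        raise ValueError(f"no data columns found in {path}")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    try:
        return validate_expression(frame)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_expression(matrix: pd.DataFrame, path, sep: str = "\t") -> None:
    matrix.to_csv(path, sep=sep, index_label="gene_id")


def read_annotation(path, stage_order=None,
                    sep: str | None = None) -> StageAnnotation:
    """Load a (sample_id, stage) table; stage order defaults to first
    appearance unless given explicitly."""
    path = Path(path)
    if sep is None:
        sep = _detect_separator(path)
    frame = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    first = [str(v).strip().lower() for v in frame.iloc[0]]
    if first[0] in ("sample", "sample_id") or "stage" in first[1:2]:
        frame = frame.iloc[1:].reset_index(drop=True)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: need 2 columns (sample_id, stage)")
    try:
        return StageAnnotation.from_frame(frame, stage_order)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_annotation(annotation: StageAnnotation, path,
                     sep: str = "\t") -> None:
    annotation.to_frame().to_csv(path, sep=sep, index=False)


def _write_json(obj, path) -> None:
    with open(path, "w") as handle:
        json.dump(obj, handle, indent=2, sort_keys=True)
        handle.write("\n")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclass
class PipelineConfig:
    """Validated parameters of one end-to-end run."""

    expression_path: str
    annotation_path: str
    output_dir: str
    stage_order: list[str] | None = None
    threshold: float = 0.5
    feature_method: str = "elbow"
    n_features: int | None = None
    ddof: int = 1
    grid_size: int = 50
    margin: float = 0.1
    run_perturbation: bool = False
    fractions: list[float] = field(
        default_factory=lambda: list(DEFAULT_FRACTIONS))
    repeats: int = 100
    run_switching: bool = True
    pairs: str = "successive"
    lenient: bool = False
    seed: int = 0
    plots: bool = False

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError(f"threshold must be positive, got {self.threshold}")
        if self.feature_method not in ("elbow", "top_k", "none"):
            raise ValueError(f"unknown feature_method {self.feature_method!r}")
        if self.feature_method == "top_k" and not self.n_features:
            raise ValueError("feature_method='top_k' requires n_features")
        if self.grid_size < 2:
            raise ValueError(f"grid_size must be >= 2, got {self.grid_size}")
        if self.repeats < 2:
            raise ValueError(f"repeats must be >= 2, got {self.repeats}")
        for fraction in self.fractions:
            if not 0.0 < fraction <= 1.0:
                raise ValueError(f"fractions must be in (0, 1], got {fraction}")
        if self.pairs not in ("successive", "all_pairs"):
            raise ValueError(f"pairs must be successive/all_pairs, got "
                             f"{self.pairs!r}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle,
                           default_flow_style=False, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle)
        return cls(**data)


# ---------------------------------------------------------------------------
# end-to-end pipeline

def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        start = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - start)
        return out
    return wrap


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute preprocess -> weights -> energies -> landscape
    (-> perturbation -> switching) and write all artefacts.

    Returns a mapping artefact-name -> path.  Any stage error raises
    :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    timings: dict[str, float] = {}
    artefacts: dict[str, str] = {}

    def save(name: str, filename: str, writer) -> None:
        path = outdir / filename
        writer(path)
        artefacts[name] = str(path)

    try:
        t0 = time.perf_counter()
        matrix = _stage("load_expression")(read_expression,
                                           config.expression_path)
        annotation = _stage("load_annotation")(
            read_annotation, config.annotation_path, config.stage_order)
        logger.info("input: %d genes x %d samples, %d stages",
                    matrix.shape[0], matrix.shape[1],
                    len(annotation.stage_order))

        model = _stage("model")(
            HopfieldLandscape, matrix, annotation,
            threshold=config.threshold, feature_method=config.feature_method,
            n_features=config.n_features, ddof=config.ddof)
        results = _stage("fit")(model.fit)
        logger.info("selected %d genes", results.n_genes_selected)
        timings["fit"] = time.perf_counter() - t0

        save("normalized", "normalized.tsv",
             lambda p: write_expression(results.normalized, p))
        save("states", "states.tsv",
             lambda p: write_expression(results.states, p))
        save("weights", "weights.tsv",
             lambda p: results.weights.to_csv(p, sep="\t",
                                              index_label="gene_id"))
        save("energies", "energies.tsv",
             lambda p: results.energies.to_frame(annotation)
             .to_csv(p, sep="\t", index=False))
        save("energies_json", "energies.json",
             lambda p: _write_json(results.energies.to_dict(), p))
        save("summary", "summary.txt",
             lambda p: Path(p).write_text(results.summary() + "\n"))

        t0 = time.perf_counter()
        surface = _stage("landscape")(results.render_surface,
                                      config.grid_size, margin=config.margin)
        traj = results.trajectory()
        timings["landscape"] = time.perf_counter() - t0
        save("surface", "surface.tsv",
             lambda p: surface.to_frame().to_csv(p, sep="\t", index=False))
        save("surface_json", "surface.json",
             lambda p: _write_json(surface.to_dict(), p))
        save("trajectory", "trajectory.tsv",
             lambda p: traj.to_csv(p, sep="\t", index=False))
        if config.plots:
            save("plot_3d", "landscape_3d.png",
                 lambda p: results.plot_landscape(p, grid_size=config.grid_size,
                                                  view="3d"))
            save("plot_top", "landscape_top.png",
                 lambda p: results.plot_landscape(p, grid_size=config.grid_size,
                                                  view="top"))
            save("plot_energies", "stage_energies.png",
                 lambda p: results.plot_stage_energies(p))

        if config.run_perturbation:
            t0 = time.perf_counter()
            pert = _stage("perturbation")(
                results.perturbation_analysis, config.fractions,
                config.repeats, config.seed)
            timings["perturbation"] = time.perf_counter() - t0
            save("perturbation", "perturbation.tsv",
                 lambda p: results_to_tidy(pert).to_csv(p, sep="\t",
                                                        index=False))
            save("perturbation_summary", "perturbation_summary.json",
                 lambda p: _write_json(
                     [r.summary().to_dict(orient="records") for r in pert], p))

        if config.run_switching:
            report = _stage("switching")(results.detect_switches,
                                         config.pairs, lenient=config.lenient)
            save("switches", "switches.tsv",
                 lambda p: report.to_frame().to_csv(p, sep="\t", index=False))
            save("switch_counts", "switch_counts.json",
                 lambda p: _write_json(report.counts_dict(), p))

        manifest = {
            "package": "hopland",
            "version": _package_version(),
            "config": dataclasses.asdict(config),
            "inputs": {
                "expression": {"path": str(config.expression_path),
                               "sha256": _sha256(Path(config.expression_path))},
                "annotation": {"path": str(config.annotation_path),
                               "sha256": _sha256(Path(config.annotation_path))},
            },
            "n_genes_input": int(matrix.shape[0]),
            "n_genes_selected": int(results.n_genes_selected),
            "n_samples": int(matrix.shape[1]),
            "stage_order": annotation.stage_order,
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "artefacts": sorted(artefacts),
        }
        save("manifest", "manifest.json", lambda p: _write_json(manifest, p))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return artefacts


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version
    try:
        return version("hopland")
    except PackageNotFoundError:
        return "unknown"
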