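"""Follow classification and refinement runs from their iteration files.

RELION classification/refinement jobs write a ``run_itNNN_model.star``
and ``run_itNNN_optimiser.star`` pair after every expectation-
maximization iteration, so a run can be followed live rather than only
on completion.  This module extracts per-iteration series (e.g.
``ChangesOptimalClasses`` for classifications, ``CurrentResolution``
for refinements), class-distribution matrices, per-class spectral
curves (FSC, spectral orientability, Fourier completeness, SSNR),
FSC threshold crossings, angular-assignment histograms, and live
backlog counts for pre-processing jobs.

Series lookup searches optimiser files first, then model files; any
scalar metadata label present in either can be plotted against the
iteration number.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .pipeline_graph import PipelineGraph, JobNode
from .star_io import (
    LoopTable,
    StarDocument,
    StarLookupError,
    read_star,
)

logger = logging.getLogger(__name__)

__all__ = [
    "IterationSeries",
    "ClassDistributionMatrix",
    "AngularHistogram",
    "FscCrossing",
    "TrackingError",
    "discover_iterations",
    "extract_series",
    "class_distribution",
    "model_spectra",
    "fsc_crossing",
    "angular_histogram",
    "job_backlog",
]


class TrackingError(ValueError):
    pass


_ITER_RE = re.compile(r"run_it(\d{3})_(model|optimiser)\.star$")

MODEL_CLASSES_BLOCK = "model_classes"
MODEL_GENERAL_BLOCK = "model_general"
CLASS_DISTRIBUTION_LABEL = "_rlnClassDistribution"
RESOLUTION_LABEL = "_rlnResolution"


@dataclass
class IterationSeries:
    """One scalar per iteration for a tracked metadata label."""

    iterations: List[int]
    values: List[float]
    label: str

    def __post_init__(self) -> None:
        if len(self.iterations) != len(self.values):
            raise TrackingError("iterations and values must align")
        if any(b <= a for a, b in zip(self.iterations, self.iterations[1:])):
            raise TrackingError("iterations must be strictly increasing")


@dataclass
class ClassDistributionMatrix:
    """Particle fraction per class (columns) per iteration (rows)."""

    iterations: List[int]
    classes: List[int]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (len(self.iterations), len(self.classes)):
            raise TrackingError(
                f"fractions shape {self.fractions.shape} does not match "
                f"{len(self.iterations)} iterations x {len(self.classes)} classes"
            )
        if np.any(self.fractions < 0):
            raise TrackingError("class fractions must be non-negative")
        sums = self.fractions.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise TrackingError(f"class fractions must sum to 1 per iteration: {sums}")


@dataclass
class AngularHistogram:
    """2D counts of particle orientations (rotation x tilt)."""

    rot_edges: np.ndarray
    tilt_edges: np.ndarray
    counts: np.ndarray

    @property
    def n_particles(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class FscCrossing:
    """Resolution (Å) where the FSC first drops through a threshold."""

    resolution: float
    at_nyquist: bool = False


def discover_iterations(job_dir) -> List[Tuple[int, Path, Path]]:
    """Find complete (iteration, model, optimiser) file triples, sorted.

    Iterations missing either file of the pair are skipped with a
    warning; an empty or missing directory yields an empty list.
    """
    job_dir = Path(job_dir)
    if not job_dir.is_dir():
        return []
    found: Dict[int, Dict[str, Path]] = {}
    for path in job_dir.iterdir():
        m = _ITER_RE.search(path.name)
        if m:
            found.setdefault(int(m.group(1)), {})[m.group(2)] = path
    out: List[Tuple[int, Path, Path]] = []
    for it in sorted(found):
        pair = found[it]
        if "model" in pair and "optimiser" in pair:
            out.append((it, pair["model"], pair["optimiser"]))
        else:
            missing = "model" if "model" not in pair else "optimiser"
            logger.warning("iteration %03d skipped: missing %s file", it, missing)
    return out


def _find_pair(doc: StarDocument, label: str):
    for block in doc.blocks:
        if block.has_pair(label):
            return block.get_pair(label)
    return None


def _available_pairs(doc: StarDocument) -> List[str]:
    labels: List[str] = []
    for block in doc.blocks:
        labels.extend(block.pairs)
    return labels


def extract_series(job_dir, label: str) -> IterationSeries:
    """Per-iteration values of a scalar metadata label.

    The label is looked up among the simple key/value pairs of each
    iteration's optimiser file first, then its model file.  Typical
    choices: ``ChangesOptimalClasses`` (classifications),
    ``CurrentResolution`` (refinements).
    """
    triples = discover_iterations(job_dir)
    iterations: List[int] = []
    values: List[float] = []
    available: List[str] = []
    for it, model_path, opt_path in triples:
        opt_doc = read_star(opt_path)
        value = _find_pair(opt_doc, label)
        if value is None:
            model_doc = read_star(model_path)
            value = _find_pair(model_doc, label)
            available = _available_pairs(opt_doc) + _available_pairs(model_doc)
        if value is None:
            raise StarLookupError(
                f"label {label!r} not found in iteration {it:03d}; "
                f"available: {sorted(set(available))}"
            )
        iterations.append(it)
        values.append(value)
    if not iterations:
        raise TrackingError(f"no complete iterations found in {job_dir}")
    return IterationSeries(iterations=iterations, values=values, label=label)


def class_distribution(job_dir) -> ClassDistributionMatrix:
    """Class-occupancy fractions per iteration, classes in class order."""
    triples = discover_iterations(job_dir)
    if not triples:
        raise TrackingError(f"no complete iterations found in {job_dir}")
    iterations: List[int] = []
    rows: List[List[float]] = []
    n_classes: Optional[int] = None
    for it, model_path, _ in triples:
        doc = read_star(model_path)
        table = doc.get_block(MODEL_CLASSES_BLOCK).table
        if table is None:
            raise TrackingError(f"{model_path}: no class table")
        fractions = [float(v) for v in table.column(CLASS_DISTRIBUTION_LABEL)]
        if n_classes is None:
            n_classes = len(fractions)
        elif len(fractions) != n_classes:
            raise TrackingError(
                f"{model_path}: {len(fractions)} classes, expected {n_classes} "
                "(class count changed across iterations)"
            )
        iterations.append(it)
        rows.append(fractions)
    return ClassDistributionMatrix(
        iterations=iterations,
        classes=list(range(1, (n_classes or 0) + 1)),
        fractions=np.array(rows),
    )


def model_spectra(model_path, label: str) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Per-class spectral curves from a model file.

    Returns one ``(resolution 1/Å, value)`` curve per class for labels
    such as ``GoldStandardFsc``, ``SpectralOrientabilityContribution``,
    ``FourierCompleteness`` or ``SsnrMap``.
    """
    doc = read_star(model_path)
    class_blocks = [
        b for b in doc.blocks
        if re.fullmatch(r"model_class_\d+", b.name) and b.table is not None
    ]
    class_blocks.sort(key=lambda b: int(b.name.rsplit("_", 1)[1]))
    if not class_blocks:
        raise TrackingError(f"{model_path}: no per-class spectral tables")
    curves: List[Tuple[np.ndarray, np.ndarray]] = []
    for block in class_blocks:
        table = block.table
        assert table is not None
        if table.n_rows == 0:
            raise TrackingError(f"{model_path}: empty class table data_{block.name}")
        freqs = np.array([float(v) for v in table.column(RESOLUTION_LABEL)])
        values = np.array([float(v) for v in table.column(label)])
        curves.append((freqs, values))
    return curves


def fsc_crossing(
    curve: Sequence[Tuple[float, float]], threshold: float = 0.143
) -> FscCrossing:
    """Resolution at the first downward crossing of an FSC threshold.

    The crossing frequency is found by linear interpolation between the
    bracketing samples and reported as a real-space resolution 1/f in Å.
    A curve that never drops to the threshold is flagged ``at_nyquist``
    and reported at its maximum frequency.  The default threshold 0.143
    is the gold-standard half-map convention.
    """
    freqs = np.array([f for f, _ in curve], dtype=float)
    fscs = np.array([v for _, v in curve], dtype=float)
    if len(freqs) < 2:
        raise TrackingError("FSC curve needs at least 2 samples")
    if np.any(np.diff(freqs) <= 0):
        raise TrackingError("FSC frequency axis must be strictly increasing")
    if fscs[0] <= threshold:
        raise TrackingError(
            f"first FSC sample {fscs[0]} is not above the threshold {threshold}"
        )
    for i in range(1, len(freqs)):
        if fscs[i] <= threshold:
            if fscs[i] == threshold:
                f_cross = freqs[i]
            else:
                f0, f1 = freqs[i - 1], freqs[i]
                v0, v1 = fscs[i - 1], fscs[i]
                f_cross = f0 + (v0 - threshold) / (v0 - v1) * (f1 - f0)
            return FscCrossing(resolution=1.0 / f_cross, at_nyquist=False)
    return FscCrossing(resolution=1.0 / freqs[-1], at_nyquist=True)


def angular_histogram(
    particles: LoopTable, n_rot_bins: int = 72, n_tilt_bins: int = 36
) -> AngularHistogram:
    """Histogram particle Euler angles on a regular rot x tilt grid.

    Rotation spans [-180°, 180°], tilt [0°, 180°]; values on a right or
    top edge fall in the last bin, so the total count always equals the
    number of particles.  The 72 x 36 default gives 5° x 5° bins.
    """
    rot = np.array([float(v) for v in particles.column("AngleRot")])
    tilt = np.array([float(v) for v in particles.column("AngleTilt")])
    bad = np.nonzero(
        (rot < -180) | (rot > 180) | (tilt < 0) | (tilt > 180)
        | ~np.isfinite(rot) | ~np.isfinite(tilt)
    )[0]
    if bad.size:
        raise TrackingError(
            f"angles out of range ([-180,180] x [0,180]) in rows: {bad.tolist()}"
        )
    rot_edges = np.linspace(-180.0, 180.0, n_rot_bins + 1)
    tilt_edges = np.linspace(0.0, 180.0, n_tilt_bins + 1)
    counts, _, _ = np.histogram2d(rot, tilt, bins=(rot_edges, tilt_edges))
    return AngularHistogram(
        rot_edges=rot_edges,
        tilt_edges=tilt_edges,
        counts=counts.astype(int),
    )


def _count_rows(path: Path) -> Optional[int]:
    """Row count of a STAR file's data table (the optics block is skipped)."""
    if not path.exists():
        return None
    try:
        doc = read_star(path)
    except ValueError:
        return None
    for block in doc.blocks:
        if block.table is not None and block.name != "optics":
            return block.table.n_rows
    return None


def job_backlog(
    project_root,
    graph: PipelineGraph,
    jobs: Optional[Sequence[JobNode]] = None,
) -> Dict[str, Tuple[int, int]]:
    """Done/pending image counts per job, for the live-processing header.

    For each job, ``done`` is the row count of its output STAR table and
    ``pending`` is the upstream input count minus ``done``, floored at
    zero (output can momentarily run ahead of input while both files are
    being polled).  A missing output file counts as zero done.
    """
    root = Path(project_root)
    if jobs is None:
        jobs = graph.jobs
    result: Dict[str, Tuple[int, int]] = {}
    for job in jobs:
        inputs = graph.inputs_of(job.name)
        upstream = 0
        for node in inputs:
            n = _count_rows(root / node)
            if n is not None:
                upstream = max(upstream, n)
        done = 0
        for node in graph.outputs_of(job.name):
            n = _count_rows(root / node)
            if n is not None:
                done = max(done, n)
        if not inputs:
            # source jobs (e.g. Import) have nothing pending by definition
            pending = 0
        else:
            pending = upstream - done
            if pending < 0:
                logger.warning(
                    "job %s output (%d) ahead of input (%d); "
                    "clamping pending to 0",
                    job.name, done, upstream,
                )
                pending = 0
        result[job.name] = (done, pending)
    return result
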