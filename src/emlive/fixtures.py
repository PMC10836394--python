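"""Synthetic cryo-EM project generator.

Builds miniature but structurally faithful RELION-style projects —
micrographs with a controllable ice-ring signal, CTFFIND-style radial
profiles, pipeline/job metadata, and classification/refinement iteration
series with planted values — entirely from a seed.  Every output is a
pure function of its spec: the same spec produces byte-identical trees.

The micrograph model is deliberately minimal: unit-variance Gaussian
white noise plus an isotropic ring of extra Fourier amplitude in a
narrow Gaussian annulus around 1/ring_center (default 3.8 Å, inside the
3.6–4.0 Å window where both vitreous and crystalline ice diffract).
The ring amplitude is added *in phase* with the noise spectrum, so band
power — and hence the ice score — is strictly increasing in the ring
amplitude for a fixed seed.  No particles, CTF envelope or detector
model are simulated; the generator emulates exactly the signal the ice
score measures, nothing more.

Planted numeric metadata are quantized through the STAR serialization
format first, so every planted value is recovered bit-exactly after a
write/parse round trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import star_io
from .preview import Image2D, write_mrc
from .star_io import LoopTable, StarBlock, StarDocument, write_star_file

__all__ = [
    "FixtureSpec",
    "RunPlan",
    "FixtureError",
    "quantize",
    "make_micrograph",
    "make_ctffind_profile",
    "make_particles",
    "make_project",
]


class FixtureError(ValueError):
    pass


def quantize(value: float) -> float:
    """Round a real through the STAR serialization format.

    Planted values pass through this so that what the generator records
    equals bit-for-bit what a reader recovers after one round trip.
    """
    return float(star_io.format_value(float(value)))


@dataclass
class RunPlan:
    """Planted classification/refinement series for a fixture job.

    ``kind`` is a RELION job-type directory name (``Class2D``,
    ``Class3D`` or ``Refine3D``).  Series left as None are generated
    deterministically from the seed: ChangesOptimalClasses decays
    geometrically, CurrentResolution improves toward ~3 Å, class
    distributions drift on the simplex, and the FSC is a smooth
    sigmoid-like falloff.
    """

    kind: str = "Class2D"
    n_classes: int = 3
    n_iterations: int = 6
    changes_optimal_classes: Optional[List[float]] = None
    current_resolution: Optional[List[float]] = None
    class_distributions: Optional[List[List[float]]] = None  # iter x K
    fsc: Optional[List[Tuple[float, float]]] = None  # (freq 1/Å, fsc)
    n_spectral_samples: int = 20

    def job_name(self, index: int) -> str:
        return f"{self.kind}/job{index:03d}/"


@dataclass
class FixtureSpec:
    """Everything a synthetic project is generated from."""

    seed: int = 0
    n_micrographs: int = 10
    image_size: int = 128
    pixel_size: float = 1.0
    ring_amplitudes: Optional[Sequence[float]] = None  # default: spread 0..2
    ring_center: float = 3.8
    n_processed: Optional[int] = None  # micrographs past MotionCorr/CtfFind
    planted_metadata: Optional[Dict[str, Sequence[float]]] = None
    run_plan: Optional[RunPlan] = None
    optics_groups: Optional[List[Tuple[float, float, float]]] = None
    n_particles: int = 200
    write_images: bool = True

    def resolved_ring_amplitudes(self) -> List[float]:
        if self.ring_amplitudes is not None:
            if len(self.ring_amplitudes) != self.n_micrographs:
                raise FixtureError(
                    f"{len(self.ring_amplitudes)} ring amplitudes for "
                    f"{self.n_micrographs} micrographs"
                )
            return [float(a) for a in self.ring_amplitudes]
        if self.n_micrographs == 1:
            return [0.0]
        return [
            2.0 * i / (self.n_micrographs - 1) for i in range(self.n_micrographs)
        ]


_DOC_TEXT_ALPHABET = "abcdefghijklmnopqrstuvwxyz0123456789._/-"


def make_random_star_document(rng: np.random.Generator) -> StarDocument:
    """A random STAR document for round-trip exercising.

    Cell values cover integers, serialization-representable reals and
    text (including tokens that look numeric and must stay text); blocks
    mix simple pairs and loop tables.
    """

    def rand_ident() -> str:
        n = int(rng.integers(1, 10))
        return "".join(
            _DOC_TEXT_ALPHABET[i]
            for i in rng.integers(0, 36, size=n)  # letters+digits only
        )

    def rand_scalar():
        kind = rng.integers(0, 3)
        if kind == 0:
            return int(rng.integers(-(10**9), 10**9))
        if kind == 1:
            return quantize(float(rng.uniform(-1e6, 1e6)) * 10.0 ** int(rng.integers(-6, 4)))
        n = int(rng.integers(0, 12))
        return "".join(
            _DOC_TEXT_ALPHABET[i]
            for i in rng.integers(0, len(_DOC_TEXT_ALPHABET), size=n)
        )

    blocks = []
    names = set()
    for _ in range(int(rng.integers(0, 4))):
        name = rand_ident()
        if name in names:
            continue
        names.add(name)
        pairs = {}
        for _ in range(int(rng.integers(0, 4))):
            pairs.setdefault("_rln" + rand_ident(), rand_scalar())
        table = None
        if rng.random() < 0.8 or not pairs:
            labels = list(dict.fromkeys(
                "_rln" + rand_ident() for _ in range(int(rng.integers(1, 5)))
            ))
            rows = [
                tuple(rand_scalar() for _ in labels)
                for _ in range(int(rng.integers(0, 6)))
            ]
            table = LoopTable(labels, rows)
        blocks.append(StarBlock(name=name, pairs=pairs, table=table))
    return StarDocument(blocks)


# ---------------------------------------------------------------------------
# Micrographs and profiles

RING_SIGMA = 0.01  # annulus width in 1/Å


def make_micrograph(
    size: int,
    pixel_size: float,
    seed: int,
    ring_amplitude: float = 0.0,
    ring_center: float = 3.8,
) -> Image2D:
    """White noise plus an isotropic ice-like ring at 1/ring_center.

    With amplitude 0 the image is pure unit-variance noise.  The ring is
    injected as extra Fourier amplitude in phase with the noise, so the
    power in the ring band is strictly increasing in the amplitude.
    """
    if ring_center <= 2.0 * pixel_size:
        raise FixtureError(
            f"ring at {ring_center} Å is beyond Nyquist for pixel size "
            f"{pixel_size} Å (need ring_center > {2.0 * pixel_size} Å)"
        )
    if ring_amplitude < 0:
        raise FixtureError(f"ring amplitude must be >= 0, got {ring_amplitude}")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((size, size))
    if ring_amplitude == 0.0:
        return Image2D(noise.astype(np.float32), pixel_size)
    ft = np.fft.rfft2(noise)
    fy = np.fft.fftfreq(size, d=pixel_size)
    fx = np.fft.rfftfreq(size, d=pixel_size)
    fr = np.hypot(fy[:, None], fx[None, :])
    annulus = np.exp(-((fr - 1.0 / ring_center) ** 2) / (2.0 * RING_SIGMA**2))
    mag = np.abs(ft)
    unit = np.where(mag > 0, ft / np.where(mag > 0, mag, 1.0), 1.0)
    # in-phase amplitude boost; scale ~N so the ring competes with the
    # noise floor (E|F| ≈ N for unit-variance noise)
    ft_ring = ft + ring_amplitude * size * annulus * unit
    image = np.fft.irfft2(ft_ring, s=(size, size))
    return Image2D(image.astype(np.float32), pixel_size)


def make_ctffind_profile(path, frequencies: Sequence[float],
                         signal_rows: Sequence[Sequence[float]]) -> None:
    """Write a CTFFIND4 ``_avrot``-style text profile.

    The file gets comment lines, the frequency row, then every signal
    row, each whitespace-separated; all rows must have equal length.
    """
    freqs = list(frequencies)
    rows = [list(r) for r in signal_rows]
    if not rows:
        raise FixtureError("need at least one signal row")
    for r in rows:
        if len(r) != len(freqs):
            raise FixtureError(
                f"signal row length {len(r)} != frequency row length {len(freqs)}"
            )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# Synthetic CTFFIND4-style radial profile\n")
        fh.write("# 1 - spatial frequency (1/Angstroms); further rows - signal\n")
        for row in [freqs] + rows:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def _avrot_rows_for(image: Image2D, band_values_seed: int) -> List[List[float]]:
    """Six-row avrot layout derived from the image's own radial average."""
    from .spectra import power_spectrum, radial_average

    profile = radial_average(
        power_spectrum(image.pixels, image.pixel_size or 1.0),
        image.pixel_size or 1.0,
    )
    total = profile.values.sum()
    values = (profile.values / total if total > 0 else profile.values).tolist()
    n = len(values)
    rng = np.random.default_rng(band_values_seed)
    fit = np.clip(np.linspace(1.0, 0.0, n) + 0.01 * rng.standard_normal(n), 0, 1)
    return [
        [v * 1.1 for v in values],  # raw rotational average
        values,  # background-subtracted rotational average (row index 2)
        fit.tolist(),  # CTF fit
        np.abs(rng.standard_normal(n)).tolist(),  # cross-correlation
        [0.5] * n,  # 2-sigma significance
    ]


# ---------------------------------------------------------------------------
# Particle tables


def make_particles(
    n: int,
    optics_groups: Sequence[Tuple[float, float, float]],
    seed: int = 0,
) -> LoopTable:
    """Particle table with planted orientation structure.

    ``optics_groups`` is a list of (fraction, tilt_center °, tilt
    spread °); rotations are uniform in [-180, 180], tilts Gaussian
    around each group's center, truncated to [0, 180].  Emulates merged
    untilted/tilted collections whose optics groups occupy different
    tilt bands.
    """
    fractions = [g[0] for g in optics_groups]
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise FixtureError(f"group fractions must sum to 1, got {sum(fractions)}")
    rng = np.random.default_rng(seed)
    counts = [int(round(f * n)) for f in fractions]
    counts[-1] = n - sum(counts[:-1])
    if any(c < 0 for c in counts):
        raise FixtureError(f"group fractions {fractions} infeasible for n={n}")
    rows = []
    for group_id, ((_, center, spread), count) in enumerate(
        zip(optics_groups, counts), start=1
    ):
        rot = rng.uniform(-180.0, 180.0, size=count)
        tilt = np.clip(center + spread * rng.standard_normal(count), 0.0, 180.0)
        for i in range(count):
            rows.append(
                (
                    f"{i + 1:06d}@particles_group{group_id}.mrcs",
                    quantize(rot[i]),
                    quantize(tilt[i]),
                    group_id,
                )
            )
    return LoopTable(
        ["_rlnImageName", "_rlnAngleRot", "_rlnAngleTilt", "_rlnOpticsGroup"],
        rows,
    )


def default_optics_block(n_groups: int = 1, pixel_size: float = 1.0) -> StarBlock:
    rows = [
        (g, f"opticsGroup{g}", quantize(pixel_size), 300.0, 2.7)
        for g in range(1, n_groups + 1)
    ]
    return StarBlock(
        name="optics",
        table=LoopTable(
            [
                "_rlnOpticsGroup",
                "_rlnOpticsGroupName",
                "_rlnImagePixelSize",
                "_rlnVoltage",
                "_rlnSphericalAberration",
            ],
            rows,
        ),
    )


# ---------------------------------------------------------------------------
# Whole-project generation

_JOB_CHAIN = (
    ("Import/job001/", "relion.import.movies"),
    ("MotionCorr/job002/", "relion.motioncorr.own"),
    ("CtfFind/job003/", "relion.ctffind.ctffind4"),
    ("External/job004/", "relion.external"),  # the ice-scoring job
)


def _job_star_doc(job_type: str, options: Dict[str, object]) -> StarDocument:
    return StarDocument(
        [
            StarBlock(
                name="job",
                pairs={"_rlnJobTypeLabel": job_type, "_rlnJobIsContinue": 0},
            ),
            StarBlock(
                name="joboptions_values",
                table=LoopTable(
                    ["_rlnJobOptionVariable", "_rlnJobOptionValue"],
                    [(k, v) for k, v in options.items()],
                ),
            ),
        ]
    )


def _planted_or_default(spec: FixtureSpec, rng: np.random.Generator,
                        label: str, lo: float, hi: float) -> List[float]:
    planted = (spec.planted_metadata or {}).get(label)
    if planted is not None:
        if len(planted) != spec.n_micrographs:
            raise FixtureError(
                f"planted {label} has {len(planted)} values for "
                f"{spec.n_micrographs} micrographs"
            )
        return [quantize(v) for v in planted]
    return [quantize(v) for v in rng.uniform(lo, hi, size=spec.n_micrographs)]


def _default_run_series(plan: RunPlan, rng: np.random.Generator):
    it = plan.n_iterations
    k = plan.n_classes
    changes = plan.changes_optimal_classes
    if changes is None:
        changes = [quantize(0.9 * 0.55**i) for i in range(it)]
    else:
        changes = [quantize(v) for v in changes]
    resolution = plan.current_resolution
    if resolution is None:
        resolution = [quantize(12.0 * (0.8**i) + 3.0) for i in range(it)]
    else:
        resolution = [quantize(v) for v in resolution]
    dists = plan.class_distributions
    if dists is None:
        raw = rng.dirichlet(np.ones(k) * 5.0, size=it)
        dists = raw.tolist()
    dists = [_quantized_simplex(row) for row in dists]
    fsc = plan.fsc
    if fsc is None:
        freqs = np.linspace(0.01, 0.5, plan.n_spectral_samples)
        fsc = [
            (quantize(f), quantize(1.0 / (1.0 + math.exp((f - 0.25) / 0.03))))
            for f in freqs
        ]
    else:
        fsc = [(quantize(f), quantize(v)) for f, v in fsc]
    return changes, resolution, dists, fsc


def _quantized_simplex(row: Sequence[float]) -> List[float]:
    """Quantize simplex fractions so they still sum to 1 exactly at 1e-6."""
    q = [quantize(v) for v in row[:-1]]
    last = quantize(1.0 - sum(q))
    if last < 0:
        raise FixtureError(f"class distribution row not on the simplex: {row}")
    return q + [last]


def _write_run_files(job_dir: Path, plan: RunPlan, rng: np.random.Generator) -> None:
    changes, resolution, dists, fsc = _default_run_series(plan, rng)
    freqs = [f for f, _ in fsc]
    n_spec = len(freqs)
    for it in range(plan.n_iterations):
        # model.star: general pairs, class table, per-class spectral tables
        class_rows = [
            (f"class{ci + 1:03d}", dists[it][ci], quantize(10.0 + ci))
            for ci in range(plan.n_classes)
        ]
        blocks = [
            StarBlock(
                name="model_general",
                pairs={
                    "_rlnNrClasses": plan.n_classes,
                    "_rlnCurrentResolution": resolution[it],
                    "_rlnPixelSize": 1.0,
                },
            ),
            StarBlock(
                name="model_classes",
                table=LoopTable(
                    [
                        "_rlnReferenceImage",
                        "_rlnClassDistribution",
                        "_rlnEstimatedResolution",
                    ],
                    class_rows,
                ),
            ),
        ]
        for ci in range(plan.n_classes):
            rows = []
            for si in range(n_spec):
                f = freqs[si]
                rows.append(
                    (
                        si,
                        f,
                        fsc[si][1],
                        quantize(max(0.0, 1.0 - f - 0.05 * ci)),
                        quantize(min(1.0, 0.2 + f + 0.1 * ci)),
                        quantize(10.0 * math.exp(-f * 6.0) + 0.01 * ci),
                    )
                )
            blocks.append(
                StarBlock(
                    name=f"model_class_{ci + 1}",
                    table=LoopTable(
                        [
                            "_rlnSpectralIndex",
                            "_rlnResolution",
                            "_rlnGoldStandardFsc",
                            "_rlnSpectralOrientabilityContribution",
                            "_rlnFourierCompleteness",
                            "_rlnSsnrMap",
                        ],
                        rows,
                    ),
                )
            )
        write_star_file(StarDocument(blocks), job_dir / f"run_it{it:03d}_model.star")
        opt_doc = StarDocument(
            [
                StarBlock(
                    name="optimiser_general",
                    pairs={
                        "_rlnCurrentIteration": it,
                        "_rlnChangesOptimalClasses": changes[it],
                        "_rlnChangesOptimalOrientations": quantize(5.0 * 0.6**it),
                        "_rlnChangesOptimalOffsets": quantize(2.0 * 0.7**it),
                    },
                )
            ]
        )
        write_star_file(opt_doc, job_dir / f"run_it{it:03d}_optimiser.star")


def make_project(spec: FixtureSpec, root) -> Path:
    """Materialize a miniature RELION-style project tree under ``root``.

    Writes ``pipeline.star`` (Import → MotionCorr → CtfFind → External
    ice chain, plus the run-plan job when present), per-job ``job.star``
    files, micrograph metadata STAR tables with planted values, MRC
    micrographs and CTF images, CTFFIND-style radial profiles, a
    particles file when optics groups are configured, and planted
    iteration series for the run plan.  Refuses a non-empty root.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    if any(root.iterdir()):
        raise FixtureError(f"project root {root} is not empty")
    rng = np.random.default_rng(spec.seed)
    amplitudes = spec.resolved_ring_amplitudes()
    n = spec.n_micrographs
    n_done = spec.n_processed if spec.n_processed is not None else n
    if not 0 <= n_done <= n:
        raise FixtureError(f"n_processed {n_done} outside 0..{n}")

    jobs = list(_JOB_CHAIN)
    data_nodes = [
        "Import/job001/movies.star",
        "MotionCorr/job002/corrected_micrographs.star",
        "CtfFind/job003/micrographs_ctf.star",
        "External/job004/micrographs_ice.star",
    ]
    output_edges = list(zip([j for j, _ in jobs], data_nodes))
    input_edges = [
        ("Import/job001/movies.star", "MotionCorr/job002/"),
        ("MotionCorr/job002/corrected_micrographs.star", "CtfFind/job003/"),
        ("CtfFind/job003/micrographs_ctf.star", "External/job004/"),
    ]

    job_options: Dict[str, Dict[str, object]] = {
        "Import/job001/": {"fn_in_raw": "Movies/*.tiff", "kV": 300,
                           "angpix": spec.pixel_size},
        "MotionCorr/job002/": {"input_star_mics": "Import/job001/movies.star",
                               "bin_factor": 1, "dose_weighting": "Yes"},
        "CtfFind/job003/": {
            "input_star_mics": "MotionCorr/job002/corrected_micrographs.star",
            "use_ctffind4": "Yes", "dast": 100},
        "External/job004/": {
            "fn_exe": "ice_score",
            "in_mics": "CtfFind/job003/micrographs_ctf.star"},
    }

    run_job_name = None
    if spec.run_plan is not None:
        run_job_name = spec.run_plan.job_name(len(jobs) + 1)
        jobs.append((run_job_name, f"relion.{spec.run_plan.kind.lower()}"))
        particles_node = f"{run_job_name}run_data.star"
        data_nodes.append(particles_node)
        output_edges.append((run_job_name, particles_node))
        input_edges.append(
            ("CtfFind/job003/micrographs_ctf.star", run_job_name)
        )
        job_options[run_job_name] = {
            "nr_classes": spec.run_plan.n_classes,
            "nr_iter": spec.run_plan.n_iterations,
        }

    # --- micrograph content ------------------------------------------------
    mic_names = [
        f"MotionCorr/job002/Movies/mic_{i:03d}.mrc" for i in range(n)
    ]
    mic_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]
    if spec.write_images:
        (root / "MotionCorr/job002/Movies").mkdir(parents=True)
        (root / "CtfFind/job003/Movies").mkdir(parents=True)
        for i, name in enumerate(mic_names[:n_done]):
            img = make_micrograph(
                spec.image_size, spec.pixel_size, mic_seeds[i],
                amplitudes[i], spec.ring_center,
            )
            write_mrc(img, root / name)
            # CTF "image": the centered power spectrum of the micrograph
            from .spectra import power_spectrum

            ctf_img = Image2D(
                np.log1p(
                    power_spectrum(img.pixels, spec.pixel_size)
                ).astype(np.float32),
                spec.pixel_size,
            )
            ctf_name = f"CtfFind/job003/Movies/mic_{i:03d}_ctf.mrc"
            write_mrc(ctf_img, root / ctf_name)
            rows = _avrot_rows_for(img, band_values_seed=mic_seeds[i])
            profile_freqs = [
                r / (spec.image_size * spec.pixel_size)
                for r in range(1, spec.image_size // 2 + 1)
            ]
            make_ctffind_profile(
                root / f"MotionCorr/job002/Movies/mic_{i:03d}_avrot.txt",
                profile_freqs,
                rows,
            )
    for job_name, _ in jobs:
        (root / job_name).mkdir(parents=True, exist_ok=True)

    # --- metadata tables ---------------------------------------------------
    motion = _planted_or_default(spec, rng, "AccumMotionTotal", 10.0, 80.0)
    defocus_u = _planted_or_default(spec, rng, "DefocusU", 5000.0, 30000.0)
    astig = _planted_or_default(spec, rng, "CtfAstigmatism", 0.0, 400.0)
    defocus_v = [quantize(u - a) for u, a in zip(defocus_u, astig)]
    ctf_res = _planted_or_default(spec, rng, "CtfMaxResolution", 3.0, 8.0)
    ctf_fom = _planted_or_default(spec, rng, "CtfFigureOfMerit", 0.05, 0.3)

    movies_table = LoopTable(
        ["_rlnMicrographMovieName", "_rlnOpticsGroup"],
        [(f"Movies/movie_{i:03d}.tiff", 1) for i in range(n)],
    )
    write_star_file(
        StarDocument([
            default_optics_block(1, spec.pixel_size),
            StarBlock(name="movies", table=movies_table),
        ]),
        root / "Import/job001/movies.star",
    )

    mc_table = LoopTable(
        ["_rlnMicrographName", "_rlnAccumMotionTotal", "_rlnOpticsGroup"],
        [(mic_names[i], motion[i], 1) for i in range(n_done)],
    )
    write_star_file(
        StarDocument([
            default_optics_block(1, spec.pixel_size),
            StarBlock(name="micrographs", table=mc_table),
        ]),
        root / "MotionCorr/job002/corrected_micrographs.star",
    )

    ctf_table = LoopTable(
        [
            "_rlnMicrographName",
            "_rlnAccumMotionTotal",
            "_rlnDefocusU",
            "_rlnDefocusV",
            "_rlnCtfAstigmatism",
            "_rlnCtfMaxResolution",
            "_rlnCtfFigureOfMerit",
            "_rlnCtfImage",
        ],
        [
            (
                mic_names[i],
                motion[i],
                defocus_u[i],
                defocus_v[i],
                astig[i],
                ctf_res[i],
                ctf_fom[i],
                f"CtfFind/job003/Movies/mic_{i:03d}_ctf.mrc",
            )
            for i in range(n_done)
        ],
    )
    write_star_file(
        StarDocument([
            default_optics_block(1, spec.pixel_size),
            StarBlock(name="micrographs", table=ctf_table),
        ]),
        root / "CtfFind/job003/micrographs_ctf.star",
    )

    # --- job.star files ----------------------------------------------------
    type_by_name = dict(jobs)
    for job_name, job_type in jobs:
        write_star_file(
            _job_star_doc(job_type, job_options[job_name]),
            root / job_name / "job.star",
        )

    # --- particles ---------------------------------------------------------
    if spec.optics_groups is not None:
        particles = make_particles(
            spec.n_particles, spec.optics_groups,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        target_dir = root / (run_job_name or "External/job004/")
        write_star_file(
            StarDocument([
                default_optics_block(len(spec.optics_groups), spec.pixel_size),
                StarBlock(name="particles", table=particles),
            ]),
            target_dir / "run_data.star",
        )

    # --- run plan ----------------------------------------------------------
    if spec.run_plan is not None and run_job_name is not None:
        _write_run_files(root / run_job_name, spec.run_plan, rng)

    # --- pipeline.star -----------------------------------------------------
    from .pipeline_graph import JobNode, PipelineGraph, pipeline_to_star

    graph = PipelineGraph(
        jobs=[
            JobNode(name=name, type=type_by_name[name], status="Succeeded")
            for name, _ in jobs
        ],
        data_nodes=data_nodes,
        output_edges=output_edges,
        input_edges=input_edges,
    )
    write_star_file(pipeline_to_star(graph), root / "pipeline.star")
    return root
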