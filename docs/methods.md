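# Methods

This note documents the models, conventions and numerical choices behind
`emlive`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## STAR metadata model

A STAR document is an ordered list of uniquely named `data_` blocks;
each block holds ordered `_label value` pairs and/or one `loop_` table
whose rows are tuples of individually typed cells.  Typing follows the
untyped STAR convention used throughout cryo-EM processing: a token is
an integer if it matches an integer literal, a real if it matches a
float literal (scientific notation included), otherwise text.  Quoted
tokens are always text, and text that *looks* numeric is re-quoted on
write, so typing survives round trips.

Reals serialize with six decimal places (fixed notation for magnitudes
in [10⁻⁴, 10⁶), scientific otherwise), mirroring the `%12.6f`-style
columns RELION writes.  Round-trip identity is therefore defined **after
one write**: for any document whose reals are representable at that
precision, `parse(write(doc)) == doc`, and `write ∘ parse ∘ write` is
always byte-stable.  Freshly computed quantities (e.g. ice scores)
quantize on their first serialization; the synthetic generator
pre-quantizes every planted value through the same formatter so planted
values are recovered bit-exactly.

Label lookup is case-sensitive but tolerant of the `_`/`_rln` prefix
(`"CtfMaxResolution"` resolves `_rlnCtfMaxResolution`), matching how
the labels are written in prose and plot axes.  Comments are discarded
on parse; multi-line (semicolon-delimited) values and save frames are
out of scope — RELION does not emit them.  There is no missing-value
convention in these files; the parser treats any bare token as text and
the generator never produces missing cells.

## Ice-quality score

The score for a micrograph is the arithmetic mean of its rotationally
averaged power spectrum over spatial frequencies 1/4.0 to 1/3.6 Å⁻¹,
edges inclusive — the window where vitreous and crystalline ice
diffract.  Inclusive edges maximize the number of contributing samples
of a discrete profile.  The score is dimensionless and has no absolute
calibration; only its ranking across micrographs is meaningful.

**Native route.** The power spectrum is `|FFT(image)|²` with the DC
component centered; non-square micrographs are center-cropped to the
largest square so radial bins stay isotropic.  The radial average bins
every Fourier pixel (DC excluded) by nearest-integer radius, ties at .5
rounding half away from zero; the value at radius *r* is the mean over
its annulus, its frequency is *r/(N·pixel_size)*, and bins beyond
Nyquist are discarded.  By default the spectrum is divided by its total
power (DC excluded) before averaging, making the score invariant to
overall image intensity — a deliberate convention, since the score has
no physical scale anyway; with normalization disabled, scaling an image
by *k* scales the score by *k²* (DFT homogeneity).  The band requires at
least one profile sample, which bounds the usable pixel size at 2 Å
(Nyquist must reach 0.25 Å⁻¹).

**Profile route.** CTFFIND4 already computes the radially averaged
spectrum per micrograph and writes it as a text file (`*_avrot.txt`:
comment lines, then equal-length numeric rows, the first being spatial
frequency in 1/Å).  The reader takes a configurable signal row,
defaulting to row index 2 — the background-subtracted rotational average
in the six-row layout — because background subtraction removes the
defocus-envelope trend that would otherwise dominate the band mean.
Whether the raw or subtracted row (or a log scale) is preferable is a
judgement call; both are exposed, the subtracted linear row is the
default.  The zero-frequency sample is always dropped.

The two routes agree in ranking, not in value; the test suite and the
acceptance script quantify this with a Spearman correlation on a
30-micrograph synthetic set (ρ > 0.99 observed; the design requirement
is ρ > 0.9).

## Filtering and selection

Threshold rules are `(label, min, max)` with inclusive bounds and
absent bounds unbounded: with a maximum accumulated motion of 50 Å, a
micrograph at exactly 50 Å is kept — "over 50 Å" is discarded.  NaN in
a thresholded column discards the row with a logged warning, the
fail-safe choice for partially processed micrographs.  Filters are pure
functions: they never mutate the input table, and the kept/discarded
outputs always partition it in order.  Live use is polling plus
re-filtering (default 10 s); no filesystem-event subscription is used,
keeping the behaviour portable and trivially testable.

Lasso selection takes a simple polygon over any two numeric metadata
columns.  Points on the polygon boundary count as selected — a user
circling points intends to include the ones they traced over.  Geometry
predicates are delegated to shapely; the test suite checks them against
an independently written winding-number oracle.  Degenerate
(zero-area) and self-intersecting polygons are rejected at
construction; since a bowtie's signed area cancels to zero, degeneracy
is judged on the repaired geometry before simplicity is judged on the
original.

Selections re-export as STAR files with the optics block (when present)
ahead of the data block, so RELION re-imports them directly.  Block
names follow the RELION 4 convention (`data_optics` +
`data_particles`, or `data_micrographs`); exports keep the source
block's name so the table kind is preserved.

## Pipeline graph

`pipeline.star` describes a bipartite graph: jobs produce data nodes
(files) via output edges and consume them via input edges.  The induced
job graph (job A → job B iff A outputs a file B consumes) must be
acyclic — a job consuming its own output is rejected as a self-loop.
Job types and statuses are open vocabularies passed through verbatim, so
new job types in future RELION versions need no code change; the exact
block/label spellings live in a single dialect table, making a renamed
dialect a one-line change.  Topological order breaks ties by job name
for determinism.  Per-job parameters come from `<job>/job.star` in file
order, with values kept in their text form (paths and `Yes`/`No`
booleans verbatim; numeric options re-rendered through the standard
column format, since cells are typed on parse).  Aliases are retained
alongside names; the caller chooses which to display.

## Run tracking

Classification/refinement jobs write a
`run_itNNN_model.star`/`run_itNNN_optimiser.star` pair per iteration;
discovery pairs them by iteration number and skips incomplete pairs
with a warning, so a job can be followed while it runs.  Series
extraction searches the optimiser file's key/value pairs first, then
the model file's — a documented, deterministic order, since both files
carry scalar metadata.  Class distributions require a constant class
count across iterations and each row must sum to 1 within 1e-6.

The FSC crossing interpolates linearly between the samples bracketing
the first downward crossing of the threshold and reports 1/f in Å; the
default threshold 0.143 is the gold-standard half-map convention (the
choice is exposed).  A curve that never drops to the threshold reports
the resolution at its maximum frequency flagged `at_nyquist`.

Angular histograms bin rotation ∈ [−180°, 180°] × tilt ∈ [0°, 180°] on
a regular grid, 72 × 36 (5° × 5°) by default — a typical granularity
for orientation plots; values on the right/top edge fall in the last
bin so the total count always equals the particle count.

Backlog counts for the live header are computed per job as `done` =
rows of the job's output STAR table and `pending` = upstream input rows
− done, floored at zero (polling can catch output momentarily ahead of
input, which is clamped with a warning).  The job's input and output
files come from the pipeline graph, so the function takes the graph
rather than bare job records; source jobs with no inputs report zero
pending.

## Preview rendering

MRC I/O covers the subset RELION emits for 2D images: MRC2014 headers,
little-endian modes 0/1/2, pixel size from the header cell dimensions;
multi-section stacks return the first section.  Images stay row-major
with origin at top-left; no axis flips are applied.  8-bit normalization
maps the [1, 99] intensity percentiles linearly onto [0, 255] with
clipping — robust to hot pixels, unlike min–max — and a constant image
maps to mid-gray 128.  Previews are mean-pooled by an integer factor
(default 4; output dims are the ceiling of input/factor, trailing
partial blocks averaging over the pixels they cover) and written as
deterministic 8-bit grayscale PNGs, `<stem>.png` and `<stem>_ctf.png`;
a side-by-side composite is optional, two separate files being the
default paired display.

## Synthetic data generator

Every generator output is a pure function of its spec: the same seed
produces byte-identical trees.

*Micrographs* are unit-variance Gaussian white noise plus an isotropic
"ice ring": extra Fourier amplitude in a Gaussian annulus (σ =
0.01 Å⁻¹) around 1/ring_center, default 3.8 Å — inside the 3.6–4.0 Å
ice window.  The ring amplitude is added in phase with the noise
spectrum, so band power is strictly increasing in the amplitude at a
fixed seed, which is exactly the property the score tests need;
amplitude 0 yields pure noise.  A project's default amplitudes spread
evenly over [0, 2], spanning clean to heavily contaminated.  The
default project is 10 micrographs of 128 × 128 px at 1 Å/px — small
enough for fast tests, large enough for 4 radial bins inside the ice
band.

*Projects* mimic the RELION 4 layout: an Import → MotionCorr → CtfFind
→ External(ice) chain in `pipeline.star`, per-job `job.star`, micrograph
tables with planted metadata (motion, defocus, astigmatism, CTF fit
scores drawn uniformly from realistic ranges: motion 10–80 Å, defocus
5 000–30 000 Å, CtfMaxResolution 3–8 Å, CtfFigureOfMerit 0.05–0.3),
MRC micrographs with CTF-image companions, CTFFIND-style avrot profiles
derived from each micrograph's own radial average, and — when a run
plan is set — planted per-iteration model/optimiser files.  Planted
class-distribution rows are quantized to the 6-decimal STAR format with
the last class rebalanced so each row still sums to exactly 1.
Particle tables draw rotations uniformly and tilts from truncated
Gaussians per optics group, emulating merged untilted/tilted
collections.

What the generator does **not** emulate: particles, CTF oscillations
and envelopes, detector noise statistics, drift, or any physically
calibrated ice model.  Passing tests therefore demonstrate that the
metadata plumbing, the score's ranking behaviour and the recovery of
planted values are correct — not that the score predicts physical ice
thickness on real micrographs (no such calibration is claimed anywhere).

## Problem sizes and determinism

The test suite and acceptance script use 32–128 px images, 5–30
micrograph projects, 200 random STAR documents, 50 random DAGs,
20 × 1000 polygon/point checks and 10⁴-particle histograms — sizes
chosen so the whole suite completes in seconds while every code path
and oracle comparison is exercised at full fidelity.  All randomness
flows from explicit seeds; property tests run derandomized.

## Known limitations

- The STAR dialect is RELION-oriented: no mmCIF dictionaries, save
  frames, or multi-line values.
- MRC modes other than 0/1/2 (e.g. complex, float16) are rejected.
- The profile-route ice score assumes the CTFFIND `_avrot.txt` naming
  convention for locating profiles next to micrographs.
- `run_it*` discovery assumes the three-digit iteration naming of
  current RELION versions and ignores half-map model files.
- The web dashboard layer this library could serve is intentionally
  absent; `--port` is accepted for configuration parity but unused.
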