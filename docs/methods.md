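# Methods

This note records what the package computes, the choices made where the
workflow is conventionally underspecified, and what the synthetic tests do
and do not establish about real data.

## Data model

An `ImageStack` is a float64 array `(n_frames, height, width)` plus a frame
rate. A reserved NaN marks *undefined* pixels — masked by a polygon crop,
exposed at the border by rigid resampling, or degenerate (zero ΔF/F₀
baseline). Every operation either propagates NaN or skips it explicitly;
nothing silently treats an undefined pixel as zero. For whole-series
operations (filtering, regression) a pixel counts as defined only if it is
finite at every frame, which is the case produced by masking and alignment
(both make a pixel undefined for the entire stack).

Imports convert everything to this representation immediately: RAW files
are read as pixel-interleaved channels (R,G,B,R,G,B…, row-major, frames
consecutive — the standard RGB24 camera layout; plane-interleaved input is
not supported), TIFF pages are taken in file order as time with no OME
metadata interpretation, and one channel is kept per import. Persisted
stacks are plain NPY (3-D, C order); NPY cannot carry a frame rate, so fps
is stored per file in the project manifest and `load_stack` takes it as an
argument.

## Project manifest and pipeline

A project is one flat directory: stack files plus
`mesoconn_project.json` holding the pixel width, the global bregma origin,
and per file its name, source, frame rate, optional per-stack origin and
the ordered manipulation history. A derived file's history is its source's
history plus exactly one entry, so filtering files by manipulation and
reconstructing provenance are trivial. Manifest writes are atomic
(write-temp-then-rename): a crashed step cannot corrupt the project.
Because records use bare file names, copying the directory moves the whole
project.

The runner executes an ordered list of registered steps. Steps are `map`
(per file), `batch` (all files in, one output per input — alignment, which
needs one reference for the whole set) or `reduce` (all files in, one out —
concatenation, evoked averaging, correlation matrices). New steps register
by name without touching the runner. Determinism is a contract: the same
config on the same inputs produces bit-identical outputs, which the
acceptance suite checks end to end. Both global and per-stack origins are
stored; the global origin is used unless a per-stack origin is explicitly
present (origin shifting consults the per-stack one first).

## Rigid registration

Sessions are aligned to a reference frame built from one template stack:
every frame is unsharp-filtered (`frame + (frame − blur)`, Gaussian blur
with σ = kernel/2 and support radius kernel//2; default kernel 8) to
emphasize the blood-vessel pattern, and a band of frames (default
[400, 500)) is averaged to suppress activity transients.

One transform per stack — translation, rotation, scale — is estimated from
a single frame (default the first), on the assumption that within-stack
movement is negligible. The estimator:

1. difference-of-Gaussians band-pass (σ = 1 and 2.5 px) of both frames,
   keeping vessel-scale detail and discarding the smooth illumination
   profile, whose spectral energy otherwise crowds DC and dominates the
   log-radial axis;
2. Hann window, FFT, log-magnitude; rotation and scale appear as shifts of
   the log-polar resampled spectrum (360 × 256 samples over radius
   min(shape)/4; upper half only, since the spectrum is point-symmetric)
   and are read off by phase correlation with 20× upsampling. The 180°
   ambiguity is resolved to the nearer branch, so rotations must be within
   ±90°;
3. translation by a second phase correlation after undoing the recovered
   rotation/scale;
4. up to four refinement passes, each re-estimating the residual motion of
   the partially aligned frame and composing it in, with early exit when
   the residual is negligible. A single pass leaves a systematic residual
   (up to ~0.04 in scale) for large combined motions; iteration brings the
   worst case over a 50-case planted grid (±10 px, ±15°, scale 0.9–1.1,
   five scenes) to 0.37 px / 0.35° / 0.016.

Resampling is bilinear; pixels mapped from outside the frame become
undefined rather than zero, so later statistics skip them honestly.
Whether an exhaustive or log-polar search is used is an implementation
choice here; log-polar was chosen for speed and subpixel behaviour.

## Coordinates and RoIs

Pixel coordinates are 0-based, x = column rightward, y = row downward.
Anatomical coordinates are microns from bregma, x mediolateral (positive
right), y anteroposterior (positive anterior), hence
`x_px = ox + x_um/s`, `y_px = oy − y_um/s`. The origin is the mean of
repeated bregma clicks (averaging reduces click error). The default scale,
41 μm/pixel, is a 10.5 mm field over a 256-pixel sensor.

Square seed RoIs come from a `name,length,x,y` CSV (microns; length in
pixels); fractional centers round half-away-from-zero; blocks are clipped
at the frame edge. Polygon crops test pixel centers with the even–odd
rule, boundary counting as inside; masking is idempotent, and midline or
border exclusion is expressed only through user polygons. The bundled
14-area bilateral seed table (V1, BC, HL, M1, M2, RS, AC per hemisphere)
carries Allen-atlas-derived coordinates.

## Temporal processing

* **Trim** drops leading frames (default 20) that can contain
  head-fixation settling movement, and optionally trailing frames.
* **Bandpass** is a type-I Chebyshev design (default order 4, 0.1 dB
  passband ripple — the conventional unit for this design — 0.3–3 Hz),
  applied forward–backward (`sosfiltfilt`, odd-reflection padding). The
  zero-phase choice matters because downstream correlations are zero-lag:
  a causal filter would introduce a frequency-dependent lag. The applied
  gain is therefore |H(f)|²: ≥ 0.95 at 1 Hz, ≤ 0.05 at 10 Hz, DC
  rejected below 1e-6, all verified against the designed response.
* **ΔF/F₀** uses the all-frame temporal mean as F₀ per pixel; zero
  baselines become undefined (count logged). Output temporal mean is zero
  to round-off.
* **GSR** regresses each pixel (OLS with intercept — the minimal general
  linear model) on the global signal, the frame-wise mean over *defined*
  pixels only, so masked midline/border regions never contaminate it.
  Residuals are exactly orthogonal to the global signal and their spatial
  mean is the zero series (algebraic identities, tested at round-off).
* **Concatenation** appends trials in order (shape and fps must match);
  correlations computed afterwards treat the boundary as one continuous
  series, which is the intended pooled estimate.
* **Division** (e.g. fluorescence ΔF/F₀ by reflectance ΔF/F₀ for
  hemodynamic correction), **evoked averaging** (frame-wise mean across
  trials, with an opt-in truncate-to-shortest) and **standard-deviation
  maps** (population, divisor n) are elementwise and carry NaN through.

### Step order caveat

The reference chain applies bandpass before ΔF/F₀. A 0.3–3 Hz bandpass
removes DC, so the post-filter F₀ is a numerically tiny residual and
ΔF/F₀ becomes an ill-conditioned per-pixel affine rescaling; Pearson
correlations are invariant under per-pixel affine maps, but a pixel whose
residual F₀ is negative gets its sign flipped in every downstream
correlation. With ΔF/F₀ computed on raw data (baseline ≫ 0) the issue
does not arise. The runner enforces no order; the worked example in the
README uses ΔF/F₀ → bandpass for interpretable values, and the
determinism guarantee holds for either order.

## Connectivity

Pearson r is computed at zero lag with pairwise deletion of frames in
which either series is undefined (at least three complete frames, both
series non-constant, else the value is undefined and signalled). SPC maps
set the seed's own value to exactly 1 and leave masked or zero-variance
pixels undefined; computation is chunked so memory stays bounded on long
concatenated recordings. Correlation matrices are computed per trial and
summarised by the arithmetic mean and the sample (n−1) standard deviation
across trials — zero for a single trial. Maps and matrices are emitted as
arrays/CSV; rendering uses a symmetric diverging colormap centered at 0
(the colormap is configuration, not contract).

## Synthetic ground truth

The generator emulates the recording conditions the pipeline targets:
256×256 at 30 Hz in 30 s epochs by default, disk-shaped cortical regions
driven by latent sources, a shared global component, a 10 Hz
heartbeat-band sinusoid, per-pixel white noise, and a static vessel-scene
baseline multiplying everything. Per region pixel,

    F(t) = B(x, y) · (1 + a_src·source(t) + a_glob·global(t)
                        + a_heart·sin(2π f_heart t) + σ·ε(t)),

with defaults a_src = 0.05, a_heart = 0.02, σ = 0.01 (a few-percent
fluorescence fluctuation), f_heart = 10 Hz, mean baseline 100.

Sources are standardized moving-average-smoothed Gaussian series mixed
through a matrix square root of the requested correlation matrix, so
planted pairwise correlations hold in expectation and converge with
length. The smoothing window is 3 frames: enough to remove frame-to-frame
jitter while keeping the autocorrelation-induced variance inflation of
the correlation estimator small (factor ≈ 2.1), so the i.i.d. sampling
bound 3/√n used by the recovery tests remains a valid (if not generous)
yardstick. A window matched to the 3 Hz band edge would inflate the
estimator sd past that bound. Sources are *not* autoregressive and carry
no indicator kinetics.

The static anatomy (`anatomy_seed`) is shared across a project's trials,
exactly as one animal's vasculature is; without it, alignment of
structure-free noise movies is meaningless. Trials redraw sources and
noise independently from per-trial seeds, so cross-trial dispersion is
real sampling variability. Planted misalignments for registration tests
are produced as crops of a twice-larger scene (`misaligned_views`) — a
moved camera sees a full field, and border-filled warps would introduce
step edges no real recording has.

What passing these tests shows: the implementation recovers planted
translation/rotation/scale, planted correlation structure, and the
filter/GSR contracts under controlled conditions. What it does not show:
robustness to non-rigid motion, hemodynamic contamination, photobleaching,
indicator decay kinetics or anatomy that changes between sessions — none
of which the generator models.

## Numerical choices

* 64-bit floating point throughout; imports convert immediately.
* Rounding of RoI centers: half away from zero.
* `sosfiltfilt` default odd-reflection padding; stacks must exceed three
  filter lengths.
* Sample (n−1) std across trials in correlation matrices; population
  (divisor n) std in temporal standard-deviation maps.
* Registration estimates require non-constant, fully defined frames;
  degenerate inputs raise.
* Problem sizes in the test suite and acceptance script (e.g. five
  900-frame 128×128 trials for the determinism check; 9 000 frames for
  correlation recovery; 64×64 fixtures elsewhere) were chosen as the
  smallest sizes at which the measured quantities are statistically
  meaningful.

## Known limitations

* Rigid alignment only; no within-stack motion correction or elastic
  registration.
* Rotation recovery is limited to ±90° by the spectrum symmetry (±15° is
  the validated range).
* GSR removes genuine widespread neural co-activation along with
  confounds and lowers (even sign-flips) between-region correlations when
  sources share variance — an inherent property of the method, not a bug;
  compare with and without.
* Correlation matrices and SPC maps are functional connectivity: no
  directionality or causality.
* The bandpass→ΔF/F₀ order caveat above.
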