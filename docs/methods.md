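# Methods

## Scoring model

A quadrant chemotaxis plate is scored from a single grayscale photograph.
Let A₁…A₄ be the segmented nematode pixel areas in quadrants 1–4
(numbered counter-clockwise from upper-right) and let the test compound
occupy one diagonal pair T ∈ {{1,3}, {2,4}}. The chemotaxis index is

    CI = (Σ_{q∈T} A_q − Σ_{q∉T} A_q) / Σ_q A_q ,

with pixels inside the center-exclusion disk reported separately and
excluded from the denominator — animals that never left the dispensing
origin made no choice. Pixel area stands in for animal counts because
individual counting fails on tightly clumped animals; the proxy is
linear in animal number as long as the imaging scale is constant within
an experiment, which is all the CI ratio requires. When no pixels fall
in any quadrant the CI is undefined and written as `NA` — reporting 0
would fabricate a neutral response.

## Plate geometry

Plate detection thresholds the image with Otsu's method, takes the
largest connected bright region (trying the inverted hypothesis if that
fails), fills holes, and fits a circle to the boundary pixels by the
Kåsa least-squares method. A fit is accepted only if the radius is a
plausible fraction of the frame (0.15–0.75 of the short side) and the
RMS boundary residual is below 5% of the radius; otherwise a detection
error instructs the caller to pass `--center/--radius` manually. On
synthetic plates spanning translations, radii and vignette strengths the
detector is sub-pixel accurate (see `scripts/acceptance.py`), comfortably
inside the 2 px / 2% contract asserted in the tests.

The region map trims `margin_frac` (default 0.05) of the radius at the
plate wall (meniscus and wall reflections) and excludes a central disk of
`center_exclusion_frac` (default 0.15) of the radius. Neither value is
dictated by the assay itself; both are exposed on the CLI. Quadrant
boundaries are two perpendicular lines through the center at
`axis_rotation_deg` (default 0: plates photographed square in the
holder); pixels exactly on a boundary are assigned by half-open angular
intervals [0°, 90°), [90°, 180°), … so every pixel is counted exactly
once.

## Segmentation

Internally worms are dark on a lighter agar; images with the opposite
polarity are inverted up front, making the two configurations exactly
symmetric. Illumination is flattened by estimating the large-scale
background inside the plate — a grey-value closing (window 9 px, wider
than a worm body, so worms do not bias the estimate) followed by a
Gaussian blur with σ = 0.06 × radius computed as a normalized
convolution over plate-interior pixels only — and subtracting it,
re-centered at 0.5. The nearest-neighbour extension of interior values
past the plate wall and the normalized convolution both exist to keep
the estimate unbiased at the wall, where a naive blur drags in
background intensity; without them the residual after flattening a
strong vignette is several times larger.

Foreground is an automatic Otsu threshold over plate-interior pixels (a
fixed threshold is available). Otsu always returns *some* split, so a
guard rejects segmentations whose two classes are separated by less than
`min_contrast` (0.1): a blank plate yields an empty mask and a warning,
not an exception or a mask full of noise.

Connected components (8-neighbourhood, so thin diagonal bodies stay
connected) are filtered by size: below 0.2× or above 50× the expected
single-worm area (`expected_worm_area_px`, default 120 px — the scale of
the rig the defaults model; rescale it with the imaging scale). The
ceiling keeps large clumps, which are deliberately never split. A
component is additionally removed as a spot-edge artifact when it is
both thin (perimeter²/area > 30) and hollow (filled area > 1.5× area):
a closed ring satisfies both, while a worm — equally thin at ~4·L/w —
is solid and fails the hollowness test. The ring filter can be disabled
(`--no-ring-filter`). Removed pixels are counted exactly, so
kept + filtered = thresholded in-plate foreground is an integer
identity.

## Synthetic plates

The generator renders the study conditions end to end: a bright plate
disk (peak 0.85) on a dark background (0.08) with a radial-quadratic
vignette (default strength 0.3), worm blobs drawn as thick random-walk
curves with ~13:1 aspect so shape-based filters are exercised, optional
tight clumps (several worms overlaid, kept as one connected object),
debris specks below worm size, and an optional ring artifact at a
test-spot position. Foreground sits 0.55 below the local plate
intensity, a 0.7 px Gaussian PSF blur and additive Gaussian noise
(σ = 0.01) finish the render. Defaults: 384–768 px images, plate radius
300 px at 768 (the benchmark suites use 150 px at 384), 60–120 px worms,
50 animals per plate split between the diagonal pairs by a random
preference — mirroring how a real population distributes between test
and control spots.

Blobs are placed by rejection sampling directly inside the target
region (quadrant wedge or center disk) with a 4 px clearance from all
region boundaries and a 2 px separation between objects; the blob shape
is redrawn every 100 failed attempts because a given random shape may be
too extended for the region even when the requested area fits, and a
bounded total number of attempts turns truly impossible requests into a
capacity error. Ground truth is read off the rendered masks, so
per-quadrant areas, center area and artifact pixels are exact integers
and the true CI is exact; ring and debris pixels share the artifact
bucket, which keeps the conservation identity (quadrants + center +
artifacts = total foreground) exact.

What the generator does **not** emulate: agar texture, condensation,
reflections other than the spot ring, partially out-of-frame plates,
tilted (elliptical) plates, or animals touching the plate wall. Passing
the benchmark therefore demonstrates correctness of the pipeline's
logic and its tolerance contracts under controlled optics, not
performance on arbitrary real rigs — on real images the free parameters
(polarity, expected worm area, margin and center fractions) must match
the rig.

## Validation statistics

Method agreement is an OLS fit of automated on manual CI; R² is reported
as 1 − SSE/SST (defined as 0 when the response is constant). The
strain-effect test fits `automated ~ manual + strain` with treatment
coding against a reference strain (lexicographically first unless
specified) and compares it with the manual-only model by an
extra-sum-of-squares F test with (k−1, n−k−1) degrees of freedom; the
implementation builds the design matrices explicitly and matches the
formula-API result to machine precision while being fast enough for
1000-replicate calibration. Under a correctly specified null the test's
type-I error is 5% by construction; the calibration simulation confirms
the implementation.

Broad-sense heritability uses the one-way random-effects decomposition
H² = σ²_strain/(σ²_strain + σ²_residual). The default estimator is
method-of-moments: σ̂²_strain = (MS_between − MS_within)/n₀ with the
standard n₀ for unbalanced group sizes, truncated at zero so H² ∈ [0,1].
A REML backend (random intercept per strain) is provided and agrees with
the moments estimator in expectation on balanced designs; the moments
default avoids iterative fitting and is exact in the balanced case. Both
require ≥2 strains with ≥2 replicates; a single strain is an error, not
H² = 1. The recovery simulation (11 strains × 9 replicates, both
variances 1) shows the truncation's small downward bias (≈0.47 mean at a
true 0.5), well inside the tolerance asserted.

## Numerical and design choices

- Benchmark problem sizes (384 px plates, 100/50/50-plate batches,
  1000 ANOVA replicates, 200 H² seeds) are chosen so the whole
  verification runs in well under a minute per section on one CPU while
  leaving the tolerance contracts meaningful.
- Determinism: a single seeded `numpy` generator per synthetic plate
  (the seed lives in the spec); the pipeline itself has no randomness,
  so fixed inputs give byte-identical result files.
- CI arithmetic is done in exact integers until the final division;
  antisymmetry under test-pair swap and invariance under integer area
  rescaling are exact, not approximate.
- Failure isolation: a batch run records an `NA` row for an unreadable
  or undetectable plate and exits nonzero, rather than aborting the
  batch.

## Known limitations

- One plate per image; no elliptical plate model for tilted cameras.
- Otsu segmentation assumes a roughly bimodal interior histogram; very
  sparse plates rely on the contrast guard to avoid noise masks.
- An open (gapped) spot ring degrades into arcs that can evade the
  hollowness test; the generator draws rings before worms so rendered
  rings are closed, and real gapped rings would need the size filters or
  manual review.
- The pixel-area proxy is blind to systematic size differences between
  quadrants (e.g. developmental heterogeneity co-varying with position).
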