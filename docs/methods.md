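# Methods

## Coordinate frame and data model

All geometry lives in a right-handed millimetre frame fixed to the scanner:
`z` along the couch / CBCT rotation axis (the slice-stacking axis), `y`
vertical up, `x` lateral. A `CTVolume` stores voxels as `(slice, row, col)`
with voxel centers at `mm(i,j,k) = origin + (k·sx, j·sy, i·sz)` in
`(x, y, z)`. Transversal planes (fixed `z`) are therefore ordinary CT
slices, the gel container lies along `z`, and the star-shot pattern lives in
a transversal slab. Beam angles use the machine convention: gantry 0 fires
straight down (`−y`), gantry 90 along `+x`, `d(g, c) = Ry(−c)·(sin g,
−cos g, 0)` with the couch rotating about the vertical axis; the collimator
angle only spins the slit about the beam axis and never moves the central
axis. Background and irradiated scans of the same session are assumed
exactly co-registered (same container, same couch position); no image
registration is performed, and a strict co-registration check (shape,
spacing, origin, frame token) guards every voxelwise combination.

## The phantom simulator

The simulator emulates what the analysis actually has to cope with in a
CBCT scan of a gel container in air, with exact ground truth:

* **Container**: gel cylinder (inner diameter 90 mm by default, 80 mm for
  the smaller container; ~20 HU) inside a 3 mm plastic wall (~120 HU),
  surrounded by air (−1000 HU).
* **Beam hardening**: a radial parabola added to the gel,
  `amp·(1 − (r/R)²)`, with the full amplitude (default −20 HU) on the
  container axis — the cupping a cylinder scanned in air shows. Optional
  concentric rings (`ring_amp_hu`, period 8 mm) model ring artifacts.
* **Noise**: i.i.d. white Gaussian HU noise per series. Mode realism comes
  solely from the Std presets per accelerator/algorithm/mode
  (`NOISE_PRESETS`, e.g. 1.555 HU for the TrueBeam iterative Pelvis mode,
  2.743 HU for its conventional reconstruction); no noise correlation or
  spatial texture is modelled.
* **Tracks**: each beam adds `dose_to_hu(dose) · box(s_n; gap/2) ·
  box(s_l; L/2)` inside the gel, where the boxes have erf-smoothed edges
  (penumbra σ = 0.5 mm — not a measured value; sub-voxel smoothness is
  needed for stable line fitting) and `(s_n, s_l)` are slit-normal and
  slit-length coordinates oriented by the gantry/couch/collimator angles.
  The star-shot slit (2 mm gap) extends 20 mm along the container axis; the
  3D pattern uses a 5 × 5 mm field, which gives a compact rod whose axis is
  well defined in space.
* **Dose response**: linear at `s` HU/Gy up to ~18 Gy, half slope to the
  ~40 Gy saturation, flat beyond — the linear-then-saturating behaviour of
  a polymerizing gel. The bend slope (s/2) and the absolute track amplitude
  are modelling choices: no absolute HU amplitude of an irradiated track is
  published for this gel/readout, so the default sensitivity is set to give
  a saturated track of ~+60 HU at 10,000 MU (with ~1 Gy per 100 MU). Only
  the relative amplitude matters for geometry; the post-irradiation signal
  growth of real gels is representable only as a user-set amplitude scale.
* **Fiducials**: three bright spheres (+500 HU, radius 1.5 mm) on the outer
  wall at 0/90/270° in the transversal plane z = −1 mm, emulating the
  copper-wire dot markers that image cleanly; streak artifacts of metal
  markers are *not* simulated (such markers are simply unsuitable).
* **Scatter**: each beam axis may miss the target by a seeded perpendicular
  offset uniform in [0, `beam_scatter_mm`]; the ground truth records the
  exact axes, the target (true isocenter), marker centers and the
  fiducial-derived reference point.

The simulator is a pure seeded function of its spec; same seed, same spec,
bitwise-identical volumes. It does **not** perform projection-domain CBCT
simulation (no Feldkamp reconstruction, no scatter/cupping beyond the
parabola, no streaks), so passing recovery tests demonstrate the analysis
chain's correctness and noise robustness, not robustness to every real CBCT
artifact.

## Preprocessing

Averaging is a voxelwise mean over co-registered series; background
subtraction is voxelwise. All kernels use reflect padding (no rim artifacts
inside the container) and work per transversal slice (2D) or volumetrically
(3D). Non-obvious filter definitions:

* **envelope** — midpoint of the grayscale morphological upper (dilation)
  and lower (erosion) envelopes with a square structuring element, iterated.
  The commercial filter of the same name is unpublished; this definition
  reproduces its parameter list (kernel, iterations, 2D mode, inner mean)
  and its smoothing-with-edge-respect behaviour, and is flagged as an
  approximation.
* **adaptive mean** — Lee-style local-variance shrinkage towards the local
  mean, with the noise variance either given or taken as the median local
  variance.
* **adaptive median** — the window grows (3, 5, …, kernel) until the local
  median is not an extreme, then the center pixel passes through unless it
  is itself an extreme.
* **fft_window** — per-slice frequency-domain multiplication by a separable
  named window centered at DC; 12 windows are provided (hann, hamming,
  blackman, nuttall, blackman-nuttall, blackman-harris, flat-top, bartlett,
  welch, cosine, tukey, rectangular).
* **savitzky_golay** — separable along the in-plane (or all three) axes,
  `interp` edge handling; exact on polynomials up to `polyorder` per axis.

Filtering, when used at all, should be symmetric: the linear filters
commute with subtraction (filter-both-then-subtract equals
subtract-then-filter to machine precision), and filtering only the
irradiated image leaves ring-like container residuals in the difference;
the pipeline logs a warning when asked to filter asymmetrically. The
default protocol applies no filter at all.

## QA metrics

Uniformity follows the installation-product-acceptance layout: five
cylindrical VOIs (center + left/top/right/bottom), `diff = peripheral −
center`, pass iff |diff| ≤ 30 HU, plus the mean of the four diffs per
series and its mean across series. The arithmetic is plain means over the
inputs; report display rounds to 2 decimals half away from zero, matching
printed QA reports. When the pipeline places the VOIs itself, peripherals
sit at 0.8 × module radius (configurable — the canonical offset is not
published), clamped so a VOI stays 2 mm inside the gel.

The scan scheduler encodes acquisition rules, not a thermal model: a
TrueBeam runs up to five consecutive scans with no gap; a Halcyon may run
only the first two back to back and then needs 5 min (Pelvis) or 6 min
(Pelvis Large) of tube cool-down before each further scan; more than five
scans is flagged as outside the validated range.

## Track detection

**2D (star shot).** Pixels above 5 × the robust noise Std (1.4826 × MAD)
are projected over an angle grid (0.25° steps, 0.5-voxel offset bins); a
track parallel to the projection rays concentrates into the sharpest,
tallest peak, so track angles are the most prominent local maxima of the
per-angle peak height (ties broken by prominence, then smaller angle; the
noise floor is median + 6 robust-Std of the angle metric). Each line is
then refined by three rounds of intensity-weighted orthogonal regression
(principal axis of the weighted pixel cloud) over a ribbon around the
current line — ±3 gaps first, then ±1.5 gaps so that neighbouring tracks
(30° away at closest in the four-beam pattern) cannot lean the fit — always
excluding a disk (max(8 mm, 3 gaps)) around the coarse crossing point where
all tracks overlap.

**3D (guided).** Candidate voxels above the same robust threshold are
assigned to the nearest planned axis through the coarse centroid; each
beam's axis is the intensity-weighted first principal axis of its cloud,
iterated with re-selection within 2 gaps of the current line until the axis
moves < 0.01 mm / 0.01°. Two details matter for accuracy: the crossing
region is excluded as in 2D, and 12 % of the rod length is trimmed off each
end before the principal-axis step — the rod ends are cut obliquely by the
gel wall or the volume boundary, and those sheared end faces would
otherwise bias the axis by a few tenths of a degree.

**Fiducials.** Markers are found in a ±5 mm slab around the nominal plane
as the intensity-weighted centroids of voxels standing out above the
container wall (peak must exceed the 99th body percentile by 50 HU —
otherwise "no markers" is reported rather than mistaking the wall for one),
within ±20° angular windows. The reference point is the foot of the
perpendicular from the 0° marker onto the 90°–270° chord — for a perfectly
placed set this is the container axis. The construction is a package
choice (the commercial definition is not algorithmically specified); an
explicitly configured reference point overrides it.

## Isocenter fits and numerical choices

The 2D min–max center is an exact linear program (HiGHS); optimality is
~1e−9 mm. The 3D min–max center minimizes the largest point-to-line
distance: an epigraph SLSQP solve seeded at the closed-form least-squares
center, polished by Nelder–Mead on the max-distance itself, keeping the
better of the two (≤ 1e−6 mm from optimal on non-degenerate bundles; the
test suite checks 200 constructed bundles against tangent constructions and
a grid + simplex oracle at 1e−4 mm). Parallel bundles raise a degenerate
geometry error in both dimensions. The "radius" reported is the min–max
(smallest touching circle/sphere) radius — standard star-shot semantics —
with the least-squares center reported alongside for transparency.

Offsets: the offset vector from the fiducial reference is always reported,
plus two scalars — the full distance and the in-plane (transversal)
distance. Whether a commercial "Offset" is the 3D or the in-plane reading
is not documented; keeping the vector makes either recoverable. Note that
markers sit in their own transversal plane (z = −1 mm by default), so the
3D offset includes the longitudinal distance between that plane and the
beam crossing.

Verdicts: radius ≤ 1 mm (star-shot tolerance per the linac-QA task-group
report) and offset ≤ 0.5 mm (vendor machine-performance-check style); both
tolerances are configurable.

## Validation strategy and problem sizes

Real scans cannot ship with the code, so validation is two-legged:

1. **Oracle equivalence** — the fits against closed forms (incircle,
   two skew lines), constructions (lines tangent to a known circle/sphere
   with surrounding normals, making the known center the unique optimum),
   and an independent grid + simplex search.
2. **End-to-end recovery** — the reference protocol (four 2 mm beams,
   gantry 0/90/150/240°, zero scatter, noise Std 1.555 HU, 3 + 3 series,
   mean of three, background subtracted) simulated on a
   112 × 112 × 32 grid at 1 × 1 × 2 mm, 20 seeds: the fitted center lands
   within 0.3 mm of the truth in ≥ 95 % of seeds and the radius stays far
   inside the 1 mm tolerance in all of them. The grid and seed counts are
   chosen so the whole suite runs in well under a minute while the central
   VOI still contains > 10³ voxels for noise statistics.

`scripts/acceptance.py` re-runs leg 2 from scratch and reports the largest
recovered radius over 20 seeded runs.

## Known limitations

* Voxel-domain simulation only; no projection-domain physics, metal
  streaks, scatter, or motion.
* The envelope and adaptive filters are principled reconstructions of
  commercial filters known only by name and parameter list.
* Only single-frame axial DICOM with identity orientation is read;
  enhanced multi-frame objects and oblique orientations are out of scope.
* Registration between background and irradiated scans is assumed exact;
  the tool detects geometric mismatch but does not correct it.
* Uniformity VOI placement reproduces the published arithmetic exactly,
  but the peripheral-VOI radial offset of the hardware phantom layout is a
  configurable default, not a published constant.
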