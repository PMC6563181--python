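# Methods

`sternomet` measures the two large sternal segments — the manubrium and the
sternal body (corpus sterni) — on 2D grayscale projection images, and uses
the resulting osteometry for sex estimation. This note describes the models
and procedures the package implements, the parameters that matter, and what
the synthetic validation does and does not demonstrate.

## Measurements and indices

Five standard osteometric variables, all in centimeters:

| name | definition |
|------|------------|
| M    | manubrium length: from the midpoint between the incisura jugularis and the incisurae claviculares down to the manubriosternal junction |
| MW   | manubrium width: chord at the level of the line through the left and right incisura costalis 1 midpoints |
| B    | sternal body length: manubriosternal junction to mesoxiphoid junction |
| CSW1 | body width at the level of the line through the incisurae costales 2/3 midpoints |
| CSW2 | body width at the level of the line through the incisurae costales 4/5 midpoints |

Three derived indices: sternal index `SI = 100·M/B`, combined length
`CL = M + B`, and sternal area `SA = (M+B)·(MW+CSW1+CSW2)/3` (cm²).

Because a single-bone image contains no between-bone joint, the
manubriosternal junction is operationalized as the inferior midline extreme
of the manubrium silhouette and the superior midline extreme of the body
silhouette; the configuration's confidence reflects this.

## Segmentation

Five deterministic stages recover a closed silhouette contour:

1. **Adaptive threshold on local areas.** A pixel is foreground iff its
   intensity exceeds the mean of a `window × window` neighbourhood
   (reflected boundaries) plus `offset`. The window (default 151 px) must
   be large relative to the bone so that interior neighbourhoods still see
   background; `offset` (default 80 intensity units) suppresses noise.
2. **Topological-potential border filtering.** Border pixels (foreground
   4-adjacent to background) receive a potential
   `p_i = Σ_j exp(−‖x_i−x_j‖²/2σ²)` over all border pixels (σ =
   `potential_scale`, default 2 px). Isolated speckle borders score low and
   are removed at `potential_threshold` (default 2.5, in units of weighted
   neighbour counts). The sum is computed exactly (pairwise) for border
   sets up to 6000 pixels and by a truncated separable convolution
   (radius 5σ, omitted tail < 4·10⁻⁶) beyond that.
3. **Structural connection modelling.** Open border chains are bridged
   greedily, nearest endpoint pair first, when the gap is ≤ `max_gap`
   (default 12 px) and the bridge direction is tangent-compatible with both
   ends (cosine ≥ 0.5). Each endpoint is used at most once; chains may
   close onto themselves; existing points are never moved.
4. **Contour reconstruction.** Chain components whose adjacency graph
   contains a cycle are closed loops: spurs are pruned and the cycle walked
   into an ordered polygon. Shoelace area, polygon centroid, perimeter,
   mean interior intensity, elongation (major/minor axis ratio) and
   solidity (area over convex-hull area) are attached.
5. **Classification.** A contour is accepted iff every feature lies inside
   configured bone-like bounds (area, interior intensity, elongation,
   solidity). Among accepted contours the largest area wins; ties fall to
   higher interior intensity, then the smaller centroid row.

## Landmark detection ("local extremes in sections")

The accepted contour is resampled to 1 px arc length, smoothed with a
circular moving average (`smooth_window`, default 5 samples), and offset
0.5 px along the outward normal in the automatic pipeline: a pixel-traced
border runs through the centers of the outermost foreground pixels, about
half a pixel inside the physical edge, and the offset removes that known
metrological bias. For exact polygon input the offset defaults to 0.

The anatomical frame is found by reflection symmetry: both bones are
bilaterally symmetric, so the midline is the axis (searched over
orientation, seeded at the principal axes; near-ties resolve to the major
axis) minimizing the area of the symmetric difference between the contour
and its reflection. Polarity along the midline uses shape cues that do not
depend on the sampled widths: the body tapers into an elongated point at
the xiphoid end (tip elongation is measured as the distance until the
profile reaches 70 % of the locally prevailing width), and the manubrium's
superior midline crossing is indented (jugular notch) while the inferior
one is convex.

Costal notches are local extrema of the lateral indentation profile −|s|
along each border arc (`scipy.signal.find_peaks`, prominence ≥ 1 px within
a 41-sample window; candidates inside the rounded end caps are rejected by
a width-level floor). Robustness against artifacts comes from anatomy:

* **Bilateral pairing** — genuine costal notches appear at matching
  midline levels on both sides; one-sided dents (border breaks) do not and
  are discarded.
* **Slot assignment** — the five notches are expected at roughly regular
  fractions of the shaft between the end caps; bilateral pairs fill their
  nearest slot, and an empty slot may be filled by a one-sided candidate
  mirrored across the midline at half confidence.
* **Dent-robust width chords** — a width section line is sampled together
  with parallel offsets (±3/6/9 px); each side's lateral extent is fit
  linearly against the offset with one-sided outlier rejection (dents only
  shorten a chord) and evaluated at offset zero. If the two half-widths
  still disagree by more than 2 px, the larger (intact) side wins — valid
  because the section origin lies on the symmetry midline.

Lengths are Euclidean landmark distances × pixel spacing (cm/px). The
pipeline measures at smoothing windows {5, 7, 9} and reduces the candidate
stack per measurement by 1-D single-linkage clustering (gap threshold 5 %
of the median), keeping the highest-confidence candidate of the most
populous cluster.

## Parameter training

`tune_parameters` exhaustively evaluates a grid of segmentation parameters
(default: offset ∈ {60, 80, 100} × potential threshold ∈ {2.0, 2.5} ×
window ∈ {121, 151}) on training images with known reference lengths.
Efficiency of a parameter set is the fraction of images whose every defined
measurement lands within a relative tolerance (default 5 %) of its
reference; the first argmax wins, making training deterministic.

## Sex estimation

Nine published discriminant functions (a three-variable function, five
single measurements, three indices) ship as a versioned JSON resource with
their sectioning points; a score above the point classifies as male, below
as female, exact equality as indeterminate (configurable). Refitting uses
the two-group Fisher rule: coefficients ∝ pooled-within-covariance⁻¹ ×
mean difference, scaled to unit pooled within-group score variance, the
constant centering the grand-mean score at zero, and the sectioning point
at the unweighted midpoint of the group mean scores (equal priors,
standard practice in osteometric work; a prior-weighted point is available).
Validation is leave-one-out (each record classified by a function fit on
the remaining n−1) or plain application of a fixed function. Sex
differences use the pooled-variance two-sample t test (Welch by flag).

## Agreement statistics

Per measurement, manual and automatic tables joined on subject id yield
signed differences (manual − automatic), the mean absolute distance (cm),
the percentage discrepancy = 100 × mean distance / mean automatic value
(the automatic mean is the documented denominator; a flag switches to the
manual mean), a two-sided paired t test (reported missing for fewer than
two pairs or zero difference variance), and an 11-bin equal-width
difference histogram spanning the observed range, so bin widths differ
between measurements.

## Synthetic phantoms

The phantom generator is the package's ground-truth instrument.

**Population model.** Subjects are drawn from a sex-structured
multivariate normal. Pooled means and SDs default to the reference
measurement table (M 5.23 ± 0.53, MW 5.63 ± 0.53, B 9.46 ± 1.44,
CSW1 2.65 ± 0.36, CSW2 3.12 ± 0.56 cm; 73 men, 55 women). Sex separation
per measurement is parameterized as a Mahalanobis distance d chosen so a
midpoint-threshold classifier on that single variable reproduces its
published classification rate (d = 2·Φ⁻¹(rate), e.g. d ≈ 1.89 for B at
82.8 %); the pooled moments are preserved exactly by construction. The
within-sex covariance is equicorrelated (ρ = 0.5 by default).

**Shape model.** Outlines are smooth parametric curves: shape-preserving
cubic (PCHIP) width profiles with notch bumps. The body is an elongated
blade with a blunt superior cap, an elongated inferior taper (the polarity
cue), and five flat-topped costal notches (depth 0.20 cm, half-width
0.28 cm) at fixed fractions (0.09…0.88) of the shaft; its widths at the
notch-midpoint levels equal the requested CSW1/CSW2 exactly. The manubrium
is a broad superiorly-widest plate with a jugular notch (0.55 cm deep), two
clavicular notches (0.30 cm) and one deep Gaussian costal notch per side
(0.30 cm) whose floors are separated by exactly MW. Every landmark pair
reproduces its requested length to 10⁻⁶ cm by construction. Rendering uses
3× supersampled coverage, a bright cortical rim (+250 over a 1000/100
foreground/background), and seeded interior speckle (SD 25), written as
16-bit TIFF with a JSON truth sidecar. The default pixel spacing is
0.05 cm/px.

**Corruption model** (defaults, chosen once as moderate CT-projection
artifact levels): additive Gaussian noise SD 25, a linear illumination
gradient of amplitude 60 in a random direction, three bright distractor
blobs (radius 4–9 px) placed off the bone, and two border breaks — 10 px
arcs of the outline erased to background intensity with a 2 px radius,
the failure mode that degrades real low-quality projections.

**What passing tests show — and what they do not.** The phantoms exercise
every pipeline stage with exactly known truth, including notch loss,
border erosion and distractor rejection. They are still idealized:
bilaterally symmetric smooth outlines, a single bone per image, ideal
en-face projection, no xiphoid process, no osteophytes or degenerative
remodelling, no partial-volume texture. Discrepancy figures obtained on
phantoms therefore characterize the algorithmic measurement chain, not
performance on clinical material.

## Numerical choices and degenerate inputs

Segmentation is fully deterministic given image and parameters; all
randomness (population sampling, rendering speckle, corruption) is seeded.
Equal-area contour ties break by interior intensity then centroid row.
Fully symmetric shapes (e.g. rectangles) resolve their midline to the
principal axis. A zero-width difference range in the histogram is widened
by a machine-epsilon margin. Degenerate two-group fits (no separating
direction) warn and return near-zero coefficients; singular pooled
covariance raises. Strict landmark detection raises with the list of
missing landmarks; `strict=False` returns a partial configuration (used
for simple geometric inputs that carry no notches).

## Validation experiment sizes

`scripts/acceptance.py` measures a 126-image batch (63 bodies, 63
manubria) for the discrepancy figures and trains on 35 body images for the
efficiency figure — the batch sizes at which the reference workflow is
quoted — and completes in a few minutes on one CPU. Larger sweeps ran
during development only.

## Known limitations

* The notch-slot prior assumes five roughly evenly spaced costal notches;
  strongly pathological spacing would need a per-population recalibration.
* Widths are chords of the silhouette; cortical-versus-trabecular edge
  definitions (windowing effects in real CT) are not modelled.
* The discrepancy denominator follows the documented convention
  (automatic mean); comparisons against literature using the manual mean
  should set `denominator="manual"`.
* Sex classification is binary with a hard sectioning point; no posterior
  probabilities are produced.
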