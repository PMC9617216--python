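# Methods

## Problem setting

Large-scale color-pattern analysis needs every photograph masked: specimen
pixels separated from the background mat and calibration objects. For
limbless, elongate organisms photographed in coiled postures, landmark-based
masking is slow and hard to automate, so the package treats masking as tiled
per-pixel segmentation with a trainable backend, followed by deterministic
post-processing, calibration, and a pattern-energy validation analysis.

Conventions used everywhere: x = column, y = row, origin at the top-left,
0-based, pixel centers at half-integer coordinates; masks are boolean rasters
with 1 = specimen. TPS files written with a bottom-left origin are flipped at
read time (`tps_origin` flag; flipping needs the image height).

## Polygon rasterization and tracing

A polygon fills a pixel iff the pixel's center lies inside under the even-odd
(crossing-number) rule. This choice is deterministic, orientation-independent
and directly checkable against a brute-force point-in-polygon loop, which the
tests do. Out-of-bounds vertices are clamped to the image boundary rather
than rejected, because hand landmarks routinely overshoot edges. Mask-to-
polygon tracing walks the 0.5-level contour of each 8-connected component;
one outer contour per component, so interior holes are filled — a limitation,
not a bug: the label format deliberately excludes polygons-with-holes. The
round trip polygon → mask → polygon is exact on interior pixels and may
disagree only on boundary pixels.

## Tiling and stitching

Training samples are drawn "photograph first, then tile": one uniform random
photograph, then one uniform random tile position inside it. This
over-represents small photographs relative to area-uniform sampling; it is
kept because it is the natural protocol when photographs are the unit of
curation, and it is documented rather than corrected. The fixed validation
set samples `tiles_per_photo` (default 32) tiles per validation photograph
using a per-photo seed derived from (seed, photo id) by CRC, so adding
photographs never moves existing tiles. Validation tiles may overlap each
other; training and validation tiles never share a photograph.

Inference grids start at 0 with stride `tile − overlap` per axis and append a
final start clamped to `dim − tile` when a strip would otherwise be
uncovered; duplicates are removed. Defaults are 512 px tiles with 100 px
overlap; desk-scale runs use 128/32 on 256×256 scenes. Stitching averages
all tile probabilities covering a pixel and thresholds at 0.5 with ties to
foreground — a symmetric, order-independent merge. Where all covering tiles
agree the stitched value is set to the agreed value exactly (bypassing the
float division) so agreement is conserved bit-for-bit.

## Loss, epochs, and checkpoint selection

The reported metric is pixel recall against the label,
`|mask ∧ label| / |label|`, and its complement as "loss". False positives do
not move it, by construction — they are handled by post-processing. Because
an empty prediction is likewise unpunished, recall cannot be the training
gradient; the reference backend trains a standard per-pixel logistic loss and
uses recall only for reporting and epoch selection. Validation evaluation
never updates state; validation tiles with empty labels carry no recall
information and are skipped (with a warning). The per-epoch validation score
is the *soft* recall complement — the mean predicted probability over label
pixels — rather than recall of the thresholded mask: the two agree at
convergence, but the thresholded score saturates to exactly zero on easy
validation pools, and a saturated score gives argmin selection no way to find
the plateau onset (it would deploy the first, least-trained checkpoint). Non-finite training loss aborts
with a suggestion to lower the learning rate. Checkpoints are
content-addressed files written after every epoch and never deleted;
selection returns the earliest epoch achieving the minimum validation loss
(plateau onset — later epochs tend to overfit).

`TrainingConfig` defaults (learning rate 1e-4, 450 training and 50 validation
steps per epoch, 20 epochs, 512 px tiles) describe a full-scale run with a
heavyweight backend. The number of validation steps is exposed as a free
parameter rather than being tied to the validation-set size; the two
conventions circulating for this quantity contradict each other, and tying it
would forbid the common case of spot-checking on a subset.

## Reference backend

A logistic per-pixel classifier over a 25-dimensional local feature stack:
raw RGB; normalized chromaticity (each channel divided by the pixel's channel
sum), raw and Gaussian-smoothed at σ=4, plus the squares of the smoothed
chromaticity; Gaussian-smoothed RGB and local SD (texture) at σ=2 and σ=8;
and a bias. Chromaticity is the load-bearing part: it is
brightness-invariant, so a dark body band and a dark mat that are nearly
indistinguishable in intensity separate cleanly by hue, and without it
inferred bodies fragment at dark bands. The σ=8 color means carry body color
across band interiors.

Updates are plain SGD on class-balanced minibatches (2048 pixels, half
foreground where available, L2 1e-5). With bounded features and logistic
gradients of order 0.1, a unit learning rate is the natural step size; the
desk-scale preset uses lr = 1.0 with 120 steps × 10 epochs. The per-step
reported loss is the recall complement on the tile just fitted (or the
false-positive rate when the tile contains no specimen). Training, given the
creation seed and the sampled tile sequence, is exactly reproducible; state
save/load is a flat weight vector in an `.npz`.

`lowres_mask_upsample` bilinearly maps a coarse mask head (e.g. 28×28) onto a
tile, the adapter step needed when an external instance-segmentation model is
plugged into the backend contract in place of the reference model.

## Post-processing and preblur

Largest-component cleanup uses 8-connectivity (diagonal coil contacts must
not fragment a body) and pixel counts as the size measure; equal sizes break
deterministically toward the smallest row-major coordinate. It never adds
pixels, so it can only lower recall if the body itself fragments — with the
trained reference backend on the synthetic scenes it never does. Hole
filling, smoothing and active contours are deliberately out of scope.

The preblur is a separable discrete Gaussian with an explicit odd kernel
width k (default 5) and σ = 0.3·((k−1)/2 − 1) + 0.8, mirrored borders — the
kernel convention of common image libraries, reproduced explicitly so the
kernel is inspectable and `k = 1` is the exact identity.

## Gray-standard detection and scale

Candidate circles come from a Circle Hough Transform over Canny edges
computed per color channel and OR-ed — an achromatic disk on a colored mat
can vanish in the luminance mean while contrasting strongly in one channel.
Candidates are screened lexicographically: achromaticity (mean absolute
inter-channel difference inside the disk, rim excluded) and uniformity
(intensity SD) must both fall below thresholds (0.08 each), then the highest
Hough accumulator wins. The screening exists because color-checker patches
and coil arcs also generate strong circular edges. No candidate passing the
screen raises an error carrying all candidate diagnostics. The standard's
physical diameter is a required configuration value with no default — it
depends on the standard in use and must not be guessed.

## Pattern energy

For pattern size *s* the band filter is a difference of Gaussians with
σ = (s/2π, s/π). This tuning makes the filter's peak response sit at spatial
wavelength *s* exactly — a sinusoid of period 32 px has its energy argmax at
size 32 — which is the property that makes "energy at size s" interpretable.
(The superficially natural choice σ = (s/2, s) peaks near wavelength 3.3·s
and would mislabel the bands.) Sizes default to powers of two from 2 px to
the largest power ≤ min(image dims)/2. Filtering runs on the full image with
reflected borders and 6σ-truncated kernels; the mask is applied only when
the SD is taken, avoiding the edge artifacts that masking before filtering
would create. Energy is therefore exactly invariant to constant offsets and
exactly linear in contrast. A frequency-domain implementation of the same
sampled kernels serves as an independent oracle in the tests, never as the
production path.

Residual comparisons subtract per-photo spectra (set A − set B) and report
mean ± SD across photographs per channel and size; a single photograph yields
SD 0 with `sd_defined=False`. The paired t-test summarizes each photo and
channel by the energy summed over sizes (the scalar is a choice; a per-size
battery is available from the same spectra). Identical inputs yield t = 0,
p = 1 by convention; one pair (df = 0) is an error.

## Synthetic scenes

The generator emulates the stated variability of field photographs of coiled
organisms: an Archimedean spiral r(θ) = a + bθ sampled uniformly by arc
length (0.5 px steps), swept by a linearly tapering thickness profile
(head 10–18 px at 256×256, tail 30–50 % of head); banded, blotched or plain
coloration drawn against the *local arc position* so bands run perpendicular
to the body, not to the image axes; warm or green body hues on a blue (70 %)
or near-black (30 %) mat; a gray disk standard (radius 12–20 px, gray
0.35–0.5) placed in the corner farthest from the coil; a multiplicative
linear lighting gradient (amplitude up to 0.12); background texture and
sensor noise (SD 0.01 / 0.008). The specimen mask is the exact swept region
(union of disks along the dense centerline, z-buffered so each pixel knows
its nearest arc position). Scenes are deterministic per spec+seed, and a
manifest CSV storing each scene's full spec reproduces files byte-for-byte.

What the generator does **not** emulate: scale texture, specular highlights,
cast shadows, interreflections, out-of-plane anatomy, and the full color
gamut of real mats and animals. Tests passing on these scenes demonstrate
that the pipeline's machinery is correct and that the training loop can
recover a known signal; they do not certify accuracy on real photographs,
which depends on the backend and training data used.

Hue/brightness augmentation rotates hue (mod 1) and scales brightness
multiplicatively within configured jitter bounds, leaving masks untouched —
the standard remedy when training-set diversity cannot be expanded with more
photographs.

## Desk-scale experiment sizes

The end-to-end parameter-recovery experiment trains the reference backend on
20 synthetic 256×256 scenes (split 18/2 into training/validation pools,
32 validation tiles per photo, tile 128, overlap 32, lr 1.0, 120 training +
60 validation steps × 10 epochs) and infers 5 held-out scenes, repeated for
3 seeds; the replay check runs a 4+2-scene pipeline twice and compares masks
and CSVs byte-wise. These sizes were chosen so the full suite runs in a few
minutes on one CPU while still exercising every stage at realistic geometry.

## Known limitations

- The recall-only metric says nothing about false positives; qualitative QC
  (overlay contact sheets) or a precision metric is needed when backgrounds
  matter.
- One outer contour per component: ring-shaped masks lose their holes on
  polygon export.
- The reference backend is per-pixel and local; it has no notion of object
  instances and will not separate touching specimens.
- Gray-standard detection assumes exactly one achromatic circle in the
  radius range; two standards in frame would return only the stronger one.
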