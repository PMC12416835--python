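# Methods

## The model

`distseg` frames whole-cell instance segmentation as regression of a
**per-cell normalized Euclidean distance map**.  For a label mask with
cells c and pixels p,

    raw(p)   = Euclidean distance from p to the nearest pixel center not
               belonging to p's cell (background, another cell, or outside
               the image frame),
    value(p) = raw(p) / max_{q in c} raw(q),        value = 0 on background.

Each cell's interior therefore peaks at exactly 1 regardless of its size,
and two touching cells produce a valley of low values along their shared
boundary — the signal the watershed later uses to separate them.  A
boundary-adjacent cell pixel has raw distance 1 (the standard discrete EDT
convention, pixel-center metric; exact Euclidean, not a chamfer
approximation).  Distances are computed per label with `scipy`'s exact
EDT on padded bounding boxes; an O(N²) brute-force nearest-different-label
search serves as the independent test oracle.

Predicting a continuous field instead of discrete classes is what lets the
pipeline keep clumped cells apart when their shared edge has almost no
contrast: the class boundary may be invisible, but the two interior peaks
are not.

## Inference pipeline

1. **CLAHE** (contrast-limited adaptive histogram equalization): min–max
   scale to [0, 255], 8×8 tile grid, 256-bin per-tile histograms clipped at
   `clip_limit · tile_pixels / 256` (default clip 2.0) with the excess
   redistributed uniformly, per-tile CDF transfer functions blended
   bilinearly between tile centers.  Removes field-level illumination
   gradients and lifts weak edges.  Constant images pass through unchanged.
2. **Z-normalization** per image (zero mean, unit variance; constant images
   map to zero).
3. **Overlapped sliding windows**: 256×256 windows with a 32-px disposable
   margin per side, i.e. stride 192.  The image is reflect-padded by the
   margin (mirror without edge duplication, so no artificial dark rims);
   window anchors sit at multiples of the stride with the last window
   clamped to the padded edge.  Each window's *core* (its central block, at
   least the margin away from every window edge except at padded-image
   borders) is stitched back; the cores partition the padded image, so
   every output pixel comes from exactly one window, away from any window
   edge where context is truncated.  Stitching is hard cropping, not
   blending — output is independent of visitation order and
   bit-reproducible, and with a translation-equivariant predictor tiled
   inference is exactly equal to whole-image application (a test asserts
   this with a 3×3-convolution oracle).
4. **Backbone**: any function mapping a preprocessed 256×256 patch to a
   256×256 map in [0, 1] (sigmoid head).
5. **Post-processing**: dual thresholds and marker-controlled watershed
   (below).

## Post-processing

Two strict (">") thresholds on the predicted map: the *cell fill
threshold* (default 0.09) defines cell-vs-background; the *cell peak
threshold* (default 0.47) defines the cell-center markers (8-connected
components, components under `min_peak_area` = 16 px discarded as
speckle).  A marker-controlled watershed floods from the markers over
elevation −dmap, restricted to the fill mask; boundaries form where floods
meet, i.e. along the valley between touching cells.  Fill-mask pixels
unreachable from any marker stay background.  The default thresholds are
the published ablation optimum across evaluation datasets and are exposed
as configuration and CLI flags.

Two behaviors worth knowing about:

* With fill threshold 0.09, a cell whose maximum interior distance m
  exceeds ≈11 px has its outermost 1-px ring below threshold
  (raw 1 / m < 0.09), so very large cells are recovered minus a thin
  boundary ring.  This is a property of the published defaults, not of the
  implementation; lower the fill threshold for low-magnification images.
* Marker count is monotone (non-increasing) in the peak threshold only for
  isolated convex cells, whose superlevel sets are nested and connected.
  Between touching cells a saddle above the lower threshold merges two
  peaks into one component, so the global claim is false; the property is
  tested in the regime where it holds.
* A dividing, peanut-shaped cell carries two peaks and is deliberately
  segmented as two cells.

## Evaluation metrics

SEG: each reference cell R is matched to the predicted cell S with
|R∩S| > 0.5·|R| (unique by disjointness), scored by Jaccard |R∩S|/|R∪S|
(0 if unmatched), averaged over reference cells.  DET: the detection
graph-edit measure with the canonical weights — false negative 10, false
positive 1, split 5:

    AOGM-D  = 10·FN + 1·FP + 5·NS,     AOGM-D0 = 10·n_ref
    DET     = 1 − min(AOGM-D, AOGM-D0) / AOGM-D0

where predictions claim the reference cells they majority-cover, FN are
unclaimed references, FP are predictions claiming nothing, and a
prediction claiming k ≥ 2 references needs k−1 splits.  A Dijkstra search
over explicit edit sequences (delete / split / add) in the test suite
confirms the closed-form count is the true minimum on small instances.
OP_CSB = 0.5·(SEG + DET).  When both masks are empty, SEG = DET = 1
(perfect agreement always scores 1); an empty prediction against a
non-empty reference scores 0.  Culture metrics (cell count, mean area,
confluency, neighbor counts with a 2-px dilation adjacency) summarize a
mask without a reference.

## Training protocol

AdamW (β₁ = 0.9, β₂ = 0.999, decoupled weight decay 0.1, biases undecayed),
L2 loss on the distance map, batch size 8.  Learning rate: linear warm-up
to `lr_init` over `warmup_iters` iterations, then linear decay to zero
over a fixed horizon of `max_epochs × ceil(n_train/batch)` iterations
(early stopping truncates the schedule; it does not reshape it).  Each
epoch draws exactly one augmented 256×256 patch per training image.
Early stopping watches validation loss (90/10 seeded split) with patience
7 and minimum improvement 1e-4, never stopping before `min_epochs`; the
parameter snapshot with the lowest validation loss is returned.  Training
is bitwise reproducible from (seed, config, dataset) on a fixed platform.

The `TrainConfig` defaults (lr 1e-4, warm-up 250, 35–100 epochs) mirror
the published fine-tuning protocol for a large pretrained encoder.  The
desk-scale recovery runs in the test suite instead use lr 1e-3 with a
10-iteration warm-up and ~16 epochs: a 28k-parameter network trained from
scratch for ~80 steps needs a higher rate than a ViT being fine-tuned for
thousands.

### Augmentation

Mirror (p = 0.5), rotation U[−180°, 180°], rescale U[0.8, 1.2], brightness
U[0.95, 1.05], inversion (p = 0.5; x → max − x on the raw intensity scale,
making the model agnostic to bright-on-dark vs dark-on-bright polarity).
Only the geometric transforms touch the distance-map target (bilinear,
re-clipped to [0, 1]; fill value 0 = background, while the image uses
reflect continuation).  Per-cell normalization makes the target
scale-invariant up to interpolation error, so targets are precomputed once
and never renormalized after rescaling.  Operation order (the protocol
leaves it open): geometric → brightness → inversion → CLAHE → z-norm,
keeping CLAHE's nonlinearity downstream of the photometric jitter so the
jitter is not undone by normalization.

## Reference backbone

A numpy convolutional encoder–decoder: three 2× average-pool stages
(8/16/32 channels), a 32-channel bottleneck, three nearest-upsample stages
with encoder skips, 1×1 sigmoid head; leaky-ReLU activations (slope 0.05)
and the head bias initialized at −2 so the initial output sits near the
background-dominated target prior — without both, the L2 objective on
~80%-background targets collapses the net into a dead constant within a
few dozen iterations.  ~28k parameters; forward and backward passes are
hand-written (channels-last im2col + GEMM), fully deterministic, and train
on one CPU core in minutes.  The backbone is deliberately a contract: a
SAM-style encoder/decoder (patch upsampled 256→1024, frozen default
prompt, trainable image encoder + mask decoder) plugs into the same
interface via `sam_adapter` when its optional dependencies (torch,
segment_anything, local weights) are present.

## Synthetic data

The generator emulates the structure the method targets, with exact
ground-truth masks: sequential rejection placement of ellipses (round) or
radially-perturbed ellipses (irregular); non-clumped cells keep ≥ 2 px
separation, while a configurable fraction is forced into 1-px contact with
an existing cell (a candidate walks inward along a random direction until
it first touches the 1-px grown occupancy, never overlapping).  Images
render each cell as an intensity plateau shaded by its true distance field
(bright centers fading to the boundary), Gaussian-blurred edges, a linear
illumination gradient, optional polarity flip, and Gaussian noise.  Two
profiles: `round_easy` (round cells, semi-axes 6–12 px, 250 cells per
512² frame ≈ 20% confluency, 10% clumped, crisp edges) and `clumped_hard`
(irregular, semi-axes 8–24 px, 120 cells ≈ 23% confluency, 60% clumped,
soft edges, stronger noise/gradient) — the easy-circular vs
dense-irregular regimes cultured cell lines actually present.

What the generator does *not* emulate: phase-contrast optics (halos,
shade-off), out-of-focus debris, annotation noise, and cell-type texture.
Passing the end-to-end recovery test therefore shows the pipeline's
machinery (targets, tiling, training, watershed, metrics) is correct and
learnable end-to-end — not that the reference backbone would rival a
fine-tuned foundation model on real micrographs.  Because the rendered
intensity is tied to the true distance field, the regression is
well-posed by construction; real data is harder in exactly the ways the
published fine-tuned encoder is meant to absorb.

## Numerical choices and degenerate inputs

* Thresholds are strict inequalities; watershed ties resolve by the
  deterministic flood-queue order, so repeated runs are bit-identical.
* Empty masks are legal everywhere: empty → empty round trips, SEG/DET
  vacuous conventions as above, mean cell area of an empty mask reported
  as 0.
* Constant images: CLAHE returns a constant, z-norm returns zeros (flagged
  at the caller's log level), segmentation returns an empty mask.
* Bilinear resampling uses the corner-aligned-off convention (output pixel
  i samples input (i+0.5)·n_in/n_out − 0.5, edge-clamped); linear ramps are
  reproduced exactly away from the half-pixel border.
* Label masks are written 16-bit when the maximum label fits, 32-bit TIFF
  otherwise; distance-map targets are cached as float32 TIFF keyed by mask
  content hash.
* RGB inputs are reduced by an unweighted channel mean (microscopy
  channels are not photometric RGB), making the reduction idempotent and
  exact on replicated-channel files.

## Problem sizes in the shipped tests

The suite verifies the distance transform against brute force on 200
random masks ≤ 32², the detection measure against exhaustive edit search
on 100 instances ≤ 5×5 cells, the watershed round trip on 50 easy-profile
masks of 20–40 cells, stitching equivalence on 10 image sizes including a
full 704×520 microscope frame, and one seeded end-to-end run (40 training
/ 10 held-out 512² images, ~16 epochs) that must reach mean OP_CSB ≥ 0.80
and beat the untrained backbone by ≥ 0.25.  These sizes are chosen so the
whole suite runs on a single CPU core in well under half an hour.
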