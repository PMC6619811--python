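# Methods

`planktonseg` implements an automated identification and enumeration
pipeline for dark-field in situ plankton imagery.  The pipeline has four
computational stages — adaptive ROI extraction, ROI feature enhancement,
rarity-aware dataset augmentation, and one-vs-one SVM classification over
pluggable features — plus a seeded synthetic-scene generator that provides
ground truth for every stage.  This note records the models, the parameter
choices, and the places where the design was genuinely open.

## Contrast statistic and branch routing

In situ frames span a wide contrast range: clear frames with bright, sharp
targets, and murky frames where targets barely rise above the noise floor.
Each frame is scored with

    MSNR = max_i ((M − x_i) / I_max)²

where `M` is the frame mean, `x_i` ranges over pixels and `I_max` is the
maximum representable intensity (255 for 8-bit).  Frames with `MSNR ≤ 0.1`
route to the local-threshold (Sauvola) branch; frames strictly above route
to MSER.  Normalizing by `I_max` makes the statistic unit-scaled so the
fixed 0.1 threshold is meaningful across bit depths; a switch
(`normalize_by_observed_max`) normalizes by the maximum observed pixel
instead, for users who prefer a frame-relative statistic.  Ties go to the
Sauvola branch.

## Sliding-window Sauvola binarization

Low-contrast frames are binarized pixel by pixel.  Every pixel centers its
own window of side `round(window_frac · min(H, W))`, forced odd with a
floor of 3 (`window_frac ∈ [0.01, 0.03]`, default 0.02); the window's local
threshold is

    T = m · (1 + k · (σ/R − 1))

with window mean `m`, population standard deviation `σ`, `k = 0.34` and
`R = 128` (the largest standard deviation an 8-bit grayscale window can
attain).  In flat regions `T ≈ 0.66·m`; where local contrast is high `σ`
approaches `R` and `T` approaches `m`.  The default polarity marks pixels
*strictly above* their threshold as foreground (bright organisms on a dark
field); classical document polarity (dark foreground) is available by flag.

Numerical choices: windows are clipped at frame edges and statistics taken
over the intersection, avoiding reflective-padding artifacts in dark noisy
borders.  Window sums use integral images in float64, which are exact for
integer 8-bit intensities, so the vectorized implementation is bit-exact
against a per-pixel brute-force evaluation (asserted in tests).  An
optional stride > 1 reuses thresholds on a subsampled grid as an
acceleration; the default stride of 1 is the definition.

A consequence of this thresholding worth stating plainly: with bright
polarity, any *smooth positive* background sits above `0.66·m` of its own
neighborhood and binarizes to foreground.  The method is therefore
selective only on heavy-dark frames whose background is mostly at or near
zero — exactly the regime of dark-field in situ imagery — and the synthetic
generator (below) reproduces that regime by construction.

## MSER branch

High-contrast frames are segmented with maximally stable extremal regions,
computed here on the max-tree (component tree) of the frame.  For a
component whose canonical level is `l`, stability is the relative area
growth `(|C_{l−Δ}| − |C_l|) / |C_l|`, where `C_{l−Δ}` is the connected
component of `pixels ≥ l−Δ` containing it (its tree ancestor).  Components
within area bounds (`min_area = 25` px, `max_area_frac = 0.25`) whose
variation is at most `max_variation = 0.5` at `Δ = 5` are selected; nested
selections whose relative area difference is below `min_diversity = 0.2`
are deduplicated keeping the more stable.  Tests verify each returned
region equals a per-level threshold component and that its variation
matches a from-scratch recomputation.  The Δ/area/variation values are
exposed configuration, not claims about any particular instrument.

## Breakpoint-connection denoising ("edge roughening")

Binarized low-contrast frames contain broken target outlines and surviving
speckle.  Every pixel is re-decided from a small centered window (side 1–3%
of the mask dimension, default 2%, floor 3×3).  With `N_rect` the window
pixel count and `N_valid` its foreground count, the pixel becomes
foreground iff

1. `N_valid ≥ T_value`, where `T_value = floor(√(2·⌊√N_rect⌋²)) − 2` — the
   window's diagonal length minus 2.  A genuine boundary crossing the
   window contributes at least a diagonal's worth of pixels, so anything
   sparser is noise.
2. the foreground is clustered rather than scattered: the largest
   8-connected cluster within the centered window, or within the union of
   the centered window and any one of its four side-adjacent windows,
   holds at least `0.75 · N_valid` pixels.  The adjacent-window unions let
   a boundary that exits the window still count as one cluster.

The rule removes isolated speckle (condition 1), removes scattered noise
patches (condition 2), and thickens genuine boundaries: background pixels
adjacent to a line satisfy both conditions and turn foreground, which
reconnects breakpoints.  Border handling: `T_value` comes from the nominal
window size (it is a property of the chosen window), while `N_valid` is
counted over the border-clipped window.  The vectorized fast path
(box-sum prefilter, cluster labeling only at candidate pixels) is asserted
bit-exact against a literal per-pixel flood-fill oracle.

The printed form of the threshold formula in its source is typographically
ambiguous (lost radicals); the diagonal-minus-2 reading adopted here is the
one consistent with the stated diagonal rationale, and the formula is
isolated in `valid_pixel_threshold` so an alternative can be swapped in.

## Background suppression

With the target mask fixed, the nonzero background intensities `p` of a
crop define the boundary threshold

    T_b = p_min + (p_max − p_min)/δ,   δ ∈ [3, 4]

and each nonzero background pixel is remapped by

    p′ = p + 5 · (p − T_b) · (δ − 3)

then rounded half-up and clamped to `[0, I_max]`.  Background below `T_b`
darkens (usually to 0), background above brightens; target pixels and
exact-zero background are untouched (zeros mark masked-out target locations
and carry no radiometric meaning).  The transform is the identity at
`δ = 3`, fixes `p = T_b`, and is monotone increasing in `p` for `δ ≥ 3`;
the default working point is `δ = 3.7`.  Enhancement is intended for
training-set crops; test crops are evaluated raw.

## Augmentation

Rare classes are expanded with geometric recipes whose length grows with
rarity: euphausiids get 90° CW and 180° rotations plus an up/down mirror
(3 variants per ROI); chaetognatha and medusae add a left/right mirror (4);
fish larvae further add a widened-dynamic-range variant (5), implemented as
a linear rescale of the crop onto the full `[0, I_max]` range.  Rotations
of non-square crops swap dimensions; crops stay tight.  All geometric ops
are intensity-preserving pixel permutations (asserted by histogram
equality).

A second expansion re-renders each training crop at five contrast levels
δ ∈ {3.1, 3.3, 3.5, 3.7, 3.9} using the background-suppression transform —
the same δ that controls enhancement doubles as the contrast-level knob —
so 2048 training crops per class become 10,240.  Recipes are applied
before levels and both tags are recorded.  `build_training_set` partitions
*base* ROIs into train/test pools first, expands only the train pool, and
subsamples with a seeded generator to exact per-class targets, so no
augmented descendant of a test ROI ever reaches training.

## Classification

Features are pluggable: any callable mapping a crop to a fixed-length
vector registers as an extractor (CNN embeddings plug in this way; the
conventional canonical input for such backends is a 224×224 square, and no
weights ship with the package).  The shipped baseline is HOG (9
orientations, 8×8 cells, 2×2 blocks, L2-Hys) on crops resized to a 64×64
canonical square — at the baseline's descriptor density, 64 px retains the
shape information the synthetic families carry while keeping the
descriptor at 1764 dimensions.

The classifier is one-vs-one: one binary linear max-margin classifier
`f(X) = WᵀX + b` per unordered class pair, `k(k−1)/2` in total (21 for
k = 7).  Each pair's decision values get a Platt-style sigmoid calibration
fitted on the pair's training samples.  A class's score for a query is the
sum of calibrated pairwise probabilities it receives across its `k−1`
pairs (scores over all classes sum to the pair count); prediction is the
argmax, with exact ties broken toward the lexicographically smaller label.
A majority-vote aggregation can be obtained by thresholding the pairwise
probabilities at 0.5 before summing; the probability sum is the default
because it preserves margin information.  The soft-margin constant defaults
to `C = 1`.  Binary fits and calibrations use scikit-learn primitives
(`LinearSVC`, `LogisticRegression`) with seeded state, so training is
deterministic.  Evaluation reports per-class precision `TP/(TP+FP)`,
recall `TP/(TP+FN)`, macro averages, and the full confusion matrix whose
row sums conserve test counts; a replicate helper averages macro metrics
over reseeded training runs.

## Synthetic scenes and crops

The generator emulates the dark-field regime: background pixels are 0 with
probability ~0.95, low-amplitude noise (values 1–2 at density 0.05)
elsewhere, sparse particulate speckle (density 10⁻³, intensity ~35), and a
multiplicative linear or radial illumination field (±10%) acting on the
signal.  An optional additive background glow exists but defaults to 0 —
see the Sauvola note above for why a smooth positive background is
incompatible with bright-polarity local thresholding.  Seven parametric
shape families map onto the class scheme (fat ellipse → copepoda,
elongated ellipse → euphausiids, dome-plus-tentacles → medusae, thin rod →
chaetognatha, curved rod with head → fish larvae, spiral → limacina,
irregular blob → other), rendered with ±0.3–0.4 rad orientation jitter,
size jitter, and ±15% internal texture.  Scene presets fix the target
contrast: "hard" at 45 (MSNR stays at ~0.05, Sauvola branch), "easy" at
220 (MSNR ≈ 0.97, MSER branch).  Everything is a pure function of
(spec, seed).

What this does and does not show: the generator produces the *regime* the
method assumes (near-black background, bright compact targets, scattered
noise), so passing tests demonstrate the algorithms implement their rules
correctly and behave as designed in that regime.  Real frames add optical
blur, overlapping and out-of-focus organisms, non-stationary turbidity and
within-class morphological diversity that the parametric shapes do not
capture; classification scores on synthetic crops (macro accuracy ≈ 1.0)
say nothing about accuracy on real taxa.  At the default conditions the
segmentation chain recovers ~100% of planted targets at IoU ≥ 0.3 with a
mean of ~0.3 spurious ROIs per noise-only frame (both measured by
`scripts/acceptance.py`, not asserted as constants).

## Box merging

The learned region-proposal merging used by the original pipeline's figure
stage is not specified; this package substitutes an auditable rule: boxes
merge iff IoU ≥ 0.2 or both edge gaps ≤ half the Sauvola window side, with
connected groups collapsing to their union box, iterated to a fixed point
via union-find per round.  The round structure makes the result independent
of input order; at the fixed point no surviving pair satisfies either
criterion.  The rule reproduces the visible effect (multi-part targets
become one ROI) without claiming fidelity to the original.

## Problem sizes and other defaults

Synthetic frames default to 256×256 (Sauvola window 5×5 at 2%), scenes
carry 5 targets of 26–38 px; recovery statistics use 6–8 frames, and the
classifier checks use 256 crops per class with a 3:1 train/test split —
sizes chosen so the whole suite and the acceptance script run at desk
scale in seconds to minutes.  `min_area = 25` px suppresses residual
speckle after denoising.  All randomness flows through
`numpy.random.default_rng` seeds; fixed seeds reproduce manifests
byte-identically (hashed in tests).

## Known limitations

- The bright-polarity Sauvola branch is unusable on frames with a smooth
  positive background level (everything binarizes to foreground); such
  frames need background subtraction first, which is out of scope.
- The denoise rule is O(candidate pixels × cluster labelings); on frames
  where most pixels pass the valid-pixel prefilter it degrades toward
  per-pixel labeling cost.
- MSER diversity pruning is a greedy heuristic (largest-area first); it
  can keep a slightly less stable region than an optimal selection would.
- `R = 128` is the 8-bit grayscale bound; 16-bit inputs need an explicit
  `R` (and threshold rescale) from the caller.
- The probability calibration is fitted on the same samples as the margin,
  which can overconfidence-bias pairwise probabilities on small classes;
  with the default separable-feature regimes this has no measurable effect.
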