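# Methods

## Model and assumptions

The package localizes two retinal landmarks by matching a learned appearance
subspace over a sliding window. Training builds a PCA decomposition of `N`
contrast-normalized, mean-centred, row-major-flattened square patches
(`N = 10` and `n = 100` px for the disc, `n = 70` px for the fovea in the
standard configuration). The covariance is taken in patch space
(`C = DᵀD / N`, an `N × N` matrix), so the decomposition cost is governed by
the number of training patches, not the patch dimension — the classic
eigenimage trick. All `N` components are retained; there is no truncation.

The method assumes: landmarks appear at roughly the training scale (there is
no multi-scale pyramid, and no rotation invariance); test images are 8-bit
grayscale (the green channel of RGB inputs, which carries the best retinal
contrast); and models are trained in left-eye orientation, with right-eye
images mirrored before matching (`eye_side: right` or `auto`, which tries
both orientations and keeps the lower final error).

### Scoring statistics

`featvec` is the matrix of eigenvectors of `C` — as written, the defining
equation of the trained feature matrix names the *eigenvalues* of `C`, but it
is then used as an `N × N` factor multiplying `Dᵀ`, which only the
eigenvector matrix satisfies dimensionally, so that is what is implemented
(rows = unit eigenvectors, descending eigenvalue order).

Two scoring modes are deliberately kept side by side:

- **literal**: `error = sum1 − sum2` with
  `sum2 = ‖outer(featvec row 1, patch vector)‖²_F`. Because the leading
  eigenvector has unit norm, `sum2` collapses to the squared norm of the
  preprocessed patch vector — the statistic ranks patches by their energy
  relative to the training mean and never uses eigenvector directions. It is
  retained as the faithful transcription of the defining equations, and the
  rank-1 factorization identity is asserted in the tests.
- **reconstruction** (default): the squared residual of the patch vector
  after orthogonal projection onto the span of the eigen-templates. This is
  the standard subspace-distance statistic of eigenimage matching and is the
  mode used for all end-to-end evaluations. Whether the literal statistic
  was intended as written cannot be resolved from its source; both are
  exposed and neither is silently substituted for the other.

Test patches are preprocessed *identically to training patches* (own-min/max
stretch to [0, 255], mean-image subtraction, row-major flattening). This is a
deliberate resolution of an underspecified point: feeding raw patches into
machinery built from preprocessed training vectors would make the statistic
scale-dependent in an uncontrolled way.

### Search

The coarse grid starts at pixel (0, 0) with step `s = 25` px (about half a
patch side, the printed speed/accuracy compromise); the map has
`⌊(H − n)/s⌋ + 1 × ⌊(W − n)/s⌋ + 1` cells, so a residual border narrower than
one step is not scanned coarsely but remains reachable by refinement. The
first `k` minima (3 disc / 4 fovea; ties broken row-major) are each refined
by an exhaustive step-1 scan of a 50 × 50 window of patch corners centred on
the coarse corner, clipped to the image. The refinement window (50 px) is
stated for the disc and adopted unchanged for the fovea. Internally all
coordinates are 0-based (row, col) from the top-left; squares are reported by
their top-left corner, with a CLI flag for bottom-left display coordinates.
The reported centre is `corner + (n+1)//2` on each axis — the intersection of
the square's diagonals rounded to a pixel.

### Fast scanning

The step-1 refinement scan is evaluated with an FFT-based engine: the
preprocessed patch vector is an affine function `v = s·p + (o − M̄)` of the
raw window `p` (per-window gain `s` and offset `o` from the window min/max),
so patch energy and projection coefficients expand into per-window sums
(integral images, sliding min/max filters) and a handful of template
cross-correlations (FFT). The engine is algebraically identical to scoring
each window independently; the test suite asserts agreement with the direct
per-patch path to ~1e−8 relative. The coarse map uses the direct vectorized
scorer so that its evaluated/total cell counts reflect exactly the patches
admitted by candidate masking.

## Candidate masking

- **Vessel rule**: disc cells need ≥ `min_thick_pixels` (default 50) thick
  -vessel pixels in their patch footprint (the arcades converge at the disc);
  fovea cells may contain at most `max_thick_pixels` (default 0) of them
  (the fovea is avascular). "Thick" means surviving a morphological opening
  with a radius-2 disc (width ≳ 5 px at 500 × 500 resolution) — a definition
  chosen here, since none is inherited, to separate arcades from capillaries.
  The fovea bound is implemented inclusively (`count ≤ max_thick_pixels`) so
  that the documented default of 0 means "no thick vessels", not "nothing".
- **Intensity clusters**: connected components (≥ `min_cluster_px`, default
  100) of the brightest in-FOV pixels (disc, quantile 0.98) or darkest
  in-FOV non-vessel pixels (fovea, quantile 0.05, vessel pixels excluded
  before the quantile is taken). A constant image yields no clusters.
- **Fovea annulus**: cells whose patch centre lies within
  `2.5 · (1 ± 0.2)` disc diameters of a previously localized disc centre.
- **FOV handling**: when no field-of-view mask is supplied it is estimated by
  Otsu thresholding (the histogram of a fundus image is bimodal: near-black
  camera surround vs retina), largest component, convex hull. For the fovea
  the out-of-FOV border is first filled with each pixel's nearest in-FOV
  value, because the raw border is darker than the fovea itself.

Masks compose by conjunction and only ever shrink the evaluated cell set.
The vessel tree, when not supplied externally, comes from a generic
multi-orientation matched filter (12 rotated zero-mean negative-Gaussian line
kernels, σ = 2 px, length 9 px), thresholded at quantile 0.98 of the in-FOV
response. The filter parameters and all masking quantiles are free
parameters with no inherited values; the defaults were tuned once on the
synthetic generator (at quantile 0.98 the thick tree falls entirely on true
vessels and never contaminates the foveal avascular zone) and are all
configurable.

## Synthetic generator

`eigenfundus.synthetic` renders 500 × 500 left-eye scenes: circular FOV
(radius 240 px) on a near-black surround; smooth background (base 120, mild
linear gradient, quadratic vignette of depth 15); bright Gaussian disc
(diameter 80 ± 20 %, peak ≈ 100 above background, optional ellipticity);
dark Gaussian fovea (depth 40–60, σ ≈ 15 px) at 2.4–2.6 disc diameters from
the disc along the raphe with ±0.15 rad jitter; two parabolic arcades
converging at the disc (width tapering 8 → 3 px) plus two thin nasal
branches (2 px), all ~60 grey levels dark; optional bright exudate blobs;
additive Gaussian noise (default σ = 5, evaluations also run at σ = 8). One
seeded generator drives all randomness; identical seeds give bit-identical
images. Training crops are jittered by ≤ 5 px to emulate human-grader
variability in marking landmark centres; train and held-out scene seed
streams are disjoint by construction.

What the generator does *not* emulate: colour, illumination and compression
artefacts, pathology beyond bright blobs, vessel texture/branching realism,
corneal reflections, anatomical variation of the arcades. Passing the
end-to-end tests therefore demonstrates that the implementation recovers
known geometry under controlled contrast and noise — it does not certify
performance on real fundus photographs.

## Numerical choices

- Covariance divisor is `N` exactly (as defined), not `N − 1`.
- Eigen-decomposition symmetrizes `(C + Cᵀ)/2` first; rows are sorted by
  descending eigenvalue with a stable sort (ties keep `eigh` order), and each
  eigenvector's sign is fixed so its first non-negligible (>1e−12) component
  is positive — training is therefore bit-deterministic.
- Intensities stay real-valued after normalization; nothing is re-quantized.
- A constant (zero-range) patch cannot be normalized: single-patch scoring
  raises a degenerate-patch error, while map building records the cell as
  "not evaluated" (NaN sentinel, distinct from every finite error; rendering
  maps it to white).
- Negative literal errors are stored as-is; only image export rescales.
- Minima searches break ties row-major (sort key: error, row, column).
- The reconstruction basis is an orthonormal basis of the eigen-template row
  space (rank ≤ N − 1, since centred patches sum to zero), computed once per
  model and cached.

## Problem sizes in the shipped tests

Unit tests run on small random matrices and single scenes. The end-to-end
evaluations train on 10 synthetic scenes per landmark and evaluate 50
held-out scenes at noise σ = 8 (the acceptance script uses 40 scenes), with
vessel-masking comparisons on 20 scenes — sizes chosen to keep the full suite
around a minute on one CPU while leaving success-rate estimates stable to a
few percent across seeds.

## Known limitations

- Single-scale, rotation-sensitive matching: a disc much larger or smaller
  than the training patches will be missed or localized loosely.
- The literal scoring mode is energy-based and cannot distinguish structures
  of equal energy; it is provided for fidelity, not performance.
- The matched filter is a generic line detector, not a validated vessel
  segmenter; on real images an external vessel mask is preferable.
- Masking defaults are tuned on the synthetic generator; real images will
  need their quantiles and thickness thresholds revisited.
- `locate` assumes the landmark is present; there is no detection/rejection
  score calibrated for absence (e.g. disc outside the FOV).
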