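# eigenfundus

Automatic localization of the **optic disc** and **fovea** in retinal fundus
photographs by eigen-template (PCA) matching, with a coarse-to-fine
sliding-window search, vessel-tree and intensity-cluster candidate masking,
and a synthetic fundus generator so the whole pipeline can be trained and
evaluated without any real retinal dataset.

The optic disc — the bright, quasi-circular entry point of the optic nerve —
and the fovea — the small, dark, avascular pit at the centre of the macula,
roughly 2.5 disc diameters temporal to the disc — are the anchor landmarks of
automated retinal image analysis. The disc is usually the brightest structure
in a fundus image, but bright exudates can mimic or exceed it; the fovea has
the lowest contrast of any landmark, comparable to weak vessels. Template
matching against a learned appearance subspace handles both cases with the
same machinery.

## Method

Given `N` square training patches `I_1 … I_N` (side `n`), each cropped from a
different retinal image and centred on the same landmark (right-eye crops are
mirrored into left-eye orientation first):

1. **Normalize** each patch to the full 8-bit range:
   `I_i^n = (I_i − min I_i) / max(I_i − min I_i) · 255` (kept real-valued).
2. **Centre** on the mean patch `M = (1/N) Σ I_i^n` and **flatten** row-major
   into length-`n²` vectors, stacked as columns of the data matrix `D`
   (shape `n² × N`).
3. **Covariance** `C = DᵀD / N` (shape `N × N`); its orthonormal eigenvectors,
   rows of `featvec` ordered by descending eigenvalue, span the patch
   subspace. The **eigen-templates** are `finaldat1 = featvec · Dᵀ`
   (shape `N × n²` — "eigendiscs" / "eigenfoveae" when reshaped to images),
   with total energy `sum1 = Σ finaldat1²`.

At test time every candidate patch is preprocessed exactly like a training
patch and scored; the image is scanned with a coarse step (default 25 px),
the resulting grid of errors is the **Euclidean distance map**, its first
`k` minima (3 for disc, 4 for fovea) are each refined by an exhaustive
step-1 rescan of a 50 × 50 corner window, and the lowest refined error wins.
The landmark centre is the intersection of the winning square's diagonals.
Two scoring statistics are available:

- `literal` — `error = sum1 − sum2`, where `sum2` is the squared Frobenius
  norm of `finaldat2 = (featvec[1])ᵀ · {patch}`, the outer product of the
  leading eigenvector with the patch vector. Since the eigenvector has unit
  norm this reduces algebraically to the energy of the preprocessed patch.
- `reconstruction` (default) — the squared residual of the patch vector
  after orthogonal projection onto the span of all `N` eigen-templates
  (the standard "distance from feature space" of eigenimage matching).

Because PCA scanning is expensive, candidate masking restricts the coarse
scan: the disc is sought only where the binary vessel tree shows **thick
vessels** (the arcades converge at the disc), the fovea only in patches
**free of thick vessels**, optionally intersected with clusters of the
brightest (disc) or darkest non-vessel (fovea) pixels and with a 2.5 ± 20 %
disc-diameter annulus around a known disc. A multi-orientation Gaussian
matched filter is included to extract the vessel tree; any external binary
vessel mask can be supplied instead.

## Worked example

Train a disc model on ten synthetic scenes, then locate the disc in a
held-out scene:

```bash
eigenfundus simulate --n-scenes 1 --seed 42 --out-dir scenes
python - <<'PY'
import eigenfundus as ef
patches, _ = ef.make_training_set(10, landmark="disc", patch_size=100, rng_seed=0)
model = ef.train(patches)
ef.save_model(model, "disc.npz")
PY
eigenfundus locate scenes/scene_000.png --model disc.npz --out result.json
```

which prints

```
disc centre=(247,137) corner=(197,87) side=100 error=1.015e+06
```

The scene's ground truth (`scenes/scene_000_truth.json`) places the disc
centre at (245.1, 133.6), so the localization error is about 3.9 px — well
inside the disc. `result.json` holds the full ranked candidate list, the
resolved configuration and the scan statistics (here 289 of 289 coarse
patches scored; add `--mask vessel` to roughly halve that). The `error`
value is the reconstruction residual at the accepted position: the patch's
squared distance from the training subspace, on the squared 8-bit intensity
scale (lower is more disc-like).

The same flow with `--landmark fovea` (70 × 70 patches, 4 coarse minima,
dark-cluster + vessel-exclude masking) localizes the fovea; `eigenfundus
evaluate` runs batch success rates, and `eigenfundus render` draws result
squares onto images.

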