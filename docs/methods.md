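# Methods

This note records the model implemented by `mvct_enhance`, the conventions
chosen where the method description leaves room, and what the synthetic
validation does and does not demonstrate.

## Problem and model

Megavoltage CT (MVCT), the 3.5 MV imaging mode of helical TomoTherapy, is
dominated by Compton interactions: images are noisy and soft-tissue
contrast is poor, which hampers registration for image-guided radiotherapy
and delineation for adaptive re-planning. Because raw projections are
usually unavailable, enhancement must operate on reconstructed 2D slices —
and it must not move CT numbers (HU), since the same images feed dose
calculation.

The pipeline combines two ideas:

1. **Block-matching collaborative filtering (BM3D).** For each reference
   block `Z_xR` (8×8 px), the `L×L = 39×39` search window is scanned at
   every integer offset and the distance

       d(Z_xR, Z_x) = ‖γ′(τ2D(Z_xR)) − γ′(τ2D(Z_x))‖₂² / N_block²

   is evaluated in the 2D transform domain, where `γ′` hard-thresholds
   coefficients at `λ_2D·σ`. Blocks with `d ≤ τ_match = 400` form the
   group `S_xR` (up to `N_number = 5` members), stacked into an
   `8×8×m` array. A separable 3D transform (2D bior-1.5 per block, 1D
   orthonormal transform along the stack) is applied, coefficients with
   magnitude ≤ `λ_3D·σ` are zeroed, and the inverse transform yields one
   filtered estimate per member block.

2. **Discriminative feature representation (DFR).** A dictionary
   `D = [D_hq | D_na]` holds vectorized 8×8×5 atoms: `D_hq` sampled from a
   high-quality (KVCT-like) training volume, `D_na` from the voxelwise
   difference between registered KVCT-like and MVCT-like volumes — an
   explicit model of what should be removed. Each group, after per-block
   mean (DC) removal, is sparse-coded by orthogonal matching pursuit under
   the joint cap `‖α‖₀ < C_DFR = 10`; the group is then rebuilt from the
   high-quality part only, `V_hq = D_hq α_hq + dc`, and handed to the
   collaborative filter. In the combined method the dictionary step
   precedes 3D thresholding.

All block estimates are aggregated per pixel as `Σ ω·Y / Σ ω` with
`ω = 1/(σ²·N_retained)`, `N_retained` being the coefficient count surviving
the 3D threshold.

## Processing scale and density stability

All matching/transform/dictionary work happens on a windowed 8-bit-like
scale: HU are mapped through the soft-tissue window (width 400 HU, level
40 HU) to [0, 255]. The distance cap 400 and the threshold multipliers
then carry their customary meanings from the 8-bit denoising literature.
The enhanced image is mapped back through the exact inverse window;
pixels whose **original** HU lies outside the window (air, dense bone)
are passed through unchanged. This pass-through, plus the mean-preserving
nature of the filters, is what keeps ROI-mean HU drift near zero.

## Conventions and numerical choices

* **2D block transform.** The bior-1.5 wavelet at full dyadic depth with
  periodic boundary handling, realized as a precomputed 8×8 matrix pair
  (analysis/synthesis built from the transform of the canonical basis).
  Round trips are exact to ~1e−15, and a constant block concentrates on a
  single approximation coefficient. The transform preserves the norm of
  constant offsets, so with `λ_2D = 0` the matching distance of uniformly
  shifted blocks equals the pixel-domain mean squared difference.
* **1D stack transform.** Orthonormal Walsh–Hadamard for power-of-two
  depths; for other depths — including the default group depth 5, to which
  Hadamard does not apply — the orthonormal DCT-II, likewise unitary, so
  Parseval holds at every depth and short groups need no padding.
* **Hard threshold boundary.** `|c| ≤ λ` is zeroed (boundary hits killed);
  with `λ = 0` only exact zeros are removed, giving a clean identity limit.
* **Tie-breaks.** Equal matching distances resolve in ascending row-major
  candidate order (stable sort); the reference block always heads its
  group. OMP resolves correlation ties by lowest atom index. Everything is
  deterministic given input, configuration and dictionary.
* **Border handling.** Reference anchors advance by `Δd = 3` px and the
  final anchor per axis is clamped so the last patch touches the border:
  every pixel is covered, and no intensities are invented by padding.
* **`λ_2D` default 0.** No prefilter shrinkage at the noise levels of
  interest (σ ≲ 40 on the 0–255 scale), the common practice for this
  family of filters. Configurable.
* **σ estimation.** When not supplied, σ is the MAD/0.6745 of the finest
  diagonal wavelet subband, computed only over coefficients whose 2×2
  footprint is strictly inside the window — window-saturated regions
  (clipped air) carry no noise and would drag the median to zero.
* **Aggregation weight.** `ω = 1/(σ²·max(N_retained, 1))`. For σ = 0 the
  σ² factor is dropped (weights are only relative); the floor avoids a
  division by zero for fully annihilated groups.
* **Group/atom depth mismatch.** When the distance cap leaves a group with
  fewer than 5 blocks, atoms are truncated to the group depth, re-centred
  per slice and renormalized; atoms that vanish under truncation are
  dropped for that depth.
* **Within-group coverage.** Each stack voxel receives exactly one
  dictionary reconstruction, so the per-group coverage normalization is
  identically 1; overlap across groups is normalized at aggregation.

## Dictionary construction

The sub-dictionary scheme is this package's concrete realization of
"maximum features, minimum redundancy": candidates are 8×8×5 patches on a
stride-4 grid (optionally jittered), DC-removed per 2D slice — per-slice
centring keeps atoms in the same subspace as the DC-removed coding signal —
and recorded with their pre-normalization energy. Selection is greedy by
descending energy; a candidate is skipped when its absolute correlation
with any selected atom exceeds `ρ_max = 0.9`. Defaults: 256 HQ + 256 NA
atoms. The noise sub-dictionary uses the `hq − lq` sign convention, i.e.
atoms model what must be removed. Training pairs are assumed registered;
no deformable registration is attempted. Identical `hq`/`lq` inputs raise
a degenerate-training error rather than emitting zero atoms.

## Synthetic phantom and noise model

The generator emulates a Catphan-like quality phantom: a 256 px image with
a uniform body disc (radius 100 px, 0 HU) in air (−1000 HU) and four plugs
at −100, −40, +40, +120 HU on the disc diagonals — the ±40 pair mimics
low-contrast soft tissue. The MVCT degradation is (in order) soft-tissue
contrast compression toward the body mean (factor 0.7 on the −300…300 HU
band), Gaussian detector blur (0.5 px), and additive Gaussian noise
(20 HU); the KVCT-like reference uses 2 HU noise, no blur, full contrast.
These defaults are the conditions under which all shipped results are
computed. The model deliberately omits scatter, beam hardening, streaking
and anatomical texture; consequently, passing tests demonstrate the
algorithmic behavior of the pipeline (noise removal, contrast recovery,
HU stability, the CNR ordering original < BM3D < BM3D+DFR), not clinical
performance on patient scans, where registration error and non-Gaussian
artifacts will reduce the margin.

The canonical evaluation ROIs are a disc inside the +40 HU plug (target)
and an equal-sized disc on the plug-free horizontal axis of the body
(background), both strictly in "soft tissue".

## Problem sizes

Tests and the acceptance script run on the 256 px default phantom (single
slice per arm, five seeds for the ordering property, 5-slice training
stacks); oracle-equivalence tests use 32×32 images and 256-atom random
dictionaries. These sizes were chosen so the full verification cycle
completes in a few minutes on one CPU while still exercising the default
parameter set unchanged.

## Known limitations

* Single hard-threshold stage; no Wiener refinement pass.
* Matching is within-slice only; the stack axis is "similar blocks", not
  the longitudinal anatomy axis.
* CNR of a noiseless image with unequal ROI means is reported as +inf
  (zero-variance degenerate).
* DICOM output rounds HU to integers (int16 stored values); NIfTI and RAW
  fixtures store float32.
* The dictionary cannot restore contrast lost to compression beyond what
  the image itself still carries; reported RMSE-to-truth inside the body
  therefore improves markedly but does not approach zero.
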