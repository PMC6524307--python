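# mvct-enhance

Image enhancement for megavoltage CT (MVCT) — the 3.5 MV imaging mode of
helical TomoTherapy — aimed at image-guided (IGRT) and adaptive (ART)
radiotherapy workflows. MVCT slices are noisy and show poor soft-tissue
contrast; this package sharpens them **without moving CT numbers**, so the
enhanced series remains usable for dose calculation.

## Method

Two post-reconstruction ideas are combined on a windowed [0, 255]
processing scale (soft-tissue window: width 400 HU, level 40 HU):

1. **Block-matching collaborative 3D filtering.** For each 8×8 reference
   block `Z_xR`, similar blocks inside a 39×39 search window are found by
   the prefiltered transform-domain distance
   `d(Z_xR, Z_x) = ‖γ′(τ2D(Z_xR)) − γ′(τ2D(Z_x))‖₂²/N²` and stacked into a
   3D group `S_xR` (≤ 5 blocks, distance cap τ = 400). The group is
   transformed (bior-1.5 per block × orthonormal 1D along the stack),
   hard-thresholded at `λ_3D·σ`, inverted, and every block estimate is
   re-aggregated with weights `ω = 1/(σ²·N_retained)`.
2. **Discriminative feature representation (DFR).** A dictionary
   `D = [D_hq | D_na]` of 8×8×5 atoms is trained from registered
   high-quality (KVCT-like) and low-quality (MVCT-like) volumes: `D_hq`
   from the clean volume, `D_na` from their difference. Each group is
   sparse-coded by orthogonal matching pursuit (`‖α‖₀ < 10`) and rebuilt
   from the high-quality atoms only — the noise-model content is simply
   discarded — before collaborative filtering.

Quality is assessed with the contrast-to-noise ratio between soft-tissue
regions of interest,

    CNR = 2 |A_t − A_b| / sqrt(α_t² + α_b²),

with canny edge maps, and with an HU-stability check (mean HU drift per
uniform ROI, RMS drift over the body) that verifies density preservation.
A synthetic Catphan-like phantom generator (body disc + HU plugs, Gaussian
noise + blur + contrast compression) makes the entire chain verifiable
without clinical scans.

## Worked example

```python
import mvct_enhance as m

spec = m.PhantomSpec()                                   # 256 px phantom
clean, noisy, target, bg = m.make_eval_scene(spec, seed=1)
pairs = m.make_training_pairs(spec, n_slices=5, seed=2)  # KVCT/MVCT pairs
D = m.build_dictionary(pairs)

bm3d = m.enhance_slice(noisy, m.PipelineConfig(method="bm3d"))
dfr  = m.enhance_slice(noisy, m.PipelineConfig(method="bm3d_dfr"), D)

for name, img in [("original", noisy), ("bm3d", bm3d), ("bm3d+dfr", dfr)]:
    print(f"{name:9s} CNR = {m.cnr(img, target, bg).cnr:.2f}")
```

prints

```
original  CNR = 1.98
bm3d      CNR = 17.11
bm3d+dfr  CNR = 51.12
```

The noisy phantom's soft-tissue CNR (≈2) rises under plain collaborative
filtering and rises further when the discriminative dictionary removes the
noise-model content first — the ordering original < BM3D < BM3D+DFR that
motivates the combined method. Meanwhile the mean HU of every uniform ROI
moves by ~1 HU (well under the 5 HU stability tolerance), so density
information is preserved.

The same workflow is available from the shell:

```
mvct-enhance simulate   --out scene.raw --side 256 --n-slices 5 --seed 1
mvct-enhance train-dict --out dict --side 256 --seed 1
mvct-enhance enhance scene.json --out enhanced --method bm3d+dfr \
    --dict dict --report report.json
mvct-enhance evaluate scene.json enhanced.json --out eval.json
```

Series I/O supports DICOM directories, NIfTI volumes and a RAW+JSON
fixture format (flat float32 + sidecar).

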