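# echofuse

Pixel-level fusion of co-registered cardiac ultrasound images.

Echocardiographic frames are degraded by multiplicative speckle, low
contrast and a restricted sector-shaped field of view, which makes
downstream tasks — above all segmentation of the ventricular endocardium
— unreliable on any single frame. Acquiring several views of the same
anatomy with small probe shifts and fusing them pixel by pixel reduces
speckle, expands the covered field and restores boundary information.
`echofuse` implements this workflow for researchers working on cardiac
image analysis: the fusion methods, the quality metrics to compare them,
and a synthetic phantom generator so everything can be validated against
a known ground truth without clinical data.

## Methods

All images are single-channel rasters with intensities on [0, 1].
Given two co-registered inputs `A(i,j)` and `B(i,j)`:

* **Baselines** — elementwise maximum, minimum, mean, and the weighted
  mean `F = w·A + (1−w)·B`.
* **PCA fusion** — flatten the images into an n×2 data matrix, subtract
  the column means, and eigendecompose the 2×2 covariance matrix `C`.
  With `V` the eigenvector of the larger eigenvalue (`λ V = C V`), the
  weights are the normalized components

      P1 = V(1) / ΣV,   P2 = V(2) / ΣV,   P1 + P2 = 1,

  and the fused image is `F = P1·A + P2·B` — the view carrying more
  variance contributes more.
* **DWT fusion** — a multilevel separable 2-D discrete wavelet transform
  (Daubechies-4 by default) splits each image into an approximation band
  LL and per-level detail bands LH/HL/HH; bands of the two inputs are
  merged per band (average, or largest-magnitude coefficient for
  details) and the merged pyramid is inverted.
* **Hybrid PCA+DWT** — the package's headline method: PCA weighting is
  applied where it preserves spectral content (the approximation band,
  in the default `subband` mode; or as a pre-scaling phase in
  `sequential` mode) and the wavelet detail bands are merged where
  directional structure lives.

The metric panel: RMSE, Pearson correlation (CC), the Wang–Bovik
universal image quality index extended to two inputs (IQI), overall
cross entropy of histograms (OCE), Shannon entropy, and spatial
frequency; for segmentation masks, the Dice similarity index
`DSI = 2|V∩V_ref| / (|V|+|V_ref|)` and the symmetric mean surface
distance `d_mean = (d(S,S_ref) + d(S_ref,S)) / 2`.

## Worked example

```python
import numpy as np
import echofuse as ef

# one synthetic case: ground-truth phantom and two speckled sector views
phantom, deg1, deg2 = ef.default_case_specs(seed=7)
truth, view1, view2, cavity = ef.make_fusion_case(phantom, deg1, deg2)

weights = ef.compute_pca_weights(view1, view2)
print(f"PCA weights: p1={weights.p1:.3f}, p2={weights.p2:.3f}")

fused = ef.hybrid_fuse(view1, view2)
common = ef.sector_mask(truth.shape, deg1) & ef.sector_mask(truth.shape, deg2)
for name, img in [("view 1", view1), ("view 2", view2), ("hybrid", fused)]:
    err = np.sqrt(np.mean((img[common] - truth[common]) ** 2))
    print(f"RMSE vs truth ({name}): {err:.4f}")
```

prints

```
PCA weights: p1=0.286, p2=0.714
RMSE vs truth (view 1): 0.1808
RMSE vs truth (view 2): 0.1814
RMSE vs truth (hybrid): 0.1337
```

The second view carries a slightly higher gain, hence more variance and
the larger PCA weight. Restricted to the field of view both sectors
cover, the hybrid fusion is substantially closer to the noise-free
phantom than either single view — the quantitative form of "fusion
improves image quality". The same comparison is available from the
shell:

```sh
echofuse simulate --out case --seed 7
echofuse fuse case/in1.png case/in2.png -o fused.png --method hybrid
echofuse metrics fused.png case/in1.png case/in2.png \
    --reference case/truth.png --out report.json
```

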