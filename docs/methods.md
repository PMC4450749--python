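# Methods

## Problem setting

Several co-registered B-mode echocardiographic views of the same anatomy
are combined pixel by pixel into one image. The package assumes
registration has already happened: inputs share a pixel grid, and a
pixel coordinate refers to the same anatomical location in every input.
Registration, DICOM/cine-loop handling and color fusion are out of
scope. Internally every image is a 2-D float64 array on [0, 1]; files
(8/16-bit grayscale PNG/TIFF) are scaled by the integer dtype maximum on
read and quantized with round-half-away-from-zero on write, so a
write/read round trip is exact to one quantization step.

## PCA weighting

The two images are flattened into the columns of an n×2 matrix, column
means are removed, and the 2×2 sample covariance matrix (divisor n−1;
the weights are invariant to the divisor, which only scales the reported
eigenvalues) is eigendecomposed. The weights are the sum-normalized
components of the dominant eigenvector, and the fusion is applied to the
*original* (not mean-centered) intensities, so brightness is preserved.

Numerical conventions:

* Eigenvectors are sign-ambiguous; the vector is flipped so its
  largest-magnitude component is positive. If the components still have
  mixed signs — possible only for anti-correlated inputs, where
  sum-normalization would produce non-convex, unstable weights — the
  implementation warns and falls back to p1 = p2 = 0.5, keeping the
  fused image inside the input envelope.
* If both images are constant the covariance matrix is zero and no
  principal direction exists; this raises a `DegenerateInputError`
  rather than silently guessing, so pipelines surface pathological
  inputs. (Inside wavelet-domain fusion, where constant approximation
  bands arise legitimately from constant images, the fallback to equal
  weights is applied automatically.)
* More than two images are fused by left-fold pairwise application —
  a pragmatic extension beyond the two-input weight derivation.

## Wavelet fusion

The multilevel 2-D DWT uses PyWavelets (`wavedec2`/`waverec2`).
Defaults and their reasons:

* **Wavelet `db4`** — a compactly supported orthogonal wavelet, the
  standard choice for image fusion filter banks; configurable.
* **Levels 3** — deeper decompositions put more of the image into
  subbands where the fusion rules act at coarser scales and perform
  better; 3 levels on a 128-pixel image leaves a 16×16 approximation.
  Depth is validated against `floor(log2(min(h, w)))` and clamped with
  a warning by the high-level entry points.
* **Boundary mode `symmetric`** — best edge behavior for images. It is
  not energy preserving; the `periodization` mode gives an orthonormal
  transform whose coefficient energy equals the image energy (Parseval),
  but only on images whose side lengths stay even through every level —
  odd lengths are padded internally, which adds energy. Perfect
  reconstruction (decompose→reconstruct identity to well below 1e−8)
  holds for every mode and shape, including odd dimensions, because the
  original shape is recorded and the inverse is cropped to it.
* **Band rules** — approximation: `mean` or `pca`; details: `mean`
  (default) or `max_abs`. The default is deliberate: for two speckle
  realizations of the *same* scene the detail coefficients are dominated
  by noise, and picking the larger-magnitude coefficient selects the
  larger noise excursion — for iid zero-mean coefficients
  E[max(X², Y²)] ≈ 1.64 σ², i.e. max-selection *amplifies* noise power
  by ~64% while averaging halves it. `max_abs` is the right rule when
  detail coefficients are signal (multifocus or multimodal inputs) and
  remains available everywhere, but it is not the right default for
  speckle-limited single-modality fusion, where it measurably degrades
  ground-truth agreement below that of a single input.
  Ties under `max_abs` keep the first pyramid's coefficient — the only
  asymmetry of the rule set.
* DWT outputs are not clipped to [0, 1] (ringing can overshoot);
  clipping happens once, at write time.

## The hybrid method

Two readings of "PCA phase feeding a DWT phase" are implemented:

* `subband` (default): decompose both inputs; merge approximation bands
  with PCA weights computed *on those bands*, detail bands with the
  configured detail rule; invert. This applies PCA exactly where it
  preserves spectral content and the wavelet rule where directional
  detail lives, and is the standard published PCA+DWT hybrid.
* `sequential`: compute PCA weights (p1, p2) on the full images, scale
  the inputs to J1 = 2·p1·A and J2 = 2·p2·B, then DWT-fuse (J1, J2).
  The factor 2 is a normalization convention of this package: it makes
  the phase-2 mean of (J1, J2) equal the PCA fusion p1·A + p2·B, so
  overall brightness is preserved. With fully linear band rules the
  sequential mode reduces exactly to PCA fusion — the wavelet stage only
  matters when a nonlinear detail rule is chosen.

## Metrics

Named fusion metrics are implemented with the following conventions
(recorded in every report, since several have no single canonical
definition):

* **IQI** — the Wang–Bovik universal image quality index:
  `Q = 4·cov·m_x·m_y / ((v_x+v_y)(m_x²+m_y²))` in sliding windows
  (default 7×7, fully interior windows only), averaged. Degenerate
  windows follow the original convention (luminance term alone when both
  variances vanish; 1 when the luminance denominator also vanishes).
  The two-input fusion score is the mean of IQI against each input.
* **OCE** — mean base-2 KL divergence of each input's histogram from the
  fused histogram; 256 equal-width bins on [0, 1] (8-bit heritage) with
  additive smoothing ε = 1e−12. Zero when the histograms coincide.
* **RMSE / CC** — computed against a ground-truth reference when one
  exists (synthetic data only); otherwise the mean of the per-input
  values, with the convention flagged in the report.
* **Entropy** (bits) and **spatial frequency**
  (`sqrt(RF² + CF²)` from first differences over valid positions).
* **Dice** and **mean surface distance** — boundary pixels are mask
  pixels with a background 4-neighbor (image border counts as
  background); distances are nearest-neighbor Euclidean via a KD-tree,
  scaled by `pixel_spacing` (mm/pixel, default 1). Both masks empty is
  an error, not a silent 0.

## Synthetic data

The generator emulates the statistical structure of short-axis
echocardiograms, not their physics:

* **Phantom** — a dark elliptical blood-pool cavity (level 0.1) inside a
  bright myocardial ring (0.9) on a mid-gray background (0.4), 128×128
  by default; the cavity mask is the exact discrete ellipse and serves
  as segmentation ground truth.
* **Speckle** — per-pixel multiplicative unit-mean gamma noise with
  shape L ("looks") and scale 1/L, variance 1/L; default L = 4, a
  heavily speckled image. This is the standard L-look amplitude
  approximation; it reproduces the first two moments and the
  granular appearance of speckle but not its spatial correlation, the
  Rayleigh statistics of raw RF envelopes, or depth-dependent
  attenuation.
* **Field of view** — a circular sector from a virtual transducer vertex
  above the image; the default study geometry uses two 60° sectors
  aimed 15° either side of vertical, sharing a vertex, with mild
  per-view gain (1.0 vs 1.08) and offset (0 vs 0.02) mismatch.
* All randomness flows through per-spec seeds; identical specs give
  bit-identical fixtures.

Because the phantom is piecewise constant with known geometry, passing
the ground-truth study shows that fusion suppresses independent
multiplicative noise and tolerates mild contrast mismatch; it does not
show robustness to misregistration, correlated speckle, shadowing or
anatomical variation, none of which the generator produces.

## Study sizes and numerical tolerances

The synthetic study (test suite and `scripts/acceptance.py`) uses 20
fixtures of 128×128 pixels — enough for the seed-to-seed spread of the
mean RMSE differences between methods to be an order of magnitude
smaller than the effects measured. Exact linear-algebra identities are
asserted at 1e−10 … 1e−12; transform round trips at 1e−8; statistical
checks use 3σ moment bounds.

## Known limitations

* PCA weighting is derived for exactly two inputs; multi-image fusion is
  pairwise left-fold and order dependent for nonlinear rules.
* The sector geometry has no range (depth) limit — the sector extends to
  the image border.
* IQI of heavily speckled input pairs is low (~0.4) even for good
  fusions; it compares the fusion to the *noisy* inputs and is best used
  to rank methods, not as an absolute quality score.
* Clinical-scale claims (expert delineation agreement, segmentability
  rates) require real echocardiograms and are outside what the synthetic
  study can support.
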