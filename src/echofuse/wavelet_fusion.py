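"""Multilevel 2-D discrete wavelet transform fusion.

An image is decomposed with a separable orthogonal filter bank into one
coarse approximation band (LL) and, per level, three detail bands
(LH/HL/HH) carrying horizontal, vertical and diagonal structure.  Two
decompositions of co-registered images are merged band by band and the
merged pyramid is inverted back to an image.  By default both the
approximation bands and the detail bands are averaged: for two speckle
realizations of the same scene, averaging detail coefficients halves the
noise variance, whereas keeping the larger-magnitude coefficient
(``max_abs``, offered for multifocus-style inputs whose details are
signal rather than noise) amplifies it by about 1.6x.

The default wavelet is Daubechies-4 (``db4``) with symmetric boundary
extension and 3 decomposition levels.  Symmetric extension behaves well
at image borders but is not energy preserving; the ``periodization``
mode yields an orthonormal transform (Parseval equality) on images whose
side lengths stay even through every level.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pywt

from .image_io import as_image, check_compatible
from .pca_fusion import DegenerateInputError, compute_pca_weights

__all__ = [
    "WaveletSpec",
    "WaveletPyramid",
    "dwt_decompose",
    "idwt_reconstruct",
    "fuse_pyramids",
    "dwt_fuse",
]

logger = logging.getLogger(__name__)

APPROX_RULES = ("mean", "pca")
DETAIL_RULES = ("max_abs", "mean")


@dataclass(frozen=True)
class WaveletSpec:
    """Transform configuration: wavelet family, depth and boundary rule."""

    wavelet: str = "db4"
    levels: int = 3
    mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError(f"levels must be >= 1, got {self.levels}")
        pywt.Wavelet(self.wavelet)  # raises on unknown name

    def max_levels(self, shape: tuple[int, int]) -> int:
        """Deepest admissible decomposition for an image shape (dyadic rule)."""
        return int(math.floor(math.log2(min(shape))))

    def clamped(self, shape: tuple[int, int]) -> "WaveletSpec":
        """Return a spec whose depth is admissible for ``shape``.

        Emits a warning when the requested depth had to be reduced.
        """
        admissible = self.max_levels(shape)
        if self.levels > admissible:
            warnings.warn(
                f"decomposition depth {self.levels} too deep for image "
                f"shape {shape}; clamped to {admissible}",
                UserWarning,
                stacklevel=2,
            )
            return replace(self, levels=admissible)
        return self


@dataclass
class WaveletPyramid:
    """Multilevel 2-D DWT coefficient set.

    ``approximation`` is the coarsest LL band; ``details`` holds one
    (LH, HL, HH) triple per level, ordered coarsest to finest.
    ``original_shape`` allows exact-size reconstruction for odd
    dimensions.
    """

    approximation: np.ndarray
    details: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    spec: WaveletSpec
    original_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.details) != self.spec.levels:
            raise ValueError(
                f"pyramid has {len(self.details)} detail levels but spec "
                f"requests {self.spec.levels}"
            )
        for bands in self.details:
            if len({b.shape for b in bands}) != 1:
                raise ValueError("detail bands within a level must share a shape")


def _to_coeffs(pyr: WaveletPyramid) -> list:
    return [pyr.approximation] + [tuple(bands) for bands in pyr.details]


def dwt_decompose(img: np.ndarray, spec: WaveletSpec | None = None) -> WaveletPyramid:
    """Decompose an image into a multilevel wavelet pyramid.

    Raises a validation error if the requested depth exceeds
    ``floor(log2(min(height, width)))``.
    """
    img = as_image(img)
    spec = spec or WaveletSpec()
    if spec.levels > spec.max_levels(img.shape):
        raise ValueError(
            f"levels={spec.levels} too deep for image shape {img.shape}; "
            f"maximum admissible is {spec.max_levels(img.shape)}"
        )
    with warnings.catch_warnings():
        # pywt warns when the depth exceeds its filter-length heuristic;
        # the transform remains exactly invertible, which is what matters here
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec2(img, spec.wavelet, mode=spec.mode, level=spec.levels)
    return WaveletPyramid(
        approximation=coeffs[0],
        details=[tuple(level) for level in coeffs[1:]],
        spec=spec,
        original_shape=img.shape,
    )


def idwt_reconstruct(pyr: WaveletPyramid) -> np.ndarray:
    """Invert a wavelet pyramid back to an image of its original shape.

    The output is cropped to ``original_shape`` (the forward transform of
    an odd-sized image pads internally) and is NOT clipped to [0, 1];
    clipping happens only when writing to disk.
    """
    rec = pywt.waverec2(_to_coeffs(pyr), pyr.spec.wavelet, mode=pyr.spec.mode)
    h, w = pyr.original_shape
    return rec[:h, :w]


def _check_pyramids_match(pyr1: WaveletPyramid, pyr2: WaveletPyramid) -> None:
    if pyr1.spec != pyr2.spec:
        raise ValueError(f"wavelet specs differ: {pyr1.spec} vs {pyr2.spec}")
    if pyr1.approximation.shape != pyr2.approximation.shape:
        raise ValueError("approximation band shapes differ")
    for lev, (b1, b2) in enumerate(zip(pyr1.details, pyr2.details)):
        for a, b in zip(b1, b2):
            if a.shape != b.shape:
                raise ValueError(f"detail band shapes differ at level {lev}")


def fuse_pyramids(
    pyr1: WaveletPyramid,
    pyr2: WaveletPyramid,
    approx_rule: str = "mean",
    detail_rule: str = "mean",
) -> WaveletPyramid:
    """Merge two wavelet pyramids band by band.

    Approximation rules: ``mean`` averages elementwise; ``pca`` weights
    the two approximation bands by their principal-component weights
    (falling back to equal weights when both bands are constant).
    Detail rules: ``max_abs`` keeps the coefficient of larger magnitude
    (sign preserved, ties go to ``pyr1``); ``mean`` averages.
    """
    if approx_rule not in APPROX_RULES:
        raise ValueError(f"unknown approx_rule {approx_rule!r}; use one of {APPROX_RULES}")
    if detail_rule not in DETAIL_RULES:
        raise ValueError(f"unknown detail_rule {detail_rule!r}; use one of {DETAIL_RULES}")
    _check_pyramids_match(pyr1, pyr2)

    a1, a2 = pyr1.approximation, pyr2.approximation
    if approx_rule == "mean":
        approx = (a1 + a2) / 2.0
    else:
        try:
            w = compute_pca_weights(a1, a2)
            approx = w.p1 * a1 + w.p2 * a2
        except DegenerateInputError:
            logger.info("constant approximation bands; using equal PCA weights")
            approx = (a1 + a2) / 2.0

    details = []
    for bands1, bands2 in zip(pyr1.details, pyr2.details):
        fused_level = []
        for d1, d2 in zip(bands1, bands2):
            if detail_rule == "max_abs":
                fused_level.append(np.where(np.abs(d2) > np.abs(d1), d2, d1))
            else:
                fused_level.append((d1 + d2) / 2.0)
        details.append(tuple(fused_level))

    return WaveletPyramid(
        approximation=approx,
        details=details,
        spec=pyr1.spec,
        original_shape=pyr1.original_shape,
    )


def dwt_fuse(
    img1: np.ndarray,
    img2: np.ndarray,
    spec: WaveletSpec | None = None,
    approx_rule: str = "mean",
    detail_rule: str = "mean",
) -> np.ndarray:
    """Decompose both images, merge band by band, and reconstruct.

    The result is not clipped; DWT fusion can overshoot [0, 1] slightly
    near strong edges (ringing).
    """
    img1 = as_image(img1)
    img2 = as_image(img2)
    check_compatible([img1, img2])
    spec = (spec or WaveletSpec()).clamped(img1.shape)
    pyr1 = dwt_decompose(img1, spec)
    pyr2 = dwt_decompose(img2, spec)
    return idwt_reconstruct(fuse_pyramids(pyr1, pyr2, approx_rule, detail_rule))
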