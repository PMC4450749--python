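"""PCA-weighted fusion of two co-registered images.

Each image is flattened into one column of an *n* x 2 data matrix, the
per-column mean is subtracted, and the 2 x 2 sample covariance matrix is
eigendecomposed.  The eigenvector ``V`` of the dominant eigenvalue gives
the fusion weights

    p1 = V(1) / (V(1) + V(2)),    p2 = V(2) / (V(1) + V(2)),

so p1 + p2 = 1 and the fused image is the convex combination
``p1 * I1 + p2 * I2``.  The image that carries more variance (more signal
structure relative to the common scene) receives the larger weight.

Notes on conventions: the covariance uses the unbiased 1/(n-1) divisor
(the weights are invariant to this choice); the eigenvector's sign is
fixed so that its largest-magnitude component is positive, since the
normalization divides by the component sum.  Weights are computed from
mean-centered data but applied to the original intensities, so the fused
image keeps the inputs' brightness scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .image_io import as_image, check_compatible

__all__ = ["DegenerateInputError", "PCAWeights", "compute_pca_weights", "pca_fuse"]

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """Raised when PCA weights are undefined (e.g. both images constant).

    Callers that can tolerate the degenerate case should fall back to
    equal weights p1 = p2 = 0.5.
    """


@dataclass(frozen=True)
class PCAWeights:
    """Normalized principal-component fusion weights with provenance.

    Attributes
    ----------
    p1, p2
        Convex weights for image 1 and image 2; ``p1 + p2 == 1``.
    eigenvalues
        Both eigenvalues of the 2x2 pixel covariance matrix, descending.
    principal_eigenvector
        Unit eigenvector of the larger eigenvalue, sign-fixed so its
        largest-magnitude component is positive.
    """

    p1: float
    p2: float
    eigenvalues: tuple[float, float]
    principal_eigenvector: tuple[float, float]


def compute_pca_weights(img1: np.ndarray, img2: np.ndarray) -> PCAWeights:
    """Derive normalized PCA fusion weights from two same-shape images.

    Raises
    ------
    DegenerateInputError
        If both images are constant (zero covariance matrix), in which
        case no principal direction exists; callers may fall back to
        equal weights.
    ShapeError
        If the images differ in shape.
    """
    img1 = as_image(img1)
    img2 = as_image(img2)
    check_compatible([img1, img2])

    x = np.column_stack([img1.ravel(), img2.ravel()])
    xc = x - x.mean(axis=0)
    n = x.shape[0]
    cov = xc.T @ xc / (n - 1)

    if np.allclose(cov, 0.0, atol=1e-30):
        raise DegenerateInputError(
            "both images are constant; PCA weights are undefined "
            "(fall back to p1 = p2 = 0.5)"
        )

    evals, evecs = np.linalg.eigh(cov)  # ascending
    evals = evals[::-1]
    v = evecs[:, 1].copy()
    # eigenvectors are sign-ambiguous; normalize by component sum only
    # after making the dominant component positive
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    # clamp numerical fuzz of a structurally zero component
    v[np.abs(v) < 1e-12] = np.abs(v[np.abs(v) < 1e-12])

    if v[0] < 0 or v[1] < 0:
        # anti-correlated inputs: the dominant eigenvector has mixed signs
        # and sum-normalization would produce non-convex weights
        warnings.warn(
            "mixed-sign principal eigenvector (anti-correlated inputs); "
            "falling back to equal weights",
            RuntimeWarning,
            stacklevel=2,
        )
        p1, p2 = 0.5, 0.5
    else:
        s = v[0] + v[1]
        p1, p2 = float(v[0] / s), float(v[1] / s)

    return PCAWeights(
        p1=p1,
        p2=p2,
        eigenvalues=(float(max(evals[0], 0.0)), float(max(evals[1], 0.0))),
        principal_eigenvector=(float(v[0]), float(v[1])),
    )


def pca_fuse(
    img1: np.ndarray, img2: np.ndarray, weights: PCAWeights | None = None
) -> np.ndarray:
    """Fuse two images by their PCA weights: ``p1 * I1 + p2 * I2``.

    The weights are convex, so the output lies pixelwise between the
    input envelope; no clipping is applied.
    """
    img1 = as_image(img1)
    img2 = as_image(img2)
    check_compatible([img1, img2])
    if weights is None:
        weights = compute_pca_weights(img1, img2)
    logger.debug("pca_fuse weights p1=%.6f p2=%.6f", weights.p1, weights.p2)
    return weights.p1 * img1 + weights.p2 * img2
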