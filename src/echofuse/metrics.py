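"""Quantitative evaluation of fused images and segmentation overlap.

Fusion quality measures
-----------------------
* ``rmse`` — root mean square pixel error between two images.
* ``correlation_coefficient`` — Pearson correlation over all pixels.
* ``iqi`` — the universal image quality index of Wang & Bovik: within
  each sliding window the product of a correlation term, a luminance
  closeness term and a contrast closeness term,

      Q = 4 * cov(x, y) * mx * my / ((vx + vy) * (mx^2 + my^2)),

  averaged over all fully interior windows; 1 for identical images,
  range [-1, 1].  ``fusion_iqi`` extends it to a no-reference fusion
  score as the mean of IQI against each input.
* ``overall_cross_entropy`` — histogram divergence of the fused image
  from the two inputs: the mean base-2 Kullback-Leibler divergence of
  each input's intensity histogram from the fused histogram (smaller is
  better, 0 when all histograms coincide).
* ``entropy`` — Shannon entropy (bits) of the intensity histogram.
* ``spatial_frequency`` — sqrt(RF^2 + CF^2) where RF and CF are the root
  mean square of horizontal and vertical first differences; an overall
  activity/sharpness measure.

Segmentation validation measures
--------------------------------
* ``dice_similarity`` — Dice overlap 2|A∩B| / (|A| + |B|) of two binary
  regions, 0 (disjoint) to 1 (identical).
* ``mean_surface_distance`` — symmetric average nearest-neighbour
  Euclidean distance between two region boundaries, in physical units
  via ``pixel_spacing``.

Histograms are always taken over [0, 1] with equal-width bins (default
256, the 8-bit heritage of the inputs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .image_io import ShapeError, as_image, check_compatible

__all__ = [
    "UndefinedMetricError",
    "Contour",
    "MetricsReport",
    "rmse",
    "correlation_coefficient",
    "iqi",
    "fusion_iqi",
    "overall_cross_entropy",
    "entropy",
    "spatial_frequency",
    "dice_similarity",
    "extract_contour",
    "mean_surface_distance",
    "evaluate",
]

HIST_SMOOTHING = 1e-12
_DEGENERATE_EPS = 1e-12


class UndefinedMetricError(ValueError):
    """Raised when a metric is mathematically undefined for its inputs."""


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean square error over all pixels."""
    a, b = as_image(a), as_image(b)
    check_compatible([a, b])
    return float(np.sqrt(np.mean((a - b) ** 2)))


def correlation_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation coefficient over flattened pixels."""
    a, b = as_image(a), as_image(b)
    check_compatible([a, b])
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedMetricError("correlation undefined for a constant image")
    return float(np.corrcoef(a.ravel(), b.ravel())[0, 1])


def _window_stats(a: np.ndarray, b: np.ndarray, window: int):
    """Per-window means, variances and covariance over interior windows."""
    off = window // 2
    h, w = a.shape
    crop = (slice(off, h - off), slice(off, w - off))
    uf = lambda x: ndimage.uniform_filter(x, size=window)[crop]
    ma, mb = uf(a), uf(b)
    va = uf(a * a) - ma * ma
    vb = uf(b * b) - mb * mb
    cov = uf(a * b) - ma * mb
    return ma, mb, va, vb, cov


def iqi(fused: np.ndarray, ref: np.ndarray, window: int = 7) -> float:
    """Universal image quality index, averaged over sliding windows.

    Degenerate windows follow the original convention: when both windows
    have zero variance the luminance term alone is used, and when the
    luminance denominator also vanishes the window scores 1.
    """
    fused, ref = as_image(fused), as_image(ref)
    check_compatible([fused, ref])
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if window > min(fused.shape):
        raise ValueError(
            f"window {window} exceeds smallest image dimension {min(fused.shape)}"
        )

    ma, mb, va, vb, cov = _window_stats(fused, ref, window)
    lum_den = ma * ma + mb * mb
    den = (va + vb) * lum_den

    q = np.ones_like(den)
    full = den > _DEGENERATE_EPS
    q[full] = 4.0 * cov[full] * ma[full] * mb[full] / den[full]
    lum_only = ~full & (lum_den > _DEGENERATE_EPS)
    q[lum_only] = 2.0 * ma[lum_only] * mb[lum_only] / lum_den[lum_only]
    return float(q.mean())


def fusion_iqi(
    fused: np.ndarray, in1: np.ndarray, in2: np.ndarray, window: int = 7
) -> float:
    """No-reference fusion quality: mean IQI of the result against each input."""
    return (iqi(fused, in1, window) + iqi(fused, in2, window)) / 2.0


def _histogram(img: np.ndarray, bins: int) -> np.ndarray:
    counts, _ = np.histogram(np.clip(img, 0.0, 1.0), bins=bins, range=(0.0, 1.0))
    return counts.astype(np.float64)


def _smoothed_prob(counts: np.ndarray) -> np.ndarray:
    p = counts + HIST_SMOOTHING
    return p / p.sum()


def overall_cross_entropy(
    fused: np.ndarray, in1: np.ndarray, in2: np.ndarray, bins: int = 256
) -> float:
    """Mean KL divergence (base 2) of each input histogram from the fused one."""
    fused, in1, in2 = as_image(fused), as_image(in1), as_image(in2)
    check_compatible([fused, in1, in2])
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    hf = _smoothed_prob(_histogram(fused, bins))
    kl = lambda h: stats.entropy(_smoothed_prob(_histogram(h, bins)), hf, base=2)
    return float((kl(in1) + kl(in2)) / 2.0)


def entropy(img: np.ndarray, bins: int = 256) -> float:
    """Shannon entropy (bits) of the intensity histogram over [0, 1]."""
    img = as_image(img)
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    counts = _histogram(img, bins)
    return float(stats.entropy(counts / counts.sum(), base=2))


def spatial_frequency(img: np.ndarray) -> float:
    """Root mean square of first differences: sqrt(RF^2 + CF^2)."""
    img = as_image(img)
    row_diff = img[:, 1:] - img[:, :-1]   # differences along rows (horizontal)
    col_diff = img[1:, :] - img[:-1, :]   # differences along columns (vertical)
    rf = np.sqrt(np.mean(row_diff**2))
    cf = np.sqrt(np.mean(col_diff**2))
    return float(np.sqrt(rf**2 + cf**2))


def _as_mask(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ShapeError(f"mask must be 2-D, got {arr.ndim}-D")
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be strictly binary")
        arr = arr.astype(bool)
    return arr


def dice_similarity(v: np.ndarray, v_ref: np.ndarray) -> float:
    """Dice overlap 2|V∩Vref| / (|V| + |Vref|) of two binary masks."""
    v, v_ref = _as_mask(v), _as_mask(v_ref)
    if v.shape != v_ref.shape:
        raise ShapeError(f"incompatible mask shapes: {v.shape} vs {v_ref.shape}")
    total = int(v.sum()) + int(v_ref.sum())
    if total == 0:
        raise UndefinedMetricError("Dice undefined: both masks are empty")
    return float(2.0 * np.logical_and(v, v_ref).sum() / total)


@dataclass(frozen=True)
class Contour:
    """Boundary of a binary region as integer (row, col) pixel coordinates.

    Boundary pixels belong to the mask and touch background in their
    4-neighbourhood (pixels beyond the image border count as background).
    ``pixel_spacing`` converts pixel distances to physical units (mm).
    """

    boundary_pixels: np.ndarray  # (k, 2) int array of (row, col)
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.boundary_pixels, dtype=np.int64).reshape(-1, 2)
        object.__setattr__(self, "boundary_pixels", pts)
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")


def extract_contour(mask: np.ndarray, pixel_spacing: float = 1.0) -> Contour:
    """Extract the 4-adjacency boundary of a binary mask as a Contour."""
    mask = _as_mask(mask)
    if not mask.any():
        raise UndefinedMetricError("cannot extract a contour from an empty mask")
    cross = ndimage.generate_binary_structure(2, 1)
    interior = ndimage.binary_erosion(mask, structure=cross, border_value=0)
    boundary = mask & ~interior
    return Contour(np.argwhere(boundary), pixel_spacing)


def mean_surface_distance(s: Contour, s_ref: Contour) -> float:
    """Symmetric mean nearest-neighbour distance between two contours (mm).

    ``(d(S, S_ref) + d(S_ref, S)) / 2`` where each directed term averages,
    over the pixels of one contour, the Euclidean distance to the closest
    pixel of the other.
    """
    if s.boundary_pixels.size == 0 or s_ref.boundary_pixels.size == 0:
        raise ValueError("contours must be non-empty")
    if s.pixel_spacing != s_ref.pixel_spacing:
        raise ValueError(
            f"pixel spacings differ: {s.pixel_spacing} vs {s_ref.pixel_spacing}"
        )
    pts_a = s.boundary_pixels.astype(np.float64)
    pts_b = s_ref.boundary_pixels.astype(np.float64)
    d_ab = cKDTree(pts_b).query(pts_a)[0].mean()
    d_ba = cKDTree(pts_a).query(pts_b)[0].mean()
    return float(0.5 * (d_ab + d_ba) * s.pixel_spacing)


@dataclass
class MetricsReport:
    """Named metric values for one fused image, with provenance.

    ``reference_convention`` records what RMSE and CC were computed
    against: ``"reference"`` when a ground-truth image was supplied,
    ``"input_mean"`` (the mean of the per-input values) otherwise.
    """

    values: dict[str, float]
    method: str | None = None
    reference_convention: str = "input_mean"
    parameters: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "values": dict(self.values),
            "method": self.method,
            "reference_convention": self.reference_convention,
            "parameters": dict(self.parameters),
        }


METRIC_KEYS = ("iqi", "rmse", "cc", "oce", "entropy", "spatial_frequency")


def evaluate(
    fused: np.ndarray,
    in1: np.ndarray,
    in2: np.ndarray,
    reference: np.ndarray | None = None,
    bins: int = 256,
    window: int = 7,
    method: str | None = None,
) -> MetricsReport:
    """Compute the full metric panel for one fusion result.

    IQI (against both inputs), overall cross entropy, entropy and spatial
    frequency are always computed from the fused image and the inputs.
    RMSE and CC are computed against ``reference`` when one is supplied
    (possible only with synthetic ground truth); otherwise each is the
    mean of its value against the two inputs, and the report's
    ``reference_convention`` field says so.
    """
    fused, in1, in2 = as_image(fused), as_image(in1), as_image(in2)
    check_compatible([fused, in1, in2])

    if reference is not None:
        reference = as_image(reference)
        check_compatible([fused, reference])
        rmse_val = rmse(fused, reference)
        cc_val = correlation_coefficient(fused, reference)
        convention = "reference"
    else:
        rmse_val = (rmse(fused, in1) + rmse(fused, in2)) / 2.0
        cc_val = (
            correlation_coefficient(fused, in1) + correlation_coefficient(fused, in2)
        ) / 2.0
        convention = "input_mean"

    values = {
        "iqi": fusion_iqi(fused, in1, in2, window),
        "rmse": rmse_val,
        "cc": cc_val,
        "oce": overall_cross_entropy(fused, in1, in2, bins),
        "entropy": entropy(fused, bins),
        "spatial_frequency": spatial_frequency(fused),
    }
    return MetricsReport(
        values=values,
        method=method,
        reference_convention=convention,
        parameters={"bins": bins, "window": window},
    )
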