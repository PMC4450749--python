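"""Synthetic echocardiography-like phantoms and speckle degradation.

Clinical echocardiograms are not redistributable, so test fixtures are
generated: a piecewise-smooth anatomy phantom — a dark elliptical
ventricular cavity surrounded by a bright myocardial ring on a mid-gray
background — degraded per view by

* multiplicative speckle: unit-mean gamma noise with shape ``L``
  ("looks") and scale ``1/L``, so the noise variance is ``1/L`` — the
  standard L-look amplitude speckle approximation with a single
  interpretable noise-level knob;
* a sector field of view: a circular sector from a virtual transducer
  vertex, mimicking the restricted insonified region, with everything
  outside set to a constant;
* mild per-view gain (contrast) and offset (brightness) perturbation.

Two such views of one ground-truth phantom, with different seeds, sector
orientations and gains, form one fusion test case.  All generation is
bit-reproducible from the specs' seeds; each spec owns its own
generator, no global random state is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import as_image

__all__ = [
    "PhantomSpec",
    "DegradationSpec",
    "make_phantom",
    "sector_mask",
    "degrade",
    "make_fusion_case",
    "default_case_specs",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensities of the clean anatomy phantom.

    The cavity is the ellipse ``((r-cr)/ar)^2 + ((c-cc)/ac)^2 <= 1``; the
    myocardial ring is the band between that ellipse and the one whose
    semi-axes are larger by ``ring_thickness`` pixels.  Intensities must
    satisfy cavity < background < ring, the contrast ordering of a B-mode
    short-axis view (anechoic blood pool, echogenic myocardium).
    """

    height: int = 128
    width: int = 128
    cavity_center: tuple[float, float] = (64.0, 64.0)  # (row, col)
    cavity_axes: tuple[float, float] = (24.0, 32.0)    # (row, col) semi-axes
    ring_thickness: float = 10.0
    background_level: float = 0.4
    cavity_level: float = 0.1
    ring_level: float = 0.9
    texture_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise ValueError("phantom must be at least 2x2")
        if not 0.0 <= self.cavity_level < self.background_level < self.ring_level <= 1.0:
            raise ValueError(
                "intensity ordering must be 0 <= cavity < background < ring <= 1"
            )
        cr, cc = self.cavity_center
        ar, ac = self.cavity_axes
        t = self.ring_thickness
        if ar <= 0 or ac <= 0 or t < 0:
            raise ValueError("cavity axes must be positive and ring_thickness >= 0")
        if (
            cr - (ar + t) < 0
            or cr + (ar + t) > self.height - 1
            or cc - (ac + t) < 0
            or cc + (ac + t) > self.width - 1
        ):
            raise ValueError("cavity plus ring must fit inside the image")


@dataclass(frozen=True)
class DegradationSpec:
    """One view's speckle, field-of-view and contrast degradation.

    ``speckle_looks`` is the gamma shape L (noise variance 1/L; large L
    approaches noiseless).  The sector opens from ``fov_vertex`` (row,
    col; may lie outside the image) around the central-axis direction
    ``fov_orientation_deg`` (degrees, 90 = straight down the rows) with
    full opening angle ``fov_angle_deg``.
    """

    speckle_looks: float = 4.0
    fov_vertex: tuple[float, float] = (-8.0, 64.0)  # (row, col)
    fov_angle_deg: float = 60.0
    fov_orientation_deg: float = 90.0
    gain: float = 1.0
    offset: float = 0.0
    outside_fov_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speckle_looks <= 0:
            raise ValueError("speckle_looks must be positive")
        if not 0.0 < self.fov_angle_deg <= 180.0:
            raise ValueError("fov_angle_deg must be in (0, 180]")


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Build the clean phantom image and its cavity ground-truth mask.

    Deterministic given the spec; the seed is used only when
    ``texture_jitter > 0``, which adds smooth low-amplitude intra-region
    texture (clipped so region ordering is preserved).
    """
    rows = np.arange(spec.height, dtype=np.float64)[:, None]
    cols = np.arange(spec.width, dtype=np.float64)[None, :]
    cr, cc = spec.cavity_center
    ar, ac = spec.cavity_axes

    cavity = ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2 <= 1.0
    outer = ((rows - cr) / (ar + spec.ring_thickness)) ** 2 + (
        (cols - cc) / (ac + spec.ring_thickness)
    ) ** 2 <= 1.0
    ring = outer & ~cavity

    img = np.full((spec.height, spec.width), spec.background_level)
    img[ring] = spec.ring_level
    img[cavity] = spec.cavity_level

    if spec.texture_jitter > 0:
        from scipy import ndimage

        rng = np.random.default_rng(spec.seed)
        noise = ndimage.gaussian_filter(
            rng.standard_normal(img.shape), sigma=2.0
        )
        noise *= spec.texture_jitter / max(np.abs(noise).max(), 1e-12)
        img = np.clip(img + noise, 0.0, 1.0)

    return as_image(img), cavity


def sector_mask(shape: tuple[int, int], spec: DegradationSpec) -> np.ndarray:
    """Boolean mask of the sector field of view on an image grid."""
    rows = np.arange(shape[0], dtype=np.float64)[:, None]
    cols = np.arange(shape[1], dtype=np.float64)[None, :]
    vr, vc = spec.fov_vertex
    angle = np.degrees(np.arctan2(rows - vr, cols - vc))
    delta = (angle - spec.fov_orientation_deg + 180.0) % 360.0 - 180.0
    return np.abs(delta) <= spec.fov_angle_deg / 2.0


def degrade(img: np.ndarray, spec: DegradationSpec) -> np.ndarray:
    """Apply speckle, gain/offset and the sector field of view to an image.

    Inside the sector the output is ``clip(gain * img * N + offset, 0, 1)``
    with per-pixel unit-mean gamma speckle ``N ~ Gamma(L, 1/L)``; outside
    it is ``outside_fov_level``.  Bit-reproducible from ``spec.seed``.
    """
    img = as_image(img)
    rng = np.random.default_rng(spec.seed)
    speckle = rng.gamma(spec.speckle_looks, 1.0 / spec.speckle_looks, img.shape)
    out = np.clip(spec.gain * img * speckle + spec.offset, 0.0, 1.0)
    fov = sector_mask(img.shape, spec)
    out[~fov] = spec.outside_fov_level
    return out


def make_fusion_case(
    phantom_spec: PhantomSpec,
    deg1: DegradationSpec,
    deg2: DegradationSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Build one fixture: (truth, degraded view 1, degraded view 2, cavity mask).

    Raises a validation error if the two sector fields of view do not
    overlap anywhere — fusion of disjoint views is meaningless.
    """
    truth, cavity = make_phantom(phantom_spec)
    fov1 = sector_mask(truth.shape, deg1)
    fov2 = sector_mask(truth.shape, deg2)
    if not np.any(fov1 & fov2):
        raise ValueError("sector fields of view do not overlap")
    return truth, degrade(truth, deg1), degrade(truth, deg2), cavity


def default_case_specs(
    seed: int,
) -> tuple[PhantomSpec, DegradationSpec, DegradationSpec]:
    """Study-default fixture parameters, seeded.

    128x128 phantom; two 60-degree sectors from the same virtual
    transducer, aimed 15 degrees either side of straight down; 4-look
    speckle; a mild gain/offset mismatch between the views.  Per-view
    speckle seeds are derived from ``seed`` so the two views carry
    independent noise.
    """
    phantom = PhantomSpec(seed=seed)
    deg1 = DegradationSpec(
        speckle_looks=4.0,
        fov_orientation_deg=75.0,
        gain=1.0,
        offset=0.0,
        seed=(2 * seed + 1) % 2**31,
    )
    deg2 = DegradationSpec(
        speckle_looks=4.0,
        fov_orientation_deg=105.0,
        gain=1.08,
        offset=0.02,
        seed=(2 * seed + 2) % 2**31,
    )
    return phantom, deg1, deg2
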