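"""Hematoxylin/eosin stain modeling in optical-density space.

Stain amounts mix linearly in optical density (Beer-Lambert): the OD of a
pixel is a non-negative combination of a hematoxylin direction and an eosin
direction plus residual. Estimating those unit directions from a region that
contains both stained tissue and blank background lets the downstream
segmentation and feature code work on separated stain channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

# Ruifrok & Johnston reference directions, unit-normalized; used by the
# synthetic renderer and as a sanity anchor when assigning H vs E.
RUIFROK_HEMATOXYLIN = np.array([0.65, 0.70, 0.29]) / np.linalg.norm([0.65, 0.70, 0.29])
RUIFROK_EOSIN = np.array([0.07, 0.99, 0.11]) / np.linalg.norm([0.07, 0.99, 0.11])


@dataclass(frozen=True)
class StainModel:
    """Unit OD vectors for the two dyes plus background white point.

    ``residual`` is the unit vector orthogonal to both stain directions; OD
    mass along it is "unrecognized color" (neither dye).
    """

    hematoxylin: np.ndarray
    eosin: np.ndarray
    background_rgb: np.ndarray
    residual: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        h = np.asarray(self.hematoxylin, dtype=float)
        e = np.asarray(self.eosin, dtype=float)
        for name, v in (("hematoxylin", h), ("eosin", e)):
            if v.shape != (3,):
                raise ValueError(f"{name} vector must be a 3-vector")
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-6):
                raise ValueError(f"{name} vector must be unit-norm")
            if (v < -1e-9).any():
                raise ValueError(f"{name} vector must have non-negative components")
        cos = float(np.clip(np.dot(h, e), -1.0, 1.0))
        if np.degrees(np.arccos(cos)) <= 1.0:
            raise ValueError("stain vectors are collinear (angle <= 1 degree)")
        object.__setattr__(self, "hematoxylin", h)
        object.__setattr__(self, "eosin", e)
        object.__setattr__(
            self, "background_rgb", np.asarray(self.background_rgb, dtype=float)
        )
        if self.residual is None:
            r = np.cross(h, e)
            object.__setattr__(self, "residual", r / np.linalg.norm(r))


@dataclass
class OdImage:
    """Per-pixel optical density (H, W, 3) with physical pixel size."""

    od: np.ndarray
    pixel_size_um: float

    def __post_init__(self):
        if self.od.ndim != 3 or self.od.shape[2] != 3:
            raise ValueError("OD image must be (H, W, 3)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")

    def stain_channel(self, vector: np.ndarray) -> np.ndarray:
        """Project OD onto a unit stain direction -> (H, W) stain amount."""
        return self.od @ np.asarray(vector, dtype=float)


def rgb_to_od(
    image: np.ndarray,
    background_rgb,
    od_max: float = 2.0,
    pixel_size_um: float = 1.0,
) -> OdImage:
    """Beer-Lambert transform: OD_c = log10(background_c / pixel_c).

    Zero pixel values are floored at 1 before the ratio; the result is
    clipped to ``[0, od_max]`` so fully dark pixels report ``od_max``.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    bg = np.asarray(background_rgb, dtype=float)
    if (bg <= 0).any():
        raise ValueError("background channel values must be > 0")
    denom = np.maximum(image.astype(float), 1.0)
    od = np.log10(bg[None, None, :] / denom)
    od = np.clip(od, 0.0, od_max)
    return OdImage(od=od, pixel_size_um=pixel_size_um)


class StainVectorEstimator(BaseEstimator):
    """Automated H&E stain-vector estimation (Macenko-style).

    Background is read from the brightest pixels; low-OD pixels and pixels
    whose OD direction lies far from the plane spanned by the two dominant
    directions (unrecognized colors) are excluded; hematoxylin and eosin are
    the extreme-angle percentiles of the remaining OD directions in that
    plane.

    Parameters
    ----------
    od_threshold : minimum OD norm for a pixel to count as stained.
    angle_percentile : percentile for the extreme-angle vectors (the
        complementary percentile gives the other stain).
    residual_fraction_max : pixels with more than this fraction of their OD
        norm outside the 2-D stain plane are discarded as unrecognized.
    background_quantile : brightness quantile defining background pixels.
    min_stained, min_background : minimum pixel counts of each kind.
    """

    def __init__(
        self,
        od_threshold: float = 0.10,
        angle_percentile: float = 1.0,
        residual_fraction_max: float = 0.25,
        background_quantile: float = 0.95,
        min_stained: int = 200,
        min_background: int = 50,
        od_max: float = 2.0,
    ):
        self.od_threshold = od_threshold
        self.angle_percentile = angle_percentile
        self.residual_fraction_max = residual_fraction_max
        self.background_quantile = background_quantile
        self.min_stained = min_stained
        self.min_background = min_background
        self.od_max = od_max

    def fit(self, image: np.ndarray, roi_mask: np.ndarray | None = None):
        image = np.asarray(image)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError("expected an RGB image of shape (H, W, 3)")
        pixels = image.reshape(-1, 3).astype(float)
        if roi_mask is not None:
            pixels = pixels[np.asarray(roi_mask).reshape(-1)]

        brightness = pixels.mean(axis=1)
        bright_cut = np.quantile(brightness, self.background_quantile)
        bg_pixels = pixels[brightness >= bright_cut]
        if len(bg_pixels) < self.min_background:
            raise ValueError("insufficient background pixels")
        background = np.median(bg_pixels, axis=0)
        background = np.maximum(background, 1.0)

        od = np.log10(background[None, :] / np.maximum(pixels, 1.0))
        od = np.clip(od, 0.0, self.od_max)
        norms = np.linalg.norm(od, axis=1)
        stained = od[norms > self.od_threshold]
        if len(stained) < self.min_stained:
            raise ValueError("insufficient stained pixels")

        # dominant 2-D plane of the OD cloud; orient the first basis vector
        # along the cloud so angles do not wrap around +/- pi
        _, _, vt = np.linalg.svd(stained, full_matrices=False)
        plane = vt[:2].copy()
        if (stained @ plane[0]).mean() < 0:
            plane[0] = -plane[0]
        proj = stained @ plane.T
        # exclude unrecognized colors: large out-of-plane residual
        in_plane_norm = np.linalg.norm(proj, axis=1)
        residual = np.linalg.norm(stained - proj @ plane, axis=1)
        ok = residual <= self.residual_fraction_max * np.maximum(in_plane_norm, 1e-12)
        proj = proj[ok]
        if len(proj) < self.min_stained:
            raise ValueError("insufficient stained pixels")

        phi = np.arctan2(proj[:, 1], proj[:, 0])
        lo, hi = np.percentile(
            phi, [self.angle_percentile, 100.0 - self.angle_percentile]
        )
        v1 = np.cos(lo) * plane[0] + np.sin(lo) * plane[1]
        v2 = np.cos(hi) * plane[0] + np.sin(hi) * plane[1]
        vectors = []
        for v in (v1, v2):
            if v.sum() < 0:
                v = -v
            v = np.clip(v, 0.0, None)
            n = np.linalg.norm(v)
            if n == 0:
                raise ValueError("degenerate stain direction")
            vectors.append(v / n)
        # hematoxylin absorbs red most strongly of the two dyes
        if vectors[0][0] >= vectors[1][0]:
            h, e = vectors
        else:
            e, h = vectors
        cos = float(np.clip(np.dot(h, e), -1.0, 1.0))
        if np.degrees(np.arccos(cos)) <= 1.0:
            raise ValueError("degenerate (collinear) stain solution")

        self.model_ = StainModel(hematoxylin=h, eosin=e, background_rgb=background)
        self.background_rgb_ = background
        self.hematoxylin_ = h
        self.eosin_ = e
        return self


def estimate_stain_vectors(
    image: np.ndarray, roi_mask: np.ndarray | None = None, **kwargs
) -> StainModel:
    """Functional wrapper over :class:`StainVectorEstimator`."""
    return StainVectorEstimator(**kwargs).fit(image, roi_mask).model_


def default_stain_model(background_rgb=(242.0, 242.0, 242.0)) -> StainModel:
    """Reference H&E model used when no per-image estimation is wanted."""
    return StainModel(
        hematoxylin=RUIFROK_HEMATOXYLIN.copy(),
        eosin=RUIFROK_EOSIN.copy(),
        background_rgb=np.asarray(background_rgb, dtype=float),
    )
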