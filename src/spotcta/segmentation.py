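"""Watershed nucleus segmentation on the hematoxylin channel.

The hematoxylin amount per pixel (OD projected on the hematoxylin stain
vector) is smoothed, thresholded, and split into nuclei by marker-controlled
watershed seeded at distance-transform peaks — the classical unsupervised
H&E cell-detection recipe. Nuclei are then grown into cell masks by
constrained dilation; cytoplasm is the cell minus the nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import expand_labels, watershed
from sklearn.base import BaseEstimator

from .stains import OdImage, StainModel


@dataclass
class NucleusSet:
    """Labeled nucleus mask plus a per-nucleus geometry table.

    Labels are contiguous positive integers; ``table`` has one row per
    nucleus: label, centroid_x_px, centroid_y_px, area_px2, perimeter_px.
    """

    labels: np.ndarray
    table: pd.DataFrame
    pixel_size_um: float

    def __len__(self) -> int:
        return len(self.table)


class NucleusSegmenter(BaseEstimator):
    """Marker-controlled watershed segmentation of nuclei.

    Parameters (micrometer units; divide by the pixel size internally):

    sigma_um : Gaussian smoothing of the hematoxylin channel before
        thresholding.
    threshold : absolute hematoxylin-OD threshold, or None for Otsu.
    min_area_um2, max_area_um2 : size gate on detected objects.
    min_peak_distance_um : minimum separation of watershed seed peaks; sets
        how close two touching nuclei can be and still be split.
    """

    def __init__(
        self,
        sigma_um: float = 1.5,
        threshold: float | None = None,
        min_area_um2: float = 5.0,
        max_area_um2: float = 400.0,
        min_peak_distance_um: float = 3.0,
    ):
        self.sigma_um = sigma_um
        self.threshold = threshold
        self.min_area_um2 = min_area_um2
        self.max_area_um2 = max_area_um2
        self.min_peak_distance_um = min_peak_distance_um

    def segment(self, od: OdImage, stains: StainModel) -> NucleusSet:
        ps = od.pixel_size_um
        hchan = od.stain_channel(stains.hematoxylin)
        if self.sigma_um > 0:
            hchan = ndi.gaussian_filter(hchan, self.sigma_um / ps)

        if self.threshold is not None:
            thr = self.threshold
        else:
            # Otsu needs signal; a blank image yields no foreground
            if hchan.max() - hchan.min() < 1e-6:
                return _empty_nucleus_set(od)
            thr = threshold_otsu(hchan)
        mask = hchan > thr
        if not mask.any():
            return _empty_nucleus_set(od)

        distance = ndi.distance_transform_edt(mask)
        min_dist_px = max(1, int(round(self.min_peak_distance_um / ps)))
        # smooth the distance map a little so plateau tops give one peak
        peaks = peak_local_max(
            ndi.gaussian_filter(distance, 1.0),
            min_distance=min_dist_px,
            labels=mask,
            exclude_border=False,
        )
        if len(peaks) == 0:
            return _empty_nucleus_set(od)
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-distance, markers=markers, mask=mask)

        min_area_px = self.min_area_um2 / ps**2
        max_area_px = self.max_area_um2 / ps**2
        rows = []
        keep_labels = []
        for rp in regionprops(labels):
            if not (min_area_px <= rp.area <= max_area_px):
                continue
            keep_labels.append(rp.label)
            rows.append(
                {
                    "centroid_x_px": rp.centroid[1],
                    "centroid_y_px": rp.centroid[0],
                    "area_px2": float(rp.area),
                    "perimeter_px": float(rp.perimeter),
                }
            )
        relabeled = np.zeros_like(labels)
        for new, old in enumerate(keep_labels, start=1):
            relabeled[labels == old] = new
        table = pd.DataFrame(
            rows, columns=["centroid_x_px", "centroid_y_px", "area_px2", "perimeter_px"]
        )
        table.insert(0, "label", np.arange(1, len(rows) + 1))
        return NucleusSet(labels=relabeled, table=table, pixel_size_um=ps)


def _empty_nucleus_set(od: OdImage) -> NucleusSet:
    return NucleusSet(
        labels=np.zeros(od.od.shape[:2], dtype=np.int32),
        table=pd.DataFrame(
            columns=["label", "centroid_x_px", "centroid_y_px", "area_px2", "perimeter_px"]
        ),
        pixel_size_um=od.pixel_size_um,
    )


def segment_nuclei(
    od: OdImage, stains: StainModel, params: NucleusSegmenter | dict | None = None
) -> NucleusSet:
    """Functional wrapper over :class:`NucleusSegmenter`."""
    if params is None:
        seg = NucleusSegmenter()
    elif isinstance(params, NucleusSegmenter):
        seg = params
    else:
        seg = NucleusSegmenter(**params)
    return seg.segment(od, stains)


def expand_cells(nuclei: NucleusSet, expansion_um: float) -> np.ndarray:
    """Grow each nucleus into a cell mask by up to ``expansion_um``.

    Expansion is distance-limited and competitive: contested pixels go to
    the nearest nucleus, so cell masks never overlap and always contain
    their nucleus. Returns a labeled cell mask aligned with the nucleus
    labels.
    """
    if expansion_um < 0:
        raise ValueError("expansion must be >= 0")
    if expansion_um == 0:
        return nuclei.labels.copy()
    return expand_labels(nuclei.labels, distance=expansion_um / nuclei.pixel_size_um)
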