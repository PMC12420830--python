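"""Per-cell morphology and stain-intensity features, plus spatial smoothing.

Feature conventions follow the common detection-table dialect of H&E cell
analysis tools: one row per cell, centroids in full-resolution pixels,
areas in square micrometers, circularity 4*pi*A/P^2 capped at 1, and
mean/max hematoxylin and eosin optical density over the nucleus, cytoplasm
and whole-cell compartments. Smoothed copies of every numeric feature are
appended for each configured radius (defaults 25 and 50 um), computed as a
Gaussian-distance-weighted mean over neighboring cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .segmentation import NucleusSet
from .stains import OdImage, StainModel

DEFAULT_SMOOTHING_RADII_UM = (25.0, 50.0)


def _region_stats(channel, labels, index):
    with np.errstate(invalid="ignore"):  # empty compartments divide by zero
        mean = ndi.mean(channel, labels=labels, index=index)
        mx = ndi.maximum(channel, labels=labels, index=index)
    return np.asarray(mean, dtype=float), np.asarray(mx, dtype=float)


def compute_features(
    nuclei: NucleusSet,
    cells: np.ndarray,
    od: OdImage,
    stains: StainModel,
    pixel_size_um: float | None = None,
) -> pd.DataFrame:
    """Build the cell feature table from nucleus/cell masks and OD image.

    Cells whose cytoplasm compartment is empty keep their row with the
    cytoplasm features set to NaN.
    """
    ps = pixel_size_um if pixel_size_um is not None else od.pixel_size_um
    table = nuclei.table
    if len(table) == 0:
        cols = ["cell_id", "centroid_x_px", "centroid_y_px"] + _feature_names()
        return pd.DataFrame(columns=cols)
    index = table["label"].to_numpy()

    hchan = od.stain_channel(stains.hematoxylin)
    echan = od.stain_channel(stains.eosin)
    cytoplasm = np.where(nuclei.labels == 0, cells, 0)

    nuc_area_px = table["area_px2"].to_numpy()
    cell_area_px = ndi.sum_labels(np.ones_like(cells, dtype=float), labels=cells, index=index)
    cyto_area_px = cell_area_px - nuc_area_px

    perimeter = table["perimeter_px"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        circ = 4.0 * np.pi * nuc_area_px / perimeter**2
    circ = np.clip(circ, None, 1.0)

    out = pd.DataFrame(
        {
            "cell_id": index,
            "centroid_x_px": table["centroid_x_px"].to_numpy(),
            "centroid_y_px": table["centroid_y_px"].to_numpy(),
            "nucleus_area_um2": nuc_area_px * ps**2,
            "cell_area_um2": cell_area_px * ps**2,
            "circularity": circ,
        }
    )
    for chan_name, chan in (("h_od", hchan), ("e_od", echan)):
        for comp_name, comp_labels in (
            ("nucleus", nuclei.labels),
            ("cytoplasm", cytoplasm),
            ("cell", cells),
        ):
            mean, mx = _region_stats(chan, comp_labels, index)
            if comp_name == "cytoplasm":
                empty = cyto_area_px <= 0
                mean[empty] = np.nan
                mx[empty] = np.nan
            out[f"{comp_name}_{chan_name}_mean"] = mean
            out[f"{comp_name}_{chan_name}_max"] = mx
    return out


def _feature_names() -> list[str]:
    names = ["nucleus_area_um2", "cell_area_um2", "circularity"]
    for chan in ("h_od", "e_od"):
        for comp in ("nucleus", "cytoplasm", "cell"):
            names += [f"{comp}_{chan}_mean", f"{comp}_{chan}_max"]
    return names


def smooth_features(
    table: pd.DataFrame,
    radius: float,
    pixel_size_um: float | None = None,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Append Gaussian-distance-weighted smoothed copies of each feature.

    For each cell, each numeric feature is averaged over all cells within
    ``2 * radius`` with weight exp(-d^2 / (2 sigma^2)), sigma = radius / 2;
    the cell itself contributes with weight 1. ``radius`` is in micrometers
    when ``pixel_size_um`` is given, otherwise in the centroid units (pixel
    mode for images without physical metadata). Original columns are kept;
    smoothed ones get a ``_smoothed_<radius>`` suffix.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    out = table.copy()
    if len(table) == 0:
        return out
    coords = table[["centroid_x_px", "centroid_y_px"]].to_numpy(dtype=float)
    if pixel_size_um is not None:
        coords = coords * pixel_size_um
    if columns is None:
        skip = {"cell_id", "centroid_x_px", "centroid_y_px"}
        columns = [
            c
            for c in table.columns
            if c not in skip
            and pd.api.types.is_numeric_dtype(table[c])
            and "_smoothed_" not in c
        ]
    sigma = radius / 2.0
    support = 2.0 * radius
    tree = cKDTree(coords)
    pairs = tree.query_pairs(support, output_type="ndarray")
    n = len(table)
    values = table[columns].to_numpy(dtype=float)
    # weight matrix rows: self weight 1 plus symmetric neighbor weights
    wsum = np.ones(n)
    vsum = np.where(np.isnan(values), 0.0, values).copy()
    valid = (~np.isnan(values)).astype(float)
    wsum_mat = valid.copy()  # per-column weight sums (NaN-aware)
    if len(pairs):
        d2 = np.sum((coords[pairs[:, 0]] - coords[pairs[:, 1]]) ** 2, axis=1)
        w = np.exp(-d2 / (2.0 * sigma**2))
        for i, j, wij in zip(pairs[:, 0], pairs[:, 1], w):
            vi, vj = values[i], values[j]
            mi, mj = ~np.isnan(vi), ~np.isnan(vj)
            vsum[i, mj] += wij * vj[mj]
            wsum_mat[i, mj] += wij
            vsum[j, mi] += wij * vi[mi]
            wsum_mat[j, mi] += wij
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = vsum / wsum_mat
    smoothed[valid == 0] = np.nan  # cell's own value missing -> stays missing
    label = int(radius) if float(radius).is_integer() else radius
    for k, c in enumerate(columns):
        out[f"{c}_smoothed_{label}"] = smoothed[:, k]
    return out


def add_smoothed_features(
    table: pd.DataFrame,
    radii=DEFAULT_SMOOTHING_RADII_UM,
    pixel_size_um: float | None = None,
) -> pd.DataFrame:
    """Run :func:`smooth_features` once per configured radius."""
    for r in radii:
        table = smooth_features(table, r, pixel_size_um=pixel_size_um)
    return table
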