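"""Cell-to-spot alignment: geometry, square-window assignment, composition.

Visium spot coordinates often live in the frame of a down-sized registration
image. The transform to full-resolution pixels is a uniform scale (s =
registration height / full height) plus, for pipelines that registered a
y-flipped image, reflection of y about the full image height. Cells are
assigned to a spot when their centroid falls inside the square window
centered on the spot (center +/- radius on both axes); per-spot class counts
and fractions form the pipeline's central exchange object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

CLASSES = ("tumor", "immune", "stroma")


@dataclass
class ImageGeometry:
    full_width_px: float
    full_height_px: float
    registered_height_px: float | None = None
    scale: float | None = None
    y_flip: bool = True

    def __post_init__(self):
        if self.scale is None:
            if self.registered_height_px is None:
                raise ValueError("give either scale or registered_height_px")
            self.scale = compute_scale_factor(self.full_height_px, self.registered_height_px)
        if not (0 < self.scale <= 1):
            raise ValueError("scale factor must lie in (0, 1]")


@dataclass
class SpotGrid:
    """Spot table (barcode, array_row, array_col, x_px, y_px, radius_px,
    in_tissue) tagged with the coordinate frame it lives in."""

    table: pd.DataFrame
    frame: str = "registration"

    def __post_init__(self):
        if self.table["barcode"].duplicated().any():
            raise ValueError("spot barcodes must be unique")
        if (self.table["radius_px"] <= 0).any():
            raise ValueError("spot radius must be > 0")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SpotComposition:
    """Per-spot tumor/immune/stroma counts and fractions.

    ``table`` columns: barcode, n_tumor, n_immune, n_stroma, n_total,
    frac_tumor, frac_immune, frac_stroma (fractions NaN when n_total = 0).
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpotComposition":
        return cls(table=pd.read_csv(path))


def compute_scale_factor(full_height_px: float, registered_height_px: float) -> float:
    """s = registered height / full height (the "30p image" convention)."""
    if full_height_px <= 0 or registered_height_px <= 0:
        raise ValueError("image heights must be > 0")
    if registered_height_px > full_height_px:
        raise ValueError("registered image cannot be taller than the full image")
    return registered_height_px / full_height_px


def registered_to_fullres(grid: SpotGrid, geom: ImageGeometry) -> SpotGrid:
    """Scale (and optionally y-flip) spot coordinates into the full-res frame.

    Spots whose transformed center falls outside the image are kept and
    flagged in an ``out_of_bounds`` column, with a warning.
    """
    if grid.frame != "registration":
        raise ValueError(f"grid is in frame '{grid.frame}', expected 'registration'")
    s = geom.scale
    t = grid.table.copy()
    t["x_px"] = t["x_px"] / s
    y = t["y_px"] / s
    if geom.y_flip:
        y = geom.full_height_px - y
    t["y_px"] = y
    t["radius_px"] = t["radius_px"] / s
    oob = (
        (t["x_px"] < 0)
        | (t["x_px"] > geom.full_width_px)
        | (t["y_px"] < 0)
        | (t["y_px"] > geom.full_height_px)
    )
    t["out_of_bounds"] = oob.to_numpy()
    if oob.any():
        warnings.warn(
            f"{int(oob.sum())} spot center(s) transformed outside the image bounds",
            stacklevel=2,
        )
    return SpotGrid(table=t, frame="fullres")


def fullres_to_registered(grid: SpotGrid, geom: ImageGeometry) -> SpotGrid:
    """Exact inverse of :func:`registered_to_fullres`."""
    if grid.frame != "fullres":
        raise ValueError(f"grid is in frame '{grid.frame}', expected 'fullres'")
    s = geom.scale
    t = grid.table.copy()
    y = t["y_px"]
    if geom.y_flip:
        y = geom.full_height_px - y
    t["x_px"] = t["x_px"] * s
    t["y_px"] = y * s
    t["radius_px"] = t["radius_px"] * s
    t = t.drop(columns=["out_of_bounds"], errors="ignore")
    return SpotGrid(table=t, frame="registration")


def assign_cells_to_spots(cells: pd.DataFrame, grid: SpotGrid) -> pd.Series:
    """Assign each cell to the spot whose square window contains it.

    A cell belongs to a spot iff |x_cell - x_spot| <= r and
    |y_cell - y_spot| <= r (closed inequalities). If several squares contain
    the cell it goes to the spot with the nearest center (Euclidean), ties
    broken by barcode sort order. Returns a Series indexed by cell_id with
    the barcode, or NA for unassigned cells.
    """
    if grid.frame != "fullres" and cells.attrs.get("frame", "fullres") != grid.frame:
        raise ValueError(
            f"frame mismatch: cells in '{cells.attrs.get('frame')}', grid in '{grid.frame}'"
        )
    cell_ids = cells["cell_id"].to_numpy()
    xy = cells[["centroid_x_px", "centroid_y_px"]].to_numpy(dtype=float)
    spots = grid.table
    result = pd.Series(pd.NA, index=pd.Index(cell_ids, name="cell_id"), dtype="object")
    if len(xy) == 0 or len(spots) == 0:
        return result
    best_dist = np.full(len(xy), np.inf)
    best_barcode = np.full(len(xy), None, dtype=object)
    tree = cKDTree(xy)
    # iterate spots in barcode sort order so strict '<' keeps the first
    # (smallest) barcode on exact distance ties
    for row in spots.sort_values("barcode").itertuples():
        r = row.radius_px
        center = np.array([row.x_px, row.y_px])
        # Chebyshev ball == the square window
        candidates = tree.query_ball_point(center, r, p=np.inf)
        if not candidates:
            continue
        idx = np.asarray(candidates)
        d = np.sqrt(np.sum((xy[idx] - center) ** 2, axis=1))
        better = d < best_dist[idx]
        upd = idx[better]
        best_dist[upd] = d[better]
        best_barcode[upd] = row.barcode
    assigned = best_barcode != None  # noqa: E711
    result.iloc[np.flatnonzero(assigned)] = best_barcode[assigned]
    return result


def compose_spots(
    assignment: pd.Series,
    labels: pd.Series,
    barcodes=None,
    classes=CLASSES,
) -> SpotComposition:
    """Count cell classes per spot and derive fractions.

    ``assignment`` maps cell_id -> barcode (NA = unassigned), ``labels``
    maps cell_id -> class. ``barcodes`` fixes the output spot universe
    (default: barcodes present in the assignment). Spots with no cells get
    zero counts and missing fractions.
    """
    labels = labels.reindex(assignment.index)
    assigned = assignment.notna()
    if labels[assigned].isna().any():
        bad = assignment.index[assigned & labels.isna()]
        raise ValueError(f"assigned cells without a class label: {list(bad[:5])}")
    unknown = set(labels[assigned].unique()) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the class set: {sorted(unknown)}")
    if barcodes is None:
        barcodes = sorted(assignment.dropna().unique())
    counts = pd.DataFrame(0, index=pd.Index(barcodes, name="barcode"), columns=list(classes))
    grouped = (
        pd.DataFrame({"barcode": assignment[assigned], "cls": labels[assigned]})
        .groupby(["barcode", "cls"], observed=True)
        .size()
    )
    for (bc, cls), n in grouped.items():
        if bc in counts.index:
            counts.loc[bc, cls] = n
    table = pd.DataFrame({"barcode": counts.index})
    for c in classes:
        table[f"n_{c}"] = counts[c].to_numpy()
    table["n_total"] = table[[f"n_{c}" for c in classes]].sum(axis=1)
    for c in classes:
        with np.errstate(invalid="ignore", divide="ignore"):
            table[f"frac_{c}"] = np.where(
                table["n_total"] > 0, table[f"n_{c}"] / table["n_total"], np.nan
            )
    return SpotComposition(table=table)


@dataclass
class QcThresholds:
    """Spot quality-control gates (strict comparisons, per the defaults:
    removed iff detected genes < 500 OR mito fraction > 0.25 OR hemoglobin
    fraction > 0.20)."""

    min_detected_genes: int = 500
    max_mito_fraction: float = 0.25
    max_hemoglobin_fraction: float = 0.20
    mito_pattern: str = r"^(?:MT-|mt-)"
    hemoglobin_pattern: str = r"^HB[^P]"

    def __post_init__(self):
        for f in (self.max_mito_fraction, self.max_hemoglobin_fraction):
            if not (0 <= f <= 1):
                raise ValueError("QC fractions must lie in [0, 1]")


def qc_filter_spots(
    counts: pd.DataFrame, thresholds: QcThresholds | None = None
) -> tuple[list, pd.DataFrame]:
    """Filter low-quality spots from a barcode x gene count table.

    Returns (kept barcodes, per-spot report) where the report lists
    detected genes, mito/hemoglobin fractions, pass flag and removal
    reasons.
    """
    thr = thresholds or QcThresholds()
    if counts.index.duplicated().any():
        raise ValueError("barcodes must be unique")
    genes = counts.columns.astype(str)
    mito = genes.str.contains(thr.mito_pattern, regex=True)
    hemo = genes.str.contains(thr.hemoglobin_pattern, regex=True)
    mat = counts.to_numpy(dtype=float)
    total = mat.sum(axis=1)
    detected = (mat > 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mat[:, mito].sum(axis=1) / total, np.nan)
        hemo_frac = np.where(total > 0, mat[:, hemo].sum(axis=1) / total, np.nan)
    reasons = []
    for i in range(len(counts)):
        r = []
        if total[i] == 0:
            r.append("no counts")
        else:
            if detected[i] < thr.min_detected_genes:
                r.append(f"detected genes < {thr.min_detected_genes}")
            if mito_frac[i] > thr.max_mito_fraction:
                r.append(f"mito fraction > {thr.max_mito_fraction}")
            if hemo_frac[i] > thr.max_hemoglobin_fraction:
                r.append(f"hemoglobin fraction > {thr.max_hemoglobin_fraction}")
        reasons.append("; ".join(r))
    report = pd.DataFrame(
        {
            "barcode": counts.index,
            "total_umis": total,
            "detected_genes": detected,
            "mito_fraction": mito_frac,
            "hemoglobin_fraction": hemo_frac,
            "qc_pass": [r == "" for r in reasons],
            "reason": reasons,
        }
    )
    kept = list(report.loc[report["qc_pass"], "barcode"])
    return kept, report


def spot_density(comp: SpotComposition, cluster_labels: pd.Series) -> pd.Series:
    """Cells per spot for each cluster: sum of cell totals / member spots."""
    t = comp.table.set_index("barcode")
    missing = cluster_labels.index.difference(t.index)
    if len(missing):
        raise ValueError(f"labeled spots missing from composition: {list(missing[:5])}")
    groups = cluster_labels.groupby(cluster_labels)
    out = {}
    for cluster, members in groups.groups.items():
        n_spots = len(members)
        out[cluster] = t.loc[list(members), "n_total"].sum() / n_spots if n_spots else np.nan
    return pd.Series(out, name="cells_per_spot").sort_index()
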