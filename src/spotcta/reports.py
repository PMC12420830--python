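"""Downstream integrations: subtype spot filtering, group summaries,
pseudo-bulk aggregation, per-spot clone reports and transcript subsampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spots import CLASSES, SpotComposition, spot_density


@dataclass
class SubtypeInclusion:
    """Inclusion rules for molecular subtype calling on spots: QC pass,
    epithelial (deconvolved cancer + normal epithelial) fraction of at
    least ``min_epithelial_fraction`` and at least ``min_tumor_cells``
    annotated tumor cells."""

    min_epithelial_fraction: float = 0.20
    min_tumor_cells: int = 1
    require_qc_pass: bool = True

    def __post_init__(self):
        if not (0 <= self.min_epithelial_fraction <= 1):
            raise ValueError("epithelial fraction must lie in [0, 1]")
        if self.min_tumor_cells < 0:
            raise ValueError("minimum tumor count must be >= 0")


def filter_spots_for_subtyping(
    comp,
    epithelial_fraction: pd.Series,
    qc_pass=None,
    rules: SubtypeInclusion | None = None,
) -> tuple[list, pd.DataFrame]:
    """Spots eligible for subtype estimation, plus a per-spot reason table."""
    rules = rules or SubtypeInclusion()
    t = (comp.table if hasattr(comp, "table") else comp).set_index("barcode")
    qc = set(qc_pass) if qc_pass is not None else None
    rows = []
    for bc in t.index:
        reasons = []
        if rules.require_qc_pass and qc is not None and bc not in qc:
            reasons.append("failed QC")
        if bc not in epithelial_fraction.index or pd.isna(epithelial_fraction.get(bc)):
            reasons.append("no epithelial fraction")
        elif epithelial_fraction[bc] < rules.min_epithelial_fraction:
            reasons.append(f"epithelial < {rules.min_epithelial_fraction}")
        if t.loc[bc, "n_tumor"] < rules.min_tumor_cells:
            reasons.append(f"tumor cells < {rules.min_tumor_cells}")
        rows.append({"barcode": bc, "eligible": not reasons, "reason": "; ".join(reasons)})
    report = pd.DataFrame(rows)
    return list(report.loc[report["eligible"], "barcode"]), report


def summarize_composition_by_group(
    comp: SpotComposition, labels: pd.Series
) -> pd.DataFrame:
    """Pooled class percentages, spot count and cell density per group.

    Percentages pool counts (sum of class counts / sum of totals), not
    mean per-spot fractions; groups with zero cells get missing
    percentages.
    """
    t = (comp.table if hasattr(comp, "table") else comp).set_index("barcode")
    labels = labels[labels.index.isin(t.index)]
    if labels.empty:
        raise ValueError("no labeled spots present in the composition")
    density = spot_density(comp if hasattr(comp, "table") else SpotComposition(t.reset_index()), labels)
    rows = []
    for group, members in labels.groupby(labels).groups.items():
        sub = t.loc[list(members)]
        total = sub["n_total"].sum()
        row = {"group": group, "n_spots": len(sub), "n_cells": int(total)}
        for c in CLASSES:
            row[f"pct_{c}"] = 100.0 * sub[f"n_{c}"].sum() / total if total > 0 else np.nan
        row["cells_per_spot"] = density[group]
        rows.append(row)
    return pd.DataFrame(rows).sort_values("group").reset_index(drop=True)


def mean_fraction_by_group(comp: SpotComposition, labels: pd.Series) -> pd.DataFrame:
    """Alternative summary: mean of per-spot fractions within each group."""
    t = (comp.table if hasattr(comp, "table") else comp).set_index("barcode")
    labels = labels[labels.index.isin(t.index)]
    out = []
    for group, members in labels.groupby(labels).groups.items():
        sub = t.loc[list(members)]
        row = {"group": group, "n_spots": len(sub)}
        for c in CLASSES:
            row[f"mean_frac_{c}"] = sub[f"frac_{c}"].mean()
        out.append(row)
    return pd.DataFrame(out).sort_values("group").reset_index(drop=True)


def pseudobulk(counts: pd.DataFrame, labels: pd.Series, stage: str = "log") -> pd.DataFrame:
    """Aggregate spot counts per group: raw sums -> CPM -> log2(x+1).

    Returns a gene x group table at the requested stage ("raw-sum", "cpm"
    or "log"). All-zero group columns are left NaN at the CPM/log stages
    and reported with a warning.
    """
    if stage not in {"raw-sum", "cpm", "log"}:
        raise ValueError("stage must be raw-sum, cpm, or log")
    labels = labels[labels.index.isin(counts.index)]
    if labels.empty:
        raise ValueError("labels cover no spot in the count matrix")
    sums = {}
    for group, members in labels.groupby(labels).groups.items():
        sums[group] = counts.loc[list(members)].sum(axis=0)
    raw = pd.DataFrame(sums)
    raw.index.name = "gene"
    if stage == "raw-sum":
        return raw
    totals = raw.sum(axis=0)
    zero = totals[totals == 0].index
    if len(zero):
        warnings.warn(f"groups with zero total counts: {list(zero)}", stacklevel=2)
    cpm = raw / totals.replace(0, np.nan) * 1e6
    if stage == "cpm":
        return cpm
    return np.log2(cpm + 1.0)


def clone_spot_report(
    spot_ids,
    comp: SpotComposition,
    fine: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-spot report for a set of spots of interest (e.g. one clone).

    Each row: annotation class counts and fractions, majority class by
    count (ties broken alphabetically), and the spot's full fine-type
    deconvolution fractions when available.
    """
    t = (comp.table if hasattr(comp, "table") else comp).set_index("barcode")
    unknown = [s for s in spot_ids if s not in t.index]
    if unknown:
        raise ValueError(f"unknown spot ids: {unknown}")
    rows = []
    for bc in spot_ids:
        spot = t.loc[bc]
        counts = {c: int(spot[f"n_{c}"]) for c in CLASSES}
        majority = min(
            counts, key=lambda c: (-counts[c], c)
        ) if spot["n_total"] > 0 else pd.NA
        row = {"barcode": bc, **{f"n_{c}": counts[c] for c in CLASSES}}
        row["n_total"] = int(spot["n_total"])
        for c in CLASSES:
            row[f"frac_{c}"] = spot[f"frac_{c}"]
        row["majority_class"] = majority
        if fine is not None and bc in fine.index:
            for ft in fine.columns:
                row[f"deconv:{ft}"] = fine.loc[bc, ft]
        rows.append(row)
    return pd.DataFrame(rows)


def plot_spot_crop(
    image: np.ndarray,
    center_xy,
    radius_px: float,
    cells: pd.DataFrame | None = None,
    pad: float = 1.5,
    ax=None,
):
    """Magnified crop of one spot with its circle and per-cell class colors."""
    import matplotlib.patches as mpatches
    import matplotlib.pyplot as plt

    colors = {"tumor": "red", "immune": "gold", "stroma": "royalblue"}
    cx, cy = center_xy
    half = radius_px * pad
    x0, x1 = int(max(0, cx - half)), int(min(image.shape[1], cx + half))
    y0, y1 = int(max(0, cy - half)), int(min(image.shape[0], cy + half))
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(image[y0:y1, x0:x1], extent=(x0, x1, y1, y0))
    ax.add_patch(
        mpatches.Circle((cx, cy), radius_px, fill=False, color="black", lw=1.5)
    )
    if cells is not None:
        for row in cells.itertuples():
            if x0 <= row.centroid_x_px <= x1 and y0 <= row.centroid_y_px <= y1:
                ax.plot(
                    row.centroid_x_px,
                    row.centroid_y_px,
                    "o",
                    ms=4,
                    color=colors.get(getattr(row, "cell_class", None), "gray"),
                )
    ax.set_xticks([])
    ax.set_yticks([])
    return ax


def transcript_match_subsample(
    points_per_marker: dict[str, np.ndarray],
    fraction_per_marker: dict[str, float],
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Subsample transcript point sets to visually match annotated cell
    densities on image-based platforms.

    Draws round(fraction * n) points per marker uniformly without
    replacement, keeping the original point order; deterministic under the
    seed.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for marker, points in points_per_marker.items():
        frac = fraction_per_marker[marker]
        if not (0 < frac <= 1):
            raise ValueError(f"fraction for '{marker}' must lie in (0, 1]")
        points = np.asarray(points)
        n = len(points)
        if n == 0:
            warnings.warn(f"marker '{marker}' has no points", stacklevel=2)
            out[marker] = points
            continue
        k = int(round(frac * n))
        chosen = np.sort(rng.choice(n, size=k, replace=False))
        out[marker] = points[chosen]
    return out
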