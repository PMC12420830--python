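"""Readers and writers for the pipeline's exchange formats.

Covers the Space Ranger spot-geometry dialects (`tissue_positions_list.csv`
headerless and headered, `scalefactors_json.json`), 10x-style MTX count
triplets, the QuPath detection-export TSV dialect for cell tables, and the
gene genomic-order TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .spots import SpotGrid

TISSUE_POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


# --------------------------------------------------------------------- images


def read_image(path, pixel_size_um: float | None = None):
    """Read TIFF/PNG/JPEG as RGB; pixel size from TIFF resolution tags
    unless overridden (an explicit value always wins)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            image = tf.asarray()
            if pixel_size_um is None:
                page = tf.pages[0]
                res = page.tags.get("XResolution")
                unit = page.tags.get("ResolutionUnit")
                if res is not None and unit is not None:
                    num, den = res.value
                    per_unit = num / den
                    unit_um = {2: 25400.0, 3: 10000.0}.get(getattr(unit.value, "value", unit.value))
                    if unit_um and per_unit > 0:
                        pixel_size_um = unit_um / per_unit
    else:
        from PIL import Image

        image = np.asarray(Image.open(path).convert("RGB"))
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    return image, pixel_size_um


def write_image(path, image: np.ndarray, pixel_size_um: float | None = None) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        kwargs = {}
        if pixel_size_um:
            per_cm = 10000.0 / pixel_size_um
            kwargs = {"resolution": (per_cm, per_cm), "resolutionunit": "CENTIMETER"}
        tifffile.imwrite(path, image, **kwargs)
    else:
        from PIL import Image

        Image.fromarray(image).save(path)


# --------------------------------------------------- Space Ranger spot files


def write_spaceranger(grid: SpotGrid, outdir, pixel_size_um: float, hires_scalef: float = 1.0) -> None:
    """Write `tissue_positions_list.csv` (headerless dialect) and
    `scalefactors_json.json` for a spot grid in the full-resolution frame."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = grid.table
    pd.DataFrame(
        {
            "barcode": t["barcode"],
            "in_tissue": t["in_tissue"],
            "array_row": t["array_row"],
            "array_col": t["array_col"],
            "pxl_row_in_fullres": t["y_px"],
            "pxl_col_in_fullres": t["x_px"],
        }
    ).to_csv(outdir / "tissue_positions_list.csv", header=False, index=False)
    scalefactors = {
        "spot_diameter_fullres": float(2.0 * t["radius_px"].iloc[0]),
        "tissue_hires_scalef": hires_scalef,
    }
    (outdir / "scalefactors_json.json").write_text(json.dumps(scalefactors))


def read_spaceranger(indir) -> SpotGrid:
    """Read the Space Ranger spot geometry (both tissue-positions dialects)."""
    indir = Path(indir)
    pos_path = indir / "tissue_positions_list.csv"
    if not pos_path.exists():
        pos_path = indir / "tissue_positions.csv"
    first = pos_path.read_text().splitlines()[0]
    has_header = "barcode" in first.lower()
    df = pd.read_csv(
        pos_path, header=0 if has_header else None,
        names=None if has_header else TISSUE_POSITION_COLUMNS,
    )
    df.columns = [c.lower() for c in df.columns]
    scalefactors = json.loads((indir / "scalefactors_json.json").read_text())
    radius = scalefactors["spot_diameter_fullres"] / 2.0
    table = pd.DataFrame(
        {
            "barcode": df["barcode"],
            "array_row": df["array_row"],
            "array_col": df["array_col"],
            "x_px": df["pxl_col_in_fullres"].astype(float),
            "y_px": df["pxl_row_in_fullres"].astype(float),
            "radius_px": radius,
            "in_tissue": df["in_tissue"],
        }
    )
    return SpotGrid(table=table, frame="fullres")


# ----------------------------------------------------------------- MTX counts


def write_mtx(counts: pd.DataFrame, outdir) -> None:
    """Write a barcode x gene count table as a 10x-style MTX triplet
    (matrix.mtx genes x barcodes, features.tsv, barcodes.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = csr_matrix(counts.to_numpy().T)
    mmwrite(str(outdir / "matrix.mtx"), mat)
    pd.DataFrame(
        {"id": counts.columns, "name": counts.columns, "type": "Gene Expression"}
    ).to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(counts.index).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)


def read_mtx(indir) -> pd.DataFrame:
    """Read a 10x-style MTX triplet into a barcode x gene DataFrame."""
    indir = Path(indir)
    mat = mmread(str(indir / "matrix.mtx")).tocsr()
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    genes = features[1] if features.shape[1] > 1 else features[0]
    return pd.DataFrame(
        mat.T.toarray(), index=pd.Index(barcodes, name="barcode"), columns=list(genes)
    )


# -------------------------------------------------------- QuPath cell tables

_QUPATH_RENAME = {
    "centroid_x_px": "Centroid X px",
    "centroid_y_px": "Centroid Y px",
}


def write_cell_table(table: pd.DataFrame, path, pixel_size_um: float | None = None) -> None:
    """Write a cell feature table in the QuPath detection-export dialect:
    tab-separated, centroids in micrometers when the pixel size is known
    ("Centroid X µm"), a "Class" column when labels are present."""
    out = table.copy()
    if pixel_size_um is not None:
        out["Centroid X µm"] = out.pop("centroid_x_px") * pixel_size_um
        out["Centroid Y µm"] = out.pop("centroid_y_px") * pixel_size_um
    else:
        out = out.rename(columns=_QUPATH_RENAME)
    if "cell_class" in out.columns:
        out = out.rename(columns={"cell_class": "Class"})
    if "predicted_class" in out.columns:
        out = out.rename(columns={"predicted_class": "Class"})
    out.to_csv(path, sep="\t", index=False)


def read_cell_table(path, pixel_size_um: float | None = None) -> pd.DataFrame:
    """Read a QuPath-dialect detection TSV back into pipeline columns.

    Micrometer centroid columns are converted to full-resolution pixels
    using ``pixel_size_um`` (required when only µm columns are present).
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.strip(): c for c in df.columns}
    um_x = next((cols[c] for c in cols if c.lower().startswith("centroid x") and "m" in c.lower().split()[-1]), None)
    out = pd.DataFrame()
    if "Centroid X px" in cols:
        out["centroid_x_px"] = df[cols["Centroid X px"]]
        out["centroid_y_px"] = df[cols["Centroid Y px"]]
    elif um_x is not None:
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required to convert µm centroids to pixels")
        um_y = next(cols[c] for c in cols if c.lower().startswith("centroid y"))
        out["centroid_x_px"] = df[um_x] / pixel_size_um
        out["centroid_y_px"] = df[um_y] / pixel_size_um
    else:
        raise ValueError("no centroid columns found")
    for c in df.columns:
        if c in {um_x, "Centroid X px", "Centroid Y px"} or c.lower().startswith("centroid y"):
            continue
        name = "cell_class" if c.strip() == "Class" else c
        out[name] = df[c]
    if "cell_id" not in out.columns:
        out.insert(0, "cell_id", np.arange(len(out)))
    return out


# ------------------------------------------------------------------- various


def write_gene_order(gene_order: pd.DataFrame, path) -> None:
    gene_order[["gene", "chrom", "start", "stop"]].to_csv(path, sep="\t", index=False)


def read_barcode_labels(path, label_column: str | None = None) -> pd.Series:
    """Read a (barcode, label) CSV into a Series indexed by barcode."""
    df = pd.read_csv(path)
    if label_column is None:
        label_column = df.columns[1]
    return pd.Series(df[label_column].to_numpy(), index=df[df.columns[0]], name=label_column)
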