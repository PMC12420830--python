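"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators: (1) H&E-like scenes rendered by Beer-Lambert mixing of
known hematoxylin/eosin vectors, so the optical-density math downstream is
exactly invertible; (2) hexagonally packed Visium-style spot lattices;
(3) fine-grained deconvolution fraction matrices whose aggregation matches a
known tumor/immune/stroma composition up to Dirichlet noise; (4) clone-
structured spot x gene count matrices with segmental copy-number gains and
losses. All generators are pure functions of (params, seed).

These emulate the geometry and signal structure of real Visium + H&E data,
not its appearance: nuclei are blurred ellipses with an eosin cytoplasm
halo, no staining artifacts, folds or focus gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .stains import RUIFROK_EOSIN, RUIFROK_HEMATOXYLIN

CLASSES = ("tumor", "immune", "stroma")

PLACEMENT_ATTEMPT_CAP = 100_000


@dataclass(frozen=True)
class ClassAppearance:
    """Rendering parameters for one cell class.

    Radii are nucleus equivalent radii in micrometers (mean, sd);
    eccentricity and stain intensities are sampled uniformly in the given
    ranges. Eosin intensity controls the cytoplasm halo darkness, the main
    morphology-independent discriminator between classes.
    """

    radius_um: tuple[float, float]
    eccentricity: tuple[float, float]
    hematoxylin: tuple[float, float]
    eosin: tuple[float, float]


DEFAULT_APPEARANCE: dict[str, ClassAppearance] = {
    # large round weakly eosinophilic-cytoplasm nuclei
    "tumor": ClassAppearance((5.0, 0.35), (0.0, 0.3), (0.75, 0.95), (0.55, 0.70)),
    # small dense round lymphocyte-like nuclei, little cytoplasm
    "immune": ClassAppearance((2.5, 0.20), (0.0, 0.3), (0.85, 1.05), (0.05, 0.15)),
    # elongated fibroblast-like nuclei in eosinophilic matrix
    "stroma": ClassAppearance((3.5, 0.25), (0.75, 0.92), (0.70, 0.90), (0.30, 0.42)),
}


@dataclass
class SceneParams:
    width_px: int = 1024
    height_px: int = 1024
    pixel_size_um: float = 0.5
    background_rgb: tuple[float, float, float] = (242.0, 242.0, 242.0)
    counts: dict = field(default_factory=lambda: {"tumor": 60, "immune": 60, "stroma": 60})
    appearance: dict = field(default_factory=lambda: dict(DEFAULT_APPEARANCE))
    min_spacing_um: float = 14.0
    halo_um: float = 2.5
    blur_um: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")
        if self.min_spacing_um < 0:
            raise ValueError("minimum spacing must be >= 0")
        unknown = set(self.counts) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes {sorted(unknown)}; expected {CLASSES}")
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("per-class counts must be >= 0")


@dataclass
class SyntheticScene:
    image: np.ndarray  # uint8 RGB
    truth: pd.DataFrame  # cell_id, centroid_x_px, centroid_y_px, cell_class, nucleus_area_um2
    params: SceneParams


class PackingInfeasibleError(RuntimeError):
    pass


def _place_centroids(params: SceneParams, rng: np.random.Generator) -> pd.DataFrame:
    """Rejection-sample centroids with a hard minimum spacing."""
    spacing_px = params.min_spacing_um / params.pixel_size_um
    margin = {
        c: (params.appearance[c].radius_um[0] * 2 + params.halo_um)
        / params.pixel_size_um
        for c in params.counts
    }
    placed_xy: list[tuple[float, float]] = []
    rows = []
    attempts = 0
    cell_id = 0
    order = [c for c in CLASSES if params.counts.get(c, 0) > 0]
    for cls in order:
        for _ in range(params.counts[cls]):
            m = margin[cls]
            while True:
                attempts += 1
                if attempts > PLACEMENT_ATTEMPT_CAP:
                    dens = max(params.counts, key=lambda c: params.counts[c])
                    raise PackingInfeasibleError(
                        f"could not place {params.counts[cls]} '{cls}' cells at "
                        f"{params.min_spacing_um} um spacing (densest class: {dens})"
                    )
                x = rng.uniform(m, params.width_px - m)
                y = rng.uniform(m, params.height_px - m)
                if all(
                    (x - px) ** 2 + (y - py) ** 2 >= spacing_px**2
                    for px, py in placed_xy
                ):
                    break
            placed_xy.append((x, y))
            rows.append({"cell_id": cell_id, "centroid_x_px": x, "centroid_y_px": y, "cell_class": cls})
            cell_id += 1
    return pd.DataFrame(rows, columns=["cell_id", "centroid_x_px", "centroid_y_px", "cell_class"])


def _paint_ellipse(canvas, cx, cy, a_px, b_px, theta, value):
    """Add `value` inside the rotated ellipse; bounding-box local update."""
    h, w = canvas.shape
    r = int(np.ceil(max(a_px, b_px))) + 2
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    canvas[y0:y1, x0:x1][inside] += value


def generate_he_scene(params: SceneParams) -> SyntheticScene:
    """Render an H&E-like scene plus its ground-truth cell table.

    Per-pixel hematoxylin and eosin concentration fields are accumulated
    from per-cell ellipses (nucleus: hematoxylin; cytoplasm halo: eosin),
    Gaussian-blurred, converted to OD along the reference stain vectors and
    exponentiated back to RGB against the background white point.
    """
    rng = np.random.default_rng(params.seed)
    truth = _place_centroids(params, rng)

    h_field = np.zeros((params.height_px, params.width_px), dtype=float)
    e_field = np.zeros_like(h_field)
    ps = params.pixel_size_um
    areas = []
    for row in truth.itertuples():
        app = params.appearance[row.cell_class]
        r_um = max(0.5, rng.normal(*app.radius_um))
        ecc = rng.uniform(*app.eccentricity)
        # semi-axes preserving pi*a*b = pi*r^2 at the given eccentricity
        ratio = np.sqrt(max(1e-6, 1.0 - ecc**2))
        a_um = r_um / np.sqrt(ratio)
        b_um = r_um * np.sqrt(ratio)
        theta = rng.uniform(0, np.pi)
        h_int = rng.uniform(*app.hematoxylin)
        e_int = rng.uniform(*app.eosin)
        cx, cy = row.centroid_x_px, row.centroid_y_px
        _paint_ellipse(h_field, cx, cy, a_um / ps, b_um / ps, theta, h_int)
        # eosin halo: cytoplasm ellipse (nucleus grown by halo_um) minus nucleus
        _paint_ellipse(
            e_field, cx, cy, (a_um + params.halo_um) / ps, (b_um + params.halo_um) / ps, theta, e_int
        )
        # keep a trace of eosin inside the nucleus too (real nuclei are not eosin-free)
        _paint_ellipse(e_field, cx, cy, a_um / ps, b_um / ps, theta, 0.05 * e_int)
        areas.append(np.pi * a_um * b_um)
    truth["nucleus_area_um2"] = areas

    sigma_px = params.blur_um / ps
    if sigma_px > 0:
        h_field = gaussian_filter(h_field, sigma_px)
        e_field = gaussian_filter(e_field, sigma_px)

    od = (
        h_field[:, :, None] * RUIFROK_HEMATOXYLIN[None, None, :]
        + e_field[:, :, None] * RUIFROK_EOSIN[None, None, :]
    )
    bg = np.asarray(params.background_rgb, dtype=float)
    rgb = bg[None, None, :] * 10.0 ** (-od)
    image = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    return SyntheticScene(image=image, truth=truth, params=params)


# ---------------------------------------------------------------------------
# spot lattice


@dataclass
class GridParams:
    rows: int = 6
    cols: int = 6
    pitch_um: float = 100.0
    diameter_um: float = 55.0
    pixel_size_um: float = 0.5
    origin_px: tuple[float, float] = (150.0, 150.0)

    def __post_init__(self):
        if not (self.pitch_um > self.diameter_um > 0):
            raise ValueError("require pitch > diameter > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")


def generate_spot_grid(params: GridParams):
    """Hexagonally packed spot centers in full-resolution pixels.

    Odd array rows are shifted by pitch/2 in x; row spacing is
    pitch * sqrt(3)/2, so the minimum center-to-center distance equals the
    pitch. Spot radius is diameter / (2 * pixel size).
    """
    from .spots import SpotGrid

    pitch_px = params.pitch_um / params.pixel_size_um
    radius_px = params.diameter_um / (2.0 * params.pixel_size_um)
    x0, y0 = params.origin_px
    rows = []
    for r in range(params.rows):
        for c in range(params.cols):
            x = x0 + c * pitch_px + (pitch_px / 2.0 if r % 2 else 0.0)
            y = y0 + r * pitch_px * np.sqrt(3.0) / 2.0
            rows.append(
                {
                    "barcode": f"SYN-{r:03d}x{c:03d}-1",
                    "array_row": r,
                    "array_col": c,
                    "x_px": x,
                    "y_px": y,
                    "radius_px": radius_px,
                    "in_tissue": 1,
                }
            )
    return SpotGrid(table=pd.DataFrame(rows), frame="fullres")


# ---------------------------------------------------------------------------
# deconvolution fractions

DEFAULT_FINE_TYPES: dict[str, tuple[str, ...]] = {
    "tumor": ("Cancer Epithelial", "Normal Epithelial"),
    "immune": ("T-cells", "ILC", "B-cells", "Plasmablasts", "Myeloid"),
    "stroma": ("CAFs", "PVL", "Endothelial"),
}


def _exact_partition(mass: float, weights: np.ndarray) -> list[float]:
    """Split ``mass`` proportionally to ``weights`` such that the
    left-to-right floating-point sum of the parts equals ``mass`` exactly.

    The last part takes the residual; when round-half-even makes the exact
    sum unreachable, the second-to-last part is nudged by ulps until a
    consistent pair exists (a couple of steps at most).
    """
    k = len(weights)
    if k == 1:
        return [mass]
    values = [mass * w for w in weights[:-1]]
    for _ in range(256):
        acc = 0.0
        for v in values:
            acc += v
        resid = mass - acc
        # fine-tune the residual by ulps around the first guess
        for _ in range(8):
            s = acc + resid
            if s == mass:
                return values + [resid]
            resid = np.nextafter(resid, np.inf if s < mass else -np.inf)
        # unreachable with this prefix sum: perturb the previous part
        values[-1] = float(np.nextafter(values[-1], np.inf))
    raise ArithmeticError("could not build an exactly summing partition")


def generate_deconv_fractions(
    truth,
    aggregation_map: dict[str, str] | None = None,
    noise_concentration: float = np.inf,
    seed: int = 0,
) -> pd.DataFrame:
    """Fine-type fraction matrix consistent with a known composition.

    Per spot the true major-class fractions are perturbed with Dirichlet
    noise of the given concentration (``inf`` switches noise off), then each
    major class's mass is split uniformly-at-random among its fine types, so
    aggregating back through the map recovers the perturbed major fractions
    exactly. Spots with zero cells are emitted as uniform fractions and
    flagged in the ``uniform_fallback`` attribute column.
    """
    from .spots import SpotComposition

    if isinstance(truth, SpotComposition):
        comp = truth.table
    else:
        comp = truth
    if aggregation_map is None:
        aggregation_map = {
            fine: major for major, fines in DEFAULT_FINE_TYPES.items() for fine in fines
        }
    fines_by_major: dict[str, list[str]] = {c: [] for c in CLASSES}
    for fine, major in aggregation_map.items():
        fines_by_major.setdefault(major, []).append(fine)
    for major in CLASSES:
        if not fines_by_major[major]:
            raise ValueError(f"aggregation map has no fine type for class '{major}'")
    fine_types = list(aggregation_map)

    rng = np.random.default_rng(seed)
    out = np.zeros((len(comp), len(fine_types)), dtype=float)
    fallback = np.zeros(len(comp), dtype=bool)
    col_idx = {f: i for i, f in enumerate(fine_types)}
    for i, row in enumerate(comp.itertuples()):
        total = row.n_total
        if total == 0:
            out[i] = 1.0 / len(fine_types)
            fallback[i] = True
            continue
        p = np.array([getattr(row, f"frac_{c}") for c in CLASSES], dtype=float)
        if np.isfinite(noise_concentration):
            alpha = noise_concentration * p
            noisy = np.zeros(3)
            pos = alpha > 0
            noisy[pos] = rng.gamma(alpha[pos])
            s = noisy.sum()
            noisy = noisy / s if s > 0 else p
        else:
            noisy = p
        for major, mass in zip(CLASSES, noisy):
            fines = fines_by_major[major]
            split = rng.dirichlet(np.ones(len(fines)))
            values = _exact_partition(mass, split)
            for f, v in zip(fines, values):
                out[i, col_idx[f]] = v
    result = pd.DataFrame(out, index=comp["barcode"].to_numpy(), columns=fine_types)
    result.index.name = "barcode"
    result.attrs["uniform_fallback"] = pd.Series(fallback, index=result.index)
    return result


# ---------------------------------------------------------------------------
# clone-structured counts


@dataclass(frozen=True)
class Segment:
    """Altered genomic segment: half-open gene-index range within a chromosome."""

    chrom: str
    start_index: int
    end_index: int
    log2_fc: float

    def __post_init__(self):
        if not np.isfinite(self.log2_fc):
            raise ValueError("fold-change must be finite")
        if self.end_index <= self.start_index or self.start_index < 0:
            raise ValueError("require 0 <= start_index < end_index")


@dataclass
class CloneSpec:
    clone_id: str
    segments: list[Segment]
    barcodes: list[str]


def generate_cnv_counts(
    gene_order: pd.DataFrame,
    clones: list[CloneSpec],
    reference_barcodes: list[str],
    baseline_expression: np.ndarray | None = None,
    depth: float = 10_000.0,
    seed: int = 0,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Spot x gene counts with clone-specific segmental gains/losses.

    Baseline per-gene expression (gamma-distributed by default) is scaled so
    the unaltered expectation sums to ``depth`` per spot, then multiplied by
    ``2**log2_fc`` inside each clone's altered segments, and counts drawn
    from a Poisson (or negative binomial when ``dispersion`` is given; the
    value is the gamma shape, smaller = more overdispersed).
    """
    genes = gene_order["gene"].to_numpy()
    if len(set(genes)) != len(genes):
        raise ValueError("gene names must be unique")
    chrom_index: dict[str, np.ndarray] = {
        ch: np.flatnonzero(gene_order["chrom"].to_numpy() == ch)
        for ch in pd.unique(gene_order["chrom"])
    }

    all_clone_barcodes: set[str] = set()
    for clone in clones:
        overlap = all_clone_barcodes & set(clone.barcodes)
        if overlap:
            raise ValueError(f"clone spot sets overlap: {sorted(overlap)[:3]}")
        all_clone_barcodes |= set(clone.barcodes)
    if all_clone_barcodes & set(reference_barcodes):
        raise ValueError("reference spots must carry no alterations")

    rng = np.random.default_rng(seed)
    if baseline_expression is None:
        baseline_expression = rng.gamma(shape=2.0, scale=1.0, size=len(genes)) + 0.05
    baseline = np.asarray(baseline_expression, dtype=float)
    base_mean = baseline / baseline.sum() * depth

    multipliers: dict[str, np.ndarray] = {}
    for clone in clones:
        mult = np.ones(len(genes))
        for seg in clone.segments:
            if seg.chrom not in chrom_index:
                raise ValueError(f"unknown chromosome '{seg.chrom}' in segment")
            idx = chrom_index[seg.chrom]
            if seg.end_index > len(idx):
                raise ValueError(
                    f"segment [{seg.start_index}, {seg.end_index}) exceeds "
                    f"{len(idx)} genes on chromosome {seg.chrom}"
                )
            mult[idx[seg.start_index : seg.end_index]] *= 2.0**seg.log2_fc
        multipliers[clone.clone_id] = mult

    barcodes: list[str] = list(reference_barcodes)
    means = [np.tile(base_mean, (len(reference_barcodes), 1))]
    for clone in clones:
        barcodes.extend(clone.barcodes)
        means.append(np.tile(base_mean * multipliers[clone.clone_id], (len(clone.barcodes), 1)))
    mean = np.vstack(means) if means else np.zeros((0, len(genes)))
    if dispersion is not None:
        mean = mean * rng.gamma(shape=dispersion, scale=1.0 / dispersion, size=mean.shape)
    counts = rng.poisson(mean)
    return pd.DataFrame(counts, index=pd.Index(barcodes, name="barcode"), columns=genes)
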