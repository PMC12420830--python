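"""Annotation-guided copy-number clone calling from spot expression.

Spots with zero annotated tumor cells provide the normal-expression
baseline; query spots are selected by tumor purity (tumor fraction >= a
50/70/90% threshold). Each spot's expression is turned into a genomically
smoothed relative-expression profile — normalize, log, subtract the
reference mean per gene, clip, running-mean along each chromosome, center
per spot, denoise against the reference spread — and the query profiles are
clustered with Ward linkage; cutting the dendrogram yields clones labeled
A, B, ... by decreasing size.

This is a deliberately compact relative-expression core: no HMM state
calling, no Bayesian filtering, no subclustering. It is sufficient for
clone separation when segmental gains/losses are present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

CHROMOSOME_ORDER = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


def load_gene_order(path_or_df) -> pd.DataFrame:
    """Gene table (gene, chrom, start, stop) sorted genomically.

    Chromosomes order 1..22, X, Y (then any others alphabetically); ties on
    start position break by gene name.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep="\t")
    required = {"gene", "chrom", "start", "stop"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene order table missing columns: {sorted(missing)}")
    if df["gene"].duplicated().any():
        raise ValueError("gene names must be unique")
    if (df[["start", "stop"]] < 0).to_numpy().any():
        raise ValueError("gene positions must be >= 0")
    df["chrom"] = df["chrom"].astype(str).str.replace("^chr", "", regex=True)
    rank = {c: i for i, c in enumerate(CHROMOSOME_ORDER)}
    df["_rank"] = df["chrom"].map(lambda c: rank.get(c, len(rank)))
    df = df.sort_values(["_rank", "chrom", "start", "gene"]).drop(columns="_rank")
    return df.reset_index(drop=True)


def select_reference_spots(comp, qc_pass=None) -> list:
    """Spots usable as the normal baseline: zero tumor cells, >= 1 cell."""
    t = comp.table if hasattr(comp, "table") else comp
    mask = (t["n_tumor"] == 0) & (t["n_total"] >= 1)
    if qc_pass is not None:
        mask &= t["barcode"].isin(set(qc_pass))
    ref = list(t.loc[mask, "barcode"])
    if not ref:
        raise ValueError("no reference spots (zero-tumor, >=1 cell) available")
    return ref


def select_tumor_spots(comp, purity_threshold: float, qc_pass=None) -> list:
    """Query spots with tumor fraction >= the purity threshold."""
    if not (0 < purity_threshold <= 1):
        raise ValueError("purity threshold must lie in (0, 1]")
    t = comp.table if hasattr(comp, "table") else comp
    mask = (t["n_total"] > 0) & (t["frac_tumor"] >= purity_threshold)
    if qc_pass is not None:
        mask &= t["barcode"].isin(set(qc_pass))
    query = list(t.loc[mask, "barcode"])
    if not query:
        raise ValueError(f"no query spots at purity threshold {purity_threshold}")
    return query


@dataclass
class CnvParams:
    """Tunables of the relative-expression profile.

    target_depth : library size all spots are normalized to before log2.
    min_mean_expression : per-gene floor on mean normalized counts over the
        combined reference + query set; quieter genes are dropped.
    clip_max : relative log2 expression is clipped to +/- this value.
    window_genes : running-mean window along each chromosome (truncated at
        chromosome ends); must be odd.
    denoise_sd : values within +/- denoise_sd * SD(reference profiles) of
        zero are set to zero.
    """

    target_depth: float = 10_000.0
    min_mean_expression: float = 0.1
    clip_max: float = 3.0
    window_genes: int = 101
    denoise_sd: float = 1.3

    def __post_init__(self):
        if self.window_genes < 1 or self.window_genes % 2 == 0:
            raise ValueError("window_genes must be a positive odd integer")


@dataclass
class CnvProfileMatrix:
    """Smoothed relative-expression profiles (spots x ordered genes)."""

    query: pd.DataFrame
    reference: pd.DataFrame
    chromosomes: pd.Series  # per retained gene
    params: CnvParams
    sd_reference: float


def _running_mean_by_chrom(mat: np.ndarray, chroms: np.ndarray, window: int) -> np.ndarray:
    out = np.empty_like(mat)
    half = window // 2
    for ch in pd.unique(chroms):
        idx = np.flatnonzero(chroms == ch)
        sub = mat[:, idx]
        n = len(idx)
        csum = np.cumsum(np.pad(sub, ((0, 0), (1, 0))), axis=1)
        starts = np.maximum(np.arange(n) - half, 0)
        ends = np.minimum(np.arange(n) + half + 1, n)
        out[:, idx] = (csum[:, ends] - csum[:, starts]) / (ends - starts)
    return out


def infer_cnv_profile(
    counts: pd.DataFrame,
    reference: list,
    query: list,
    gene_order: pd.DataFrame,
    params: CnvParams | None = None,
) -> CnvProfileMatrix:
    """Genomically smoothed relative-expression profiles for query spots.

    Steps, in order: depth-normalize and log2(x+1); drop low-mean genes;
    subtract the per-gene reference mean; clip; within-chromosome running
    mean; per-spot median centering; zero out values within
    ``denoise_sd * SD`` of zero, where SD is taken over the reference-spot
    profiles after the same smoothing.
    """
    params = params or CnvParams()
    reference = list(reference)
    query = list(query)
    if set(reference) & set(query):
        raise ValueError("reference and query spot sets must be disjoint")
    order = load_gene_order(gene_order)
    genes = [g for g in order["gene"] if g in counts.columns]
    order = order.set_index("gene").loc[genes]
    # drop chromosomes too short to smooth meaningfully
    sizes = order.groupby("chrom", sort=False)["start"].size()
    small = sizes[sizes < 2].index
    if len(small):
        warnings.warn(f"skipping chromosomes with < 2 genes: {list(small)}", stacklevel=2)
        keep = ~order["chrom"].isin(small)
        order = order[keep]
        genes = list(order.index)

    spots = reference + query
    mat = counts.loc[spots, genes].to_numpy(dtype=float)
    totals = mat.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    norm = mat / totals * params.target_depth

    keep_genes = norm.mean(axis=0) > params.min_mean_expression
    norm = norm[:, keep_genes]
    genes = [g for g, k in zip(genes, keep_genes) if k]
    chroms = order.loc[genes, "chrom"].to_numpy()

    logx = np.log2(norm + 1.0)
    n_ref = len(reference)
    ref_mean = logx[:n_ref].mean(axis=0)
    rel = np.clip(logx - ref_mean, -params.clip_max, params.clip_max)
    smooth = _running_mean_by_chrom(rel, chroms, params.window_genes)
    smooth = smooth - np.median(smooth, axis=1, keepdims=True)

    sd_ref = float(smooth[:n_ref].std())
    cut = params.denoise_sd * sd_ref
    denoised = np.where(np.abs(smooth) <= cut, 0.0, smooth)

    cols = pd.Index(genes, name="gene")
    return CnvProfileMatrix(
        query=pd.DataFrame(denoised[n_ref:], index=pd.Index(query, name="barcode"), columns=cols),
        reference=pd.DataFrame(
            denoised[:n_ref], index=pd.Index(reference, name="barcode"), columns=cols
        ),
        chromosomes=pd.Series(chroms, index=cols, name="chrom"),
        params=params,
        sd_reference=sd_ref,
    )


@dataclass
class CloneAssignment:
    labels: pd.Series  # barcode -> clone letter
    linkage_matrix: np.ndarray
    linkage_variant: str
    cut: dict = field(default_factory=dict)

    @property
    def n_clones(self) -> int:
        return self.labels.nunique()


def _clone_letters(n: int) -> list[str]:
    letters = []
    for i in range(n):
        name = ""
        k = i
        while True:
            name = chr(ord("A") + k % 26) + name
            k = k // 26 - 1
            if k < 0:
                break
        letters.append(name)
    return letters


def call_clones(
    profile: CnvProfileMatrix | pd.DataFrame,
    k: int | None = None,
    height: float | None = None,
    linkage_variant: str = "ward.D",
    scale: bool = True,
) -> CloneAssignment:
    """Ward-linkage clone clustering of query CNV profiles.

    Profiles are optionally scaled (per-gene z-score across spots) before
    clustering. ``linkage_variant`` selects classical Ward on the given
    Euclidean distances ("ward.D", the R hclust naming) or the
    distance-squaring variant ("ward.D2"). Cut either at ``k`` clusters or
    at ``height`` (in the chosen variant's height units); a height above
    the root yields a single clone with a warning. Clones are relabeled
    A, B, ... by decreasing size (ties by cluster order).
    """
    values = profile.query if isinstance(profile, CnvProfileMatrix) else profile
    if len(values) < 2:
        raise ValueError("need at least 2 query spots to cluster")
    if (k is None) == (height is None):
        raise ValueError("give exactly one of k or height")
    X = values.to_numpy(dtype=float)
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    d = pdist(X, metric="euclidean")
    if linkage_variant == "ward.D2":
        Z = linkage(d, method="ward")
    elif linkage_variant == "ward.D":
        # scipy's ward recurrence squares its input distances; feeding
        # sqrt(d) therefore runs the Lance-Williams update on d itself,
        # i.e. R hclust's ward.D merge order. Heights are squared back.
        Z = linkage(np.sqrt(d), method="ward")
        Z = Z.copy()
        Z[:, 2] = Z[:, 2] ** 2
    else:
        raise ValueError("linkage_variant must be 'ward.D' or 'ward.D2'")

    if k is not None:
        flat = fcluster(Z, t=k, criterion="maxclust")
        cut = {"k": k}
    else:
        if len(Z) and height > Z[-1, 2]:
            warnings.warn("cut height above the dendrogram root; single clone", stacklevel=2)
        flat = fcluster(Z, t=height, criterion="distance")
        cut = {"height": height}

    sizes = pd.Series(flat).value_counts()
    order = sizes.sort_values(ascending=False, kind="stable").index
    letters = _clone_letters(len(order))
    rename = {cluster: letter for cluster, letter in zip(order, letters)}
    labels = pd.Series(
        [rename[c] for c in flat], index=values.index, name="clone"
    )
    return CloneAssignment(
        labels=labels, linkage_matrix=Z, linkage_variant=linkage_variant, cut=cut
    )
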