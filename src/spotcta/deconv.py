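"""Scoring spot deconvolution against computational tissue annotation.

Fine cell-type fractions from any deconvolution method are aggregated to
tumor / immune / stroma through a fine-type -> major-class map, correlated
per sample and class with the annotation-derived composition (Spearman),
and methods are compared with a Kruskal-Wallis omnibus test followed by
Dunn's post-hoc z-tests against a reference method with Benjamini-Hochberg
correction within each class.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CLASSES = ("tumor", "immune", "stroma")

MIN_SPOTS_FOR_CORRELATION = 3


def load_aggregation_map(path=None) -> dict[str, str]:
    """Read a fine-type -> major-class map from TSV (default: shipped map).

    The shipped map groups the 29-type breast tumor single-cell taxonomy:
    cancer and normal epithelial -> tumor; lymphoid and myeloid -> immune;
    CAFs, perivascular-like and endothelial -> stroma.
    """
    if path is None:
        ref = resources.files("spotcta").joinpath("data/aggregation_map.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    mapping = dict(zip(df["fine_type"], df["major_class"]))
    bad = set(mapping.values()) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown major classes in map: {sorted(bad)}")
    return mapping


def aggregate_fractions(fine: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    """Sum fine-type fractions up to the three major classes per spot."""
    unmapped = [c for c in fine.columns if c not in mapping]
    if unmapped:
        raise ValueError(f"fine types missing from the aggregation map: {unmapped}")
    out = pd.DataFrame(0.0, index=fine.index, columns=list(CLASSES))
    for fine_type in fine.columns:
        out[mapping[fine_type]] += fine[fine_type]
    return out


@dataclass
class CorrelationRecord:
    sample: str
    method: str
    major_class: str
    rho: float
    n_spots: int
    reason: str = ""


def correlate_composition(
    major: pd.DataFrame,
    comp,
    method: str = "",
    sample: str | pd.Series = "",
    qc_pass=None,
    classes=CLASSES,
    min_spots: int = MIN_SPOTS_FOR_CORRELATION,
) -> pd.DataFrame:
    """Spearman rho between deconvolved and annotation fractions per class.

    Spots are intersected on shared barcodes that pass QC (when ``qc_pass``
    is given) and have at least one annotated cell. ``sample`` may be a
    single id or a barcode -> sample Series for per-section grouping.
    Groups below ``min_spots`` yield records with missing rho and a reason.
    """
    comp_table = comp.table if hasattr(comp, "table") else comp
    cta = comp_table.set_index("barcode")
    shared = major.index.intersection(cta.index)
    if qc_pass is not None:
        shared = shared.intersection(pd.Index(qc_pass))
    shared = shared[cta.loc[shared, "n_total"] > 0]

    if isinstance(sample, pd.Series):
        groups = sample.reindex(shared).dropna()
        group_items = [(str(g), idx) for g, idx in groups.groupby(groups).groups.items()]
    else:
        group_items = [(str(sample), shared)]

    records = []
    for sample_id, idx in group_items:
        idx = pd.Index(idx)
        for cls in classes:
            if len(idx) == 0:
                records.append(
                    CorrelationRecord(sample_id, method, cls, np.nan, 0, "no overlap")
                )
                continue
            if len(idx) < min_spots:
                records.append(
                    CorrelationRecord(
                        sample_id, method, cls, np.nan, len(idx), "too few spots"
                    )
                )
                continue
            rho = stats.spearmanr(
                major.loc[idx, cls], cta.loc[idx, f"frac_{cls}"]
            ).statistic
            records.append(CorrelationRecord(sample_id, method, cls, rho, len(idx)))
    return pd.DataFrame([vars(r) for r in records])


def _dunn_vs_reference(values_by_group: dict[str, np.ndarray], reference: str):
    """Dunn's post-hoc z statistics against the reference group.

    Normal approximation on mean ranks with the tie correction
    sum(t^3 - t) / (12 (N - 1)) subtracted from N(N+1)/12.
    """
    names = list(values_by_group)
    pooled = np.concatenate([values_by_group[g] for g in names])
    ranks = stats.rankdata(pooled)  # average ranks on ties
    n_total = len(pooled)
    mean_rank = {}
    pos = 0
    for g in names:
        k = len(values_by_group[g])
        mean_rank[g] = ranks[pos : pos + k].mean()
        pos += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    n_ref = len(values_by_group[reference])
    for g in names:
        if g == reference:
            continue
        se = np.sqrt(var_unit * (1.0 / len(values_by_group[g]) + 1.0 / n_ref))
        if se == 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_rank[g] - mean_rank[reference]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"method": g, "z": z, "p_raw": p})
    return pd.DataFrame(rows)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_methods(
    records: pd.DataFrame,
    reference_method: str,
    alpha: float = 0.05,
    classes=CLASSES,
) -> dict:
    """Kruskal-Wallis omnibus + Dunn-vs-reference with BH correction.

    ``records`` is the output of :func:`correlate_composition` pooled over
    methods. Per class: H and p over per-sample rho values grouped by
    method; Dunn z and raw/BH-adjusted p for each method against the
    reference; methods with fewer than 2 usable records are excluded with a
    warning entry. Returns {"omnibus": DataFrame, "pairwise": DataFrame,
    "excluded": list}.
    """
    usable = records.dropna(subset=["rho"])
    methods = usable["method"].unique()
    if reference_method not in methods:
        raise ValueError(f"reference method '{reference_method}' has no usable records")
    omnibus_rows, pairwise_frames, excluded = [], [], []
    for cls in classes:
        sub = usable[usable["major_class"] == cls]
        groups = {}
        for m in sorted(sub["method"].unique()):
            vals = sub.loc[sub["method"] == m, "rho"].to_numpy(dtype=float)
            if len(vals) < 2:
                excluded.append((cls, m, "fewer than 2 records"))
                continue
            groups[m] = vals
        if len(groups) < 2 or reference_method not in groups:
            excluded.append((cls, "*", "not enough methods for comparison"))
            continue
        pooled = np.concatenate(list(groups.values()))
        if np.all(pooled == pooled[0]):
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*groups.values())
        omnibus_rows.append({"major_class": cls, "H": h, "p": p, "n_methods": len(groups)})
        dunn = _dunn_vs_reference(groups, reference_method)
        if len(dunn):
            dunn["p_adj"] = multipletests(dunn["p_raw"], method="fdr_bh")[1]
            dunn["significant"] = dunn["p_adj"] < alpha
            dunn["stars"] = dunn["p_adj"].map(_stars)
            dunn.insert(0, "major_class", cls)
            pairwise_frames.append(dunn)
    pairwise = (
        pd.concat(pairwise_frames, ignore_index=True)
        if pairwise_frames
        else pd.DataFrame(
            columns=["major_class", "method", "z", "p_raw", "p_adj", "significant", "stars"]
        )
    )
    return {
        "omnibus": pd.DataFrame(omnibus_rows),
        "pairwise": pairwise,
        "excluded": excluded,
    }
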