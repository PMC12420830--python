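"""Purity-guided spot selection, relative-expression profiles, clone calling."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from spotcta import (
    CnvParams,
    SpotComposition,
    call_clones,
    infer_cnv_profile,
    load_gene_order,
    select_reference_spots,
    select_tumor_spots,
)
from spotcta.synthetic import CloneSpec, Segment, generate_cnv_counts


def comp_from_counts(rows):
    df = pd.DataFrame(rows)
    df["n_total"] = df[["n_tumor", "n_immune", "n_stroma"]].sum(axis=1)
    for c in ("tumor", "immune", "stroma"):
        df[f"frac_{c}"] = np.where(df["n_total"] > 0, df[f"n_{c}"] / df["n_total"], np.nan)
    return SpotComposition(table=df)


class TestGeneOrder:
    def test_sorts_by_chromosome_then_start(self):
        df = pd.DataFrame(
            {"gene": ["g1", "g2", "g3", "g4"], "chrom": ["X", "2", "1", "chr2"],
             "start": [5, 10, 50, 1], "stop": [6, 11, 51, 2]}
        )
        out = load_gene_order(df)
        assert out["gene"].tolist() == ["g3", "g4", "g2", "g1"]
        assert out["chrom"].tolist() == ["1", "2", "2", "X"]

    def test_duplicate_gene_rejected(self):
        df = pd.DataFrame({"gene": ["g", "g"], "chrom": ["1", "1"], "start": [0, 1], "stop": [1, 2]})
        with pytest.raises(ValueError, match="unique"):
            load_gene_order(df)


class TestSpotSelection:
    def _comp(self):
        return comp_from_counts(
            [
                {"barcode": "ref", "n_tumor": 0, "n_immune": 3, "n_stroma": 2},
                {"barcode": "mixed", "n_tumor": 1, "n_immune": 9, "n_stroma": 0},
                {"barcode": "empty", "n_tumor": 0, "n_immune": 0, "n_stroma": 0},
                {"barcode": "pure", "n_tumor": 7, "n_immune": 2, "n_stroma": 1},
                {"barcode": "half", "n_tumor": 5, "n_immune": 5, "n_stroma": 0},
            ]
        )

    def test_reference_is_zero_tumor_with_cells(self):
        assert select_reference_spots(self._comp()) == ["ref"]

    def test_tumor_spots_inclusive_boundary(self):
        comp = comp_from_counts(
            [{"barcode": "at", "n_tumor": 70, "n_immune": 30, "n_stroma": 0},
             {"barcode": "below", "n_tumor": 69, "n_immune": 31, "n_stroma": 0}]
        )
        assert select_tumor_spots(comp, 0.7) == ["at"]

    def test_purity_sets_are_nested(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(200):
            nt = int(rng.integers(0, 12))
            rows.append({"barcode": f"S{i}", "n_tumor": nt,
                         "n_immune": int(rng.integers(0, 6)), "n_stroma": int(rng.integers(0, 6))})
        comp = comp_from_counts(rows)
        s50 = set(select_tumor_spots(comp, 0.5))
        s70 = set(select_tumor_spots(comp, 0.7))
        s90 = set(select_tumor_spots(comp, 0.9))
        assert s90 <= s70 <= s50

    def test_empty_selections_raise(self):
        comp = comp_from_counts([{"barcode": "t", "n_tumor": 5, "n_immune": 0, "n_stroma": 0}])
        with pytest.raises(ValueError, match="reference"):
            select_reference_spots(comp)
        with pytest.raises(ValueError, match="0.9"):
            select_tumor_spots(
                comp_from_counts([{"barcode": "r", "n_tumor": 1, "n_immune": 9, "n_stroma": 0}]), 0.9
            )


class TestProfile:
    def test_null_query_profiles_are_flat(self, gene_order_4chrom):
        refs = [f"r{i}" for i in range(100)]
        queries = [f"q{i}" for i in range(50)]
        counts = generate_cnv_counts(
            gene_order_4chrom, [CloneSpec("N", [], queries)], refs, depth=10_000, seed=5
        )
        prof = infer_cnv_profile(counts, refs, queries, gene_order_4chrom)
        assert np.abs(prof.query.to_numpy()).mean() < 0.02

    def test_gain_segment_clearly_elevated(self, two_clone_fixture):
        order, clones, refs = two_clone_fixture
        counts = generate_cnv_counts(order, clones, refs, depth=10_000, seed=11)
        queries = clones[0].barcodes + clones[1].barcodes
        prof = infer_cnv_profile(counts, refs, queries, order)
        chroms = prof.chromosomes.to_numpy()
        interior = np.flatnonzero(chroms == "2")[50:100]
        inside = prof.query.loc[clones[0].barcodes].to_numpy()[:, interior].mean()
        outside = np.abs(
            prof.query.loc[clones[0].barcodes].to_numpy()[:, np.isin(chroms, ["1", "3"])]
        ).mean()
        assert inside >= 0.3
        assert inside >= 5 * outside

    def test_short_chromosome_window_truncates(self):
        order = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(60)], "chrom": "1",
             "start": range(60), "stop": range(1, 61)}
        )
        refs, queries = ["r0", "r1", "r2"], ["q0", "q1"]
        counts = generate_cnv_counts(order, [CloneSpec("N", [], queries)], refs, depth=5000, seed=0)
        prof = infer_cnv_profile(counts, refs, queries, order, CnvParams(window_genes=101))
        assert prof.query.shape[1] == 60
        assert np.isfinite(prof.query.to_numpy()).all()

    def test_reference_profiles_sparser_than_altered(self, two_clone_fixture):
        order, clones, refs = two_clone_fixture
        counts = generate_cnv_counts(order, clones, refs, depth=10_000, seed=11)
        prof = infer_cnv_profile(counts, refs, clones[0].barcodes, order)
        ref_zero = (prof.reference.to_numpy() == 0).mean()
        query_zero = (prof.query.to_numpy() == 0).mean()
        assert ref_zero > query_zero

    def test_profile_grows_with_fold_change(self, gene_order_4chrom):
        refs = [f"r{i}" for i in range(80)]
        means = []
        for lfc in (0.5, 1.0, 2.0):
            clone = CloneSpec("C", [Segment("2", 0, 150, lfc)], [f"q{i}" for i in range(80)])
            counts = generate_cnv_counts(gene_order_4chrom, [clone], refs, depth=10_000, seed=3)
            prof = infer_cnv_profile(counts, refs, clone.barcodes, gene_order_4chrom)
            interior = np.flatnonzero(prof.chromosomes.to_numpy() == "2")[50:100]
            means.append(prof.query.to_numpy()[:, interior].mean())
        assert means[0] < means[1] < means[2]

    def test_overlapping_reference_query_rejected(self, gene_order_4chrom):
        counts = generate_cnv_counts(
            gene_order_4chrom, [CloneSpec("N", [], ["q0"])], ["r0", "r1"], seed=0
        )
        with pytest.raises(ValueError, match="disjoint"):
            infer_cnv_profile(counts, ["r0"], ["r0", "q0"], gene_order_4chrom)


@pytest.fixture(scope="module")
def two_clone_profile(two_clone_fixture):
    order, clones, refs = two_clone_fixture
    counts = generate_cnv_counts(order, clones, refs, depth=10_000, seed=11)
    queries = clones[0].barcodes + clones[1].barcodes
    prof = infer_cnv_profile(counts, refs, queries, order)
    truth = ["A"] * len(clones[0].barcodes) + ["B"] * len(clones[1].barcodes)
    return prof, truth


class TestCloneCalling:
    def test_k1_puts_everything_in_clone_a(self, two_clone_profile):
        prof, _ = two_clone_profile
        asg = call_clones(prof, k=1)
        assert set(asg.labels) == {"A"}

    def test_two_clones_recovered_exactly(self, two_clone_profile):
        prof, truth = two_clone_profile
        asg = call_clones(prof, k=2)
        assert adjusted_rand_score(truth, asg.labels.to_numpy()) == 1.0
        # clone letters ordered by decreasing size (equal here: both present)
        assert set(asg.labels) == {"A", "B"}

    def test_deterministic_assignment(self, two_clone_profile):
        prof, _ = two_clone_profile
        a = call_clones(prof, k=2)
        b = call_clones(prof, k=2)
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_height_cut_above_root_single_clone(self, two_clone_profile):
        prof, _ = two_clone_profile
        root = call_clones(prof, k=2).linkage_matrix[-1, 2]
        with pytest.warns(UserWarning, match="root"):
            asg = call_clones(prof, height=root * 2)
        assert set(asg.labels) == {"A"}

    @pytest.mark.parametrize("variant", ["ward.D", "ward.D2"])
    def test_matches_r_hclust_cutree(self, variant, tmp_path):
        """Cut-by-k partitions agree with R's hclust/cutree on a toy matrix."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 5))
        X[:4] += 3
        X[4:8] -= 2
        prof = pd.DataFrame(X, index=[f"s{i}" for i in range(12)])
        asg = call_clones(prof, k=3, linkage_variant=variant, scale=False)
        csv = tmp_path / "x.csv"
        np.savetxt(csv, X, delimiter=",")
        r = subprocess.run(
            ["Rscript", "-e",
             f'x<-as.matrix(read.csv("{csv}",header=FALSE));'
             f'h<-hclust(dist(x),method="{variant}");cat(cutree(h,k=3))'],
            capture_output=True, text=True, check=True,
        )
        r_labels = np.array(r.stdout.split(), dtype=int)
        assert adjusted_rand_score(r_labels, asg.labels.to_numpy()) == 1.0
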