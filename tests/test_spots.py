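"""Coordinate transforms, square-window spot assignment, composition, QC."""

import numpy as np
import pandas as pd
import pytest

from spotcta import (
    ImageGeometry,
    QcThresholds,
    SpotGrid,
    assign_cells_to_spots,
    compose_spots,
    compute_scale_factor,
    fullres_to_registered,
    qc_filter_spots,
    registered_to_fullres,
    spot_density,
)


def make_grid(rows, frame="fullres"):
    return SpotGrid(table=pd.DataFrame(rows), frame=frame)


def brute_force_assignment(cells: pd.DataFrame, grid: SpotGrid) -> pd.Series:
    """Independent all-pairs oracle for the square-window rule."""
    out = {}
    spots = grid.table.sort_values("barcode")
    for c in cells.itertuples():
        best, best_d = None, np.inf
        for s in spots.itertuples():
            if (
                abs(c.centroid_x_px - s.x_px) <= s.radius_px
                and abs(c.centroid_y_px - s.y_px) <= s.radius_px
            ):
                d = np.hypot(c.centroid_x_px - s.x_px, c.centroid_y_px - s.y_px)
                if d < best_d:
                    best, best_d = s.barcode, d
        out[c.cell_id] = best
    return pd.Series(out, dtype="object")


class TestScaleFactor:
    def test_thirty_percent_convention(self):
        assert compute_scale_factor(20000, 6000) == 0.3

    def test_equal_heights_identity(self):
        assert compute_scale_factor(512, 512) == 1.0

    def test_degenerate_heights_rejected(self):
        with pytest.raises(ValueError):
            compute_scale_factor(100, 0)
        with pytest.raises(ValueError):
            compute_scale_factor(0, 100)
        with pytest.raises(ValueError):
            compute_scale_factor(100, 200)


class TestFrameTransforms:
    def _grid(self, x, y, r=10.0, frame="registration"):
        return make_grid(
            [{"barcode": "S-1", "array_row": 0, "array_col": 0, "x_px": x, "y_px": y,
              "radius_px": r, "in_tissue": 1}],
            frame=frame,
        )

    def test_y_flip_subtracts_from_height(self):
        geom = ImageGeometry(full_width_px=100, full_height_px=100, scale=1.0, y_flip=True)
        out = registered_to_fullres(self._grid(10, 30), geom)
        assert out.table.loc[0, "x_px"] == 10
        assert out.table.loc[0, "y_px"] == 70

    def test_double_flip_is_identity(self):
        geom = ImageGeometry(full_width_px=100, full_height_px=100, scale=1.0, y_flip=True)
        once = registered_to_fullres(self._grid(10, 30), geom)
        back = fullres_to_registered(once, geom)
        assert back.table.loc[0, "y_px"] == 30

    def test_scale_only_transform(self):
        geom = ImageGeometry(full_width_px=400, full_height_px=400, scale=0.3, y_flip=False)
        out = registered_to_fullres(self._grid(30, 60, r=16.5), geom)
        assert out.table.loc[0, "x_px"] == pytest.approx(100)
        assert out.table.loc[0, "y_px"] == pytest.approx(200)
        assert out.table.loc[0, "radius_px"] == pytest.approx(55)

    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_recovers_coordinates(self, seed):
        rng = np.random.default_rng(seed)
        rows = [
            {"barcode": f"S-{i}", "array_row": 0, "array_col": i,
             "x_px": rng.uniform(0, 3000), "y_px": rng.uniform(0, 3000),
             "radius_px": 16.5, "in_tissue": 1}
            for i in range(20)
        ]
        grid = make_grid(rows, frame="registration")
        geom = ImageGeometry(
            full_width_px=12000, full_height_px=10000, registered_height_px=3000, y_flip=True
        )
        out = fullres_to_registered(registered_to_fullres(grid, geom), geom)
        np.testing.assert_allclose(out.table["x_px"], grid.table["x_px"], atol=1e-9)
        np.testing.assert_allclose(out.table["y_px"], grid.table["y_px"], atol=1e-9)

    def test_out_of_bounds_spot_kept_and_flagged(self):
        geom = ImageGeometry(full_width_px=50, full_height_px=50, scale=1.0, y_flip=False)
        with pytest.warns(UserWarning, match="outside"):
            out = registered_to_fullres(self._grid(80, 10), geom)
        assert len(out.table) == 1
        assert out.table.loc[0, "out_of_bounds"]


class TestAssignment:
    def _one_spot(self):
        return make_grid(
            [{"barcode": "S-1", "array_row": 0, "array_col": 0, "x_px": 50.0,
              "y_px": 50.0, "radius_px": 10.0, "in_tissue": 1}]
        )

    def test_cell_inside_square_assigned(self):
        cells = pd.DataFrame({"cell_id": [0], "centroid_x_px": [45.0], "centroid_y_px": [58.0]})
        assert assign_cells_to_spots(cells, self._one_spot()).loc[0] == "S-1"

    def test_cell_outside_square_unassigned(self):
        cells = pd.DataFrame({"cell_id": [0], "centroid_x_px": [61.0], "centroid_y_px": [50.0]})
        assert pd.isna(assign_cells_to_spots(cells, self._one_spot()).loc[0])

    def test_boundary_is_inclusive(self):
        cells = pd.DataFrame({"cell_id": [0], "centroid_x_px": [60.0], "centroid_y_px": [40.0]})
        assert assign_cells_to_spots(cells, self._one_spot()).loc[0] == "S-1"

    def test_overlap_resolved_by_nearest_center_then_barcode(self):
        grid = make_grid(
            [
                {"barcode": "S-b", "array_row": 0, "array_col": 0, "x_px": 0.0, "y_px": 0.0,
                 "radius_px": 20.0, "in_tissue": 1},
                {"barcode": "S-a", "array_row": 0, "array_col": 1, "x_px": 10.0, "y_px": 0.0,
                 "radius_px": 20.0, "in_tissue": 1},
            ]
        )
        cells = pd.DataFrame(
            {"cell_id": [0, 1], "centroid_x_px": [2.0, 5.0], "centroid_y_px": [0.0, 0.0]}
        )
        a = assign_cells_to_spots(cells, grid)
        assert a.loc[0] == "S-b"  # nearer center
        assert a.loc[1] == "S-a"  # equidistant: alphabetical barcode

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_geometry(self, seed):
        rng = np.random.default_rng(seed)
        n_cells, n_spots = rng.integers(20, 200), rng.integers(3, 30)
        cells = pd.DataFrame(
            {"cell_id": np.arange(n_cells),
             "centroid_x_px": rng.uniform(0, 500, n_cells),
             "centroid_y_px": rng.uniform(0, 500, n_cells)}
        )
        grid = make_grid(
            [{"barcode": f"S-{i:03d}", "array_row": 0, "array_col": i,
              "x_px": rng.uniform(0, 500), "y_px": rng.uniform(0, 500),
              "radius_px": rng.uniform(5, 60), "in_tissue": 1}
             for i in range(n_spots)]
        )
        fast = assign_cells_to_spots(cells, grid)
        slow = brute_force_assignment(cells, grid)
        assert (fast.fillna("~") == slow.fillna("~")).all()


class TestComposition:
    def test_fraction_arithmetic(self):
        assignment = pd.Series(["S"] * 10, index=range(10))
        labels = pd.Series(["tumor"] * 7 + ["immune"] * 2 + ["stroma"], index=range(10))
        t = compose_spots(assignment, labels).table
        assert t.loc[0, ["frac_tumor", "frac_immune", "frac_stroma"]].tolist() == [0.7, 0.2, 0.1]

    def test_empty_spot_has_missing_fractions(self):
        assignment = pd.Series([pd.NA], index=[0], dtype="object")
        labels = pd.Series(["tumor"], index=[0])
        t = compose_spots(assignment, labels, barcodes=["S-empty"]).table
        assert t.loc[0, "n_total"] == 0
        assert t.loc[0, ["frac_tumor", "frac_immune", "frac_stroma"]].isna().all()

    def test_counts_conserved_across_spots(self):
        from conftest import random_composition

        comp, assignment, labels = random_composition(seed=8)
        t = comp.table
        assigned = assignment.notna()
        for cls in ("tumor", "immune", "stroma"):
            assert t[f"n_{cls}"].sum() == (labels[assigned] == cls).sum()
        occupied = t["n_total"] > 0
        np.testing.assert_allclose(
            t.loc[occupied, ["frac_tumor", "frac_immune", "frac_stroma"]].sum(axis=1),
            1.0, atol=1e-12,
        )

    def test_unlabeled_assigned_cell_rejected(self):
        assignment = pd.Series(["S"], index=[0])
        labels = pd.Series([np.nan], index=[0])
        with pytest.raises(ValueError, match="without a class label"):
            compose_spots(assignment, labels)


class TestQcFilter:
    def _counts(self, rows: dict) -> pd.DataFrame:
        genes = [f"GENE{i}" for i in range(600)] + ["MT-CO1", "HBB"]
        return pd.DataFrame(rows, index=genes).T

    def test_low_gene_spot_removed_at_499(self):
        good = {f"GENE{i}": 1 for i in range(600)}
        low = {f"GENE{i}": 1 for i in range(499)}
        counts = pd.DataFrame([good, low], index=["ok", "low"]).fillna(0)
        kept, report = qc_filter_spots(counts)
        assert kept == ["ok"]
        assert "detected genes" in report.set_index("barcode").loc["low", "reason"]

    def test_mito_fraction_just_over_threshold_removed(self):
        base = {f"GENE{i}": 1 for i in range(600)}
        counts = pd.DataFrame([{**base, "MT-CO1": 0}, {**base, "MT-CO1": 211}],
                              index=["ok", "mito"]).fillna(0)
        # 211 / 811 = 0.2602 > 0.25
        kept, report = qc_filter_spots(counts)
        assert "mito" not in kept
        assert "mito fraction" in report.set_index("barcode").loc["mito", "reason"]

    def test_exact_boundaries_kept(self):
        # 501 detected genes, mito exactly 25%, hemoglobin exactly 20%:
        # 550 non-special UMIs + 250 mito + 200 hemoglobin -> total 1000
        base = {f"GENE{i}": 1 for i in range(498)}
        spot = {**base, "GENE498": 52, "MT-CO1": 250, "HBB": 200}
        counts = pd.DataFrame([spot], index=["edge"]).fillna(0)
        kept, report = qc_filter_spots(counts)
        r = report.iloc[0]
        assert r["detected_genes"] == 501
        assert r["mito_fraction"] == 0.25
        assert r["hemoglobin_fraction"] == 0.20
        assert kept == ["edge"]

    def test_zero_umi_spot_removed_with_reason(self):
        counts = pd.DataFrame([{f"GENE{i}": 0 for i in range(600)}], index=["dead"])
        kept, report = qc_filter_spots(counts)
        assert kept == []
        assert report.iloc[0]["reason"] == "no counts"

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            QcThresholds(max_mito_fraction=1.5)


class TestSpotDensity:
    def _comp(self, totals):
        rows = []
        for i, n in enumerate(totals):
            rows.append({"barcode": f"S{i}", "n_tumor": n, "n_immune": 0, "n_stroma": 0,
                         "n_total": n, "frac_tumor": 1.0 if n else np.nan,
                         "frac_immune": 0.0 if n else np.nan, "frac_stroma": 0.0 if n else np.nan})
        from spotcta import SpotComposition

        return SpotComposition(table=pd.DataFrame(rows))

    def test_three_spot_cluster(self):
        comp = self._comp([10, 12, 8])
        labels = pd.Series(["c"] * 3, index=["S0", "S1", "S2"])
        assert spot_density(comp, labels)["c"] == 10.0

    def test_single_spot_cluster(self):
        comp = self._comp([5])
        assert spot_density(comp, pd.Series(["c"], index=["S0"]))["c"] == 5.0

    def test_two_clusters_hand_values(self):
        comp = self._comp([4, 6, 0])
        labels = pd.Series(["a", "a", "b"], index=["S0", "S1", "S2"])
        d = spot_density(comp, labels)
        assert d["a"] == 5.0 and d["b"] == 0.0
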