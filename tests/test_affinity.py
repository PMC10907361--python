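"""Occurrence cleaning, STI/breadth estimation and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

import thermoshift as ts
from conftest import occurrence_frame


class TestCleanOccurrences:
    def test_exact_duplicates_reduced_to_one(self):
        occ = occurrence_frame([("A", 9.5, 0.5), ("A", 9.5, 0.5)])
        out, report = ts.clean_occurrences(occ)
        assert len(out) == 1
        assert report["duplicates"] == 1

    def test_zero_zero_point_removed(self):
        occ = occurrence_frame([("A", 0.0, 0.0), ("A", 9.5, 0.5)])
        out, report = ts.clean_occurrences(occ)
        assert len(out) == 1
        assert report["invalid_coords"] == 1

    def test_preserved_specimen_removed_when_flagged(self):
        occ = occurrence_frame([("A", 9.5, 0.5, 2000, "PRESERVED_SPECIMEN"),
                                ("A", 8.5, 0.5, 2000, "HUMAN_OBSERVATION")])
        out, report = ts.clean_occurrences(occ, drop_preserved=True)
        assert len(out) == 1
        assert report["preserved"] == 1
        out2, _ = ts.clean_occurrences(occ, drop_preserved=False)
        assert len(out2) == 2

    def test_out_of_bounds_coordinates_removed(self):
        occ = occurrence_frame([("A", 95.0, 0.5), ("A", 9.5, 200.0),
                                ("A", np.nan, 0.5), ("A", 9.5, 0.5)])
        out, report = ts.clean_occurrences(occ)
        assert len(out) == 1
        assert report["invalid_coords"] == 3

    def test_empty_output_is_legal(self):
        occ = occurrence_frame([("A", 0.0, 0.0)])
        out, _ = ts.clean_occurrences(occ)
        assert len(out) == 0


class TestEstimateSTI:
    def test_mean_over_occupied_cells(self, toy_grid):
        # three cells with bio01 5, 7, 9 -> STI 7
        occ = occurrence_frame([("A", 9.5, 0.5), ("A", 8.5, 0.5),
                                ("A", 7.5, 0.5), ("A", 9.4, 0.5),
                                ("A", 8.4, 0.5)])
        prof, _ = ts.estimate_sti(occ, toy_grid)
        assert prof["sti"].item() == pytest.approx(7.0)

    def test_unique_cell_rule_ignores_record_density(self, toy_grid):
        dense = occurrence_frame([("A", 9.5, 0.5)] * 100
                                 + [("A", 8.5, 0.5)] * 1
                                 + [("A", 7.5, 0.5)] * 1)
        sparse = occurrence_frame([("A", 9.6, 0.4), ("A", 8.5, 0.5),
                                   ("A", 7.5, 0.5), ("A", 9.5, 0.5),
                                   ("A", 9.7, 0.7)])
        p1, _ = ts.estimate_sti(dense, toy_grid)
        p2, _ = ts.estimate_sti(sparse, toy_grid)
        assert p1["sti"].item() == p2["sti"].item() == pytest.approx(7.0)

    def test_per_record_flag_weights_by_density(self, toy_grid):
        occ = occurrence_frame([("A", 9.5, 0.5)] * 3 + [("A", 7.5, 0.5)] * 1
                               + [("A", 9.5, 0.7)])
        prof, _ = ts.estimate_sti(occ, toy_grid, per_record=True)
        assert prof["sti"].item() == pytest.approx((4 * 5 + 9) / 5)

    def test_min_record_threshold_excludes_and_reports(self, toy_grid):
        occ = occurrence_frame([("A", 9.5, 0.5), ("A", 8.5, 0.5),
                                ("A", 7.5, 0.5), ("A", 9.5, 1.5)])
        prof, report = ts.estimate_sti(occ, toy_grid, min_records=5)
        assert len(prof) == 0
        assert report["too_few_records"] == ["A"]

    def test_all_records_out_of_extent_reported(self, toy_grid):
        occ = occurrence_frame([("A", -50.0, 100.0)] * 6)
        prof, report = ts.estimate_sti(occ, toy_grid)
        assert len(prof) == 0
        assert report["no_records_in_extent"] == ["A"]

    @settings(deadline=None, derandomize=True, max_examples=25,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(perm=st.permutations(list(range(8))),
           dup=st.integers(min_value=1, max_value=4))
    def test_invariant_to_order_and_within_cell_duplication(self, perm, dup,
                                                            toy_grid):
        base = [("A", 9.5, 0.5), ("A", 8.5, 0.5), ("A", 7.5, 0.5),
                ("A", 9.5, 1.5), ("A", 8.5, 1.5), ("A", 7.5, 1.5),
                ("A", 9.5, 2.5), ("A", 8.2, 2.5)]
        ref, _ = ts.estimate_sti(occurrence_frame(base), toy_grid)
        shuffled = [base[i] for i in perm] + [base[0]] * dup
        got, _ = ts.estimate_sti(occurrence_frame(shuffled), toy_grid,
                                 min_records=5)
        assert got["sti"].item() == pytest.approx(ref["sti"].item())

    def test_sti_bounded_by_occupied_cell_temperatures(self, toy_grid):
        pool = ts.generate_species_pool(10, seed=1)
        occ = ts.generate_occurrences(pool, toy_grid, 30, seed=1)
        prof, _ = ts.estimate_sti(occ, toy_grid)
        bio = toy_grid.layers["bio01"]
        assert ((prof["sti"] >= bio.min()) & (prof["sti"] <= bio.max())).all()


class TestNicheBreadth:
    def test_single_cell_difference(self, toy_grid):
        occ = occurrence_frame([("A", 9.5, 0.5)] * 5)
        b = ts.estimate_niche_breadth(occ, toy_grid)
        assert b["A"] == pytest.approx(16.0)

    def test_difference_of_means_rule(self):
        # two cells: bio10 {20, 22}, bio11 {4, 6} -> 21 - 5 = 16
        grid = ts.TemperatureGrid(10.0, 0.0, 1.0, 1, 2, layers={
            "bio01": np.array([[12.0, 14.0]]),
            "bio10": np.array([[20.0, 22.0]]),
            "bio11": np.array([[4.0, 6.0]])})
        occ = occurrence_frame([("A", 9.5, 0.5)] * 3 + [("A", 9.5, 1.5)] * 3)
        b = ts.estimate_niche_breadth(occ, grid, min_records=5)
        assert b["A"] == pytest.approx(16.0)

    def test_constant_amplitude_landscape_gives_constant_breadth(self):
        sc = ts.SimulationScenario(seasonal_amplitude=8.0, rng_seed=0)
        land = ts.generate_landscape(sc, 10, 10)
        pool = ts.generate_species_pool(20, seed=2)
        occ = ts.generate_occurrences(pool, land.grid, 50, seed=2)
        b = ts.estimate_niche_breadth(occ, land.grid)
        np.testing.assert_allclose(b.to_numpy(), 16.0)


class TestAggregateSTI:
    def _profiles(self, stis):
        return pd.DataFrame({
            "species": list(stis), "sti": list(stis.values()),
            "niche_breadth": 10.0, "n_records": 9, "provenance": "species"})

    def test_genus_mean(self):
        prof = self._profiles({"Poa alpina": 10.0, "Poa annua": 14.0})
        out = ts.aggregate_sti(prof, taxonomy={"Poa alpina": "Poa",
                                               "Poa annua": "Poa"})
        genus = out[out["provenance"] == "genus_mean"]
        assert genus["sti"].item() == pytest.approx(12.0)
        assert genus["species"].item() == "Poa"

    def test_single_member_complex_is_identity(self):
        prof = self._profiles({"X a": 9.5})
        out = ts.aggregate_sti(prof, complexes={"X-cx": ["X a"]})
        assert out[out["provenance"] == "complex_mean"]["sti"].item() == 9.5

    def test_unprofiled_members_dropped_from_complex_mean(self):
        prof = self._profiles({"a": 8.0, "b": 10.0})
        out = ts.aggregate_sti(prof, complexes={"cx": ["a", "b", "c"]})
        assert out[out["provenance"] == "complex_mean"]["sti"].item() \
            == pytest.approx(9.0)

    def test_empty_complex_skipped(self, caplog):
        prof = self._profiles({"a": 8.0})
        with caplog.at_level("WARNING", logger="thermoshift"):
            out = ts.aggregate_sti(prof, complexes={"cx": ["zz"]})
        assert (out["provenance"] == "complex_mean").sum() == 0


class TestTemporalStability:
    def test_identical_records_across_bins_correlate_perfectly(self, toy_grid):
        rows = []
        for year in (1985, 1995, 2005, 2015):
            for sp, lats in (("A", [9.5, 9.4, 8.5, 8.4, 8.3]),
                             ("B", [9.5, 9.4, 9.3, 7.5, 7.4]),
                             ("C", [8.5, 8.4, 7.5, 7.4, 7.3])):
                rows += [(sp, la, 0.5, year) for la in lats]
        corr, counts = ts.sti_temporal_stability(occurrence_frame(rows),
                                                 toy_grid)
        off_diag = corr.to_numpy()[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off_diag, 1.0)
        assert (counts.to_numpy() == 3).all()

    def test_empty_bin_is_undefined(self, toy_grid):
        rows = ([("A", la, 0.5, 2015) for la in (9.5, 9.4, 8.5, 8.4, 8.3)]
                + [("B", la, 0.5, 2015) for la in (9.5, 9.4, 9.3, 7.5, 7.4)]
                + [("C", la, 0.5, 2015) for la in (8.5, 8.4, 7.5, 7.4, 7.3)])
        corr, _ = ts.sti_temporal_stability(occurrence_frame(rows), toy_grid)
        assert corr.loc["<= 1990"].isna().all()
        assert corr.loc["> 2010", "> 2010"] == pytest.approx(1.0)

    def test_stationary_simulation_bins_highly_correlated(self):
        # under a stationary landscape the per-bin STIs of 500 species
        # should agree across all time bins
        sc = ts.SimulationScenario(rng_seed=0)
        land = ts.generate_landscape(sc, 15, 15)
        pool = ts.generate_species_pool(500, seed=7)
        occ = ts.generate_occurrences(pool, land.grid, 100, seed=7)
        corr, counts = ts.sti_temporal_stability(occ, land.grid)
        off = corr.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.nanmin(off) > 0.9
        assert counts.to_numpy().min() >= 400
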