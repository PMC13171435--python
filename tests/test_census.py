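"""Census parsing, validation, linking and species-eligibility filters."""

import numpy as np
import pandas as pd
import pytest

from hoiforest.census import (
    CensusConsistencyError,
    CensusValidationError,
    LinkReport,
    PlotMeta,
    SchemaError,
    apply_species_filters,
    link_censuses,
    main_stems,
    read_census_table,
    write_census_table,
)


def census_frame(rows):
    return pd.DataFrame(
        rows, columns=["treeID", "stemID", "sp", "gx", "gy", "dbh", "status", "date"]
    )


@pytest.fixture
def meta():
    return PlotMeta("p1", 5.0, 100.0, 100.0, (2000.0, 2005.0))


class TestReadCensusTable:
    def test_well_formed_rows_parse_identically(self, tmp_path):
        df = census_frame(
            [
                ["t1", "1", "spA", 1.0, 2.0, 10.0, "alive", 2000.0],
                ["t2", "1", "spB", 3.0, 4.0, 5.0, "alive", 2000.0],
                ["t3", "1", "spA", 5.0, 6.0, 2.5, "dead", 2000.0],
            ]
        )
        path = tmp_path / "c1.tsv"
        write_census_table(df, path)
        back = read_census_table(path)
        assert len(back) == 3
        pd.testing.assert_frame_equal(back, df)

    def test_roundtrip_preserves_all_records(self, tmp_path, rng):
        n = 40
        df = census_frame(
            [
                [f"t{i}", "1", f"s{i % 4}", float(i), float(i) / 2, 1.0 + i, "alive", 2000.0]
                for i in range(n)
            ]
        )
        path = tmp_path / "c.tsv"
        write_census_table(df, path)
        pd.testing.assert_frame_equal(read_census_table(path), df)

    def test_alive_stem_below_census_minimum_rejected(self, tmp_path, caplog):
        df = census_frame(
            [
                ["t1", "1", "spA", 1.0, 2.0, 0.5, "alive", 2000.0],
                ["t2", "1", "spA", 3.0, 4.0, 2.0, "alive", 2000.0],
            ]
        )
        path = tmp_path / "c.tsv"
        write_census_table(df, path)
        with caplog.at_level("INFO"):
            back = read_census_table(path)
        assert list(back["treeID"]) == ["t2"]
        assert "dbh below census minimum" in caplog.text

    def test_out_of_bounds_coordinate_names_the_row(self, tmp_path):
        df = census_frame(
            [
                ["t1", "1", "spA", 101.0, 2.0, 3.0, "alive", 2000.0],
            ]
        )
        path = tmp_path / "c.tsv"
        write_census_table(df, path)
        with pytest.raises(CensusValidationError, match=r"gx outside \[0, 100.0\].*\[0\]"):
            read_census_table(path, x_extent=100.0, y_extent=100.0)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "c.csv"
        pd.DataFrame({"treeID": ["t1"], "sp": ["a"]}).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="missing required columns"):
            read_census_table(path)

    def test_schema_map_renames_dialect_columns(self, tmp_path):
        pd.DataFrame(
            {
                "tag": ["t1"], "stem": ["1"], "species": ["a"], "x": [1.0],
                "y": [2.0], "diam": [5.0], "state": ["alive"], "year": [2000.0],
            }
        ).to_csv(tmp_path / "c.csv", index=False)
        schema = {"tag": "treeID", "stem": "stemID", "species": "sp", "x": "gx",
                  "y": "gy", "diam": "dbh", "state": "status", "year": "date"}
        back = read_census_table(tmp_path / "c.csv", schema)
        assert back.loc[0, "dbh"] == 5.0


class TestLinkCensuses:
    def test_growth_and_survival_arithmetic(self, meta):
        c1 = census_frame([["t1", "1", "spA", 1.0, 2.0, 10.0, "alive", 2000.0]])
        c2 = census_frame([["t1", "1", "spA", 1.0, 2.0, 15.0, "alive", 2005.0]])
        dyn = link_censuses(c1, c2, meta)
        assert dyn.loc[0, "growth"] == pytest.approx(1.0)
        assert dyn.loc[0, "survived"] == 1

    def test_death_leaves_growth_undefined(self, meta):
        c1 = census_frame([["t1", "1", "spA", 1.0, 2.0, 10.0, "alive", 2000.0]])
        c2 = census_frame([["t1", "1", "spA", 1.0, 2.0, 10.0, "dead", 2005.0]])
        dyn = link_censuses(c1, c2, meta)
        assert dyn.loc[0, "survived"] == 0
        assert np.isnan(dyn.loc[0, "growth"])

    def test_nonpositive_increment_floored(self, meta):
        c1 = census_frame([["t1", "1", "spA", 1.0, 2.0, 10.0, "alive", 2000.0]])
        c2 = census_frame([["t1", "1", "spA", 1.0, 2.0, 9.0, "alive", 2005.0]])
        rep = LinkReport()
        dyn = link_censuses(c1, c2, meta, growth_floor=0.01, report=rep)
        assert dyn.loc[0, "growth"] == pytest.approx(0.01)
        assert rep.n_nonpositive_growth == 1

    def test_drop_policy_removes_nonpositive_growth(self, meta):
        c1 = census_frame([["t1", "1", "spA", 1.0, 2.0, 10.0, "alive", 2000.0]])
        c2 = census_frame([["t1", "1", "spA", 1.0, 2.0, 9.0, "alive", 2005.0]])
        dyn = link_censuses(c1, c2, meta, nonpositive_policy="drop")
        assert np.isnan(dyn.loc[0, "growth"])
        assert dyn.loc[0, "survived"] == 1

    def test_unflagged_new_stem_is_consistency_error(self, meta):
        c1 = census_frame([["t1", "1", "spA", 1.0, 2.0, 10.0, "alive", 2000.0]])
        c2 = census_frame(
            [
                ["t1", "1", "spA", 1.0, 2.0, 11.0, "alive", 2005.0],
                ["t9", "1", "spA", 5.0, 5.0, 2.0, "alive", 2005.0],
            ]
        )
        with pytest.raises(CensusConsistencyError):
            link_censuses(c1, c2, meta)

    def test_recruits_excluded_from_dynamics(self, meta):
        c1 = census_frame([["t1", "1", "spA", 1.0, 2.0, 10.0, "alive", 2000.0]])
        c2 = census_frame(
            [
                ["t1", "1", "spA", 1.0, 2.0, 11.0, "alive", 2005.0],
                ["t9", "1", "spA", 5.0, 5.0, 2.0, "recruit", 2005.0],
            ]
        )
        dyn = link_censuses(c1, c2, meta)
        assert list(dyn["treeID"]) == ["t1"]

    def test_main_stem_is_largest_dbh(self):
        c1 = census_frame(
            [
                ["t1", "1", "spA", 1.0, 2.0, 10.0, "alive", 2000.0],
                ["t1", "2", "spA", 1.0, 2.0, 14.0, "alive", 2000.0],
            ]
        )
        ms = main_stems(c1)
        assert len(ms) == 1
        assert ms.loc[0, "stemID"] == "2"

    def test_linking_partitions_census1_main_stems(self, meta, rng):
        n = 60
        c1 = census_frame(
            [
                [f"t{i}", "1", "spA", float(rng.uniform(0, 100)), 1.0,
                 float(rng.uniform(1, 30)), "alive", 2000.0]
                for i in range(n)
            ]
        )
        survived = rng.random(n) < 0.8
        c2 = c1.copy()
        c2["status"] = np.where(survived, "alive", "dead")
        c2["date"] = 2005.0
        dyn = link_censuses(c1, c2, meta)
        assert len(dyn) == n
        assert set(dyn["treeID"]) == set(c1["treeID"])
        assert dyn["survived"].sum() == survived.sum()


class TestSpeciesFilters:
    @staticmethod
    def dynamics(counts):
        rows = []
        for sp, (n_alive, n_dead) in counts.items():
            for i in range(n_alive):
                rows.append({"sp": sp, "survived": 1})
            for i in range(n_dead):
                rows.append({"sp": sp, "survived": 0})
        return pd.DataFrame(rows)

    def test_growth_threshold_is_strictly_more_than_100(self):
        dyn = self.dynamics({"a": (100, 0), "b": (101, 0)})
        assert apply_species_filters(dyn, "growth") == ["b"]

    def test_survival_needs_both_outcome_classes(self):
        dyn = self.dynamics({"a": (135, 15)})
        assert apply_species_filters(dyn, "growth") == ["a"]
        assert apply_species_filters(dyn, "survival") == []

    def test_survival_twenty_twenty_rule(self):
        dyn = self.dynamics({"a": (101, 20), "b": (82, 19)})
        assert apply_species_filters(dyn, "survival") == ["a"]

    def test_empty_plot_gives_empty_list(self):
        assert apply_species_filters(pd.DataFrame(columns=["sp", "survived"]), "growth") == []

    def test_adding_trees_never_removes_growth_eligibility(self):
        base = {"a": (120, 10)}
        dyn = self.dynamics(base)
        assert apply_species_filters(dyn, "growth") == ["a"]
        bigger = self.dynamics({"a": (180, 30)})
        assert apply_species_filters(bigger, "growth") == ["a"]
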