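import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitspace.trait_data import (
    TraitDataError,
    default_dictionary,
    load_fuzzy_table,
    load_trait_dictionary,
    merge_tables,
    standardize_by_group,
    summarize_missing,
    write_fuzzy_table,
)

from conftest import make_dictionary, make_table


class TestTraitDictionary:
    def test_bundled_dictionary_has_full_trait_inventory(self):
        d = default_dictionary()
        assert d.n_groups == 11
        assert d.n_traits == 63
        assert d.abbreviations[0] == "FH1"
        assert d.abbreviations[-1] == "RP8"
        assert set(np.unique(d.column_max_codes())) == {3, 5}

    def test_minimal_dictionary_is_valid(self):
        d = make_dictionary([("G", 3, ["X1"])])
        assert d.n_groups == 1 and d.n_traits == 1

    def test_duplicate_abbreviation_rejected(self):
        with pytest.raises(TraitDataError, match="FH1"):
            make_dictionary([("A", 3, ["FH1"]), ("B", 5, ["FH1"])])

    def test_empty_group_rejected(self):
        with pytest.raises(TraitDataError, match="no traits"):
            make_dictionary([("A", 3, [])])

    def test_json_and_tsv_loaders_agree(self, tiny_dictionary, tmp_path):
        payload = {
            "groups": [
                {
                    "name": g.name,
                    "max_code": g.max_code,
                    "traits": [{"name": t.name, "abbr": t.abbr} for t in g.traits],
                }
                for g in tiny_dictionary.groups
            ]
        }
        jpath = tmp_path / "dict.json"
        jpath.write_text(json.dumps(payload))
        lines = ["group\tmax_code\ttrait\tabbr"]
        for g in tiny_dictionary.groups:
            for t in g.traits:
                lines.append(f"{g.name}\t{g.max_code}\t{t.name}\t{t.abbr}")
        tpath = tmp_path / "dict.tsv"
        tpath.write_text("\n".join(lines) + "\n")
        assert load_trait_dictionary(jpath) == load_trait_dictionary(tpath)


class TestLoadFuzzyTable:
    def _write(self, tmp_path, rows, header="taxon\tgroup\tF1\tF2\tS1\tS2\tS3"):
        path = tmp_path / "table.tsv"
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    def test_complete_file_masks_all_true(self, tiny_dictionary, tmp_path):
        path = self._write(
            tmp_path, ["a\tG1\t0\t3\t1\t4\t5", "b\tG2\t2\t1\t0\t0\t3"]
        )
        t = load_fuzzy_table(path, tiny_dictionary)
        assert t.mask.all()
        assert t.matrix.tolist() == [[0, 3, 1, 4, 5], [2, 1, 0, 0, 3]]
        assert t.groups == ["G1", "G2"]

    def test_na_cell_is_masked(self, tiny_dictionary, tmp_path):
        path = self._write(tmp_path, ["a\tG\t0\tNA\t1\t\t5"])
        t = load_fuzzy_table(path, tiny_dictionary)
        assert not t.mask[0, 1] and not t.mask[0, 3]
        assert t.mask[0, [0, 2, 4]].all()

    def test_negative_value_raises_range_error(self, tiny_dictionary, tmp_path):
        path = self._write(tmp_path, ["a\tG\t0\t-1\t1\t2\t5"])
        with pytest.raises(TraitDataError, match="out of range"):
            load_fuzzy_table(path, tiny_dictionary)

    def test_value_above_group_max_names_row_and_column(
        self, tiny_dictionary, tmp_path
    ):
        path = self._write(tmp_path, ["a\tG\t0\t7\t1\t2\t5"])
        with pytest.raises(TraitDataError, match=r"'a'.*'F2'"):
            load_fuzzy_table(path, tiny_dictionary)

    def test_unknown_trait_column_listed(self, tiny_dictionary, tmp_path):
        path = self._write(
            tmp_path, ["a\tG\t0\t1\t1\t2\t5"], header="taxon\tgroup\tF1\tF2\tS1\tS2\tZZ9"
        )
        with pytest.raises(TraitDataError, match="ZZ9"):
            load_fuzzy_table(path, tiny_dictionary)

    def test_columns_reordered_to_dictionary_order(self, tiny_dictionary, tmp_path):
        path = self._write(
            tmp_path, ["a\tG\t5\t4\t0\t3\t1"], header="taxon\tgroup\tS3\tS2\tF1\tF2\tS1"
        )
        t = load_fuzzy_table(path, tiny_dictionary)
        assert t.matrix.tolist() == [[0, 3, 1, 4, 5]]


class TestRoundTrip:
    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(data=st.data())
    def test_write_then_load_is_bit_exact(self, tmp_path_factory, data):
        tiny_dictionary = make_dictionary(
            [("Feeding", 3, ["F1", "F2"]), ("Size", 5, ["S1", "S2", "S3"])]
        )
        n = data.draw(st.integers(1, 8))
        max_codes = tiny_dictionary.column_max_codes()
        matrix = np.array(
            [
                [data.draw(st.integers(0, int(m))) for m in max_codes]
                for _ in range(n)
            ]
        )
        mask = np.array(
            [[data.draw(st.booleans()) for _ in max_codes] for _ in range(n)]
        )
        table = make_table(tiny_dictionary, matrix, mask=mask)
        # unobserved cells are written empty; normalize them to 0 for comparison
        path = tmp_path_factory.mktemp("rt") / "t.tsv"
        write_fuzzy_table(table, path)
        back = load_fuzzy_table(path, tiny_dictionary)
        assert (back.mask == table.mask).all()
        assert (back.matrix[back.mask] == table.matrix[table.mask]).all()
        assert back.taxon_ids == table.taxon_ids


class TestMergeTables:
    def test_merge_reaches_full_taxon_count(self, tiny_dictionary):
        # mirrors extending a 552-taxon base with 44 extra taxa to reach 596,
        # scaled down
        base = make_table(tiny_dictionary, np.zeros((5, 5), dtype=int))
        add_dict = make_dictionary([("Feeding", 3, ["F2"]), ("Size", 5, ["S1", "S2", "S3"])])
        addition = make_table(add_dict, np.ones((3, 4), dtype=int))
        addition.taxon_ids = [f"x{i}" for i in range(3)]
        merged = merge_tables(base, addition, zero_fill=["F1"])
        assert merged.n_taxa == 8
        assert merged.n_traits == base.n_traits

    def test_zero_fill_gives_observed_zeros(self, tiny_dictionary):
        base = make_table(tiny_dictionary, np.ones((2, 5), dtype=int))
        add_dict = make_dictionary([("Size", 5, ["S1", "S2", "S3"])])
        addition = make_table(add_dict, [[1, 2, 3]])
        addition.taxon_ids = ["x0"]
        merged = merge_tables(base, addition, zero_fill=["F1", "F2"])
        assert merged.matrix[2, :2].tolist() == [0, 0]
        assert merged.mask[2, :2].all()  # explicit zeros, not missing

    def test_name_map_matches_renamed_traits(self, tiny_dictionary):
        base = make_table(tiny_dictionary, np.ones((1, 5), dtype=int))
        add_dict = make_dictionary(
            [("Feeding", 3, ["D1", "D2"]), ("Size", 5, ["S1", "S2", "S3"])]
        )
        addition = make_table(add_dict, [[3, 2, 1, 1, 1]])
        addition.taxon_ids = ["x0"]
        merged = merge_tables(base, addition, name_map={"D1": "F1", "D2": "F2"})
        assert merged.matrix[1].tolist() == [3, 2, 1, 1, 1]

    def test_unmapped_addition_trait_rejected(self, tiny_dictionary):
        base = make_table(tiny_dictionary, np.ones((1, 5), dtype=int))
        add_dict = make_dictionary([("Other", 3, ["Q1"])])
        addition = make_table(add_dict, [[1]])
        addition.taxon_ids = ["x0"]
        with pytest.raises(TraitDataError, match="Q1"):
            merge_tables(base, addition)

    def test_taxon_collision_rejected(self, tiny_dictionary):
        base = make_table(tiny_dictionary, np.ones((2, 5), dtype=int))
        addition = make_table(tiny_dictionary, np.ones((1, 5), dtype=int))
        with pytest.raises(TraitDataError, match="collision"):
            merge_tables(base, addition)

    def test_empty_addition_leaves_base_unchanged(self, tiny_dictionary):
        base = make_table(tiny_dictionary, np.ones((3, 5), dtype=int))
        addition = make_table(tiny_dictionary, np.zeros((0, 5), dtype=int))
        merged = merge_tables(base, addition)
        assert merged.n_taxa == 3
        assert (merged.matrix == base.matrix).all()


class TestStandardize:
    @pytest.mark.parametrize(
        "cell, expected",
        [((0, 0), 1.0), ((0, 1), 0.0), ((0, 2), 0.4)],
        ids=["max of 0-3 group -> 1", "zero -> 0", "2 in 0-5 group -> 0.4"],
    )
    def test_max_code_division(self, tiny_dictionary, cell, expected):
        table = make_table(tiny_dictionary, [[3, 0, 2, 5, 1]])
        std = standardize_by_group(table)
        assert std.matrix[cell] == pytest.approx(expected)
        assert std.standardization_mode == "max_code"

    def test_missing_cells_stay_missing_and_range_holds(self, tiny_dictionary):
        mask = [[True, False, True, True, False]]
        table = make_table(tiny_dictionary, [[3, 0, 2, 5, 1]], mask=mask)
        std = standardize_by_group(table)
        assert (std.mask == table.mask).all()
        vals = std.matrix[std.mask]
        assert (vals >= 0).all() and (vals <= 1).all()

    def test_rescaling_already_unit_coded_table_is_identity(self):
        d = make_dictionary([("G", 1, ["U1", "U2"])])
        table = make_table(d, [[1, 0], [0, 1]])
        std = standardize_by_group(table)
        assert np.array_equal(std.matrix, table.matrix.astype(float))

    def test_observed_minmax_mode(self, tiny_dictionary):
        table = make_table(tiny_dictionary, [[1, 3, 0, 2, 4], [2, 1, 1, 3, 0]])
        std = standardize_by_group(table, mode="observed_minmax")
        feeding = std.matrix[:, :2]
        assert feeding.min() == 0.0 and feeding.max() == 1.0


class TestSummarizeMissing:
    def test_study_scale_missingness_percent(self, tiny_dictionary):
        # 388 missing cells out of 596 x 63 is 1.03%
        rng = np.random.default_rng(0)
        mask = np.ones((596, 63), dtype=bool)
        flat = rng.choice(596 * 63, size=388, replace=False)
        mask[np.unravel_index(flat, mask.shape)] = False
        d = make_dictionary([("G", 3, [f"T{j}" for j in range(63)])])
        table = make_table(d, np.zeros((596, 63), dtype=int), mask=mask)
        assert summarize_missing(table) == {"count": 388, "percent": 1.03}

    def test_fully_observed_table(self, tiny_dictionary):
        table = make_table(tiny_dictionary, np.zeros((2, 5), dtype=int))
        assert summarize_missing(table) == {"count": 0, "percent": 0.0}

    def test_one_of_four_cells(self):
        d = make_dictionary([("G", 3, ["A1", "A2"])])
        mask = [[True, False], [True, True]]
        table = make_table(d, np.zeros((2, 2), dtype=int), mask=mask)
        assert summarize_missing(table) == {"count": 1, "percent": 25.0}
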