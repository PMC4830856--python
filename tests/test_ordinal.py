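"""Reading, recoding and domain scoring of ordinal questionnaire data."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qolnet import (
    DataError,
    ItemSpec,
    OrdinalDataset,
    default_sf36_map,
    read_ordinal_csv,
    score_domains,
    sf36_instrument,
)

THREE_ITEMS = [
    ItemSpec("a", 3, domain="D"),
    ItemSpec("b", 3, domain="D"),
    ItemSpec("c", 5, domain="E"),
]


def _write(tmp_path, text, name="data.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadOrdinalCsv:
    def test_one_based_codes_recode_to_zero_based(self, tmp_path):
        path = _write(tmp_path, "a,b,c\n1,2,5\n2,3,1\n3,1,3\n")
        data = read_ordinal_csv(path, THREE_ITEMS)
        assert data.values[:, 0].tolist() == [0, 1, 2]
        assert set(np.unique(data.values)) <= {0, 1, 2, 3, 4}

    def test_incomplete_rows_dropped_listwise(self, tmp_path, caplog):
        path = _write(tmp_path, "a,b,c\n1,2,5\n2,,1\n3,1,3\n")
        with caplog.at_level("INFO"):
            data = read_ordinal_csv(path, THREE_ITEMS)
        assert data.n_respondents == 2
        assert "1" in caplog.text  # drop count logged

    def test_out_of_range_code_identifies_the_cell(self, tmp_path):
        path = _write(tmp_path, "a,b,c\n1,2,7\n2,3,1\n3,2,1\n")
        with pytest.raises(DataError, match="c"):
            read_ordinal_csv(path, THREE_ITEMS)

    def test_unknown_column_rejected_by_name(self, tmp_path):
        path = _write(tmp_path, "a,b,c,zzz\n1,2,3,1\n2,1,2,1\n3,1,1,1\n")
        with pytest.raises(DataError, match="zzz"):
            read_ordinal_csv(path, THREE_ITEMS)

    def test_empty_file_rejected(self, tmp_path):
        path = _write(tmp_path, "a,b,c\n")
        with pytest.raises(DataError):
            read_ordinal_csv(path, THREE_ITEMS)

    def test_group_column_is_preserved(self, tmp_path):
        path = _write(tmp_path, "a,b,c,grp\n1,2,5,x\n2,3,1,y\n3,1,3,x\n")
        data = read_ordinal_csv(path, THREE_ITEMS, group_col="grp")
        assert data.group.tolist() == ["x", "y", "x"]
        groups = data.split_groups()
        assert groups["x"].n_respondents == 2

    def test_offset_invariance_of_scores(self, tmp_path):
        """Codes {1..K} and {0..K-1} give identical domain scores."""
        rng = np.random.default_rng(0)
        codes = np.column_stack(
            [rng.integers(0, 3, 30), rng.integers(0, 3, 30), rng.integers(0, 5, 30)]
        )
        # force the full range so the origin is unambiguous in both codings
        codes[0] = [0, 0, 0]
        codes[1] = [2, 2, 4]
        zero = _write(tmp_path, "a,b,c\n" + "\n".join(
            ",".join(map(str, row)) for row in codes), "zero.csv")
        one = _write(tmp_path, "a,b,c\n" + "\n".join(
            ",".join(map(str, row + 1)) for row in codes), "one.csv")
        s0 = score_domains(read_ordinal_csv(zero, THREE_ITEMS))
        s1 = score_domains(read_ordinal_csv(one, THREE_ITEMS))
        np.testing.assert_allclose(s0.scores, s1.scores)


class TestScoreDomains:
    def test_anchors_and_midpoint(self):
        items = [ItemSpec(f"i{k}", 3, domain="D") for k in range(10)]
        lo = OrdinalDataset(np.zeros((1, 10), dtype=int), items)
        hi = OrdinalDataset(np.full((1, 10), 2, dtype=int), items)
        mid = OrdinalDataset(np.array([[1] * 10]), items)
        assert score_domains(lo).scores[0, 0] == 0.0
        assert score_domains(hi).scores[0, 0] == 100.0
        # raw sum 10 of max 20 -> 50
        assert score_domains(mid).scores[0, 0] == 50.0

    def test_reverse_coded_items_flip(self):
        items = [ItemSpec("r", 4, reverse_coded=True, domain="D")]
        data = OrdinalDataset(np.array([[0], [3]]), items)
        scores = score_domains(data).scores[:, 0]
        assert scores.tolist() == [100.0, 0.0]

    def test_domain_without_items_rejected(self):
        data = OrdinalDataset(np.array([[0, 1]]), [ItemSpec("a", 3), ItemSpec("b", 3)])
        with pytest.raises(DataError, match="empty"):
            score_domains(data, {"empty": []})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_monotone_in_any_item(self, data):
        """Raising a non-reversed item's code never lowers its domain score."""
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        items = [ItemSpec(f"i{k}", 4, domain="D") for k in range(4)]
        values = rng.integers(0, 4, size=(5, 4))
        row = data.draw(st.integers(0, 4))
        col = data.draw(st.integers(0, 3))
        values[row, col] = min(values[row, col], 2)
        base = score_domains(OrdinalDataset(values.copy(), items)).scores[row, 0]
        values[row, col] += 1
        bumped = score_domains(OrdinalDataset(values, items)).scores[row, 0]
        assert bumped >= base


class TestSf36Instrument:
    def test_domain_cardinalities(self):
        mapping = default_sf36_map()
        sizes = {d: len(v) for d, v in mapping.items()}
        assert sizes == {
            "Physical functioning": 10,
            "Role limitations-physical": 4,
            "Bodily pain": 2,
            "General health": 5,
            "Vitality": 4,
            "Social functioning": 2,
            "Role limitations-emotional": 3,
            "Mental health": 5,
        }
        assert sum(sizes.values()) == 35  # item 2 excluded

    def test_table_allocations(self):
        mapping = default_sf36_map()
        assert set(mapping["Mental health"]) == {"9b", "9c", "9d", "9f", "9h"}
        assert set(mapping["Role limitations-physical"]) == {"4a", "4b", "4c", "4d"}

    def test_item_2_outside_every_domain(self):
        instrument = sf36_instrument()
        item2 = next(it for it in instrument if it.label == "2")
        assert item2.domain == "none"
        assert len(instrument) == 36

    def test_diagnostic_status_is_binary_extra_item(self):
        instrument = sf36_instrument(include_diagnostic_status=True)
        assert len(instrument) == 37
        ds = instrument[-1]
        assert ds.label == "DS" and ds.n_categories == 2 and ds.domain == "none"
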