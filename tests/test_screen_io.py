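"""Readers/writers, identifier harmonization, and parse accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from uvddr import screen_io
from uvddr.screen_io import (
    CategorySet,
    Condition,
    FormatError,
    PTMSiteTable,
    RNAiWellProfile,
    ScreenTable,
    harmonize_id,
    read_categories,
    read_network,
    read_ptm_table,
    read_rnai_wells,
    read_screen_table,
    write_categories,
    write_network,
    write_ptm_table,
    write_rnai_wells,
    write_screen_table,
)


class TestHarmonizeId:
    @pytest.mark.parametrize(
        "raw, aliases, expected",
        [
            (" csb ", None, "CSB"),
            ("ERCC6", {"ERCC6": "CSB"}, "CSB"),  # CSB is also named ERCC6
            ("Stk19", None, "STK19"),
            ("trf2", {"TRF2": "TERF2"}, "TERF2"),
        ],
    )
    def test_examples(self, raw, aliases, expected):
        assert harmonize_id(raw, aliases) == expected

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            harmonize_id("   ")

    @given(st.text(alphabet=st.characters(categories=["Lu", "Ll", "Nd"]), min_size=1))
    def test_idempotent(self, raw):
        aliases = {"ERCC6": "CSB"}
        once = harmonize_id(raw, aliases)
        assert harmonize_id(once, aliases) == once


class TestReadScreenTable:
    def _write(self, tmp_path, rows, header="protein_id\tlog2_ratio"):
        p = tmp_path / "screen.tsv"
        p.write_text("\n".join([header, *rows]) + "\n")
        return p

    def test_direct_parse(self, tmp_path):
        p = self._write(tmp_path, ["A\t1.0", "B\t-0.5", "C\t2.2"])
        table, report = read_screen_table(p, "csb_interactome", Condition())
        assert len(table.data) == 3
        assert table.ratios["C"] == pytest.approx(2.2)
        assert report.rows_in == report.rows_kept == 3

    def test_duplicate_collapses_to_max_abs(self, tmp_path):
        p = self._write(tmp_path, ["A\t1.0", "A\t3.0", "B\t-4.0", "B\t0.5"])
        table, report = read_screen_table(p, "csb_interactome")
        assert table.ratios["A"] == pytest.approx(3.0)
        assert table.ratios["B"] == pytest.approx(-4.0)  # strongest |ratio| wins
        assert report.duplicates_collapsed == 2

    def test_duplicate_mean_rule(self, tmp_path):
        p = self._write(tmp_path, ["A\t1.0", "A\t3.0"])
        table, _ = read_screen_table(p, "csb_interactome", collapse="mean")
        assert table.ratios["A"] == pytest.approx(2.0)

    def test_empty_file_with_header(self, tmp_path):
        p = self._write(tmp_path, [])
        table, report = read_screen_table(p, "chromatin")
        assert len(table.data) == 0
        assert any("no rows" in m for m in report.messages)

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("protein_id\tvalue\nA\t1.0\n")
        with pytest.raises(FormatError, match="log2_ratio"):
            read_screen_table(p, "chromatin")

    def test_non_numeric_rows_dropped_and_accounted(self, tmp_path):
        p = self._write(tmp_path, ["A\t1.0", "B\tnot_a_number", "C\t2.0"])
        table, report = read_screen_table(p, "chromatin")
        assert len(table.data) == 2
        assert report.rows_in == report.rows_kept + report.rows_rejected

    def test_roundtrip(self, tmp_path, small_bundle):
        original = small_bundle.screens["csb_interactome"][0]
        path = tmp_path / "rt.tsv"
        write_screen_table(original, path)
        back, _ = read_screen_table(path, original.screen_id, original.condition)
        pd.testing.assert_frame_equal(
            back.data.sort_values("protein_id").reset_index(drop=True),
            original.data.sort_values("protein_id").reset_index(drop=True),
            check_exact=False,
        )


class TestScreenTableInvariants:
    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame({"protein_id": ["A", "A"], "log2_ratio": [1.0, 2.0]})
        with pytest.raises(ValueError):
            ScreenTable("chromatin", Condition(), df)

    def test_nonfinite_ratio_rejected(self):
        df = pd.DataFrame({"protein_id": ["A"], "log2_ratio": [np.inf]})
        with pytest.raises(ValueError):
            ScreenTable("chromatin", Condition(), df)


class TestReadPTMTable:
    def _write(self, tmp_path, rows):
        p = tmp_path / "ptm.tsv"
        p.write_text("protein_id\tsite\twindow\tlog2_ratio\n" + "\n".join(rows) + "\n")
        return p

    def test_site_token_parse(self, tmp_path):
        # ubiquitylated RPA1 K163, a canonical UV-induced site
        p = self._write(tmp_path, ["RPA1\tK163\tAAAKAAA\t2.1"])
        table, report = read_ptm_table(p, "ubiquitin")
        row = table.data.iloc[0]
        assert (row.protein_id, row.residue, row.position) == ("RPA1", "K", 163)
        assert report.rows_kept == 1

    def test_window_centre_mismatch_rejected(self, tmp_path):
        p = self._write(tmp_path, ["H2AFX\tS140\tAAAQAAA\t1.0"])
        table, report = read_ptm_table(p, "phospho")
        assert len(table.data) == 0 and report.rows_invalid == 1

    def test_five_valid_one_invalid(self, tmp_path):
        rows = [f"P{i}\tS{10 + i}\tAAASAAA\t0.{i}" for i in range(5)]
        rows.append("BAD\tXYZ\tAAASAAA\t1.0")  # malformed site token
        table, report = read_ptm_table(self._write(tmp_path, rows), "phospho")
        assert len(table.data) == 5
        assert report.rows_invalid == 1
        assert report.rows_in == report.rows_kept + report.rows_rejected

    def test_residue_modification_consistency(self, tmp_path):
        p = self._write(tmp_path, ["A\tK5\tAAKAA\t1.0".replace("AAKAA", "AAKAA")])
        table, _ = read_ptm_table(p, "phospho")  # K centre invalid for phospho
        assert len(table.data) == 0

    def test_roundtrip(self, tmp_path, small_bundle):
        original = small_bundle.ptm["phospho"]
        path = tmp_path / "rt.tsv"
        write_ptm_table(original, path)
        back, report = read_ptm_table(path, "phospho")
        assert report.rows_invalid == 0
        pd.testing.assert_frame_equal(back.data, original.data, check_exact=False)


class TestCategories:
    def test_gmt_universe_restriction(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("TCR\tdesc\tCSB\tCSA\tUVSSA\n")
        cats = read_categories(p, universe={"CSB", "CSA", "UVSSA", "X"})
        assert cats.members("TCR") == {"CSB", "CSA", "UVSSA"}

    def test_member_outside_universe_dropped(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("TCR\tdesc\tCSB\tNOTTHERE\n")
        cats = read_categories(p, universe={"CSB"})
        assert cats.members("TCR") == {"CSB"}

    def test_duplicate_members_deduplicated(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("TCR\tdesc\tCSB\tCSB\tCSA\n")
        cats = read_categories(p)
        assert len(cats.members("TCR")) == 2

    def test_empty_category_dropped(self):
        cats = CategorySet({"E": ("empty", {"Z"})}, universe={"A"})
        assert "E" not in cats

    def test_roundtrip(self, tmp_path, small_bundle):
        path = tmp_path / "rt.gmt"
        write_categories(small_bundle.categories, path)
        back = read_categories(path, universe=small_bundle.categories.universe)
        assert back.categories.keys() == small_bundle.categories.categories.keys()
        for cid in back.categories:
            assert back.members(cid) == small_bundle.categories.members(cid)


class TestNetworkAndWells:
    def test_network_dedupe_and_self_loops(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("protein_a\tprotein_b\nA\tB\nB\tA\nC\tC\nA\tD\n")
        g = read_network(p)
        assert g.number_of_edges() == 2
        assert not any(a == b for a, b in g.edges)

    def test_network_roundtrip(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("protein_a\tprotein_b\nCDK9\tCCNT2\nCDK9\tHTATSF1\n")
        g = read_network(p)
        write_network(g, tmp_path / "rt.tsv")
        g2 = read_network(tmp_path / "rt.tsv")
        assert set(map(frozenset, g.edges)) == set(map(frozenset, g2.edges))

    def test_wells_roundtrip_cells(self, tmp_path, small_bundle):
        subset = small_bundle.rnai_wells[:20]
        path = tmp_path / "wells.tsv"
        write_rnai_wells(subset, path, decimals=4)
        back = read_rnai_wells(path)
        assert len(back) == len(subset)
        for a, b in zip(subset, back):
            assert (a.plate_id, a.well_id, a.target_gene, a.control_type) == (
                b.plate_id, b.well_id, b.target_gene, b.control_type)
            np.testing.assert_allclose(a.cells, b.cells, rtol=0, atol=1e-3)

    def test_wells_summary_mode(self, tmp_path):
        w = RNAiWellProfile("PL1", "W1", "STK19", n_cells=120,
                            median_intensity=800.0, fraction_low=0.4)
        path = tmp_path / "wells.tsv"
        write_rnai_wells([w], path)
        back = read_rnai_wells(path)[0]
        assert back.cells is None
        assert back.n_cells == 120
        assert back.fraction_low == pytest.approx(0.4)

    def test_fraction_low_bounds_enforced(self):
        with pytest.raises(ValueError):
            RNAiWellProfile("PL1", "W1", "X", n_cells=10, fraction_low=1.2)


def test_parse_reports_conserve_rows(tmp_path):
    """rows_in == rows_kept + rows_rejected for every reader."""
    p = tmp_path / "s.tsv"
    p.write_text("protein_id\tlog2_ratio\nA\t1\nA\t2\nB\tbad\nC\t3\n")
    _, report = read_screen_table(p, "chromatin")
    assert report.rows_in == report.rows_kept + report.rows_rejected == 4
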