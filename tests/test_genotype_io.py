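"""Panel I/O: AB coding, missing-data conventions, sorting, round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rohmap.genotypes import (AA, AB, BB, MISSING, GenotypePanel,
                              GenotypeError, PanelParseError,
                              PanelValidationError, Sample, natural_chrom_key,
                              read_annotation, read_matrix, read_panel,
                              write_matrix, write_panel)
from .conftest import build_panel


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadPanel:
    def test_single_allele_markers_code_as_AA(self, tmp_path):
        map_p = _write(tmp_path, "a.map",
                       "1 m1 0.0 100\n1 m2 0.1 200\n1 m3 0.2 300\n")
        ped_p = _write(tmp_path, "a.ped",
                       "F i1 0 0 1 2 1 1 1 1 1 1\nF i2 0 0 2 1 1 1 1 1 1 1\n")
        panel = read_panel(ped_p, map_p)
        assert panel.calls.shape == (3, 2)
        assert (panel.calls == AA).all()
        assert panel.samples[0].status == "affected"
        assert panel.samples[1].status == "unaffected"

    def test_ab_coding_lexicographic_and_unordered(self, tmp_path):
        map_p = _write(tmp_path, "b.map", "1 m1 0.0 100\n")
        ped_p = _write(tmp_path, "b.ped",
                       "F i1 0 0 0 0 A A\nF i2 0 0 0 0 A G\n"
                       "F i3 0 0 0 0 G A\nF i4 0 0 0 0 G G\n")
        panel = read_panel(ped_p, map_p)
        assert panel.calls[0].tolist() == [AA, AB, AB, BB]

    def test_zero_alleles_become_missing(self, tmp_path):
        map_p = _write(tmp_path, "c.map", "1 m1 0.0 100\n1 m2 0.1 200\n")
        ped_p = _write(tmp_path, "c.ped", "F i1 0 0 0 0 0 0 A A\n")
        panel = read_panel(ped_p, map_p)
        assert panel.calls[:, 0].tolist() == [MISSING, AA]

    def test_markers_sorted_naturally_by_chrom_then_bp(self, tmp_path):
        map_p = _write(tmp_path, "d.map",
                       "10 m1 0.0 100\n2 m2 0.0 500\n2 m3 0.0 100\nX m4 0.0 50\n")
        ped_p = _write(tmp_path, "d.ped",
                       "F i1 0 0 0 0 A A C C G G T T\n")
        panel = read_panel(ped_p, map_p)
        assert panel.markers["id"].tolist() == ["m3", "m2", "m1", "m4"]

    def test_malformed_row_names_line(self, tmp_path):
        map_p = _write(tmp_path, "e.map", "1 m1 0.0 100\n")
        ped_p = _write(tmp_path, "e.ped", "F i1 0 0 0 0 A\n")
        with pytest.raises(PanelParseError, match="line 1"):
            read_panel(ped_p, map_p)

    def test_three_alleles_rejected(self, tmp_path):
        map_p = _write(tmp_path, "f.map", "1 m1 0.0 100\n")
        ped_p = _write(tmp_path, "f.ped",
                       "F i1 0 0 0 0 A C\nF i2 0 0 0 0 G G\n")
        with pytest.raises(PanelValidationError, match="alleles"):
            read_panel(ped_p, map_p)

    def test_duplicate_marker_id_rejected(self, tmp_path):
        map_p = _write(tmp_path, "g.map", "1 m1 0.0 100\n1 m1 0.1 200\n")
        ped_p = _write(tmp_path, "g.ped", "F i1 0 0 0 0 A A A A\n")
        with pytest.raises(PanelValidationError, match="duplicate"):
            read_panel(ped_p, map_p)


class TestWritePanel:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(11)
        calls = rng.choice(["AA", "AB", "BB", "NA"], size=(10, 4))
        panel = build_panel(calls.tolist(),
                            statuses=["affected", "affected", "unaffected", "unknown"])
        write_panel(panel, tmp_path / "rt.ped", tmp_path / "rt.map")
        back = read_panel(tmp_path / "rt.ped", tmp_path / "rt.map")
        assert np.array_equal(back.calls, panel.calls)
        assert back.markers["id"].tolist() == panel.markers["id"].tolist()
        assert [s.status for s in back.samples] == [s.status for s in panel.samples]

    def test_missing_emitted_as_zero_zero(self, tmp_path):
        panel = build_panel(["NA AA"])
        write_panel(panel, tmp_path / "m.ped", tmp_path / "m.map")
        line = (tmp_path / "m.ped").read_text().splitlines()[0]
        assert line.endswith("0 0")

    def test_empty_sample_list_refused(self, tmp_path):
        markers = pd.DataFrame({"id": ["m1"], "chrom": ["1"], "pos_bp": [100],
                                "cm": [0.0], "maf": [0.1]})
        panel = GenotypePanel(markers, [], np.empty((1, 0), dtype=np.int8))
        with pytest.raises(GenotypeError):
            write_panel(panel, tmp_path / "x.ped", tmp_path / "x.map")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(2, 30), st.integers(1, 6))
def test_round_trip_property_random_panels(tmp_path_factory, seed, n_mark, n_samp):
    """read(write(p)) reproduces calls, marker order and pedigree fields."""
    rng = np.random.default_rng(seed)
    tmp = tmp_path_factory.mktemp("rt")
    calls = rng.choice(["AA", "AB", "BB", "NA"], size=(n_mark, n_samp))
    statuses = rng.choice(["affected", "unaffected", "unknown"], size=n_samp)
    panel = build_panel(calls.tolist(), statuses=list(statuses))
    write_panel(panel, tmp / "p.ped", tmp / "p.map")
    back = read_panel(tmp / "p.ped", tmp / "p.map")
    assert np.array_equal(back.calls, panel.calls)
    assert back.markers["pos_bp"].tolist() == panel.markers["pos_bp"].tolist()


class TestAnnotation:
    def test_full_row_parsed(self, tmp_path):
        p = _write(tmp_path, "ann.tsv",
                   "snp\tchrom\tpos_bp\tcm\tmaf\n"
                   "rs1324475\t9\t122423730\t135.2\t0.21\n"
                   "rs10987845\t9\t129841977\t140.0\t0.3\n")
        table = read_annotation(p)
        row = table.iloc[0]
        assert (row["id"], row["chrom"], row["pos_bp"]) == ("rs1324475", "9", 122423730)
        assert row["cm"] == 135.2 and row["maf"] == 0.21

    def test_empty_cm_preserved_as_nan(self, tmp_path):
        p = _write(tmp_path, "ann.tsv",
                   "snp\tchrom\tpos_bp\tcm\tmaf\n"
                   "rs1\t1\t100\t\t0.2\nrs2\t1\t200\t1.0\t0.2\n")
        table = read_annotation(p)
        assert np.isnan(table["cm"].iloc[0]) and table["cm"].iloc[1] == 1.0

    def test_duplicate_position_lists_both_ids(self, tmp_path):
        p = _write(tmp_path, "ann.tsv",
                   "snp\tchrom\tpos_bp\tcm\tmaf\n"
                   "rsA\t1\t100\t0.0\t0.2\nrsB\t1\t100\t0.1\t0.2\n")
        with pytest.raises(PanelValidationError) as err:
            read_annotation(p)
        assert "rsA" in str(err.value) and "rsB" in str(err.value)

    def test_missing_column_is_schema_error(self, tmp_path):
        p = _write(tmp_path, "ann.tsv", "snp\tchrom\tpos_bp\tcm\nrs1\t1\t100\t0\n")
        with pytest.raises(PanelParseError, match="maf"):
            read_annotation(p)


def test_matrix_tsv_round_trip(tmp_path):
    panel = build_panel(["AA AB", "BB NA", "AB AA"],
                        statuses=["affected", "unaffected"])
    write_matrix(panel, tmp_path / "g.tsv", tmp_path / "ped.tsv", tmp_path / "ann.tsv")
    back = read_matrix(tmp_path / "g.tsv", tmp_path / "ped.tsv", tmp_path / "ann.tsv")
    assert np.array_equal(back.calls, panel.calls)
    assert [s.status for s in back.samples] == ["affected", "unaffected"]


def test_unsorted_positions_rejected():
    with pytest.raises(PanelValidationError, match="increasing"):
        build_panel(["AA", "AA"], pos=[200, 100])


def test_pedigree_cycle_rejected():
    markers = pd.DataFrame({"id": ["m1"], "chrom": ["1"], "pos_bp": [100],
                            "cm": [0.0], "maf": [0.1]})
    samples = [Sample("a", "b", "b"), Sample("b", "a", "a")]
    with pytest.raises(PanelValidationError, match="cycle"):
        GenotypePanel(markers, samples, np.zeros((1, 2), dtype=np.int8))


def test_natural_chrom_order():
    labels = ["2", "10", "1", "X", "9"]
    assert sorted(labels, key=natural_chrom_key) == ["1", "2", "9", "10", "X"]
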