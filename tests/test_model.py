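"""Cell-table data model, I/O dialects, and ROI validation."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_cell, make_roi
from mifcyto.model import (MARKERS, STROMA, TUMOR_NEST, ParseError,
                           ROIValidationError, Sample, SchemaError,
                           read_cell_table, read_metadata_sidecar,
                           validate_roi, write_cell_table,
                           write_metadata_sidecar)
from mifcyto.synthetic import archetype_defaults, generate_roi


CANONICAL_HEADER = "cell_id,x_um,y_um,compartment," + ",".join(MARKERS)


def write_canonical(path, rows):
    lines = [CANONICAL_HEADER] + rows
    path.write_text("\n".join(lines) + "\n")


class TestReadCanonical:
    def test_three_row_table_parses_positions_and_area(self, tmp_path):
        p = tmp_path / "img0.csv"
        write_canonical(p, [
            "c1,10.5,20.0,stroma,1,0,0,1,0,0,0,0,0,0,1",
            "c2,30.0,40.0,tumor_nest,0,1,0,0,0,0,0,0,0,1,1",
            "c3,50.0,60.0,stroma,1,0,1,0,0,0,0,0,1,0,1",
        ])
        roi = read_cell_table(p, stroma_area_mm2=0.25, field_width_um=100,
                              field_height_um=100)
        assert roi.n_cells == 3
        assert roi.stroma_area_mm2 == 0.25
        assert roi.table.loc[0, "x_um"] == 10.5
        assert bool(roi.table.loc[1, "PDL1"])
        assert list(roi.table["compartment"]) == ["stroma", "tumor_nest",
                                                  "stroma"]

    def test_missing_marker_column_names_it(self, tmp_path):
        p = tmp_path / "bad.csv"
        header = CANONICAL_HEADER.replace(",Foxp3", "")
        p.write_text(header + "\n")
        with pytest.raises(SchemaError, match="Foxp3"):
            read_cell_table(p, stroma_area_mm2=0.25)

    def test_non_numeric_coordinate_reports_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        write_canonical(p, [
            "c1,1.0,2.0,stroma,1,0,0,0,0,0,0,0,0,0,1",
            "c2,oops,2.0,stroma,1,0,0,0,0,0,0,0,0,0,1",
        ])
        with pytest.raises(ParseError, match="row 3"):
            read_cell_table(p, stroma_area_mm2=0.25)

    def test_decimal_comma_rejected_loudly(self, tmp_path):
        p = tmp_path / "locale.csv"
        write_canonical(p, ['c1,"1,5",2.0,stroma,1,0,0,0,0,0,0,0,0,0,1'])
        with pytest.raises(ParseError, match="decimal comma"):
            read_cell_table(p, stroma_area_mm2=0.25)

    def test_zero_stromal_area_rejected(self, tmp_path):
        p = tmp_path / "img.csv"
        write_canonical(p, [])
        with pytest.raises(ROIValidationError, match="stroma_area"):
            read_cell_table(p, stroma_area_mm2=0.0)


class TestInformDialect:
    FIXTURE = (
        'Cell ID\tCell X Position\tCell Y Position\tTissue Category\t'
        + "\t".join(f"{m} Positivity" for m in
                    ["CD45", "CK", "CD4", "CD8", "Foxp3", "CD68", "CD163",
                     "CD66b", "PD1", "PDL1", "DAPI"]) + "\n"
        "1\t12.0\t8.0\tStroma\tpos\tneg\tneg\tpos\tneg\tneg\tneg\tneg\tneg\tneg\tpos\n"
        "2\t40.0\t9.0\tTumor\tneg\tpos\tneg\tneg\tneg\tneg\tneg\tneg\tneg\tpos\tpos\n"
        "3\t15.0\t30.0\tStroma\tpos\tneg\tpos\tneg\tpos\tneg\tneg\tneg\tneg\tneg\tpos\n"
        "4\t22.0\t44.0\tStroma\tpos\tneg\tneg\tneg\tneg\tpos\tpos\tneg\tneg\tneg\tpos\n"
    )

    def test_tissue_categories_and_markers_match_hand_count(self, tmp_path):
        # hand count of the fixture: 3 stromal cells, 1 tumor-nest cell,
        # CD45+ = 3, CK+ = 1, PD-L1+ = 1
        p = tmp_path / "inform.txt"
        p.write_text(self.FIXTURE)
        roi = read_cell_table(p, dialect="inform_like", stroma_area_mm2=0.1,
                              field_width_um=100, field_height_um=100)
        assert roi.n_cells == 4
        assert (roi.table["compartment"] == STROMA).sum() == 3
        assert (roi.table["compartment"] == TUMOR_NEST).sum() == 1
        assert int(roi.table["CD45"].sum()) == 3
        assert int(roi.table["CK"].sum()) == 1
        assert int(roi.table["PDL1"].sum()) == 1

    def test_missing_marker_column_is_schema_error(self, tmp_path):
        p = tmp_path / "broken.txt"
        # drop the Foxp3 column wholesale
        rows = [line.split("\t") for line in self.FIXTURE.strip().splitlines()]
        idx = rows[0].index("Foxp3 Positivity")
        rows = [[c for i, c in enumerate(r) if i != idx] for r in rows]
        p.write_text("\n".join("\t".join(r) for r in rows) + "\n")
        with pytest.raises(SchemaError, match="Foxp3"):
            read_cell_table(p, dialect="inform_like", stroma_area_mm2=0.1)


class TestRoundTrip:
    def test_small_roi_round_trips_identically(self, tmp_path):
        roi = make_roi([
            make_cell("a", 1.25, 2.5, "CD45", "CD8"),
            make_cell("b", 3.0, 4.0, "CK", compartment=TUMOR_NEST),
        ])
        p = tmp_path / "roi.csv"
        write_cell_table(roi, p)
        back = read_cell_table(p, image_id=roi.image_id,
                               sample_id=roi.sample_id,
                               stroma_area_mm2=roi.stroma_area_mm2,
                               tumor_area_mm2=roi.tumor_area_mm2,
                               field_width_um=roi.field_width_um,
                               field_height_um=roi.field_height_um)
        pd.testing.assert_frame_equal(roi.table, back.table)

    def test_empty_roi_round_trips(self, tmp_path):
        roi = make_roi([])
        p = tmp_path / "empty.csv"
        write_cell_table(roi, p)
        back = read_cell_table(p, stroma_area_mm2=0.5)
        assert back.n_cells == 0

    def test_generator_roi_round_trips_cell_by_cell(self, tmp_path):
        roi, _ = generate_roi(archetype_defaults("III"), seed=7)
        assert roi.n_cells > 1000
        p = tmp_path / "gen.csv"
        write_cell_table(roi, p)
        back = read_cell_table(p, image_id=roi.image_id,
                               sample_id=roi.sample_id,
                               stroma_area_mm2=roi.stroma_area_mm2,
                               tumor_area_mm2=roi.tumor_area_mm2,
                               field_width_um=roi.field_width_um,
                               field_height_um=roi.field_height_um)
        pd.testing.assert_frame_equal(roi.table, back.table)

    def test_metadata_sidecar_round_trips(self, tmp_path):
        roi = make_roi([make_cell("a", 1, 1, "CD45")])
        p = tmp_path / "meta.csv"
        write_metadata_sidecar([roi], p)
        table = read_metadata_sidecar(p)
        md = table[roi.image_id]
        assert md.stroma_area_mm2 == roi.stroma_area_mm2
        assert md.sample_id == roi.sample_id


class TestValidation:
    def test_valid_roi_has_no_violations(self):
        assert validate_roi(make_roi([make_cell("a", 5, 5, "CD45")])) == []

    def test_out_of_field_cell_named(self):
        roi = make_roi([make_cell("weird", -5.0, 5.0, "CD45")])
        violations = validate_roi(roi)
        assert any("weird" in v for v in violations)

    def test_zero_stroma_area_flagged(self):
        roi = make_roi([make_cell("a", 5, 5, "CD45")])
        roi.stroma_area_mm2 = 0.0
        assert any("stroma_area" in v for v in validate_roi(roi))

    def test_areas_exceeding_field_flagged(self):
        roi = make_roi([make_cell("a", 5, 5, "CD45")], stroma_area_mm2=0.9,
                       tumor_area_mm2=0.9, field_width_um=1000,
                       field_height_um=1000)  # field is 1 mm² total
        assert any("field area" in v for v in validate_roi(roi))

    def test_sample_rejects_foreign_images(self):
        roi = make_roi([make_cell("a", 5, 5, "CD45")], sample_id="other")
        with pytest.raises(ROIValidationError):
            Sample("s0", [roi])

    def test_sample_requires_images(self):
        with pytest.raises(ROIValidationError):
            Sample("s0", [])
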