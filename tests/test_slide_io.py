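"""Parsing, design inference, validation and output formatting."""

import math

import numpy as np
import pytest

from rppaquant import (
    SimScenario,
    SlideError,
    infer_design,
    read_slide_file,
    validate_against_design,
)
from rppaquant.simulate import generate_slide
from rppaquant.slide_io import format_number

from conftest import FIXTURE_HEADER, fixture_rows, small_scenario


class TestReadSlideFile:
    def test_well_formed_fixture_preserves_order(self, fixture_file):
        slide = read_slide_file(fixture_file)
        assert slide.antibody_name == "AB_fixture"
        assert len(slide.records) == 8
        assert [r.order for r in slide.records] == list(range(1, 9))
        assert slide.records[0].series_id == "A"
        assert slide.records[0].dilution_step == 1
        assert slide.records[3].dilution_step == 4
        assert not slide.warnings

    def test_missing_column_error_names_column(self, tmp_path):
        lines = [FIXTURE_HEADER.replace("\tDilution", "")]
        for row in fixture_rows():
            parts = row.split("\t")
            del parts[7]
            lines.append("\t".join(parts))
        path = tmp_path / "bad.txt"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(SlideError, match="Dilution"):
            read_slide_file(path)

    def test_duplicate_coordinate_error(self, tmp_path):
        rows = fixture_rows()
        rows.append(rows[0])
        path = tmp_path / "dup.txt"
        path.write_text(FIXTURE_HEADER + "\n" + "\n".join(rows) + "\n")
        with pytest.raises(SlideError, match="duplicate grid coordinate"):
            read_slide_file(path)

    def test_negative_intensity_retained_with_warning(self, tmp_path):
        rows = fixture_rows()
        parts = rows[0].split("\t")
        parts[8] = "-12.5"
        rows[0] = "\t".join(parts)
        path = tmp_path / "neg.txt"
        path.write_text(FIXTURE_HEADER + "\n" + "\n".join(rows) + "\n")
        slide = read_slide_file(path)
        assert slide.records[0].net_intensity == -12.5
        assert any("negative net intensity" in w for w in slide.warnings)

    def test_unparseable_numeric_reported_not_dropped(self, tmp_path):
        rows = fixture_rows()
        parts = rows[2].split("\t")
        parts[8] = "oops"
        rows[2] = "\t".join(parts)
        path = tmp_path / "unp.txt"
        path.write_text(FIXTURE_HEADER + "\n" + "\n".join(rows) + "\n")
        slide = read_slide_file(path)
        assert len(slide.records) == 8
        assert math.isnan(slide.records[2].net_intensity)
        assert any("unparseable" in w and "Net.Value" in w for w in slide.warnings)

    def test_generator_round_trip_768_records(self, tmp_path):
        scenario = SimScenario(seed=7)
        path, truth = generate_slide(scenario, "AB", tmp_path)
        slide = read_slide_file(path)
        assert len(slide.records) == 768
        for rec, (_, row) in zip(slide.records, truth.table.iterrows()):
            assert rec.order == row["Order"]
            assert (rec.main_row, rec.main_col, rec.sub_row, rec.sub_col) == (
                row["Main.Row"], row["Main.Col"], row["Sub.Row"], row["Sub.Col"]
            )
            assert rec.series_id == row["Series.Id"]
            assert rec.spot_type == row["Spot.Type"]
            assert rec.net_intensity == pytest.approx(row["Net.Value"], rel=1e-9)
            assert rec.dilution == pytest.approx(row["Dilution"], rel=1e-9)


class TestInferDesign:
    def test_fixture_ladder(self, fixture_file):
        design = infer_design(read_slide_file(fixture_file))
        assert design.n_dilution_steps == 4
        assert design.dilution_factor == pytest.approx(2.0)
        assert design.dilution_ladder == (1.0, 0.5, 0.25, 0.125)
        assert design.n_sub_rows == 2 and design.n_sub_cols == 4
        assert [sid for sid, _ in design.series_roster] == ["A", "B"]

    def test_single_dilution_step_rejected(self, tmp_path):
        rows = [r for r in fixture_rows() if r.split("\t")[7] == "1"]
        path = tmp_path / "onedot.txt"
        path.write_text(FIXTURE_HEADER + "\n" + "\n".join(rows) + "\n")
        with pytest.raises(SlideError, match="serial dilutions"):
            infer_design(read_slide_file(path))

    def test_generator_factor_and_steps_recovered(self, tmp_path):
        scenario = small_scenario(13, dilution_factor=3.0, n_dilution_steps=5,
                                  n_main_cols=8, n_sub_cols=5)
        path, _ = generate_slide(scenario, "AB", tmp_path)
        design = infer_design(read_slide_file(path))
        assert design.dilution_factor == pytest.approx(3.0, rel=1e-9)
        assert design.n_dilution_steps == 5

    def test_inconsistent_series_steps_named(self, tmp_path):
        rows = fixture_rows()
        del rows[5]  # series B loses step 2
        path = tmp_path / "inc.txt"
        path.write_text(FIXTURE_HEADER + "\n" + "\n".join(rows) + "\n")
        with pytest.raises(SlideError, match="B"):
            infer_design(read_slide_file(path))

    def test_irregular_ladder_rejected(self, tmp_path):
        rows = []
        for row in fixture_rows():
            parts = row.split("\t")
            if parts[7] == "0.25":
                parts[7] = "0.3"
            rows.append("\t".join(parts))
        path = tmp_path / "irr.txt"
        path.write_text(FIXTURE_HEADER + "\n" + "\n".join(rows) + "\n")
        with pytest.raises(SlideError, match="ladder"):
            infer_design(read_slide_file(path))

    def test_idempotent_on_conforming_slide(self, small_slide_noise_free):
        slide, design, _ = small_slide_noise_free
        assert infer_design(slide) == design


class TestValidateAgainstDesign:
    def test_identity_is_clean(self, small_slide_noise_free):
        slide, design, _ = small_slide_noise_free
        assert validate_against_design(slide, design) == []

    def test_single_spot_type_change_flagged_once(self, tmp_path):
        path, _ = generate_slide(small_scenario(21), "AB", tmp_path)
        design = infer_design(read_slide_file(path))
        text = path.read_text().splitlines()
        # flip one Buffer spot to NegCtrl (keeps Sample series consistent)
        for i, line in enumerate(text):
            if "\tBuffer\t" in line:
                text[i] = line.replace("\tBuffer\t", "\tNegCtrl\t")
                break
        path.write_text("\n".join(text) + "\n")
        discrepancies = validate_against_design(read_slide_file(path), design)
        spot_type_d = [d for d in discrepancies if d.field == "spot_type"]
        assert len(spot_type_d) == 1
        assert spot_type_d[0].expected == "Buffer"
        assert spot_type_d[0].observed == "NegCtrl"

    def test_permuted_roster_flags_every_repositioned_series(self, tmp_path):
        path, _ = generate_slide(small_scenario(22), "AB", tmp_path)
        design = infer_design(read_slide_file(path))
        # swap the identities of two sample series everywhere
        text = path.read_text()
        text = text.replace("S001\t", "@@@\t").replace("S002\t", "S001\t").replace("@@@\t", "S002\t")
        path.write_text(text)
        slide = read_slide_file(path)
        observed = validate_against_design(slide, design)
        # independent brute-force oracle: positionwise roster comparison
        own_roster = []
        for rec in slide.records:
            if rec.spot_type != "Blank" and rec.series_id not in own_roster:
                own_roster.append(rec.series_id)
        expected_mismatches = sum(
            1 for k, (sid, _) in enumerate(design.series_roster)
            if own_roster[k] != sid
        )
        roster_d = [d for d in observed if d.field.startswith("series_roster")]
        assert expected_mismatches == 2
        assert len(roster_d) == expected_mismatches


@pytest.mark.parametrize(
    "value,expected",
    [
        (1234567.0, "1.23457e+06"),
        (0.000123456789, "0.000123457"),
        (float("nan"), "NA"),
        (None, "NA"),
        (42, "42"),
    ],
)
def test_numeric_output_format(value, expected):
    assert format_number(value) == expected
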