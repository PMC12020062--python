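"""Raw-file readers, filename parsing and annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from htstox import plate_io
from htstox.plate_io import (
    AnnotationTemplate,
    FormatError,
    AnnotationError,
    autofill_files_sheet,
    canonicalize,
    format_well,
    parse_raw_filename,
    parse_well,
    read_imaging_table,
    read_plate_reader_table,
)


class TestWellAddressing:
    @pytest.mark.parametrize(
        "label,expected",
        [("A01", (0, 0)), ("A1", (0, 0)), ("P24", (15, 23)), ("h12", (7, 11))],
    )
    def test_parse(self, label, expected):
        assert parse_well(label) == expected

    @pytest.mark.parametrize("label", ["Q1", "A0", "A25", "1A", ""])
    def test_rejects_outside_geometry(self, label):
        with pytest.raises(FormatError):
            parse_well(label)

    def test_round_trip(self):
        for row in range(16):
            for col in range(24):
                assert parse_well(format_well(row, col)) == (row, col)


class TestCanonicalize:
    @pytest.mark.parametrize("variant", ["HepG2", "HEPG2", "HEP-G2", "hep g2"])
    def test_cell_line_spellings_collapse(self, variant):
        assert canonicalize(variant) == "HepG2"

    def test_unknown_label_passes_through(self):
        assert canonicalize("MysteryAssay") == "MysteryAssay"

    @given(st.sampled_from(["CTG", "gammaH2AX", "casp-3", "BEAS2B", "weird_label"]))
    @settings(deadline=None)
    def test_idempotent(self, label):
        once = canonicalize(label)
        assert canonicalize(once) == once


class TestParseRawFilename:
    def test_default_dialect(self):
        meta = parse_raw_filename("CTG_24h_R2_BEAS2B.csv")
        assert meta.endpoint == "CTG"
        assert meta.time_h == 24
        assert meta.replicate == 2
        assert meta.cell_line == "BEAS-2B"

    def test_imaging_file_has_no_single_endpoint(self):
        meta = parse_raw_filename("imaging_72h_R4.txt")
        assert meta.endpoint == ""
        assert meta.time_h == 72
        assert meta.replicate == 4

    def test_unrecognized_tokens_left_empty(self):
        meta = parse_raw_filename("notes.bak")
        assert meta.endpoint == "" and meta.cell_line == "" and meta.serum == ""
        assert meta.time_h is None and meta.replicate is None

    def test_serum_tokens(self):
        assert parse_raw_filename("CTG_6h_R1_serum.csv").serum == "with"
        assert parse_raw_filename("CTG_6h_R1_noserum.csv").serum == "without"


class TestAutofill:
    def empty_template(self):
        front = pd.DataFrame(
            [{"well": "A1", "material_id": "M", "dose_value": 1.0,
              "dose_unit": "ug/ml", "role": "treated"}]
        )
        return AnnotationTemplate(front_sheet=front)

    def test_one_row_per_filename(self):
        t = autofill_files_sheet(
            ["CTG_6h_R1.csv", "CTG_6h_R2.csv", "imaging_6h_R1.txt"],
            self.empty_template(),
        )
        assert len(t.files_sheet) == 3

    def test_cell_line_spellings_harmonized(self):
        names = ["CTG_6h_R1_HEPG2.csv", "CTG_6h_R2_HEP-G2.csv", "CTG_6h_R3_HepG2.csv"]
        t = autofill_files_sheet(names, self.empty_template())
        assert set(t.files_sheet["cell_line"]) == {"HepG2"}

    def test_idempotent_and_preserves_manual_edits(self):
        t = autofill_files_sheet(["CTG_6h_R1.csv"], self.empty_template())
        t.files_sheet.loc[0, "cell_line"] = "A549"  # manual correction
        t2 = autofill_files_sheet(["CTG_6h_R1.csv"], t)
        pd.testing.assert_frame_equal(t.files_sheet, t2.files_sheet)

    def test_duplicate_filenames_rejected(self):
        with pytest.raises(AnnotationError, match="duplicate"):
            autofill_files_sheet(["a.csv", "a.csv"], self.empty_template())


class TestPlateReaderTable:
    def write(self, tmp_path, rows, header=True):
        path = tmp_path / "plate.csv"
        lines = (["# my plate header"] if header else []) + rows
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_all_ones(self, tmp_path):
        rows = [",".join(["1.0"] * 24) for _ in range(16)]
        grid, plate_id = read_plate_reader_table(self.write(tmp_path, rows))
        assert grid.shape == (16, 24)
        assert (grid == 1.0).all()
        assert plate_id == "plate"

    def test_empty_cell_is_missing(self, tmp_path):
        rows = [",".join(["2.5"] * 24) for _ in range(16)]
        cells = rows[3].split(",")
        cells[7] = ""
        rows[3] = ",".join(cells)
        grid, _ = read_plate_reader_table(self.write(tmp_path, rows))
        assert np.isnan(grid[3, 7])
        assert np.isfinite(grid).sum() == 383

    def test_wrong_row_count_reports_dimensions(self, tmp_path):
        rows = [",".join(["1"] * 24) for _ in range(15)]
        with pytest.raises(FormatError, match="15"):
            read_plate_reader_table(self.write(tmp_path, rows))

    def test_wrong_column_count(self, tmp_path):
        rows = [",".join(["1"] * 24) for _ in range(16)]
        rows[5] = ",".join(["1"] * 23)
        with pytest.raises(FormatError, match="23 columns"):
            read_plate_reader_table(self.write(tmp_path, rows))


class TestImagingTable:
    def test_basic_row(self, tmp_path):
        p = tmp_path / "img.txt"
        p.write_text("A01\tDAPI\t523.0\n")
        assert read_imaging_table(p) == [("A1", "DAPI", 523.0)]

    def test_dapi_technical_duplicates_preserved(self, tmp_path):
        p = tmp_path / "img.txt"
        p.write_text("A01\tDAPI\t500\nA01\tDAPI\t520\nA01\t8OHG\t10\n")
        rows = read_imaging_table(p)
        assert [r for r in rows if r[1] == "DAPI"] == [
            ("A1", "DAPI", 500.0),
            ("A1", "DAPI", 520.0),
        ]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "img.txt"
        p.write_text("")
        assert read_imaging_table(p) == []

    def test_unknown_endpoint_warns_and_passes_through(self, tmp_path):
        p = tmp_path / "img.txt"
        p.write_text("B02\tTUNEL\t1.0\n")
        with pytest.warns(UserWarning, match="TUNEL"):
            rows = read_imaging_table(p)
        assert rows == [("B2", "TUNEL", 1.0)]


class TestAnnotate:
    def test_one_plate_gives_384_records(self):
        front = pd.DataFrame(
            [
                {"well": format_well(r, c), "material_id": "M1", "dose_value": 1.0,
                 "dose_unit": "ug/ml", "role": "treated"}
                for r in range(16)
                for c in range(24)
            ]
        )
        template = AnnotationTemplate(front_sheet=front)
        template = autofill_files_sheet(["CTG_6h_R1_BEAS2B.csv"], template)
        grid = np.ones((16, 24))
        out = plate_io.annotate_dataset({"CTG_6h_R1_BEAS2B.csv": grid}, None, template)
        assert set(out) == {"CTG"}
        assert out["CTG"].n_records == 384
        assert (out["CTG"].layers["raw"] == 1.0).all()

    def test_control_wells_forced_to_dose_zero(self):
        front = pd.DataFrame(
            [
                {"well": format_well(r, c), "material_id": "vehicle",
                 "dose_value": 5.0, "dose_unit": "ug/ml", "role": "control"}
                for r in range(16)
                for c in range(24)
            ]
        )
        template = autofill_files_sheet(
            ["CTG_6h_R1.csv"], AnnotationTemplate(front_sheet=front)
        )
        out = plate_io.annotate_dataset({"CTG_6h_R1.csv": np.ones((16, 24))}, None, template)
        rec = out["CTG"].records
        assert (rec["role"] == "control").all()
        assert (rec["dose_value"] == 0.0).all()

    def test_file_without_meta_named_in_error(self):
        front = pd.DataFrame(
            [{"well": "A1", "material_id": "M", "dose_value": 1.0,
              "dose_unit": "ug/ml", "role": "treated"}]
        )
        template = AnnotationTemplate(front_sheet=front)
        with pytest.raises(AnnotationError, match="mystery.csv"):
            plate_io.annotate_dataset({"mystery.csv": np.ones((16, 24))}, None, template)


class TestCampaignRoundTrip:
    """Ingesting emitted fixtures recovers the generator's coordinates."""

    def test_design_record_counts(self, noiseless_campaign):
        datasets = noiseless_campaign["datasets"]
        # 384 wells x plates; DAPI doubled by technical duplicates
        assert datasets["CTG"].n_records == 384 * 4 * 4 * 2
        assert datasets["DAPI"].n_records == 384 * 2 * 3 * 4 * 2
        for ep in ("CASP", "H2AX", "8OHG"):
            assert datasets[ep].n_records == 384 * 3 * 4 * 2

    def test_truth_coordinates_recovered(self, noiseless_campaign):
        truth = noiseless_campaign["truth"]
        layout = truth.layout()
        ds = noiseless_campaign["datasets"]["CTG"]
        rec = ds.records
        for well, entry in layout.items():
            rows = rec[rec["well"] == well]
            assert set(rows["material_id"]) == {entry["material_id"]}
            assert set(rows["role"]) == {entry["role"]}
            if entry["role"] == "treated":
                assert set(rows["dose_value"]) == {entry["dose_value"]}

    def test_workbook_round_trip(self, noiseless_campaign, tmp_path):
        template = noiseless_campaign["template"]
        template.to_workbook(tmp_path / "t.xlsx")
        back = AnnotationTemplate.from_workbook(tmp_path / "t.xlsx")
        assert len(back.front_sheet) == len(template.front_sheet)
        assert list(back.files_sheet["filename"]) == list(
            template.files_sheet["filename"]
        )
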