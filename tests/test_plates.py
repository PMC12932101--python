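"""Plate I/O: schema validation, layout contracts, round-trips."""

from fractions import Fraction

import pandas as pd
import pytest
import yaml

import nabtiter as nt
from nabtiter.plates import format_dilution, normalize_well_label, parse_dilution


def make_wells_df():
    """96-well long table: 7 samples x 6 dilutions x 2 formats + controls."""
    rows = []
    dilutions = [Fraction(1, 2**k) for k in range(2, 8)]
    for fmt in ("CSC", "VSC"):
        idx = 0
        for s in range(7):
            for d in dilutions:
                idx += 1
                rows.append(
                    dict(
                        plate_id=f"P-{fmt}",
                        well=f"{'ABCDEFGH'[(idx - 1) // 12]}{(idx - 1) % 12 + 1}",
                        sample_id=f"S{s + 1}",
                        role="test",
                        serotype="AAV9",
                        format=fmt,
                        dilution=f"{d.numerator}/{d.denominator}",
                        replicate=1,
                        rlu=1000.0 + idx,
                    )
                )
        for r in range(1, 7):
            idx += 1
            rows.append(
                dict(
                    plate_id=f"P-{fmt}",
                    well=f"{'ABCDEFGH'[(idx - 1) // 12]}{(idx - 1) % 12 + 1}",
                    sample_id="control",
                    role="antibody_free_control",
                    serotype="AAV9",
                    format=fmt,
                    dilution="none",
                    replicate=r,
                    rlu=2000.0,
                )
            )
    return pd.DataFrame(rows)


class TestReadWells:
    def test_row_count_conserved(self, tmp_path):
        df = make_wells_df()
        path = tmp_path / "wells.csv"
        df.to_csv(path, index=False)
        ps = nt.read_wells(path)
        assert len(ps.wells) == len(df) == 96

    def test_missing_column_named_in_error(self, tmp_path):
        df = make_wells_df().drop(columns=["dilution"])
        path = tmp_path / "wells.csv"
        df.to_csv(path, index=False)
        with pytest.raises(nt.PlateValidationError, match="dilution"):
            nt.read_wells(path)

    def test_group_without_control_identified(self, tmp_path):
        df = make_wells_df()
        df = df[~((df.format == "CSC") & (df.role == "antibody_free_control"))]
        path = tmp_path / "wells.csv"
        df.to_csv(path, index=False)
        with pytest.raises(nt.PlateValidationError, match="AAV9/CSC"):
            nt.read_wells(path)

    def test_duplicate_well_rejected(self, tmp_path):
        df = make_wells_df()
        df.loc[1, "well"] = df.loc[0, "well"]
        path = tmp_path / "wells.csv"
        df.to_csv(path, index=False)
        with pytest.raises(nt.PlateValidationError, match="duplicate"):
            nt.read_wells(path)

    def test_negative_rlu_rejected(self, tmp_path):
        df = make_wells_df()
        df.loc[0, "rlu"] = -5.0
        path = tmp_path / "wells.csv"
        df.to_csv(path, index=False)
        with pytest.raises(nt.PlateValidationError, match="negative RLU"):
            nt.read_wells(path)

    def test_well_labels_normalized(self):
        assert normalize_well_label("a01") == "A1"
        assert normalize_well_label("H12") == "H12"
        with pytest.raises(nt.PlateValidationError):
            normalize_well_label("I1")
        with pytest.raises(nt.PlateValidationError):
            normalize_well_label("A13")

    def test_wide_grid_with_plate_map(self, tmp_path):
        grid = pd.DataFrame(
            [[1000.0, 800.0], [950.0, 400.0]],
            index=["A", "B"],
            columns=["1", "2"],
        )
        grid_path = tmp_path / "grid.csv"
        grid.to_csv(grid_path)
        pmap = {
            "plate_id": "P1",
            "serotype": "AAV5",
            "format": "CSC",
            "wells": {
                "A1": {"sample_id": "control", "role": "antibody_free_control"},
                "A2": {"sample_id": "X", "role": "test", "dilution": "1/4",
                       "replicate": 1},
                "B1": {"sample_id": "control", "role": "antibody_free_control"},
                "B2": {"sample_id": "X", "role": "test", "dilution": "1/8",
                       "replicate": 1},
            },
        }
        map_path = tmp_path / "map.yaml"
        map_path.write_text(yaml.safe_dump(pmap))
        ps = nt.read_wells(grid_path, plate_map=map_path)
        assert len(ps.wells) == 4
        x = [w for w in ps.wells if w.sample_id == "X" and w.dilution == Fraction(1, 4)]
        assert x[0].rlu == 800.0


class TestRoundTrips:
    def test_wells_roundtrip_identity(self, tmp_path):
        truth = nt.masking_demo_truth("VSC", noise_sigma=0.05)
        ps = nt.simulate_plate(truth)
        path = tmp_path / "wells.csv"
        nt.write_wells(ps, path)
        back = nt.read_wells(path)
        assert back.wells == ps.wells

    def test_nd50_table_roundtrip_field_by_field(self, tmp_path):
        results = [
            nt.ND50Result("S1", "AAV9", "CSC", 0.125, 0.10, 0.15, "linear",
                          False, Fraction(1, 8)),
            nt.ND50Result("S2", "AAV9", "VSC", None, None, None, "linear",
                          True, Fraction(1, 1)),
        ]
        path = tmp_path / "nd50.csv"
        nt.write_results(nt.nd50_table(results), path)
        back = nt.read_nd50_table(path)
        assert back == results

    def test_titer_serialized_as_decimal_plus_display(self, tmp_path):
        res = [nt.ND50Result("S", "AAV1", "CSC", 0.125, 0.1, 0.15, "hill",
                             False, Fraction(1, 8))]
        path = tmp_path / "nd50.csv"
        nt.write_results(nt.nd50_table(res), path)
        df = pd.read_csv(path)
        assert df.loc[0, "nd50"] == pytest.approx(0.125)
        assert df.loc[0, "nd50_display"] == "1/8"

    def test_empty_results_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        nt.write_results(nt.nd50_table([]), path)
        df = pd.read_csv(path)
        assert len(df) == 0


class TestDilutionParsing:
    @pytest.mark.parametrize(
        "raw,expected",
        [("1/8", Fraction(1, 8)), ("0.125", Fraction(1, 8)), ("none", None),
         ("", None)],
    )
    def test_parse(self, raw, expected):
        assert parse_dilution(raw) == expected

    def test_format_roundtrip(self):
        assert format_dilution(Fraction(1, 8)) == "1/8"
        assert parse_dilution(format_dilution(Fraction(3, 64))) == Fraction(3, 64)
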