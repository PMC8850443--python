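import dataclasses

import pytest

from cropclim.corpus import (
    ColumnMapping,
    MappingError,
    RejectedRow,
    average_over_esms,
    filter_top_producers,
    read_corpus,
    records_to_frame,
    frame_to_records,
    validate_record,
    write_corpus,
)

from conftest import make_record


class TestValidation:
    def test_valid_record_has_no_violations(self):
        assert validate_record(make_record()) == []

    def test_lat_out_of_range(self):
        reasons = validate_record(make_record(lat=123.0))
        assert any("lat" in r for r in reasons)

    def test_bad_crop(self):
        assert validate_record(make_record(crop="barley"))

    def test_period_ordering(self):
        rec = make_record(base_start=2050, base_end=2060, base_mid=None)
        assert any("period" in r for r in validate_record(rec))

    def test_yi_below_floor(self):
        assert any("-100" in r for r in validate_record(make_record(YI_raw=-130.0)))

    def test_preindustrial_offset_mismatch(self):
        rec = make_record(dTg_pi=3.5)  # dTg_2005=1.8 -> gap 1.7 != 0.8
        assert any("offset" in r for r in validate_record(rec))

    def test_options_require_flag(self):
        rec = make_record(adaptation=False, adaptation_options={"irrigation"})
        assert any("flag" in r for r in validate_record(rec))

    def test_midpoints_round_half_years_down(self):
        rec = make_record(future_start=2041, future_end=2050, future_mid=None)
        assert rec.future_mid == 2045  # 2045.5 rounds down


class TestReadWrite:
    def test_three_valid_rows(self, tmp_path, three_records):
        path = write_corpus(three_records, tmp_path / "c.csv")
        result = read_corpus(path)
        assert len(result.records) == 3
        assert result.rejects == []

    def test_invalid_row_rejected_with_reason(self, tmp_path, three_records):
        bad = make_record(site_label="siteX", lat=123.0)
        path = write_corpus(three_records + [bad], tmp_path / "c.csv")
        result = read_corpus(path)
        assert len(result.records) == 3
        assert len(result.rejects) == 1
        assert isinstance(result.rejects[0], RejectedRow)
        assert any("lat" in r for r in result.rejects[0].reasons)

    def test_accepted_plus_rejected_equals_total(self, tmp_path, three_records):
        rows = three_records + [make_record(lat=99.9, lon=900.0), make_record(crop="oats")]
        path = write_corpus(rows, tmp_path / "c.csv")
        result = read_corpus(path)
        assert result.n_total == len(rows)

    def test_round_trip_identity_csv(self, tmp_path, three_records):
        path = write_corpus(three_records, tmp_path / "c.csv")
        assert read_corpus(path).records == three_records

    def test_round_trip_identity_xlsx(self, tmp_path, three_records):
        path = write_corpus(three_records, tmp_path / "c.xlsx")
        assert read_corpus(path).records == three_records

    def test_empty_corpus_writes_header_only(self, tmp_path):
        path = write_corpus([], tmp_path / "c.csv")
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("study_id")

    def test_single_record_single_row(self, tmp_path):
        path = write_corpus([make_record()], tmp_path / "c.csv")
        assert len(path.read_text().splitlines()) == 2

    def test_writes_are_deterministic(self, tmp_path, three_records):
        p1 = write_corpus(three_records, tmp_path / "a.csv")
        p2 = write_corpus(three_records, tmp_path / "b.csv")
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_corpus("nope.csv")

    def test_mapping_absent_column(self, tmp_path, three_records):
        path = write_corpus(three_records, tmp_path / "c.csv")
        mapping = ColumnMapping(columns={**{f: f for f in ("study_id", "crop", "country", "lat", "lon", "scale", "scenario", "adaptation")}, "Yb": "baseline_yield"})
        with pytest.raises(MappingError, match="absent"):
            read_corpus(path, mapping)

    def test_missing_sheet_xlsx(self, tmp_path, three_records):
        path = write_corpus(three_records, tmp_path / "c.xlsx")
        mapping = ColumnMapping(sheet="WrongSheet")
        with pytest.raises(MappingError, match="sheet"):
            read_corpus(path, mapping)

    def test_missing_values_not_coerced_to_zero(self, tmp_path):
        rec = make_record(Yb=None, Yf=None, YI_raw=None, co2_ppm=None)
        path = write_corpus([rec], tmp_path / "c.csv")
        back = read_corpus(path).records[0]
        assert back.Yb is None and back.co2_ppm is None

    def test_unit_scales_applied_on_read(self, tmp_path):
        path = write_corpus([make_record(Yb=5000.0, Yf=4500.0, YI_raw=-10.0)], tmp_path / "c.csv")
        mapping = ColumnMapping(unit_scales={"Yb": 1e-3, "Yf": 1e-3})
        rec = read_corpus(path, mapping).records[0]
        assert rec.Yb == pytest.approx(5.0) and rec.Yf == pytest.approx(4.5)


class TestColumnMapping:
    def test_duplicate_target_column(self):
        cols = {f: f for f in ("study_id", "crop", "country", "lat", "lon", "scale", "scenario", "adaptation")}
        cols["Yb"] = "lat"  # collides
        with pytest.raises(MappingError, match="mapped by both"):
            ColumnMapping(columns=cols)

    def test_required_fields_covered(self):
        with pytest.raises(MappingError, match="required"):
            ColumnMapping(columns={"study_id": "id"})


class TestEsmAveraging:
    def test_mean_of_two_esms(self):
        recs = [
            make_record(esm="ESM1", YI_raw=-10.0),
            make_record(esm="ESM2", YI_raw=-20.0),
        ]
        out = average_over_esms(recs)
        assert len(out) == 1
        assert out[0].YI_raw == pytest.approx(-15.0)
        assert out[0].esm == "ensemble_mean"

    def test_single_esm_passthrough(self):
        rec = make_record(esm="ESM1")
        (out,) = average_over_esms([rec])
        assert out.esm == "ensemble_mean"
        assert dataclasses.replace(out, esm=rec.esm) == rec

    def test_conflicting_crop_raises(self):
        recs = [make_record(esm="ESM1"), make_record(esm="ESM2", crop="wheat")]
        with pytest.raises(ValueError, match="conflicting"):
            average_over_esms(recs, group_keys=("study_id", "site_label", "scenario"))

    def test_group_count_preserved(self, synthetic_2000):
        records, _ = synthetic_2000
        keys = {
            (
                r.study_id,
                r.site_label,
                r.crop,
                r.scenario,
                r.future_mid,
                r.adaptation,
                frozenset(r.adaptation_options),
            )
            for r in records
        }
        out = average_over_esms(records)
        assert len(out) == len(keys)

    def test_missing_values_ignored_in_mean(self):
        recs = [make_record(esm="ESM1", dPr=None), make_record(esm="ESM2", dPr=-40.0)]
        (out,) = average_over_esms(recs)
        assert out.dPr == pytest.approx(-40.0)


class TestTopProducerFilter:
    table = {
        ("maize", "A"): 0.6,
        ("maize", "B"): 0.35,
        ("maize", "C"): 0.05,
    }

    def grid_record(self, country):
        return make_record(country=country, scale="country_aggregated_grid", region_group="")

    def test_full_coverage_keeps_all(self):
        recs = [self.grid_record(c) for c in "ABC"]
        assert len(filter_top_producers(recs, self.table, coverage=1.0)) == 3

    def test_cumulative_share_cutoff(self):
        # hand cumsum: 0.6 -> 0.95 at B -> C dropped
        recs = [self.grid_record(c) for c in "ABC"]
        kept = filter_top_producers(recs, self.table, coverage=0.95)
        assert sorted(r.country for r in kept) == ["A", "B"]

    def test_single_producer(self):
        recs = [self.grid_record("A")]
        assert len(filter_top_producers(recs, {("maize", "A"): 1.0}, coverage=0.95)) == 1

    def test_site_records_untouched(self):
        recs = [make_record(country="C")]  # site scale, C would fail the cutoff
        assert filter_top_producers(recs, self.table, coverage=0.95) == recs

    def test_unknown_crop_raises(self):
        recs = [self.grid_record("A")]
        with pytest.raises(KeyError):
            filter_top_producers(recs, {("wheat", "A"): 1.0}, coverage=0.95)

    def test_bad_coverage(self):
        with pytest.raises(ValueError):
            filter_top_producers([], self.table, coverage=0.0)


def test_frame_bridge_round_trip(three_records):
    frame = records_to_frame(three_records)
    assert frame_to_records(frame) == three_records
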