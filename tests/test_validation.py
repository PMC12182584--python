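"""Rule semantics of the validator: per-record rules, cross-record
checks, exemptions for untested samples, and report algebra."""

import copy

import pytest

from helpers import make_record

from wdds import read_csv, validate_dataset, validate_record
from wdds.io import Dataset
from wdds.validation import check_fit_for_purpose


def rule_ids(issues):
    return [i.rule_id for i in issues]


class TestRecordRules:
    def test_clean_record_has_no_issues(self):
        assert validate_record(make_record()) == []

    @pytest.mark.parametrize("over,rule", [
        (dict(host_identification=None), "REQ_FIELD"),
        (dict(sample_id=None), "REQ_FIELD"),
        (dict(latitude="north"), "FIELD_TYPE"),
        (dict(detection_outcome="detected"), "VOCAB"),
        (dict(age=3.0), "UNITS_PAIR"),
        (dict(mass=0.5), "UNITS_PAIR"),
        (dict(organism_quantity=30.0), "UNITS_PAIR"),
        (dict(latitude=91.0), "COORD_RANGE"),
        (dict(longitude=181.0), "COORD_RANGE"),
        (dict(spatial_uncertainty=-5.0), "COORD_RANGE"),
        (dict(collection_month=13), "DATE_VALID"),
        (dict(collection_day=32), "DATE_VALID"),
        (dict(collection_day=30, collection_month=2,
              collection_year=2019), "DATE_VALID"),
        (dict(latitude=0.0, longitude=0.0), "PLACEHOLDER"),
        (dict(detection_outcome="positive"), "POS_NO_ID"),
        (dict(parasite_identification="Borrelia burgdorferi"),
         "NEG_WITH_ID"),
    ])
    def test_single_violations_fire_their_rule(self, over, rule):
        assert rule_ids(validate_record(make_record(**over))) == [rule]

    def test_length_needs_both_units_and_axis(self):
        issues = validate_record(make_record(length=0.12))
        fields = {i.field for i in issues}
        assert rule_ids(issues) == ["UNITS_PAIR", "UNITS_PAIR"]
        assert fields == {"length_measurement", "length_units"}

    def test_units_pair_satisfied(self):
        rec = make_record(mass=0.5, mass_units="kg", age=3.0,
                          age_units="years")
        assert validate_record(rec) == []

    def test_case_insensitive_vocabulary(self):
        assert validate_record(make_record(
            detection_outcome="Negative")) == []

    def test_partial_dates_are_legal(self):
        rec = make_record(collection_year=2019)
        assert validate_record(rec) == []
        rec = make_record(collection_year=2019, collection_month=4)
        assert validate_record(rec) == []

    def test_leap_day_valid_only_in_leap_years(self):
        ok = make_record(collection_day=29, collection_month=2,
                         collection_year=2020)
        bad = make_record(collection_day=29, collection_month=2,
                          collection_year=2019)
        assert validate_record(ok) == []
        assert rule_ids(validate_record(bad)) == ["DATE_VALID"]

    def test_untested_sample_row_is_exempt_from_test_fields(self):
        rec = make_record(detection_outcome=None, detection_target=None,
                          detection_method=None)
        assert validate_record(rec) == []

    def test_untested_exemption_does_not_cover_other_required(self):
        rec = make_record(detection_outcome=None, detection_target=None,
                          detection_method=None, host_identification=None)
        assert rule_ids(validate_record(rec)) == ["REQ_FIELD"]

    def test_positive_with_identity_is_clean(self):
        rec = make_record(detection_outcome="positive",
                          parasite_identification="Alphacoronavirus")
        assert validate_record(rec) == []


class TestDatasetRules:
    def test_worked_example_is_conformant(self, fixture_dataset):
        report = validate_dataset(fixture_dataset)
        assert report.conformant
        assert report.n_errors == 0

    def test_cross_record_host_conflict(self, fixture_dataset):
        ds = copy.deepcopy(fixture_dataset)
        ds.records[1].host_identification = "Desmodus youngi"
        report = validate_dataset(ds)
        conflicts = report.by_rule("XREC_CONFLICT")
        assert len(conflicts) == 1
        assert "BZ19-114" in conflicts[0].message
        assert report.conformant  # warning only

    def test_mass_may_change_between_captures(self, fixture_dataset):
        ds = copy.deepcopy(fixture_dataset)
        ds.records[1].mass = 0.031
        assert validate_dataset(ds).by_rule("XREC_CONFLICT") == []

    def test_out_of_range_latitude_breaks_conformance(self, fixture_dataset):
        ds = copy.deepcopy(fixture_dataset)
        ds.records[0].latitude = 91.0
        report = validate_dataset(ds)
        assert not report.conformant
        assert report.by_rule("COORD_RANGE")

    def test_duplicate_rows_warn(self):
        rec = make_record()
        dup = copy.deepcopy(rec)
        dup.source_row = 3
        report = validate_dataset(Dataset(records=[rec, dup]))
        assert len(report.by_rule("DUP_ROW")) == 1
        assert report.conformant

    def test_repeat_testing_of_a_sample_is_not_an_error(self):
        first = make_record()
        second = make_record(detection_target="Paramyxoviridae",
                             source_row=3)
        report = validate_dataset(Dataset(records=[first, second]))
        assert report.conformant
        assert report.by_rule("DUP_ROW") == []

    def test_dangling_pool_link_is_an_error(self):
        ds = Dataset(records=[make_record()],
                     pooled_links=[("S1", "A1"), ("GHOST", "A2")])
        report = validate_dataset(ds)
        links = report.by_rule("POOL_LINK")
        assert len(links) == 1 and "GHOST" in links[0].message
        assert not report.conformant

    def test_missing_required_column_reported_from_parsing(self):
        text = "Sample ID,Latitude\nS1,10.5"
        ds, findings = read_csv(text)
        report = validate_dataset(ds, parse_findings=findings)
        missing = {i.field for i in report.by_rule("REQ_FIELD")
                   if i.record is None}
        assert "longitude" in missing and "detection_outcome" in missing

    def test_validation_is_idempotent(self, fixture_dataset):
        first = validate_dataset(fixture_dataset)
        second = validate_dataset(fixture_dataset)
        assert [i.to_dict() for i in first.issues] == \
            [i.to_dict() for i in second.issues]

    def test_appending_conformant_record_adds_no_errors(self,
                                                        simple_dataset):
        ds = copy.deepcopy(simple_dataset)
        extra = make_record(sample_id="NEW1", animal_id="NEWA",
                            source_row=len(ds.records) + 2)
        ds.records.append(extra)
        report = validate_dataset(ds)
        assert report.conformant

    def test_report_counts_match_issue_tallies(self, fixture_dataset):
        ds = copy.deepcopy(fixture_dataset)
        ds.records[0].latitude = 91.0
        ds.records[1].detection_outcome = "positive"  # POS_NO_ID warning
        report = validate_dataset(ds)
        assert report.n_errors == \
            sum(1 for i in report.issues if i.severity == "error")
        assert report.n_warnings == \
            sum(1 for i in report.issues if i.severity == "warning")
        assert not report.conformant

    def test_report_serializes_to_json_and_text(self, fixture_dataset):
        report = validate_dataset(fixture_dataset)
        assert '"conformant": true' in report.to_json()
        assert "conformant=True" in report.to_text()


class TestFitForPurpose:
    def test_worked_example_has_all_six_elements(self, fixture_dataset):
        elements = check_fit_for_purpose(fixture_dataset)
        assert len(elements) == 6
        assert all(e.present for e in elements)
        date = next(e for e in elements if e.element == "sampling date")
        assert date.completeness == 1.0

    def test_missing_years_flag_date_absent(self, fixture_dataset):
        ds = copy.deepcopy(fixture_dataset)
        for rec in ds.records:
            rec.collection_year = None
        date = next(e for e in check_fit_for_purpose(ds)
                    if e.element == "sampling date")
        assert not date.present

    def test_empty_dataset_all_absent(self):
        elements = check_fit_for_purpose(Dataset())
        assert all(not e.present for e in elements)
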