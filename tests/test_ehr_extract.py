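"""Staging condensation, patient-level queries, and regimen classification."""

import datetime as dt

import pandas as pd
import pytest

from neurocds.ehr_extract import (
    DIAGNOSIS_COLUMNS,
    ORDER_COLUMNS,
    ComorbidityMap,
    CurrentMed,
    StagingStore,
    build_staging,
    classify_regimen,
    current_np_meds,
    facts_from_ehr,
    icd9_matches_prefix,
    years_before,
)

AS_OF = dt.date(2014, 6, 1)


def diag_frame(rows):
    return pd.DataFrame(rows, columns=DIAGNOSIS_COLUMNS)


def order_frame(rows):
    return pd.DataFrame(rows, columns=ORDER_COLUMNS)


def order(pid="P1", drug="gabapentin", dose="300 mg", start="2014-01-01",
          end="", status="active"):
    return {"patient_id": pid, "drug_name": drug, "dose_text": dose,
            "start_date": start, "end_date": end, "status": status}


class TestIcd9Matching:
    @pytest.mark.parametrize("code,prefix,expected", [
        ("311", "311", True),
        ("311.0", "311", True),
        ("3110", "311", False),
        ("250.60", "250.6", True),
        ("250.6", "250.6", True),
        ("250.7", "250.6", False),
        ("296.2", "296.2", True),
        ("296.25", "296.2", True),
        ("29", "296.2", False),
    ])
    def test_dotted_prefix_match(self, code, prefix, expected):
        assert icd9_matches_prefix(code, prefix) is expected

    def test_overlapping_prefixes_across_comorbidities_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            ComorbidityMap({"a": ["250"], "b": ["250.6"]})


class TestNormalization:
    def test_case_and_salt_suffix_insensitive(self, taxonomy):
        assert taxonomy.lookup("Amitriptyline HCl") == ("TCA", 1)
        assert taxonomy.lookup("  GABAPENTIN ") == ("gabapentinoid", 1)
        assert taxonomy.lookup("valproic acid sodium") == \
            ("third_line_other", 3)
        assert taxonomy.lookup("ibuprofen") is None

    def test_variable_names(self, taxonomy, comorbidity_map):
        assert taxonomy.variable_name("Amitriptyline HCl") == \
            "amitriptyline_tx"
        assert taxonomy.variable_name("valproic acid") == "valproic_acid_tx"
        assert comorbidity_map.variable_name("depression") == "depression_hx"


class TestBuildStaging:
    def test_heart_disease_prefix_sets_flag(self, taxonomy, comorbidity_map):
        diags = diag_frame([{"patient_id": "P1", "icd9_code": "414.01",
                             "date": "2013-01-01"}])
        store = build_staging(diags, order_frame([]), taxonomy,
                              comorbidity_map, AS_OF)
        assert store.flag("P1", "heart_disease") is True
        assert store.flag("P1", "depression") is False

    def test_patient_absent_from_all_tables_absent_from_staging(
            self, taxonomy, comorbidity_map):
        store = build_staging(diag_frame([]), order_frame([]), taxonomy,
                              comorbidity_map, AS_OF)
        assert store.records == {}
        # the empty record view is all-false
        assert not any(store.record("ghost").flags)

    @pytest.mark.parametrize("years_back,included", [(6, False), (4, True)])
    def test_lookback_excludes_old_orders(self, taxonomy, comorbidity_map,
                                          years_back, included):
        end = years_before(AS_OF, years_back)
        start = end - dt.timedelta(days=90)
        orders = order_frame([order(start=start.isoformat(),
                                    end=end.isoformat(),
                                    status="discontinued")])
        store = build_staging(diag_frame([]), orders, taxonomy,
                              comorbidity_map, AS_OF)
        drugs = [m.drug for m in store.record("P1").past_np_meds]
        assert (drugs == ["gabapentin"]) is included

    def test_lookback_boundary_is_closed(self, taxonomy, comorbidity_map):
        """An order ending exactly five years before as-of is included;
        one day earlier is excluded."""
        boundary = years_before(AS_OF, 5)
        on = order_frame([order(start="2008-01-01",
                                end=boundary.isoformat(),
                                status="discontinued")])
        off = order_frame([order(
            start="2008-01-01",
            end=(boundary - dt.timedelta(days=1)).isoformat(),
            status="discontinued")])
        store_on = build_staging(diag_frame([]), on, taxonomy,
                                 comorbidity_map, AS_OF)
        store_off = build_staging(diag_frame([]), off, taxonomy,
                                  comorbidity_map, AS_OF)
        assert [m.drug for m in store_on.record("P1").past_np_meds] \
            == ["gabapentin"]
        assert store_off.record("P1").past_np_meds == ()

    def test_malformed_rows_rejected_and_counted(self, taxonomy,
                                                 comorbidity_map):
        diags = diag_frame([
            {"patient_id": "P1", "icd9_code": "311", "date": "not-a-date"},
            {"patient_id": "P2", "icd9_code": "311", "date": "2013-01-01"},
            {"patient_id": "P3", "icd9_code": "311", "date": "2099-01-01"},
        ])
        orders = order_frame([
            order(pid="P4", start="2014-01-01", end="2013-01-01",
                  status="discontinued"),  # negative interval
            order(pid="P5"),
        ])
        store = build_staging(diags, orders, taxonomy, comorbidity_map, AS_OF)
        assert store.rejected_diagnoses == 2
        assert store.rejected_orders == 1
        assert set(store.records) == {"P2", "P5"}

    def test_rebuild_is_byte_identical(self, tmp_path, taxonomy,
                                       comorbidity_map):
        diags = diag_frame([{"patient_id": "P1", "icd9_code": "311",
                             "date": "2013-01-01"}])
        orders = order_frame([order()])
        for i, sub in enumerate(("a", "b")):
            store = build_staging(diags, orders, taxonomy, comorbidity_map,
                                  AS_OF)
            store.save(tmp_path / sub)
        files = ["staging_flags.csv", "staging_past_meds.csv",
                 "staging_meta.csv"]
        for name in files:
            assert (tmp_path / "a" / name).read_bytes() \
                == (tmp_path / "b" / name).read_bytes()

    @pytest.mark.parametrize("fmt", ["csv", "sqlite"])
    def test_save_load_round_trip(self, tmp_path, taxonomy, comorbidity_map,
                                  fmt):
        diags = diag_frame([{"patient_id": "P1", "icd9_code": "414",
                             "date": "2013-01-01"}])
        orders = order_frame([order(pid="P1"), order(pid="P2",
                                                     drug="oxycodone")])
        store = build_staging(diags, orders, taxonomy, comorbidity_map, AS_OF)
        target = tmp_path / ("staging.db" if fmt == "sqlite" else "staging")
        store.save(target, fmt=fmt)
        loaded = StagingStore.load(target, fmt=fmt)
        assert loaded.comorbidity_names == store.comorbidity_names
        assert loaded.records == store.records
        assert loaded.as_of == store.as_of

    def test_unknown_format_refused(self, taxonomy, comorbidity_map,
                                    tmp_path):
        store = build_staging(diag_frame([]), order_frame([]), taxonomy,
                              comorbidity_map, AS_OF)
        with pytest.raises(ValueError, match="unknown staging format"):
            store.save(tmp_path / "x", fmt="parquet")

    def test_stale_staging_logs_warning(self, taxonomy, comorbidity_map,
                                        caplog):
        store = build_staging(diag_frame([]), order_frame([]), taxonomy,
                              comorbidity_map, AS_OF)
        fresh_now = dt.datetime.combine(AS_OF, dt.time(12))
        stale_now = fresh_now + dt.timedelta(days=3)
        assert store.check_freshness(now=fresh_now) is True
        with caplog.at_level("WARNING", logger="neurocds.ehr_extract"):
            assert store.check_freshness(now=stale_now) is False
        assert "older" in caplog.text


class TestCurrentMeds:
    def test_active_order_returned_with_class_and_line(self, taxonomy):
        meds = current_np_meds(order_frame([order(drug="Amitriptyline HCl",
                                                  dose="25 mg qhs")]),
                               taxonomy, AS_OF)
        assert meds == [CurrentMed("amitriptyline", "TCA", 1, "25 mg qhs")]

    def test_empty_orders(self, taxonomy):
        assert current_np_meds(order_frame([]), taxonomy, AS_OF) == []

    def test_mixed_lines_both_returned(self, taxonomy):
        meds = current_np_meds(order_frame([order(), order(drug="oxycodone",
                                                           dose="5 mg")]),
                               taxonomy, AS_OF)
        assert [(m.drug, m.line) for m in meds] == [("gabapentin", 1),
                                                    ("oxycodone", 2)]

    @pytest.mark.parametrize("status,span_covers,expected", [
        ("active", True, True),
        ("discontinued", True, False),   # never current, even if span covers
        ("expired", True, False),
        ("active", False, False),
    ])
    def test_current_requires_active_status_and_span(self, taxonomy, status,
                                                     span_covers, expected):
        end = "" if span_covers else "2014-01-01"
        meds = current_np_meds(
            order_frame([order(start="2013-06-01", end=end, status=status)]),
            taxonomy, AS_OF)
        assert bool(meds) is expected

    def test_non_taxonomy_drugs_silently_ignored(self, taxonomy):
        meds = current_np_meds(order_frame([order(drug="lisinopril")]),
                               taxonomy, AS_OF)
        assert meds == []


class TestFactsFromEhr:
    def test_flags_and_meds_become_true_inputs(self, taxonomy,
                                               comorbidity_map):
        diags = diag_frame([{"patient_id": "P1", "icd9_code": "300.4",
                             "date": "2013-01-01"}])
        orders = order_frame([order(pid="P1", drug="amitriptyline")])
        store = build_staging(diags, orders, taxonomy, comorbidity_map, AS_OF)
        meds = current_np_meds(orders, taxonomy, AS_OF, patient_id="P1")
        fs = facts_from_ehr(store.record("P1"), meds, taxonomy,
                            comorbidity_map)
        assert fs.value("amitriptyline_tx") is True
        assert fs.value("depression_hx") is True
        assert fs.value("nortriptyline_tx") is False
        assert fs.value("heart_disease_hx") is False
        assert all(f.provenance == "extracted"
                   for f in fs.bindings.values())

    def test_empty_record_gives_all_false(self, taxonomy, comorbidity_map):
        store = build_staging(diag_frame([]), order_frame([]), taxonomy,
                              comorbidity_map, AS_OF)
        fs = facts_from_ehr(store.record("P9"), [], taxonomy,
                            comorbidity_map)
        assert fs.bindings and not any(f.value for f in fs.bindings.values())

    def test_collision_with_derived_variable_refused(self, taxonomy,
                                                     comorbidity_map):
        store = build_staging(diag_frame([]), order_frame([]), taxonomy,
                              comorbidity_map, AS_OF)
        with pytest.raises(ValueError, match="collide"):
            facts_from_ehr(store.record("P1"), [], taxonomy, comorbidity_map,
                           derived_vars=["depression_hx"])


class TestRegimen:
    def med(self, drug, cls, line):
        return CurrentMed(drug, cls, line, "dose")

    def test_first_plus_second_triggers_scope_warning(self):
        summary = classify_regimen([
            self.med("gabapentin", "gabapentinoid", 1),
            self.med("oxycodone", "opioid", 2)])
        assert summary.first_line_present and summary.second_line_present
        assert summary.scope_warning is True

    def test_first_line_only_no_warning(self):
        summary = classify_regimen([self.med("gabapentin", "gabapentinoid",
                                             1)])
        assert summary.first_line_present
        assert not summary.scope_warning

    def test_third_line_only(self):
        summary = classify_regimen([self.med("citalopram",
                                             "third_line_other", 3)])
        assert summary.third_line_present and summary.scope_warning
        assert summary.by_line[3] == ("citalopram",)
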