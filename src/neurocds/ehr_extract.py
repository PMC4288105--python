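"""EHR condensation and patient-level queries.

Emulates the nightly batch that scans the full EHR and condenses what the
CDS needs into a small, query-fast staging store: one bit per comorbidity
per patient (driven by ICD9 prefix match) and the list of neuropathic-pain
drugs the patient received during the five-year lookback window.  Staging
is a cache, never a semantic change: every staging-backed answer must
equal the same query run as a direct scan of the full tables.

Conventions (documented, configurable where marked):

* ICD9 matching is prefix match on the dotted code: prefix ``311``
  matches ``311`` and ``311.x`` but not ``3110``.
* The lookback window is the closed interval ``[as_of - 5 years, as_of]``;
  any overlap of an order's active span counts, so an order ending exactly
  five years before ``as_of`` is included.
* A medication is *current* when its status is ``active`` and its date
  span covers ``as_of``; a discontinued order is never current even if
  its span covers ``as_of``.
* Drug names are normalized (lowercase, trimmed, salt suffixes from the
  taxonomy config stripped) before taxonomy lookup.
* Staging carries its build date; queries against staging older than a
  configurable threshold (default 36 h) log a staleness warning.
"""

from __future__ import annotations

import datetime as dt
import io
import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from neurocds.config import default_comorbidity_config, default_taxonomy_config
from neurocds.kb_engine import Demographics, Fact, FactSet

logger = logging.getLogger(__name__)

__all__ = [
    "DrugTaxonomy", "ComorbidityMap", "StagingRecord", "StagingStore",
    "CurrentMed", "PastMed", "RegimenSummary",
    "build_staging", "current_np_meds", "facts_from_ehr", "classify_regimen",
    "years_before", "icd9_matches_prefix", "load_ehr_tables",
    "LOOKBACK_YEARS", "STALENESS_HOURS",
]

LOOKBACK_YEARS = 5
STALENESS_HOURS = 36.0

PATIENT_COLUMNS = ["patient_id", "name", "age", "sex"]
DIAGNOSIS_COLUMNS = ["patient_id", "icd9_code", "date"]
ORDER_COLUMNS = ["patient_id", "drug_name", "dose_text",
                 "start_date", "end_date", "status"]

ORDER_STATUSES = ("active", "discontinued", "expired")


# ---------------------------------------------------------------------------
# Configuration-backed lookups
# ---------------------------------------------------------------------------

class DrugTaxonomy:
    """Normalized drug name → (class, treatment line 1/2/3)."""

    def __init__(self, drugs: Mapping[str, tuple[str, int]],
                 salt_suffixes: Sequence[str] = ()) -> None:
        self._salt_suffixes = frozenset(s.lower() for s in salt_suffixes)
        self._drugs = {self.normalize(k): (cls, int(line))
                       for k, (cls, line) in drugs.items()}

    @classmethod
    def from_config(cls, config: Optional[dict] = None) -> "DrugTaxonomy":
        cfg = config if config is not None else default_taxonomy_config()
        drugs = {name: (entry["class"], entry["line"])
                 for name, entry in cfg["drugs"].items()}
        return cls(drugs, cfg.get("salt_suffixes", ()))

    def normalize(self, name: str) -> str:
        tokens = name.strip().lower().split()
        while tokens and tokens[-1] in getattr(self, "_salt_suffixes",
                                               frozenset()):
            tokens.pop()
        return " ".join(tokens)

    def lookup(self, name: str) -> Optional[tuple[str, int]]:
        return self._drugs.get(self.normalize(name))

    def __contains__(self, name: str) -> bool:
        return self.lookup(name) is not None

    def drug_names(self) -> list[str]:
        return sorted(self._drugs)

    def variable_name(self, drug: str) -> str:
        """KB input variable for a taxonomy drug, e.g. ``gabapentin_tx``."""
        return self.normalize(drug).replace(" ", "_") + "_tx"


def icd9_matches_prefix(code: str, prefix: str) -> bool:
    """Dotted-code prefix match: '311' matches '311' and '311.x'; '250.6'
    matches '250.6' and '250.60'; '311' does not match '3110'."""
    code = code.strip()
    prefix = prefix.strip()
    if not code.startswith(prefix):
        return False
    if len(code) == len(prefix):
        return True
    return code[len(prefix)] == "." or "." in prefix


class ComorbidityMap:
    """Ordered comorbidity name → ICD9 prefix set; order fixes bit position."""

    def __init__(self, mapping: Mapping[str, Sequence[str]]) -> None:
        self._map: dict[str, tuple[str, ...]] = {
            name: tuple(prefixes) for name, prefixes in mapping.items()}
        self._check_disjoint()

    def _check_disjoint(self) -> None:
        items = list(self._map.items())
        for i, (name_a, pa) in enumerate(items):
            for name_b, pb in items[i + 1:]:
                for a in pa:
                    for b in pb:
                        if a.startswith(b) or b.startswith(a):
                            raise ValueError(
                                f"overlapping ICD9 prefixes: {name_a}:{a} "
                                f"vs {name_b}:{b}")

    @classmethod
    def from_config(cls, config: Optional[dict] = None) -> "ComorbidityMap":
        cfg = config if config is not None else default_comorbidity_config()
        return cls(cfg["comorbidities"])

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._map)

    def prefixes(self, name: str) -> tuple[str, ...]:
        return self._map[name]

    def match(self, code: str) -> Optional[str]:
        for name, prefixes in self._map.items():
            if any(icd9_matches_prefix(code, p) for p in prefixes):
                return name
        return None

    def variable_name(self, comorbidity: str) -> str:
        """KB input variable for a comorbidity, e.g. ``depression_hx``."""
        return comorbidity + "_hx"


def declared_input_variables(taxonomy: DrugTaxonomy,
                             comorbidity_map: ComorbidityMap) -> list[str]:
    """The input-variable list the extraction layer publishes to the KB."""
    names = [taxonomy.variable_name(d) for d in taxonomy.drug_names()]
    names += [comorbidity_map.variable_name(c) for c in comorbidity_map.names]
    return names


# ---------------------------------------------------------------------------
# Staging store
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PastMed:
    drug: str
    drug_class: str
    last_dispense: dt.date


@dataclass(frozen=True)
class StagingRecord:
    patient_id: str
    flags: tuple[bool, ...]          # positions follow ComorbidityMap order
    past_np_meds: tuple[PastMed, ...]

    def bitset(self) -> int:
        value = 0
        for i, flag in enumerate(self.flags):
            if flag:
                value |= 1 << i
        return value


@dataclass
class StagingStore:
    """Condensed per-patient facts plus build metadata."""

    comorbidity_names: tuple[str, ...]
    build_date: dt.date
    as_of: dt.date
    records: dict[str, StagingRecord] = field(default_factory=dict)
    rejected_diagnoses: int = 0
    rejected_orders: int = 0

    def record(self, patient_id: str) -> StagingRecord:
        """The staging record for a patient; empty (all-false, no meds)
        when the patient is absent from staging."""
        if patient_id in self.records:
            return self.records[patient_id]
        return StagingRecord(patient_id,
                             (False,) * len(self.comorbidity_names), ())

    def flag(self, patient_id: str, comorbidity: str) -> bool:
        idx = self.comorbidity_names.index(comorbidity)
        return self.record(patient_id).flags[idx]

    def check_freshness(self, now: Optional[dt.datetime] = None,
                        threshold_hours: float = STALENESS_HOURS) -> bool:
        """True if fresh; logs a staleness warning otherwise."""
        now = now or dt.datetime.now()
        age = now - dt.datetime.combine(self.build_date, dt.time())
        if age > dt.timedelta(hours=threshold_hours):
            logger.warning(
                "staging store built %s is older than %.0f h; "
                "consider rebuilding", self.build_date, threshold_hours)
            return False
        return True

    # -- serialization: CSV bundle (default) or single-file sqlite ---------

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        flag_rows = []
        for pid in sorted(self.records):
            rec = self.records[pid]
            row = {"patient_id": pid}
            row.update({name: int(flag) for name, flag
                        in zip(self.comorbidity_names, rec.flags)})
            flag_rows.append(row)
        flags = pd.DataFrame(flag_rows,
                             columns=["patient_id", *self.comorbidity_names])
        med_rows = [
            {"patient_id": pid, "drug": med.drug,
             "drug_class": med.drug_class,
             "last_dispense": med.last_dispense.isoformat()}
            for pid in sorted(self.records)
            for med in self.records[pid].past_np_meds
        ]
        meds = pd.DataFrame(
            med_rows,
            columns=["patient_id", "drug", "drug_class", "last_dispense"])
        return flags, meds

    def save(self, path: Path, fmt: str = "csv") -> None:
        path = Path(path)
        if fmt == "csv":
            path.mkdir(parents=True, exist_ok=True)
            flags, meds = self.to_frames()
            flags.to_csv(path / "staging_flags.csv", index=False)
            meds.to_csv(path / "staging_past_meds.csv", index=False)
            meta = pd.DataFrame([{
                "build_date": self.build_date.isoformat(),
                "as_of": self.as_of.isoformat(),
                "comorbidities": "|".join(self.comorbidity_names),
                "rejected_diagnoses": self.rejected_diagnoses,
                "rejected_orders": self.rejected_orders,
            }])
            meta.to_csv(path / "staging_meta.csv", index=False)
        elif fmt == "sqlite":
            path.parent.mkdir(parents=True, exist_ok=True)
            if path.exists():
                path.unlink()
            flags, meds = self.to_frames()
            with sqlite3.connect(path) as conn:
                flags.to_sql("flags", conn, index=False)
                meds.to_sql("past_meds", conn, index=False)
                conn.execute(
                    "CREATE TABLE meta (build_date TEXT, as_of TEXT, "
                    "comorbidities TEXT, rejected_diagnoses INT, "
                    "rejected_orders INT)")
                conn.execute(
                    "INSERT INTO meta VALUES (?,?,?,?,?)",
                    (self.build_date.isoformat(), self.as_of.isoformat(),
                     "|".join(self.comorbidity_names),
                     self.rejected_diagnoses, self.rejected_orders))
        else:
            raise ValueError(f"unknown staging format {fmt!r}; "
                             f"supported: csv, sqlite")

    @classmethod
    def load(cls, path: Path, fmt: str = "csv") -> "StagingStore":
        path = Path(path)
        if fmt == "csv":
            flags = pd.read_csv(path / "staging_flags.csv",
                                dtype={"patient_id": str})
            meds = pd.read_csv(path / "staging_past_meds.csv",
                               dtype={"patient_id": str})
            meta = pd.read_csv(path / "staging_meta.csv").iloc[0]
        elif fmt == "sqlite":
            with sqlite3.connect(path) as conn:
                flags = pd.read_sql("SELECT * FROM flags", conn)
                meds = pd.read_sql("SELECT * FROM past_meds", conn)
                meta = pd.read_sql("SELECT * FROM meta", conn).iloc[0]
            flags["patient_id"] = flags["patient_id"].astype(str)
            meds["patient_id"] = meds["patient_id"].astype(str)
        else:
            raise ValueError(f"unknown staging format {fmt!r}")
        names = tuple(str(meta["comorbidities"]).split("|"))
        store = cls(comorbidity_names=names,
                    build_date=dt.date.fromisoformat(str(meta["build_date"])),
                    as_of=dt.date.fromisoformat(str(meta["as_of"])),
                    rejected_diagnoses=int(meta["rejected_diagnoses"]),
                    rejected_orders=int(meta["rejected_orders"]))
        meds_by_pid: dict[str, list[PastMed]] = {}
        for row in meds.itertuples(index=False):
            meds_by_pid.setdefault(str(row.patient_id), []).append(PastMed(
                str(row.drug), str(row.drug_class),
                dt.date.fromisoformat(str(row.last_dispense))))
        for row in flags.itertuples(index=False):
            pid = str(row.patient_id)
            rec_flags = tuple(bool(getattr(row, name)) for name in names)
            store.records[pid] = StagingRecord(
                pid, rec_flags, tuple(meds_by_pid.get(pid, ())))
        return store


# ---------------------------------------------------------------------------
# Date helpers
# ---------------------------------------------------------------------------

def years_before(day: dt.date, years: int) -> dt.date:
    """Calendar-year subtraction; Feb 29 falls back to Feb 28."""
    try:
        return day.replace(year=day.year - years)
    except ValueError:
        return day.replace(year=day.year - years, day=28)


def _parse_date(value: object) -> Optional[dt.date]:
    """ISO date or None for blank; raises ValueError on junk."""
    if value is None:
        return None
    text = str(value).strip()
    if not text or text.lower() == "nan":
        return None
    return dt.date.fromisoformat(text)


# ---------------------------------------------------------------------------
# Build + queries
# ---------------------------------------------------------------------------

def build_staging(diagnoses: pd.DataFrame, orders: pd.DataFrame,
                  taxonomy: DrugTaxonomy, comorbidity_map: ComorbidityMap,
                  as_of: dt.date,
                  build_date: Optional[dt.date] = None) -> StagingStore:
    """Nightly condensation pass over the full tables.

    One record per patient appearing in either table.  Flag *i* is true
    iff some diagnosis code matches a prefix of comorbidity *i*.  Past NP
    meds are taxonomy drugs with any order span overlapping
    ``[as_of - 5 years, as_of]``.  Malformed rows (unparseable dates,
    end before start, future diagnosis dates) are rejected and logged;
    the build continues and totals are reported on the store.
    """
    store = StagingStore(comorbidity_names=comorbidity_map.names,
                         build_date=build_date or as_of, as_of=as_of)
    names = comorbidity_map.names
    window_start = years_before(as_of, LOOKBACK_YEARS)

    flags_by_pid: dict[str, list[bool]] = {}
    meds_by_pid: dict[str, dict[str, tuple[str, dt.date]]] = {}
    patients: set[str] = set()

    for row in diagnoses.itertuples(index=False):
        pid = str(row.patient_id)
        code = str(row.icd9_code).strip()
        try:
            date = _parse_date(row.date)
            if date is None:
                raise ValueError("missing date")
            if date > as_of:
                raise ValueError("diagnosis date after as-of date")
            if not code:
                raise ValueError("empty ICD9 code")
        except ValueError as exc:
            store.rejected_diagnoses += 1
            logger.warning("rejected diagnosis row for %s: %s", pid, exc)
            continue
        patients.add(pid)
        hit = comorbidity_map.match(code)
        if hit is not None:
            flags = flags_by_pid.setdefault(pid, [False] * len(names))
            flags[names.index(hit)] = True

    for row in orders.itertuples(index=False):
        pid = str(row.patient_id)
        try:
            start = _parse_date(row.start_date)
            end = _parse_date(row.end_date)
            if start is None:
                raise ValueError("missing start date")
            if end is not None and end < start:
                raise ValueError("end date before start date")
            status = str(row.status).strip().lower()
            if status not in ORDER_STATUSES:
                raise ValueError(f"unknown status {status!r}")
        except ValueError as exc:
            store.rejected_orders += 1
            logger.warning("rejected order row for %s: %s", pid, exc)
            continue
        patients.add(pid)
        entry = taxonomy.lookup(str(row.drug_name))
        if entry is None:
            continue
        drug = taxonomy.normalize(str(row.drug_name))
        # closed-interval overlap with [as_of - 5y, as_of]; an open end
        # means the order is still running at as_of
        effective_end = end if end is not None else as_of
        if start <= as_of and effective_end >= window_start:
            last = min(effective_end, as_of)
            per_patient = meds_by_pid.setdefault(pid, {})
            prev = per_patient.get(drug)
            if prev is None or last > prev[1]:
                per_patient[drug] = (entry[0], last)

    for pid in sorted(patients):
        flags = tuple(flags_by_pid.get(pid, [False] * len(names)))
        meds = tuple(
            PastMed(drug, cls_last[0], cls_last[1])
            for drug, cls_last in sorted(meds_by_pid.get(pid, {}).items()))
        store.records[pid] = StagingRecord(pid, flags, meds)

    logger.info("staging built: %d patients, %d diagnosis rows rejected, "
                "%d order rows rejected", len(store.records),
                store.rejected_diagnoses, store.rejected_orders)
    return store


@dataclass(frozen=True)
class CurrentMed:
    drug: str
    drug_class: str
    line: int
    dose_text: str


def current_np_meds(orders: pd.DataFrame, taxonomy: DrugTaxonomy,
                    as_of: dt.date,
                    patient_id: Optional[str] = None) -> list[CurrentMed]:
    """NP medications active at ``as_of``: status ``active``, start ≤
    as_of, and no end date or end ≥ as_of, intersected with the taxonomy.
    Non-taxonomy drugs are silently ignored.  Drug-name matching is
    case-insensitive after normalization."""
    out: dict[str, CurrentMed] = {}
    for row in orders.itertuples(index=False):
        if patient_id is not None and str(row.patient_id) != patient_id:
            continue
        if str(row.status).strip().lower() != "active":
            continue
        entry = taxonomy.lookup(str(row.drug_name))
        if entry is None:
            continue
        try:
            start = _parse_date(row.start_date)
            end = _parse_date(row.end_date)
        except ValueError:
            continue
        if start is None or start > as_of:
            continue
        if end is not None and end < as_of:
            continue
        drug = taxonomy.normalize(str(row.drug_name))
        out.setdefault(drug, CurrentMed(drug, entry[0], entry[1],
                                        str(row.dose_text)))
    return [out[k] for k in sorted(out)]


def facts_from_ehr(record: StagingRecord, current_meds: Sequence[CurrentMed],
                   taxonomy: DrugTaxonomy,
                   comorbidity_map: Optional[ComorbidityMap] = None,
                   demographics: Demographics = Demographics(),
                   derived_vars: Iterable[str] = ()) -> FactSet:
    """Set the KB input variables from extracted data: ``<drug>_tx`` true
    for each current NP drug, ``<comorbidity>_hx`` true for each staging
    flag, every other published input false — all with
    ``provenance='extracted'``.

    Refuses when an extracted variable name collides with a KB derived
    variable (keeps the DSL namespace sound).
    """
    cmap = comorbidity_map or ComorbidityMap.from_config()
    bindings: dict[str, Fact] = {}
    for drug in taxonomy.drug_names():
        bindings[taxonomy.variable_name(drug)] = Fact(False, "extracted")
    for name in cmap.names:
        bindings[cmap.variable_name(name)] = Fact(False, "extracted")

    derived = set(derived_vars)
    collisions = sorted(set(bindings) & derived)
    if collisions:
        raise ValueError(
            f"extracted variable(s) {collisions} collide with KB derived "
            f"variables; rename the drug/comorbidity or the rule target")

    for med in current_meds:
        bindings[taxonomy.variable_name(med.drug)] = Fact(True, "extracted")
    for name, flag in zip(cmap.names, record.flags):
        if flag:
            bindings[cmap.variable_name(name)] = Fact(True, "extracted")
    return FactSet(bindings=bindings, demographics=demographics)


@dataclass(frozen=True)
class RegimenSummary:
    first_line_present: bool
    second_line_present: bool
    third_line_present: bool
    by_line: dict[int, tuple[str, ...]]

    @property
    def scope_warning(self) -> bool:
        """The CDS covers first-line management only; current second- or
        third-line drugs trigger the scope warning."""
        return self.second_line_present or self.third_line_present


def classify_regimen(current_meds: Sequence[CurrentMed],
                     past_meds: Sequence[PastMed] = ()) -> RegimenSummary:
    """Classify the *current* regimen by treatment line.  Past meds are
    accepted for reporting completeness but do not set the line flags."""
    by_line: dict[int, list[str]] = {1: [], 2: [], 3: []}
    for med in current_meds:
        by_line[med.line].append(med.drug)
    return RegimenSummary(
        first_line_present=bool(by_line[1]),
        second_line_present=bool(by_line[2]),
        third_line_present=bool(by_line[3]),
        by_line={k: tuple(sorted(v)) for k, v in by_line.items()},
    )


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

def load_ehr_tables(directory: Path) -> tuple[pd.DataFrame, pd.DataFrame,
                                              pd.DataFrame]:
    """Read patients.csv, diagnoses.csv, medication_orders.csv."""
    directory = Path(directory)
    patients = pd.read_csv(directory / "patients.csv",
                           dtype=str, keep_default_na=False)
    diagnoses = pd.read_csv(directory / "diagnoses.csv",
                            dtype=str, keep_default_na=False)
    orders = pd.read_csv(directory / "medication_orders.csv",
                         dtype=str, keep_default_na=False)
    for frame, cols in ((patients, PATIENT_COLUMNS),
                        (diagnoses, DIAGNOSIS_COLUMNS),
                        (orders, ORDER_COLUMNS)):
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise ValueError(f"EHR table missing columns: {missing}")
    return patients, diagnoses, orders
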