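"""Reproducible synthetic EHR cohorts.

Every other layer of the package is exercised on synthetic patients, so
the generator controls exactly the statistical structure the extractor
consumes: comorbidity prevalence (Bernoulli per comorbidity, realized as
ICD9-coded diagnosis rows), and one medication *scenario* per patient:

``naive``
    no NP drugs and no mapped comorbidity diagnosis requirement beyond
    the prevalence draw;
``first_line_only``
    one currently active first-line drug (TCA / SNRI / gabapentinoid);
``first_plus_second``
    an active first-line drug plus an active opioid or tramadol — the
    combination that triggers the report's scope warning;
``third_line``
    one currently active third-line drug;
``past_only``
    a first-line drug discontinued within the five-year lookback, nothing
    currently active.

Randomness is a single numpy stream per cohort; each patient draws from a
substream keyed by ``(seed, patient index)`` so that insertion order can
never change another patient's records.  Twenty percent of diagnosis rows
carry decoy ICD9 codes mapping to no comorbidity, exercising the negative
path of prefix matching.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from neurocds.ehr_extract import (
    DIAGNOSIS_COLUMNS,
    ORDER_COLUMNS,
    PATIENT_COLUMNS,
    ComorbidityMap,
    DrugTaxonomy,
    years_before,
)

__all__ = ["CohortSpec", "generate_cohort", "demo_patient",
           "DEMO_SCENARIOS", "SCENARIOS"]

SCENARIOS = ("naive", "first_line_only", "first_plus_second",
             "third_line", "past_only")

# codes that match no comorbidity prefix in the shipped map
DECOY_ICD9 = ("401.9", "272.4", "715.90", "530.81", "780.52")
DECOY_FRACTION = 0.2

FIRST_LINE = ("amitriptyline", "nortriptyline", "duloxetine",
              "venlafaxine", "gabapentin", "pregabalin")
SECOND_LINE = ("oxycodone", "morphine", "hydrocodone", "tramadol")
THIRD_LINE = ("carbamazepine", "lamotrigine", "topiramate",
              "valproic acid", "bupropion", "citalopram", "paroxetine")

DOSE_TEXT = {
    "amitriptyline": "25 mg PO qhs", "nortriptyline": "25 mg PO qhs",
    "duloxetine": "60 mg PO daily", "venlafaxine": "75 mg PO daily",
    "gabapentin": "300 mg PO tid", "pregabalin": "75 mg PO bid",
    "oxycodone": "5 mg PO q6h prn", "morphine": "15 mg PO q12h",
    "hydrocodone": "5 mg PO q6h prn", "tramadol": "50 mg PO q6h prn",
    "carbamazepine": "200 mg PO bid", "lamotrigine": "100 mg PO bid",
    "topiramate": "50 mg PO bid", "valproic acid": "250 mg PO tid",
    "bupropion": "150 mg PO bid", "citalopram": "20 mg PO daily",
    "paroxetine": "20 mg PO daily",
}


@dataclass(frozen=True)
class CohortSpec:
    """Controls for one synthetic cohort draw."""

    n_patients: int = 1000
    seed: int = 0
    prevalence: dict[str, float] = field(default_factory=lambda: {
        "depression": 0.30,
        "heart_disease": 0.25,
        "diabetes": 0.30,
        "renal_disease": 0.10,
        "liver_disease": 0.05,
        "substance_abuse": 0.10,
        "glaucoma": 0.05,
        "seizure_disorder": 0.03,
    })
    scenario_weights: dict[str, float] = field(default_factory=lambda: {
        "naive": 0.30,
        "first_line_only": 0.35,
        "first_plus_second": 0.15,
        "third_line": 0.08,
        "past_only": 0.12,
    })
    age_range: tuple[int, int] = (35, 90)
    as_of: dt.date = dt.date(2014, 6, 1)

    def validate(self) -> None:
        problems: list[str] = []
        if self.n_patients < 0:
            problems.append(f"n_patients must be >= 0, got {self.n_patients}")
        for name, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                problems.append(f"prevalence[{name}]={p} outside [0, 1]")
        for name in self.scenario_weights:
            if name not in SCENARIOS:
                problems.append(f"unknown scenario {name!r}; "
                                f"known: {list(SCENARIOS)}")
        for name, w in self.scenario_weights.items():
            if w < 0:
                problems.append(f"scenario_weights[{name}]={w} negative")
        total = sum(self.scenario_weights.values())
        if abs(total - 1.0) > 1e-9:
            problems.append(f"scenario weights sum to {total}, expected 1")
        lo, hi = self.age_range
        if lo > hi or lo < 0:
            problems.append(f"invalid age_range {self.age_range}")
        if problems:
            raise ValueError("invalid cohort spec: " + "; ".join(problems))


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # counter-keyed substream: independent of cohort size and order
    return np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(index,)))


def _rand_date(rng: np.random.Generator, start: dt.date,
               end: dt.date) -> dt.date:
    span = (end - start).days
    return start + dt.timedelta(days=int(rng.integers(0, span + 1)))


def _diagnosis_rows(rng: np.random.Generator, pid: str, spec: CohortSpec,
                    cmap: ComorbidityMap) -> list[dict]:
    rows: list[dict] = []
    window_start = years_before(spec.as_of, 5)
    for name in cmap.names:
        p = spec.prevalence.get(name, 0.0)
        if rng.random() < p:
            prefixes = cmap.prefixes(name)
            prefix = prefixes[int(rng.integers(0, len(prefixes)))]
            # realize the prefix as a longer concrete code half the time
            if rng.random() < 0.5:
                code = prefix
            else:
                sep = "" if "." in prefix else "."
                code = prefix + sep + str(int(rng.integers(0, 10)))
            rows.append({"patient_id": pid, "icd9_code": code,
                         "date": _rand_date(rng, window_start,
                                            spec.as_of).isoformat()})
    # decoy rows: codes matching no comorbidity
    n_decoys = rng.binomial(max(1, len(rows)), DECOY_FRACTION) \
        if rows else int(rng.random() < DECOY_FRACTION)
    for _ in range(int(n_decoys)):
        code = DECOY_ICD9[int(rng.integers(0, len(DECOY_ICD9)))]
        rows.append({"patient_id": pid, "icd9_code": code,
                     "date": _rand_date(rng, window_start,
                                        spec.as_of).isoformat()})
    return rows


def _active_order(rng: np.random.Generator, pid: str, drug: str,
                  as_of: dt.date) -> dict:
    start = _rand_date(rng, years_before(as_of, 2), as_of)
    return {"patient_id": pid, "drug_name": drug,
            "dose_text": DOSE_TEXT.get(drug, "dose per protocol"),
            "start_date": start.isoformat(), "end_date": "",
            "status": "active"}


def _past_order(rng: np.random.Generator, pid: str, drug: str,
                as_of: dt.date) -> dict:
    # ended 0.5–4.5 years ago, within the 5-year lookback
    end = _rand_date(rng, years_before(as_of, 5) + dt.timedelta(days=180),
                     as_of - dt.timedelta(days=180))
    start = end - dt.timedelta(days=int(rng.integers(30, 365)))
    return {"patient_id": pid, "drug_name": drug,
            "dose_text": DOSE_TEXT.get(drug, "dose per protocol"),
            "start_date": start.isoformat(), "end_date": end.isoformat(),
            "status": "discontinued"}


def _pick(rng: np.random.Generator, options: tuple[str, ...]) -> str:
    return options[int(rng.integers(0, len(options)))]


def _order_rows(rng: np.random.Generator, pid: str, scenario: str,
                spec: CohortSpec) -> list[dict]:
    as_of = spec.as_of
    if scenario == "naive":
        return []
    if scenario == "first_line_only":
        rows = [_active_order(rng, pid, _pick(rng, FIRST_LINE), as_of)]
        if rng.random() < 0.4:  # optionally also a past first-line trial
            other = _pick(rng, FIRST_LINE)
            if other != rows[0]["drug_name"]:
                rows.append(_past_order(rng, pid, other, as_of))
        return rows
    if scenario == "first_plus_second":
        return [_active_order(rng, pid, _pick(rng, FIRST_LINE), as_of),
                _active_order(rng, pid, _pick(rng, SECOND_LINE), as_of)]
    if scenario == "third_line":
        return [_active_order(rng, pid, _pick(rng, THIRD_LINE), as_of)]
    if scenario == "past_only":
        return [_past_order(rng, pid, _pick(rng, FIRST_LINE), as_of)]
    raise ValueError(f"unknown scenario {scenario!r}")


def generate_cohort(spec: CohortSpec,
                    comorbidity_map: Optional[ComorbidityMap] = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw a cohort: (patients, diagnoses, medication_orders) tables.

    Deterministic for a fixed spec and seed; each patient realizes
    exactly one medication scenario.
    """
    spec.validate()
    cmap = comorbidity_map or ComorbidityMap.from_config()
    scenario_names = list(spec.scenario_weights)
    weights = np.array([spec.scenario_weights[s] for s in scenario_names])
    weights = weights / weights.sum()

    patient_rows: list[dict] = []
    diagnosis_rows: list[dict] = []
    order_rows: list[dict] = []
    for i in range(spec.n_patients):
        rng = _patient_rng(spec.seed, i)
        pid = f"P{i:06d}"
        age = int(rng.integers(spec.age_range[0], spec.age_range[1] + 1))
        sex = "M" if rng.random() < 0.9 else "F"  # VA-like cohort skew
        patient_rows.append({"patient_id": pid,
                             "name": f"Test Patient {i:06d}",
                             "age": age, "sex": sex})
        diagnosis_rows.extend(_diagnosis_rows(rng, pid, spec, cmap))
        scenario = scenario_names[int(rng.choice(len(scenario_names),
                                                 p=weights))]
        order_rows.extend(_order_rows(rng, pid, scenario, spec))

    patients = pd.DataFrame(patient_rows, columns=PATIENT_COLUMNS)
    diagnoses = pd.DataFrame(diagnosis_rows, columns=DIAGNOSIS_COLUMNS)
    orders = pd.DataFrame(order_rows, columns=ORDER_COLUMNS)
    return patients, diagnoses, orders


# ---------------------------------------------------------------------------
# Hand-authored single-patient fixtures for docs and golden tests
# ---------------------------------------------------------------------------

_DEMO_AS_OF = dt.date(2014, 6, 1)


def _demo_tables(patient: dict, diagnoses: list[dict],
                 orders: list[dict]) -> tuple[pd.DataFrame, pd.DataFrame,
                                              pd.DataFrame]:
    return (pd.DataFrame([patient], columns=PATIENT_COLUMNS),
            pd.DataFrame(diagnoses, columns=DIAGNOSIS_COLUMNS),
            pd.DataFrame(orders, columns=ORDER_COLUMNS))


DEMO_SCENARIOS = ("tca_depression", "naive", "first_line_only",
                  "first_plus_second", "third_line", "past_only")


def demo_patient(name: str) -> tuple[pd.DataFrame, pd.DataFrame,
                                     pd.DataFrame]:
    """A hand-authored one-patient fixture; ``as_of`` for all demo
    patients is 2014-06-01.  Unknown names raise with the available list.
    """
    pid = "DEMO01"
    base = {"patient_id": pid, "name": "Demo, Patient", "age": 62, "sex": "M"}
    if name == "tca_depression":
        # on amitriptyline with a depression-prefix ICD9 code
        return _demo_tables(
            base,
            [{"patient_id": pid, "icd9_code": "311",
              "date": "2013-11-02"}],
            [{"patient_id": pid, "drug_name": "amitriptyline",
              "dose_text": "25 mg PO qhs", "start_date": "2014-01-15",
              "end_date": "", "status": "active"}])
    if name == "naive":
        return _demo_tables(
            base,
            [{"patient_id": pid, "icd9_code": "401.9",
              "date": "2013-05-20"}],
            [])
    if name == "first_line_only":
        return _demo_tables(
            base,
            [],
            [{"patient_id": pid, "drug_name": "gabapentin",
              "dose_text": "300 mg PO tid", "start_date": "2014-02-01",
              "end_date": "", "status": "active"}])
    if name == "first_plus_second":
        # gabapentin plus an opioid, both currently active
        return _demo_tables(
            base,
            [],
            [{"patient_id": pid, "drug_name": "gabapentin",
              "dose_text": "300 mg PO tid", "start_date": "2014-02-01",
              "end_date": "", "status": "active"},
             {"patient_id": pid, "drug_name": "oxycodone",
              "dose_text": "5 mg PO q6h prn", "start_date": "2014-03-10",
              "end_date": "", "status": "active"}])
    if name == "third_line":
        return _demo_tables(
            base,
            [],
            [{"patient_id": pid, "drug_name": "citalopram",
              "dose_text": "20 mg PO daily", "start_date": "2014-01-05",
              "end_date": "", "status": "active"}])
    if name == "past_only":
        return _demo_tables(
            base,
            [],
            [{"patient_id": pid, "drug_name": "nortriptyline",
              "dose_text": "25 mg PO qhs", "start_date": "2011-03-01",
              "end_date": "2011-09-01", "status": "discontinued"}])
    raise ValueError(
        f"unknown demo scenario {name!r}; available: {list(DEMO_SCENARIOS)}")


def demo_as_of() -> dt.date:
    return _DEMO_AS_OF
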