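"""End-to-end glue: EHR tables → facts → evaluation → report.

This is the library-level equivalent of invoking the CDS screen for one
patient: load the KB, stage or query the EHR, set the input variables by
program code, run the logic, apply any clinician overrides, and assemble
the report.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from neurocds import kb_dsl
from neurocds.config import default_layout_config, demo_kb_source
from neurocds.ehr_extract import (
    ComorbidityMap,
    DrugTaxonomy,
    StagingStore,
    build_staging,
    classify_regimen,
    current_np_meds,
    declared_input_variables,
    facts_from_ehr,
)
from neurocds.kb_engine import Demographics, EvaluationResult, evaluate
from neurocds.report import Report, ReportLayout, assemble_report

__all__ = ["CdsContext", "run_patient"]


@dataclass
class CdsContext:
    """Shared, patient-independent state: compiled plan + config."""

    plan: kb_dsl.EvaluationPlan
    kb: kb_dsl.KnowledgeBase
    taxonomy: DrugTaxonomy
    comorbidity_map: ComorbidityMap
    layout: ReportLayout

    @classmethod
    def from_sources(cls, kb_source: Optional[str] = None,
                     taxonomy: Optional[DrugTaxonomy] = None,
                     comorbidity_map: Optional[ComorbidityMap] = None,
                     layout_config: Optional[dict] = None) -> "CdsContext":
        taxonomy = taxonomy or DrugTaxonomy.from_config()
        cmap = comorbidity_map or ComorbidityMap.from_config()
        layout_cfg = layout_config if layout_config is not None \
            else default_layout_config()
        inputs = declared_input_variables(taxonomy, cmap)
        kb = kb_dsl.parse_kb(kb_source if kb_source is not None
                             else demo_kb_source(),
                             declared_inputs=inputs,
                             locations=layout_cfg["locations"])
        plan = kb_dsl.compile_kb(kb)
        return cls(plan=plan, kb=kb, taxonomy=taxonomy, comorbidity_map=cmap,
                   layout=ReportLayout.from_config(layout_cfg))


def run_patient(ctx: CdsContext, patients: pd.DataFrame,
                diagnoses: pd.DataFrame, orders: pd.DataFrame,
                patient_id: str, as_of: dt.date,
                overrides: Sequence[tuple[str, bool]] = (),
                staging: Optional[StagingStore] = None
                ) -> tuple[Report, EvaluationResult]:
    """Produce the CDS report for one patient as of a given date.

    ``staging`` may be a prebuilt store (the nightly condensation); when
    absent, staging is built on the fly from the full tables.
    """
    if staging is None:
        staging = build_staging(diagnoses, orders, ctx.taxonomy,
                                ctx.comorbidity_map, as_of)
    staging.check_freshness(now=dt.datetime.combine(as_of, dt.time()))

    row = patients.loc[patients["patient_id"].astype(str) == patient_id]
    if row.empty:
        raise KeyError(f"patient {patient_id!r} not found")
    demo = Demographics(name=str(row.iloc[0]["name"]),
                        age=int(row.iloc[0]["age"]),
                        sex=str(row.iloc[0]["sex"]))

    meds = current_np_meds(orders, ctx.taxonomy, as_of,
                           patient_id=patient_id)
    record = staging.record(patient_id)
    facts = facts_from_ehr(record, meds, ctx.taxonomy, ctx.comorbidity_map,
                           demographics=demo,
                           derived_vars=ctx.plan.derived_vars)
    for var, value in overrides:
        facts = facts.with_fact(var, value, provenance="override")

    result = evaluate(ctx.plan, facts)
    regimen = classify_regimen(meds, record.past_np_meds)
    # the past-meds section lists *other* NP drugs from the lookback,
    # not the ones the patient is currently on
    current_names = {m.drug for m in meds}
    past = tuple(m for m in record.past_np_meds
                 if m.drug not in current_names)
    report = assemble_report(demo, result.facts, regimen, result,
                             layout=ctx.layout, current_meds=meds,
                             past_meds=past)
    return report, result
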