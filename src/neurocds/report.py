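"""Sectioned patient report: header with overridable comorbidity
checkboxes, current and past NP medications, Comments/Recommendations,
the hover-box outline of first-line management, and static links.

The screen being modeled is a single page a clinician can process in
under a minute: demographics and comorbidity checkboxes on top (set from
ICD9 codes but changeable), medication lists below, then
comments/recommendations produced by the KB logic, then a visual outline
whose per-category "hover boxes" carry conditionally tailored text.
Hover boxes render as expandable sections in static HTML; the
plain-text and JSON renderings carry identical texts in identical order.

Patients currently on second- or third-line NP drugs fall outside the
system's first-line scope, and their reports carry a fixed explanatory
warning.
"""

from __future__ import annotations

import html as _html
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from neurocds.config import default_layout_config
from neurocds.ehr_extract import CurrentMed, PastMed, RegimenSummary
from neurocds.kb_engine import (
    Demographics,
    EvaluationResult,
    FactSet,
    PlacedComment,
)

__all__ = ["Report", "ReportLayout", "Checkbox", "assemble_report",
           "render", "SCOPE_WARNING_TEXT", "FORMATS"]

FORMATS = ("json", "html", "text")

SCOPE_WARNING_TEXT = (
    "This system is designed ONLY for first-line pharmacologic management "
    "of neuropathic pain (NP). Some patients receive second- or third-line "
    "NP drugs for other reasons (not for NP), in which case the comments "
    "below may still be relevant. If this patient is receiving a "
    "second-line drug (eg, an opioid or tramadol) or a third-line drug "
    "(eg, carbamazepine, lamotrigine, topiramate, valproic acid, "
    "bupropion, citalopram, or paroxetine) for NP, and you have concerns "
    "about NP management, please consider referral to neurology."
)


@dataclass(frozen=True)
class ReportLayout:
    """Which locations the report can display, and where: the
    Comments/Recommendations section, the outline categories (label →
    location), and the static-link registry."""

    recommendations_location: str = "Recommendations"
    outline: dict[str, str] = field(default_factory=dict)
    links: tuple[tuple[str, str], ...] = ()

    @classmethod
    def from_config(cls, config: Optional[dict] = None) -> "ReportLayout":
        cfg = config if config is not None else default_layout_config()
        links = tuple((entry["label"], entry["target"])
                      for entry in cfg.get("links", ()))
        return cls(outline=dict(cfg.get("outline", {})), links=links)

    def known_locations(self) -> set[str]:
        return {self.recommendations_location, *self.outline.values()}


@dataclass(frozen=True)
class Checkbox:
    name: str
    checked: bool
    provenance: str  # extracted | override


@dataclass(frozen=True)
class Report:
    name: str
    age: int
    sex: str
    checkboxes: tuple[Checkbox, ...]
    current_meds: tuple[CurrentMed, ...]
    past_meds: tuple[PastMed, ...]
    recommendations: tuple[PlacedComment, ...]
    outline: dict[str, tuple[PlacedComment, ...]]
    scope_warning: Optional[str]
    links: tuple[tuple[str, str], ...]

    def to_dict(self) -> dict:
        return {
            "header": {
                "name": self.name, "age": self.age, "sex": self.sex,
                "comorbidities": [
                    {"name": c.name, "checked": c.checked,
                     "provenance": c.provenance} for c in self.checkboxes],
            },
            "current_np_meds": [
                {"drug": m.drug, "class": m.drug_class, "line": m.line,
                 "dose": m.dose_text,
                 "side_effect_note": f"side_effects:{m.drug_class}"
                                     if m.line == 1 else None}
                for m in self.current_meds],
            "past_np_meds": [
                {"drug": m.drug, "class": m.drug_class,
                 "last_dispense": m.last_dispense.isoformat()}
                for m in self.past_meds],
            "scope_warning": self.scope_warning,
            "recommendations": [
                {"comment": p.comment_name, "order": p.order, "text": p.text}
                for p in self.recommendations],
            "outline": {
                category: [{"comment": p.comment_name, "order": p.order,
                            "text": p.text} for p in placements]
                for category, placements in self.outline.items()},
            "links": [{"label": label, "target": target}
                      for label, target in self.links],
        }


def _checkboxes(facts: FactSet) -> tuple[Checkbox, ...]:
    boxes = []
    for name in sorted(facts.bindings):
        fact = facts.bindings[name]
        if name.endswith("_hx"):
            boxes.append(Checkbox(name[:-3], fact.value, fact.provenance))
    return tuple(boxes)


def assemble_report(demographics: Demographics, facts: FactSet,
                    regimen: RegimenSummary, result: EvaluationResult,
                    layout: Optional[ReportLayout] = None,
                    current_meds: Sequence[CurrentMed] = (),
                    past_meds: Sequence[PastMed] = ()) -> Report:
    """Pure assembly of the report from evaluated state.

    Section ordering follows the EvaluationResult exactly.  Refuses when
    the evaluation placed a comment at a location the layout does not
    display (catches KB/layout drift).
    """
    layout = layout or ReportLayout.from_config()
    known = layout.known_locations()
    placed_locations = {loc for loc, items in result.placements.items()
                        if items}
    unknown = sorted(placed_locations - known)
    if unknown:
        raise ValueError(
            f"evaluation placed comments at location(s) {unknown} absent "
            f"from the report layout")

    outline = {category: result.at(location)
               for category, location in layout.outline.items()}
    warning = SCOPE_WARNING_TEXT if regimen.scope_warning else None
    return Report(
        name=demographics.name, age=demographics.age, sex=demographics.sex,
        checkboxes=_checkboxes(facts),
        current_meds=tuple(current_meds),
        past_meds=tuple(past_meds),
        recommendations=result.at(layout.recommendations_location),
        outline=outline,
        scope_warning=warning,
        links=layout.links,
    )


# ---------------------------------------------------------------------------
# Renderers — identical texts in identical order across all three formats
# ---------------------------------------------------------------------------

def render(report: Report, fmt: str = "text") -> str:
    if fmt == "json":
        return _render_json(report)
    if fmt == "html":
        return _render_html(report)
    if fmt == "text":
        return _render_text(report)
    raise ValueError(f"unknown format {fmt!r}; supported: {list(FORMATS)}")


def _render_json(report: Report) -> str:
    return json.dumps(report.to_dict(), indent=2, ensure_ascii=False) + "\n"


def _render_text(report: Report) -> str:
    lines: list[str] = []
    lines.append(f"Patient: {report.name}   Age: {report.age}   "
                 f"Sex: {report.sex}")
    lines.append("Comorbidities:")
    for box in report.checkboxes:
        mark = "x" if box.checked else " "
        lines.append(f"  [{mark}] {box.name} ({box.provenance})")
    lines.append("Current NP medications:")
    if not report.current_meds:
        lines.append("  (none)")
    for med in report.current_meds:
        lines.append(f"  {med.drug} ({med.drug_class}, line {med.line}) "
                     f"- {med.dose_text}")
    lines.append("Past NP medications (last 5 years):")
    if not report.past_meds:
        lines.append("  (none)")
    for past in report.past_meds:
        lines.append(f"  {past.drug} ({past.drug_class}) - last "
                     f"{past.last_dispense.isoformat()}")
    if report.scope_warning:
        lines.append("")
        lines.append("NOTE: " + report.scope_warning)
    lines.append("")
    lines.append("Comments/Recommendations:")
    if not report.recommendations:
        lines.append("  (none)")
    for placed in report.recommendations:
        lines.append(f"  [{placed.order}] {placed.text}")
    lines.append("")
    lines.append("First-line management outline:")
    for category, placements in report.outline.items():
        lines.append(f"  == {category} ==")
        for placed in placements:
            lines.append(f"    [{placed.order}] {placed.text}")
    lines.append("")
    lines.append("Links:")
    for label, target in report.links:
        lines.append(f"  {label} -> [{target}]")
    return "\n".join(lines) + "\n"


def _render_html(report: Report) -> str:
    esc = _html.escape
    parts: list[str] = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>",
        f"<title>NP CDS report: {esc(report.name)}</title></head><body>",
        f"<h1>Neuropathic pain CDS report</h1>",
        f"<p class='header'>Patient: {esc(report.name)} &mdash; "
        f"Age: {report.age} &mdash; Sex: {esc(report.sex)}</p>",
        "<h2>Comorbidities</h2><ul class='checkboxes'>",
    ]
    for box in report.checkboxes:
        checked = " checked" if box.checked else ""
        parts.append(
            f"<li><input type='checkbox' disabled{checked}> "
            f"{esc(box.name)} <small>({esc(box.provenance)})</small></li>")
    parts.append("</ul><h2>Current NP medications</h2><ul>")
    if not report.current_meds:
        parts.append("<li>(none)</li>")
    for med in report.current_meds:
        parts.append(f"<li>{esc(med.drug)} ({esc(med.drug_class)}, line "
                     f"{med.line}) - {esc(med.dose_text)}</li>")
    parts.append("</ul><h2>Past NP medications (last 5 years)</h2><ul>")
    if not report.past_meds:
        parts.append("<li>(none)</li>")
    for past in report.past_meds:
        parts.append(f"<li>{esc(past.drug)} ({esc(past.drug_class)}) - "
                     f"last {past.last_dispense.isoformat()}</li>")
    parts.append("</ul>")
    if report.scope_warning:
        parts.append(f"<p class='scope-warning'><strong>"
                     f"{esc(report.scope_warning)}</strong></p>")
    parts.append("<h2>Comments/Recommendations</h2><ol class='recs'>")
    if not report.recommendations:
        parts.append("<li>(none)</li>")
    for placed in report.recommendations:
        parts.append(f"<li>{esc(placed.text)}</li>")
    parts.append("</ol><h2>First-line management outline</h2>")
    # hover boxes become expandable <details> sections: one per category
    for category, placements in report.outline.items():
        parts.append(f"<details class='hover-box'><summary>"
                     f"{esc(category.replace('_', ' '))}</summary><ul>")
        for placed in placements:
            parts.append(f"<li>{esc(placed.text)}</li>")
        if not placements:
            parts.append("<li>(no patient-specific comments)</li>")
        parts.append("</ul></details>")
    parts.append("<h2>Links</h2><ul class='links'>")
    for label, target in report.links:
        parts.append(f"<li><a href='#{esc(target)}'>{esc(label)}</a></li>")
    parts.append("</ul></body></html>")
    return "\n".join(parts) + "\n"
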