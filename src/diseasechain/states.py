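"""Interoperable representations of abnormal states.

One clinical abnormality can be written three ways: quantitatively
(blood pressure 180 mmHg), qualitatively (blood pressure high) or as a
property (hypertension: true). A :class:`RuleTable` carries the
user-supplied cut-points and pairings that convert between them; the
package ships the conversion machinery, never the thresholds.

Also here: three-layer level consistency checks over a state hierarchy
and exact-string-match candidate detection against external
vocabularies (candidates are flagged, never auto-accepted).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import yaml

from .core_model import AbnormalState, DiseaseOntology, Finding, ValidationReport
from .errors import (
    MissingRuleError,
    OutOfRangeError,
    RuleTableError,
    UnitMismatchError,
)

__all__ = [
    "QuantitativeForm",
    "QualitativeForm",
    "PropertyForm",
    "QuantizationRule",
    "RuleTable",
    "quantize",
    "to_property",
    "to_qualitative",
    "normalize_form",
    "interoperable",
    "check_levels",
    "normalize_label",
    "MappingCandidate",
    "match_external",
    "mapping_summary",
]

Form = Union["QuantitativeForm", "QualitativeForm", "PropertyForm"]


@dataclass(frozen=True)
class QuantitativeForm:
    """<Object, Sub-Object?, Attribute, magnitude, unit>."""

    object: str
    attribute: str
    magnitude: float
    unit: str
    sub_object: Optional[str] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.magnitude):
            raise ValueError("magnitude must be finite")
        if not self.unit:
            raise ValueError("unit must be nonempty")


@dataclass(frozen=True)
class QualitativeForm:
    """<Object, Sub-Object?, Attribute, qualitative value>."""

    object: str
    attribute: str
    qualitative_value: str
    sub_object: Optional[str] = None


@dataclass(frozen=True)
class PropertyForm:
    """<Property, property value> -- e.g. (hypertension, true)."""

    property: str
    property_value: bool

    def __post_init__(self) -> None:
        if not self.property:
            raise ValueError("property must be nonempty")


@dataclass(frozen=True)
class QuantizationRule:
    """Ordered, non-overlapping half-open intervals [low, high) mapping
    a magnitude to a category for one (object, sub_object?, attribute,
    unit) tuple."""

    object: str
    attribute: str
    unit: str
    intervals: tuple[tuple[float, float, str], ...]
    sub_object: Optional[str] = None

    def __post_init__(self) -> None:
        ordered = sorted(self.intervals, key=lambda iv: iv[0])
        for (lo, hi, _) in ordered:
            if not lo < hi:
                raise RuleTableError(f"empty interval [{lo}, {hi}) in rule for {self.key()}")
        for (_, hi_prev, _), (lo_next, _, _) in zip(ordered, ordered[1:]):
            if lo_next < hi_prev:
                raise RuleTableError(f"overlapping intervals in rule for {self.key()}")
        object.__setattr__(self, "intervals", tuple(ordered))

    def key(self) -> tuple:
        return (self.object, self.sub_object, self.attribute, self.unit)

    def category_for(self, magnitude: float) -> str:
        for lo, hi, label in self.intervals:
            if lo <= magnitude < hi:
                return label
        raise OutOfRangeError(
            f"magnitude {magnitude} outside all intervals of rule for {self.key()}"
        )


class RuleTable:
    """Quantization rules plus bidirectional qualitative<->property pairs."""

    def __init__(
        self,
        quantization_rules: Iterable[QuantizationRule] = (),
        property_rules: Iterable[tuple[QualitativeForm, PropertyForm]] = (),
    ):
        self.quantization_rules: dict[tuple, QuantizationRule] = {}
        for rule in quantization_rules:
            if rule.key() in self.quantization_rules:
                raise RuleTableError(f"duplicate quantization rule for {rule.key()}")
            self.quantization_rules[rule.key()] = rule

        self._ql_to_prop: dict[QualitativeForm, PropertyForm] = {}
        self._prop_to_ql: dict[PropertyForm, QualitativeForm] = {}
        for ql, prop in property_rules:
            if ql in self._ql_to_prop or prop in self._prop_to_ql:
                raise RuleTableError(f"property rules must be bijective; duplicate entry {ql} <-> {prop}")
            self._ql_to_prop[ql] = prop
            self._prop_to_ql[prop] = ql

    def categories_for(self, object: str, attribute: str, sub_object: Optional[str] = None) -> set[str]:
        cats: set[str] = set()
        for rule in self.quantization_rules.values():
            if (rule.object, rule.sub_object, rule.attribute) == (object, sub_object, attribute):
                cats.update(label for _, _, label in rule.intervals)
        return cats

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleTable":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RuleTable":
        quant = [
            QuantizationRule(
                object=entry["object"],
                sub_object=entry.get("sub_object"),
                attribute=entry["attribute"],
                unit=entry["unit"],
                intervals=tuple(
                    (float(iv["low"]), float(iv.get("high", math.inf)), iv["category"])
                    for iv in entry["intervals"]
                ),
            )
            for entry in data.get("quantization", [])
        ]
        props = [
            (
                QualitativeForm(
                    object=entry["object"],
                    sub_object=entry.get("sub_object"),
                    attribute=entry["attribute"],
                    qualitative_value=entry["qualitative_value"],
                ),
                PropertyForm(property=entry["property"], property_value=bool(entry["property_value"])),
            )
            for entry in data.get("properties", [])
        ]
        return cls(quant, props)

    def to_dict(self) -> dict:
        return {
            "quantization": [
                {
                    "object": r.object,
                    **({"sub_object": r.sub_object} if r.sub_object else {}),
                    "attribute": r.attribute,
                    "unit": r.unit,
                    "intervals": [
                        {"low": lo, **({"high": hi} if math.isfinite(hi) else {}), "category": label}
                        for lo, hi, label in r.intervals
                    ],
                }
                for r in self.quantization_rules.values()
            ],
            "properties": [
                {
                    "object": ql.object,
                    **({"sub_object": ql.sub_object} if ql.sub_object else {}),
                    "attribute": ql.attribute,
                    "qualitative_value": ql.qualitative_value,
                    "property": prop.property,
                    "property_value": prop.property_value,
                }
                for ql, prop in self._ql_to_prop.items()
            ],
        }


# ---------------------------------------------------------------------------
# conversions


def quantize(q: QuantitativeForm, rules: RuleTable) -> QualitativeForm:
    """Map a measurement to its qualitative category.

    The rule is looked up by (object, sub_object, attribute); its unit
    must equal the datum's unit exactly -- there is no conversion engine.
    """
    matching = [
        rule for rule in rules.quantization_rules.values()
        if (rule.object, rule.sub_object, rule.attribute) == (q.object, q.sub_object, q.attribute)
    ]
    if not matching:
        raise MissingRuleError(f"no quantization rule for ({q.object}, {q.sub_object}, {q.attribute})")
    exact = [rule for rule in matching if rule.unit == q.unit]
    if not exact:
        raise UnitMismatchError(
            f"rule for ({q.object}, {q.sub_object}, {q.attribute}) uses unit "
            f"{matching[0].unit!r}, datum has {q.unit!r}"
        )
    category = exact[0].category_for(q.magnitude)
    return QualitativeForm(object=q.object, sub_object=q.sub_object, attribute=q.attribute, qualitative_value=category)


def to_property(ql: QualitativeForm, rules: RuleTable) -> PropertyForm:
    """Qualitative tuple -> (property, value) via the table's pairings."""
    try:
        return rules._ql_to_prop[ql]
    except KeyError:
        raise MissingRuleError(f"no property rule for {ql}") from None


def to_qualitative(p: PropertyForm, rules: RuleTable) -> QualitativeForm:
    """Inverse of :func:`to_property` under the same table."""
    try:
        return rules._prop_to_ql[p]
    except KeyError:
        raise MissingRuleError(f"no qualitative rule for {p}") from None


def normalize_form(form: Form, rules: RuleTable) -> PropertyForm:
    """Normalize any representation to its property form."""
    if isinstance(form, QuantitativeForm):
        form = quantize(form, rules)
    if isinstance(form, QualitativeForm):
        form = to_property(form, rules)
    if isinstance(form, PropertyForm):
        return form
    raise TypeError(f"not a state form: {form!r}")


def interoperable(a: Form, b: Form, rules: RuleTable) -> bool:
    """True iff both forms denote the same property-form state."""
    return normalize_form(a, rules) == normalize_form(b, rules)


# ---------------------------------------------------------------------------
# three-layer level checks


def check_levels(ontology: DiseaseOntology) -> ValidationReport:
    """Layer-consistency over the state hierarchy.

    Violations: a parent with a strictly greater level than its child;
    a Level-2 state with no ancestor path reaching Level 1; a Level-3
    state with no Level-2 ancestor. Unknown placeholder nodes are
    exempt (they carry no layer semantics).
    """
    report = ValidationReport()

    def ancestor_levels(state: AbnormalState) -> set[int]:
        seen: set[str] = set()
        frontier = list(state.parents)
        levels: set[int] = set()
        while frontier:
            current = frontier.pop()
            if current in seen or current not in ontology.states:
                continue
            seen.add(current)
            parent = ontology.states[current]
            levels.add(parent.level)
            frontier.extend(parent.parents)
        return levels

    for sid in sorted(ontology.states):
        state = ontology.states[sid]
        if state.is_unknown:
            continue
        for pid in sorted(state.parents):
            parent = ontology.states.get(pid)
            if parent is not None and parent.level > state.level:
                report.append(
                    Finding("level-order", f"state {sid!r} (level {state.level}) has higher-level parent {pid!r} (level {parent.level})",
                            (sid, pid))
                )
        if state.level == 2 and 1 not in ancestor_levels(state):
            report.append(Finding("level2-no-level1-ancestor", f"level-2 state {sid!r} reaches no level-1 ancestor", (sid,)))
        if state.level == 3 and 2 not in ancestor_levels(state):
            report.append(Finding("level3-no-level2-ancestor", f"level-3 state {sid!r} has no level-2 ancestor", (sid,)))
    return report


# ---------------------------------------------------------------------------
# external vocabulary mapping

_WHITESPACE = re.compile(r"\s+")


def normalize_label(label: str, case_sensitive: bool = False) -> str:
    """Trim, collapse internal whitespace and (by default) case-fold."""
    collapsed = _WHITESPACE.sub(" ", label.strip())
    return collapsed if case_sensitive else collapsed.casefold()


@dataclass(frozen=True)
class MappingCandidate:
    """An exact-label match against one external vocabulary.

    Candidates are detected automatically but acceptance is a manual,
    downstream decision; ``accepted`` therefore defaults to False.
    """

    state_id: str
    resource: str
    external_id: str
    external_label: str
    status: str = "candidate"
    accepted: bool = False

    def accept(self) -> "MappingCandidate":
        return replace(self, status="accepted", accepted=True)


def match_external(
    states: Iterable[AbnormalState],
    vocab: Iterable[tuple[str, str]],
    resource: str = "external",
    case_sensitive: bool = False,
) -> list[MappingCandidate]:
    """Perfect-string-match candidate detection.

    A vocabulary row (id, label) is a candidate for a state iff the two
    normalized labels are equal. The result is independent of vocab row
    order (sorted by state id, then external id).
    """
    index: dict[str, list[tuple[str, str]]] = {}
    for ext_id, ext_label in vocab:
        index.setdefault(normalize_label(ext_label, case_sensitive), []).append((ext_id, ext_label))
    candidates = [
        MappingCandidate(state_id=state.id, resource=resource, external_id=ext_id, external_label=ext_label)
        for state in states
        for ext_id, ext_label in index.get(normalize_label(state.label, case_sensitive), ())
    ]
    return sorted(candidates, key=lambda c: (c.state_id, c.resource, c.external_id))


def load_vocab_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Two-column (id, label) TSV with a header row."""
    rows: list[tuple[str, str]] = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        ext_id, _, label = line.partition("\t")
        rows.append((ext_id.strip(), label.strip()))
    return rows


def mapping_summary(
    candidates: Sequence[MappingCandidate],
    ontology: DiseaseOntology,
    accepted_only: bool = True,
) -> dict:
    """Per-level count of states with at least one (accepted) mapping
    per vocabulary, in the shape of a mapping-results table: rows are
    levels 1..3 plus a totals row equal to the column sums; the
    ``states`` column counts ontology states per level."""
    relevant = [c for c in candidates if c.accepted or not accepted_only]
    resources = sorted({c.resource for c in candidates})
    mapped: dict[tuple[int, str], set[str]] = {}
    for cand in relevant:
        state = ontology.states.get(cand.state_id)
        if state is None:
            continue
        mapped.setdefault((state.level, cand.resource), set()).add(cand.state_id)

    table: dict = {}
    for level in (1, 2, 3):
        row = {"states": sum(1 for s in ontology.states.values() if s.level == level)}
        for resource in resources:
            row[resource] = len(mapped.get((level, resource), ()))
        table[level] = row
    table["total"] = {
        key: sum(table[level][key] for level in (1, 2, 3))
        for key in (["states"] + resources)
    }
    return table
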