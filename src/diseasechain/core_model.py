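"""Domain types for disease causal-chain ontologies.

A disease is modelled as a set of abnormal states connected by a global
pool of directed causal links; its chain is the subgraph of that pool
induced on the states it references (directly or via super-diseases).
Two separate acyclic hierarchies exist: ``subStateOf`` over abnormal
states and ``subDiseaseOf`` over diseases.

This module owns the data model, referential-integrity validation and
the state subsumption test; algorithms live in :mod:`diseasechain.rfm`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import networkx as nx

from .errors import FormatError, UnknownIdentifierError

__all__ = [
    "AbnormalState",
    "CausalLink",
    "Disease",
    "CausalGraph",
    "DiseaseOntology",
    "Finding",
    "ValidationReport",
    "state_subsumes",
    "validate_ontology",
    "model_equal",
    "load_ontology_tsv",
    "save_ontology_tsv",
]

LEVELS = (1, 2, 3)


@dataclass
class AbnormalState:
    """A node of disease causal chains.

    ``object``/``sub_object``/``attribute``/``value`` carry the
    descriptor tuple of the state (all optional); ``level`` places the
    state in the three-layer hierarchy (1 generic, 2 object-dependent,
    3 context-dependent); ``parents`` are ``subStateOf`` targets.
    """

    id: str
    label: str = ""
    level: int = 1
    object: Optional[str] = None
    sub_object: Optional[str] = None
    attribute: Optional[str] = None
    value: Optional[str] = None
    parents: frozenset[str] = field(default_factory=frozenset)
    is_unknown: bool = False
    external_refs: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.label:
            self.label = self.id
        self.parents = frozenset(self.parents)


@dataclass(frozen=True)
class CausalLink:
    """Directed cause -> effect edge in the global link pool."""

    cause: str
    effect: str
    probable: bool = False


@dataclass
class Disease:
    """A named disease: own core/derived state references plus supers.

    ``core_states``/``derived_states`` are ordered (authoring order is
    preserved for deterministic output) but order carries no meaning.
    """

    id: str
    label: str = ""
    core_states: tuple[str, ...] = ()
    derived_states: tuple[str, ...] = ()
    supers: frozenset[str] = field(default_factory=frozenset)
    area: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.label:
            self.label = self.id
        self.core_states = tuple(self.core_states)
        self.derived_states = tuple(self.derived_states)
        self.supers = frozenset(self.supers)


@dataclass
class CausalGraph:
    """An induced directed graph over a set of state ids.

    ``branch_mode`` annotates effect nodes with multiple incoming causes
    as ``"OR"`` (default, any cause suffices) or ``"AND"``; the
    annotation is carried and reported, never used to prune traversal.
    """

    states: frozenset[str] = field(default_factory=frozenset)
    links: frozenset[CausalLink] = field(default_factory=frozenset)
    branch_mode: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = frozenset(self.states)
        self.links = frozenset(self.links)
        bad = [l for l in self.links if l.cause not in self.states or l.effect not in self.states]
        if bad:
            raise FormatError(f"links with endpoints outside the state set: {sorted((l.cause, l.effect) for l in bad)}")

    def sorted_states(self) -> list[str]:
        return sorted(self.states)

    def sorted_links(self) -> list[CausalLink]:
        return sorted(self.links, key=lambda l: (l.cause, l.effect, l.probable))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.states)
        for link in self.links:
            g.add_edge(link.cause, link.effect, probable=link.probable)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CausalGraph):
            return NotImplemented
        return self.states == other.states and self.links == other.links

    def __hash__(self):  # pragma: no cover - graphs used as values, not keys
        return hash((self.states, self.links))


@dataclass
class DiseaseOntology:
    """Container for a full dataset: states, diseases, global links."""

    states: dict[str, AbnormalState] = field(default_factory=dict)
    diseases: dict[str, Disease] = field(default_factory=dict)
    links: set[CausalLink] = field(default_factory=set)
    #: effect nodes whose multiple incoming causes are conjunctive
    and_nodes: set[str] = field(default_factory=set)
    #: foreign RDF triples preserved verbatim by the RDF reader
    extra_triples: list = field(default_factory=list, compare=False)

    def state(self, state_id: str) -> AbnormalState:
        try:
            return self.states[state_id]
        except KeyError:
            raise UnknownIdentifierError("state", state_id) from None

    def disease(self, disease_id: str) -> Disease:
        try:
            return self.diseases[disease_id]
        except KeyError:
            raise UnknownIdentifierError("disease", disease_id) from None

    def add_state(self, state: AbnormalState) -> AbnormalState:
        self.states[state.id] = state
        return state

    def add_disease(self, disease: Disease) -> Disease:
        self.diseases[disease.id] = disease
        return disease

    def add_link(self, cause: str, effect: str, probable: bool = False) -> CausalLink:
        if cause == effect:
            raise FormatError(f"self-loop causal link rejected: {cause!r}")
        link = CausalLink(cause, effect, probable)
        self.links.add(link)
        return link

    def subclasses_of(self, disease_id: str, transitive: bool = True) -> set[str]:
        """Declared subDiseaseOf descendants of ``disease_id``."""
        self.disease(disease_id)
        direct: dict[str, set[str]] = {d: set() for d in self.diseases}
        for d in self.diseases.values():
            for sup in d.supers:
                direct.setdefault(sup, set()).add(d.id)
        found: set[str] = set()
        frontier = [disease_id]
        while frontier:
            current = frontier.pop()
            for sub in direct.get(current, ()):
                if sub not in found:
                    found.add(sub)
                    if transitive:
                        frontier.append(sub)
        return found

    def super_closure(self, disease_id: str) -> set[str]:
        """Transitive subDiseaseOf ancestors, excluding the disease itself."""
        self.disease(disease_id)
        seen: set[str] = set()
        frontier = [disease_id]
        while frontier:
            current = frontier.pop()
            for sup in self.diseases[current].supers if current in self.diseases else ():
                if sup not in seen:
                    seen.add(sup)
                    frontier.append(sup)
        return seen


# ---------------------------------------------------------------------------
# subsumption


def state_subsumes(general: str, specific: str, ontology: DiseaseOntology) -> bool:
    """True iff ``general`` is ``specific`` or an ancestor via subStateOf.

    Reflexive-transitive closure over declared parents; a visited set
    makes the walk terminate even on (invalid) cyclic hierarchies.
    """
    ontology.state(general)
    ontology.state(specific)
    if general == specific:
        return True
    seen: set[str] = set()
    frontier = [specific]
    while frontier:
        current = frontier.pop()
        state = ontology.states.get(current)
        if state is None:
            continue
        for parent in state.parents:
            if parent == general:
                return True
            if parent not in seen:
                seen.add(parent)
                frontier.append(parent)
    return False


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Finding:
    """One violated invariant; ``subjects`` names the offending entities."""

    code: str
    message: str
    subjects: tuple[str, ...] = ()


class ValidationReport(list):
    """List of findings; empty iff the ontology satisfies all invariants."""

    @property
    def ok(self) -> bool:
        return not self

    def codes(self) -> set[str]:
        return {f.code for f in self}

    def __str__(self) -> str:
        if self.ok:
            return "ontology valid: no findings"
        return "\n".join(f"[{f.code}] {f.message}" for f in self)


def _hierarchy_cycles(edges: Iterable[tuple[str, str]]) -> list[tuple[str, ...]]:
    g = nx.DiGraph()
    g.add_edges_from(edges)
    return [tuple(sorted(c)) for c in nx.simple_cycles(g)]


def validate_ontology(ontology: DiseaseOntology) -> ValidationReport:
    """Check every structural invariant; side-effect-free and idempotent."""
    report = ValidationReport()
    states = ontology.states
    diseases = ontology.diseases

    for state in states.values():
        if state.level not in LEVELS:
            report.append(Finding("bad-level", f"state {state.id!r} has level {state.level}", (state.id,)))
        if state.is_unknown:
            if any(x is not None for x in (state.object, state.sub_object, state.attribute, state.value)):
                report.append(
                    Finding("unknown-with-descriptors", f"unknown state {state.id!r} carries descriptors", (state.id,))
                )
        else:
            if state.level == 1 and state.object is not None:
                report.append(
                    Finding("level-object-mismatch", f"level-1 state {state.id!r} has a target object", (state.id,))
                )
            if state.level in (2, 3) and state.object is None:
                report.append(
                    Finding("level-object-mismatch", f"level-{state.level} state {state.id!r} lacks an object", (state.id,))
                )
        for parent in sorted(state.parents):
            if parent not in states:
                report.append(
                    Finding("dangling-state-parent", f"state {state.id!r} has unknown parent {parent!r}", (state.id, parent))
                )

    for cycle in _hierarchy_cycles((p, s.id) for s in states.values() for p in s.parents if p in states):
        report.append(Finding("state-cycle", f"subStateOf cycle through {cycle}", cycle))

    for link in sorted(ontology.links, key=lambda l: (l.cause, l.effect)):
        if link.cause == link.effect:
            report.append(Finding("self-loop-link", f"self-loop causal link on {link.cause!r}", (link.cause,)))
        for endpoint in (link.cause, link.effect):
            if endpoint not in states:
                report.append(
                    Finding("dangling-link-endpoint", f"link {link.cause!r}->{link.effect!r} references unknown state {endpoint!r}",
                            (link.cause, link.effect, endpoint))
                )

    for disease in diseases.values():
        overlap = set(disease.core_states) & set(disease.derived_states)
        if overlap:
            report.append(
                Finding("core-derived-overlap", f"disease {disease.id!r} lists {sorted(overlap)} as both core and derived",
                        (disease.id, *sorted(overlap)))
            )
        for sid in (*disease.core_states, *disease.derived_states):
            if sid not in states:
                report.append(
                    Finding("dangling-disease-state", f"disease {disease.id!r} references unknown state {sid!r}", (disease.id, sid))
                )
        for sup in sorted(disease.supers):
            if sup not in diseases:
                report.append(
                    Finding("dangling-disease-super", f"disease {disease.id!r} has unknown super {sup!r}", (disease.id, sup))
                )

    for cycle in _hierarchy_cycles((sup, d.id) for d in diseases.values() for sup in d.supers if sup in diseases):
        report.append(Finding("disease-cycle", f"subDiseaseOf cycle through {cycle}", cycle))

    for sid in sorted(ontology.and_nodes):
        if sid not in states:
            report.append(Finding("dangling-and-node", f"AND annotation on unknown state {sid!r}", (sid,)))

    return report


def model_equal(a: DiseaseOntology, b: DiseaseOntology) -> bool:
    """Model equality: state sets, disease definitions (core/derived
    compared as sets -- order is not semantically meaningful), and the
    global link pool."""
    if set(a.states) != set(b.states) or set(a.diseases) != set(b.diseases):
        return False
    for sid, sa in a.states.items():
        sb = b.states[sid]
        if (sa.label, sa.level, sa.object, sa.sub_object, sa.attribute, sa.value, sa.parents, sa.is_unknown) != (
            sb.label, sb.level, sb.object, sb.sub_object, sb.attribute, sb.value, sb.parents, sb.is_unknown
        ):
            return False
        if {k: sorted(v) for k, v in sa.external_refs.items() if v} != {k: sorted(v) for k, v in sb.external_refs.items() if v}:
            return False
    for did, da in a.diseases.items():
        db = b.diseases[did]
        if (da.label, set(da.core_states), set(da.derived_states), da.supers, da.area) != (
            db.label, set(db.core_states), set(db.derived_states), db.supers, db.area
        ):
            return False
    return set(a.links) == set(b.links) and set(a.and_nodes) == set(b.and_nodes)


# ---------------------------------------------------------------------------
# TSV interchange format
#
# Three UTF-8 tables with header rows; multi-valued cells pipe-separated;
# external refs encoded "RESOURCE:external_id".

STATE_COLUMNS = ["id", "label", "level", "object", "sub_object", "attribute", "value", "parents", "is_unknown", "external_refs"]
LINK_COLUMNS = ["cause", "effect", "probable"]
DISEASE_COLUMNS = ["id", "label", "area", "supers", "core_states", "derived_states"]


def _split_multi(cell: str) -> list[str]:
    return [part for part in cell.split("|") if part] if cell else []


def _parse_refs(cell: str) -> dict[str, list[str]]:
    refs: dict[str, list[str]] = {}
    for token in _split_multi(cell):
        if ":" not in token:
            raise FormatError(f"external ref {token!r} is not RESOURCE:id")
        resource, ext = token.split(":", 1)
        refs.setdefault(resource, []).append(ext)
    return refs


def _format_refs(refs: Mapping[str, Sequence[str]]) -> str:
    return "|".join(f"{res}:{ext}" for res in sorted(refs) for ext in refs[res])


def _parse_bool(cell: str) -> bool:
    if cell in ("", "0", "false", "False"):
        return False
    if cell in ("1", "true", "True"):
        return True
    raise FormatError(f"not a boolean cell: {cell!r}")


def _read_table(path: Path, columns: list[str]) -> Iterator[dict[str, str]]:
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != columns:
            raise FormatError(f"{path.name}: expected columns {columns}, found {reader.fieldnames}")
        for row in reader:
            yield {k: (v or "").strip() for k, v in row.items()}


def load_ontology_tsv(directory: str | Path) -> DiseaseOntology:
    """Read states.tsv / links.tsv / diseases.tsv from ``directory``."""
    directory = Path(directory)
    ontology = DiseaseOntology()
    for row in _read_table(directory / "states.tsv", STATE_COLUMNS):
        ontology.add_state(
            AbnormalState(
                id=row["id"],
                label=row["label"] or row["id"],
                level=int(row["level"] or 1),
                object=row["object"] or None,
                sub_object=row["sub_object"] or None,
                attribute=row["attribute"] or None,
                value=row["value"] or None,
                parents=frozenset(_split_multi(row["parents"])),
                is_unknown=_parse_bool(row["is_unknown"]),
                external_refs=_parse_refs(row["external_refs"]),
            )
        )
    links_path = directory / "links.tsv"
    if links_path.exists():
        for row in _read_table(links_path, LINK_COLUMNS):
            ontology.add_link(row["cause"], row["effect"], _parse_bool(row["probable"]))
    diseases_path = directory / "diseases.tsv"
    if diseases_path.exists():
        for row in _read_table(diseases_path, DISEASE_COLUMNS):
            ontology.add_disease(
                Disease(
                    id=row["id"],
                    label=row["label"] or row["id"],
                    area=row["area"] or None,
                    supers=frozenset(_split_multi(row["supers"])),
                    core_states=tuple(_split_multi(row["core_states"])),
                    derived_states=tuple(_split_multi(row["derived_states"])),
                )
            )
    return ontology


def save_ontology_tsv(ontology: DiseaseOntology, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def writer(name: str, columns: list[str]):
        handle = open(directory / name, "w", encoding="utf-8", newline="")
        w = csv.writer(handle, delimiter="\t", lineterminator="\n")
        w.writerow(columns)
        return handle, w

    handle, w = writer("states.tsv", STATE_COLUMNS)
    with handle:
        for sid in sorted(ontology.states):
            s = ontology.states[sid]
            w.writerow([
                s.id, s.label, s.level, s.object or "", s.sub_object or "", s.attribute or "", s.value or "",
                "|".join(sorted(s.parents)), "true" if s.is_unknown else "false", _format_refs(s.external_refs),
            ])
    handle, w = writer("links.tsv", LINK_COLUMNS)
    with handle:
        for link in sorted(ontology.links, key=lambda l: (l.cause, l.effect)):
            w.writerow([link.cause, link.effect, "true" if link.probable else "false"])
    handle, w = writer("diseases.tsv", DISEASE_COLUMNS)
    with handle:
        for did in sorted(ontology.diseases):
            d = ontology.diseases[did]
            w.writerow([
                d.id, d.label, d.area or "", "|".join(sorted(d.supers)),
                "|".join(d.core_states), "|".join(d.derived_states),
            ])
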