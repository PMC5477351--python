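"""RDF serialization and the query layer.

Diseases and abnormal states become typed resources; causal links
become ``hasCause`` arcs (by convention pointing from an effect to its
cause -- "this state has cause X" -- switchable via
:class:`Vocabulary`) with the ``hasResult`` inverse always
materialized, and ``hasProbableCause``/``hasProbableResult`` used for
probable links. ``hasCoreState``/``hasDerivedState`` arcs are emitted
for a disease's OWN states only; inherited states are recovered at
query time by aggregating over ``subDiseaseOf*``.

Model content that the core vocabulary cannot carry (levels,
descriptor tuples, external refs, AND-branch flags) goes into a
separate extension namespace so that round-trips are lossless.

Each of the nine named query patterns exists twice: a pure-Python
evaluation over the in-memory model (:func:`run_query`) and a SPARQL
text (shipped under ``queries/``) executable against the serialized
graph with any conformant engine (:func:`run_query_sparql`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Union

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import RDF, RDFS, XSD

from .core_model import (
    AbnormalState,
    CausalLink,
    Disease,
    DiseaseOntology,
    validate_ontology,
)
from .errors import ArgumentError, FormatError, InvalidOntologyError, UnknownIdentifierError

__all__ = [
    "Vocabulary",
    "QUERY_NAMES",
    "to_rdf",
    "from_rdf",
    "serialize_turtle",
    "parse_rdf",
    "query_text",
    "run_query",
    "run_query_sparql",
]

DEFAULT_NAMESPACE = "http://diseasechain.example.org/ontology#"
DEFAULT_EXTENSION_NAMESPACE = "http://diseasechain.example.org/extension#"

QUERY_NAMES = (
    "all_states",      # a1
    "causes_of",       # a2
    "general_chain",   # a3
    "all_diseases",    # d1
    "super_diseases",  # d2
    "core_states",     # d3
    "derived_states",  # d4
    "definition_states",  # d5
    "definition_links",   # d6
)

_STATE_QUERIES = {"causes_of", "general_chain"}
_DISEASE_QUERIES = {"super_diseases", "core_states", "derived_states", "definition_states", "definition_links"}


@dataclass(frozen=True)
class Vocabulary:
    """The term set of the RDF model.

    ``cause_points_to_cause`` keeps the default reading of ``hasCause``
    as an arc from an effect resource to its cause ("has cause");
    setting it False flips both inverse pairs on write and read.
    """

    namespace: str = DEFAULT_NAMESPACE
    extension_namespace: str = DEFAULT_EXTENSION_NAMESPACE
    prefix: str = "dont"
    extension_prefix: str = "dontx"
    cause_points_to_cause: bool = True

    @property
    def ns(self) -> Namespace:
        return Namespace(self.namespace)

    @property
    def ext(self) -> Namespace:
        return Namespace(self.extension_namespace)

    # types
    @property
    def Disease(self) -> URIRef:
        return self.ns["Disease"]

    @property
    def Abnormal_State(self) -> URIRef:
        return self.ns["Abnormal_State"]

    # properties
    def term(self, name: str) -> URIRef:
        return self.ns[name]

    @property
    def properties(self) -> tuple[URIRef, ...]:
        return tuple(
            self.ns[name]
            for name in (
                "hasCause", "hasResult", "hasProbableCause", "hasProbableResult",
                "hasCoreState", "hasDerivedState", "subDiseaseOf", "subStateOf",
            )
        )

    def uri(self, local_id: str) -> URIRef:
        return self.ns[local_id]

    def local(self, uri: URIRef) -> str:
        text = str(uri)
        if text.startswith(self.namespace):
            return text[len(self.namespace):]
        return text


DEFAULT_VOCAB = Vocabulary()


# ---------------------------------------------------------------------------
# writing


def _bind(graph: Graph, vocab: Vocabulary) -> Graph:
    graph.bind(vocab.prefix, vocab.ns)
    graph.bind(vocab.extension_prefix, vocab.ext)
    graph.bind("rdf", RDF)
    graph.bind("rdfs", RDFS)
    graph.bind("xsd", XSD)
    return graph


def to_rdf(ontology: DiseaseOntology, vocab: Vocabulary = DEFAULT_VOCAB) -> Graph:
    """Serialize the full model into an RDF graph.

    Refuses invalid ontologies. Both members of each inverse causal
    pair are materialized so any engine can follow either direction.
    """
    report = validate_ontology(ontology)
    if not report.ok:
        raise InvalidOntologyError(report)

    graph = _bind(Graph(), vocab)
    ns, ext = vocab.ns, vocab.ext

    for sid in sorted(ontology.states):
        state = ontology.states[sid]
        s = vocab.uri(sid)
        graph.add((s, RDF.type, vocab.Abnormal_State))
        graph.add((s, RDFS.label, Literal(state.label)))
        for parent in sorted(state.parents):
            graph.add((s, ns["subStateOf"], vocab.uri(parent)))
        if state.level != 1:
            graph.add((s, ext["level"], Literal(state.level)))
        for attr in ("object", "sub_object", "attribute", "value"):
            value = getattr(state, attr)
            if value is not None:
                graph.add((s, ext[_camel(attr)], Literal(value)))
        if state.is_unknown:
            graph.add((s, ext["isUnknown"], Literal(True)))
        for resource in sorted(state.external_refs):
            for ext_id in sorted(state.external_refs[resource]):
                graph.add((s, ext["externalRef"], Literal(f"{resource}:{ext_id}")))

    for did in sorted(ontology.diseases):
        disease = ontology.diseases[did]
        d = vocab.uri(did)
        graph.add((d, RDF.type, vocab.Disease))
        graph.add((d, RDFS.label, Literal(disease.label)))
        if disease.area is not None:
            graph.add((d, ext["area"], Literal(disease.area)))
        for sup in sorted(disease.supers):
            graph.add((d, ns["subDiseaseOf"], vocab.uri(sup)))
        for sid in disease.core_states:
            graph.add((d, ns["hasCoreState"], vocab.uri(sid)))
        for sid in disease.derived_states:
            graph.add((d, ns["hasDerivedState"], vocab.uri(sid)))

    for link in sorted(ontology.links, key=lambda l: (l.cause, l.effect)):
        cause, effect = vocab.uri(link.cause), vocab.uri(link.effect)
        cause_pred = "hasProbableCause" if link.probable else "hasCause"
        result_pred = "hasProbableResult" if link.probable else "hasResult"
        if vocab.cause_points_to_cause:
            graph.add((effect, ns[cause_pred], cause))
            graph.add((cause, ns[result_pred], effect))
        else:
            graph.add((cause, ns[cause_pred], effect))
            graph.add((effect, ns[result_pred], cause))

    for sid in sorted(ontology.and_nodes):
        graph.add((vocab.uri(sid), ext["branchAnd"], Literal(True)))

    for triple in ontology.extra_triples:
        graph.add(triple)
    return graph


def _camel(snake: str) -> str:
    head, *rest = snake.split("_")
    return head + "".join(part.capitalize() for part in rest)


def serialize_turtle(source: Union[DiseaseOntology, Graph], vocab: Vocabulary = DEFAULT_VOCAB) -> str:
    """Deterministic Turtle: prefix block, then one triple per line
    sorted by subject, predicate, object. Byte-stable for equal models."""
    graph = source if isinstance(source, Graph) else to_rdf(source, vocab)
    _bind(graph, vocab)
    nm = graph.namespace_manager
    lines = [
        f"@prefix {prefix}: <{ns}> ."
        for prefix, ns in sorted(graph.namespaces())
        if prefix in {vocab.prefix, vocab.extension_prefix, "rdf", "rdfs", "xsd"}
    ]
    lines.append("")
    triples = sorted(graph, key=lambda t: (str(t[0]), str(t[1]), str(t[2])))
    for s, p, o in triples:
        lines.append(f"{s.n3(nm)} {p.n3(nm)} {o.n3(nm)} .")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# reading


def parse_rdf(text: str, format: str = "turtle") -> Graph:
    graph = Graph()
    graph.parse(data=text, format=format)
    return graph


def from_rdf(graph: Graph, vocab: Vocabulary = DEFAULT_VOCAB) -> DiseaseOntology:
    """Rebuild the model from a graph produced by :func:`to_rdf`.

    Accepts graphs carrying only one member of an inverse pair (the
    other is completed). Triples with predicates outside the vocabulary
    are preserved verbatim on ``ontology.extra_triples`` and re-emitted
    by :func:`to_rdf`. Dangling references surface later as
    validation findings, not parse errors.
    """
    ns, ext = vocab.ns, vocab.ext
    known_predicates = set(vocab.properties) | {
        RDF.type, RDFS.label,
        ext["level"], ext["object"], ext["subObject"], ext["attribute"], ext["value"],
        ext["isUnknown"], ext["externalRef"], ext["area"], ext["branchAnd"],
    }

    state_uris = set(graph.subjects(RDF.type, vocab.Abnormal_State))
    disease_uris = set(graph.subjects(RDF.type, vocab.Disease))
    both = state_uris & disease_uris
    if both:
        raise FormatError(f"resources typed both Disease and Abnormal_State: {sorted(map(str, both))}")

    ontology = DiseaseOntology()

    def value_of(s: URIRef, p: URIRef):
        for o in graph.objects(s, p):
            return o
        return None

    for s in sorted(state_uris, key=str):
        sid = vocab.local(s)
        refs: dict[str, list[str]] = {}
        for o in graph.objects(s, ext["externalRef"]):
            resource, _, ext_id = str(o).partition(":")
            refs.setdefault(resource, []).append(ext_id)
        label = value_of(s, RDFS.label)
        level = value_of(s, ext["level"])
        ontology.add_state(
            AbnormalState(
                id=sid,
                label=str(label) if label is not None else sid,
                level=int(level) if level is not None else 1,
                object=_opt_str(value_of(s, ext["object"])),
                sub_object=_opt_str(value_of(s, ext["subObject"])),
                attribute=_opt_str(value_of(s, ext["attribute"])),
                value=_opt_str(value_of(s, ext["value"])),
                parents=frozenset(vocab.local(p) for p in graph.objects(s, ns["subStateOf"])),
                is_unknown=bool(value_of(s, ext["isUnknown"]) is not None and value_of(s, ext["isUnknown"]).toPython()),
                external_refs={k: sorted(v) for k, v in refs.items()},
            )
        )

    for d in sorted(disease_uris, key=str):
        did = vocab.local(d)
        label = value_of(d, RDFS.label)
        area = value_of(d, ext["area"])
        ontology.add_disease(
            Disease(
                id=did,
                label=str(label) if label is not None else did,
                area=_opt_str(area),
                supers=frozenset(vocab.local(s) for s in graph.objects(d, ns["subDiseaseOf"])),
                core_states=tuple(sorted(vocab.local(s) for s in graph.objects(d, ns["hasCoreState"]))),
                derived_states=tuple(sorted(vocab.local(s) for s in graph.objects(d, ns["hasDerivedState"]))),
            )
        )

    for cause_pred, result_pred, probable in (
        ("hasCause", "hasResult", False),
        ("hasProbableCause", "hasProbableResult", True),
    ):
        for s, o in graph.subject_objects(ns[cause_pred]):
            effect, cause = (s, o) if vocab.cause_points_to_cause else (o, s)
            ontology.links.add(CausalLink(vocab.local(cause), vocab.local(effect), probable))
        for s, o in graph.subject_objects(ns[result_pred]):
            cause, effect = (s, o) if vocab.cause_points_to_cause else (o, s)
            ontology.links.add(CausalLink(vocab.local(cause), vocab.local(effect), probable))

    for s in graph.subjects(ext["branchAnd"], Literal(True)):
        ontology.and_nodes.add(vocab.local(s))

    ontology.extra_triples = sorted(
        (t for t in graph if t[1] not in known_predicates),
        key=lambda t: (str(t[0]), str(t[1]), str(t[2])),
    )
    return ontology


def _opt_str(term) -> Optional[str]:
    return str(term) if term is not None else None


# ---------------------------------------------------------------------------
# query layer


def query_text(name: str, vocab: Vocabulary = DEFAULT_VOCAB, target_id: Optional[str] = None) -> str:
    """The SPARQL pattern for a query name, with the target id (and the
    configured namespace) substituted in."""
    if name not in QUERY_NAMES:
        raise ArgumentError(f"unknown query name {name!r}; expected one of {QUERY_NAMES}")
    text = resources.files("diseasechain.queries").joinpath(f"{name}.rq").read_text(encoding="utf-8")
    text = text.replace(DEFAULT_NAMESPACE, vocab.namespace)
    if "__ID__" in text:
        if target_id is None:
            raise ArgumentError(f"query {name!r} requires a target id")
        text = text.replace("__ID__", target_id)
    return text


def run_query(
    name: str,
    ontology: DiseaseOntology,
    target_id: Optional[str] = None,
) -> list:
    """Evaluate a named query pattern directly over the model.

    Returns sorted state/disease ids, except ``definition_links`` which
    returns sorted (subject, predicate, object) id triples mirroring
    the materialized arcs.
    """
    if name not in QUERY_NAMES:
        raise ArgumentError(f"unknown query name {name!r}; expected one of {QUERY_NAMES}")
    if name in _STATE_QUERIES:
        if target_id is None:
            raise ArgumentError(f"query {name!r} requires a state id")
        ontology.state(target_id)
    if name in _DISEASE_QUERIES:
        if target_id is None:
            raise ArgumentError(f"query {name!r} requires a disease id")
        ontology.disease(target_id)

    if name == "all_states":
        return sorted(ontology.states)
    if name == "all_diseases":
        return sorted(ontology.diseases)
    if name == "causes_of":
        return sorted({l.cause for l in ontology.links if l.effect == target_id and not l.probable})
    if name == "general_chain":
        neighbors: dict[str, set[str]] = {}
        for link in ontology.links:
            neighbors.setdefault(link.cause, set()).add(link.effect)
            neighbors.setdefault(link.effect, set()).add(link.cause)
        seen = {target_id}
        frontier = [target_id]
        while frontier:
            for nxt in neighbors.get(frontier.pop(), ()):
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append(nxt)
        return sorted(seen)
    if name == "super_diseases":
        return sorted(ontology.super_closure(target_id))

    scope = {target_id} | ontology.super_closure(target_id)
    scope &= set(ontology.diseases)
    if name == "core_states":
        return sorted({s for d in scope for s in ontology.diseases[d].core_states})
    if name == "derived_states":
        return sorted({s for d in scope for s in ontology.diseases[d].derived_states})
    definition = {
        s for d in scope
        for s in (*ontology.diseases[d].core_states, *ontology.diseases[d].derived_states)
    }
    if name == "definition_states":
        return sorted(definition)
    # definition_links: every materialized causal arc among definition states
    rows: set[tuple[str, str, str]] = set()
    for link in ontology.links:
        if link.cause in definition and link.effect in definition:
            cause_pred = "hasProbableCause" if link.probable else "hasCause"
            result_pred = "hasProbableResult" if link.probable else "hasResult"
            rows.add((link.effect, cause_pred, link.cause))
            rows.add((link.cause, result_pred, link.effect))
    return sorted(rows)


def run_query_sparql(
    name: str,
    source: Union[DiseaseOntology, Graph],
    target_id: Optional[str] = None,
    vocab: Vocabulary = DEFAULT_VOCAB,
) -> list:
    """Execute the shipped SPARQL text against the serialized graph with
    the bundled SPARQL engine; results are converted back to local ids
    so they are directly comparable with :func:`run_query`."""
    graph = source if isinstance(source, Graph) else to_rdf(source, vocab)
    result = graph.query(query_text(name, vocab, target_id))
    rows = []
    for binding in result:
        values = tuple(vocab.local(term) if isinstance(term, URIRef) else str(term) for term in binding)
        rows.append(values[0] if len(values) == 1 else values)
    return sorted(set(rows))
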