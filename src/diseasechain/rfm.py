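"""Causal-chain algorithms.

The operations here implement the computational disease model: a
disease's chain is the subgraph of the global link pool induced on its
aggregated state set; disease subclassing is inferred from
subsumption-aware inclusion of one chain in another; the core chain of
a disease is the part of its chain covered by every subclass chain.

Inclusion matching (:func:`chain_included_in`) is a deterministic
backtracking search for an injective node map under state subsumption,
with link matching either against direct links (``strict``) or against
nonempty directed paths (``path``, the default: authored chains may
elide intermediate states).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import networkx as nx

from .core_model import CausalGraph, CausalLink, DiseaseOntology, state_subsumes
from .errors import ArgumentError, UnknownIdentifierError

__all__ = [
    "InclusionWitness",
    "IsaResult",
    "effective_states",
    "chain_graph",
    "chain_included_in",
    "disease_is_super_of",
    "infer_isa_hierarchy",
    "core_causal_chain",
    "validate_core_against_subclasses",
    "upstream_closure",
    "downstream_closure",
    "general_graph",
    "diseases_containing",
]

Mode = Literal["path", "strict"]
Which = Literal["core", "derived", "all"]


def _check_mode(mode: str) -> None:
    if mode not in ("path", "strict"):
        raise ArgumentError(f"mode must be 'path' or 'strict', not {mode!r}")


@dataclass
class InclusionWitness:
    """Proof object for one chain being included in another.

    ``node_map`` sends each state of the included graph to a distinct
    state of the including graph that it subsumes; ``edge_map`` sends
    each link of the included graph to a directed path (list of links)
    in the including graph between the mapped endpoints.
    """

    node_map: dict[str, str] = field(default_factory=dict)
    edge_map: dict[CausalLink, list[CausalLink]] = field(default_factory=dict)


@dataclass
class IsaResult:
    """Inferred disease is-a relation.

    ``pairs`` is the set of (sub, super) pairs, transitively closed by
    construction; ``reduced_pairs`` its transitive reduction;
    ``equivalences`` unordered disease pairs whose chains include each
    other; ``discrepancies`` declared subDiseaseOf pairs that the
    inclusion test does not confirm.
    """

    pairs: set[tuple[str, str]] = field(default_factory=set)
    reduced_pairs: set[tuple[str, str]] = field(default_factory=set)
    equivalences: set[frozenset[str]] = field(default_factory=set)
    discrepancies: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# chain assembly


def effective_states(disease_id: str, which: Which, ontology: DiseaseOntology) -> set[str]:
    """Union of the requested state sets over the disease and all its
    transitive super-diseases (chains of a sub-disease aggregate those
    of its supers)."""
    if which not in ("core", "derived", "all"):
        raise ArgumentError(f"which must be core|derived|all, not {which!r}")
    result: set[str] = set()
    for did in {disease_id} | ontology.super_closure(disease_id):
        disease = ontology.diseases.get(did)
        if disease is None:
            continue
        if which in ("core", "all"):
            result.update(disease.core_states)
        if which in ("derived", "all"):
            result.update(disease.derived_states)
    return result


def chain_graph(disease_id: str, which: Which, ontology: DiseaseOntology) -> CausalGraph:
    """Subgraph of the global link pool induced on the disease's
    aggregated state set; a link belongs to the chain iff both of its
    endpoints do."""
    states = effective_states(disease_id, which, ontology)
    links = {l for l in ontology.links if l.cause in states and l.effect in states}
    mode = {s: "AND" for s in ontology.and_nodes if s in states}
    return CausalGraph(states=states, links=links, branch_mode=mode)


def general_graph(ontology: DiseaseOntology) -> CausalGraph:
    """The bottom-up union of every authored chain: all states, all
    global links."""
    return CausalGraph(
        states=set(ontology.states),
        links=set(ontology.links),
        branch_mode={s: "AND" for s in ontology.and_nodes},
    )


# ---------------------------------------------------------------------------
# inclusion matching


def _node_cover_ok(a: str, b: str, ontology: DiseaseOntology) -> bool:
    # Unknown nodes stand for elided segments: they match only other
    # unknown nodes as map targets (but are freely traversed on paths).
    state_a = ontology.state(a)
    state_b = ontology.state(b)
    if state_a.is_unknown or state_b.is_unknown:
        return state_a.is_unknown and state_b.is_unknown
    return state_subsumes(a, b, ontology)


def chain_included_in(
    included: CausalGraph,
    including: CausalGraph,
    ontology: DiseaseOntology,
    mode: Mode = "path",
) -> Optional[InclusionWitness]:
    """Search for a witness that ``included`` is contained in
    ``including`` up to state subsumption.

    Nodes map injectively; each node of ``included`` must subsume its
    image. Each link must be matched by a direct link (``strict``) or a
    nonempty directed path (``path``) between the images. Ties are
    broken by sorted state id, so the returned witness is reproducible.
    Returns ``None`` when no witness exists.
    """
    _check_mode(mode)
    for sid in included.states | including.states:
        ontology.state(sid)

    graph_b = including.to_networkx()
    if mode == "path":
        reach = {n: nx.descendants(graph_b, n) for n in graph_b.nodes}
    else:
        reach = {n: set(graph_b.successors(n)) for n in graph_b.nodes}

    nodes_a = sorted(included.states)
    candidates = {
        a: [b for b in sorted(including.states) if _node_cover_ok(a, b, ontology)]
        for a in nodes_a
    }
    if any(not candidates[a] for a in nodes_a):
        return None

    out_links: dict[str, list[CausalLink]] = {a: [] for a in nodes_a}
    in_links: dict[str, list[CausalLink]] = {a: [] for a in nodes_a}
    for link in included.links:
        out_links[link.cause].append(link)
        in_links[link.effect].append(link)

    assignment: dict[str, str] = {}
    used: set[str] = set()

    def feasible(a: str, b: str) -> bool:
        for link in out_links[a]:
            if link.effect in assignment and assignment[link.effect] not in reach[b]:
                return False
        for link in in_links[a]:
            if link.cause in assignment and b not in reach[assignment[link.cause]]:
                return False
        return True

    def search(index: int) -> bool:
        if index == len(nodes_a):
            return True
        a = nodes_a[index]
        for b in candidates[a]:
            if b in used or not feasible(a, b):
                continue
            assignment[a] = b
            used.add(b)
            if search(index + 1):
                return True
            del assignment[a]
            used.discard(b)
        return False

    if not search(0):
        return None

    edge_map: dict[CausalLink, list[CausalLink]] = {}
    edge_index = {(l.cause, l.effect): l for l in including.links}
    for link in sorted(included.links, key=lambda l: (l.cause, l.effect)):
        source, target = assignment[link.cause], assignment[link.effect]
        if mode == "strict":
            path_nodes = [source, target]
        else:
            path_nodes = nx.shortest_path(graph_b, source, target)
        edge_map[link] = [edge_index[(u, v)] for u, v in zip(path_nodes, path_nodes[1:])]
    return InclusionWitness(node_map=dict(assignment), edge_map=edge_map)


def disease_is_super_of(
    super_id: str,
    sub_id: str,
    ontology: DiseaseOntology,
    mode: Mode = "path",
    which: Which = "all",
) -> bool:
    """True iff the (aggregated) chain of ``super_id`` is included in
    the chain of ``sub_id``."""
    if super_id == sub_id:
        raise ArgumentError("a disease cannot be compared with itself")
    a = chain_graph(super_id, which, ontology)
    b = chain_graph(sub_id, which, ontology)
    return chain_included_in(a, b, ontology, mode) is not None


def infer_isa_hierarchy(ontology: DiseaseOntology, mode: Mode = "path", which: Which = "all") -> IsaResult:
    """Classify all disease pairs by chain inclusion.

    Mutually-including pairs are reported as equivalences and excluded
    from ``pairs`` (which therefore stays antisymmetric and admits a
    transitive reduction). Declared subDiseaseOf links not confirmed by
    the inclusion test are reported as discrepancies.
    """
    _check_mode(mode)
    ids = sorted(ontology.diseases)
    graphs = {d: chain_graph(d, which, ontology) for d in ids}
    includes: dict[tuple[str, str], bool] = {}
    for a in ids:
        for b in ids:
            if a != b:
                includes[(a, b)] = chain_included_in(graphs[a], graphs[b], ontology, mode) is not None

    result = IsaResult()
    for a in ids:
        for b in ids:
            if a == b:
                continue
            if includes[(a, b)] and includes[(b, a)]:
                result.equivalences.add(frozenset((a, b)))
            elif includes[(a, b)]:
                # chain of a is included in chain of b: a is the super
                result.pairs.add((b, a))

    dag = nx.DiGraph()
    dag.add_nodes_from(ids)
    dag.add_edges_from(result.pairs)
    result.reduced_pairs = set(nx.transitive_reduction(dag).edges)

    for disease in ontology.diseases.values():
        for sup in sorted(disease.supers):
            if sup in ontology.diseases and (disease.id, sup) not in result.pairs \
                    and frozenset((disease.id, sup)) not in result.equivalences:
                result.discrepancies.append((disease.id, sup))
    result.discrepancies.sort()
    return result


# ---------------------------------------------------------------------------
# core chains


def _state_covered(state: str, target: CausalGraph, ontology: DiseaseOntology) -> bool:
    return any(_node_cover_ok(state, t, ontology) for t in target.states)


def _link_covered(link: CausalLink, target: CausalGraph, ontology: DiseaseOntology, mode: Mode) -> bool:
    graph = target.to_networkx()
    sources = [t for t in target.states if _node_cover_ok(link.cause, t, ontology)]
    targets = [t for t in target.states if _node_cover_ok(link.effect, t, ontology)]
    for s in sources:
        for t in targets:
            if s == t:
                continue
            if mode == "strict":
                if graph.has_edge(s, t):
                    return True
            elif nx.has_path(graph, s, t):
                return True
    return False


def core_causal_chain(
    disease_id: str,
    ontology: DiseaseOntology,
    mode: Mode = "path",
    subclasses: Optional[Iterable[str]] = None,
) -> CausalGraph:
    """The part of the disease's chain covered by every subclass chain.

    Per-element filtering: a state survives iff every subclass chain
    contains an equal-or-more-specific state; a link survives iff every
    subclass chain realizes it as a direct link (``strict``) or a
    directed path (``path``). A disease without subclasses falls back
    to its declared core chain.

    ``subclasses`` defaults to the declared subDiseaseOf descendants;
    pass an explicit set (e.g. from an inferred hierarchy) to compare
    against standalone-authored chains. Note that a declared subclass
    aggregates its supers' chains, so against declared subclasses the
    filter can only remove elements uncovered for link-direction
    reasons.
    """
    _check_mode(mode)
    if subclasses is None:
        subclasses = ontology.subclasses_of(disease_id)
    subclasses = sorted(subclasses)
    if not subclasses:
        return chain_graph(disease_id, "core", ontology)
    own = chain_graph(disease_id, "all", ontology)
    sub_chains = [chain_graph(s, "all", ontology) for s in subclasses]

    kept_states = {
        s for s in own.states
        if all(_state_covered(s, chain, ontology) for chain in sub_chains)
    }
    kept_links = {
        l for l in own.links
        if l.cause in kept_states and l.effect in kept_states
        and all(_link_covered(l, chain, ontology, mode) for chain in sub_chains)
    }
    mode_ann = {s: "AND" for s in ontology.and_nodes if s in kept_states}
    return CausalGraph(states=kept_states, links=kept_links, branch_mode=mode_ann)


def validate_core_against_subclasses(
    disease_id: str,
    ontology: DiseaseOntology,
    mode: Mode = "path",
    subclasses: Optional[Iterable[str]] = None,
) -> list[tuple[str, object]]:
    """Check that the declared core chain is included in every subclass
    chain; returns (subclass, uncovered element) pairs."""
    _check_mode(mode)
    if subclasses is None:
        subclasses = ontology.subclasses_of(disease_id)
    core = chain_graph(disease_id, "core", ontology)
    violations: list[tuple[str, object]] = []
    for sub in sorted(subclasses):
        target = chain_graph(sub, "all", ontology)
        if chain_included_in(core, target, ontology, mode) is not None:
            continue
        for state in core.sorted_states():
            if not _state_covered(state, target, ontology):
                violations.append((sub, state))
        for link in core.sorted_links():
            if not _link_covered(link, target, ontology, mode):
                violations.append((sub, link))
    return violations


# ---------------------------------------------------------------------------
# traversal


def _closure(seed: str, graph: CausalGraph, forward: bool, max_depth: Optional[int]) -> CausalGraph:
    if seed not in graph.states:
        raise UnknownIdentifierError("state", seed)
    g = graph.to_networkx()
    step = g.successors if forward else g.predecessors
    visited = {seed}
    frontier = [seed]
    depth = 0
    while frontier and (max_depth is None or depth < max_depth):
        depth += 1
        next_frontier = []
        for node in frontier:
            for neighbor in step(node):
                if neighbor not in visited:
                    visited.add(neighbor)
                    next_frontier.append(neighbor)
        frontier = next_frontier
    links = {l for l in graph.links if l.cause in visited and l.effect in visited}
    mode_ann = {s: m for s, m in graph.branch_mode.items() if s in visited}
    return CausalGraph(states=visited, links=links, branch_mode=mode_ann)


def downstream_closure(state_id: str, graph: CausalGraph, max_depth: Optional[int] = None) -> CausalGraph:
    """All states reachable from ``state_id`` along cause->effect edges
    (possible consequences); terminates on cycles via a visited set."""
    return _closure(state_id, graph, forward=True, max_depth=max_depth)


def upstream_closure(state_id: str, graph: CausalGraph, max_depth: Optional[int] = None) -> CausalGraph:
    """All states from which ``state_id`` is reachable (possible
    causes); terminates on cycles via a visited set."""
    return _closure(state_id, graph, forward=False, max_depth=max_depth)


# ---------------------------------------------------------------------------
# navigation


def diseases_containing(
    state_id: str,
    ontology: DiseaseOntology,
    include_state_descendants: bool = False,
) -> list[str]:
    """Diseases whose aggregated state set contains the state (or any
    subStateOf descendant of it when the flag is on); sorted by id."""
    ontology.state(state_id)
    if include_state_descendants:
        wanted = {s for s in ontology.states if state_subsumes(state_id, s, ontology)}
    else:
        wanted = {state_id}
    return sorted(
        d for d in ontology.diseases
        if effective_states(d, "all", ontology) & wanted
    )
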