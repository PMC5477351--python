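"""Independent oracles used by unit and acceptance tests.

Everything here is deliberately naive and self-contained: exhaustive
enumeration over all injective node maps, hand-rolled reachability, no
reuse of the package's search code beyond the plain data types.
"""

from __future__ import annotations

import itertools
import random

from diseasechain.core_model import (
    AbnormalState,
    CausalGraph,
    CausalLink,
    DiseaseOntology,
)


def ancestors_of(state_id: str, ontology: DiseaseOntology) -> set[str]:
    """Reflexive-transitive parent closure, by explicit stack walk."""
    closure = {state_id}
    stack = [state_id]
    while stack:
        current = stack.pop()
        for parent in ontology.states[current].parents:
            if parent not in closure and parent in ontology.states:
                closure.add(parent)
                stack.append(parent)
    return closure


def reachable_from(start: str, links: set[CausalLink]) -> set[str]:
    """Nodes reachable from ``start`` by one or more directed links."""
    adjacency: dict[str, set[str]] = {}
    for link in links:
        adjacency.setdefault(link.cause, set()).add(link.effect)
    seen: set[str] = set()
    stack = list(adjacency.get(start, ()))
    while stack:
        node = stack.pop()
        if node not in seen:
            seen.add(node)
            stack.extend(adjacency.get(node, ()))
    return seen


def node_match_allowed(a: str, b: str, ontology: DiseaseOntology) -> bool:
    sa, sb = ontology.states[a], ontology.states[b]
    if sa.is_unknown or sb.is_unknown:
        return sa.is_unknown and sb.is_unknown
    return a in ancestors_of(b, ontology)


def brute_force_included(
    a: CausalGraph, b: CausalGraph, ontology: DiseaseOntology, mode: str
) -> bool:
    """Enumerate every injective map from a's states into b's states and
    check subsumption plus edge realization."""
    nodes_a = sorted(a.states)
    nodes_b = sorted(b.states)
    if len(nodes_a) > len(nodes_b):
        return False
    direct = {(l.cause, l.effect) for l in b.links}
    reach = {n: reachable_from(n, set(b.links)) for n in nodes_b}
    for image in itertools.permutations(nodes_b, len(nodes_a)):
        assignment = dict(zip(nodes_a, image))
        if not all(node_match_allowed(x, y, ontology) for x, y in assignment.items()):
            continue
        ok = True
        for link in a.links:
            u, v = assignment[link.cause], assignment[link.effect]
            if mode == "strict":
                ok = (u, v) in direct
            else:
                ok = v in reach[u]
            if not ok:
                break
        if ok:
            return True
    return False


def random_hierarchy_ontology(rng: random.Random, n_states: int, p_unknown: float = 0.1) -> DiseaseOntology:
    """A random acyclic state forest (parents always have lower index)."""
    ontology = DiseaseOntology()
    for i in range(n_states):
        unknown = rng.random() < p_unknown
        parents = frozenset()
        if i > 0 and not unknown and rng.random() < 0.6:
            parents = frozenset({f"n{rng.randrange(i):03d}"})
        ontology.add_state(
            AbnormalState(id=f"n{i:03d}", label=f"state {i}", level=1,
                          parents=parents, is_unknown=unknown)
        )
    return ontology


def random_graph(rng: random.Random, ontology: DiseaseOntology, max_nodes: int, p_edge: float = 0.3) -> CausalGraph:
    pool = sorted(ontology.states)
    k = rng.randint(0, min(max_nodes, len(pool)))
    nodes = rng.sample(pool, k)
    links = {
        CausalLink(u, v)
        for u in nodes
        for v in nodes
        if u != v and rng.random() < p_edge
    }
    return CausalGraph(states=set(nodes), links=links)
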