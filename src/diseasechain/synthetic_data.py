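"""Packaged worked-example fixtures and a random ontology generator.

The fixtures carry the diabetes disease family (four chains, with
elided segments realized as single unknown nodes), the stenosis state
hierarchy with its external-vocabulary annotations, four mini
vocabularies, and the interoperability rule table.

The generator emulates clinician authoring: root diseases get fresh
causal chains; subclasses copy the parent chain, optionally specialize
inherited states to planted descendants (``p_refine``), optionally
split inherited edges with new intermediates (``p_insert``), and always
extend the chain upstream or downstream with fresh states. The planted
disease hierarchy, core chains and state hierarchy are returned as
ground truth for parameter-recovery tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .core_model import (
    AbnormalState,
    CausalGraph,
    Disease,
    DiseaseOntology,
    load_ontology_tsv,
)
from .errors import ConfigError
from .states import RuleTable, load_vocab_tsv

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "fixture_diabetes",
    "fixture_stenosis_hierarchy",
    "fixture_interop_rules",
    "fixture_vocabularies",
    "generate",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("diabetes", "stenosis")

# resource names of the packaged mini vocabularies
_VOCABS = {"PATO": "pato.tsv", "HPO": "hpo.tsv", "MeSH": "mesh.tsv", "SNOMED-CT": "snomed.tsv"}


def _fixture_dir(name: str) -> Path:
    if name not in FIXTURE_NAMES:
        raise ConfigError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    return Path(str(resources.files("diseasechain.data.fixtures").joinpath(name)))


def fixture_diabetes() -> DiseaseOntology:
    """The diabetes family: diabetes plus three subclasses whose chains
    extend it upstream/downstream; "..." segments appear as single
    unknown nodes."""
    return load_ontology_tsv(_fixture_dir("diabetes"))


def fixture_stenosis_hierarchy() -> DiseaseOntology:
    """Three-level state hierarchy around stenosis with external
    mapping annotations; no diseases or links."""
    return load_ontology_tsv(_fixture_dir("stenosis"))


def fixture_interop_rules() -> RuleTable:
    """Rule table for blood pressure, arterial cross-sectional area,
    blood glucose and colon polyp count; cut-points are fixture
    parameters, not clinical reference values."""
    path = resources.files("diseasechain.data").joinpath("interop_rules.yaml")
    return RuleTable.from_yaml(str(path))


def fixture_vocabularies() -> dict[str, list[tuple[str, str]]]:
    """The four packaged mini vocabularies as (id, label) row lists."""
    base = resources.files("diseasechain.data.vocab")
    return {name: load_vocab_tsv(str(base.joinpath(filename))) for name, filename in _VOCABS.items()}


# ---------------------------------------------------------------------------
# generator


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the authoring emulation.

    ``declare_supers`` controls whether the planted hierarchy is also
    declared via subDiseaseOf (aggregation semantics: subclasses then
    carry only their new states). Leave it off to test hierarchy
    *inference* against the planted ground truth.
    """

    n_level1_states: int = 5
    n_level2_states: int = 15
    n_diseases: int = 10
    hierarchy_depth: int = 3
    chain_length_min: int = 3
    chain_length_max: int = 5
    p_refine: float = 0.0
    p_insert: float = 0.0
    p_probable: float = 0.0
    p_unknown: float = 0.0
    declare_supers: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_refine", "p_insert", "p_probable", "p_unknown"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        for name in ("n_level1_states", "n_level2_states", "n_diseases", "hierarchy_depth", "chain_length_min"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.chain_length_max < self.chain_length_min:
            raise ConfigError("chain_length_max < chain_length_min")
        if self.hierarchy_depth > self.n_diseases:
            raise ConfigError("hierarchy_depth exceeds the number of diseases available")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    isa_pairs: set[tuple[str, str]] = field(default_factory=set)  # (sub, super), direct
    isa_closure: set[tuple[str, str]] = field(default_factory=set)
    core_chains: dict[str, CausalGraph] = field(default_factory=dict)
    state_parents: dict[str, str] = field(default_factory=dict)


def generate(config: GeneratorConfig) -> tuple[DiseaseOntology, GroundTruth]:
    """Build a random ontology with planted ground truth.

    Deterministic under ``config.seed``. The emitted ontology always
    satisfies every structural invariant, and every planted (sub,
    super) disease pair satisfies chain inclusion by construction.
    """
    config.validate()
    rng = random.Random(config.seed)
    ontology = DiseaseOntology()
    truth = GroundTruth()
    counter = {"state": 0}

    level1 = [f"g{i:02d}" for i in range(config.n_level1_states)]
    for sid in level1:
        ontology.add_state(AbnormalState(id=sid, label=f"generic state {sid}", level=1))

    level2 = []
    for i in range(config.n_level2_states):
        sid = f"s{i:03d}"
        # parent is a level-1 root or an earlier level-2 state
        pool = level1 + level2
        parent = rng.choice(pool)
        ontology.add_state(
            AbnormalState(id=sid, label=f"object state {sid}", level=2, object=f"organ_{i % 7}",
                          parents=frozenset({parent}))
        )
        truth.state_parents[sid] = parent
        level2.append(sid)

    def fresh_state(parent: str | None = None, unknown: bool = False) -> str:
        counter["state"] += 1
        sid = f"x{counter['state']:04d}"
        if unknown:
            ontology.add_state(AbnormalState(id=sid, label="unknown", level=3, is_unknown=True))
        else:
            anchor = parent or rng.choice(level2)
            ontology.add_state(
                AbnormalState(id=sid, label=f"contextual state {sid}", level=3,
                              object=ontology.states[anchor].object or f"organ_{counter['state'] % 7}",
                              parents=frozenset({anchor}))
            )
            truth.state_parents[sid] = anchor
        return sid

    def refine_state(sid: str) -> str:
        """A fresh planted specialization (subStateOf child) of ``sid``."""
        counter["state"] += 1
        child = f"x{counter['state']:04d}"
        base = ontology.states[sid]
        ontology.add_state(
            AbnormalState(id=child, label=f"specialized {base.label}", level=3,
                          object=base.object or f"organ_{counter['state'] % 7}",
                          parents=frozenset({sid}))
        )
        truth.state_parents[child] = sid
        return child

    def new_chain_states(n: int) -> list[str]:
        return [
            fresh_state(unknown=rng.random() < config.p_unknown)
            for _ in range(n)
        ]

    linked: dict[tuple[str, str], bool] = {}

    def ensure_link(cause: str, effect: str) -> None:
        # one link per ordered pair; the probable flag is drawn once
        if (cause, effect) not in linked:
            probable = rng.random() < config.p_probable
            linked[(cause, effect)] = probable
            ontology.add_link(cause, effect, probable)

    def add_chain_links(path: list[str]) -> None:
        for cause, effect in zip(path, path[1:]):
            ensure_link(cause, effect)

    # disease forest ------------------------------------------------------
    depth_of: dict[str, int] = {}
    chains: dict[str, list[str]] = {}  # authored chain as a node path

    for i in range(config.n_diseases):
        did = f"d{i:03d}"
        eligible = sorted(d for d, depth in depth_of.items() if depth < config.hierarchy_depth - 1)
        parent = rng.choice(eligible) if eligible and rng.random() < 0.7 else None

        if parent is None:
            length = rng.randint(config.chain_length_min, config.chain_length_max)
            path = new_chain_states(length)
            own = list(path)
            depth_of[did] = 0
        else:
            depth_of[did] = depth_of[parent] + 1
            truth.isa_pairs.add((did, parent))
            path = list(chains[parent])
            own = []
            # refinement: specialize inherited states to planted children
            for idx, sid in enumerate(path):
                if not ontology.states[sid].is_unknown and rng.random() < config.p_refine:
                    child = refine_state(sid)
                    path[idx] = child
                    own.append(child)
            # node insertion: split an edge with a new intermediate
            idx = 0
            while idx < len(path) - 1:
                if rng.random() < config.p_insert:
                    mid = fresh_state(unknown=rng.random() < config.p_unknown)
                    path.insert(idx + 1, mid)
                    own.append(mid)
                    idx += 1
                idx += 1
            # mandatory extension keeps sibling chains mutually exclusive
            extension = new_chain_states(rng.randint(1, 2))
            if rng.random() < 0.5:
                path = extension + path
            else:
                path = path + extension
            own.extend(extension)

        add_chain_links(path)
        chains[did] = path
        depth_of.setdefault(did, 0)

        if config.declare_supers and parent is not None:
            listed = own
            supers = frozenset({parent})
        else:
            listed = path
            supers = frozenset()
        split = max(1, round(len(listed) * 0.7)) if listed else 0
        ontology.add_disease(
            Disease(
                id=did,
                label=f"disease {did}",
                area=f"division_{i % 3}",
                supers=supers,
                core_states=tuple(listed[:split]),
                derived_states=tuple(listed[split:]),
            )
        )

    # planted closure and core chains
    closure = set(truth.isa_pairs)
    changed = True
    while changed:
        changed = False
        for (a, b) in list(closure):
            for (c, d) in list(closure):
                if b == c and (a, d) not in closure:
                    closure.add((a, d))
                    changed = True
    truth.isa_closure = closure

    for did, path in chains.items():
        states = set(path)
        links = {l for l in ontology.links if l.cause in states and l.effect in states}
        truth.core_chains[did] = CausalGraph(states=states, links=links)

    return ontology, truth
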