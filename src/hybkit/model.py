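"""In-memory mechanistic model: compartments, species, parameters,
reactions, rate rules and assignment rules, sharing one flat identifier
namespace.

Conventions (documented once, applied everywhere):

* concentrations — not amounts — are the canonical species quantity;
* kinetic-law local parameters are hoisted to global parameters on read
  (``<reactionId>__<localId>``) so the namespace stays flat;
* stoichiometries are positive; direction is the reactant/product role.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .expressions import Expr, IDENTIFIER_RE
from .report import ValidationReport

#: parameter provenance tags ("ml-node" marks generated ANN node-value symbols)
PARAM_ORIGINS = ("mechanistic", "ml-weight", "ml-bias", "ml-scaling", "ml-node")


@dataclass
class Compartment:
    id: str
    size: float = 1.0
    name: str = ""
    constant: bool = True


@dataclass
class Species:
    id: str
    compartment: str
    initial_concentration: float = 0.0
    name: str = ""
    boundary: bool = False
    constant: bool = False


@dataclass
class Parameter:
    id: str
    value: float = 0.0
    constant: bool = True
    origin: str = "mechanistic"
    name: str = ""


@dataclass
class SpeciesRef:
    species: str
    stoichiometry: float = 1.0


@dataclass
class Reaction:
    id: str
    reactants: list[SpeciesRef] = field(default_factory=list)
    products: list[SpeciesRef] = field(default_factory=list)
    kinetic_law: Optional[Expr] = None
    reversible: bool = False
    name: str = ""


@dataclass
class RateRule:
    variable: str
    expression: Expr


@dataclass
class AssignmentRule:
    variable: str
    expression: Expr


@dataclass
class KineticModel:
    """A mechanistic (or compiled hybrid) kinetic model.

    Every entity lives in one global id namespace; cross-references are by
    id.  ``check_consistency`` verifies all referential invariants and is
    the gate every writer applies before serializing.
    """

    id: str = "model"
    name: str = ""
    notes: str = ""
    compartments: list[Compartment] = field(default_factory=list)
    species: list[Species] = field(default_factory=list)
    parameters: list[Parameter] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    rate_rules: list[RateRule] = field(default_factory=list)
    assignment_rules: list[AssignmentRule] = field(default_factory=list)

    # -- lookup helpers -----------------------------------------------------
    def compartment_ids(self) -> list[str]:
        return [c.id for c in self.compartments]

    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def parameter_ids(self) -> list[str]:
        return [p.id for p in self.parameters]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def all_ids(self) -> list[str]:
        return (self.compartment_ids() + self.species_ids()
                + self.parameter_ids() + self.reaction_ids())

    def get_compartment(self, cid: str) -> Compartment:
        for c in self.compartments:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def get_species(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def get_parameter(self, pid: str) -> Parameter:
        for p in self.parameters:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def assignment_targets(self) -> set[str]:
        return {a.variable for a in self.assignment_rules}

    def rate_rule_targets(self) -> set[str]:
        return {r.variable for r in self.rate_rules}

    def copy(self) -> "KineticModel":
        """Deep-enough copy: entity objects are fresh, Expr trees shared
        (they are immutable)."""
        return KineticModel(
            id=self.id, name=self.name, notes=self.notes,
            compartments=[replace(c) for c in self.compartments],
            species=[replace(s) for s in self.species],
            parameters=[replace(p) for p in self.parameters],
            reactions=[Reaction(r.id, [replace(x) for x in r.reactants],
                                [replace(x) for x in r.products],
                                r.kinetic_law, r.reversible, r.name)
                       for r in self.reactions],
            rate_rules=[RateRule(r.variable, r.expression) for r in self.rate_rules],
            assignment_rules=[AssignmentRule(a.variable, a.expression)
                              for a in self.assignment_rules],
        )


class ModelError(ValueError):
    pass


class CyclicAssignmentError(ModelError):
    def __init__(self, cycle: list[str]):
        super().__init__("cyclic assignment-rule dependency: " + " -> ".join(cycle + cycle[:1]))
        self.cycle = cycle


def _find_assignment_cycle(m: KineticModel) -> Optional[list[str]]:
    targets = m.assignment_targets()
    deps = {a.variable: a.expression.symbols() & targets for a in m.assignment_rules}
    WHITE, GREY, BLACK = 0, 1, 2
    color = {v: WHITE for v in deps}
    stack: list[str] = []

    def visit(v: str) -> Optional[list[str]]:
        color[v] = GREY
        stack.append(v)
        for w in sorted(deps[v]):
            if color[w] == GREY:
                return stack[stack.index(w):]
            if color[w] == WHITE:
                cyc = visit(w)
                if cyc is not None:
                    return cyc
        color[v] = BLACK
        stack.pop()
        return None

    for v in sorted(deps):
        if color[v] == WHITE:
            cyc = visit(v)
            if cyc is not None:
                return cyc
    return None


def check_consistency(m: KineticModel) -> ValidationReport:
    """Semantic validation: duplicate ids, dangling references, negative
    sizes/concentrations, doubly-determined variables and assignment
    cycles.  Problems are report entries, never exceptions; an empty
    report means the model is consistent.
    """
    rep = ValidationReport()
    seen: set[str] = set()
    for kind, ident in [("compartment", c.id) for c in m.compartments] + \
                       [("species", s.id) for s in m.species] + \
                       [("parameter", p.id) for p in m.parameters] + \
                       [("reaction", r.id) for r in m.reactions]:
        loc = f"{kind}:{ident}"
        if not IDENTIFIER_RE.match(ident):
            rep.error("BAD_IDENTIFIER", loc, f"invalid identifier {ident!r}")
        if ident in seen:
            rep.error("DUPLICATE_ID", loc, f"id {ident!r} declared more than once")
        seen.add(ident)

    for c in m.compartments:
        if not c.size > 0:
            rep.error("NEGATIVE_SIZE", f"compartment:{c.id}",
                      f"compartment size must be > 0, got {c.size}")

    known = set(m.all_ids())
    for s in m.species:
        if s.compartment not in {c.id for c in m.compartments}:
            rep.error("DANGLING_REF", f"species:{s.id}",
                      f"unknown compartment {s.compartment!r}")
        if s.initial_concentration < 0:
            rep.error("NEGATIVE_CONCENTRATION", f"species:{s.id}",
                      f"initial concentration must be >= 0, got {s.initial_concentration}")

    for p in m.parameters:
        if p.origin not in PARAM_ORIGINS:
            rep.error("BAD_ORIGIN", f"parameter:{p.id}",
                      f"unknown parameter origin {p.origin!r}")

    species_ids = set(m.species_ids())
    for r in m.reactions:
        loc = f"reaction:{r.id}"
        for ref in r.reactants + r.products:
            if ref.species not in species_ids:
                rep.error("DANGLING_REF", loc, f"unknown species {ref.species!r}")
            if not ref.stoichiometry > 0:
                rep.error("BAD_STOICHIOMETRY", loc,
                          f"stoichiometry must be > 0, got {ref.stoichiometry}")
        if r.kinetic_law is None:
            rep.error("MISSING_KINETIC_LAW", loc, "reaction has no kinetic law")
        else:
            for sym in sorted(r.kinetic_law.symbols() - known):
                rep.error("DANGLING_REF", loc, f"kinetic law references undefined symbol {sym!r}")

    assignable = species_ids | set(m.parameter_ids())
    determined: dict[str, str] = {}
    for rr in m.rate_rules:
        loc = f"rate_rule:{rr.variable}"
        if rr.variable not in assignable:
            rep.error("DANGLING_REF", loc, f"rate rule targets unknown variable {rr.variable!r}")
        if rr.variable in determined:
            rep.error("RULE_CONFLICT", loc,
                      f"variable {rr.variable!r} already determined by {determined[rr.variable]}")
        determined[rr.variable] = "rate rule"
        for sym in sorted(rr.expression.symbols() - known):
            rep.error("DANGLING_REF", loc, f"expression references undefined symbol {sym!r}")

    for ar in m.assignment_rules:
        loc = f"assignment_rule:{ar.variable}"
        if ar.variable not in assignable:
            rep.error("DANGLING_REF", loc,
                      f"assignment rule targets unknown variable {ar.variable!r}")
        if ar.variable in determined:
            rep.error("RULE_CONFLICT", loc,
                      f"variable {ar.variable!r} already determined by {determined[ar.variable]}")
        determined[ar.variable] = "assignment rule"
        for sym in sorted(ar.expression.symbols() - known):
            rep.error("DANGLING_REF", loc, f"expression references undefined symbol {sym!r}")

    # species produced/consumed by reactions must not also carry a rule
    reacting = {ref.species for r in m.reactions for ref in r.reactants + r.products}
    for rr in m.rate_rules:
        if rr.variable in reacting and not _is_boundary(m, rr.variable):
            rep.error("RULE_CONFLICT", f"rate_rule:{rr.variable}",
                      f"species {rr.variable!r} is determined both by reactions and a rate rule")
    for ar in m.assignment_rules:
        if ar.variable in reacting and not _is_boundary(m, ar.variable):
            rep.error("RULE_CONFLICT", f"assignment_rule:{ar.variable}",
                      f"species {ar.variable!r} is determined both by reactions and an assignment rule")

    cycle = _find_assignment_cycle(m)
    if cycle is not None:
        rep.error("ASSIGNMENT_CYCLE", f"assignment_rule:{cycle[0]}",
                  "cyclic dependency: " + " -> ".join(cycle + cycle[:1]))
    return rep.sorted()


def _is_boundary(m: KineticModel, sid: str) -> bool:
    try:
        return m.get_species(sid).boundary
    except KeyError:
        return False


def topo_order_assignments(m: KineticModel) -> list[AssignmentRule]:
    """Assignment rules ordered so every rule reads only variables assigned
    earlier (Kahn's algorithm; ties broken by declaration order, so already
    sorted input is returned unchanged).  Raises
    :class:`CyclicAssignmentError` naming one cycle if the dependency graph
    is cyclic.
    """
    rules = list(m.assignment_rules)
    targets = {a.variable for a in rules}
    index = {a.variable: i for i, a in enumerate(rules)}
    deps = {a.variable: a.expression.symbols() & targets for a in rules}
    indegree = {v: len(d) for v, d in deps.items()}
    dependents: dict[str, list[str]] = {v: [] for v in deps}
    for v, d in deps.items():
        for w in d:
            dependents[w].append(v)

    ready = sorted((v for v, k in indegree.items() if k == 0), key=index.__getitem__)
    order: list[str] = []
    while ready:
        v = ready.pop(0)
        order.append(v)
        changed = False
        for w in dependents[v]:
            indegree[w] -= 1
            if indegree[w] == 0:
                ready.append(w)
                changed = True
        if changed:
            ready.sort(key=index.__getitem__)
    if len(order) != len(rules):
        cycle = _find_assignment_cycle(m)
        raise CyclicAssignmentError(cycle or sorted(set(deps) - set(order)))
    by_var = {a.variable: a for a in rules}
    return [by_var[v] for v in order]
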