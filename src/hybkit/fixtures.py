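"""Deterministic generators for test and demonstration inputs.

Everything here is seed-reproducible and self-contained: small
mass-action / Michaelis-Menten toy models with known closed forms or
conserved quantities, random feedforward networks, a least-squares
rate-mimicking network (the hybrid-vs-mechanistic comparison input), and
a corpus of deliberately malformed HMOD/SBML files that each violate
exactly one validation rule.
"""

from __future__ import annotations

import string
from typing import Optional

import numpy as np

from .ann import AnnInput, AnnLayer, AnnOutput, AnnSpec
from .expressions import Expr, evaluate, parse_infix
from .model import (AssignmentRule, Compartment, KineticModel, Parameter,
                    RateRule, Reaction, Species, SpeciesRef)
from .simulate import run, state_variables, evaluate_assignments, _constant_env

TOY_KINDS = ("chain", "reversible-pair", "michaelis-menten-pathway", "stiff-pair")


def make_toy_model(kind: str, seed: int = 0, n: int = 2) -> KineticModel:
    """Build a consistent toy model (compartment size 1.0).

    * ``chain``: linear pathway A -> B -> ... -> 0, mass action, rate
      constants drawn U[0.1, 2].
    * ``reversible-pair``: A <-> B with law ``kf*A - kr*B``; conserves
      A + B.  Includes a rate-ruled "clock" parameter (dc/dt = 1) so the
      rate-rule path is exercised by round trips.
    * ``michaelis-menten-pathway``: S -> P (Michaelis-Menten) -> 0 (mass
      action), plus an assignment-rule observable ``total = S + P``.
    * ``stiff-pair``: A -> B -> C with rate constants 1000 and 1 — two
      well-separated timescales.
    """
    rng = np.random.default_rng(seed)
    if kind == "chain":
        if not 2 <= n <= 26:
            raise ValueError("chain length must be in [2, 26]")
        names = list(string.ascii_uppercase[:n])
        m = KineticModel(id=f"chain{n}", name=f"Linear chain of {n} species")
        m.compartments.append(Compartment(id="cell", size=1.0))
        for i, sp in enumerate(names):
            m.species.append(Species(id=sp, compartment="cell",
                                     initial_concentration=1.0 if i == 0 else 0.0))
        for i in range(n):
            k = float(rng.uniform(0.1, 2.0))
            m.parameters.append(Parameter(id=f"k{i + 1}", value=k))
            products = [SpeciesRef(names[i + 1])] if i + 1 < n else []
            m.reactions.append(Reaction(
                id=f"r{i + 1}", reactants=[SpeciesRef(names[i])], products=products,
                kinetic_law=parse_infix(f"k{i + 1}*{names[i]}")))
        return m

    if kind == "reversible-pair":
        m = KineticModel(id="revpair", name="Reversible isomerization")
        m.compartments.append(Compartment(id="cell", size=1.0))
        m.species.append(Species(id="A", compartment="cell", initial_concentration=1.5))
        m.species.append(Species(id="B", compartment="cell", initial_concentration=0.5))
        m.parameters.append(Parameter(id="kf", value=float(rng.uniform(0.1, 2.0))))
        m.parameters.append(Parameter(id="kr", value=float(rng.uniform(0.1, 2.0))))
        m.parameters.append(Parameter(id="clock", value=0.0, constant=False))
        m.reactions.append(Reaction(
            id="r1", reactants=[SpeciesRef("A")], products=[SpeciesRef("B")],
            reversible=True, kinetic_law=parse_infix("kf*A-kr*B")))
        m.rate_rules.append(RateRule(variable="clock", expression=Expr.num(1.0)))
        return m

    if kind == "michaelis-menten-pathway":
        m = KineticModel(id="mmpath", name="Michaelis-Menten two-step pathway")
        m.compartments.append(Compartment(id="cell", size=1.0))
        m.species.append(Species(id="S", compartment="cell", initial_concentration=2.0))
        m.species.append(Species(id="P", compartment="cell", initial_concentration=0.0))
        m.parameters.append(Parameter(id="Vmax", value=float(rng.uniform(0.5, 2.0))))
        m.parameters.append(Parameter(id="Km", value=float(rng.uniform(0.2, 1.0))))
        m.parameters.append(Parameter(id="k2", value=float(rng.uniform(0.1, 1.0))))
        m.parameters.append(Parameter(id="total", value=0.0, constant=False))
        m.reactions.append(Reaction(
            id="uptake", reactants=[SpeciesRef("S")], products=[SpeciesRef("P")],
            kinetic_law=parse_infix("Vmax*S/(Km+S)")))
        m.reactions.append(Reaction(
            id="drain", reactants=[SpeciesRef("P")], products=[],
            kinetic_law=parse_infix("k2*P")))
        m.assignment_rules.append(AssignmentRule(variable="total",
                                                 expression=parse_infix("S+P")))
        return m

    if kind == "stiff-pair":
        m = KineticModel(id="stiffpair", name="Two-timescale chain")
        m.compartments.append(Compartment(id="cell", size=1.0))
        for sp, init in (("A", 1.0), ("B", 0.0), ("C", 0.0)):
            m.species.append(Species(id=sp, compartment="cell", initial_concentration=init))
        m.parameters.append(Parameter(id="kfast", value=1000.0))
        m.parameters.append(Parameter(id="kslow", value=1.0))
        m.reactions.append(Reaction(id="fast", reactants=[SpeciesRef("A")],
                                    products=[SpeciesRef("B")],
                                    kinetic_law=parse_infix("kfast*A")))
        m.reactions.append(Reaction(id="slow", reactants=[SpeciesRef("B")],
                                    products=[SpeciesRef("C")],
                                    kinetic_law=parse_infix("kslow*B")))
        return m

    raise ValueError(f"unknown toy-model kind {kind!r} (known: {', '.join(TOY_KINDS)})")


def make_random_ann(shape: list[int], seed: int = 0,
                    input_ids: Optional[list[str]] = None,
                    targets: Optional[list[tuple[str, str]]] = None) -> AnnSpec:
    """Random feedforward network: weights and biases U(-1, 1), tanh
    hidden layers, linear output, inputs scaled on [0, 1] by default."""
    if len(shape) < 3:
        raise ValueError("shape needs at least [inputs, hidden, outputs]")
    rng = np.random.default_rng(seed)
    n_in = shape[0]
    if input_ids is None:
        input_ids = [f"x{i + 1}" for i in range(n_in)]
    if len(input_ids) != n_in:
        raise ValueError("input_ids length must match shape[0]")
    inputs = [AnnInput(xid, 0.0, 1.0) for xid in input_ids]
    layers = []
    for li in range(1, len(shape)):
        w = rng.uniform(-1.0, 1.0, size=(shape[li], shape[li - 1]))
        b = rng.uniform(-1.0, 1.0, size=shape[li])
        act = "linear" if li == len(shape) - 1 else "tanh"
        layers.append(AnnLayer(w, b, act))
    if targets is None:
        targets = [("reaction-rate", f"r{k + 1}") for k in range(shape[-1])]
    outputs = [AnnOutput(kind, tid) for kind, tid in targets]
    a = AnnSpec(inputs, layers, outputs)
    a.validate()
    return a


def make_rate_mimicking_ann(m: KineticModel, reaction_id: str, n_hidden: int = 20,
                            seed: int = 0, t_end: float = 10.0,
                            n_samples: int = 400) -> AnnSpec:
    """Fit a 1-hidden-layer network to reproduce a reaction's rate law.

    The mechanistic model is simulated once; the network's inputs are the
    state variables appearing in the law, scaled by the min-max box of
    that trajectory (slightly widened).  Hidden weights/biases are random
    tanh features; the linear output layer is the least-squares fit over
    trajectory points plus uniform samples in the box
    (extreme-learning-machine style — no iterative training).  The
    achieved max-abs fit error over the sample set is recorded in
    ``metadata["fit_error"]``.
    """
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    rxn = m.get_reaction(reaction_id)
    if rxn.kinetic_law is None:
        raise ValueError(f"reaction {reaction_id!r} has no kinetic law")
    rng = np.random.default_rng(seed)

    traj = run(m, t_end=t_end, n_points=200)
    states = set(state_variables(m))
    input_ids = sorted(rxn.kinetic_law.symbols() & states)
    if not input_ids:
        raise ValueError(f"kinetic law of {reaction_id!r} involves no state variables")

    lo = np.array([traj.column(sid).min() for sid in input_ids])
    hi = np.array([traj.column(sid).max() for sid in input_ids])
    span = hi - lo
    pad = np.where(span > 0, 0.05 * span, 0.5)
    lo, hi = lo - pad, hi + pad

    # sample set: trajectory points + uniform draws in the box
    traj_pts = np.column_stack([traj.column(sid) for sid in input_ids])
    extra = rng.uniform(lo, hi, size=(max(n_samples - traj_pts.shape[0], 0), len(input_ids)))
    X = np.vstack([traj_pts, extra])

    base_env = _constant_env(m)
    for sid in states - set(input_ids):
        try:
            base_env[sid] = m.get_species(sid).initial_concentration
        except KeyError:
            base_env[sid] = m.get_parameter(sid).value
    y = np.empty(X.shape[0])
    for i, row in enumerate(X):
        env = dict(base_env)
        env.update(zip(input_ids, row))
        env = evaluate_assignments(m, env)
        y[i] = evaluate(rxn.kinetic_law, env)

    Xs = (X - lo) / (hi - lo)  # the same scaling the compiled model applies
    W1 = rng.uniform(-3.0, 3.0, size=(n_hidden, len(input_ids)))
    b1 = rng.uniform(-3.0, 3.0, size=n_hidden)
    H = np.tanh(Xs @ W1.T + b1)
    design = np.column_stack([H, np.ones(H.shape[0])])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    W2, b2 = coef[:-1].reshape(1, -1), coef[-1:]

    fit_error = float(np.max(np.abs(design @ coef - y)))
    a = AnnSpec(
        inputs=[AnnInput(sid, float(l), float(h)) for sid, l, h in zip(input_ids, lo, hi)],
        layers=[AnnLayer(W1, b1, "tanh"), AnnLayer(W2, b2, "linear")],
        outputs=[AnnOutput("reaction-rate", reaction_id)],
        metadata={"fit_error": fit_error},
    )
    a.validate()
    return a


# ---------------------------------------------------------------------------
# malformed corpus: one file per validator error code
# ---------------------------------------------------------------------------

_HMOD_OK_HEADER = '[HMOD]\nformat : version="HMOD/1"\nmodel : id=bad\n'
_EMPTY_BLOCKS = ("[COMPARTMENTS]\n[SPECIES]\n[PARAMETERS]\n[REACTIONS]\n"
                 "[RATE_RULES]\n[ASSIGNMENT_RULES]\n")


def _hmod(body: str) -> str:
    return _HMOD_OK_HEADER + body


_MALFORMED_HMOD: list[tuple[str, str, str]] = [
    ("non_ascii.hmod", "NON_ASCII",
     _hmod("[COMPARTMENTS]\ncell : size=1, constant=true  # café\n"
           "[SPECIES]\n[PARAMETERS]\n[REACTIONS]\n[RATE_RULES]\n[ASSIGNMENT_RULES]\n")),
    ("bad_header.hmod", "BAD_HEADER", _EMPTY_BLOCKS),
    ("unknown_version.hmod", "UNKNOWN_VERSION",
     '[HMOD]\nformat : version="HMOD/9"\nmodel : id=bad\n' + _EMPTY_BLOCKS),
    ("unknown_block.hmod", "UNKNOWN_BLOCK", _hmod(_EMPTY_BLOCKS + "[WEIRD]\n")),
    ("order_violation.hmod", "ORDER_VIOLATION",
     _hmod("[SPECIES]\n[COMPARTMENTS]\n[PARAMETERS]\n[REACTIONS]\n"
           "[RATE_RULES]\n[ASSIGNMENT_RULES]\n")),
    ("bad_record.hmod", "BAD_RECORD",
     _hmod("[COMPARTMENTS]\nthis line has no colon separator\n[SPECIES]\n[PARAMETERS]\n"
           "[REACTIONS]\n[RATE_RULES]\n[ASSIGNMENT_RULES]\n")),
    ("bad_identifier.hmod", "BAD_IDENTIFIER",
     _hmod("[COMPARTMENTS]\n2cell : size=1, constant=true\n[SPECIES]\n[PARAMETERS]\n"
           "[REACTIONS]\n[RATE_RULES]\n[ASSIGNMENT_RULES]\n")),
    ("bad_number.hmod", "BAD_NUMBER",
     _hmod("[COMPARTMENTS]\ncell : size=big, constant=true\n[SPECIES]\n[PARAMETERS]\n"
           "[REACTIONS]\n[RATE_RULES]\n[ASSIGNMENT_RULES]\n")),
    ("bad_boolean.hmod", "BAD_BOOLEAN",
     _hmod("[COMPARTMENTS]\ncell : size=1, constant=yes\n[SPECIES]\n[PARAMETERS]\n"
           "[REACTIONS]\n[RATE_RULES]\n[ASSIGNMENT_RULES]\n")),
    ("bad_expression.hmod", "BAD_EXPRESSION",
     _hmod("[COMPARTMENTS]\ncell : size=1, constant=true\n"
           "[SPECIES]\nA : compartment=cell, init=1, boundary=false, constant=false\n"
           "[PARAMETERS]\nk1 : value=1, constant=true, origin=mechanistic\n"
           "[REACTIONS]\nr1 : reactants=\"A\", products=\"\", reversible=false, law=\"k1*(\"\n"
           "[RATE_RULES]\n[ASSIGNMENT_RULES]\n")),
    ("missing_field.hmod", "MISSING_FIELD",
     _hmod("[COMPARTMENTS]\ncell : size=1, constant=true\n"
           "[SPECIES]\nA : init=1, boundary=false, constant=false\n"
           "[PARAMETERS]\n[REACTIONS]\n[RATE_RULES]\n[ASSIGNMENT_RULES]\n")),
    ("unknown_field.hmod", "UNKNOWN_FIELD",
     _hmod("[COMPARTMENTS]\ncell : size=1, constant=true, colour=blue\n[SPECIES]\n"
           "[PARAMETERS]\n[REACTIONS]\n[RATE_RULES]\n[ASSIGNMENT_RULES]\n")),
    ("dangling_ref.hmod", "DANGLING_REF",
     _hmod("[COMPARTMENTS]\ncell : size=1, constant=true\n"
           "[SPECIES]\nA : compartment=vesicle, init=1, boundary=false, constant=false\n"
           "[PARAMETERS]\n[REACTIONS]\n[RATE_RULES]\n[ASSIGNMENT_RULES]\n")),
    ("duplicate_id.hmod", "DUPLICATE_ID",
     _hmod("[COMPARTMENTS]\ncell : size=1, constant=true\ncell : size=2, constant=true\n"
           "[SPECIES]\n[PARAMETERS]\n[REACTIONS]\n[RATE_RULES]\n[ASSIGNMENT_RULES]\n")),
    ("assignment_cycle.hmod", "ASSIGNMENT_CYCLE",
     _hmod("[COMPARTMENTS]\ncell : size=1, constant=true\n[SPECIES]\n"
           "[PARAMETERS]\na : value=0, constant=false, origin=mechanistic\n"
           "b : value=0, constant=false, origin=mechanistic\n"
           "[REACTIONS]\n[RATE_RULES]\n"
           "[ASSIGNMENT_RULES]\na : expr=\"b+1\"\nb : expr=\"a+1\"\n")),
    ("rule_conflict.hmod", "RULE_CONFLICT",
     _hmod("[COMPARTMENTS]\ncell : size=1, constant=true\n[SPECIES]\n"
           "[PARAMETERS]\np : value=0, constant=false, origin=mechanistic\n"
           "[REACTIONS]\n[RATE_RULES]\np : expr=\"1\"\n"
           "[ASSIGNMENT_RULES]\np : expr=\"2\"\n")),
    ("ann_shape_mismatch.hmod", "ANN_SHAPE_MISMATCH",
     _hmod("[COMPARTMENTS]\ncell : size=1, constant=true\n"
           "[SPECIES]\nA : compartment=cell, init=1, boundary=false, constant=false\n"
           "[PARAMETERS]\nk1 : value=1, constant=true, origin=mechanistic\n"
           "[REACTIONS]\nr1 : reactants=\"A\", products=\"\", reversible=false, law=\"k1*A\"\n"
           "[RATE_RULES]\n[ASSIGNMENT_RULES]\n"
           "[ML]\ninput_1 : id=A, min=0, max=2\n"
           "layer_1 : size=3, activation=tanh\n"
           "w_1_1 : values=\"0.1 0.2\"\nw_1_2 : values=\"0.3\"\nw_1_3 : values=\"0.5\"\n"
           "b_1 : values=\"0 0 0\"\n"
           "layer_2 : size=1, activation=linear\n"
           "w_2_1 : values=\"1 1 1\"\nb_2 : values=\"0\"\n"
           "output_1 : target=reaction, id=r1\n")),
    ("unsupported_activation.hmod", "UNSUPPORTED_ACTIVATION",
     _hmod("[COMPARTMENTS]\ncell : size=1, constant=true\n"
           "[SPECIES]\nA : compartment=cell, init=1, boundary=false, constant=false\n"
           "[PARAMETERS]\nk1 : value=1, constant=true, origin=mechanistic\n"
           "[REACTIONS]\nr1 : reactants=\"A\", products=\"\", reversible=false, law=\"k1*A\"\n"
           "[RATE_RULES]\n[ASSIGNMENT_RULES]\n"
           "[ML]\ninput_1 : id=A, min=0, max=2\n"
           "layer_1 : size=1, activation=relu\n"
           "w_1_1 : values=\"0.1\"\nb_1 : values=\"0\"\n"
           "layer_2 : size=1, activation=linear\n"
           "w_2_1 : values=\"1\"\nb_2 : values=\"0\"\n"
           "output_1 : target=reaction, id=r1\n")),
]

_SBML_PRELUDE = ('<?xml version="1.0" encoding="UTF-8"?>\n'
                 '<sbml xmlns="http://www.sbml.org/sbml/level3/version2/core" '
                 'level="3" version="2">\n')

_MALFORMED_SBML: list[tuple[str, str, str]] = [
    ("not_xml.xml", "NOT_XML", "this is not xml at all <<<"),
    ("not_sbml.xml", "NOT_SBML",
     '<?xml version="1.0"?>\n<notes xmlns="http://example.org/ns"><model/></notes>\n'),
    ("missing_attribute.xml", "MISSING_ATTRIBUTE",
     _SBML_PRELUDE + '<model id="m">\n<listOfCompartments>'
     '<compartment size="1" constant="true"/></listOfCompartments>\n'
     "</model>\n</sbml>\n"),
    ("duplicate_id.xml", "DUPLICATE_ID",
     _SBML_PRELUDE + '<model id="m">\n'
     '<listOfCompartments><compartment id="cell" size="1" constant="true"/>'
     "</listOfCompartments>\n"
     '<listOfSpecies>'
     '<species id="A" compartment="cell" initialConcentration="1" '
     'hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>'
     '<species id="A" compartment="cell" initialConcentration="2" '
     'hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>'
     "</listOfSpecies>\n</model>\n</sbml>\n"),
    ("dangling_ref.xml", "DANGLING_REF",
     _SBML_PRELUDE + '<model id="m">\n'
     '<listOfCompartments><compartment id="cell" size="1" constant="true"/>'
     "</listOfCompartments>\n"
     '<listOfSpecies>'
     '<species id="A" compartment="cell" initialConcentration="1" '
     'hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>'
     "</listOfSpecies>\n"
     '<listOfReactions><reaction id="r1" reversible="false">'
     "<listOfReactants>"
     '<speciesReference species="A" stoichiometry="1" constant="true"/>'
     "</listOfReactants>"
     "<kineticLaw><math xmlns=\"http://www.w3.org/1998/Math/MathML\">"
     "<apply><times/><ci>kmissing</ci><ci>A</ci></apply></math></kineticLaw>"
     "</reaction></listOfReactions>\n</model>\n</sbml>\n"),
    ("bad_math.xml", "BAD_MATH",
     _SBML_PRELUDE + '<model id="m">\n'
     '<listOfParameters><parameter id="p" value="0" constant="false"/></listOfParameters>\n'
     '<listOfRules><assignmentRule variable="p">'
     "<math xmlns=\"http://www.w3.org/1998/Math/MathML\">"
     "<apply><factorial/><cn>3</cn></apply></math></assignmentRule></listOfRules>\n"
     "</model>\n</sbml>\n"),
]


def make_malformed_corpus() -> list[tuple[str, str, str]]:
    """(filename, expected error code, file content) for every validator
    error code — >= 10 HMOD files and >= 4 SBML files, each violating
    exactly one rule.  Static text, byte-stable across runs."""
    return list(_MALFORMED_HMOD) + list(_MALFORMED_SBML)
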