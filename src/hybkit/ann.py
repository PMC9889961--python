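"""Feedforward neural networks and their compilation into kinetic-model
constructs.

A hybrid semiparametric model couples a mechanistic reaction network with
a data-driven component.  Here that component is a feedforward ANN
(:class:`AnnSpec`): min-max-scaled model quantities enter the input layer,
each layer computes ``activation(W.prev + b)``, and each output drives a
reaction rate (or a parameter) of the mechanistic model.

:func:`hybridize` compiles the network into *standard* model constructs —
one constant parameter per weight and bias, one assignment rule per scaled
input / hidden node / output node — so the hybrid model is expressible in
plain SBML and simulatable by any SBML-aware tool.  :func:`dehybridize`
inverts the compilation, recovering the weights bit-exactly.

Weights travel in a portable ASCII container (same line grammar as HMOD's
``[ML]`` block); training happens elsewhere — networks arrive trained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._linefmt import LineFormatError, Record, format_record, parse_record, strip_comment
from .expressions import Expr, format_number, parse_infix, write_infix, ExprError
from .model import (AssignmentRule, KineticModel, Parameter, check_consistency)
from .report import ValidationReport

ACTIVATIONS = ("tanh", "linear")
ANNW_VERSION = "ANNW/1"


class AnnError(ValueError):
    """ANN container/compilation problem; ``code`` is a stable identifier."""

    def __init__(self, message: str, code: str = "ANN_ERROR"):
        super().__init__(message)
        self.code = code


@dataclass
class AnnInput:
    id: str
    scale_min: float
    scale_max: float


@dataclass
class AnnLayer:
    weights: np.ndarray  # rows = this layer size, cols = previous layer size
    biases: np.ndarray
    activation: str = "tanh"


@dataclass
class AnnOutput:
    kind: str  # "reaction-rate" | "parameter"
    target: str
    factor: Optional[Expr] = None  # retained multiplicative mechanistic factor


@dataclass
class AnnSpec:
    inputs: list[AnnInput]
    layers: list[AnnLayer]
    outputs: list[AnnOutput]
    metadata: dict = field(default_factory=dict)

    @property
    def n_inputs(self) -> int:
        return len(self.inputs)

    @property
    def shape(self) -> list[int]:
        return [self.n_inputs] + [layer.weights.shape[0] for layer in self.layers]

    def validate(self) -> None:
        """Check dimension chaining and the structural invariants."""
        if not self.layers:
            raise AnnError("network needs at least one layer (>= 1 hidden)",
                           "ANN_SHAPE_MISMATCH")
        if len(self.layers) < 2:
            raise AnnError("network needs at least one hidden layer before the output layer",
                           "ANN_SHAPE_MISMATCH")
        prev = self.n_inputs
        if prev < 1:
            raise AnnError("network needs at least one input", "ANN_SHAPE_MISMATCH")
        for idx, layer in enumerate(self.layers, start=1):
            w = np.asarray(layer.weights, dtype=float)
            b = np.asarray(layer.biases, dtype=float)
            if w.ndim != 2:
                raise AnnError(f"layer {idx}: weight matrix must be 2-D", "ANN_SHAPE_MISMATCH")
            rows, cols = w.shape
            if cols != prev:
                raise AnnError(
                    f"layer {idx}: weight matrix has {cols} columns, previous layer size is {prev}",
                    "ANN_SHAPE_MISMATCH")
            if b.shape != (rows,):
                raise AnnError(
                    f"layer {idx}: bias length {b.shape} does not match layer size {rows}",
                    "ANN_SHAPE_MISMATCH")
            if layer.activation not in ACTIVATIONS:
                raise AnnError(f"layer {idx}: unknown activation {layer.activation!r}",
                               "UNSUPPORTED_ACTIVATION")
            prev = rows
        if len(self.outputs) != prev:
            raise AnnError(
                f"{len(self.outputs)} output mappings declared but last layer has {prev} nodes",
                "ANN_SHAPE_MISMATCH")
        for inp in self.inputs:
            if not inp.scale_max > inp.scale_min:
                raise AnnError(f"input {inp.id!r}: scale_max must exceed scale_min",
                               "BAD_SCALING")
        for out in self.outputs:
            if out.kind not in ("reaction-rate", "parameter"):
                raise AnnError(f"unknown output target kind {out.kind!r}", "BAD_TARGET")


def ann_forward(a: AnnSpec, x: Sequence[float]) -> np.ndarray:
    """Forward pass in model units: inputs are min-max scaled to [0, 1]
    before the first layer; returns the last layer's values."""
    x = np.asarray(x, dtype=float)
    if x.shape != (a.n_inputs,):
        raise AnnError(f"input vector has shape {x.shape}, expected ({a.n_inputs},)",
                       "ANN_SHAPE_MISMATCH")
    lo = np.array([i.scale_min for i in a.inputs])
    hi = np.array([i.scale_max for i in a.inputs])
    h = (x - lo) / (hi - lo)
    for layer in a.layers:
        z = np.asarray(layer.weights, dtype=float) @ h + np.asarray(layer.biases, dtype=float)
        h = np.tanh(z) if layer.activation == "tanh" else z
    return h


# ---------------------------------------------------------------------------
# record (de)serialization — shared between .annw files and HMOD [ML] blocks
# ---------------------------------------------------------------------------

def _vector_str(v: np.ndarray) -> str:
    return " ".join(format_number(float(x)) for x in v)


def annspec_to_records(a: AnnSpec) -> list[tuple[str, list[tuple[str, str]]]]:
    """Canonical record listing: inputs, then per-layer header / weight
    rows / bias vector, then output mappings."""
    recs: list[tuple[str, list[tuple[str, str]]]] = []
    for i, inp in enumerate(a.inputs, start=1):
        recs.append((f"input_{i}", [("id", inp.id),
                                    ("min", format_number(inp.scale_min)),
                                    ("max", format_number(inp.scale_max))]))
    for l, layer in enumerate(a.layers, start=1):
        w = np.asarray(layer.weights, dtype=float)
        recs.append((f"layer_{l}", [("size", str(w.shape[0])),
                                    ("activation", layer.activation)]))
        for i in range(w.shape[0]):
            recs.append((f"w_{l}_{i + 1}", [("values", _vector_str(w[i]))]))
        recs.append((f"b_{l}", [("values", _vector_str(np.asarray(layer.biases, dtype=float)))]))
    for k, out in enumerate(a.outputs, start=1):
        fields = [("target", out.kind), ("id", out.target)]
        if out.factor is not None:
            fields.append(("factor", write_infix(out.factor)))
        recs.append((f"output_{k}", fields))
    return recs


def records_to_annspec(records: list[Record], rep: ValidationReport,
                       loc_prefix: str = "ml") -> Optional[AnnSpec]:
    """Rebuild an AnnSpec from parsed records, reporting problems.

    Returns None if errors were reported.  Used both by the standalone
    container loader and by the HMOD parser.
    """
    def loc(r: Record) -> str:
        return f"{loc_prefix}:line {r.line_no}" if r.line_no else loc_prefix

    inputs: list[AnnInput] = []
    layers: list[dict] = []
    outputs: list[AnnOutput] = []
    start_len = len(rep)

    def need(r: Record, *names: str) -> Optional[list[str]]:
        vals = []
        for n in names:
            if n not in r.fields:
                rep.error("MISSING_FIELD", loc(r), f"record {r.id!r} lacks field {n!r}")
                return None
            vals.append(r.fields[n])
        return vals

    def fnum(r: Record, text: str) -> Optional[float]:
        try:
            return float(text)
        except ValueError:
            rep.error("BAD_NUMBER", loc(r), f"cannot parse number {text!r}")
            return None

    for r in records:
        if r.id.startswith("input_"):
            got = need(r, "id", "min", "max")
            if got is None:
                continue
            lo, hi = fnum(r, got[1]), fnum(r, got[2])
            if lo is None or hi is None:
                continue
            inputs.append(AnnInput(got[0], lo, hi))
        elif r.id.startswith("layer_"):
            got = need(r, "size", "activation")
            if got is None:
                continue
            try:
                size = int(got[0])
            except ValueError:
                rep.error("BAD_NUMBER", loc(r), f"layer size {got[0]!r} is not an integer")
                continue
            if got[1] not in ACTIVATIONS:
                rep.error("UNSUPPORTED_ACTIVATION", loc(r),
                          f"unknown activation {got[1]!r} (supported: {', '.join(ACTIVATIONS)})")
                # keep the layer so shape checking does not cascade
            layers.append({"size": size, "activation": got[1], "rows": {}, "bias": None,
                           "record": r})
        elif r.id.startswith("w_"):
            parts = r.id.split("_")
            got = need(r, "values")
            if got is None or len(parts) != 3:
                if len(parts) != 3:
                    rep.error("BAD_RECORD", loc(r),
                              f"weight record id must be w_<layer>_<row>, got {r.id!r}")
                continue
            try:
                l, i = int(parts[1]), int(parts[2])
            except ValueError:
                rep.error("BAD_RECORD", loc(r), f"bad weight record id {r.id!r}")
                continue
            row = _parse_vector(r, got[0], rep, loc)
            if row is None:
                continue
            if not (1 <= l <= len(layers)):
                rep.error("ANN_SHAPE_MISMATCH", loc(r),
                          f"weight row for undeclared layer {l}")
                continue
            layers[l - 1]["rows"][i] = (row, r)
        elif r.id.startswith("b_"):
            parts = r.id.split("_")
            got = need(r, "values")
            if got is None or len(parts) != 2:
                if len(parts) != 2:
                    rep.error("BAD_RECORD", loc(r), f"bad bias record id {r.id!r}")
                continue
            try:
                l = int(parts[1])
            except ValueError:
                rep.error("BAD_RECORD", loc(r), f"bad bias record id {r.id!r}")
                continue
            vec = _parse_vector(r, got[0], rep, loc)
            if vec is None:
                continue
            if not (1 <= l <= len(layers)):
                rep.error("ANN_SHAPE_MISMATCH", loc(r), f"bias vector for undeclared layer {l}")
                continue
            layers[l - 1]["bias"] = (vec, r)
        elif r.id.startswith("output_"):
            got = need(r, "target", "id")
            if got is None:
                continue
            kind = got[0]
            if kind == "reaction":
                kind = "reaction-rate"
            if kind not in ("reaction-rate", "parameter"):
                rep.error("BAD_RECORD", loc(r), f"unknown output target kind {got[0]!r}")
                continue
            factor = None
            if "factor" in r.fields:
                try:
                    factor = parse_infix(r.fields["factor"])
                except ExprError as exc:
                    rep.error("BAD_EXPRESSION", loc(r), f"bad factor expression: {exc}")
                    continue
            outputs.append(AnnOutput(kind, got[1], factor))
        else:
            rep.error("BAD_RECORD", loc(r), f"unknown record {r.id!r} in ml section")

    # assemble matrices, checking shapes
    built: list[AnnLayer] = []
    prev = len(inputs)
    for l, spec in enumerate(layers, start=1):
        size = spec["size"]
        r = spec["record"]
        rows = spec["rows"]
        if sorted(rows) != list(range(1, size + 1)):
            rep.error("ANN_SHAPE_MISMATCH", loc(r),
                      f"layer {l}: declared size {size} but weight rows {sorted(rows)} given")
            continue
        mat = []
        ok = True
        for i in range(1, size + 1):
            row, rr = rows[i]
            if len(row) != prev:
                rep.error("ANN_SHAPE_MISMATCH", loc(rr),
                          f"layer {l} row {i}: {len(row)} weights given, previous layer size is {prev}")
                ok = False
            mat.append(row)
        if spec["bias"] is None:
            rep.error("ANN_SHAPE_MISMATCH", loc(r), f"layer {l}: bias vector missing")
            ok = False
        else:
            bias, br = spec["bias"]
            if len(bias) != size:
                rep.error("ANN_SHAPE_MISMATCH", loc(br),
                          f"layer {l}: bias length {len(bias)} does not match size {size}")
                ok = False
        if not ok:
            continue
        built.append(AnnLayer(np.array(mat, dtype=float),
                              np.array(spec["bias"][0], dtype=float), spec["activation"]))
        prev = size

    if len(rep) > start_len:
        return None
    a = AnnSpec(inputs, built, outputs)
    try:
        a.validate()
    except AnnError as exc:
        rep.error(exc.code, loc_prefix, str(exc))
        return None
    return a


def _parse_vector(r: Record, text: str, rep: ValidationReport, loc) -> Optional[list[float]]:
    try:
        return [float(t) for t in text.split()]
    except ValueError:
        rep.error("BAD_NUMBER", loc(r), f"cannot parse numeric vector {text!r}")
        return None


# ---------------------------------------------------------------------------
# standalone .annw container
# ---------------------------------------------------------------------------

def save_ann_weights(a: AnnSpec) -> str:
    """Serialize to the portable ASCII weight container (byte-deterministic)."""
    a.validate()
    lines = ["[ANNW]", format_record("format", [("version", ANNW_VERSION)])]
    for rid, fields in annspec_to_records(a):
        lines.append(format_record(rid, fields))
    return "\n".join(lines) + "\n"


def load_ann_weights(text: str) -> AnnSpec:
    """Load the ASCII weight container; raises :class:`AnnError` with a
    stable ``code`` on any problem."""
    rep = ValidationReport()
    records: list[Record] = []
    saw_header = False
    saw_version = False
    for no, raw in enumerate(text.splitlines(), start=1):
        line = strip_comment(raw).strip()
        if not line:
            continue
        if line == "[ANNW]":
            saw_header = True
            continue
        if line.startswith("["):
            raise AnnError(f"line {no}: unexpected section {line!r}", "BAD_RECORD")
        try:
            rec = parse_record(line, no)
        except LineFormatError as exc:
            raise AnnError(f"line {no}: {exc}", "BAD_RECORD") from exc
        if rec.id == "format":
            version = rec.fields.get("version", "")
            if not version.startswith("ANNW/1"):
                raise AnnError(f"unsupported container version {version!r}", "UNKNOWN_VERSION")
            saw_version = True
            continue
        records.append(rec)
    if not saw_header or not saw_version:
        raise AnnError("missing [ANNW] header or format record", "BAD_HEADER")
    a = records_to_annspec(records, rep, loc_prefix="annw")
    if a is None:
        first = rep.sorted().entries[0]
        raise AnnError(f"{first.location}: {first.message}", first.code)
    return a


def load_keras_h5(path: str, inputs: list[AnnInput],
                  outputs: list[AnnOutput]) -> AnnSpec:  # pragma: no cover - optional extra
    """Best-effort reader for Keras HDF5 weight files (dense layers only).

    Requires h5py; hidden layers are assumed tanh, the last layer linear.
    The caller supplies the input/output variable mappings, which the H5
    file does not contain.
    """
    import h5py

    layers: list[AnnLayer] = []
    with h5py.File(path, "r") as f:
        grp = f["model_weights"] if "model_weights" in f else f
        names = [n for n in grp if len(grp[n])]
        for name in names:
            sub = grp[name]
            while len(sub) == 1 and not any(k in sub for k in ("kernel:0", "kernel")):
                sub = sub[list(sub)[0]]
            kernel = sub.get("kernel:0", sub.get("kernel"))
            bias = sub.get("bias:0", sub.get("bias"))
            if kernel is None:
                continue
            w = np.array(kernel).T  # Keras stores (in, out); we store (out, in)
            b = np.array(bias) if bias is not None else np.zeros(w.shape[0])
            layers.append(AnnLayer(w, b, "tanh"))
    if layers:
        layers[-1].activation = "linear"
    a = AnnSpec(inputs, layers, outputs)
    a.validate()
    return a


# ---------------------------------------------------------------------------
# hybridization: compile an ANN into parameters + assignment rules
# ---------------------------------------------------------------------------

@dataclass
class HybridizationPlan:
    """Record of what :func:`hybridize` generated, sufficient to invert it.

    Generated ids follow ``<prefix>W_<l>_<i>_<j>`` (weights),
    ``<prefix>B_<l>_<i>`` (biases), ``<prefix>X_<i>`` (scaled inputs),
    ``<prefix>H_<l>_<i>`` (hidden nodes) and ``<prefix>Y_<k>`` (outputs);
    all indices 1-based.
    """

    prefix: str
    input_ids: list[str]
    layer_shapes: list[tuple[int, int]]  # (rows, cols) per layer
    activations: list[str]
    outputs: list[AnnOutput]

    # -- generated-name helpers --------------------------------------------
    def w_id(self, l: int, i: int, j: int) -> str:
        return f"{self.prefix}W_{l}_{i}_{j}"

    def b_id(self, l: int, i: int) -> str:
        return f"{self.prefix}B_{l}_{i}"

    def x_id(self, i: int) -> str:
        return f"{self.prefix}X_{i}"

    def h_id(self, l: int, i: int) -> str:
        return f"{self.prefix}H_{l}_{i}"

    def y_id(self, k: int) -> str:
        return f"{self.prefix}Y_{k}"

    def node_id(self, l: int, i: int) -> str:
        """Value symbol of node i of layer l (output layer uses Y names)."""
        if l == len(self.layer_shapes):
            out = self.outputs[i - 1]
            if out.kind == "parameter":
                return out.target
            return self.y_id(i)
        return self.h_id(l, i)

    def parameter_ids(self) -> list[str]:
        ids = []
        for l, (rows, cols) in enumerate(self.layer_shapes, start=1):
            for i in range(1, rows + 1):
                for j in range(1, cols + 1):
                    ids.append(self.w_id(l, i, j))
            for i in range(1, rows + 1):
                ids.append(self.b_id(l, i))
        return ids

    def rule_variables(self) -> list[str]:
        ids = [self.x_id(i) for i in range(1, len(self.input_ids) + 1)]
        for l, (rows, _) in enumerate(self.layer_shapes, start=1):
            for i in range(1, rows + 1):
                ids.append(self.node_id(l, i))
        return ids

    def node_parameter_ids(self) -> list[str]:
        """Generated node-value symbols that are declared as (non-constant)
        parameters; excludes pre-existing parameter-target ids."""
        param_targets = {o.target for o in self.outputs if o.kind == "parameter"}
        return [v for v in self.rule_variables() if v not in param_targets]


class HybridizeError(ValueError):
    pass


_MAX_PREFIX_TRIES = 100


def _choose_prefix(existing: set[str], a: AnnSpec, base: str) -> str:
    """Deterministic collision avoidance: try base, base_h1, base_h2, ..."""
    for k in range(_MAX_PREFIX_TRIES):
        prefix = base if k == 0 else f"{base}_h{k}"
        plan = _make_plan(prefix, a)
        generated = set(plan.parameter_ids()) | set(plan.node_parameter_ids())
        if not (generated & existing):
            return prefix
    raise HybridizeError(f"could not find a collision-free id prefix from base {base!r}")


def _make_plan(prefix: str, a: AnnSpec) -> HybridizationPlan:
    return HybridizationPlan(
        prefix=prefix,
        input_ids=[i.id for i in a.inputs],
        layer_shapes=[tuple(np.asarray(l.weights).shape) for l in a.layers],
        activations=[l.activation for l in a.layers],
        outputs=list(a.outputs),
    )


def _affine_expr(plan: HybridizationPlan, l: int, i: int, prev_syms: list[str]) -> Expr:
    terms = None
    for j, sym in enumerate(prev_syms, start=1):
        term = Expr.bin("*", Expr.sym(plan.w_id(l, i, j)), Expr.sym(sym))
        terms = term if terms is None else Expr.bin("+", terms, term)
    assert terms is not None
    return Expr.bin("+", terms, Expr.sym(plan.b_id(l, i)))


def hybridize(m: KineticModel, a: AnnSpec,
              prefix: str = "ann") -> tuple[KineticModel, HybridizationPlan]:
    """Compile the network into the model.

    Adds one constant parameter per weight (origin ``ml-weight``) and bias
    (``ml-bias``), one assignment rule per scaled input
    (``X = (x - min)/(max - min)`` with the bounds as literals), one per
    hidden node (``H = tanh(W.prev + b)``), one per output node; every
    targeted reaction's kinetic law is replaced by the output symbol,
    optionally multiplied by the declared mechanistic factor.  Parameter
    targets are assigned directly.  The returned model passes
    :func:`~hybkit.model.check_consistency`.
    """
    a.validate()
    rep = check_consistency(m)
    if rep.has_errors():
        raise HybridizeError("refusing to hybridize inconsistent model:\n" + str(rep))

    model_ids = set(m.all_ids())
    known = model_ids | {rr.variable for rr in m.rate_rules}
    for inp in a.inputs:
        if inp.id not in model_ids:
            raise HybridizeError(f"ANN input {inp.id!r} is not a species/parameter of the model")
    param_ids = set(m.parameter_ids())
    reaction_ids = set(m.reaction_ids())
    for out in a.outputs:
        if out.kind == "reaction-rate" and out.target not in reaction_ids:
            raise HybridizeError(f"ANN output targets unknown reaction {out.target!r}")
        if out.kind == "parameter" and out.target not in param_ids:
            raise HybridizeError(f"ANN output targets unknown parameter {out.target!r}")
        if out.factor is not None:
            bad = out.factor.symbols() - known
            if bad:
                raise HybridizeError(
                    f"mechanistic factor references undefined symbols: {sorted(bad)}")

    chosen = _choose_prefix(model_ids, a, prefix)
    plan = _make_plan(chosen, a)
    out = m.copy()

    # (i) weight/bias parameters
    for l, layer in enumerate(a.layers, start=1):
        w = np.asarray(layer.weights, dtype=float)
        b = np.asarray(layer.biases, dtype=float)
        for i in range(1, w.shape[0] + 1):
            for j in range(1, w.shape[1] + 1):
                out.parameters.append(Parameter(id=plan.w_id(l, i, j),
                                                value=float(w[i - 1, j - 1]),
                                                constant=True, origin="ml-weight"))
        for i in range(1, w.shape[0] + 1):
            out.parameters.append(Parameter(id=plan.b_id(l, i), value=float(b[i - 1]),
                                            constant=True, origin="ml-bias"))

    # node-value symbols must exist in the namespace for the assignment
    # rules (and the emitted SBML) to resolve: declare them as
    # non-constant parameters of origin "ml-node"
    for vid in plan.node_parameter_ids():
        out.parameters.append(Parameter(id=vid, value=0.0, constant=False, origin="ml-node"))

    # (ii) scaled-input rules: X_i = (x_i - min) / (max - min)
    new_rules: list[AssignmentRule] = []
    for i, inp in enumerate(a.inputs, start=1):
        expr = Expr.bin("/",
                        Expr.bin("-", Expr.sym(inp.id), Expr.num(inp.scale_min)),
                        Expr.bin("-", Expr.num(inp.scale_max), Expr.num(inp.scale_min)))
        new_rules.append(AssignmentRule(variable=plan.x_id(i), expression=expr))

    prev_syms = [plan.x_id(i) for i in range(1, a.n_inputs + 1)]
    n_layers = len(a.layers)
    for l, layer in enumerate(a.layers, start=1):
        rows = np.asarray(layer.weights).shape[0]
        this_syms = []
        for i in range(1, rows + 1):
            z = _affine_expr(plan, l, i, prev_syms)
            body = Expr.call_fn("tanh", [z]) if layer.activation == "tanh" else z
            var = plan.node_id(l, i)
            if l == n_layers:
                outk = a.outputs[i - 1]
                if outk.kind == "parameter":
                    # the output rule assigns the parameter directly
                    p = out.get_parameter(outk.target)
                    p.constant = False
                    if outk.factor is not None:
                        body = Expr.bin("*", body, outk.factor)
            new_rules.append(AssignmentRule(variable=var, expression=body))
            this_syms.append(plan.h_id(l, i) if l < n_layers else var)
        prev_syms = this_syms

    out.assignment_rules.extend(new_rules)

    # (iii) reaction-rate targets: replace the kinetic law
    for k, o in enumerate(a.outputs, start=1):
        if o.kind == "reaction-rate":
            rxn = out.get_reaction(o.target)
            law: Expr = Expr.sym(plan.y_id(k))
            if o.factor is not None:
                law = Expr.bin("*", law, o.factor)
            rxn.kinetic_law = law

    final = check_consistency(out)
    if final.has_errors():  # pragma: no cover - defensive
        raise HybridizeError("hybridized model failed consistency:\n" + str(final))
    return out, plan


class DehybridizeError(ValueError):
    pass


def _expect_scaling(expr: Expr, var: str) -> tuple[float, float]:
    """Recover (min, max) from the canonical (x - min)/(max - min) rule."""
    ok = (expr.kind == "binary" and expr.name == "/"
          and expr.args[0].kind == "binary" and expr.args[0].name == "-"
          and expr.args[1].kind == "binary" and expr.args[1].name == "-"
          and expr.args[0].args[0].kind == "symbol"
          and expr.args[0].args[1].kind == "number"
          and expr.args[1].args[0].kind == "number"
          and expr.args[1].args[1].kind == "number")
    if not ok:
        raise DehybridizeError(f"scaled-input rule {var!r} has been mutated: "
                               f"{write_infix(expr)!r}")
    lo = expr.args[0].args[1].value
    hi = expr.args[1].args[0].value
    return lo, hi


def dehybridize(m: KineticModel, plan: HybridizationPlan) -> tuple[KineticModel, AnnSpec]:
    """Invert :func:`hybridize`: strip the generated parameters and rules
    and rebuild the AnnSpec (weights recovered bit-exactly from the
    parameter values).

    The kinetic law the compilation replaced is gone; targeted reactions
    are left with the declared mechanistic factor (or the constant 0), so
    re-hybridizing with the recovered network reproduces ``m`` exactly.
    """
    missing: list[str] = []
    param_ids = set(m.parameter_ids())
    rule_vars = {a.variable for a in m.assignment_rules}
    for pid in plan.parameter_ids():
        if pid not in param_ids:
            missing.append(pid)
    for var in plan.rule_variables():
        if var not in rule_vars:
            missing.append(var)
    if missing:
        raise DehybridizeError("plan symbols missing from model: " + ", ".join(sorted(missing)))

    rules = {a.variable: a.expression for a in m.assignment_rules}

    inputs = []
    for i, xid in enumerate(plan.input_ids, start=1):
        lo, hi = _expect_scaling(rules[plan.x_id(i)], plan.x_id(i))
        inputs.append(AnnInput(xid, lo, hi))

    layers = []
    for l, (rows, cols) in enumerate(plan.layer_shapes, start=1):
        w = np.empty((rows, cols))
        b = np.empty(rows)
        for i in range(1, rows + 1):
            for j in range(1, cols + 1):
                w[i - 1, j - 1] = m.get_parameter(plan.w_id(l, i, j)).value
            b[i - 1] = m.get_parameter(plan.b_id(l, i)).value
        layers.append(AnnLayer(w, b, plan.activations[l - 1]))

    a = AnnSpec(inputs, layers, list(plan.outputs))
    a.validate()

    drop_params = set(plan.parameter_ids()) | set(plan.node_parameter_ids())
    drop_rules = set(plan.rule_variables())
    out = m.copy()
    out.parameters = [p for p in out.parameters if p.id not in drop_params]
    out.assignment_rules = [r for r in out.assignment_rules if r.variable not in drop_rules]
    for k, o in enumerate(plan.outputs, start=1):
        if o.kind == "reaction-rate":
            rxn = out.get_reaction(o.target)
            rxn.kinetic_law = o.factor if o.factor is not None else Expr.num(0.0)
        else:
            p = out.get_parameter(o.target)
            p.constant = True
    return out, a
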