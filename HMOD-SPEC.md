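# HMOD/1 — hybrid-model text format

Normative grammar for the HMOD format as read and written by `hybkit`.
HMOD is a line-oriented, pure-ASCII format that aggregates a kinetic
model's mechanistic properties with an optional machine-learning (ML)
component, so that a hybrid semiparametric model travels as a single
diff-friendly text file.

## Lexical rules

* Files are pure ASCII.  Any byte above 127 is an error (`NON_ASCII`).
* `#` starts a comment that runs to end of line, except inside a
  double-quoted value.  Blank lines are ignored.
* Numbers use `.` as the decimal separator; decimal or scientific
  notation; serialization uses the shortest decimal that round-trips the
  IEEE double exactly.
* Identifiers match `[A-Za-z_][A-Za-z0-9_]*` and live in one flat,
  model-wide namespace (compartments, species, parameters, reactions).
* Booleans are the literals `true` and `false`.

## Records

Every non-header line is a record:

```
id : field=value, field=value, ...
```

Canonical serialization puts one space around `:` and one space after
each comma.  A value is either a *bare token* (characters
`[A-Za-z0-9_.+-]`, no spaces or commas) or a *double-quoted string*
(any printable ASCII except `"`).  Expressions, species lists and names
are always quoted.

## Blocks

Blocks appear in this fixed order, each introduced by a bracketed
uppercase header.  The order makes definition-before-use checkable in a
single pass; a block out of order is an `ORDER_VIOLATION`.  The six
mechanistic blocks are always present (possibly empty); `[ML]` is
present only in hybrid documents.

| block | record form |
|---|---|
| `[HMOD]` | `format : version="HMOD/1"` and `model : id=<id>[, name="..."][, notes="..."]` |
| `[COMPARTMENTS]` | `<id> : size=<num>, constant=<bool>[, name="..."]` |
| `[SPECIES]` | `<id> : compartment=<id>, init=<num>, boundary=<bool>, constant=<bool>[, name="..."]` |
| `[PARAMETERS]` | `<id> : value=<num>, constant=<bool>, origin=<tag>[, name="..."]` |
| `[REACTIONS]` | `<id> : reactants="<list>", products="<list>", reversible=<bool>, law="<expr>"[, name="..."]` |
| `[RATE_RULES]` | `<variable> : expr="<expr>"` |
| `[ASSIGNMENT_RULES]` | `<variable> : expr="<expr>"` |
| `[ML]` | see below |

A parser must reject any major version other than `HMOD/1`
(`UNKNOWN_VERSION`).

Parameter `origin` tags record provenance: `mechanistic` (default),
`ml-weight`, `ml-bias`, `ml-scaling`, `ml-node` (a generated
network-node value symbol).

### Species lists

`reactants` / `products` are `+`-separated terms, each an optional
positive stoichiometric coefficient followed by a species id, e.g.
`"2 A + B"`.  The empty string means no reactants (or products).

### Expressions

Infix notation with operators `+ - * / ^` (power right-associative;
unary minus binds tighter than `^`), parenthesized function calls from
the closed set `exp ln log10 sqrt tanh abs min max piecewise pow`, and
relational operators `< <= > >= == !=` (for piecewise conditions).
`piecewise(v1, c1, ..., otherwise)` takes value/condition pairs with an
optional trailing otherwise.

### The `[ML]` block

Describes one feedforward network and its wiring into the mechanistic
model.  Record kinds, in canonical order (all indices 1-based):

```
input_<i>  : id=<model id>, min=<num>, max=<num>
layer_<l>  : size=<int>, activation=tanh|linear
w_<l>_<i>  : values="<w1> <w2> ..."     # row i of layer l's weight matrix
b_<l>     : values="<b1> <b2> ..."     # layer l's bias vector
output_<k> : target=reaction|parameter, id=<model id>[, factor="<expr>"]
```

Inputs are min-max scaled to [0, 1] using the declared bounds before the
first layer.  Weight row lengths must equal the previous layer's size
(the first layer's the number of inputs), bias lengths the layer's size,
and the number of outputs the last layer's size — violations are
`ANN_SHAPE_MISMATCH`.  The optional `factor` is a mechanistic expression
retained multiplicatively when the output replaces a reaction's kinetic
law.

The standalone weight container (`.annw`) uses the same records under a
single `[ANNW]` header with `format : version="ANNW/1"`.

## Validation error codes

`NON_ASCII`, `BAD_HEADER`, `UNKNOWN_VERSION`, `UNKNOWN_BLOCK`,
`ORDER_VIOLATION`, `BAD_RECORD`, `UNKNOWN_FIELD`, `MISSING_FIELD`,
`BAD_IDENTIFIER`, `BAD_NUMBER`, `BAD_BOOLEAN`, `BAD_EXPRESSION`,
`DANGLING_REF`, `DUPLICATE_ID`, `RULE_CONFLICT`, `ASSIGNMENT_CYCLE`,
`ANN_SHAPE_MISMATCH`, `UNSUPPORTED_ACTIVATION`.

Validators never throw: every problem is a `(severity, code, location,
message)` entry, ordered by location then code.  A document is valid iff
its report is empty, in which case parsing yields a fully resolved model
(plus the network for hybrid documents).

## Example

```
[HMOD]
format : version="HMOD/1"
model : id=mini

[COMPARTMENTS]
cell : size=1, constant=true

[SPECIES]
S : compartment=cell, init=2, boundary=false, constant=false
P : compartment=cell, init=0, boundary=false, constant=false

[PARAMETERS]
Vmax : value=1.2, constant=true, origin=mechanistic
Km : value=0.4, constant=true, origin=mechanistic

[REACTIONS]
uptake : reactants="S", products="P", reversible=false, law="Vmax*S/(Km+S)"

[RATE_RULES]

[ASSIGNMENT_RULES]
```
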