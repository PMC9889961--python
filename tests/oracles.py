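"""Independent oracles the tests compare the implementation against.

Each oracle is written from scratch against the documented behaviour,
deliberately using a different algorithm than the implementation:
a shunting-yard evaluator (vs recursive descent + tree walk), a
matrix-free forward-pass loop (vs numpy matmul), and a brute-force edge
check for topological order.
"""

from __future__ import annotations

import math
import re

_TOKEN = re.compile(r"\s*(?:(\d+\.\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?"
                    r"|\d+(?:[eE][+-]?\d+)?)|([A-Za-z_][A-Za-z0-9_]*)"
                    r"|(<=|>=|==|!=|[-+*/^(),<>]))")

_UNARY_FN = {"exp": math.exp, "ln": math.log, "log10": math.log10,
             "sqrt": math.sqrt, "tanh": math.tanh, "abs": abs}
_BIN_FN = {"min": min, "max": max}

# precedence: relations 1, +- 2, */ 3, ^ 4 (right), unary minus 5 (right)
_PREC = {"<": 1, "<=": 1, ">": 1, ">=": 1, "==": 1, "!=": 1,
         "+": 2, "-": 2, "*": 3, "/": 3, "^": 4, "u-": 5}
_RIGHT = {"^", "u-"}


def shunting_yard_eval(text: str, env: dict[str, float]) -> float:
    """Evaluate an infix string via shunting-yard -> RPN -> stack machine."""
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise ValueError(f"bad token at {pos}: {text[pos:]!r}")
            break
        tokens.append(m)
        pos = m.end()

    output: list = []  # RPN: floats, ("op", name), ("fn", name, nargs)
    stack: list[str] = []
    argc: list[int] = []
    prev = None  # previous significant token kind, for unary-minus detection
    i = 0
    while i < len(tokens):
        num, name, op = tokens[i].groups()
        if num is not None:
            output.append(float(num))
            prev = "value"
        elif name is not None:
            if i + 1 < len(tokens) and tokens[i + 1].group(3) == "(":
                stack.append(f"fn:{name}")
                prev = "fn"
            else:
                output.append(env[name])
                prev = "value"
        elif op == "(":
            stack.append("(")
            if prev == "fn":
                argc.append(1)
            prev = "open"
        elif op == ")":
            while stack and stack[-1] != "(":
                output.append(("op", stack.pop()))
            stack.pop()  # '('
            if stack and stack[-1].startswith("fn:"):
                fn = stack.pop()[3:]
                output.append(("fn", fn, argc.pop()))
            prev = "value"
        elif op == ",":
            while stack and stack[-1] != "(":
                output.append(("op", stack.pop()))
            argc[-1] += 1
            prev = "comma"
        else:
            this = "u-" if op == "-" and prev in (None, "op", "open", "comma", "fn") else op
            if this != "u-" or True:
                p = _PREC[this]
                while stack and stack[-1] not in ("(",) and not stack[-1].startswith("fn:"):
                    q = _PREC[stack[-1]]
                    if q > p or (q == p and this not in _RIGHT):
                        output.append(("op", stack.pop()))
                    else:
                        break
            stack.append(this)
            prev = "op"
        i += 1
    while stack:
        output.append(("op", stack.pop()))

    vals: list[float] = []
    for item in output:
        if isinstance(item, float):
            vals.append(item)
        elif item[0] == "op":
            o = item[1]
            if o == "u-":
                vals.append(-vals.pop())
                continue
            b, a = vals.pop(), vals.pop()
            if o == "+":
                vals.append(a + b)
            elif o == "-":
                vals.append(a - b)
            elif o == "*":
                vals.append(a * b)
            elif o == "/":
                vals.append(a / b if b != 0 else math.copysign(math.inf, a))
            elif o == "^":
                r = a ** b
                vals.append(math.nan if isinstance(r, complex) else r)
            elif o == "<":
                vals.append(1.0 if a < b else 0.0)
            elif o == "<=":
                vals.append(1.0 if a <= b else 0.0)
            elif o == ">":
                vals.append(1.0 if a > b else 0.0)
            elif o == ">=":
                vals.append(1.0 if a >= b else 0.0)
            elif o == "==":
                vals.append(1.0 if a == b else 0.0)
            elif o == "!=":
                vals.append(1.0 if a != b else 0.0)
            else:
                raise ValueError(o)
        else:
            _, fn, n = item
            args = [vals.pop() for _ in range(n)][::-1]
            if fn in _UNARY_FN:
                vals.append(_UNARY_FN[fn](*args))
            elif fn in _BIN_FN:
                vals.append(_BIN_FN[fn](*args))
            elif fn == "pow":
                vals.append(args[0] ** args[1])
            else:
                raise ValueError(fn)
    (result,) = vals
    return result


def loop_forward(inputs, layers, x):
    """Matrix-free ANN forward pass: plain Python loops over scalars.

    ``inputs``: list of (scale_min, scale_max); ``layers``: list of
    (weights as list-of-rows, biases as list, activation name).
    """
    h = [(xi - lo) / (hi - lo) for xi, (lo, hi) in zip(x, inputs)]
    for weights, biases, activation in layers:
        nxt = []
        for row, b in zip(weights, biases):
            z = b
            for w, v in zip(row, h):
                z += w * v
            nxt.append(math.tanh(z) if activation == "tanh" else z)
        h = nxt
    return h


def is_valid_topo_order(ordered_vars: list[str], deps: dict[str, set[str]]) -> bool:
    """Brute-force check: every dependency edge points backwards."""
    pos = {v: i for i, v in enumerate(ordered_vars)}
    for v, ds in deps.items():
        for d in ds:
            if d in pos and pos[d] >= pos[v]:
                return False
    return True
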