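from __future__ import annotations

import numpy as np
import pytest

from hybkit.expressions import Expr
from hybkit.fixtures import make_toy_model

SYMBOL_POOL = ["a", "b", "c", "k1", "Km", "S", "x_0"]


def random_expr(rng: np.random.Generator, depth: int = 4,
                with_piecewise: bool = False) -> Expr:
    """Seeded random expression tree; numeric literals are kept positive
    so negation only ever appears as an explicit unary node."""
    if depth <= 0 or rng.random() < 0.3:
        if rng.random() < 0.5:
            return Expr.num(float(np.round(rng.uniform(0.1, 9.9), 3)))
        return Expr.sym(str(rng.choice(SYMBOL_POOL)))
    kinds = ["binary"] * 4 + ["unary", "call"]
    if with_piecewise:
        kinds.append("piecewise")
    kind = rng.choice(kinds)
    if kind == "binary":
        op = str(rng.choice(["+", "-", "*", "/", "^"]))
        return Expr.bin(op, random_expr(rng, depth - 1, with_piecewise),
                        random_expr(rng, depth - 1, with_piecewise))
    if kind == "unary":
        operand = random_expr(rng, depth - 1, with_piecewise)
        if operand.kind == "number":  # negation of a literal folds; keep a real unary node
            operand = Expr.sym(str(rng.choice(SYMBOL_POOL)))
        return Expr.neg(operand)
    if kind == "piecewise":
        cond = Expr.bin(str(rng.choice(["<", "<=", ">", ">="])),
                        random_expr(rng, 1), random_expr(rng, 1))
        return Expr.call_fn("piecewise", [random_expr(rng, depth - 1), cond,
                                          random_expr(rng, depth - 1)])
    fn = str(rng.choice(["exp", "ln", "log10", "sqrt", "tanh", "abs", "min", "max"]))
    if fn in ("min", "max"):
        return Expr.call_fn(fn, [random_expr(rng, depth - 1, with_piecewise),
                                 random_expr(rng, depth - 1, with_piecewise)])
    return Expr.call_fn(fn, [random_expr(rng, depth - 1, with_piecewise)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def mm_model():
    return make_toy_model("michaelis-menten-pathway", seed=1)


@pytest.fixture
def chain_model():
    return make_toy_model("chain", seed=1)
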