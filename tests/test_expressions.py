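"""Expression tree, infix/MathML translation and evaluation."""

from __future__ import annotations

import math

import pytest
from lxml import etree

from hybkit.expressions import (Expr, ExprError, ExprSyntaxError, MathMLError,
                                UnboundSymbolError, evaluate, parse_infix,
                                parse_mathml, write_infix, write_mathml)

from conftest import random_expr
from oracles import shunting_yard_eval

MM = Expr.bin("/", Expr.bin("*", Expr.sym("k1"), Expr.sym("S")),
              Expr.bin("+", Expr.sym("Km"), Expr.sym("S")))


class TestParseInfix:
    def test_precedence_forces_michaelis_menten_shape(self):
        assert parse_infix("k1*S/(Km+S)") == MM

    def test_function_call(self):
        assert parse_infix("tanh(0)") == Expr.call_fn("tanh", [Expr.num(0)])

    def test_power_is_right_associative(self):
        assert evaluate(parse_infix("2^3^2"), {}) == 512.0

    def test_unary_minus_binds_tighter_than_power(self):
        # -x^2 is (-x)^2 under this grammar
        assert evaluate(parse_infix("-x^2"), {"x": 3.0}) == 9.0

    def test_pow_surface_syntax_normalizes_to_operator(self):
        assert parse_infix("pow(a,b)") == parse_infix("a^b")

    def test_negated_literal_folds(self):
        assert parse_infix("-2") == Expr.num(-2.0)
        assert parse_infix("-x") == Expr.neg(Expr.sym("x"))

    @pytest.mark.parametrize("text,col", [
        ("", 1),
        ("a+", 3),
        ("(a+b", 5),
        ("a+*b", 3),
        ("a $ b", 3),
    ])
    def test_syntax_error_carries_1based_column(self, text, col):
        with pytest.raises(ExprSyntaxError) as exc:
            parse_infix(text)
        assert exc.value.column == col

    def test_unknown_function_is_an_error_not_a_symbol(self):
        with pytest.raises(ExprSyntaxError, match="unknown function 'sigmoid'"):
            parse_infix("sigmoid(x)")

    def test_function_name_without_call_is_a_symbol(self):
        assert parse_infix("exp+1") == Expr.bin("+", Expr.sym("exp"), Expr.num(1))


class TestWriteInfix:
    @pytest.mark.parametrize("expr,expected", [
        (Expr.bin("*", Expr.bin("+", Expr.sym("a"), Expr.sym("b")), Expr.sym("c")), "(a+b)*c"),
        (Expr.call_fn("tanh", [Expr.bin("*", Expr.sym("w"), Expr.sym("x"))]), "tanh(w*x)"),
        (MM, "k1*S/(Km+S)"),
        (Expr.neg(Expr.bin("^", Expr.sym("x"), Expr.num(2))), "-(x^2)"),
        (Expr.bin("^", Expr.neg(Expr.sym("x")), Expr.num(2)), "-x^2"),
    ])
    def test_examples(self, expr, expected):
        assert write_infix(expr) == expected

    def test_roundtrip_identity_1000_random_trees(self, rng):
        for _ in range(1000):
            e = random_expr(rng, depth=5)
            assert parse_infix(write_infix(e)) == e

    def test_no_redundant_outer_parentheses(self, rng):
        for _ in range(300):
            e = random_expr(rng, depth=4)
            s = write_infix(e)
            if s.startswith("(") and s.endswith(")"):
                # outermost parens must be load-bearing: stripping them
                # must break the parse or change the tree
                inner = s[1:-1]
                try:
                    assert parse_infix(inner) != e
                except ExprError:
                    pass


class TestMathML:
    NS = "http://www.w3.org/1998/Math/MathML"

    def test_times_apply(self):
        xml = f'<apply xmlns="{self.NS}"><times/><ci>k1</ci><ci>S</ci></apply>'
        assert parse_mathml(xml) == Expr.bin("*", Expr.sym("k1"), Expr.sym("S"))

    def test_tanh_apply(self):
        xml = f'<apply xmlns="{self.NS}"><tanh/><cn>0</cn></apply>'
        assert parse_mathml(xml) == Expr.call_fn("tanh", [Expr.num(0)])

    def test_nary_plus_folds_left(self):
        xml = f'<apply xmlns="{self.NS}"><plus/><ci>a</ci><ci>b</ci><ci>c</ci></apply>'
        assert parse_mathml(xml) == parse_infix("a+b+c")

    def test_unary_minus(self):
        xml = f'<apply xmlns="{self.NS}"><minus/><ci>a</ci></apply>'
        assert parse_mathml(xml) == Expr.neg(Expr.sym("a"))

    def test_e_notation_cn(self):
        xml = f'<math xmlns="{self.NS}"><cn type="e-notation">1.5<sep/>-3</cn></math>'
        assert parse_mathml(xml) == Expr.num(1.5e-3)

    def test_cn_with_sbml_units_attribute_parses(self):
        xml = (f'<math xmlns="{self.NS}" '
               f'xmlns:sbml="http://www.sbml.org/sbml/level3/version2/core">'
               f'<cn sbml:units="mole">2</cn></math>')
        assert parse_mathml(xml) == Expr.num(2.0)

    def test_log_default_and_explicit_base10(self):
        for body in ("<apply><log/><ci>x</ci></apply>",
                     "<apply><log/><logbase><cn>10</cn></logbase><ci>x</ci></apply>"):
            xml = f'<math xmlns="{self.NS}">{body}</math>'
            assert parse_mathml(xml) == Expr.call_fn("log10", [Expr.sym("x")])

    def test_log10_writes_explicit_logbase(self):
        el = write_mathml(Expr.call_fn("log10", [Expr.sym("x")]))
        assert b"logbase" in etree.tostring(el)

    def test_root_is_sqrt(self):
        xml = f'<math xmlns="{self.NS}"><apply><root/><ci>x</ci></apply></math>'
        assert parse_mathml(xml) == Expr.call_fn("sqrt", [Expr.sym("x")])

    def test_unsupported_element_named_in_error(self):
        xml = f'<apply xmlns="{self.NS}"><factorial/><cn>3</cn></apply>'
        with pytest.raises(MathMLError, match="factorial"):
            parse_mathml(xml)

    def test_empty_apply_is_an_error(self):
        with pytest.raises(MathMLError, match="empty apply"):
            parse_mathml(f'<apply xmlns="{self.NS}"/>')

    def test_roundtrip_identity_random_trees(self, rng):
        for _ in range(300):
            e = random_expr(rng, depth=5, with_piecewise=True)
            xml = etree.tostring(write_mathml(e))
            assert parse_mathml(xml) == e

    def test_piecewise_roundtrip_with_otherwise(self):
        e = Expr.call_fn("piecewise", [Expr.num(1), Expr.bin("<", Expr.sym("x"), Expr.num(0)),
                                       Expr.num(2)])
        assert parse_mathml(etree.tostring(write_mathml(e))) == e
        assert parse_infix(write_infix(e)) == e


class TestEvaluate:
    def test_tanh_zero(self):
        assert evaluate(Expr.call_fn("tanh", [Expr.num(0)]), {}) == 0.0

    def test_michaelis_menten_point(self):
        assert evaluate(parse_infix("k*S/(Km+S)"), {"k": 2, "S": 1, "Km": 1}) == 1.0

    def test_division_by_zero_gives_infinity(self):
        assert evaluate(parse_infix("1/x"), {"x": 0.0}) == math.inf

    def test_unbound_symbol_named(self):
        with pytest.raises(UnboundSymbolError, match="'Km'"):
            evaluate(parse_infix("S/Km"), {"S": 1.0})

    def test_piecewise_first_true_branch_else_otherwise(self):
        e = parse_infix("piecewise(1, x < 0, 2, x < 10, 3)")
        assert evaluate(e, {"x": -5}) == 1.0
        assert evaluate(e, {"x": 5}) == 2.0
        assert evaluate(e, {"x": 50}) == 3.0

    def test_piecewise_no_match_no_otherwise_raises(self):
        with pytest.raises(ExprError, match="no branch"):
            evaluate(parse_infix("piecewise(1, x < 0)"), {"x": 5})

    def test_matches_shunting_yard_oracle_on_200_random_trees(self, rng):
        env = {name: float(v) for name, v in
               zip(["a", "b", "c", "k1", "Km", "S", "x_0"],
                   rng.uniform(0.5, 3.0, size=7))}
        checked = 0
        for _ in range(200):
            e = random_expr(rng, depth=5)
            s = write_infix(e)
            mine = evaluate(e, env)
            try:
                theirs = shunting_yard_eval(s, env)
            except (OverflowError, ValueError, ZeroDivisionError, TypeError):
                continue  # overflow / complex power: oracle cannot follow
            if math.isfinite(mine) and math.isfinite(theirs):
                assert mine == pytest.approx(theirs, rel=1e-9, abs=1e-12), s
                checked += 1
            else:
                assert not (math.isfinite(mine) or math.isfinite(theirs)), s
        assert checked > 100  # the comparison actually exercised real cases
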