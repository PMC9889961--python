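"""ANN container, forward pass, and compilation to assignment rules."""

from __future__ import annotations

import numpy as np
import pytest

from hybkit.ann import (AnnError, AnnInput, AnnLayer, AnnOutput, AnnSpec,
                        DehybridizeError, HybridizeError, ann_forward,
                        dehybridize, hybridize, load_ann_weights,
                        save_ann_weights)
from hybkit.expressions import parse_infix
from hybkit.fixtures import make_random_ann
from hybkit.model import Parameter, check_consistency
from hybkit.simulate import _constant_env, evaluate_assignments

from oracles import loop_forward


def simple_ann(seed=0):
    return make_random_ann([2, 3, 1], seed=seed, input_ids=["A", "B"],
                           targets=[("reaction-rate", "r1")])


class TestContainer:
    def test_declared_shape_2_3_1(self):
        a = load_ann_weights(save_ann_weights(simple_ann()))
        assert [np.asarray(l.weights).shape for l in a.layers] == [(3, 2), (1, 3)]

    def test_bias_length_mismatch_rejected(self):
        a = simple_ann()
        a.layers[0].biases = np.zeros(2)
        with pytest.raises(AnnError) as exc:
            a.validate()
        assert exc.value.code == "ANN_SHAPE_MISMATCH"

    def test_unknown_activation_rejected(self):
        a = simple_ann()
        a.layers[0].activation = "relu"
        with pytest.raises(AnnError) as exc:
            a.validate()
        assert exc.value.code == "UNSUPPORTED_ACTIVATION"

    def test_store_load_identity_on_random_specs(self):
        for seed in range(10):
            shape = [2 + seed % 3, 4, 1 + seed % 2]
            a = make_random_ann(shape, seed=seed)
            text = save_ann_weights(a)
            b = load_ann_weights(text)
            assert save_ann_weights(b) == text
            for la, lb in zip(a.layers, b.layers):
                assert np.array_equal(np.asarray(la.weights), np.asarray(lb.weights))
                assert np.array_equal(np.asarray(la.biases), np.asarray(lb.biases))

    def test_corrupted_container_reports_code(self):
        text = save_ann_weights(simple_ann()).replace("layer_1 : size=3", "layer_1 : size=5")
        with pytest.raises(AnnError) as exc:
            load_ann_weights(text)
        assert exc.value.code == "ANN_SHAPE_MISMATCH"


class TestForward:
    def test_zero_network_outputs_zero(self):
        a = AnnSpec(inputs=[AnnInput("x", 0, 1)],
                    layers=[AnnLayer(np.zeros((3, 1)), np.zeros(3), "tanh"),
                            AnnLayer(np.zeros((1, 3)), np.zeros(1), "linear")],
                    outputs=[AnnOutput("reaction-rate", "r1")])
        assert ann_forward(a, [0.7]) == pytest.approx([0.0])

    def test_single_linear_layer_affine(self):
        # a linear readout stacked on a pass-through is the affine map 2*x+1
        a = AnnSpec(inputs=[AnnInput("x", 0, 1)],
                    layers=[AnnLayer(np.array([[1.0]]), np.zeros(1), "linear"),
                            AnnLayer(np.array([[2.0]]), np.array([1.0]), "linear")],
                    outputs=[AnnOutput("reaction-rate", "r1")])
        assert ann_forward(a, [0.5]) == pytest.approx([2.0])

    def test_matches_loop_oracle_at_100_points(self, rng):
        a = make_random_ann([3, 4, 2], seed=9)
        inputs = [(i.scale_min, i.scale_max) for i in a.inputs]
        layers = [(np.asarray(l.weights).tolist(), np.asarray(l.biases).tolist(), l.activation)
                  for l in a.layers]
        for _ in range(100):
            x = rng.uniform(0, 1, size=3)
            assert ann_forward(a, x) == pytest.approx(loop_forward(inputs, layers, list(x)),
                                                      abs=1e-14)

    def test_input_length_mismatch(self):
        with pytest.raises(AnnError):
            ann_forward(simple_ann(), [1.0])


class TestHybridize:
    def test_counts_for_2_3_1_network(self, chain_model):
        a = simple_ann()
        before_params = len(chain_model.parameters)
        before_rules = len(chain_model.assignment_rules)
        hybrid, plan = hybridize(chain_model, a)
        new_rules = len(hybrid.assignment_rules) - before_rules
        assert new_rules == 2 + 3 + 1  # scaled inputs + hidden + output
        ml_params = [p for p in hybrid.parameters if p.origin in ("ml-weight", "ml-bias")]
        assert len(ml_params) == (3 * 2 + 3) + (1 * 3 + 1)  # the 13 weights/biases
        node_params = [p for p in hybrid.parameters if p.origin == "ml-node"]
        assert len(node_params) == new_rules
        assert check_consistency(hybrid).is_empty()

    def test_rule_evaluation_equals_forward_pass(self, chain_model, rng):
        a = simple_ann(seed=5)
        hybrid, plan = hybridize(chain_model, a)
        for _ in range(50):
            state = {"A": float(rng.uniform(0, 1)), "B": float(rng.uniform(0, 1))}
            env = dict(_constant_env(hybrid))
            env.update(state)
            env = evaluate_assignments(hybrid, env)
            expected = ann_forward(a, [state["A"], state["B"]])
            assert env[plan.y_id(1)] == pytest.approx(expected[0], abs=1e-12)

    def test_zero_weight_network_gives_zero_rate(self, chain_model):
        a = simple_ann()
        for layer in a.layers:
            layer.weights = np.zeros_like(np.asarray(layer.weights))
            layer.biases = np.zeros_like(np.asarray(layer.biases))
        hybrid, plan = hybridize(chain_model, a)
        env = evaluate_assignments(hybrid, {**_constant_env(hybrid), "A": 0.4, "B": 0.2})
        assert env[plan.y_id(1)] == 0.0

    def test_kinetic_law_replaced_with_optional_factor(self, chain_model):
        a = simple_ann()
        a.outputs[0].factor = parse_infix("A")
        hybrid, plan = hybridize(chain_model, a)
        law = hybrid.get_reaction("r1").kinetic_law
        assert law == parse_infix(f"{plan.y_id(1)}*A")

    def test_unknown_input_or_target_rejected(self, chain_model):
        bad_in = make_random_ann([1, 2, 1], seed=0, input_ids=["ghost"],
                                 targets=[("reaction-rate", "r1")])
        with pytest.raises(HybridizeError, match="ghost"):
            hybridize(chain_model, bad_in)
        bad_out = make_random_ann([1, 2, 1], seed=0, input_ids=["A"],
                                  targets=[("reaction-rate", "nope")])
        with pytest.raises(HybridizeError, match="nope"):
            hybridize(chain_model, bad_out)

    def test_id_collision_gets_deterministic_suffix(self, chain_model):
        chain_model.parameters.append(Parameter(id="annY_1", value=1.0))
        _, plan = hybridize(chain_model, simple_ann())
        assert plan.prefix == "ann_h1"

    def test_parameter_target_assigned_directly(self, chain_model):
        chain_model.parameters.append(Parameter(id="mu", value=0.0))
        a = make_random_ann([2, 3, 1], seed=1, input_ids=["A", "B"],
                            targets=[("parameter", "mu")])
        hybrid, plan = hybridize(chain_model, a)
        assert not hybrid.get_parameter("mu").constant
        assert "mu" in {r.variable for r in hybrid.assignment_rules}
        assert check_consistency(hybrid).is_empty()


class TestDehybridize:
    def test_roundtrip_recovers_weights_bit_exactly(self, chain_model):
        a = simple_ann(seed=13)
        hybrid, plan = hybridize(chain_model, a)
        base, recovered = dehybridize(hybrid, plan)
        for la, lb in zip(a.layers, recovered.layers):
            assert np.array_equal(np.asarray(la.weights), np.asarray(lb.weights))
            assert np.array_equal(np.asarray(la.biases), np.asarray(lb.biases))
        for ia, ib in zip(a.inputs, recovered.inputs):
            assert (ia.id, ia.scale_min, ia.scale_max) == (ib.id, ib.scale_min, ib.scale_max)

    def test_rehybridize_reproduces_model(self, chain_model):
        from hybkit.hmod import serialize_hmod
        hybrid, plan = hybridize(chain_model, simple_ann(seed=21))
        base, recovered = dehybridize(hybrid, plan)
        hybrid2, _ = hybridize(base, recovered, prefix=plan.prefix)
        assert serialize_hmod(hybrid2) == serialize_hmod(hybrid)

    def test_missing_plan_symbols_listed(self, chain_model):
        hybrid, plan = hybridize(chain_model, simple_ann())
        hybrid.parameters = [p for p in hybrid.parameters if p.id != plan.w_id(1, 2, 1)]
        with pytest.raises(DehybridizeError, match=plan.w_id(1, 2, 1)):
            dehybridize(hybrid, plan)
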