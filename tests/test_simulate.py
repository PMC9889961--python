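"""ODE assembly, integration, and trajectory comparison."""

from __future__ import annotations

import math

import numpy as np
import pytest

from hybkit.expressions import parse_infix
from hybkit.fixtures import make_toy_model
from hybkit.model import (Compartment, KineticModel, Parameter, Reaction,
                          Species, SpeciesRef)
from hybkit.simulate import (SimulationError, build_rhs, compare_trajectories,
                             run)


def mass_action_pair() -> KineticModel:
    m = KineticModel(id="ab")
    m.compartments.append(Compartment(id="cell", size=1.0))
    m.species.append(Species(id="A", compartment="cell", initial_concentration=1.0))
    m.species.append(Species(id="B", compartment="cell"))
    m.parameters.append(Parameter(id="k", value=1.0))
    m.reactions.append(Reaction(id="r", reactants=[SpeciesRef("A")],
                                products=[SpeciesRef("B")],
                                kinetic_law=parse_infix("k*A")))
    return m


class TestBuildRhs:
    def test_mass_action_derivative(self):
        rhs, state = build_rhs(mass_action_pair())
        dy = rhs(0.0, np.array([1.0, 0.0]))
        assert state == ["A", "B"]
        assert dy == pytest.approx([-1.0, 1.0])

    def test_boundary_species_derivative_is_zero(self):
        m = mass_action_pair()
        m.species[0].boundary = True
        rhs, state = build_rhs(m)
        dy = rhs(0.0, np.array([1.0, 0.0]))
        assert dy[state.index("A")] == 0.0
        assert dy[state.index("B")] == pytest.approx(1.0)

    def test_compartment_size_divides_flux(self):
        m = mass_action_pair()
        m.compartments[0].size = 2.0
        rhs, _ = build_rhs(m)
        assert rhs(0.0, np.array([1.0, 0.0])) == pytest.approx([-0.5, 0.5])

    def test_matches_flux_summation_oracle_on_random_networks(self, rng):
        for _ in range(10):
            n = 5
            m = KineticModel(id="net")
            m.compartments.append(Compartment(id="cell", size=1.0))
            for i in range(n):
                m.species.append(Species(id=f"S{i}", compartment="cell",
                                         initial_concentration=float(rng.uniform(0.1, 2))))
            n_rxn = int(rng.integers(2, 6))
            ks = []
            stoich = np.zeros((n_rxn, n))
            for r in range(n_rxn):
                sub, prod = rng.choice(n, size=2, replace=False)
                coeff = float(rng.integers(1, 3))
                k = float(rng.uniform(0.1, 2))
                ks.append(k)
                stoich[r, sub] -= 1
                stoich[r, prod] += coeff
                m.parameters.append(Parameter(id=f"k{r}", value=k))
                m.reactions.append(Reaction(
                    id=f"r{r}", reactants=[SpeciesRef(f"S{sub}")],
                    products=[SpeciesRef(f"S{prod}", coeff)],
                    kinetic_law=parse_infix(f"k{r}*S{sub}")))
            rhs, state = build_rhs(m)
            y = rng.uniform(0.1, 2.0, size=n)
            # oracle: explicit stoichiometry-matrix product with hand-computed fluxes
            flux = np.array([ks[r] * y[int(m.reactions[r].reactants[0].species[1:])]
                             for r in range(n_rxn)])
            expected = stoich.T @ flux
            got = rhs(0.0, y)
            order = [int(s[1:]) for s in state]
            assert got == pytest.approx(expected[order], abs=1e-12)


class TestRun:
    def test_exponential_decay_closed_form(self):
        m = mass_action_pair()
        m.parameters[0].value = 0.5
        m.reactions[0].products = []
        traj = run(m, t_end=2.0, n_points=21)
        assert traj.column("A")[-1] == pytest.approx(math.exp(-1.0), abs=1e-6)

    def test_reversible_pair_conserves_total(self):
        m = make_toy_model("reversible-pair", seed=4)
        traj = run(m, t_end=10.0, n_points=100)
        total = traj.column("A") + traj.column("B")
        assert np.max(np.abs(total - total[0])) <= 1e-8

    def test_stiff_two_timescale_model_integrates(self):
        m = make_toy_model("stiff-pair", seed=0)
        traj = run(m, t_end=2.0, n_points=100)
        # A gone almost instantly; C follows the exact two-exponential form
        assert traj.column("A")[-1] == pytest.approx(0.0, abs=1e-9)
        k1, k2, t = 1000.0, 1.0, 2.0
        exact = 1.0 - (k1 * math.exp(-k2 * t) - k2 * math.exp(-k1 * t)) / (k1 - k2)
        assert traj.column("C")[-1] == pytest.approx(exact, abs=1e-6)

    def test_rate_rule_integrates_clock(self):
        m = make_toy_model("reversible-pair", seed=4)
        traj = run(m, t_end=5.0, n_points=11)
        assert traj.column("clock") == pytest.approx(traj.times, abs=1e-8)

    def test_derived_columns_track_assignment_rules(self, mm_model):
        traj = run(mm_model, t_end=5.0, n_points=20)
        assert traj.column("total") == pytest.approx(
            traj.column("S") + traj.column("P"), abs=1e-12)

    def test_reruns_are_identical(self, mm_model):
        t1 = run(mm_model, t_end=5.0, n_points=30)
        t2 = run(mm_model, t_end=5.0, n_points=30)
        assert np.array_equal(t1.states, t2.states)

    def test_csv_export_shape(self, mm_model):
        text = run(mm_model, t_end=1.0, n_points=5).to_csv()
        lines = text.strip().splitlines()
        assert lines[0].split(",")[:3] == ["time", "S", "P"]
        assert len(lines) == 6

    def test_divergent_model_reports_failure(self):
        m = mass_action_pair()
        m.reactions[0].kinetic_law = parse_infix("k*A*A*1000000")
        m.reactions[0].products = [SpeciesRef("A", 2.0)]  # autocatalytic blow-up
        with pytest.raises(SimulationError):
            run(m, t_end=10.0, n_points=50)


class TestCompare:
    def test_identity_is_zero(self, mm_model):
        t = run(mm_model, t_end=2.0, n_points=10)
        assert compare_trajectories(t, t).worst == 0.0

    def test_symmetric(self, mm_model):
        t1 = run(mm_model, t_end=2.0, n_points=10)
        t2 = run(mm_model, t_end=2.0, n_points=10, rtol=1e-6, atol=1e-8)
        assert compare_trajectories(t1, t2).max_abs == compare_trajectories(t2, t1).max_abs

    def test_constructed_perturbation_detected(self, mm_model):
        t1 = run(mm_model, t_end=2.0, n_points=10)
        t2 = run(mm_model, t_end=2.0, n_points=10)
        t2.states = t2.states.copy()
        t2.states[3, 0] += 1e-3
        cmp = compare_trajectories(t1, t2, tol=1e-8)
        assert not cmp.passed
        assert cmp.max_abs["S"] == pytest.approx(1e-3)

    def test_grid_mismatch_raises(self, mm_model):
        t1 = run(mm_model, t_end=2.0, n_points=10)
        t2 = run(mm_model, t_end=2.0, n_points=11)
        with pytest.raises(ValueError, match="time grids"):
            compare_trajectories(t1, t2)
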