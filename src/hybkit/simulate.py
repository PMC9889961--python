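"""Deterministic ODE simulation of kinetic models.

The simulator is the toolkit's numerical referee: conversion and
hybridization claims ("the round-tripped / hybridized model behaves the
same") are checked by integrating both models and comparing trajectories.

Semantics: assignment rules are instantaneous — re-evaluated in
topological order inside the right-hand side at every integrator call;
species change by ``sum(+-stoichiometry * kinetic_law) / compartment
size`` unless they are constant, boundary, or governed by a rule; rate
rules set derivatives directly.  Integration uses LSODA (stiff-capable,
adaptive) with tight default tolerances (rtol 1e-8, atol 1e-10) so solver
error stays far below the equivalence thresholds the round-trip checks
apply.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .expressions import evaluate
from .model import KineticModel, check_consistency, topo_order_assignments


class SimulationError(RuntimeError):
    pass


def evaluate_assignments(m: KineticModel, env: Mapping[str, float]) -> dict[str, float]:
    """Evaluate all assignment rules in topological order on top of ``env``
    (state + constants); returns the extended environment."""
    out = dict(env)
    for rule in topo_order_assignments(m):
        out[rule.variable] = evaluate(rule.expression, out)
    return out


def _constant_env(m: KineticModel) -> dict[str, float]:
    assigned = m.assignment_targets()
    rated = m.rate_rule_targets()
    env: dict[str, float] = {c.id: c.size for c in m.compartments}
    for p in m.parameters:
        if p.id not in assigned and p.id not in rated:
            env[p.id] = p.value
    for s in m.species:
        if s.constant:
            env[s.id] = s.initial_concentration
    return env


def state_variables(m: KineticModel) -> list[str]:
    """ODE state: non-constant species not determined by an assignment
    rule, followed by rate-ruled parameters (declaration order)."""
    assigned = m.assignment_targets()
    rated = m.rate_rule_targets()
    ids = [s.id for s in m.species if not s.constant and s.id not in assigned]
    ids += [p.id for p in m.parameters if p.id in rated]
    return ids


def build_rhs(m: KineticModel) -> tuple[Callable[[float, np.ndarray], np.ndarray], list[str]]:
    """Assemble the derivative function ``f(t, y) -> dy/dt`` for a
    consistent model; returns ``(f, state_ids)``."""
    rep = check_consistency(m)
    if rep.has_errors():
        raise SimulationError("cannot simulate inconsistent model:\n" + str(rep))

    state_ids = state_variables(m)
    const_env = _constant_env(m)
    rules = topo_order_assignments(m)
    rate_rules = {r.variable: r.expression for r in m.rate_rules}
    species_by_id = {s.id: s for s in m.species}
    comp_size = {c.id: c.size for c in m.compartments}

    # per-state reaction contributions: (reaction index, signed stoichiometry)
    contributions: dict[str, list[tuple[int, float]]] = {sid: [] for sid in state_ids}
    for ri, r in enumerate(m.reactions):
        for ref in r.reactants:
            if ref.species in contributions:
                contributions[ref.species].append((ri, -ref.stoichiometry))
        for ref in r.products:
            if ref.species in contributions:
                contributions[ref.species].append((ri, +ref.stoichiometry))

    laws = [r.kinetic_law for r in m.reactions]

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        env = dict(const_env)
        for sid, val in zip(state_ids, y):
            env[sid] = val
        for rule in rules:
            env[rule.variable] = evaluate(rule.expression, env)
        flux = [evaluate(law, env) for law in laws]
        dy = np.zeros(len(state_ids))
        for k, sid in enumerate(state_ids):
            if sid in rate_rules:
                dy[k] = evaluate(rate_rules[sid], env)
                continue
            sp = species_by_id.get(sid)
            if sp is None or sp.boundary:
                continue
            vol = comp_size.get(sp.compartment, 1.0)
            acc = 0.0
            for ri, signed in contributions[sid]:
                acc += signed * flux[ri]
            dy[k] = acc / vol
        return dy

    return rhs, state_ids


@dataclass
class Trajectory:
    """Simulated time course: state columns plus derived (assignment-rule)
    columns, all labeled by model ids."""

    times: np.ndarray
    labels: list[str]
    states: np.ndarray  # shape (n_points, n_state)
    derived_labels: list[str] = field(default_factory=list)
    derived: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def column(self, label: str) -> np.ndarray:
        if label in self.labels:
            return self.states[:, self.labels.index(label)]
        if label in self.derived_labels:
            return self.derived[:, self.derived_labels.index(label)]
        raise KeyError(label)

    def all_labels(self) -> list[str]:
        return self.labels + self.derived_labels

    def to_csv(self) -> str:
        """CSV export: header = time + ids, one row per time point."""
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["time"] + self.all_labels())
        for i, t in enumerate(self.times):
            row = [repr(float(t))]
            row += [repr(float(v)) for v in self.states[i]]
            if self.derived_labels:
                row += [repr(float(v)) for v in self.derived[i]]
            writer.writerow(row)
        return buf.getvalue()


def run(m: KineticModel, t_end: float, n_points: int = 100,
        rtol: float = 1e-8, atol: float = 1e-10) -> Trajectory:
    """Integrate the model from its initial state to ``t_end`` on a uniform
    grid of ``n_points`` points (including t=0).  Fully deterministic.

    Raises :class:`SimulationError` (reporting the failure time) if the
    integrator cannot complete the interval or produces non-finite values.
    """
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    rhs, state_ids = build_rhs(m)

    y0 = []
    for sid in state_ids:
        try:
            y0.append(m.get_species(sid).initial_concentration)
        except KeyError:
            y0.append(m.get_parameter(sid).value)

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), np.asarray(y0, dtype=float), method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else 0.0
        raise SimulationError(f"integration failed at t={t_fail:g}: {sol.message}")
    states = sol.y.T
    if not np.all(np.isfinite(states)):
        bad = np.argwhere(~np.isfinite(states))[0]
        raise SimulationError(f"non-finite state at t={t_eval[bad[0]]:g}")

    const_env = _constant_env(m)
    rules = topo_order_assignments(m)
    derived_labels = [r.variable for r in rules]
    derived = np.empty((n_points, len(derived_labels)))
    for i in range(n_points):
        env = dict(const_env)
        for sid, val in zip(state_ids, states[i]):
            env[sid] = val
        for j, rule in enumerate(rules):
            env[rule.variable] = evaluate(rule.expression, env)
            derived[i, j] = env[rule.variable]
    if not np.all(np.isfinite(derived)) and derived.size:
        raise SimulationError("non-finite assignment-rule value along trajectory")
    return Trajectory(times=t_eval, labels=list(state_ids), states=states,
                      derived_labels=derived_labels, derived=derived)


@dataclass
class TrajectoryComparison:
    max_abs: dict[str, float]
    tol: float

    @property
    def worst(self) -> float:
        return max(self.max_abs.values()) if self.max_abs else 0.0

    @property
    def passed(self) -> bool:
        return self.worst <= self.tol


def compare_trajectories(t1: Trajectory, t2: Trajectory,
                         tol: float = 1e-8) -> TrajectoryComparison:
    """Per-column max-abs difference over the shared columns; symmetric.

    Raises ValueError if the time grids differ.
    """
    if t1.times.shape != t2.times.shape or not np.allclose(t1.times, t2.times,
                                                           rtol=0, atol=1e-12):
        raise ValueError("trajectories have different time grids")
    shared = [lab for lab in t1.all_labels() if lab in set(t2.all_labels())]
    diffs = {lab: float(np.max(np.abs(t1.column(lab) - t2.column(lab)))) for lab in shared}
    return TrajectoryComparison(max_abs=diffs, tol=tol)
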