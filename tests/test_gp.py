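import math

import numpy as np
import pandas as pd
import pytest

from dissogp.datasets import Dataset
from dissogp.gp import (
    BINARY, ExpressionTree, GPConfig, Node, eval_tree, evolve, evolve_direct,
    evolve_indirect, _random_tree,
)

ARITH = ("add", "sub", "mul", "div")


def scalar_reference_eval(node, bindings):
    """Independent scalar re-implementation of the protected semantics."""
    if node.name is not None:
        return float(bindings[node.name])
    if node.op is None:
        return float(node.value)
    clamp = lambda v: max(-1e12, min(1e12, v if math.isfinite(v) else
                                     (0.0 if math.isnan(v) else math.copysign(1e12, v))))
    if node.op in BINARY:
        a = scalar_reference_eval(node.children[0], bindings)
        b = scalar_reference_eval(node.children[1], bindings)
        if node.op == "add":
            return clamp(a + b)
        if node.op == "sub":
            return clamp(a - b)
        if node.op == "mul":
            return clamp(a * b)
        if node.op == "div":
            return clamp(1.0 if b == 0 else a / b)
        # protected power: magnitude semantics
        if a == 0:
            return 1.0 if b == 0 else (0.0 if b > 0 else 1.0)
        return clamp(math.exp(max(-700.0, min(700.0, b * math.log(abs(a))))))
    a = scalar_reference_eval(node.children[0], bindings)
    if node.op == "log":
        return clamp(0.0 if a == 0 else math.log(abs(a)))
    if node.op == "sqrt":
        return clamp(math.sqrt(abs(a)))
    return clamp(math.exp(min(700.0, max(-700.0, a))))


def tree(op, *children):
    return Node(op=op, children=children)


class TestEvalTree:
    def test_simple_sum(self):
        n = tree("add", Node.var("d"), Node.var("t"))
        assert eval_tree(n, {"d": 1.0, "t": 2.0}) == 3.0

    def test_protected_division_by_zero(self):
        n = tree("div", Node.var("x"), Node.const(0.0))
        assert eval_tree(n, {"x": 5.0}) == 1.0

    def test_protected_log_and_sqrt(self):
        assert eval_tree(tree("log", Node.const(0.0)), {}) == 0.0
        assert eval_tree(tree("log", Node.const(-math.e)), {}) == pytest.approx(1.0)
        assert eval_tree(tree("sqrt", Node.const(-4.0)), {}) == 2.0

    def test_protected_power(self):
        assert eval_tree(tree("pow", Node.const(-2.0), Node.const(2.0)), {}) == 4.0
        assert eval_tree(tree("pow", Node.const(0.0), Node.const(-1.0)), {}) == 1.0

    def test_unbound_variable(self):
        with pytest.raises(KeyError):
            eval_tree(Node.var("z"), {"x": 1.0})

    def test_random_trees_finite_and_match_reference(self, rng):
        cfg = GPConfig(population_size=2, size_limit=40)
        for k in range(200):
            t = _random_tree(("d", "t"), cfg, rng, depth=5, full=(k % 2 == 0))
            bindings = {"d": float(rng.uniform(0.6, 3.5)),
                        "t": float(rng.uniform(0.0, 1100.0))}
            got = float(eval_tree(t, bindings))
            assert math.isfinite(got)
            assert got == pytest.approx(scalar_reference_eval(t, bindings),
                                        rel=1e-9, abs=1e-9)

    def test_serialization_roundtrip(self):
        t = ExpressionTree(tree("mul", Node.const(2.5),
                                tree("sqrt", Node.var("t"))))
        t2 = ExpressionTree.from_json(t.to_json())
        assert str(t2) == str(t)
        assert t2.size == 4 and t2.depth == 3


class TestEvolveDirect:
    def test_planted_rational_form_rediscovered(self):
        # Q = 2t/(t+50): recoverable exactly once the (a*t)/(t+b) structure
        # appears and its constants are polished
        d = np.repeat([0.6, 1.0, 1.5, 2.7, 3.5], 40)
        t = np.tile(np.linspace(5, 1000, 40), 5)
        ds = Dataset(pd.DataFrame({"formulation_id": "x", "d_mm": d,
                                   "L_mm": 1.0, "t_min": t,
                                   "Q_pct": 2 * t / (t + 50)}))
        cfg = GPConfig(function_set=ARITH, population_size=500,
                       max_generations=40, fitness_stop=1e-8, seed=1,
                       size_limit=30)
        res = evolve_direct(ds, cfg)
        assert res.train_rmse <= 0.01
        assert res.tree.size <= 30

    def test_seeded_determinism(self):
        t = np.linspace(5, 500, 50)
        bindings = {"t": t}
        target = 3.0 * np.sqrt(t) + 1.0
        cfg = GPConfig(population_size=100, max_generations=5,
                       fitness_stop=1e-12, seed=6, size_limit=20)
        a = evolve(bindings, target, cfg)
        b = evolve(bindings, target, cfg)
        assert str(a.tree) == str(b.tree)
        assert a.train_rmse == b.train_rmse

    def test_best_fitness_monotone_and_size_capped(self):
        t = np.linspace(5, 500, 60)
        cfg = GPConfig(population_size=150, max_generations=8,
                       fitness_stop=1e-12, seed=3, size_limit=15)
        res = evolve({"t": t}, np.log(t) * 2.0, cfg)
        assert all(x >= y for x, y in zip(res.history, res.history[1:]))
        assert res.tree.size <= 15

    def test_zero_generation_budget_returns_initial_best(self):
        t = np.linspace(1, 10, 20)
        cfg = GPConfig(population_size=50, max_generations=0, seed=0,
                       fitness_stop=1e-12, size_limit=10, const_opt=False)
        res = evolve({"t": t}, t * 0 + 1.0, cfg)
        assert res.generations == 0
        assert math.isfinite(res.train_rmse)


class TestEvolveIndirect:
    @pytest.fixture()
    def table(self):
        d = np.array([0.6, 1.0, 1.5, 2.7, 3.5])
        return pd.DataFrame({"d": d, "A": 20.0 ** d, "K": np.full(5, 0.8)})

    def test_planted_geometry_maps_recovered(self, table):
        cfg_A = GPConfig(population_size=500, max_generations=40,
                         fitness_stop=0.01, seed=0, size_limit=20,
                         const_opt_sample=10)
        res_A, res_K = evolve_indirect(table, cfg_A=cfg_A)
        assert res_A.train_rmse <= 0.01
        # constant K: the shape map collapses to a constant expression
        assert res_K.train_rmse <= 1e-6
        assert res_A.tree.size <= 20 and res_K.tree.size <= 20

    def test_single_row_table_refused(self, table):
        with pytest.raises(ValueError):
            evolve_indirect(table.iloc[:1])

    def test_missing_column_refused(self, table):
        with pytest.raises(ValueError):
            evolve_indirect(table.drop(columns="K"))


def test_rediscovery_power_two_node_formula():
    """Most seeded runs recover sqrt(t) exactly at moderate population."""
    t = np.linspace(5, 1000, 200)
    target = np.sqrt(t)
    hits = 0
    for seed in range(10):
        cfg = GPConfig(population_size=500, max_generations=20,
                       fitness_stop=1e-9, seed=seed, size_limit=30)
        res = evolve({"t": t}, target, cfg)
        hits += res.train_rmse < 1e-6
    assert hits >= 8
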