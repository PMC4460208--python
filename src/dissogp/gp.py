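"""Tree-based genetic-programming symbolic regression.

Evolves closed-form expressions over a restricted function set
{+, -, *, /, pow, ln, sqrt, exp} with variable terminals and ephemeral
numeric constants, under a node-count complexity cap.  Two drivers mirror
the study's modeling modes:

* ``evolve_direct`` — regress cumulative release Q directly on (d, t);
* ``evolve_indirect`` — regress the per-formulation Weibull constants A
  and K on the geometry, each with its own fitness stop, yielding the
  diameter maps that turn the Weibull equation into a predictive model.

All arithmetic is *protected*: division by zero yields 1, log and sqrt act
on magnitudes (with ln 0 = 0), powers use magnitude semantics with a
clipped exponent, and every node's value is clamped to a large finite
range — a random tree therefore always evaluates to a finite number on
finite inputs, which keeps selection well defined.

Fitness is the RMSE against the target vector; evolution is generational
with tournament selection, subtree crossover, subtree and point mutation,
and single-individual elitism, so the best-so-far fitness never worsens.
An optional constant-polishing step (Nelder-Mead over the best tree's
numeric constants) refines structures the evolution discovers — ephemeral
constants are drawn from a bounded range, so planted targets with
constants outside or between grid values are otherwise unreachable.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .metrics import rmse

__all__ = ["Node", "ExpressionTree", "GPConfig", "GPResult",
           "eval_tree", "evolve", "evolve_direct", "evolve_indirect"]

_BIG = 1e12  # per-node clamp keeping all protected arithmetic finite

UNARY = ("log", "sqrt", "exp")
BINARY = ("add", "sub", "mul", "div", "pow")
DEFAULT_FUNCTION_SET = BINARY + UNARY

_SYMBOL = {"add": "+", "sub": "-", "mul": "*", "div": "/", "pow": "^"}


class Node:
    """One expression-tree node: operator, variable, or constant."""

    __slots__ = ("op", "children", "value", "name")

    def __init__(self, op=None, children=(), value=None, name=None):
        self.op = op            # function-set name, or None for terminals
        self.children = tuple(children)
        self.value = value      # float for constants
        self.name = name        # str for variables

    @classmethod
    def const(cls, v: float) -> "Node":
        return cls(value=float(v))

    @classmethod
    def var(cls, name: str) -> "Node":
        return cls(name=name)

    @property
    def is_terminal(self) -> bool:
        return self.op is None

    def size(self) -> int:
        return 1 + sum(c.size() for c in self.children)

    def depth(self) -> int:
        return 1 + (max(c.depth() for c in self.children) if self.children else 0)

    def copy(self) -> "Node":
        if self.is_terminal:
            return Node(value=self.value, name=self.name)
        return Node(op=self.op, children=[c.copy() for c in self.children])

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def variables(self) -> set:
        return {n.name for n in self.walk() if n.name is not None}

    def __str__(self) -> str:
        if self.name is not None:
            return self.name
        if self.op is None:
            return f"{self.value:.6g}"
        if self.op in BINARY:
            a, b = self.children
            return f"({a} {_SYMBOL[self.op]} {b})"
        return f"{self.op}({self.children[0]})"

    def to_prefix(self) -> str:
        if self.is_terminal:
            return self.name if self.name is not None else f"{self.value!r}"
        return f"({self.op} " + " ".join(c.to_prefix() for c in self.children) + ")"

    def to_dict(self) -> dict:
        if self.name is not None:
            return {"var": self.name}
        if self.op is None:
            return {"const": self.value}
        return {"op": self.op, "children": [c.to_dict() for c in self.children]}

    @classmethod
    def from_dict(cls, d: dict) -> "Node":
        if "var" in d:
            return cls.var(d["var"])
        if "const" in d:
            return cls.const(d["const"])
        return cls(op=d["op"], children=[cls.from_dict(c) for c in d["children"]])


def _clamp(v):
    return np.clip(np.nan_to_num(v, nan=0.0, posinf=_BIG, neginf=-_BIG), -_BIG, _BIG)


def eval_tree(node: Node, bindings: dict):
    """Evaluate a tree under protected semantics; vectorized over bindings.

    Protected rules: x/0 -> 1; ln|x| with ln 0 -> 0; sqrt|x|;
    |a|^b with the exponent's contribution clipped; exp with a clipped
    argument.  Every intermediate is clamped to +-1e12, so the result is
    finite for any finite bindings.  An unbound variable raises KeyError.
    """
    if node.name is not None:
        if node.name not in bindings:
            raise KeyError(f"unbound variable {node.name!r}")
        return np.asarray(bindings[node.name], dtype=float)
    if node.op is None:
        return node.value
    with np.errstate(all="ignore"):
        if node.op in BINARY:
            a = eval_tree(node.children[0], bindings)
            b = eval_tree(node.children[1], bindings)
            if node.op == "add":
                r = a + b
            elif node.op == "sub":
                r = a - b
            elif node.op == "mul":
                r = a * b
            elif node.op == "div":
                bz = np.asarray(b) == 0
                r = np.where(bz, 1.0, np.asarray(a) / np.where(bz, 1.0, b))
            else:  # pow, magnitude semantics
                absa = np.abs(a)
                logabs = np.where(absa > 0, np.log(np.where(absa > 0, absa, 1.0)), 0.0)
                r = np.exp(np.clip(np.asarray(b) * logabs, -700.0, 700.0))
                r = np.where(absa == 0, np.where(np.asarray(b) == 0, 1.0,
                                                 np.where(np.asarray(b) > 0, 0.0, 1.0)), r)
        else:
            a = eval_tree(node.children[0], bindings)
            if node.op == "log":
                absa = np.abs(a)
                r = np.where(absa > 0, np.log(np.where(absa > 0, absa, 1.0)), 0.0)
            elif node.op == "sqrt":
                r = np.sqrt(np.abs(a))
            elif node.op == "exp":
                r = np.exp(np.clip(a, -700.0, 700.0))
            else:
                raise ValueError(f"unknown operator {node.op!r}")
    return _clamp(r)


@dataclass(frozen=True)
class ExpressionTree:
    """An immutable GP individual with its cached complexity."""

    root: Node

    @property
    def size(self) -> int:
        return self.root.size()

    @property
    def depth(self) -> int:
        return self.root.depth()

    def __call__(self, **bindings):
        return eval_tree(self.root, bindings)

    def __str__(self) -> str:
        return str(self.root)

    def to_json(self) -> str:
        return json.dumps(self.root.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExpressionTree":
        return cls(Node.from_dict(json.loads(text)))


@dataclass
class GPConfig:
    """Symbolic-regression run parameters.

    ``size_limit`` caps individual complexity as a node count (the
    study's individualSizeLimit, swept 10-300 there); ``fitness_stop`` ends
    the run once the best RMSE falls below it (study defaults: 1.0 for
    direct Q regression, 0.01 / 5.0 for the Weibull A / K maps).  A
    generation cap and an optional wall-clock budget bound the run;
    generation-capped runs are fully deterministic per seed.
    """

    function_set: tuple = DEFAULT_FUNCTION_SET
    population_size: int = 10_000
    size_limit: int = 50
    fitness_stop: float = 1.0
    max_generations: int = 100
    time_budget_s: float | None = None
    tournament_size: int = 3
    p_crossover: float = 0.7
    p_subtree_mut: float = 0.2
    p_point_mut: float = 0.1
    erc_range: tuple = (-10.0, 10.0)
    init_depth: int = 4
    const_opt: bool = True
    const_opt_top_k: int = 3
    const_opt_sample: int = 5
    const_opt_maxiter: int = 400
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.size_limit < 3:
            raise ValueError("size_limit must be >= 3")
        if self.fitness_stop <= 0:
            raise ValueError("fitness_stop must be positive")
        unknown = set(self.function_set) - set(DEFAULT_FUNCTION_SET)
        if unknown:
            raise ValueError(f"unknown operators {sorted(unknown)}")


@dataclass
class GPResult:
    tree: ExpressionTree
    train_rmse: float
    generations: int
    history: list = field(default_factory=list)  # best RMSE per generation


# ---------------------------------------------------------------------------
# random generation and variation

def _random_terminal(variables, cfg, rng) -> Node:
    if rng.random() < 0.5:
        return Node.var(variables[int(rng.integers(len(variables)))])
    return Node.const(rng.uniform(*cfg.erc_range))


def _random_tree(variables, cfg, rng, depth: int, full: bool) -> Node:
    if depth <= 1 or (not full and rng.random() < 0.3):
        return _random_terminal(variables, cfg, rng)
    op = cfg.function_set[int(rng.integers(len(cfg.function_set)))]
    arity = 2 if op in BINARY else 1
    return Node(op=op, children=[_random_tree(variables, cfg, rng, depth - 1, full)
                                 for _ in range(arity)])


def _init_population(variables, cfg, rng) -> list:
    pop = []
    while len(pop) < cfg.population_size:
        depth = 2 + len(pop) % (cfg.init_depth - 1)
        t = _random_tree(variables, cfg, rng, depth, full=(len(pop) % 2 == 0))
        if t.size() <= cfg.size_limit:
            pop.append(t)
    return pop


def _pick_node(root: Node, rng) -> int:
    return int(rng.integers(root.size()))


def _replace_at(root: Node, index: int, repl: Node) -> Node:
    """Copy of root with the node at preorder position ``index`` replaced."""
    counter = [0]

    def rec(n: Node) -> Node:
        pos = counter[0]
        counter[0] += 1
        if pos == index:
            counter[0] = pos + n.size()  # skip past the replaced subtree
            return repl.copy()
        if n.is_terminal:
            return Node(value=n.value, name=n.name)
        return Node(op=n.op, children=[rec(c) for c in n.children])

    return rec(root)


def _node_at(root: Node, index: int) -> Node:
    for i, n in enumerate(root.walk()):
        if i == index:
            return n
    raise IndexError(index)


def _crossover(a: Node, b: Node, cfg, rng) -> Node:
    donor = _node_at(b, _pick_node(b, rng))
    child = _replace_at(a, _pick_node(a, rng), donor)
    return child if child.size() <= cfg.size_limit else a.copy()


def _subtree_mutate(a: Node, variables, cfg, rng) -> Node:
    repl = _random_tree(variables, cfg, rng, depth=3, full=False)
    child = _replace_at(a, _pick_node(a, rng), repl)
    return child if child.size() <= cfg.size_limit else a.copy()


def _point_mutate(a: Node, variables, cfg, rng) -> Node:
    child = a.copy()
    nodes = list(child.walk())
    n = nodes[int(rng.integers(len(nodes)))]
    if n.name is not None:
        n.name = variables[int(rng.integers(len(variables)))]
    elif n.op is None:
        # nudge a constant: multiplicative + additive jitter keeps both
        # scales reachable
        n.value = float(n.value * (1.0 + 0.2 * rng.standard_normal())
                        + 0.1 * rng.standard_normal())
    else:
        pool = [op for op in cfg.function_set
                if (op in BINARY) == (n.op in BINARY) and op != n.op]
        if pool:
            n.op = pool[int(rng.integers(len(pool)))]
    return child


# ---------------------------------------------------------------------------
# constant polishing

def _constants(root: Node) -> list:
    return [n for n in root.walk() if n.op is None and n.name is None]


def polish_constants(tree: Node, bindings: dict, target, maxiter: int = 400) -> Node:
    """Nelder-Mead refinement of a tree's numeric constants (RMSE loss)."""
    tree = tree.copy()
    consts = _constants(tree)
    if not consts:
        return tree
    target = np.asarray(target, dtype=float)
    x0 = np.array([c.value for c in consts])

    def loss(x):
        for c, v in zip(consts, x):
            c.value = float(v)
        pred = eval_tree(tree, bindings)
        return rmse(target, np.broadcast_to(pred, target.shape))

    best = minimize(loss, x0, method="Nelder-Mead",
                    options={"maxiter": maxiter, "fatol": 1e-12, "xatol": 1e-12})
    for c, v in zip(consts, best.x if best.fun <= loss(x0) else x0):
        c.value = float(v)
    return tree


# ---------------------------------------------------------------------------
# the evolutionary loop

def evolve(bindings: dict, target, cfg: GPConfig,
           variables: tuple | None = None) -> GPResult:
    """Run generational symbolic regression against a target vector.

    ``bindings`` maps terminal names to equal-length value arrays;
    ``target`` is the vector to approximate.  Returns the best individual
    found (constants polished when ``cfg.const_opt``), its training RMSE,
    and the per-generation best-fitness history (monotone nonincreasing).
    """
    target = np.asarray(target, dtype=float)
    if target.size == 0:
        raise ValueError("empty target")
    variables = tuple(variables) if variables is not None else tuple(sorted(bindings))
    if not variables:
        raise ValueError("need at least one terminal variable")
    rng = np.random.default_rng(cfg.seed)
    t0 = time.monotonic()

    def fitness(tree: Node) -> float:
        pred = eval_tree(tree, bindings)
        return rmse(target, np.broadcast_to(pred, target.shape))

    pop = _init_population(variables, cfg, rng)
    fits = np.array([fitness(t) for t in pop])
    best_i = int(np.argmin(fits))
    best_tree, best_fit = pop[best_i].copy(), float(fits[best_i])
    history = [best_fit]
    gen = 0

    def tournament() -> Node:
        idx = rng.integers(len(pop), size=cfg.tournament_size)
        return pop[int(idx[np.argmin(fits[idx])])]

    while (gen < cfg.max_generations and best_fit > cfg.fitness_stop
           and not (cfg.time_budget_s is not None
                    and time.monotonic() - t0 > cfg.time_budget_s)):
        gen += 1
        new_pop = [best_tree.copy()]  # elitism
        while len(new_pop) < cfg.population_size:
            child = tournament().copy()
            if rng.random() < cfg.p_crossover:
                child = _crossover(child, tournament(), cfg, rng)
            if rng.random() < cfg.p_subtree_mut:
                child = _subtree_mutate(child, variables, cfg, rng)
            if rng.random() < cfg.p_point_mut:
                child = _point_mutate(child, variables, cfg, rng)
            new_pop.append(child)
        pop = new_pop
        fits = np.array([fitness(t) for t in pop])
        if cfg.const_opt and (cfg.const_opt_top_k or cfg.const_opt_sample):
            # a promising structure with poor constants cannot out-compete
            # settled junk on raw fitness; tuning constants of the elite plus
            # a random slice of the population each generation lets
            # structure win (e.g. exp(c*d) is hopeless until c is tuned)
            idx = list(np.argsort(fits)[:cfg.const_opt_top_k])
            if cfg.const_opt_sample:
                idx.extend(rng.integers(len(pop), size=cfg.const_opt_sample))
            for i in dict.fromkeys(int(i) for i in idx):
                polished = polish_constants(pop[i], bindings, target,
                                            cfg.const_opt_maxiter)
                pf = fitness(polished)
                if pf < fits[i]:
                    pop[i], fits[i] = polished, pf
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_tree, best_fit = pop[gen_best].copy(), float(fits[gen_best])
        history.append(best_fit)

    if cfg.const_opt:
        polished = polish_constants(best_tree, bindings, target,
                                    cfg.const_opt_maxiter)
        pf = fitness(polished)
        if pf < best_fit:
            best_tree, best_fit = polished, float(pf)
    return GPResult(ExpressionTree(best_tree), best_fit, gen, history)


def evolve_direct(ds, cfg: GPConfig | None = None) -> GPResult:
    """Symbolic regression of Q on (d, t) over a dissolution dataset."""
    cfg = cfg if cfg is not None else GPConfig()
    bindings = {"d": ds.df["d_mm"].to_numpy(dtype=float),
                "t": ds.df["t_min"].to_numpy(dtype=float)}
    return evolve(bindings, ds.df["Q_pct"].to_numpy(dtype=float), cfg,
                  variables=("d", "t"))


def evolve_indirect(weibull_table, cfg_A: GPConfig | None = None,
                    cfg_K: GPConfig | None = None,
                    terminals: tuple = ("d",)) -> tuple[GPResult, GPResult]:
    """Regress the Weibull constants A and K on formulation geometry.

    ``weibull_table`` is a DataFrame with columns ``d`` (and optionally
    ``L``) plus ``A`` and ``K`` — one row per formulation, typically five.
    Runs two independent evolutions with the study's respective fitness
    stops (A: 0.01, K: 5.0) and returns (A result, K result).
    """
    import pandas as pd

    tbl = pd.DataFrame(weibull_table)
    if len(tbl) < 2:
        raise ValueError("need at least two formulations to regress geometry maps")
    for col in (*terminals, "A", "K"):
        if col not in tbl.columns:
            raise ValueError(f"weibull_table missing column {col!r}")
    cfg_A = cfg_A if cfg_A is not None else GPConfig(fitness_stop=0.01)
    cfg_K = cfg_K if cfg_K is not None else GPConfig(fitness_stop=5.0,
                                                    seed=cfg_A.seed + 1)
    bindings = {v: tbl[v].to_numpy(dtype=float) for v in terminals}
    res_A = evolve(bindings, tbl["A"].to_numpy(dtype=float), cfg_A, terminals)
    res_K = evolve(bindings, tbl["K"].to_numpy(dtype=float), cfg_K, terminals)
    return res_A, res_K
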