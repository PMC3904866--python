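"""Evolutionary learner over Boolean feature-combination programs.

A program is an expression tree over AND / OR / NOT with literal leaves
(feature index, polarity) evaluated against a binarized feature row.  A
generational genetic-programming loop — tournament selection, subtree
crossover, point/subtree mutation, single-program elitism and a parsimony
penalty — searches for the program whose predictions best match a binary
label.  This is a deliberately transparent tree GP in the same method
class (evolutionary program learning over Boolean feature combinations)
as the large meta-optimizing systems used for this problem in production,
whose deme-based machinery is out of scope here.

Internally, training evaluates programs against bit-packed columns: each
feature column over n patients is one n-bit Python integer, so an AND of
two features is one machine-word-parallel operation and accuracy is a
popcount.  The public ``evaluate_program`` / ``fitness`` functions accept
plain 0/1 rows and matrices.

Trees are immutable nested tuples::

    ("lit", feature_index, polarity)   # polarity 1 = feature, 0 = NOT feature
    ("not", child)
    ("and", child, child, ...)         # >= 2 children
    ("or",  child, child, ...)

Fitness = training accuracy - parsimony_lambda * node count.
"""

from __future__ import annotations

import logging
import random
import re
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

log = logging.getLogger("notesignal")

__all__ = [
    "BooleanProgram",
    "GPParams",
    "TrainedModel",
    "evaluate_program",
    "fitness",
    "mutate",
    "crossover",
    "train_model",
]

Tree = tuple


# --- tree basics -----------------------------------------------------------

def _validate(tree: Tree, n_features: int | None = None) -> None:
    op = tree[0]
    if op == "lit":
        _, idx, pol = tree
        if pol not in (0, 1):
            raise ValueError(f"literal polarity must be 0/1, got {pol!r}")
        if idx < 0 or (n_features is not None and idx >= n_features):
            raise ValueError(f"feature index {idx} out of bounds")
    elif op == "not":
        if len(tree) != 2:
            raise ValueError("NOT takes exactly one child")
        _validate(tree[1], n_features)
    elif op in ("and", "or"):
        if len(tree) < 3:
            raise ValueError(f"{op.upper()} needs >= 2 children")
        for c in tree[1:]:
            _validate(c, n_features)
    else:
        raise ValueError(f"unknown node type {op!r}")


def _size(tree: Tree) -> int:
    if tree[0] == "lit":
        return 1
    return 1 + sum(_size(c) for c in tree[1:])


def _depth(tree: Tree) -> int:
    if tree[0] == "lit":
        return 1
    return 1 + max(_depth(c) for c in tree[1:])


def _max_feature(tree: Tree) -> int:
    if tree[0] == "lit":
        return tree[1]
    return max(_max_feature(c) for c in tree[1:])


def _get(tree: Tree, idx: int) -> Tree:
    """Preorder node lookup (0 = root)."""
    if idx == 0:
        return tree
    idx -= 1
    for c in tree[1:] if tree[0] != "lit" else ():
        n = _size(c)
        if idx < n:
            return _get(c, idx)
        idx -= n
    raise IndexError("node index out of range")


def _replace(tree: Tree, idx: int, new: Tree) -> Tree:
    if idx == 0:
        return new
    idx -= 1
    if tree[0] == "lit":
        raise IndexError("node index out of range")
    children = list(tree[1:])
    for i, c in enumerate(children):
        n = _size(c)
        if idx < n:
            children[i] = _replace(c, idx, new)
            return (tree[0], *children)
        idx -= n
    raise IndexError("node index out of range")


def _eval_mask(tree: Tree, cols: list[int], full: int) -> int:
    op = tree[0]
    if op == "lit":
        m = cols[tree[1]]
        return m if tree[2] else m ^ full
    if op == "not":
        return _eval_mask(tree[1], cols, full) ^ full
    acc = _eval_mask(tree[1], cols, full)
    if op == "and":
        for c in tree[2:]:
            acc &= _eval_mask(c, cols, full)
    else:
        for c in tree[2:]:
            acc |= _eval_mask(c, cols, full)
    return acc


def matrix_to_masks(matrix: np.ndarray | sp.spmatrix) -> tuple[list[int], int, int]:
    """Bit-pack a binary (n x m) matrix into one integer per column.

    Row i of column j becomes bit i.  Returns (column masks, n rows,
    all-ones mask).
    """
    dense = np.asarray(
        matrix.toarray() if sp.issparse(matrix) else matrix, dtype=np.uint8
    )
    n = dense.shape[0]
    packed = np.packbits(dense, axis=0, bitorder="little")
    cols = [int.from_bytes(packed[:, j].tobytes(), "little") for j in range(dense.shape[1])]
    return cols, n, (1 << n) - 1


def _labels_to_mask(labels: np.ndarray) -> int:
    bits = np.asarray(labels, dtype=np.uint8)
    return int.from_bytes(np.packbits(bits, bitorder="little").tobytes(), "little")


def _mask_to_array(mask: int, n: int) -> np.ndarray:
    nbytes = (n + 7) // 8
    raw = np.frombuffer(mask.to_bytes(nbytes, "little"), dtype=np.uint8)
    return np.unpackbits(raw, bitorder="little")[:n].astype(np.int64)


# --- public program object -------------------------------------------------

_NAME_SAFE = re.compile(r"[^A-Za-z0-9_]")


@dataclass(frozen=True)
class BooleanProgram:
    """An immutable Boolean expression over binarized features."""

    tree: Tree

    def __post_init__(self) -> None:
        _validate(self.tree)

    @property
    def complexity(self) -> int:
        return _size(self.tree)

    @property
    def depth(self) -> int:
        return _depth(self.tree)

    def evaluate(self, row) -> int:
        """Evaluate on one 0/1 feature row."""
        return evaluate_program(self, row)

    def evaluate_matrix(self, matrix) -> np.ndarray:
        """Evaluate on every row of a binary matrix; returns a 0/1 array."""
        cols, n, full = matrix_to_masks(matrix)
        if _max_feature(self.tree) >= len(cols):
            raise IndexError("program references a feature beyond the matrix")
        return _mask_to_array(_eval_mask(self.tree, cols, full), n)

    def to_text(self, feature_names=None) -> str:
        """Prefix-notation serialization, e.g. ``(OR f_agitation (NOT f2))``."""

        def name(idx: int) -> str:
            if feature_names is not None:
                return "f_" + _NAME_SAFE.sub("_", feature_names[idx])
            return f"f{idx}"

        def render(t: Tree) -> str:
            if t[0] == "lit":
                lit = name(t[1])
                return lit if t[2] else f"(NOT {lit})"
            op = t[0].upper()
            return "(" + " ".join([op] + [render(c) for c in t[1:]]) + ")"

        return render(self.tree)

    @classmethod
    def parse(cls, text: str, feature_names=None) -> "BooleanProgram":
        """Inverse of :meth:`to_text`."""
        lookup = None
        if feature_names is not None:
            lookup = {
                "f_" + _NAME_SAFE.sub("_", n): i for i, n in enumerate(feature_names)
            }
        tokens = text.replace("(", " ( ").replace(")", " ) ").split()
        pos = 0

        def atom(tok: str) -> Tree:
            if lookup is not None and tok in lookup:
                return ("lit", lookup[tok], 1)
            m = re.fullmatch(r"f(\d+)", tok)
            if m:
                return ("lit", int(m.group(1)), 1)
            raise ValueError(f"unknown literal {tok!r}")

        def read() -> Tree:
            nonlocal pos
            tok = tokens[pos]
            pos += 1
            if tok != "(":
                return atom(tok)
            op = tokens[pos].lower()
            pos += 1
            children = []
            while tokens[pos] != ")":
                children.append(read())
            pos += 1
            if op == "not":
                (child,) = children
                if child[0] == "lit" and child[2] == 1:
                    return ("lit", child[1], 0)
                return ("not", child)
            return (op, *children)

        tree = read()
        if pos != len(tokens):
            raise ValueError("trailing tokens in program text")
        return cls(tree)


def evaluate_program(program: BooleanProgram | Tree, row) -> int:
    """Standard Boolean semantics of a program on one 0/1 feature row."""
    tree = program.tree if isinstance(program, BooleanProgram) else program
    row = np.asarray(row)
    if _max_feature(tree) >= row.shape[0]:
        raise IndexError("program references a feature beyond the row")
    cols = [int(v) & 1 for v in row]
    return _eval_mask(tree, cols, 1)


def fitness(
    program: BooleanProgram | Tree,
    matrix_binary,
    labels01: np.ndarray,
    parsimony_lambda: float = 0.0,
) -> float:
    """Training accuracy minus ``parsimony_lambda`` x node count."""
    tree = program.tree if isinstance(program, BooleanProgram) else program
    labels01 = np.asarray(labels01)
    if labels01.size == 0:
        raise ValueError("empty data")
    cols, n, full = matrix_to_masks(matrix_binary)
    ymask = _labels_to_mask(labels01)
    out = _eval_mask(tree, cols, full)
    acc = (n - (out ^ ymask).bit_count()) / n
    return acc - parsimony_lambda * _size(tree)


# --- parameters ------------------------------------------------------------

@dataclass(frozen=True)
class GPParams:
    """Hyperparameters of the generational GP loop.

    Defaults are sized so one model trains in well under two seconds on a
    ~200-patient x 2000-feature presence matrix.
    """

    population_size: int = 200
    generations: int = 50
    tournament_size: int = 4
    crossover_rate: float = 0.8
    mutation_rate: float = 0.2
    max_depth: int = 5
    parsimony_lambda: float = 0.002
    feature_bias: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0,1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.parsimony_lambda < 0:
            raise ValueError("parsimony_lambda must be >= 0")
        if self.feature_bias < 0:
            raise ValueError("feature_bias must be >= 0")


@dataclass
class TrainedModel:
    """One evolved program plus its training provenance."""

    program: BooleanProgram
    fitness: float
    accuracy: float
    seed: int
    task: str = ""
    elite_history: list[float] = field(default_factory=list)


# --- variation operators ---------------------------------------------------


def _uniform_sampler(rng: random.Random, n_features: int):
    return lambda: rng.randrange(n_features)


def _biased_sampler(rng: random.Random, n_features: int, bias: float):
    """Power-law feature sampler favoring earlier (higher-ranked) columns.

    Feature j is drawn with weight (j+1)^-bias; the trainer feeds columns
    in mutual-information order, so new literals lean toward informative
    features while keeping a heavy tail of exploration.
    """
    if bias <= 0:
        return _uniform_sampler(rng, n_features)
    import bisect

    w = np.arange(1, n_features + 1, dtype=np.float64) ** (-bias)
    cum = np.cumsum(w / w.sum())
    cum[-1] = 1.0
    return lambda: int(bisect.bisect_left(cum, rng.random()))


def _random_literal(rng: random.Random, sampler) -> Tree:
    return ("lit", sampler(), 1 if rng.random() < 0.5 else 0)


def _random_tree(rng: random.Random, sampler, depth: int, method: str) -> Tree:
    if depth <= 1 or (method == "grow" and rng.random() < 0.3):
        return _random_literal(rng, sampler)
    op = rng.choice(("and", "or", "and", "or", "not"))
    if op == "not":
        return ("not", _random_tree(rng, sampler, depth - 1, method))
    return (
        op,
        _random_tree(rng, sampler, depth - 1, method),
        _random_tree(rng, sampler, depth - 1, method),
    )


def _truncate(tree: Tree, budget: int, rng: random.Random, sampler) -> Tree:
    """Enforce a depth budget by replacing overflow subtrees with literals."""
    if tree[0] == "lit":
        return tree
    if budget <= 1:
        return _random_literal(rng, sampler)
    return (
        tree[0],
        *(_truncate(c, budget - 1, rng, sampler) for c in tree[1:]),
    )


_MUTATION_KINDS = ("literal", "polarity", "operator", "subtree", "extend")


def _mutate_tree(
    tree: Tree,
    rng: random.Random,
    sampler,
    n_features: int,
    max_depth: int,
) -> Tree:
    size = _size(tree)
    kind = rng.choice(_MUTATION_KINDS)
    nodes = [(i, _get(tree, i)) for i in range(size)]
    if kind == "literal":
        leaves = [i for i, nd in nodes if nd[0] == "lit"]
        i = rng.choice(leaves)
        old = _get(tree, i)
        new = ("lit", sampler(), old[2])
    elif kind == "polarity":
        leaves = [i for i, nd in nodes if nd[0] == "lit"]
        i = rng.choice(leaves)
        old = _get(tree, i)
        new = ("lit", old[1], 1 - old[2])
    elif kind == "operator":
        ops = [i for i, nd in nodes if nd[0] in ("and", "or")]
        if not ops:
            i = 0
            new = _random_literal(rng, sampler)
        else:
            i = rng.choice(ops)
            old = _get(tree, i)
            new = ("or" if old[0] == "and" else "and", *old[1:])
    elif kind == "extend":
        # wrap the whole program in a fresh conjunction / disjunction:
        # the shortest route from a good literal to a feature combination
        i = 0
        op = "and" if rng.random() < 0.5 else "or"
        new = (op, tree, _random_literal(rng, sampler))
    else:
        i = rng.randrange(size)
        new = _random_tree(rng, sampler, rng.randint(1, max(1, max_depth - 1)), "grow")
    return _truncate(_replace(tree, i, new), max_depth, rng, sampler)


def mutate(
    program: BooleanProgram | Tree,
    rng: random.Random,
    n_features: int | None = None,
    max_depth: int = 5,
) -> BooleanProgram:
    """One of: literal swap, polarity flip, operator flip, subtree
    replacement, or extension of the root by a fresh AND/OR with a new
    literal.  Structural invariants and the depth cap are preserved."""
    tree = program.tree if isinstance(program, BooleanProgram) else program
    if n_features is None:
        n_features = _max_feature(tree) + 1
    sampler = _uniform_sampler(rng, n_features)
    return BooleanProgram(_mutate_tree(tree, rng, sampler, n_features, max_depth))


def crossover(
    a: BooleanProgram | Tree,
    b: BooleanProgram | Tree,
    rng: random.Random,
    max_depth: int = 5,
) -> BooleanProgram:
    """Swap a uniformly chosen subtree of ``a`` with one of ``b``."""
    ta = a.tree if isinstance(a, BooleanProgram) else a
    tb = b.tree if isinstance(b, BooleanProgram) else b
    i = rng.randrange(_size(ta))
    donor = _get(tb, rng.randrange(_size(tb)))
    n_features = max(_max_feature(ta), _max_feature(tb)) + 1
    sampler = _uniform_sampler(rng, n_features)
    out = _truncate(_replace(ta, i, donor), max_depth, rng, sampler)
    return BooleanProgram(out)


# --- training loop ---------------------------------------------------------

def _init_population(
    rng: random.Random, n_features: int, params: GPParams, sampler
) -> list[Tree]:
    """Ramped half-and-half plus one single-literal program per feature."""
    pop: list[Tree] = [
        ("lit", j, 1) for j in range(min(n_features, params.population_size))
    ]
    depths = list(range(2, params.max_depth + 1)) or [1]
    i = 0
    while len(pop) < params.population_size:
        method = "grow" if i % 2 == 0 else "full"
        depth = depths[i % len(depths)]
        pop.append(_random_tree(rng, sampler, depth, method))
        i += 1
    return pop[: params.population_size]


def train_model(
    matrix_binary,
    labels01: np.ndarray,
    params: GPParams = GPParams(),
    *,
    task: str = "",
) -> TrainedModel:
    """Evolve a Boolean program predicting a binary label.

    Generational loop with tournament selection and elitism of one; the
    best-by-fitness program is returned.  Identical params (including
    seed) on identical data give an identical model.  Search stops early
    only when the elite is provably optimal (accuracy 1 with a single
    node, the fitness maximum for any parsimony penalty).
    """
    params.validate()
    labels01 = np.asarray(labels01)
    uniq, counts = np.unique(labels01, return_counts=True)
    if not set(uniq).issubset({0, 1}):
        raise ValueError("labels must be in {0,1}")
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 examples of each class")

    cols, n, full = matrix_to_masks(matrix_binary)
    n_features = len(cols)
    ymask = _labels_to_mask(labels01)
    lam = params.parsimony_lambda
    rng = random.Random(params.seed)

    cache: dict[Tree, tuple[float, int]] = {}

    def score(tree: Tree) -> tuple[float, float, int]:
        hit = cache.get(tree)
        if hit is None:
            out = _eval_mask(tree, cols, full)
            acc = (n - (out ^ ymask).bit_count()) / n
            size = _size(tree)
            cache[tree] = (acc, size)
        else:
            acc, size = hit
        return acc - lam * size, acc, size

    sampler = _biased_sampler(rng, n_features, params.feature_bias)
    pop = _init_population(rng, n_features, params, sampler)
    history: list[float] = []
    best_tree, best_fit, best_acc = None, -np.inf, 0.0

    for _gen in range(params.generations):
        scored = [score(t) for t in pop]
        gen_best = max(range(len(pop)), key=lambda i: scored[i][0])
        if scored[gen_best][0] > best_fit:
            best_fit, best_acc, _ = scored[gen_best]
            best_tree = pop[gen_best]
        history.append(best_fit)
        if best_acc == 1.0 and _size(best_tree) == 1:
            break

        def tournament() -> Tree:
            idx = [rng.randrange(len(pop)) for _ in range(params.tournament_size)]
            winner = max(idx, key=lambda i: (scored[i][0], -scored[i][2]))
            return pop[winner]

        nxt: list[Tree] = [best_tree]
        while len(nxt) < params.population_size:
            child = tournament()
            if rng.random() < params.crossover_rate:
                child = crossover(child, tournament(), rng, params.max_depth).tree
            if rng.random() < params.mutation_rate:
                child = _mutate_tree(child, rng, sampler, n_features, params.max_depth)
            nxt.append(child)
        pop = nxt

    return TrainedModel(
        program=BooleanProgram(best_tree),
        fitness=float(best_fit),
        accuracy=float(best_acc),
        seed=params.seed,
        task=task,
        elite_history=history,
    )
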