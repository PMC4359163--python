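"""Boolean regulatory networks: parsing, dynamics, fixed points, clamping.

A network is a set of named nodes, each carrying a logic update function
over the other nodes (``&``, ``|``, ``!``, parentheses, constants ``0``/``1``).
Node states are On/Off; the phenotypes of interest are the network's fixed
points (states mapped to themselves by a synchronous update), which are
identical under synchronous and asynchronous update schemes and therefore
scheme-independent.

Clamping a node (over-expression = clamp to 1, knock-down = clamp to 0)
overrides its update function; it is the formal counterpart of adding a
ligand or inhibiting a receptor kinase.

The text dialect follows the widely used BoolNet-style ``targets, factors``
format, e.g.::

    targets, factors
    A, A
    B, A & !C
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BooleanNetwork",
    "NetworkParseError",
    "NetworkValidationError",
    "CapacityError",
    "parse_network",
    "read_network",
    "step",
    "fixed_points",
    "clamp",
    "satisfies",
]

#: Exhaustive fixed-point search refuses networks above this size.
MAX_EXHAUSTIVE_NODES = 30

#: States are scanned in blocks of this many to bound memory.
_CHUNK_BITS = 20


class NetworkParseError(ValueError):
    """Raised when the equation text cannot be parsed."""


class NetworkValidationError(ValueError):
    """Raised when a structurally invalid network is constructed."""


class CapacityError(ValueError):
    """Raised when an exhaustive operation is asked for on an oversized network."""


# ---------------------------------------------------------------------------
# Expressions
# ---------------------------------------------------------------------------

# Expression AST: ("var", name) | ("const", 0 | 1) | ("not", e) |
# ("and", a, b) | ("or", a, b).  Tuples keep the AST hashable and
# structurally comparable, which the round-trip tests rely on.

_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)|(?P<const>[01])|(?P<op>[&|!()]))")


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None or match.end() == pos:
            remainder = text[pos:].strip()
            if not remainder:
                break
            raise NetworkParseError(f"unexpected character {remainder[0]!r} in expression {text!r}")
        if match.lastgroup == "name":
            tokens.append(("name", match.group("name")))
        elif match.lastgroup == "const":
            tokens.append(("const", match.group("const")))
        else:
            tokens.append(("op", match.group("op")))
        pos = match.end()
    return tokens


class _Parser:
    """Recursive-descent parser; precedence ``!`` > ``&`` > ``|``."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.index = 0

    def peek(self) -> tuple[str, str] | None:
        return self.tokens[self.index] if self.index < len(self.tokens) else None

    def next(self) -> tuple[str, str]:
        tok = self.peek()
        if tok is None:
            raise NetworkParseError(f"unexpected end of expression in {self.text!r}")
        self.index += 1
        return tok

    def parse(self) -> tuple:
        expr = self.parse_or()
        if self.peek() is not None:
            raise NetworkParseError(f"trailing tokens after expression in {self.text!r}")
        return expr

    def parse_or(self) -> tuple:
        left = self.parse_and()
        while self.peek() == ("op", "|"):
            self.next()
            left = ("or", left, self.parse_and())
        return left

    def parse_and(self) -> tuple:
        left = self.parse_not()
        while self.peek() == ("op", "&"):
            self.next()
            left = ("and", left, self.parse_not())
        return left

    def parse_not(self) -> tuple:
        tok = self.peek()
        if tok == ("op", "!"):
            self.next()
            return ("not", self.parse_not())
        return self.parse_atom()

    def parse_atom(self) -> tuple:
        kind, value = self.next()
        if kind == "name":
            return ("var", value)
        if kind == "const":
            return ("const", int(value))
        if (kind, value) == ("op", "("):
            expr = self.parse_or()
            if self.next() != ("op", ")"):
                raise NetworkParseError(f"missing ')' in {self.text!r}")
            return expr
        raise NetworkParseError(f"unexpected token {value!r} in {self.text!r}")


def parse_expression(text: str) -> tuple:
    """Parse a single Boolean expression into the tuple AST."""
    return _Parser(text).parse()


def expression_variables(expr: tuple) -> set[str]:
    op = expr[0]
    if op == "var":
        return {expr[1]}
    if op == "const":
        return set()
    out: set[str] = set()
    for child in expr[1:]:
        out |= expression_variables(child)
    return out


def expression_to_text(expr: tuple, parent: str = "or") -> str:
    """Serialize an AST with minimal parenthesisation."""
    op = expr[0]
    if op == "var":
        return expr[1]
    if op == "const":
        return str(expr[1])
    if op == "not":
        inner = expression_to_text(expr[1], parent="not")
        return f"!{inner}"
    sep = " & " if op == "and" else " | "
    text = sep.join(expression_to_text(child, parent=op) for child in expr[1:])
    needs_parens = (op == "or" and parent in ("and", "not")) or (op == "and" and parent == "not")
    return f"({text})" if needs_parens else text


def evaluate_expression(expr: tuple, env: Mapping[str, np.ndarray | bool]) -> np.ndarray | np.bool_:
    """Evaluate an AST over scalars or numpy boolean arrays (vectorized)."""
    op = expr[0]
    if op == "var":
        return np.asarray(env[expr[1]], dtype=bool) if not isinstance(env[expr[1]], np.ndarray) else env[expr[1]]
    if op == "const":
        return np.bool_(bool(expr[1]))
    if op == "not":
        return ~np.asarray(evaluate_expression(expr[1], env), dtype=bool)
    if op == "and":
        return np.asarray(evaluate_expression(expr[1], env), dtype=bool) & np.asarray(
            evaluate_expression(expr[2], env), dtype=bool
        )
    if op == "or":
        return np.asarray(evaluate_expression(expr[1], env), dtype=bool) | np.asarray(
            evaluate_expression(expr[2], env), dtype=bool
        )
    raise ValueError(f"unknown AST node {op!r}")


# ---------------------------------------------------------------------------
# Network container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BooleanNetwork:
    """An ordered collection of nodes with logic update functions.

    Parameters
    ----------
    nodes:
        Node names in declaration order.
    functions:
        One AST per node.  A node whose function is its own identity is an
        *input*: its value is a free boundary condition (a ligand that may
        or may not be present).
    clamps:
        Partial map node -> 0/1 overriding the node's function.
    metadata:
        Free-form annotations (e.g. provenance of a curated reconstruction).
    """

    nodes: tuple[str, ...]
    functions: Mapping[str, tuple]
    clamps: Mapping[str, int] = field(default_factory=dict)
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise NetworkValidationError("duplicate node names")
        missing = set(self.functions) - set(self.nodes)
        if missing:
            raise NetworkValidationError(f"functions for undeclared nodes: {sorted(missing)}")
        for node in self.nodes:
            if node not in self.functions:
                raise NetworkValidationError(f"node {node!r} has no update function")
            undeclared = expression_variables(self.functions[node]) - set(self.nodes)
            if undeclared:
                raise NetworkValidationError(
                    f"function of {node!r} references undeclared nodes {sorted(undeclared)}"
                )
        for node, value in self.clamps.items():
            if node not in set(self.nodes):
                raise NetworkValidationError(f"clamp on unknown node {node!r}")
            if value not in (0, 1):
                raise NetworkValidationError(f"clamp value for {node!r} must be 0 or 1")

    # -- structure ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def inputs(self) -> tuple[str, ...]:
        """Nodes whose function is their own identity (free boundary conditions)."""
        return tuple(n for n in self.nodes if self.functions[n] == ("var", n))

    def regulators(self, node: str) -> tuple[str, ...]:
        """Nodes appearing in ``node``'s update function, in node order."""
        used = expression_variables(self.functions[node])
        return tuple(n for n in self.nodes if n in used)

    def to_digraph(self):
        """Signed regulator graph as a :class:`networkx.DiGraph`.

        Edge attribute ``sign`` is +1/-1 for purely activating/inhibiting
        occurrences and 0 where a regulator appears under both polarities.
        """
        import networkx as nx

        graph = nx.DiGraph()
        graph.add_nodes_from(self.nodes)
        for node in self.nodes:
            if node in self.inputs:
                continue
            signs: dict[str, set[int]] = {}
            _collect_literal_signs(self.functions[node], +1, signs)
            for reg, polarity in signs.items():
                sign = polarity.pop() if len(polarity) == 1 else 0
                graph.add_edge(reg, node, sign=sign)
        return graph

    # -- serialization -----------------------------------------------------

    def to_text(self) -> str:
        """Serialize to the ``targets, factors`` dialect (clamps excluded)."""
        lines = ["targets, factors"]
        for node in self.nodes:
            lines.append(f"{node}, {expression_to_text(self.functions[node])}")
        return "\n".join(lines) + "\n"

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(self.to_text())

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_digraph(), path)

    def write_dot(self, path) -> None:
        graph = self.to_digraph()
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("digraph network {\n")
            for node in graph.nodes:
                handle.write(f'  "{node}";\n')
            for src, dst, data in graph.edges(data=True):
                color = {1: "black", -1: "green", 0: "gray"}[data.get("sign", 0)]
                handle.write(f'  "{src}" -> "{dst}" [color={color}];\n')
            handle.write("}\n")

    # -- dynamics ----------------------------------------------------------

    def step(self, state: Mapping[str, int]) -> dict[str, int]:
        """One synchronous update; clamped nodes keep their clamp value."""
        missing = set(self.nodes) - set(state)
        if missing:
            raise NetworkValidationError(f"state is not total; missing {sorted(missing)}")
        env = {n: np.bool_(bool(state[n])) for n in self.nodes}
        out: dict[str, int] = {}
        for node in self.nodes:
            if node in self.clamps:
                out[node] = int(self.clamps[node])
            else:
                out[node] = int(bool(evaluate_expression(self.functions[node], env)))
        return out

    def fixed_points(self) -> list[dict[str, int]]:
        """All states ``s`` with ``step(s) == s``, by exhaustive scan.

        Fixed points are independent of the update scheme, so the result is
        valid for synchronous and asynchronous semantics alike.  States are
        returned in deterministic (lexicographic over node order) order.
        """
        n = self.n_nodes
        if n > MAX_EXHAUSTIVE_NODES:
            raise CapacityError(
                f"exhaustive fixed-point scan limited to {MAX_EXHAUSTIVE_NODES} nodes; got {n}"
            )
        result: list[dict[str, int]] = []
        for indices in _fixed_point_indices(self):
            for index in indices:
                result.append(self._state_from_index(int(index)))
        return result

    def _state_from_index(self, index: int) -> dict[str, int]:
        # Bit j of the index is the value of nodes[j].
        return {node: (index >> j) & 1 for j, node in enumerate(self.nodes)}

    def state_index(self, state: Mapping[str, int]) -> int:
        index = 0
        for j, node in enumerate(self.nodes):
            if state[node]:
                index |= 1 << j
        return index

    # -- perturbations -----------------------------------------------------

    def clamp(self, perturbations: Mapping[str, int]) -> "BooleanNetwork":
        """Copy of the network with ``perturbations`` merged into the clamps.

        Raises on a node mapped to conflicting values.
        """
        merged = dict(self.clamps)
        for node, value in perturbations.items():
            if value not in (0, 1):
                raise NetworkValidationError(f"clamp value for {node!r} must be 0 or 1")
            if node in merged and merged[node] != value:
                raise NetworkValidationError(f"conflicting clamp on {node!r}")
            merged[node] = int(value)
        return BooleanNetwork(self.nodes, dict(self.functions), merged, dict(self.metadata))

    def unclamped(self) -> "BooleanNetwork":
        """Copy of the network with all clamps removed."""
        return BooleanNetwork(self.nodes, dict(self.functions), {}, dict(self.metadata))


def _collect_literal_signs(expr: tuple, polarity: int, out: dict[str, set[int]]) -> None:
    op = expr[0]
    if op == "var":
        out.setdefault(expr[1], set()).add(polarity)
    elif op == "not":
        _collect_literal_signs(expr[1], -polarity, out)
    elif op in ("and", "or"):
        for child in expr[1:]:
            _collect_literal_signs(child, polarity, out)


def _fixed_point_indices(network: BooleanNetwork) -> Iterator[np.ndarray]:
    """Yield arrays of state indices that are fixed points, in ascending order.

    The scan is chunked and vectorized: for each chunk of state indices the
    per-node current values are the index bits, and a state is a fixed point
    iff every free node's function reproduces its bit and every clamped
    node's bit equals its clamp.
    """
    n = network.n_nodes
    total = 1 << n
    chunk = 1 << min(n, _CHUNK_BITS)
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total), dtype=np.int64)
        bits = {node: ((idx >> j) & 1).astype(bool) for j, node in enumerate(network.nodes)}
        mask = np.ones(idx.shape, dtype=bool)
        for node in network.nodes:
            if node in network.clamps:
                mask &= bits[node] == bool(network.clamps[node])
            else:
                nxt = evaluate_expression(network.functions[node], bits)
                nxt = np.broadcast_to(np.asarray(nxt, dtype=bool), idx.shape)
                mask &= nxt == bits[node]
            if not mask.any():
                break
        yield idx[mask]


# ---------------------------------------------------------------------------
# Truth-table cache (shared by the intervention-set solvers)
# ---------------------------------------------------------------------------


class TruthTableCache:
    """Precomputed synchronous-update tables for fast clamped fixed-point queries.

    For a network of ``n`` (<= ~22) nodes the unclamped next-state value of
    every node over all ``2**n`` states is computed once; fixed points under
    any clamp assignment are then pure boolean-array algebra, which is what
    makes enumerating thousands of candidate intervention sets tractable.
    """

    def __init__(self, network: BooleanNetwork, max_nodes: int = 24):
        base = network.unclamped()
        if base.n_nodes > max_nodes:
            raise CapacityError(
                f"truth-table cache limited to {max_nodes} nodes; got {base.n_nodes}"
            )
        self.network = base
        idx = np.arange(1 << base.n_nodes, dtype=np.int64)
        self._bits = {
            node: ((idx >> j) & 1).astype(bool) for j, node in enumerate(base.nodes)
        }
        self._next = {}
        for node in base.nodes:
            table = evaluate_expression(base.functions[node], self._bits)
            self._next[node] = np.broadcast_to(np.asarray(table, dtype=bool), idx.shape)

    def fixed_point_mask(self, clamps: Mapping[str, int]) -> np.ndarray:
        mask = np.ones(1 << self.network.n_nodes, dtype=bool)
        for node in self.network.nodes:
            if node in clamps:
                mask &= self._bits[node] == bool(clamps[node])
            else:
                mask &= self._next[node] == self._bits[node]
        return mask

    def node_values(self, node: str) -> np.ndarray:
        """Current-state bit of ``node`` for every state index."""
        return self._bits[node]


# ---------------------------------------------------------------------------
# Module-level operations (spec surface)
# ---------------------------------------------------------------------------


def parse_network(text: str) -> BooleanNetwork:
    """Parse a ``targets, factors`` equation listing into a network.

    One equation per line, ``target, expression``.  Lines that are empty or
    start with ``#`` are skipped, as is an optional ``targets, factors``
    header.  Symbols used but never declared become input nodes with
    self-identity functions (logged).
    """
    functions: dict[str, tuple] = {}
    order: list[str] = []
    for lineno, raw in enumerate(io.StringIO(text), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "," not in line:
            raise NetworkParseError(f"line {lineno}: expected 'target, expression'")
        target, _, rhs = line.partition(",")
        target = target.strip()
        rhs = rhs.strip()
        if lineno == 1 or not order:
            if target.lower() == "targets" and rhs.lower() == "factors":
                continue
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", target):
            raise NetworkParseError(f"line {lineno}: invalid target name {target!r}")
        if target in functions:
            raise NetworkValidationError(f"line {lineno}: duplicate target {target!r}")
        try:
            functions[target] = parse_expression(rhs)
        except NetworkParseError as exc:
            raise NetworkParseError(f"line {lineno}: {exc}") from exc
        order.append(target)
    if not order:
        raise NetworkParseError("no equations found")
    declared = set(order)
    undeclared: list[str] = []
    for target in order:
        for symbol in sorted(expression_variables(functions[target])):
            if symbol not in declared and symbol not in undeclared:
                undeclared.append(symbol)
    for symbol in undeclared:
        logger.info("undeclared symbol %r becomes an input node", symbol)
        functions[symbol] = ("var", symbol)
    return BooleanNetwork(tuple(order) + tuple(undeclared), functions)


def read_network(path) -> BooleanNetwork:
    with open(path, "r", encoding="utf-8") as handle:
        return parse_network(handle.read())


def step(network: BooleanNetwork, state: Mapping[str, int]) -> dict[str, int]:
    return network.step(state)


def fixed_points(network: BooleanNetwork) -> list[dict[str, int]]:
    return network.fixed_points()


def clamp(network: BooleanNetwork, perturbations: Mapping[str, int]) -> BooleanNetwork:
    return network.clamp(perturbations)


def satisfies(state: Mapping[str, int], constraint: Mapping[str, int]) -> bool:
    """True iff every node required by the partial steady-state constraint matches."""
    unknown = set(constraint) - set(state)
    if unknown:
        raise NetworkValidationError(f"constraint references nodes absent from state: {sorted(unknown)}")
    return all(int(state[node]) == int(value) for node, value in constraint.items())
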