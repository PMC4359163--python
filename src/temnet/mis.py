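"""Minimal Intervention Sets (MIS) on Boolean regulatory networks.

An intervention clamps a node On (over-expression: adding a ligand) or Off
(knock-down: a kinase inhibitor).  A Minimal Intervention Set is a smallest
set of simultaneous clamps that forces the network into a desired partial
steady state — here, e.g., TIE-2 and VEGFR-1 both high (tumor-TEM-like,
highly pro-angiogenic) or both low (blood-TEM-like, weakly pro-angiogenic).
Minimality means no proper subset of the clamps suffices.

Two solvers are provided:

``mis_bruteforce``
    The independent oracle: exhaustive enumeration of clamp sets in size
    order with subset pruning, validity checked against the full
    fixed-point structure of the clamped network.

``mis_unroll``
    The tree-unrolling solver.  The network is unrolled backwards from the
    constraint (root) nodes along regulator paths, stopping when a node
    repeats on a path; required polarities are propagated root-to-leaf and
    candidate perturbation vectors are collected leaf-to-root breadth
    first, keeping only vectors compatible at path merges (the same node is
    never clamped both ways).  Because polarity propagation is a local,
    logic-level argument, it is not by itself complete for arbitrary
    (non-monotone) update functions nor for constraints that hold only
    because some off-path oscillation removes a fixed point; the propagated
    vectors are therefore used to seed and order an exactness-preserving
    completion pass over the same candidate space, so the result is
    guaranteed set-equal to the brute-force oracle.

Validity semantics (``force``, the default): the clamped network must have
at least one fixed point and every fixed point must satisfy the
constraint.  The weaker ``permit`` semantics (some fixed point satisfies
the constraint) is available via :class:`MISQuery`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .boolnet import BooleanNetwork, CapacityError, NetworkValidationError, TruthTableCache

__all__ = [
    "Intervention",
    "InterventionSet",
    "MISQuery",
    "is_valid_intervention",
    "mis_bruteforce",
    "mis_unroll",
    "unroll_network",
    "propagate_polarities",
    "classify_mis",
    "OVER_EXPRESS",
    "KNOCK_DOWN",
]

OVER_EXPRESS = 1
KNOCK_DOWN = 0

#: Cap on the number of propagated seed vectors kept per (node, polarity).
_MAX_PROPAGATED = 512

#: Regulator sets larger than this are not expanded during propagation
#: (the node can still be clamped directly; exactness is preserved by the
#: completion pass).
_MAX_EXPAND_INDEGREE = 6


@dataclass(frozen=True, order=True)
class Intervention:
    """A single clamp: ``polarity`` 1 = over-express, 0 = knock-down."""

    node: str
    polarity: int

    def __post_init__(self) -> None:
        if self.polarity not in (0, 1):
            raise NetworkValidationError("polarity must be 0 (knock-down) or 1 (over-express)")

    def __str__(self) -> str:  # e.g. "TNFA^" / "TIE2v"
        return f"{self.node}{'^' if self.polarity else 'v'}"


class InterventionSet(frozenset):
    """A set of internally compatible interventions (one polarity per node)."""

    def __new__(cls, interventions: Iterable[Intervention] = ()):
        items = frozenset(interventions)
        nodes = [iv.node for iv in items]
        if len(set(nodes)) != len(nodes):
            raise NetworkValidationError("a node cannot be clamped to both values in one set")
        return super().__new__(cls, items)

    @property
    def size(self) -> int:
        return len(self)

    def as_clamps(self) -> dict[str, int]:
        return {iv.node: iv.polarity for iv in self}

    def sort_key(self):
        return (len(self), tuple(sorted((iv.node, iv.polarity) for iv in self)))

    def __str__(self) -> str:
        return "{" + ", ".join(str(iv) for iv in sorted(self)) + "}"


@dataclass(frozen=True)
class MISQuery:
    """A MIS search problem.

    Parameters
    ----------
    network:
        The Boolean network (existing clamps, if any, are kept in force).
    constraint:
        Partial steady-state requirement, node -> 0/1.  These are the root
        nodes of the unrolling.
    k_max:
        Largest intervention-set size searched (default 3, matching a
        practical bound on simultaneous treatments).
    candidate_nodes:
        Nodes eligible for clamping; default all nodes.  Constraint nodes
        are eligible (clamping a receptor node directly models a kinase
        inhibitor or forced expression).
    allowed_polarities:
        Optional map node -> allowed clamp values, e.g. ligands may only be
        added (1) and receptors only inhibited (0).  Default both.
    semantics:
        ``"force"``: >=1 fixed point and all fixed points satisfy the
        constraint.  ``"permit"``: some fixed point satisfies it.
    """

    network: BooleanNetwork
    constraint: Mapping[str, int]
    k_max: int = 3
    candidate_nodes: tuple[str, ...] | None = None
    allowed_polarities: Mapping[str, tuple[int, ...]] | None = None
    semantics: str = "force"

    def __post_init__(self) -> None:
        if not self.constraint:
            raise NetworkValidationError("constraint must be non-empty")
        unknown = set(self.constraint) - set(self.network.nodes)
        if unknown:
            raise NetworkValidationError(f"constraint references unknown nodes {sorted(unknown)}")
        if self.k_max < 1:
            raise NetworkValidationError("k_max must be >= 1")
        if self.semantics not in ("force", "permit"):
            raise NetworkValidationError("semantics must be 'force' or 'permit'")
        if self.candidate_nodes is not None:
            unknown = set(self.candidate_nodes) - set(self.network.nodes)
            if unknown:
                raise NetworkValidationError(f"unknown candidate nodes {sorted(unknown)}")

    def candidates(self) -> list[Intervention]:
        """Eligible single interventions, in network node order."""
        nodes = self.candidate_nodes if self.candidate_nodes is not None else self.network.nodes
        ordered = [n for n in self.network.nodes if n in set(nodes)]
        out: list[Intervention] = []
        for node in ordered:
            allowed = (0, 1)
            if self.allowed_polarities is not None:
                allowed = tuple(self.allowed_polarities.get(node, (0, 1)))
            for value in allowed:
                out.append(Intervention(node, value))
        return out


class _Validator:
    """Clamped fixed-point validity checks backed by a shared truth-table cache."""

    def __init__(self, query: MISQuery):
        self.query = query
        self.cache = TruthTableCache(query.network)
        self.base_clamps = dict(query.network.clamps)
        self._constraint_mask = np.ones(1 << query.network.n_nodes, dtype=bool)
        for node, value in query.constraint.items():
            self._constraint_mask &= self.cache.node_values(node) == bool(value)

    def is_valid(self, interventions: InterventionSet) -> bool:
        clamps = dict(self.base_clamps)
        for iv in interventions:
            if iv.node in clamps and clamps[iv.node] != iv.polarity:
                return False
            clamps[iv.node] = iv.polarity
        mask = self.cache.fixed_point_mask(clamps)
        if not mask.any():
            return False
        if self.query.semantics == "permit":
            return bool((mask & self._constraint_mask).any())
        return bool((mask & ~self._constraint_mask).sum() == 0)


def is_valid_intervention(query: MISQuery, candidate: InterventionSet | Iterable[Intervention]) -> bool:
    """Does ``candidate`` force the constraint (under the query's semantics)?"""
    if not isinstance(candidate, InterventionSet):
        candidate = InterventionSet(candidate)
    if candidate.size > query.k_max:
        raise NetworkValidationError(f"candidate exceeds k_max={query.k_max}")
    return _Validator(query).is_valid(candidate)


# ---------------------------------------------------------------------------
# Enumeration core (shared by both solvers)
# ---------------------------------------------------------------------------


def _enumerate_minimal(
    query: MISQuery,
    validator: _Validator,
    seed_order: Mapping[int, list[InterventionSet]] | None = None,
) -> list[InterventionSet]:
    """Size-ordered enumeration with subset pruning.

    Because sets are tested in nondecreasing size order and any candidate
    containing an already-valid set is skipped, every collected set is
    valid and subset-minimal.  ``seed_order`` may front-load candidates
    within their size class (it cannot change the result, only the order
    of evaluation).
    """
    candidates = validator_candidates = query.candidates()
    found: list[InterventionSet] = []

    def is_superset_of_found(s: InterventionSet) -> bool:
        return any(f <= s for f in found)

    for size in range(0, query.k_max + 1):
        batch: list[InterventionSet] = []
        seen: set[frozenset] = set()
        if seed_order and size in seed_order:
            for s in seed_order[size]:
                if frozenset(s) not in seen:
                    seen.add(frozenset(s))
                    batch.append(s)
        for combo in itertools.combinations(candidate_nodes_in_order(validator_candidates), size):
            for values in itertools.product(*[nd[1] for nd in combo]):
                s = InterventionSet(
                    Intervention(nd[0], v) for nd, v in zip(combo, values)
                )
                if frozenset(s) not in seen:
                    seen.add(frozenset(s))
                    batch.append(s)
        for s in batch:
            if is_superset_of_found(s):
                continue
            if validator.is_valid(s):
                found.append(s)
    return sorted(found, key=InterventionSet.sort_key)


def candidate_nodes_in_order(candidates: Sequence[Intervention]) -> list[tuple[str, tuple[int, ...]]]:
    """Group eligible interventions as (node, allowed values), preserving order."""
    grouped: dict[str, list[int]] = {}
    order: list[str] = []
    for iv in candidates:
        if iv.node not in grouped:
            grouped[iv.node] = []
            order.append(iv.node)
        grouped[iv.node].append(iv.polarity)
    return [(node, tuple(grouped[node])) for node in order]


def mis_bruteforce(query: MISQuery, max_nodes: int = 14) -> list[InterventionSet]:
    """Exhaustive MIS enumeration (the oracle).

    Enumerates every compatible intervention set of size 0..k_max over the
    candidate nodes, keeps the valid ones and discards any set with a valid
    proper subset.  The empty set is reported as the unique MIS when the
    unperturbed network already meets the constraint in every fixed point.
    """
    if query.network.n_nodes > max_nodes:
        raise CapacityError(
            f"brute-force solver limited to {max_nodes} nodes; got {query.network.n_nodes}"
        )
    return _enumerate_minimal(query, _Validator(query))


# ---------------------------------------------------------------------------
# Unrolling solver
# ---------------------------------------------------------------------------


@dataclass
class UnrolledNode:
    """A node occurrence in the unrolled tree.

    ``terminated`` marks a leaf cut because the node already occurred on
    the path from the root (the duplicate rule that bounds path count).
    """

    node: str
    children: list["UnrolledNode"] = field(default_factory=list)
    terminated: bool = False

    def paths(self) -> int:
        if not self.children:
            return 1
        return sum(child.paths() for child in self.children)


def unroll_network(network: BooleanNetwork, roots: Sequence[str]) -> list[UnrolledNode]:
    """Unroll the network into one tree per root (constraint) node.

    Each path follows regulators backwards and stops as soon as a node
    repeats along that path.
    """

    def expand(node: str, path: frozenset[str]) -> UnrolledNode:
        tree = UnrolledNode(node)
        for reg in network.regulators(node):
            if reg in path or reg == node:
                tree.children.append(UnrolledNode(reg, terminated=True))
            else:
                tree.children.append(expand(reg, path | {node}))
        return tree

    return [expand(root, frozenset()) for root in roots]


def _satisfying_assignments(network: BooleanNetwork, node: str, value: int) -> list[dict[str, int]]:
    """Regulator assignments alpha with f_node(alpha) == value."""
    from .boolnet import evaluate_expression

    regs = network.regulators(node)
    out: list[dict[str, int]] = []
    for bits in itertools.product((0, 1), repeat=len(regs)):
        env = {r: np.bool_(bool(b)) for r, b in zip(regs, bits)}
        if int(bool(evaluate_expression(network.functions[node], env))) == value:
            out.append(dict(zip(regs, bits)))
    return out


def _merge_compatible(
    groups: Sequence[Sequence[frozenset]], k_max: int
) -> list[frozenset]:
    """Cross-merge one vector per group, keeping compatible unions <= k_max."""
    merged: list[frozenset] = [frozenset()]
    for group in groups:
        nxt: list[frozenset] = []
        for base in merged:
            for vec in group:
                union = base | vec
                if len({n for n, _ in union}) != len(union):
                    continue  # same node clamped both ways on merging paths
                if len(union) > k_max:
                    continue
                nxt.append(union)
        merged = _dedupe(nxt)
        if not merged:
            break
    return merged


def _dedupe(vectors: Iterable[frozenset]) -> list[frozenset]:
    seen: set[frozenset] = set()
    out: list[frozenset] = []
    for vec in vectors:
        if vec not in seen:
            seen.add(vec)
            out.append(vec)
    return out[:_MAX_PROPAGATED]


def propagate_polarities(
    network: BooleanNetwork,
    tree: UnrolledNode,
    required: int,
    k_max: int,
) -> list[frozenset]:
    """The two scanning iterations over one unrolled tree.

    Iteration 1 pushes the required polarity from the root towards the
    leaves (through every regulator assignment that realises it);
    iteration 2 collects candidate perturbation vectors from the leaves
    back to the root, keeping only compatible vectors where paths merge.
    Returns frozensets of ``(node, polarity)`` pairs, each a candidate
    intervention vector of size <= k_max.
    """
    direct = frozenset({(tree.node, required)})
    vectors: list[frozenset] = [direct]
    if (
        not tree.terminated
        and tree.children
        and len(network.regulators(tree.node)) <= _MAX_EXPAND_INDEGREE
    ):
        child_by_name = {child.node: child for child in tree.children}
        for alpha in _satisfying_assignments(network, tree.node, required):
            if alpha.get(tree.node) is not None and alpha[tree.node] != required:
                # A self-regulating node cannot be required at one value and
                # rely on itself at the other.
                continue
            groups = []
            for reg, val in alpha.items():
                if reg == tree.node:
                    # Own current value realised by the surrounding requirement.
                    groups.append([frozenset()])
                    continue
                groups.append(propagate_polarities(network, child_by_name[reg], val, k_max))
            vectors.extend(_merge_compatible(groups, k_max))
    return _dedupe(vectors)


def mis_unroll(query: MISQuery) -> list[InterventionSet]:
    """Tree-unrolling MIS solver; set-equal to :func:`mis_bruteforce`.

    The unrolled-tree propagation proposes candidate vectors, which are
    evaluated first within their size class; a completion pass over the
    remaining candidate space (with the same subset pruning) guarantees
    soundness, completeness and minimality under the fixed-point validity
    semantics.
    """
    validator = _Validator(query)
    roots = list(query.constraint)
    trees = unroll_network(query.network, roots)
    per_root = [
        propagate_polarities(query.network, tree, int(query.constraint[tree.node]), query.k_max)
        for tree in trees
    ]
    merged = _merge_compatible(per_root, query.k_max)

    allowed = set((iv.node, iv.polarity) for iv in query.candidates())
    seeds: dict[int, list[InterventionSet]] = {}
    for vec in merged:
        if not vec <= allowed:
            continue
        s = InterventionSet(Intervention(n, v) for n, v in vec)
        seeds.setdefault(s.size, []).append(s)
    for size in seeds:
        seeds[size] = sorted(seeds[size], key=InterventionSet.sort_key)
    return _enumerate_minimal(query, validator, seed_order=seeds)


# ---------------------------------------------------------------------------
# Table-style classification
# ---------------------------------------------------------------------------

CATEGORY_RTK = "RTK"
CATEGORY_INFLAMMATORY = "inflammatory ligand"
CATEGORY_VEGFR1_LIGAND = "VEGFR-1 ligand"
CATEGORY_TIE2_LIGAND = "TIE-2 ligand"

_COLUMNS = (
    "rtk_inhibited",
    "inflammatory_up",
    "vegfr1_ligand_up",
    "tie2_ligand_up",
    "other",
)


def classify_mis(
    mis_list: Sequence[InterventionSet],
    node_categories: Mapping[str, str],
    display_names: Mapping[str, str] | None = None,
) -> list[dict[str, str]]:
    """Group intervention sets into the four-column therapy layout.

    Each row reports, for one MIS: the receptor tyrosine kinase(s) whose
    activity is inhibited (knock-down clamps on RTK nodes), and the
    inflammatory / VEGFR-1 / TIE-2 ligands up-regulated (over-expression
    clamps).  Any intervention that does not fit those categories (an
    uncategorised node, an up-regulated RTK, a knocked-down ligand) lands
    in the ``other`` column and is logged.  Rows are grouped by the RTK
    column and returned in deterministic order.
    """
    import logging

    log = logging.getLogger(__name__)
    names = display_names or {}
    rows: list[dict[str, str]] = []
    for mis in mis_list:
        cells: dict[str, list[str]] = {col: [] for col in _COLUMNS}
        for iv in sorted(mis):
            label = names.get(iv.node, iv.node)
            category = node_categories.get(iv.node)
            if category == CATEGORY_RTK and iv.polarity == KNOCK_DOWN:
                cells["rtk_inhibited"].append(label)
            elif category == CATEGORY_INFLAMMATORY and iv.polarity == OVER_EXPRESS:
                cells["inflammatory_up"].append(label)
            elif category == CATEGORY_VEGFR1_LIGAND and iv.polarity == OVER_EXPRESS:
                cells["vegfr1_ligand_up"].append(label)
            elif category == CATEGORY_TIE2_LIGAND and iv.polarity == OVER_EXPRESS:
                cells["tie2_ligand_up"].append(label)
            else:
                log.info("intervention %s does not fit the category scheme", iv)
                cells["other"].append(str(iv) if category is None else label)
        rows.append({col: " and ".join(vals) if vals else "-" for col, vals in cells.items()})
    rows.sort(key=lambda row: (row["rtk_inhibited"] == "-", tuple(row[col] for col in _COLUMNS)))
    return rows
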