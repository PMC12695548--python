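"""Causal DAG representation, d-separation and backdoor adjustment sets.

The study's causal question — which covariates must be conditioned on to
estimate the effect of an exposure (e.g. body fat) on hair cortisol — is
answered with Pearl's backdoor criterion: a set Z is a valid adjustment set
when it contains no descendant of the exposure and blocks every path into
the exposure (equivalently, d-separates exposure and outcome in the graph
with the exposure's outgoing edges removed).  When no subset of *observed*
variables does this, the effect is unidentifiable from the data.

The shipped study DAG (``study_dag``) is a reconstruction: only the
study's adjustment sets and its two unidentifiable exposures are public
constraints, so the graph here is built to reproduce exactly those — the
adjustment sets of all eight causal models, and unidentifiability of
'weight_loss_success' and 'visit'.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from itertools import combinations
from typing import FrozenSet, List, Optional, Set, Tuple

import networkx as nx


class DAGError(ValueError):
    pass


@dataclass(frozen=True)
class CausalDAG:
    nodes: FrozenSet[str]
    edges: FrozenSet[Tuple[str, str]]
    observed: FrozenSet[str]
    exposure: Optional[str] = None
    outcome: Optional[str] = None

    def __post_init__(self):
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise DAGError(f"edge ({u}, {v}) uses an undeclared node")
        if not self.observed <= self.nodes:
            raise DAGError("observed must be a subset of nodes")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise DAGError("graph contains a cycle")
        if self.exposure is not None and self.exposure == self.outcome:
            raise DAGError("exposure and outcome must differ")
        for role, node in (("exposure", self.exposure), ("outcome", self.outcome)):
            if node is not None and node not in self.nodes:
                raise DAGError(f"{role} {node!r} is not a node")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def with_roles(self, exposure: str, outcome: str) -> "CausalDAG":
        return replace(self, exposure=exposure, outcome=outcome)

    @property
    def unobserved(self) -> FrozenSet[str]:
        return self.nodes - self.observed


@dataclass(frozen=True)
class AdjustmentResult:
    identifiable: bool
    sets: Tuple[FrozenSet[str], ...]
    blocking_failure: str = ""

    def __post_init__(self):
        assert self.identifiable == (len(self.sets) > 0)


def is_d_separated(dag: CausalDAG, a: str, b: str, conditioning: Set[str]) -> bool:
    """True iff every path between ``a`` and ``b`` is blocked given the set.

    Blocking follows the usual rules: a chain or fork is blocked when its
    middle node is conditioned on; a collider is blocked unless it, or one
    of its descendants, is conditioned on.
    """
    conditioning = set(conditioning)
    for n in {a, b} | conditioning:
        if n not in dag.nodes:
            raise DAGError(f"unknown node {n!r}")
    if a in conditioning or b in conditioning:
        raise DAGError("conditioning set must exclude the endpoint nodes")
    return nx.is_d_separator(dag.graph(), {a}, {b}, conditioning)


def _satisfies_backdoor(g: nx.DiGraph, x: str, y: str, z: Set[str], desc_x: Set[str]) -> bool:
    if z & desc_x:
        return False
    g_back = g.copy()
    g_back.remove_edges_from(list(g.out_edges(x)))
    return nx.is_d_separator(g_back, {x}, {y}, set(z))


def backdoor_sets(dag: CausalDAG, max_size: Optional[int] = None) -> AdjustmentResult:
    """Enumerate minimal observed backdoor adjustment sets for the DAG's roles.

    Returns all minimal (no valid proper subset) sets of observed
    non-descendants of the exposure, sorted by size then lexicographically.
    When no observed subset closes every backdoor path the effect is
    declared unidentifiable.
    """
    if dag.exposure is None or dag.outcome is None:
        raise DAGError("exposure and outcome must be set")
    x, y = dag.exposure, dag.outcome
    g = dag.graph()
    desc_x = nx.descendants(g, x) | {x}
    candidates = sorted(dag.observed - desc_x - {y})
    if max_size is None:
        max_size = len(candidates)

    minimal: List[FrozenSet[str]] = []
    for size in range(0, max_size + 1):
        for combo in combinations(candidates, size):
            z = frozenset(combo)
            if any(m <= z for m in minimal):
                continue
            if _satisfies_backdoor(g, x, y, set(z), desc_x):
                minimal.append(z)
    minimal.sort(key=lambda s: (len(s), tuple(sorted(s))))
    if minimal:
        return AdjustmentResult(True, tuple(minimal))
    # describe failure: open backdoor paths necessarily run through
    # unobserved ancestors of the exposure
    culprits = sorted(
        n for n in dag.unobserved if n in nx.ancestors(g, x) or (n, x) in dag.edges
    )
    msg = (
        f"no observed subset blocks all backdoor paths from {x!r} to {y!r}; "
        f"unobserved variables on open paths: {culprits}"
    )
    return AdjustmentResult(False, (), msg)


# ---------------------------------------------------------------------------
# plain-text DAG config format
# ---------------------------------------------------------------------------


def parse_dag(text: str) -> CausalDAG:
    """Parse the plain-text DAG format.

    One ``parent -> child`` per line, plus ``observed:`` / ``unobserved:`` /
    ``exposure:`` / ``outcome:`` header lines.  ``#`` starts a comment.
    """
    edges, observed, unobserved = set(), set(), set()
    exposure = outcome = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("observed:"):
            observed |= set(line.split(":", 1)[1].split())
        elif line.startswith("unobserved:"):
            unobserved |= set(line.split(":", 1)[1].split())
        elif line.startswith("exposure:"):
            exposure = line.split(":", 1)[1].strip() or None
        elif line.startswith("outcome:"):
            outcome = line.split(":", 1)[1].strip() or None
        elif "->" in line:
            u, v = (s.strip() for s in line.split("->", 1))
            edges.add((u, v))
        else:
            raise DAGError(f"cannot parse line: {raw!r}")
    nodes = observed | unobserved | {n for e in edges for n in e}
    return CausalDAG(
        nodes=frozenset(nodes),
        edges=frozenset(edges),
        observed=frozenset(observed or nodes),
        exposure=exposure,
        outcome=outcome,
    )


def load_dag(path) -> CausalDAG:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_dag(fh.read())


def study_dag(exposure: Optional[str] = None, outcome: str = "hcc") -> CausalDAG:
    """The reconstructed study DAG, optionally with roles assigned.

    For the reverse-causality question use :func:`reverse_study_dag`.
    """
    text = resources.files("canicort.data").joinpath("study_dag.txt").read_text()
    dag = parse_dag(text)
    if exposure is not None:
        dag = dag.with_roles(exposure, outcome)
    return dag


def reverse_study_dag() -> CausalDAG:
    """Study DAG with the body_fat -> hcc arrow reversed (reverse causality)."""
    dag = study_dag()
    edges = (set(dag.edges) - {("body_fat", "hcc")}) | {("hcc", "body_fat")}
    return replace(dag, edges=frozenset(edges), exposure="hcc", outcome="body_fat")
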