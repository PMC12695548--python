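"""DAG engine: d-separation vs a brute-force path oracle, backdoor sets."""

import itertools

import numpy as np
import pytest

from canicort.dag import (
    AdjustmentResult,
    CausalDAG,
    DAGError,
    backdoor_sets,
    is_d_separated,
    parse_dag,
    reverse_study_dag,
    study_dag,
)


def make_dag(edges, observed=None, exposure=None, outcome=None, nodes=None):
    if nodes is None:
        nodes = {n for e in edges for n in e}
    if observed is None:
        observed = nodes
    return CausalDAG(
        nodes=frozenset(nodes),
        edges=frozenset(edges),
        observed=frozenset(observed),
        exposure=exposure,
        outcome=outcome,
    )


# ---------------------------------------------------------------------------
# brute-force oracles, independent of the implementation
# ---------------------------------------------------------------------------


def _descendants(edges, x):
    out, stack = set(), [x]
    while stack:
        n = stack.pop()
        for u, v in edges:
            if u == n and v not in out:
                out.add(v)
                stack.append(v)
    return out


def _all_paths(nodes, edges, a, b):
    """All simple undirected paths a..b as node sequences."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    paths, stack = [], [(a, [a])]
    while stack:
        n, path = stack.pop()
        if n == b:
            paths.append(path)
            continue
        for nxt in adj[n]:
            if nxt not in path:
                stack.append((nxt, path + [nxt]))
    return paths


def brute_force_d_separated(nodes, edges, a, b, z):
    """Apply the chain/fork/collider blocking rules to every path."""
    for path in _all_paths(nodes, edges, a, b):
        blocked = False
        for i in range(1, len(path) - 1):
            prev, mid, nxt = path[i - 1], path[i], path[i + 1]
            into_left = (prev, mid) in edges
            into_right = (nxt, mid) in edges
            if into_left and into_right:  # collider
                if mid not in z and not (_descendants(edges, mid) & z):
                    blocked = True
                    break
            else:  # chain or fork
                if mid in z:
                    blocked = True
                    break
        if not blocked:
            return False
    return True


def brute_force_backdoor(dag):
    """Test every subset of observed nodes with the d-separation oracle on
    the exposure-outgoing-edge-deleted graph."""
    x, y = dag.exposure, dag.outcome
    desc = _descendants(dag.edges, x) | {x}
    candidates = sorted(dag.observed - desc - {y})
    trimmed = {(u, v) for u, v in dag.edges if u != x}
    valid = []
    for r in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, r):
            z = set(combo)
            if brute_force_d_separated(dag.nodes, trimmed, x, y, z):
                valid.append(frozenset(z))
    minimal = [s for s in valid if not any(t < s for t in valid)]
    return sorted(minimal, key=lambda s: (len(s), tuple(sorted(s))))


def random_dag(rng, n_nodes=6, p_edge=0.35):
    names = [f"n{i}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    edges = set()
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.uniform() < p_edge:
                edges.add((names[order[i]], names[order[j]]))
    nodes = set(names)
    return nodes, edges


# ---------------------------------------------------------------------------
# d-separation
# ---------------------------------------------------------------------------


def test_chain_blocked_by_middle_node():
    dag = make_dag([("A", "B"), ("B", "C")])
    assert is_d_separated(dag, "A", "C", {"B"})
    assert not is_d_separated(dag, "A", "C", set())


def test_collider_rules():
    dag = make_dag([("A", "B"), ("C", "B")])
    assert is_d_separated(dag, "A", "C", set())
    assert not is_d_separated(dag, "A", "C", {"B"})


def test_conditioning_on_collider_descendant_opens_path():
    dag = make_dag([("A", "B"), ("C", "B"), ("B", "D")])
    assert not is_d_separated(dag, "A", "C", {"D"})


def test_unknown_node_raises():
    dag = make_dag([("A", "B")])
    with pytest.raises(DAGError):
        is_d_separated(dag, "A", "Q", set())


def test_d_separation_agrees_with_path_enumeration_oracle():
    rng = np.random.default_rng(42)
    n_checked = 0
    for _ in range(30):
        nodes, edges = random_dag(rng)
        if not edges:
            continue
        dag = make_dag(edges, nodes=nodes)
        names = sorted(nodes)
        for _ in range(10):
            a, b = rng.choice(names, size=2, replace=False)
            others = [n for n in names if n not in (a, b)]
            k = rng.integers(0, len(others) + 1)
            z = set(rng.choice(others, size=k, replace=False)) if k else set()
            got = is_d_separated(dag, a, b, z)
            want = brute_force_d_separated(nodes, edges, a, b, z)
            assert got == want, (sorted(edges), a, b, sorted(z))
            n_checked += 1
    assert n_checked > 200


# ---------------------------------------------------------------------------
# backdoor sets
# ---------------------------------------------------------------------------


def test_exposure_without_parents_has_empty_adjustment_set():
    dag = make_dag([("X", "Y"), ("X", "M")], exposure="X", outcome="Y")
    res = backdoor_sets(dag)
    assert res.identifiable and res.sets == (frozenset(),)


def test_cyclic_graph_rejected():
    with pytest.raises(DAGError):
        make_dag([("A", "B"), ("B", "A")])


def test_backdoor_sets_match_subset_enumeration_oracle():
    rng = np.random.default_rng(7)
    n_nontrivial = 0
    for _ in range(40):
        nodes, edges = random_dag(rng, n_nodes=int(rng.integers(4, 9)))
        if len(edges) < 3:
            continue
        names = sorted(nodes)
        x, y = rng.choice(names, size=2, replace=False)
        n_obs = rng.integers(2, len(names) + 1)
        observed = set(rng.choice(names, size=n_obs, replace=False)) | {x, y}
        dag = make_dag(edges, observed=observed, exposure=x, outcome=y, nodes=nodes)
        res = backdoor_sets(dag)
        want = brute_force_backdoor(dag)
        assert list(res.sets) == want
        assert res.identifiable == bool(want)
        if want and want != [frozenset()]:
            n_nontrivial += 1
    assert n_nontrivial > 3


def test_adding_unobserved_confounder_breaks_identifiability():
    dag = make_dag([("Z", "X"), ("Z", "Y"), ("X", "Y")], exposure="X", outcome="Y")
    assert backdoor_sets(dag).identifiable
    edges = set(dag.edges) | {("U", "X"), ("U", "Y")}
    dag2 = CausalDAG(
        nodes=dag.nodes | {"U"},
        edges=frozenset(edges),
        observed=dag.observed,
        exposure="X",
        outcome="Y",
    )
    res = backdoor_sets(dag2)
    assert not res.identifiable
    assert "U" in res.blocking_failure


# ---------------------------------------------------------------------------
# the study DAG
# ---------------------------------------------------------------------------

STUDY_SETS = {
    "age": [{"breed"}],
    "sex": [set()],
    "breed": [set()],
    "coat": [{"breed"}],
    "season": [set()],
    "comorbidity": [{"age", "breed", "sex"}],
    "body_fat": [{"age", "breed", "sex", "comorbidity"}],
}


@pytest.mark.parametrize("exposure,expected", sorted(STUDY_SETS.items()))
def test_study_dag_reproduces_published_adjustment_sets(exposure, expected):
    res = backdoor_sets(study_dag(exposure))
    assert res.identifiable
    assert [set(s) for s in res.sets] == expected


@pytest.mark.parametrize("exposure", ["weight_loss_success", "visit"])
def test_study_dag_unidentifiable_exposures(exposure, ):
    res = backdoor_sets(study_dag(exposure))
    assert not res.identifiable
    assert res.sets == ()
    assert "owner_environment" in res.blocking_failure


def test_reverse_causality_dag_uses_same_adjustment_set():
    res = backdoor_sets(reverse_study_dag())
    assert [set(s) for s in res.sets] == [{"age", "breed", "sex", "comorbidity"}]


def test_study_dag_verified_against_oracle():
    for exposure in list(STUDY_SETS) + ["weight_loss_success", "visit"]:
        dag = study_dag(exposure)
        assert [set(s) for s in backdoor_sets(dag).sets] == [
            set(s) for s in brute_force_backdoor(dag)
        ]


def test_parse_round_trip_and_errors():
    text = "observed: A B\nunobserved: U\nA -> B\nU -> B\nexposure: A\noutcome: B\n"
    dag = parse_dag(text)
    assert dag.exposure == "A" and dag.outcome == "B"
    assert dag.unobserved == {"U"}
    with pytest.raises(DAGError):
        parse_dag("A => B")
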