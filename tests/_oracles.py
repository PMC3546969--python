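"""Independent brute-force oracles used by the test suite.

Everything here enumerates over all internal-node state assignments, so
it is exponentially slow and only usable on tiny trees -- which is the
point: it shares no code path with the pruning/outside-pass machinery it
cross-checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from cosubst.alignment_io import Alignment
from cosubst.models import ReversibleModel, StateSpace, build_gtr_model
from cosubst.tree import PhyloTree


def random_small_model(n_states: int, rng: np.random.Generator) -> ReversibleModel:
    symbols = tuple("ARNDCQEGHI"[:n_states])
    space = StateSpace("amino20", symbols, {s: s for s in symbols})
    s = rng.random((n_states, n_states))
    s = 0.5 * (s + s.T)
    np.fill_diagonal(s, 0.0)
    pi = rng.dirichlet(np.ones(n_states))
    return build_gtr_model(space, s, pi)


def _assignments(tree: PhyloTree, column: dict[str, int], n_states: int):
    internal = [v for v in range(tree.n_nodes) if v >= tree.n_leaves]
    # a leaf serving as traversal root is observed, not free
    fixed = {leaf: column[tree.labels[leaf]] for leaf in range(tree.n_leaves)}
    for states in itertools.product(range(n_states), repeat=len(internal)):
        assign = dict(zip(internal, states))
        assign.update(fixed)
        yield assign


def brute_likelihood(
    tree: PhyloTree, model: ReversibleModel, column: dict[str, int]
) -> float:
    """Sum over internal-node states of pi(root) * prod P over branches."""
    n = model.space.n_states
    Ps = {v: model.transition_matrix(L) for (_, v, L) in tree.branches()}
    total = 0.0
    for assign in _assignments(tree, column, n):
        p = model.pi[assign[tree.root]]
        for u, v, _ in tree.branches():
            p *= Ps[v][assign[u], assign[v]]
        total += p
    return total


def brute_endpoint_joint(
    tree: PhyloTree, model: ReversibleModel, column: dict[str, int], branch: int
) -> np.ndarray:
    """Exact joint posterior of one branch's endpoint states."""
    n = model.space.n_states
    Ps = {v: model.transition_matrix(L) for (_, v, L) in tree.branches()}
    u0, v0, _ = tree.branches()[branch]
    J = np.zeros((n, n))
    for assign in _assignments(tree, column, n):
        p = model.pi[assign[tree.root]]
        for u, v, _ in tree.branches():
            p *= Ps[v][assign[u], assign[v]]
        J[assign[u0], assign[v0]] += p
    return J / J.sum()


def brute_posterior_mean(
    tree: PhyloTree,
    model: ReversibleModel,
    column: dict[str, int],
    G: np.ndarray,
) -> np.ndarray:
    """Posterior mean of a change functional G on every branch."""
    out = np.zeros(tree.n_branches)
    for b in range(tree.n_branches):
        J = brute_endpoint_joint(tree, model, column, b)
        out[b] = float((J * G).sum())
    return out


def column_alignment(tree: PhyloTree, columns: list[str]) -> Alignment:
    """Alignment whose site s shows columns[s][leaf] at each leaf."""
    rows = ["".join(col[i] for col in columns) for i in range(tree.n_leaves)]
    return Alignment(list(tree.labels), rows)
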