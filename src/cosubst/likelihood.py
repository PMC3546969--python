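"""Pruning likelihoods and per-branch endpoint posteriors on phylogenies.

The column likelihood is computed by Felsenstein's pruning with per-node
scaling; the per-site likelihood under rate variation is the
equal-probability mixture over gamma categories. Because the models are
time-reversible, any node can serve as the traversal root.

Besides the standard "inside" (conditional subtree) arrays, an "outside"
pass computes, for every branch, the likelihood of the data outside the
child's subtree jointly with the parent-side endpoint state. Inside and
outside arrays together give the joint posterior of the two endpoint
states of every branch, the quantity that substitution mapping averages
feature changes over, and also make single-branch length optimisation a
cheap one-dimensional problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .alignment_io import Alignment
from .models import GammaMixture, ReversibleModel, single_rate
from .properties import AA_INDEX
from .tree import PhyloTree

BRANCH_LENGTH_BOUNDS = (1e-8, 50.0)


def leaf_partials(model: ReversibleModel, aln: Alignment, tree: PhyloTree) -> np.ndarray:
    """0/1 leaf conditionals, shape (n_leaves, n_states, n_sites).

    Gaps and unknown residues give all-ones rows (missing data). For a
    codon state space an observed amino acid sets 1 on every codon that
    encodes it.
    """
    space = model.space
    n_sites = aln.n_cols
    out = np.zeros((tree.n_leaves, space.n_states, n_sites))
    aa_idx = space.aa_indices()
    for leaf, label in enumerate(tree.labels):
        row = aln.row(label)
        for s, sym in enumerate(row):
            i = AA_INDEX.get(sym)
            if i is None:
                out[leaf, :, s] = 1.0
            else:
                out[leaf, aa_idx == i, s] = 1.0
    return out


@dataclass
class SiteLikelihoodResult:
    """Per-site likelihoods plus cached arrays for substitution mapping."""

    tree: PhyloTree
    model: ReversibleModel
    gamma: GammaMixture
    log_likelihood: np.ndarray  # (n_sites,)
    category_loglik: np.ndarray  # (K, n_sites)
    inside: list  # per category: (D, logscale)
    P: list  # per category: (n_nodes, S, S) transition matrices
    leaf_init: np.ndarray

    @property
    def total_log_likelihood(self) -> float:
        return float(self.log_likelihood.sum())


def _category_P(tree: PhyloTree, model: ReversibleModel, rate: float) -> np.ndarray:
    S = model.space.n_states
    P = np.zeros((tree.n_nodes, S, S))
    for v in range(tree.n_nodes):
        if v != tree.root:
            P[v] = model.transition_matrix(float(tree.length[v]), rate)
    return P


def _inside_pass(tree: PhyloTree, P: np.ndarray, leaf_init: np.ndarray):
    """Conditional subtree likelihoods with per-node scaling."""
    S = P.shape[1]
    n_sites = leaf_init.shape[2]
    D = np.empty((tree.n_nodes, S, n_sites))
    logscale = np.zeros((tree.n_nodes, n_sites))
    for v in tree.postorder():
        work = (
            leaf_init[v].copy()
            if v < tree.n_leaves
            else np.ones((S, n_sites))
        )
        ls = np.zeros(n_sites)
        for c in tree.children[v]:
            work *= P[c] @ D[c]
            ls += logscale[c]
        m = work.max(axis=0)
        if (m <= 0).any():
            raise ValueError("zero likelihood column (incompatible data)")
        work /= m
        D[v] = work
        logscale[v] = ls + np.log(m)
    return D, logscale


def _outside_pass(
    tree: PhyloTree,
    P: np.ndarray,
    leaf_init: np.ndarray,
    D,
    logscaleD,
    pi: np.ndarray,
):
    """For each non-root node v: likelihood of data outside subtree(v),
    jointly with the state at v's parent (root prior included)."""
    S = P.shape[1]
    n_sites = D.shape[2]
    E = np.empty((tree.n_nodes, S, n_sites))
    logscaleE = np.zeros((tree.n_nodes, n_sites))
    for u in tree.preorder():
        kids = tree.children[u]
        if not kids:
            continue
        M = [P[c] @ D[c] for c in kids]
        lsM = [logscaleD[c] for c in kids]
        own = (
            leaf_init[u]
            if u < tree.n_leaves
            else np.ones((S, n_sites))
        )
        if u == tree.root:
            base = pi[:, None] * own
            base_ls = np.zeros(n_sites)
        else:
            base = (P[u].T @ E[u]) * own
            base_ls = logscaleE[u]
        # leave-one-out products over children via prefix/suffix
        k = len(kids)
        pre = [None] * (k + 1)
        pre_ls = [None] * (k + 1)
        pre[0] = base
        pre_ls[0] = base_ls
        for i in range(k):
            pre[i + 1] = pre[i] * M[i]
            pre_ls[i + 1] = pre_ls[i] + lsM[i]
        suf = np.ones((S, n_sites))
        suf_ls = np.zeros(n_sites)
        for i in range(k - 1, -1, -1):
            work = pre[i] * suf
            ls = pre_ls[i] + suf_ls
            m = work.max(axis=0)
            m = np.where(m > 0, m, 1.0)
            E[kids[i]] = work / m
            logscaleE[kids[i]] = ls + np.log(m)
            suf = suf * M[i]
            suf_ls = suf_ls + lsM[i]
    return E, logscaleE


def site_log_likelihood(
    tree: PhyloTree,
    model: ReversibleModel,
    gamma: GammaMixture | None,
    aln: Alignment,
) -> SiteLikelihoodResult:
    """Pruning log-likelihood of every alignment column.

    Returns per-site log L = log sum_k w_k L_k together with the cached
    inside arrays and transition matrices reused by the mapping stage.
    """
    gamma = gamma or single_rate()
    if set(tree.labels) - set(aln.ids):
        raise ValueError("tree leaf without an alignment row")
    leaf_init = leaf_partials(model, aln, tree)
    K = gamma.K
    n_sites = aln.n_cols
    cat_ll = np.empty((K, n_sites))
    inside = []
    Ps = []
    for k in range(K):
        P = _category_P(tree, model, float(gamma.rates[k]))
        D, ls = _inside_pass(tree, P, leaf_init)
        root_lik = model.pi @ D[tree.root]
        cat_ll[k] = np.log(root_lik) + ls[tree.root]
        inside.append((D, ls))
        Ps.append(P)
    ll = logsumexp(cat_ll + np.log(gamma.weights)[:, None], axis=0)
    return SiteLikelihoodResult(
        tree, model, gamma, ll, cat_ll, inside, Ps, leaf_init
    )


def site_gamma_posteriors(res: SiteLikelihoodResult) -> np.ndarray:
    """Posterior weight of each rate category per site, shape (K, n_sites)."""
    logw = res.category_loglik + np.log(res.gamma.weights)[:, None]
    tot = logsumexp(logw, axis=0)
    if not np.isfinite(tot).all():
        raise ValueError("zero total likelihood at some site")
    return np.exp(logw - tot)


def branch_endpoint_posteriors(res: SiteLikelihoodResult) -> np.ndarray:
    """Joint posterior of branch endpoint states, gamma-marginalised.

    Returns an array of shape (n_branches, S, S, n_sites): entry
    [b, a, c, s] is the posterior probability that the parent-side endpoint
    of branch b is in state a and the child-side endpoint in state c at
    site s. Sums to 1 over (a, c) for every branch and site.
    """
    tree, model = res.tree, res.model
    S = model.space.n_states
    n_sites = res.leaf_init.shape[2]
    post_k = site_gamma_posteriors(res)
    joint = np.zeros((tree.n_branches, S, S, n_sites))
    for k in range(res.gamma.K):
        D, lsD = res.inside[k]
        P = res.P[k]
        E, _ = _outside_pass(tree, P, res.leaf_init, D, lsD, model.pi)
        for b, v in enumerate(tree.branch_nodes):
            J = np.einsum("as,ac,cs->acs", E[v], P[v], D[v])
            tot = J.sum(axis=(0, 1))
            J /= np.where(tot > 0, tot, 1.0)
            joint[b] += post_k[k][None, None, :] * J
    return joint


def optimize_branch_lengths(
    tree: PhyloTree,
    model: ReversibleModel,
    gamma: GammaMixture | None,
    aln: Alignment,
    tol: float = 1e-6,
    max_cycles: int = 20,
    bounds: tuple[float, float] = BRANCH_LENGTH_BOUNDS,
) -> PhyloTree:
    """Coordinate-wise ML branch lengths (Brent on one branch at a time).

    Cycles over all branches, re-deriving the inside/outside arrays around
    each branch so its one-dimensional likelihood profile is exact, until
    the total log-likelihood improves by less than ``tol`` (at least one
    full cycle, at most ``max_cycles``). Returned lengths lie in
    ``bounds``.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    gamma = gamma or single_rate()
    tree = tree.copy()
    tree.length[tree.branch_nodes] = np.clip(
        tree.length[tree.branch_nodes], bounds[0], bounds[1]
    )
    leaf_init = leaf_partials(model, aln, tree)
    logw = np.log(gamma.weights)

    def total_ll() -> float:
        return site_log_likelihood(tree, model, gamma, aln).total_log_likelihood

    prev = total_ll()
    if not np.isfinite(prev):
        raise ValueError("non-finite initial log-likelihood")
    for _cycle in range(max_cycles):
        for v in tree.branch_nodes:
            ED = []
            for k in range(gamma.K):
                P = _category_P(tree, model, float(gamma.rates[k]))
                D, lsD = _inside_pass(tree, P, leaf_init)
                E, lsE = _outside_pass(tree, P, leaf_init, D, lsD, model.pi)
                ED.append((E[v], D[v], lsE[v] + lsD[v]))

            def neg_ll(t: float) -> float:
                cat = np.empty((gamma.K, aln.n_cols))
                for k in range(gamma.K):
                    Ev, Dv, ls = ED[k]
                    P = model.transition_matrix(t, float(gamma.rates[k]))
                    lik = np.einsum("as,ac,cs->s", Ev, P, Dv)
                    with np.errstate(divide="ignore"):
                        cat[k] = np.log(lik) + ls + logw[k]
                return -float(logsumexp(cat, axis=0).sum())

            # the profile is flat to machine precision for large t, which
            # defeats plain golden-section search; bracket on a geometric
            # grid first, then refine with bounded Brent
            grid = np.geomspace(bounds[0], bounds[1], 25)
            grid = np.unique(np.append(grid, float(tree.length[v])))
            grid = grid[(grid >= bounds[0]) & (grid <= bounds[1])]
            vals = np.array([neg_ll(t) for t in grid])
            if not np.isfinite(vals).any():
                raise ValueError(
                    f"non-finite likelihood while optimising branch to node {v}"
                )
            best = int(np.nanargmin(vals))
            lo = grid[max(best - 1, 0)]
            hi = grid[min(best + 1, len(grid) - 1)]
            res = minimize_scalar(
                neg_ll, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-10},
            )
            cand = res.x if res.fun <= vals[best] else grid[best]
            if -neg_ll(float(cand)) >= -neg_ll(float(tree.length[v])):
                tree.length[v] = float(cand)
        cur = total_ll()
        if cur - prev < tol:
            break
        prev = cur
    return tree
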