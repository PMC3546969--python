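"""Ground-truthed synthetic data: Yule trees, independent sites, and
compensatorily coupled site pairs.

Coupled pairs evolve as one 400-state Markov process on ordered
amino-acid pairs, reversible with stationary law
pi(a) * pi(b) * exp(-beta_c * phi(a, b)) for a compensatory potential
phi. The default potential penalises uncompensated charge (|q_a + q_b|)
and volume (|z_a + z_b| with standardised volumes) changes. Moves combine
single-site substitutions with concerted double substitutions: a
compensating mutation fixes on a timescale far shorter than a tree
branch, so on the tree a compensated change shows up as both sites
substituting in the same branch -- exactly the concurrent/compensatory
signature the scoring stage is built to detect.

All state sampling is exact (spectral transition matrices at each branch
length); no path simulation is needed because only endpoint states are
observed.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .alignment_io import Alignment, read_alignment, write_fasta
from .contacts import ContactMap
from .models import ReversibleModel, poisson_model
from .properties import AMINO_ACIDS, PropertyTable
from .tree import PhyloTree, read_newick

DEFAULT_BIRTH_RATE = 12.0  # gives mean pairwise divergence ~0.5-1.0 at n=200


# ---------------------------------------------------------------- propagator


class _Spectral:
    """Transition probabilities for a reversible generator (any size)."""

    def __init__(self, Q: np.ndarray, mu: np.ndarray):
        d = np.sqrt(mu)
        B = (d[:, None] * Q) / d[None, :]
        B = 0.5 * (B + B.T)
        w, U = np.linalg.eigh(B)
        self.w = w
        self.L = U / d[:, None]
        self.R = U * d[:, None]

    def matrix(self, t: float) -> np.ndarray:
        P = (self.L * np.exp(self.w * t)) @ self.R.T
        np.clip(P, 0.0, None, out=P)
        return P / P.sum(axis=1, keepdims=True)

    def rows(self, states: np.ndarray, t: float) -> np.ndarray:
        uniq, inv = np.unique(states, return_inverse=True)
        P = (self.L[uniq] * np.exp(self.w * t)) @ self.R.T
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P[inv]


# ------------------------------------------------------------- coupled pairs


@dataclass
class CoupledPairProcess:
    """Reversible 400-state process for one compensatorily coupled pair."""

    Q: np.ndarray  # (400, 400)
    stationary: np.ndarray
    beta: float
    potential: np.ndarray  # phi flattened over ordered pairs


def charge_volume_potential(
    table: PropertyTable | None = None,
    pi: np.ndarray | None = None,
    charge_weight: float = 1.0,
    volume_weight: float = 1.0,
) -> np.ndarray:
    """Default compensatory potential |q_a + q_b| + |z_a + z_b|.

    z is the side-chain volume standardised to zero mean and unit
    variance under the base stationary distribution, so both terms are
    O(1) and beta_c scales them together.
    """
    table = table or PropertyTable.default()
    pi = np.full(20, 1 / 20) if pi is None else np.asarray(pi, float)
    q = table.values("charge")
    vol = table.values("volume")
    z = (vol - (pi * vol).sum()) / np.sqrt((pi * (vol - (pi * vol).sum()) ** 2).sum())
    qsum = np.abs(q[:, None] + q[None, :])
    zsum = np.abs(z[:, None] + z[None, :])
    return (charge_weight * qsum + volume_weight * zsum).ravel()


def charge_potential(table: PropertyTable | None = None) -> np.ndarray:
    """Charge-complementarity-only variant of the potential."""
    table = table or PropertyTable.default()
    q = table.values("charge")
    return np.abs(q[:, None] + q[None, :]).ravel()


def build_coupled_process(
    base: ReversibleModel,
    beta: float,
    potential: np.ndarray | None = None,
    rho_pair: float = 1.0,
) -> CoupledPairProcess:
    """Pair rate matrix from two base-model copies and a potential.

    The pair exchangeabilities combine single-site moves (either site
    changes, base exchangeability) with *concerted* double moves (both
    sites change at once, product of the base exchangeabilities scaled by
    ``rho_pair``). Target states are weighted by the coupled stationary
    law pi(a) pi(b) exp(-beta * phi), which keeps the GTR form and hence
    detailed balance. A compensating mutation fixes on a timescale far
    shorter than a tree branch, so a compensated change appears on the
    tree as a concerted double substitution -- the concerted channel is
    what makes that explicit; single uncompensated moves into
    high-potential states are suppressed by exp(-beta * phi) of the
    target. ``rho_pair = 0`` disables concerted moves.

    The generator is normalised to one expected substitution per *site*
    per unit branch length (two per pair), the same convention as every
    single-site model, so coupling shapes which substitutions occur, not
    how many.
    """
    if beta < 0:
        raise ValueError("coupling strength must be >= 0")
    if rho_pair < 0:
        raise ValueError("rho_pair must be >= 0")
    n = base.space.n_states
    pi = base.pi
    phi = (
        charge_volume_potential(pi=pi)
        if potential is None
        else np.asarray(potential, float).ravel()
    )
    if phi.shape != (n * n,):
        raise ValueError("potential must cover all ordered state pairs")
    s = base.Q / pi[None, :]  # symmetric exchangeabilities
    np.fill_diagonal(s, 0.0)
    mu = np.repeat(pi, n) * np.tile(pi, n) * np.exp(-beta * phi)
    mu = mu / mu.sum()
    N = n * n
    S2 = np.zeros((N, N))
    idx = np.arange(N).reshape(n, n)
    phi2 = phi.reshape(n, n)
    for a in range(n):
        for b in range(n):
            p = idx[a, b]
            # single-site moves: dividing by the unchanged coordinate's
            # stationary factor makes the beta = 0 limit exactly two
            # independent copies of the base process
            S2[p, idx[:, b]] += s[a, :] / pi[b]
            S2[p, idx[a, :]] += s[b, :] / pi[a]
            if rho_pair > 0:
                # concerted channel gated by the best sequential
                # intermediate's penalty: it opens only where stepwise
                # paths are blocked, and vanishes entirely at beta = 0
                m = np.minimum(phi2[:, [b]], phi2[[a], :])
                gate = -np.expm1(-beta * m)
                S2[p, :] += rho_pair * np.outer(s[a, :], s[b, :]).ravel() * gate.ravel()
            S2[p, p] = 0.0
    Q = S2 * mu[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(mu * np.diag(Q)).sum()
    if rate <= 0:
        raise ValueError("coupled process has zero total rate")
    Q *= 2.0 / rate
    return CoupledPairProcess(Q, mu, beta, phi)


# --------------------------------------------------------------------- trees


def simulate_yule_tree(
    n_leaves: int, birth_rate: float = DEFAULT_BIRTH_RATE, seed: int = 0
) -> PhyloTree:
    """Pure-birth tree with exponential waiting times, labelled t1..tn."""
    if n_leaves < 4:
        raise ValueError("need at least 4 leaves for an unrooted topology")
    if birth_rate <= 0:
        raise ValueError("birth rate must be > 0")
    from dendropy.model import birthdeath

    dtree = birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_leaves,
        rng=random.Random(int(seed)),
    )
    taxa = dendropy.TaxonNamespace()
    dtree.taxon_namespace = taxa
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(f"t{i}")
    return PhyloTree.from_dendropy(dtree)


# ------------------------------------------------------------- configuration


def spread_pairs(
    n_sites: int, n_pairs: int, offset: int | None = None
) -> list[tuple[int, int]]:
    """Disjoint coupled pairs (3k, 3k + offset), well separated."""
    if n_pairs == 0:
        return []
    if offset is None:
        offset = max(6, min(25, n_sites - 1 - 3 * (n_pairs - 1)))
    pairs = [(3 * k, 3 * k + offset) for k in range(n_pairs)]
    if offset < 6 or pairs[-1][1] >= n_sites:
        raise ValueError("n_sites too small for the requested pairs")
    return pairs


@dataclass
class SimConfig:
    """Study conditions for one synthetic data set."""

    n_leaves: int = 200
    birth_rate: float = DEFAULT_BIRTH_RATE
    n_sites: int = 50
    coupled_pairs: list[tuple[int, int]] | None = None  # default: spread_pairs
    n_coupled_pairs: int = 8
    beta: float = 5.0
    seed: int = 0
    rho_pair: float = 1.0  # concerted double-substitution weight
    potential: np.ndarray | None = None  # default charge+volume

    def __post_init__(self):
        if self.n_leaves < 4:
            raise ValueError("n_leaves must be >= 4")
        if self.coupled_pairs is None:
            self.coupled_pairs = spread_pairs(self.n_sites, self.n_coupled_pairs)
        self.coupled_pairs = [tuple(p) for p in self.coupled_pairs]
        used: set[int] = set()
        for i, j in self.coupled_pairs:
            if not (0 <= i < self.n_sites and 0 <= j < self.n_sites):
                raise ValueError(f"coupled pair {(i, j)} outside the site range")
            if abs(j - i) < 6:
                raise ValueError("coupled pairs must be separated by >= 6 sites")
            if i in used or j in used or i == j:
                raise ValueError("coupled pairs must be disjoint")
            used.update((i, j))


@dataclass
class SimOutput:
    alignment: Alignment
    tree: PhyloTree
    coupled_pairs: list[tuple[int, int]]
    contact_map: ContactMap
    config: SimConfig


# ---------------------------------------------------------------- simulation


def _sample_children(rng, P_rows: np.ndarray) -> np.ndarray:
    cdf = np.cumsum(P_rows, axis=1)
    u = rng.random(len(P_rows)) * cdf[:, -1]
    return np.array(
        [int(np.searchsorted(cdf[r], u[r], side="right")) for r in range(len(P_rows))]
    )


def simulate_alignment(
    cfg: SimConfig, base: ReversibleModel | None = None, tree: PhyloTree | None = None
) -> SimOutput:
    """Evolve independent and coupled sites down a (Yule) tree.

    Root states are drawn from the respective stationary laws; endpoint
    states on every branch are sampled from exact transition matrices.
    Deterministic for a fixed config seed.
    """
    base = base or poisson_model()
    rng = np.random.default_rng(cfg.seed)
    if tree is None:
        tree = simulate_yule_tree(
            cfg.n_leaves, cfg.birth_rate, seed=int(rng.integers(2**31 - 1))
        )
    n = base.space.n_states
    pair_proc = build_coupled_process(base, cfg.beta, cfg.potential, cfg.rho_pair)
    prop1 = _Spectral(base.Q, base.pi)
    prop2 = _Spectral(pair_proc.Q, pair_proc.stationary)

    coupled_sites = {s for p in cfg.coupled_pairs for s in p}
    ind_sites = [s for s in range(cfg.n_sites) if s not in coupled_sites]

    states1 = {
        tree.root: rng.choice(n, size=len(ind_sites), p=base.pi)
    }
    states2 = {
        tree.root: rng.choice(
            n * n, size=len(cfg.coupled_pairs), p=pair_proc.stationary
        )
    }
    for v in tree.preorder():
        if v == tree.root:
            continue
        t = float(tree.length[v])
        u = tree.parent[v]
        if ind_sites:
            states1[v] = _sample_children(rng, prop1.rows(states1[u], t))
        else:
            states1[v] = np.empty(0, dtype=int)
        if cfg.coupled_pairs:
            states2[v] = _sample_children(rng, prop2.rows(states2[u], t))
        else:
            states2[v] = np.empty(0, dtype=int)

    rows = []
    for leaf in range(tree.n_leaves):
        col = [""] * cfg.n_sites
        for k, s in enumerate(ind_sites):
            col[s] = AMINO_ACIDS[states1[leaf][k]]
        for k, (i, j) in enumerate(cfg.coupled_pairs):
            p = int(states2[leaf][k])
            col[i] = AMINO_ACIDS[p // n]
            col[j] = AMINO_ACIDS[p % n]
        rows.append("".join(col))
    aln = Alignment(list(tree.labels), rows)
    truth = ContactMap(
        {(i + 1, j + 1) for i, j in cfg.coupled_pairs},
        cutoff=None,
        min_separation=6,
    )
    return SimOutput(aln, tree, list(cfg.coupled_pairs), truth, cfg)


# ------------------------------------------------------------------ fixtures


def make_fixture(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write alignment.fasta, tree.nwk, truth_pairs.tsv, config.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_alignment(cfg)
    paths = {
        "alignment": out / "alignment.fasta",
        "tree": out / "tree.nwk",
        "truth": out / "truth_pairs.tsv",
        "config": out / "config.json",
    }
    write_fasta(sim.alignment, paths["alignment"])
    sim.tree.write_newick(paths["tree"])
    with open(paths["truth"], "w") as fh:
        fh.write("site_i\tsite_j\tpos_i\tpos_j\n")
        for i, j in sim.coupled_pairs:
            fh.write(f"{i}\t{j}\t{i + 1}\t{j + 1}\n")
    with open(paths["config"], "w") as fh:
        json.dump(
            {
                "n_leaves": cfg.n_leaves,
                "birth_rate": cfg.birth_rate,
                "n_sites": cfg.n_sites,
                "coupled_pairs": [list(p) for p in cfg.coupled_pairs],
                "beta": cfg.beta,
                "rho_pair": cfg.rho_pair,
                "seed": cfg.seed,
            },
            fh,
            indent=2,
        )
    return paths


def load_fixture(fixture_dir: str | Path) -> SimOutput:
    """Re-read a fixture directory into a SimOutput."""
    d = Path(fixture_dir)
    with open(d / "config.json") as fh:
        raw = json.load(fh)
    cfg = SimConfig(
        n_leaves=raw["n_leaves"],
        birth_rate=raw["birth_rate"],
        n_sites=raw["n_sites"],
        coupled_pairs=[tuple(p) for p in raw["coupled_pairs"]],
        beta=raw["beta"],
        rho_pair=raw.get("rho_pair", 1.0),
        seed=raw["seed"],
    )
    aln = read_alignment(d / "alignment.fasta", "fasta")
    tree = read_newick(d / "tree.nwk")
    truth = ContactMap(
        {(i + 1, j + 1) for i, j in cfg.coupled_pairs},
        cutoff=None,
        min_separation=6,
    )
    return SimOutput(aln, tree, list(cfg.coupled_pairs), truth, cfg)
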