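"""Reversible substitution models and discrete-gamma rate variation.

Two model constructions are provided:

* a general time-reversible (GTR-style) model on any state space from a
  symmetric exchangeability matrix and stationary frequencies, and
* a mechanistic codon model in which each codon substitution rate is the
  product of a nucleotide-level mutation rate (GTR nucleotide
  exchangeabilities, an extra factor rho_multi per additional nucleotide
  change within the codon) and an amino-acid-level fixation factor
  h(beta * wbar + c), where wbar is a mean selective constraint for the
  amino-acid replacement. Selection therefore acts on the protein while
  mutation acts on the DNA.

All rate matrices satisfy detailed balance and are normalised to one
expected substitution per site per unit branch length. Among-site rate
variation uses the usual equal-probability discrete gamma with
mean-per-category rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .properties import AMINO_ACIDS, AA_INDEX

_NUC = "ACGT"


# --------------------------------------------------------------- state spaces


@dataclass(frozen=True)
class StateSpace:
    """Ordered model states with their encoded amino acids."""

    kind: str  # "amino20" | "codon61"
    symbols: tuple[str, ...]
    aa_of: dict[str, str]

    @property
    def n_states(self) -> int:
        return len(self.symbols)

    def aa_indices(self) -> np.ndarray:
        """Index into AMINO_ACIDS of the amino acid encoded by each state."""
        return np.array([AA_INDEX[self.aa_of[s]] for s in self.symbols])


def amino20_space() -> StateSpace:
    return StateSpace("amino20", tuple(AMINO_ACIDS), {a: a for a in AMINO_ACIDS})


def codon61_space() -> StateSpace:
    """Sense codons of the standard genetic code (stop codons excluded)."""
    from Bio.Data.CodonTable import standard_dna_table

    table = standard_dna_table.forward_table
    codons = tuple(sorted(table))
    aa_of = {c: table[c] for c in codons}
    if len(codons) != 61:
        raise ValueError("standard code must yield 61 sense codons")
    return StateSpace("codon61", codons, aa_of)


# ------------------------------------------------------------------- models


class ReversibleModel:
    """Stationary frequencies plus a reversible, normalised rate matrix."""

    def __init__(self, space: StateSpace, pi: np.ndarray, Q: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        Q = np.asarray(Q, dtype=float)
        n = space.n_states
        if pi.shape != (n,) or Q.shape != (n, n):
            raise ValueError("pi/Q shape mismatch with state space")
        if (pi <= 0).any() or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must be positive and sum to 1")
        if np.abs(Q.sum(axis=1)).max() > 1e-10:
            raise ValueError("rows of Q must sum to 0")
        flux = pi[:, None] * Q
        if np.abs(flux - flux.T).max() > 1e-10:
            raise ValueError("detailed balance violated")
        if abs(-(pi * np.diag(Q)).sum() - 1.0) > 1e-8:
            raise ValueError("Q must be normalised to 1 expected substitution/site")
        self.space = space
        self.pi = pi
        self.Q = Q
        self._spectral: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    def _decompose(self):
        # reversibility makes D^{1/2} Q D^{-1/2} symmetric -> real spectrum
        if self._spectral is None:
            d = np.sqrt(self.pi)
            B = (d[:, None] * self.Q) / d[None, :]
            B = 0.5 * (B + B.T)
            w, U = np.linalg.eigh(B)
            self._spectral = (w, U / d[:, None], U * d[:, None])
        return self._spectral

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P = exp(Q * rate * t); rows sum to 1, entries >= 0."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        if rate <= 0:
            raise ValueError("rate multiplier must be > 0")
        w, L, R = self._decompose()
        P = (L * np.exp(w * rate * t)) @ R.T
        if not np.isfinite(P).all():
            # conditioning fallback: scipy's scaling-and-squaring
            from scipy.linalg import expm

            P = expm(self.Q * rate * t)
        np.clip(P, 0.0, None, out=P)
        return P


def transition_matrix(model: ReversibleModel, t: float, rate: float = 1.0) -> np.ndarray:
    return model.transition_matrix(t, rate)


def build_gtr_model(
    space: StateSpace, exchangeabilities: np.ndarray, pi: np.ndarray
) -> ReversibleModel:
    """GTR construction Q_ab = s_ab * pi_b, normalised to unit rate."""
    s = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(pi, dtype=float)
    n = space.n_states
    if s.shape != (n, n):
        raise ValueError("exchangeability matrix shape mismatch")
    if np.abs(s - s.T).max() > 1e-12:
        raise ValueError("exchangeability matrix must be symmetric")
    if (s < 0).any():
        raise ValueError("exchangeabilities must be non-negative")
    pi = pi / pi.sum()
    Q = s * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(pi * np.diag(Q)).sum()
    if rate <= 0:
        raise ValueError("zero total substitution rate")
    return ReversibleModel(space, pi, Q / rate)


def poisson_model(pi: np.ndarray | None = None) -> ReversibleModel:
    """Uniform-exchangeability amino-acid model (optionally custom pi)."""
    space = amino20_space()
    if pi is None:
        pi = np.full(20, 1 / 20)
    return build_gtr_model(space, 1.0 - np.eye(20), pi)


def empirical_frequencies(rows: list[str], pseudocount: float = 1.0) -> np.ndarray:
    """Amino-acid frequencies observed in alignment rows (plus pseudocount)."""
    counts = np.full(20, pseudocount)
    for row in rows:
        for sym in row:
            i = AA_INDEX.get(sym)
            if i is not None:
                counts[i] += 1
    return counts / counts.sum()


# --------------------------------------------------------------- codon model


def default_selective_constraints() -> np.ndarray:
    """Mean selective constraints per amino-acid pair.

    Derived at run time from the BLOSUM62 log-odds matrix as half the
    dissimilarity ((s_aa + s_bb)/2 - s_ab)/2, clipped at zero: similar
    replacements carry small constraints, radical ones large. Any 20x20
    symmetric non-negative table with zero diagonal may be supplied
    instead through :class:`CodonModelParams`.
    """
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    n = len(AMINO_ACIDS)
    w = np.zeros((n, n))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            w[i, j] = max(0.0, (blosum[a, a] + blosum[b, b]) / 2.0 - blosum[a, b]) / 2.0
    np.fill_diagonal(w, 0.0)
    return w


@dataclass
class CodonModelParams:
    """Parameters of the mechanistic codon model.

    exchange is keyed by unordered nucleotide pairs; the GT rate is the
    reference (1.0). rho_multi scales codon changes at d nucleotide
    positions by rho_multi**(d-1), so rho_multi = 0 forbids multi-nucleotide
    changes. Selection enters as h(slope * wbar + intercept) with h the
    (pluggable) fixation function, default exp(-w).
    """

    exchange: dict[frozenset, float] = field(
        default_factory=lambda: {
            frozenset("AG"): 4.0,
            frozenset("CT"): 4.0,
            frozenset("AC"): 1.0,
            frozenset("AT"): 1.0,
            frozenset("CG"): 1.0,
            frozenset("GT"): 1.0,
        }
    )
    rho_multi: float = 0.1
    nuc_freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    selection_slope: float = 1.0
    selection_intercept: float = 0.0
    constraints: np.ndarray | None = None  # 20x20, default BLOSUM62-derived
    fixation: Callable[[np.ndarray], np.ndarray] = staticmethod(
        lambda w: np.exp(-w)
    )
    codon_freqs: np.ndarray | None = None  # default: mutational equilibrium

    def __post_init__(self):
        self.nuc_freqs = np.asarray(self.nuc_freqs, dtype=float)
        if (self.nuc_freqs <= 0).any():
            raise ValueError("nucleotide frequencies must be positive")
        self.nuc_freqs = self.nuc_freqs / self.nuc_freqs.sum()
        if not np.isfinite(self.selection_slope):
            raise ValueError("selection slope must be finite")
        if self.rho_multi < 0:
            raise ValueError("rho_multi must be >= 0")


def build_codon_model(params: CodonModelParams) -> ReversibleModel:
    """Mechanistic codon rate matrix: mutation times fixation, reversible."""
    space = codon61_space()
    codons = space.symbols
    n = len(codons)
    nuc_i = {b: i for i, b in enumerate(_NUC)}

    wbar = params.constraints
    if wbar is None:
        wbar = default_selective_constraints()
    wbar = np.asarray(wbar, dtype=float)
    if wbar.shape != (20, 20) or np.abs(wbar - wbar.T).max() > 1e-12:
        raise ValueError("constraint table must be symmetric 20x20")

    # mutational equilibrium codon frequencies (independent positions)
    f_mut = np.array(
        [np.prod([params.nuc_freqs[nuc_i[b]] for b in c]) for c in codons]
    )
    f_mut = f_mut / f_mut.sum()
    pi = f_mut if params.codon_freqs is None else np.asarray(params.codon_freqs, float)
    pi = pi / pi.sum()

    aa_idx = space.aa_indices()
    S = np.zeros((n, n))
    for i, a in enumerate(codons):
        for j in range(i + 1, n):
            b = codons[j]
            diffs = [(x, y) for x, y in zip(a, b) if x != y]
            d = len(diffs)
            s = np.prod([params.exchange[frozenset((x, y))] for x, y in diffs])
            s *= params.rho_multi ** (d - 1)
            S[i, j] = S[j, i] = s
    # symmetric fixation factor keeps the GTR form, hence reversibility
    wmat = wbar[aa_idx[:, None], aa_idx[None, :]]
    h = params.fixation(params.selection_slope * wmat + params.selection_intercept)
    nonsyn = aa_idx[:, None] != aa_idx[None, :]
    factor = np.where(nonsyn, h, 1.0)
    return build_gtr_model(space, S * factor, pi)


def equal_codon_usage_frequencies(aa_freqs: np.ndarray) -> np.ndarray:
    """Codon frequencies from amino-acid frequencies with equal codon usage.

    The stationary assumption used when the observed data are amino-acid
    sequences: each synonymous codon of an amino acid gets an equal share
    of that amino acid's frequency.
    """
    space = codon61_space()
    aa_idx = space.aa_indices()
    counts = np.bincount(aa_idx, minlength=20)
    freqs = np.array([aa_freqs[a] / counts[a] for a in aa_idx])
    return freqs / freqs.sum()


# ------------------------------------------------------------ discrete gamma


@dataclass(frozen=True)
class GammaMixture:
    """Equal-probability discrete gamma rate categories with mean rate 1."""

    shape: float
    rates: np.ndarray
    weights: np.ndarray

    @property
    def K(self) -> int:
        return len(self.rates)


def single_rate() -> GammaMixture:
    """Degenerate mixture: one category at rate 1 (no rate variation)."""
    return GammaMixture(np.inf, np.array([1.0]), np.array([1.0]))


def discrete_gamma(alpha: float, K: int = 4) -> GammaMixture:
    """Mean-per-category discretisation of a Gamma(alpha, alpha) density."""
    if alpha <= 0:
        raise ValueError("gamma shape must be > 0")
    if K < 1:
        raise ValueError("category count must be >= 1")
    if K == 1:
        return GammaMixture(alpha, np.array([1.0]), np.array([1.0]))
    edges = stats.gamma.ppf(np.arange(1, K) / K, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate(([0.0], edges, [np.inf]))
    # E[X ; l < X < u] for X ~ Gamma(a, rate a) via the shape a+1 CDF
    upper_cdf = stats.gamma.cdf(edges, a=alpha + 1.0, scale=1.0 / alpha)
    rates = K * np.diff(upper_cdf)
    rates = rates / (rates.mean())
    return GammaMixture(alpha, rates, np.full(K, 1.0 / K))
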