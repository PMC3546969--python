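"""Coevolution scores from correlations of substitution vectors.

Pearson correlations of per-site feature vectors across branches mix
direct couplings with indirect ones (through other sites) and, for
substitution probabilities, with a phylogenetic correlation: longer
branches carry more substitutions at every site. Partial correlations --
the normalised negative entries of the inverse correlation matrix, equal
to correlations of residuals after regressing out every other site's
vector -- remove the linear part of both effects, which is the step that
makes co-substitution signals informative about spatial contacts.

Scores: concurrent substitutions require a positive direct correlation of
substitution probabilities, so zeta_sub = max(0, partial). Every other
characteristic change is gated by that premise through a geometric mean,
with the sign rule per feature fixed by which direction marks
compensation (negative for volume/charge/hydrogen bonding, positive for
cross-link and ionic, either for the rest). The overall score combines
the component scores (default: maximum). Alpha-helix propensity is
computed as a feature but excluded from the overall score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import SubstitutionVectorSet

DEGENERATE_SD = 1e-8

#: sign rule per feature entering the default overall score
SIGN_RULES = {
    "volume": "negative",
    "charge": "negative",
    "hbond": "negative",
    "hydrophobicity": "both",
    "beta_propensity": "both",
    "turn_propensity": "both",
    "aromatic": "both",
    "branched": "both",
    "crosslink": "positive",
    "ionic": "positive",
}


@dataclass
class FilterConfig:
    """Significance and site-filter settings for contact prediction."""

    e_value: float = 0.01
    hub_limit: int = 15
    min_separation: int = 6
    df_offset: int = 2  # Pearson t-test degrees of freedom: N_b - 2
    ridge: float = 1e-6
    combiner: str = "max"  # "max" | "sum"

    def __post_init__(self):
        if not 0 < self.e_value < 1:
            raise ValueError("e_value must be in (0, 1)")
        if self.hub_limit < 1:
            raise ValueError("hub_limit must be >= 1")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.combiner not in ("max", "sum"):
            raise ValueError("combiner must be 'max' or 'sum'")


@dataclass
class CorrelationSet:
    feature: str
    C: np.ndarray  # (n_sites, n_sites), NaN on degenerate rows/cols
    degenerate: np.ndarray  # bool (n_sites,)
    n_branches: int


@dataclass
class PartialSet:
    feature: str
    R: np.ndarray
    degenerate: np.ndarray
    n_branches: int


def pearson_matrix(
    V: np.ndarray | SubstitutionVectorSet,
    feature: str = "substitution",
    centered: bool = True,
) -> CorrelationSet:
    """Pearson correlation of every site pair's vectors across branches.

    Sites with (numerically) zero variance -- invariant sites in
    particular -- are marked degenerate and carry NaN rows/columns.
    ``centered=False`` gives the uncentered cosine variant for audit.
    """
    if isinstance(V, SubstitutionVectorSet):
        V = V[feature]
    V = np.asarray(V, dtype=float)
    n_sites, n_branches = V.shape
    if n_branches < 3:
        raise ValueError("need at least 3 branches for a correlation")
    X = V - V.mean(axis=1, keepdims=True) if centered else V.copy()
    sd = np.sqrt((X * X).sum(axis=1))
    degenerate = sd <= DEGENERATE_SD * np.sqrt(n_branches)
    safe = np.where(degenerate, 1.0, sd)
    Xn = X / safe[:, None]
    C = np.clip(Xn @ Xn.T, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    C[degenerate, :] = np.nan
    C[:, degenerate] = np.nan
    return CorrelationSet(feature, C, degenerate, n_branches)


def partial_matrix(C: CorrelationSet, ridge: float = 1e-6) -> PartialSet:
    """Partial correlations R_ij = -Omega_ij / sqrt(Omega_ii Omega_jj).

    Omega is the inverse of the correlation matrix restricted to
    non-degenerate sites. A well-conditioned matrix is inverted directly;
    a singular/ill-conditioned one (e.g. more sites than branches) is
    ridge-regularised with ``ridge`` on the diagonal, or pseudo-inverted
    when ``ridge`` is 0.
    """
    keep = ~C.degenerate
    Cn = C.C[np.ix_(keep, keep)]
    m = Cn.shape[0]
    cond = np.linalg.cond(Cn) if m else 1.0
    try:
        if m and m <= C.n_branches and cond < 1e10:
            omega = np.linalg.inv(Cn)
        elif ridge == 0.0:
            omega = np.linalg.pinv(Cn)
        else:
            omega = np.linalg.inv(Cn + ridge * np.eye(m))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"correlation matrix inversion failed (condition number {cond:.3g})"
        ) from exc
    d = np.sqrt(np.diag(omega))
    Rn = np.clip(-omega / np.outer(d, d), -1.0, 1.0)
    np.fill_diagonal(Rn, 1.0)
    R = np.full_like(C.C, np.nan)
    R[np.ix_(keep, keep)] = Rn
    return PartialSet(C.feature, R, C.degenerate.copy(), C.n_branches)


def partial_by_residual_regression(V: np.ndarray) -> np.ndarray:
    """Definitional partial correlations via residual projection.

    For each site pair, both vectors are projected onto the orthogonal
    complement of the span of all other sites' (centered) vectors and the
    residuals correlated. Quadratic in sites and used as the independent
    cross-check of :func:`partial_matrix`, never in the pipeline.
    """
    V = np.asarray(V, dtype=float)
    n = V.shape[0]
    X = V - V.mean(axis=1, keepdims=True)
    R = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            others = np.delete(np.arange(n), [i, j])
            B = X[others].T  # (branches, n-2)
            q, _ = np.linalg.qr(B)
            ri = X[i] - q @ (q.T @ X[i])
            rj = X[j] - q @ (q.T @ X[j])
            denom = np.linalg.norm(ri) * np.linalg.norm(rj)
            R[i, j] = R[j, i] = float(ri @ rj / denom) if denom > 0 else 0.0
    return R


def significance_threshold(
    cfg: FilterConfig, n_pairs: int, n_branches: int
) -> float:
    """Correlation magnitude at two-sided tail p = E / n_pairs.

    Under no correlation, r * sqrt(df / (1 - r^2)) follows a Student t
    distribution with df = N_b - 2; the threshold is the r whose two-sided
    tail probability equals the Bonferroni-style per-pair level.
    """
    df = n_branches - cfg.df_offset
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    p = cfg.e_value / n_pairs
    t = stats.t.isf(p / 2.0, df)
    return float(t / np.sqrt(df + t * t))


def component_scores(
    R_sub: PartialSet, R_x: PartialSet, sign_rule: str
) -> np.ndarray:
    """zeta_x = sqrt(zeta_sub * s(R_x)) with the feature's sign rule.

    ``positive`` keeps max(0, R_x), ``negative`` keeps max(0, -R_x),
    ``both`` keeps |R_x|. zeta_sub = max(0, R_sub) gates everything:
    without concurrent substitutions there is no compensation signal.
    """
    if sign_rule not in ("positive", "negative", "both"):
        raise ValueError(f"invalid sign rule {sign_rule!r}")
    zsub = np.clip(np.nan_to_num(R_sub.R), 0.0, None)
    rx = np.nan_to_num(R_x.R)
    if sign_rule == "positive":
        s = np.clip(rx, 0.0, None)
    elif sign_rule == "negative":
        s = np.clip(-rx, 0.0, None)
    else:
        s = np.abs(rx)
    return np.sqrt(zsub * s)


@dataclass
class ScoreTable:
    """Pairwise component and overall coevolution scores with filters."""

    zeta_sub: np.ndarray  # (n_sites, n_sites)
    components: dict[str, np.ndarray]  # feature -> zeta_x matrix
    zeta: np.ndarray  # overall score
    degenerate: np.ndarray  # bool per site (invariant/zero-variance)
    zeta_effective: np.ndarray | None = None  # set by site_filters
    terminal: np.ndarray | None = None  # bool per site
    anomalous: np.ndarray | None = None  # bool per site (hub rule)
    r_thr: float | None = None

    @property
    def n_sites(self) -> int:
        return self.zeta_sub.shape[0]

    def excluded_sites(self) -> np.ndarray:
        out = self.degenerate.copy()
        if self.anomalous is not None:
            out |= self.anomalous
        return out


def overall_score(
    partials: dict[str, PartialSet], cfg: FilterConfig | None = None
) -> ScoreTable:
    """Combine component scores into the overall coevolution score.

    ``partials`` must contain the ``substitution`` channel plus every
    feature named in :data:`SIGN_RULES`. The default combiner is the
    maximum of zeta_sub and the included component scores (each component
    already damped by zeta_sub through the geometric mean); ``sum`` adds
    them and clips at 1, provided for sensitivity analysis.
    """
    cfg = cfg or FilterConfig()
    if "substitution" not in partials:
        raise KeyError("missing 'substitution' partial correlations")
    missing = set(SIGN_RULES) - set(partials)
    if missing:
        raise KeyError(f"missing component partials: {sorted(missing)}")
    R_sub = partials["substitution"]
    zsub = np.clip(np.nan_to_num(R_sub.R), 0.0, None)
    np.fill_diagonal(zsub, 0.0)
    comps = {}
    for feature, rule in SIGN_RULES.items():
        z = component_scores(R_sub, partials[feature], rule)
        np.fill_diagonal(z, 0.0)
        comps[feature] = z
    stack = np.stack([zsub] + list(comps.values()))
    zeta = stack.max(axis=0) if cfg.combiner == "max" else np.clip(
        stack.sum(axis=0), 0.0, 1.0
    )
    degenerate = R_sub.degenerate.copy()
    return ScoreTable(zsub, comps, zeta, degenerate)


def site_filters(
    st: ScoreTable, cfg: FilterConfig, r_thr: float
) -> ScoreTable:
    """Terminal-site fallback, anomalous-hub exclusion, invariant removal.

    (a) pairs involving the first or last alignment column are scored by
    zeta_sub alone; (b) a site with more than ``hub_limit`` partners whose
    (effective) score exceeds ``r_thr`` is excluded entirely; (c)
    invariant/degenerate sites are excluded.
    """
    n = st.n_sites
    terminal = np.zeros(n, dtype=bool)
    terminal[0] = terminal[-1] = True
    eff = st.zeta.copy()
    tmask = terminal[:, None] | terminal[None, :]
    eff[tmask] = st.zeta_sub[tmask]
    significant = eff > r_thr
    np.fill_diagonal(significant, False)
    significant[st.degenerate, :] = False
    significant[:, st.degenerate] = False
    anomalous = significant.sum(axis=1) > cfg.hub_limit
    st.zeta_effective = eff
    st.terminal = terminal
    st.anomalous = anomalous
    st.r_thr = r_thr
    return st


@dataclass
class PredictionList:
    """Ranked site pairs predicted to be in contact."""

    frame: pd.DataFrame  # rank, i, j, pos_i, pos_j, zeta, zeta_sub

    def __len__(self) -> int:
        return len(self.frame)

    def pairs(self, k: int | None = None) -> list[tuple[int, int]]:
        sub = self.frame if k is None else self.frame.head(k)
        return list(zip(sub["pos_i"], sub["pos_j"]))


def rank_pairs(
    st: ScoreTable,
    cfg: FilterConfig,
    k: int,
    positions: np.ndarray | None = None,
) -> PredictionList:
    """Top-k unfiltered pairs by decreasing (effective) overall score.

    Pairs closer than ``min_separation`` along the chain and pairs
    involving excluded sites are never ranked. Ties break by zeta_sub,
    then smaller i, then smaller j, making the output a total order.
    ``positions`` maps site index to a 1-based target position (default
    site + 1).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if st.zeta_effective is None:
        raise ValueError("run site_filters before ranking")
    n = st.n_sites
    if positions is None:
        positions = np.arange(1, n + 1)
    excluded = st.excluded_sites()
    rows = []
    for i in range(n):
        if excluded[i]:
            continue
        for j in range(i + 1, n):
            if excluded[j]:
                continue
            if abs(positions[j] - positions[i]) < cfg.min_separation:
                continue
            rows.append(
                (
                    i,
                    j,
                    int(positions[i]),
                    int(positions[j]),
                    float(st.zeta_effective[i, j]),
                    float(st.zeta_sub[i, j]),
                )
            )
    frame = pd.DataFrame(
        rows, columns=["i", "j", "pos_i", "pos_j", "zeta", "zeta_sub"]
    )
    frame = frame.sort_values(
        by=["zeta", "zeta_sub", "i", "j"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    if k > len(frame):
        warnings.warn(
            f"requested {k} predictions but only {len(frame)} eligible pairs",
            stacklevel=2,
        )
        k = len(frame)
    frame = frame.head(k).copy()
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return PredictionList(frame)


def score_pipeline(
    vectors: SubstitutionVectorSet,
    cfg: FilterConfig | None = None,
    invariant: np.ndarray | None = None,
) -> tuple[ScoreTable, float]:
    """Vectors -> partials -> scores -> filters; returns table and r_thr.

    ``invariant`` marks alignment columns with fewer than two observed
    residues; they keep a (tiny but nonzero) substitution vector yet
    carry no coevolution information, so they are excluded from ranking
    alongside zero-variance sites.
    """
    cfg = cfg or FilterConfig()
    partials = {}
    for feature in ["substitution", *SIGN_RULES]:
        C = pearson_matrix(vectors, feature)
        partials[feature] = partial_matrix(C, ridge=cfg.ridge)
    st = overall_score(partials, cfg)
    if invariant is not None:
        st.degenerate |= np.asarray(invariant, bool)
    n_good = int((~st.degenerate).sum())
    n_pairs = max(1, n_good * (n_good - 1) // 2)
    r_thr = significance_threshold(cfg, n_pairs, partials["substitution"].n_branches)
    return site_filters(st, cfg, r_thr), r_thr
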