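"""Posterior-mean substitution vectors per site and branch.

For every branch b and site i the joint posterior of the branch's two
endpoint states is contracted with a characteristic change g_x(a -> b)
(substitution indicator, volume change, charge change, ...), giving the
posterior mean change v_x(i, b). Collecting these over branches yields,
per feature, a sites x branches matrix whose rows are the feature
vectors whose correlations across branches reveal concurrent and
compensatory substitutions between sites.

Under a codon model the characteristic change is applied to the encoded
amino acids, so synonymous codon substitutions contribute nothing to the
substitution indicator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment_io import Alignment
from .likelihood import (
    SiteLikelihoodResult,
    branch_endpoint_posteriors,
    site_log_likelihood,
)
from .models import GammaMixture, ReversibleModel
from .properties import FEATURES, PropertyTable
from .tree import PhyloTree


@dataclass
class SubstitutionVectorSet:
    """Per-feature matrices of posterior-mean changes, sites x branches."""

    vectors: dict[str, np.ndarray]
    n_sites: int
    n_branches: int

    def __getitem__(self, feature: str) -> np.ndarray:
        return self.vectors[feature]

    @property
    def features(self) -> list[str]:
        return list(self.vectors)

    def to_tsv(self, feature: str, path: str | Path) -> None:
        pd.DataFrame(
            self.vectors[feature],
            index=pd.RangeIndex(self.n_sites, name="site"),
            columns=[f"b{b}" for b in range(self.n_branches)],
        ).to_csv(path, sep="\t", float_format="%.10g")


def state_delta_matrix(
    table: PropertyTable, feature: str, model: ReversibleModel
) -> np.ndarray:
    """g_x lifted from amino-acid space to the model's state space."""
    g_aa = table.feature_delta_matrix(feature)
    aa_idx = model.space.aa_indices()
    return g_aa[np.ix_(aa_idx, aa_idx)]


def map_features(
    tree: PhyloTree,
    model: ReversibleModel,
    gamma: GammaMixture | None,
    aln: Alignment,
    features: tuple[str, ...] = FEATURES,
    table: PropertyTable | None = None,
    likelihood: SiteLikelihoodResult | None = None,
) -> SubstitutionVectorSet:
    """Posterior-mean substitution vectors for the requested features.

    ``likelihood`` may pass a precomputed :func:`site_log_likelihood`
    result (it caches the inside arrays the endpoint posteriors need);
    otherwise it is computed here.
    """
    table = table or PropertyTable.default()
    res = likelihood or site_log_likelihood(tree, model, gamma, aln)
    joint = branch_endpoint_posteriors(res)  # (Nb, S, S, sites)
    vectors: dict[str, np.ndarray] = {}
    for feature in features:
        G = state_delta_matrix(table, feature, model)
        vectors[feature] = np.einsum("bacs,ac->sb", joint, G)
    return SubstitutionVectorSet(vectors, aln.n_cols, tree.n_branches)


def map_feature(
    tree: PhyloTree,
    model: ReversibleModel,
    gamma: GammaMixture | None,
    aln: Alignment,
    feature: str,
    table: PropertyTable | None = None,
) -> np.ndarray:
    """Single-feature convenience wrapper: the sites x branches matrix."""
    return map_features(tree, model, gamma, aln, (feature,), table)[feature]
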