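"""Amino-acid property tables and per-substitution characteristic changes.

Each substitution a -> b at a site is characterised by a set of scalar
changes g_x(a, b): the substitution indicator (1 for a != b) plus signed
differences prop(b) - prop(a) of side-chain properties (volume, charge,
hydrogen-bonding capability, hydrophobicity, secondary-structure
propensities, and four class indicators). Compensation between spatially
close sites shows up as *negative* correlation of these signed changes,
which is why all difference channels keep their sign.

The default table ships with the package as a TSV and can be replaced by
any file with the same columns (`PropertyTable.from_tsv`).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: substitution indicator plus the ten property-difference channels
FEATURES = (
    "substitution",
    "volume",
    "charge",
    "hbond",
    "hydrophobicity",
    "beta_propensity",
    "turn_propensity",
    "aromatic",
    "branched",
    "crosslink",
    "ionic",
    "alpha_propensity",
)

#: channels entering the default overall coevolution score (alpha propensity
#: is computed and reported but excluded from the overall score)
SCORED_FEATURES = FEATURES[:-1]

_ACCEPTORS = set("NDQEHSTY")
_DONORS = set("RNQHKSTWY")
_AROMATIC = set("HFWY")
_BRANCHED = set("ILV")
_CROSSLINK = set("NQST")


class PropertyTable:
    """Per-amino-acid property values backing the feature channels.

    Parameters
    ----------
    frame:
        DataFrame indexed by one-letter amino-acid code with the columns of
        the packaged TSV. Validated against the fixed membership of the
        indicator channels (hydrogen-bond acceptors/donors, aromatic,
        branched, cross-link, ionic) on construction.
    """

    _INDICATOR_SETS = {
        "hbond_acceptor": _ACCEPTORS,
        "hbond_donor": _DONORS,
        "aromatic": _AROMATIC,
        "branched": _BRANCHED,
        "crosslink": _CROSSLINK,
    }

    def __init__(self, frame: pd.DataFrame):
        missing = set(AMINO_ACIDS) - set(frame.index)
        if missing:
            raise ValueError(f"property table missing amino acids: {sorted(missing)}")
        self.frame = frame.loc[list(AMINO_ACIDS)]
        self._validate()
        self._columns: dict[str, np.ndarray] = {
            c: self.frame[c].to_numpy(float) for c in self.frame.columns
        }

    def _validate(self) -> None:
        for col, members in self._INDICATOR_SETS.items():
            got = {a for a in AMINO_ACIDS if self.frame.loc[a, col] > 0}
            if got != members:
                raise ValueError(
                    f"column {col!r} must flag exactly {sorted(members)}, got {sorted(got)}"
                )
        ionic = self.frame["ionic"]
        if not all(ionic[a] == 1 for a in "DERK") or ionic["H"] != 0.1:
            raise ValueError("ionic channel must be 1 for asp/glu/arg/lys and 0.1 for his")
        charge = self.frame["charge"]
        if not (all(charge[a] == 1 for a in "RK") and all(charge[a] == -1 for a in "DE")):
            raise ValueError("charge must be +1 for arg/lys and -1 for asp/glu")

    @classmethod
    def default(cls, his_charge: float | None = None) -> "PropertyTable":
        """Load the packaged table; optionally override the histidine charge."""
        with resources.files("cosubst.data").joinpath("aa_properties.tsv").open() as fh:
            frame = pd.read_csv(fh, sep="\t", comment="#", index_col="aa")
        if his_charge is not None:
            frame.loc["H", "charge"] = his_charge
        return cls(frame)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PropertyTable":
        return cls(pd.read_csv(path, sep="\t", comment="#", index_col="aa"))

    def values(self, column: str) -> np.ndarray:
        """Property values ordered as :data:`AMINO_ACIDS`."""
        if column not in self._columns:
            raise KeyError(f"unknown property column {column!r}")
        return self._columns[column]

    def feature_delta_matrix(self, feature: str) -> np.ndarray:
        """20x20 matrix of g_x(a, b) for all ordered amino-acid pairs.

        ``substitution`` is the indicator 1 - delta(a, b); every other
        feature is the signed difference prop(b) - prop(a), with the
        hydrogen-bond channel using the combined capability
        acceptor + donor.
        """
        n = len(AMINO_ACIDS)
        if feature == "substitution":
            return 1.0 - np.eye(n)
        if feature == "hbond":
            prop = self.values("hbond_acceptor") + self.values("hbond_donor")
        elif feature in ("hbond_acceptor", "hbond_donor"):
            prop = self.values(feature)
        elif feature in FEATURES:
            prop = self.values(feature)
        else:
            raise KeyError(f"unknown feature {feature!r}")
        return prop[None, :] - prop[:, None]

    def feature_delta(self, feature: str, a: str, b: str) -> float:
        """g_x for a single substitution ``a -> b`` (one-letter codes)."""
        try:
            ia, ib = AA_INDEX[a.upper()], AA_INDEX[b.upper()]
        except KeyError as exc:
            raise KeyError(f"not a standard amino acid: {exc.args[0]!r}") from None
        return float(self.feature_delta_matrix(feature)[ia, ib])
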