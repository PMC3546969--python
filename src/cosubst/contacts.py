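"""True contact maps from structures and prediction-accuracy metrics.

A residue pair is a contact when the minimum distance over heavy-atom
pairs is strictly below the cutoff (default 5 angstroms) and the residues
are at least ``min_separation`` apart along the chain (default 6).
Prediction quality is measured by PPV among the top-k predictions and by
two distances in the 2-D sequence-position plane: MDPNT, the mean
distance from each predicted pair to its nearest true contact, and MDTNP,
the mean distance from each true contact to its nearest prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

DEFAULT_CUTOFF = 5.0
DEFAULT_MIN_SEPARATION = 6


@dataclass
class StructureChain:
    """Residues of one chain: 1-based positions, names, heavy-atom coords."""

    positions: list[int]
    residue_names: list[str]
    coordinates: list[np.ndarray]  # per residue, (n_atoms, 3)

    def __post_init__(self):
        if not self.positions:
            raise ValueError("empty structure chain")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("residue positions must be strictly increasing")
        if any(len(c) < 1 for c in self.coordinates):
            raise ValueError("every residue needs at least one atom")


def read_structure_chain(
    path: str | Path, chain_id: str | None = None, include_hydrogens: bool = False
) -> StructureChain:
    """Read one chain of a PDB/mmCIF file into a StructureChain (gemmi)."""
    import gemmi

    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    model = structure[0]
    chain = model[chain_id] if chain_id is not None else model[0]
    positions, names, coords = [], [], []
    for residue in chain:
        atoms = [
            [a.pos.x, a.pos.y, a.pos.z]
            for a in residue
            if include_hydrogens or a.element.name != "H"
        ]
        if not atoms or residue.seqid.num is None:
            continue
        if positions and residue.seqid.num <= positions[-1]:
            continue  # altloc/insertion duplicates
        positions.append(residue.seqid.num)
        names.append(residue.name)
        coords.append(np.asarray(atoms, dtype=float))
    return StructureChain(positions, names, coords)


@dataclass
class ContactMap:
    """Unordered contact pairs (i < j) with the defining parameters."""

    pairs: set[tuple[int, int]]
    cutoff: float | None = DEFAULT_CUTOFF
    min_separation: int = DEFAULT_MIN_SEPARATION

    def __post_init__(self):
        self.pairs = {(min(i, j), max(i, j)) for i, j in self.pairs}
        if any(j - i < self.min_separation for i, j in self.pairs):
            raise ValueError("contact pair closer than the minimum separation")

    def __contains__(self, pair: tuple[int, int]) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


def contacts_from_coordinates(
    chain: StructureChain,
    cutoff: float = DEFAULT_CUTOFF,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> ContactMap:
    """All residue pairs with minimum heavy-atom distance < cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    atoms = np.concatenate(chain.coordinates)
    owner = np.concatenate(
        [np.full(len(c), r) for r, c in enumerate(chain.coordinates)]
    )
    tree = cKDTree(atoms)
    pairs = set()
    for a, b in tree.query_pairs(cutoff, output_type="ndarray"):
        ra, rb = int(owner[a]), int(owner[b])
        if ra == rb:
            continue
        pi, pj = chain.positions[ra], chain.positions[rb]
        if pi > pj:
            pi, pj = pj, pi
        if pj - pi >= min_separation and np.linalg.norm(atoms[a] - atoms[b]) < cutoff:
            pairs.add((pi, pj))
    return ContactMap(pairs, cutoff, min_separation)


def _canonical(pairs) -> np.ndarray:
    arr = np.array([(min(i, j), max(i, j)) for i, j in pairs], dtype=float)
    return arr.reshape(-1, 2)


def ppv(pred, truth: ContactMap, k: int) -> float:
    """Positive predictive value TP / (TP + FP) over the top-k pairs."""
    pairs = pred.pairs(k) if hasattr(pred, "pairs") else list(pred)[:k]
    if k < 1 or not pairs:
        raise ValueError("k must be >= 1 with at least one prediction")
    pairs = pairs[:k]
    tp = sum(1 for p in pairs if p in truth)
    return tp / len(pairs)


def mdpnt(pred, truth: ContactMap, k: int) -> float:
    """Mean distance from each top-k prediction to its nearest true contact
    in the (i, j) sequence-position plane."""
    if len(truth) == 0:
        raise ValueError("empty contact map")
    pairs = pred.pairs(k) if hasattr(pred, "pairs") else list(pred)[:k]
    if not pairs:
        raise ValueError("no predictions")
    P = _canonical(pairs[:k])
    T = _canonical(truth.pairs)
    d = np.sqrt(((P[:, None, :] - T[None, :, :]) ** 2).sum(axis=2))
    return float(d.min(axis=1).mean())


def mdtnp(pred, truth: ContactMap, k: int) -> float:
    """Mean distance from every true contact to its nearest top-k
    prediction in the (i, j) sequence-position plane."""
    if len(truth) == 0:
        raise ValueError("empty contact map")
    pairs = pred.pairs(k) if hasattr(pred, "pairs") else list(pred)[:k]
    if not pairs:
        raise ValueError("no predictions")
    P = _canonical(pairs[:k])
    T = _canonical(truth.pairs)
    d = np.sqrt(((T[:, None, :] - P[None, :, :]) ** 2).sum(axis=2))
    return float(d.min(axis=1).mean())
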