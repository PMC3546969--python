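"""Alignment reading, target-column masking, and joint OTU pruning.

Alignments are amino-acid multiple sequence alignments (FASTA or
Stockholm). Lowercase symbols (Pfam insert states) are uppercased for
computation, with a per-column flag retained so downstream evaluation can
exclude such columns. Analyses are carried out on the columns where the
*target* sequence has a residue; reported site positions are 1-based
positions in the target sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import AlignIO

from .properties import AMINO_ACIDS
from .tree import PhyloTree, prune_leaves

GAP_SYMBOLS = {"-", "."}
UNKNOWN_SYMBOLS = {"X", "B", "Z"}  # treated as missing data, not errors
_VALID = set(AMINO_ACIDS) | GAP_SYMBOLS | UNKNOWN_SYMBOLS


@dataclass
class Alignment:
    """Aligned sequences over {20 amino acids, gap '-', unknown X/B/Z}."""

    ids: list[str]
    rows: list[str]
    col_meta: pd.DataFrame = field(default=None)  # orig_col, lowercase

    def __post_init__(self):
        if not self.rows:
            raise ValueError("alignment has no sequences")
        n = len(self.rows[0])
        if n < 1:
            raise ValueError("alignment length must be >= 1")
        if any(len(r) != n for r in self.rows):
            raise ValueError("unequal row lengths in alignment")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence identifiers")
        for rid, row in zip(self.ids, self.rows):
            for col, sym in enumerate(row):
                if sym not in _VALID:
                    raise ValueError(
                        f"invalid symbol {sym!r} in sequence {rid!r}, column {col}"
                    )
        if self.col_meta is None:
            self.col_meta = pd.DataFrame(
                {"orig_col": range(n), "lowercase": [False] * n}
            )

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence {seq_id!r} not in alignment") from None

    def select_columns(self, cols: list[int]) -> "Alignment":
        meta = self.col_meta.iloc[list(cols)].reset_index(drop=True)
        return Alignment(
            list(self.ids),
            ["".join(r[c] for c in cols) for r in self.rows],
            meta,
        )

    def select_rows(self, keep_ids: list[str]) -> "Alignment":
        idx = [self.ids.index(i) for i in keep_ids]
        return Alignment(keep_ids, [self.rows[i] for i in idx], self.col_meta.copy())


@dataclass
class TargetMask:
    """Mapping from kept alignment columns to target-sequence positions."""

    target_id: str
    kept_columns: list[int]  # original column indices, strictly increasing

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.kept_columns, self.kept_columns[1:])):
            raise ValueError("kept_columns must be strictly increasing")

    def target_position(self, site: int) -> int:
        """1-based target position of masked-alignment site ``site``."""
        return site + 1

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "orig_col": self.kept_columns,
                "target_pos": range(1, len(self.kept_columns) + 1),
            }
        ).to_csv(path, sep="\t", index=False)


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read a FASTA or Stockholm alignment.

    Lowercase residues are uppercased; any column containing at least one
    lowercase residue is flagged ``lowercase`` in ``col_meta``.
    """
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise ValueError(f"could not parse {path} as {format}: {exc}") from exc
    ids = [rec.id for rec in msa]
    raw = [str(rec.seq) for rec in msa]
    n = len(raw[0])
    lowercase = [any(r[c].islower() for r in raw) for c in range(n)]
    rows = [r.upper().replace(".", "-") for r in raw]
    meta = pd.DataFrame({"orig_col": range(n), "lowercase": lowercase})
    return Alignment(ids, rows, meta)


def invariant_columns(aln: Alignment) -> "np.ndarray":
    """Columns with fewer than two distinct observed residues.

    Such sites carry no co-substitution information (their feature
    vectors are almost zero) and are excluded from contact prediction.
    """
    import numpy as np

    out = np.zeros(aln.n_cols, dtype=bool)
    for c in range(aln.n_cols):
        seen = {r[c] for r in aln.rows} & set(AMINO_ACIDS)
        out[c] = len(seen) < 2
    return out


def write_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n{row}\n")


def mask_to_target(aln: Alignment, target_id: str) -> tuple[Alignment, TargetMask]:
    """Keep exactly the columns where the target row has an amino acid.

    Gap and unknown (X/B/Z) target symbols drop the column. Idempotent:
    re-masking a masked alignment is the identity.
    """
    target_row = aln.row(target_id)
    kept = [c for c, sym in enumerate(target_row) if sym in AMINO_ACIDS]
    if not kept:
        raise ValueError(f"target {target_id!r} has no amino-acid columns")
    masked = aln.select_columns(kept)
    orig = [int(aln.col_meta.iloc[c]["orig_col"]) for c in kept]
    return masked, TargetMask(target_id, orig)


def prune_similar_otus(
    aln: Alignment,
    tree: PhyloTree,
    b_min: float,
    protected: set[str] | None = None,
) -> tuple[Alignment, PhyloTree]:
    """Drop near-duplicate OTUs whose pendant branch is shorter than b_min.

    Leaves are removed greedily, shortest pendant branch first, re-measuring
    after every removal (suppressing a degree-2 node lengthens the sibling's
    pendant branch, which may lift it above threshold). Protected leaves
    (e.g. seed sequences and the target) are never removed.
    """
    if b_min < 0:
        raise ValueError("b_min must be >= 0")
    protected = set(protected or ())
    extra = set(tree.labels) - set(aln.ids)
    if extra:
        raise ValueError(f"tree leaves missing from alignment: {sorted(extra)}")
    while True:
        candidates = [
            (tree.pendant_length(lab), lab)
            for lab in tree.labels
            if lab not in protected and tree.pendant_length(lab) < b_min
        ]
        if not candidates:
            break
        if tree.n_leaves <= 4:
            raise ValueError(
                "pruning would leave fewer than 4 leaves; no unrooted topology"
            )
        _, victim = min(candidates)
        tree = prune_leaves(tree, [victim])
    kept = [i for i in aln.ids if i in set(tree.labels)]
    dropped = aln.n_seqs - len(kept)
    if dropped:
        warnings.warn(f"pruned {dropped} near-duplicate OTUs", stacklevel=2)
    return aln.select_rows(kept), tree
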