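"""End-to-end orchestration: alignment + tree (+ structure) -> ranked
coevolving site pairs and, when a structure is given, accuracy metrics.

Stages: mask columns to the target sequence, prune near-duplicate OTUs,
optionally re-optimise branch lengths, map the posterior-mean feature
vectors, convert correlations to partial correlations, score, filter and
rank. Substitution-vector matrices are cached on disk keyed by a hash of
the inputs, since the mapping stage dominates runtime.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .alignment_io import (
    Alignment,
    mask_to_target,
    prune_similar_otus,
    read_alignment,
)
from .contacts import (
    ContactMap,
    contacts_from_coordinates,
    mdpnt,
    mdtnp,
    ppv,
    read_structure_chain,
)
from .likelihood import optimize_branch_lengths
from .mapping import SubstitutionVectorSet, map_features
from .models import (
    GammaMixture,
    ReversibleModel,
    build_codon_model,
    CodonModelParams,
    discrete_gamma,
    empirical_frequencies,
    poisson_model,
)
from .properties import FEATURES, PropertyTable
from .scoring import (
    FilterConfig,
    PredictionList,
    rank_pairs,
    score_pipeline,
)
from .tree import PhyloTree, read_newick

log = logging.getLogger("cosubst")


@dataclass
class ModelSpec:
    """Config-block description of the substitution model."""

    kind: str = "amino_poisson"  # amino_poisson | amino_gtr | codon
    frequencies: str = "uniform"  # uniform | empirical
    alpha: float | None = None  # gamma shape; None = no rate variation
    categories: int = 4
    exchangeability_tsv: str | None = None  # for amino_gtr

    def build(self, aln: Alignment) -> tuple[ReversibleModel, GammaMixture | None]:
        if self.kind == "amino_poisson":
            pi = (
                empirical_frequencies(aln.rows)
                if self.frequencies == "empirical"
                else None
            )
            model = poisson_model(pi)
        elif self.kind == "amino_gtr":
            import pandas as pd

            from .models import amino20_space, build_gtr_model

            if self.exchangeability_tsv is None:
                raise ValueError("amino_gtr requires exchangeability_tsv")
            s = pd.read_csv(
                self.exchangeability_tsv, sep="\t", index_col=0
            ).to_numpy(float)
            pi = (
                empirical_frequencies(aln.rows)
                if self.frequencies == "empirical"
                else np.full(20, 1 / 20)
            )
            model = build_gtr_model(amino20_space(), s, pi)
        elif self.kind == "codon":
            from .models import equal_codon_usage_frequencies

            params = CodonModelParams()
            if self.frequencies == "empirical":
                params.codon_freqs = equal_codon_usage_frequencies(
                    empirical_frequencies(aln.rows)
                )
            model = build_codon_model(params)
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")
        gamma = (
            discrete_gamma(self.alpha, self.categories)
            if self.alpha is not None
            else None
        )
        return model, gamma


@dataclass
class PipelineConfig:
    alignment: str = ""
    tree: str = ""
    alignment_format: str = "fasta"
    target_id: str | None = None
    structure: str | None = None
    structure_chain: str | None = None
    truth_pairs: str | None = None  # TSV with pos_i/pos_j, alt. to structure
    model: ModelSpec = field(default_factory=ModelSpec)
    filters: FilterConfig = field(default_factory=FilterConfig)
    b_min: float = 0.0
    protected: list[str] = field(default_factory=list)
    optimize_branches: bool = True
    top_k_rule: str = "fraction_of_contacts"  # | fraction_of_length | absolute
    top_k_value: float = 1 / 3
    output_dir: str = "cosubst_out"
    seed: int = 0
    his_charge: float | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        model = ModelSpec(**raw.pop("model", {}))
        filters = FilterConfig(**raw.pop("filters", {}))
        return cls(model=model, filters=filters, **raw)


def _resolve_top_k(cfg: PipelineConfig, n_sites: int, truth: ContactMap | None) -> int:
    if cfg.top_k_rule == "absolute":
        return max(1, int(round(cfg.top_k_value)))
    if cfg.top_k_rule == "fraction_of_length":
        return max(1, int(round(cfg.top_k_value * n_sites)))
    if cfg.top_k_rule == "fraction_of_contacts":
        if truth is None:
            raise ValueError("fraction_of_contacts needs a structure or truth table")
        return max(1, int(round(cfg.top_k_value * len(truth))))
    raise ValueError(f"unknown top-k rule {cfg.top_k_rule!r}")


def _load_truth(cfg: PipelineConfig) -> ContactMap | None:
    if cfg.structure is not None:
        chain = read_structure_chain(cfg.structure, cfg.structure_chain)
        return contacts_from_coordinates(
            chain, min_separation=cfg.filters.min_separation
        )
    if cfg.truth_pairs is not None:
        import pandas as pd

        frame = pd.read_csv(cfg.truth_pairs, sep="\t")
        return ContactMap(
            set(zip(frame["pos_i"], frame["pos_j"])),
            cutoff=None,
            min_separation=cfg.filters.min_separation,
        )
    return None


def _vector_cache_key(aln: Alignment, tree: PhyloTree, cfg: PipelineConfig) -> str:
    h = hashlib.sha256()
    for rid, row in zip(aln.ids, aln.rows):
        h.update(rid.encode())
        h.update(row.encode())
    h.update(tree.write_newick().encode())
    h.update(
        json.dumps(
            [asdict(cfg.model), cfg.optimize_branches, cfg.his_charge]
        ).encode()
    )
    return h.hexdigest()[:16]


def compute_vectors(
    aln: Alignment,
    tree: PhyloTree,
    cfg: PipelineConfig,
    cache_dir: Path | None = None,
) -> tuple[SubstitutionVectorSet, PhyloTree]:
    """Model build, optional branch-length optimisation, feature mapping."""
    model, gamma = cfg.model.build(aln)
    table = PropertyTable.default(his_charge=cfg.his_charge)
    key = _vector_cache_key(aln, tree, cfg)
    cache = cache_dir / f"vectors_{key}.npz" if cache_dir else None
    if cache is not None and cache.exists():
        data = np.load(cache)
        vecs = SubstitutionVectorSet(
            {f: data[f] for f in FEATURES}, aln.n_cols, tree.n_branches
        )
        log.info("loaded cached substitution vectors (%s)", cache.name)
        return vecs, tree
    if cfg.optimize_branches:
        tree = optimize_branch_lengths(tree, model, gamma, aln)
    vecs = map_features(tree, model, gamma, aln, FEATURES, table)
    if cache is not None:
        cache.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(cache, **vecs.vectors)
    return vecs, tree


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full prediction pipeline and write all artifacts.

    Returns the JSON-serialisable run report. Output files: score table
    TSV, prediction TSV, report.json and a log of the key sizes
    (N OTUs, N_b, N_sites, N_pairs, r_thr).
    """
    t0 = time.time()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": cfg.seed, "stages": []}

    def stage(name):
        report["stages"].append(name)
        log.info("stage: %s", name)

    try:
        stage("read inputs")
        aln = read_alignment(cfg.alignment, cfg.alignment_format)
        tree = read_newick(cfg.tree)

        positions = np.arange(1, aln.n_cols + 1)
        if cfg.target_id is not None:
            stage("mask to target")
            aln, mask = mask_to_target(aln, cfg.target_id)
            mask.to_tsv(out / "target_mask.tsv")
            positions = np.arange(1, aln.n_cols + 1)

        if cfg.b_min > 0:
            stage("prune near-duplicate OTUs")
            protected = set(cfg.protected)
            if cfg.target_id:
                protected.add(cfg.target_id)
            aln, tree = prune_similar_otus(aln, tree, cfg.b_min, protected)

        stage("substitution mapping")
        vecs, tree = compute_vectors(aln, tree, cfg, cache_dir=out / "cache")

        stage("correlation scoring")
        from .alignment_io import invariant_columns

        st, r_thr = score_pipeline(vecs, cfg.filters, invariant_columns(aln))

        truth = _load_truth(cfg)
        k = _resolve_top_k(cfg, aln.n_cols, truth)
        stage("ranking")
        preds = rank_pairs(st, cfg.filters, k, positions=positions)
        preds.frame.to_csv(out / "predictions.tsv", sep="\t", index=False)
        _write_score_table(st, positions, out / "scores.tsv")

        n_good = int((~st.degenerate).sum())
        report.update(
            {
                "n_otus": aln.n_seqs,
                "n_branches": tree.n_branches,
                "n_sites": aln.n_cols,
                "n_variable_sites": n_good,
                "n_pairs": n_good * (n_good - 1) // 2,
                "r_thr": r_thr,
                "top_k": k,
                "n_predictions": len(preds),
                "n_anomalous_sites": int(st.anomalous.sum()),
            }
        )
        log.info(
            "N=%d N_b=%d N_sites=%d N_pairs=%d r_thr=%.4f",
            aln.n_seqs,
            tree.n_branches,
            aln.n_cols,
            report["n_pairs"],
            r_thr,
        )

        if truth is not None:
            stage("evaluation")
            report["evaluation"] = {
                "n_contacts": len(truth),
                "ppv": ppv(preds, truth, k),
                "mdpnt": mdpnt(preds, truth, k),
                "mdtnp": mdtnp(preds, truth, k),
            }
    except Exception as exc:
        report["error"] = f"{report['stages'][-1]}: {exc}"
        report["incomplete"] = True
        (out / "report.json").write_text(json.dumps(report, indent=2))
        raise
    report["runtime_s"] = round(time.time() - t0, 3)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _write_score_table(st, positions, path: Path) -> None:
    import pandas as pd

    n = st.n_sites
    iu, ju = np.triu_indices(n, 1)
    cols = {
        "pos_i": positions[iu],
        "pos_j": positions[ju],
        "zeta_sub": st.zeta_sub[iu, ju],
    }
    for feature, z in st.components.items():
        cols[f"zeta_{feature}"] = z[iu, ju]
    cols["zeta"] = st.zeta[iu, ju]
    cols["zeta_effective"] = st.zeta_effective[iu, ju]
    excl = st.excluded_sites()
    cols["terminal"] = st.terminal[iu] | st.terminal[ju]
    cols["excluded"] = excl[iu] | excl[ju]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6g")
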