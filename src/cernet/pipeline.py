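"""End-to-end study orchestration.

Runs simulate (or load) → per-profile inference → disease merge → topology
→ cross-network comparison/hubs → pathway modules and cross-talk classes,
writing every intermediate as a TSV under the output directory plus a
machine-readable ``summary.json`` of all counts.  Stages communicate only
through written files, so each is independently re-runnable; the run is
deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import comparison, inference, io, pathways, simulate, topology
from .types import CeRNANetwork, ExpressionProfile, GeneSetCollection

logger = logging.getLogger("cernet")


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run.

    Defaults encode the selection rules of the emulated study: >=3 shared
    miRNAs, Holm-adjusted hypergeometric p < 0.01, Pearson R > 0 with
    p < 0.01, hubs = top 10% by degree, neighbor-conservation Simpson
    threshold 0.8, core edges in >=16 networks, modularity communities of
    size in (3, 300), clique percolation at k = 3.
    """

    seed: int = 0
    # either a synthetic-study spec ...
    simulate: dict[str, Any] | None = None
    # ... or concrete input files
    interactions_path: str | None = None
    profiles: list[dict[str, Any]] = field(default_factory=list)
    gene_sets_path: str | None = None
    features_path: str | None = None

    min_shared: int = 3
    alpha_holm: float = 0.01
    alpha_p: float = 0.01
    r_min: float = 0.0
    filter_on: str = "p"
    top_frac: float = 0.10
    simpson_threshold: float = 0.8
    core_min: int = 16
    community_min: int = 4
    community_max: int = 299
    k_clique: int = 3
    n_permutations: int = 0
    dicer_gene: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha_holm <= 1) or not (0 <= self.alpha_p <= 1):
            raise ValueError("significance thresholds must lie in (0, 1]")
        if self.min_shared < 1 or self.core_min < 1 or self.k_clique < 3:
            raise ValueError("invalid count threshold")
        if not (0 < self.top_frac <= 1) or not (0 <= self.simpson_threshold <= 1):
            raise ValueError("invalid hub parameters")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**io.read_run_config(path))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@_stage("inputs")
def _load_inputs(config: RunConfig, outdir: Path):
    if config.simulate is not None:
        cfg = simulate.SyntheticConfig(**{"seed": config.seed, **config.simulate})
        study = simulate.generate_study(cfg)
        inputs = outdir / "inputs"
        inputs.mkdir(parents=True, exist_ok=True)
        io.write_interactions(study.interactions, inputs / "interactions.tsv")
        io.write_gene_sets(study.pathways, inputs / "pathways.gmt")
        io.write_transcript_features(study.features, inputs / "features.tsv")
        truth_df = pd.DataFrame(
            sorted(study.truth.planted_pairs), columns=["gene_a", "gene_b"]
        )
        truth_df.to_csv(inputs / "planted_pairs.tsv", sep="\t", index=False)
        for prof in study.profiles:
            io.write_expression(prof, inputs / f"expression_{prof.profile_id}.tsv")
        dicer = study.truth.dicer_gene_id
        return study.interactions, study.profiles, study.pathways, study.features, dicer
    if config.interactions_path is None or not config.profiles:
        raise ValueError("config must provide either 'simulate' or input paths")
    interactions = io.read_interactions(config.interactions_path)
    profiles = [
        io.read_expression(
            p["path"],
            profile_id=p["profile_id"],
            disease=p.get("disease", ""),
            platform=p.get("platform", ""),
            log2_transform=bool(p.get("raw", False)),
        )
        for p in config.profiles
    ]
    gene_sets = (
        io.read_gene_sets(config.gene_sets_path) if config.gene_sets_path else None
    )
    features = (
        io.read_transcript_features(config.features_path)
        if config.features_path
        else None
    )
    return interactions, profiles, gene_sets, features, config.dicer_gene


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute the full study; returns the summary dict (also written as
    ``summary.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    netdir = outdir / "networks"
    netdir.mkdir(exist_ok=True)
    summary: dict[str, Any] = {"seed": config.seed}

    interactions, profiles, gene_sets, features, dicer_gene = _load_inputs(
        config, outdir
    )

    candidates = _stage("candidate_pairs")(inference.candidate_pairs)(
        interactions, min_shared=config.min_shared, alpha_holm=config.alpha_holm
    )
    candidates.to_csv(outdir / "candidate_pairs.tsv", sep="\t", index=False)
    summary["n_pairs_min_shared"] = int(len(candidates))
    summary["n_candidate_pairs"] = int(candidates["candidate"].sum())

    profile_nets = _stage("profile_networks")(inference.infer_all_profiles)(
        profiles,
        candidates,
        r_min=config.r_min,
        alpha_p=config.alpha_p,
        filter_on=config.filter_on,
    )
    for net in profile_nets:
        io.write_network(net, netdir / f"profile_{net.network_id}.tsv")
    summary["profile_edge_counts"] = {
        n.network_id: n.n_edges for n in profile_nets
    }

    diseases = {p.profile_id: p.disease or p.profile_id for p in profiles}
    disease_nets = _stage("disease_merge")(comparison.merge_by_disease)(
        profile_nets, diseases
    )
    for dz, net in disease_nets.items():
        io.write_network(net, netdir / f"disease_{dz}.tsv")
    summary["disease_edge_counts"] = {d: n.n_edges for d, n in disease_nets.items()}

    global_net = _stage("global_merge")(comparison.merge_networks)(
        profile_nets, network_id="global", level="global"
    )
    io.write_network(global_net, netdir / "global.tsv")
    summary["global_edges"] = global_net.n_edges
    summary["global_genes"] = global_net.graph.number_of_nodes()

    # topology of the first non-empty profile network (study exemplar)
    exemplar = next((n for n in profile_nets if n.n_edges > 0), None)
    topo: dict[str, Any] = {}
    if exemplar is not None:
        topo["exemplar"] = exemplar.network_id
        try:
            fit = topology.fit_power_law(exemplar.degrees())
            topo["power_law_alpha"] = fit.alpha
            topo["power_law_xmin"] = fit.xmin
        except ValueError as exc:
            topo["power_law_alpha"] = None
            logger.info("power-law fit skipped: %s", exc)
        dvc = topology.degree_vs_coexpression(exemplar)
        topo["degree_coexpr_spearman"] = dvc.attrs["rho"]
        svc = topology.shared_mirna_vs_correlation(exemplar)
        topo["shared_mirna_coexpr_spearman"] = svc.attrs["rho"]
        comms = topology.detect_communities(
            exemplar,
            min_size=config.community_min,
            max_size=config.community_max,
            seed=config.seed,
        )
        topo["n_communities"] = len(comms)
        if dicer_gene is not None:
            prof = next(p for p in profiles if p.profile_id == exemplar.network_id)
            edges = exemplar.edges_frame()
            if len(edges) >= 2:
                r_low, r_high, p_dicer = topology.dicer_stratified_coexpression(
                    prof, edges, dicer_gene
                )
                topo["dicer_mean_r_low"] = float(np.mean(r_low))
                topo["dicer_mean_r_high"] = float(np.mean(r_high))
                topo["dicer_p"] = p_dicer
    summary["topology"] = topo

    simmat = _stage("similarity")(comparison.network_similarity_matrix)(
        profile_nets,
        n_permutations=config.n_permutations,
        seed=config.seed,
        universe=[tuple(t) for t in candidates.loc[candidates["candidate"], ["gene_a", "gene_b"]].itertuples(index=False)],
    )
    simmat.sim.to_csv(outdir / "similarity.tsv", sep="\t")
    if simmat.pvalues is not None:
        simmat.pvalues.to_csv(outdir / "similarity_pvalues.tsv", sep="\t")
    off_diag = simmat.sim.to_numpy()[~np.eye(len(simmat.sim), dtype=bool)]
    summary["similarity_mean"] = float(off_diag.mean()) if off_diag.size else None

    counts = comparison.edge_profile_counts(profile_nets)
    counts.to_csv(outdir / "edge_profile_counts.tsv", sep="\t", index=False)
    summary["edge_occurrence"] = comparison.edge_count_summary(
        counts, len(profile_nets)
    )

    core_min = min(config.core_min, len(profile_nets))
    core = _stage("core")(comparison.extract_core_network)(
        profile_nets, min_profiles=core_min
    )
    io.write_network(core, outdir / "core.tsv")
    summary["core_edges"] = core.n_edges
    summary["core_genes"] = core.graph.number_of_nodes()

    hub_records = _stage("hubs")(comparison.classify_hubs)(
        list(disease_nets.values()),
        top_frac=config.top_frac,
        simpson_threshold=config.simpson_threshold,
    )
    comparison.hubs_frame(hub_records).to_csv(outdir / "hubs.tsv", sep="\t", index=False)
    summary["hub_counts"] = comparison.hub_category_counts(hub_records)

    if gene_sets is not None:
        common_hub_genes = [r.gene for r in hub_records if r.category == "common"]
        dz_counts = {
            (r.gene_a, r.gene_b): int(r.count)
            for r in comparison.edge_profile_counts(
                list(disease_nets.values())
            ).itertuples(index=False)
        }
        modules = _stage("modules")(pathways.common_modules)(
            global_net,
            gene_sets,
            common_hub_genes,
            k=config.k_clique,
            edge_disease_counts=dz_counts,
        )
        mod_rows = [
            {
                "module": i + 1,
                "size": m.community.size,
                "genes": ",".join(sorted(m.community.members)),
            }
            for i, m in enumerate(modules)
        ]
        pd.DataFrame(mod_rows, columns=["module", "size", "genes"]).to_csv(
            outdir / "modules.tsv", sep="\t", index=False
        )
        summary["n_common_modules"] = len(modules)

        classified = _stage("crosstalk")(pathways.classify_network_pairs)(
            global_net, gene_sets
        )
        classified.to_csv(outdir / "crosstalk.tsv", sep="\t", index=False)
        summary["crosstalk_counts"] = pathways.crosstalk_counts(classified)

        norm_deg = pd.concat(
            [
                pathways.normalized_pathway_degree(net, gene_sets).assign(disease=dz)
                for dz, net in disease_nets.items()
            ],
            ignore_index=True,
        )
        norm_deg.to_csv(outdir / "normalized_pathway_degree.tsv", sep="\t", index=False)

        if core.graph.number_of_nodes() > 0:
            enr = pathways.geneset_enrichment(
                set(core.graph.nodes) & set(interactions.genes),
                gene_sets,
                interactions.genes,
            )
            enr.to_csv(outdir / "core_enrichment.tsv", sep="\t", index=False)
            summary["n_enriched_pathways_q05"] = int((enr["q_bh"] < 0.05).sum())

        if features is not None:
            annotated = gene_sets.all_genes
            pair_genes = {
                g
                for a, b in global_net.graph.edges
                for g in (a, b)
                if g in annotated
            }
            other = set(features.index) - pair_genes
            if pair_genes and other:
                feat_cmp = pathways.compare_transcript_features(
                    pair_genes, other, features
                )
                feat_cmp.to_csv(outdir / "feature_comparison.tsv", sep="\t", index=False)
                summary["feature_p"] = {
                    r.feature: r.p for r in feat_cmp.itertuples(index=False)
                }

    with (outdir / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", outdir)
    return summary


def config_to_dict(config: RunConfig) -> dict[str, Any]:
    return dataclasses.asdict(config)
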