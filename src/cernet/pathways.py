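"""Pathway-anchored analyses of ceRNA networks.

Maps pathway gene sets into networks, finds overlapping modules among
common hubs by k-clique percolation, classifies ceRNA pairs as within-
pathway (CPWP: some pathway contains both genes) or between-pathway (CPBP:
both genes annotated, no shared pathway), scores pathway-gene connectivity,
and compares transcript features of pathway-associated ceRNAs against the
rest of the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .inference import bh_fdr
from .types import CeRNANetwork, GeneSetCollection, canonical_pair

logger = logging.getLogger("cernet")

Edge = tuple[str, str]


def pathway_subnetwork(
    network: CeRNANetwork, gene_sets: GeneSetCollection
) -> CeRNANetwork:
    """Keep exactly the edges whose both endpoints are pathway genes."""
    allowed = gene_sets.all_genes
    sub = CeRNANetwork(
        network_id=f"{network.network_id}|pathway", level=network.level
    )
    for u, v, d in network.graph.edges(data=True):
        if u in allowed and v in allowed:
            sub.graph.add_edge(u, v, **d)
    return sub


@dataclass(frozen=True)
class CliqueCommunity:
    """An overlapping community from k-clique percolation."""

    members: frozenset[str]
    k: int

    @property
    def size(self) -> int:
        return len(self.members)


def clique_percolation(graph: nx.Graph | CeRNANetwork, k: int = 3) -> list[CliqueCommunity]:
    """k-clique percolation communities (CFinder-style).

    A community is the node union of a connected component of the k-clique
    adjacency graph, where two k-cliques are adjacent iff they share k-1
    nodes.  Communities may overlap.
    """
    if k < 3:
        raise ValueError("clique percolation requires k >= 3")
    g = graph.graph if isinstance(graph, CeRNANetwork) else graph
    comms = nx.community.k_clique_communities(g, k)
    out = [CliqueCommunity(members=frozenset(c), k=k) for c in comms]
    return sorted(out, key=lambda c: (-c.size, min(c.members)))


@dataclass
class CommonModule:
    """A clique-percolation module of the common-hub pathway subnetwork."""

    community: CliqueCommunity
    edges: pd.DataFrame  # gene_a, gene_b, n_diseases


def common_modules(
    global_network: CeRNANetwork,
    gene_sets: GeneSetCollection,
    common_hubs: Iterable[str],
    k: int = 3,
    edge_disease_counts: Mapping[Edge, int] | None = None,
) -> list[CommonModule]:
    """Overlapping modules among common hubs in the pathway subnetwork.

    The pathway-mapped global network is restricted to edges whose both
    endpoints are common hubs, then decomposed by k-clique percolation.
    Each module's edges are annotated with the number of disease networks
    in which they occur (0 when no counts are supplied).
    """
    hubs = set(common_hubs)
    mapped = pathway_subnetwork(global_network, gene_sets)
    sub = nx.Graph(
        (u, v, d)
        for u, v, d in mapped.graph.edges(data=True)
        if u in hubs and v in hubs
    )
    modules = []
    for comm in clique_percolation(sub, k=k):
        rows = []
        for u, v in sub.subgraph(comm.members).edges:
            a, b = canonical_pair(u, v)
            n_dz = edge_disease_counts.get((a, b), 0) if edge_disease_counts else 0
            rows.append((a, b, n_dz))
        edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "n_diseases"])
        modules.append(CommonModule(community=comm, edges=edges))
    return modules


@dataclass(frozen=True)
class PairPathwayClass:
    """Within-/between-pathway classification of one ceRNA pair."""

    gene_a: str
    gene_b: str
    label: str  # CPWP | CPBP | unclassified
    witnesses: frozenset[str]


def classify_pair(
    gene_a: str, gene_b: str, gene_sets: GeneSetCollection
) -> PairPathwayClass:
    """CPWP iff some pathway contains both genes; CPBP iff both genes are
    annotated but share no pathway; unclassified otherwise."""
    a, b = canonical_pair(gene_a, gene_b)
    sets_a, sets_b = gene_sets.sets_of(a), gene_sets.sets_of(b)
    shared = sets_a & sets_b
    if shared:
        return PairPathwayClass(a, b, "CPWP", shared)
    if sets_a and sets_b:
        return PairPathwayClass(a, b, "CPBP", sets_a | sets_b)
    return PairPathwayClass(a, b, "unclassified", frozenset())


def classify_network_pairs(
    network: CeRNANetwork, gene_sets: GeneSetCollection
) -> pd.DataFrame:
    """Classify every edge of a network; returns gene_a, gene_b, label,
    witnesses.  CPWP + CPBP rows together are exactly the edges with both
    endpoints pathway-annotated."""
    rows = []
    for u, v in network.graph.edges:
        c = classify_pair(u, v, gene_sets)
        rows.append((c.gene_a, c.gene_b, c.label, ",".join(sorted(c.witnesses))))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "label", "witnesses"])


def crosstalk_counts(classified: pd.DataFrame) -> dict[str, int]:
    vc = classified["label"].value_counts()
    return {
        "CPWP": int(vc.get("CPWP", 0)),
        "CPBP": int(vc.get("CPBP", 0)),
        "unclassified": int(vc.get("unclassified", 0)),
    }


def normalized_pathway_degree(
    network: CeRNANetwork, gene_sets: GeneSetCollection
) -> pd.DataFrame:
    """Degree of each mapped pathway gene divided by the network's max degree.

    Genes absent from the network are omitted; values lie in [0, 1], which
    makes pathway-gene connectivity comparable across disease networks.
    """
    degs = dict(network.graph.degree)
    if not degs:
        return pd.DataFrame(columns=["pathway", "gene", "normalized_degree"])
    max_deg = max(degs.values())
    rows = [
        (pw, g, degs[g] / max_deg)
        for pw, genes in sorted(gene_sets.sets.items())
        for g in sorted(genes)
        if g in degs and max_deg > 0
    ]
    return pd.DataFrame(rows, columns=["pathway", "gene", "normalized_degree"])


def geneset_enrichment(
    query_genes: Iterable[str],
    gene_sets: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided hypergeometric gene-set enrichment with BH correction.

    For each set S in a universe U and query Q ⊆ U, p = P(overlap >= |Q∩S|)
    under hypergeometric sampling of |Q| genes from U.
    """
    uni = set(universe)
    query = set(query_genes)
    if not query <= uni:
        raise ValueError("query genes must be a subset of the universe")
    rows = []
    for name, genes in sorted(gene_sets.sets.items()):
        s = genes & uni
        overlap = len(query & s)
        if overlap == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(s), len(query)))
        rows.append((name, overlap, len(s), p))
    df = pd.DataFrame(rows, columns=["pathway", "overlap", "set_size", "p"])
    df["q_bh"] = bh_fdr(df["p"].to_numpy())
    return df.sort_values("p", ignore_index=True)


def compare_transcript_features(
    pathway_pair_genes: Iterable[str],
    other_genes: Iterable[str],
    features: pd.DataFrame,
    feature_names: Sequence[str] = (
        "transcript_length",
        "exon_count",
        "conservation_score",
    ),
) -> pd.DataFrame:
    """One-sided Mann–Whitney comparison per transcript feature.

    Tests whether pathway-associated ceRNA genes exceed the background
    (alternative "greater") on each feature.  Genes missing from the
    feature table are excluded and logged.
    """
    group_a = [g for g in set(pathway_pair_genes) if g in features.index]
    group_b = [g for g in set(other_genes) if g in features.index]
    n_miss = len(set(pathway_pair_genes) | set(other_genes)) - len(group_a) - len(group_b)
    if n_miss:
        logger.info("compare_transcript_features: %d genes lack features, excluded", n_miss)
    if not group_a or not group_b:
        raise ValueError("both gene groups must have feature-annotated members")
    rows = []
    for feat in feature_names:
        xa = features.loc[group_a, feat].to_numpy(dtype=float)
        xb = features.loc[group_b, feat].to_numpy(dtype=float)
        if np.array_equal(np.sort(xa), np.sort(xb)):
            u, p = np.nan, 0.5
        else:
            res = stats.mannwhitneyu(xa, xb, alternative="greater")
            u, p = float(res.statistic), float(res.pvalue)
        rows.append(
            (feat, float(np.median(xa)), float(np.median(xb)), u, p)
        )
    return pd.DataFrame(
        rows,
        columns=["feature", "median_pathway", "median_other", "u_statistic", "p"],
    )
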