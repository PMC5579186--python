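"""Cross-network comparison: merging, Simpson similarity, conserved core,
hub identification and the common/differential/specific hub taxonomy.

The Simpson (overlap) index |A∩B| / min(|A|, |B|) is used both for network
similarity (over edge sets) and for hub-neighborhood conservation; it is
robust to unequal set sizes, which matters because profile networks differ
widely in edge count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import CeRNANetwork, canonical_pair

Edge = tuple[str, str]


def merge_networks(
    networks: Sequence[CeRNANetwork],
    network_id: str,
    level: str = "disease",
) -> CeRNANetwork:
    """Union of node and edge sets; duplicate edges deduplicated.

    When an edge occurs in several input networks its attributes are taken
    from the occurrence with the smallest Pearson p-value.
    """
    if not networks:
        raise ValueError("need at least one network to merge")
    merged = CeRNANetwork(network_id=network_id, level=level)
    for net in networks:
        merged.graph.add_nodes_from(net.graph.nodes)
        for u, v, d in net.graph.edges(data=True):
            a, b = canonical_pair(u, v)
            if merged.graph.has_edge(a, b):
                if d.get("p", np.inf) < merged.graph[a][b].get("p", np.inf):
                    merged.graph[a][b].update(d)
            else:
                merged.graph.add_edge(a, b, **d)
    return merged


def merge_by_disease(
    networks: Sequence[CeRNANetwork],
    diseases: Mapping[str, str],
) -> dict[str, CeRNANetwork]:
    """Merge profile networks into one network per disease label."""
    groups: dict[str, list[CeRNANetwork]] = {}
    for net in networks:
        groups.setdefault(diseases[net.network_id], []).append(net)
    return {
        dz: merge_networks(nets, network_id=dz, level="disease")
        for dz, nets in sorted(groups.items())
    }


def simpson_index(set_a: Iterable, set_b: Iterable) -> float:
    """Overlap coefficient |A∩B| / min(|A|,|B|); 0 when either is empty."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


@dataclass
class SimilarityMatrix:
    """Pairwise Simpson similarity of networks, with optional permutation p."""

    sim: pd.DataFrame
    pvalues: pd.DataFrame | None = None


def network_similarity_matrix(
    networks: Sequence[CeRNANetwork],
    n_permutations: int = 0,
    seed: int = 0,
    universe: Sequence[Edge] | None = None,
) -> SimilarityMatrix:
    """Simpson index over edge sets for every pair of networks.

    With ``n_permutations`` > 0 and a candidate-pair ``universe``, the
    significance of each observed index is estimated by resampling each
    network's edge count uniformly from the universe and recomputing the
    index; p = (1 + #{perm >= observed}) / (1 + n_permutations).
    """
    if len(networks) < 2:
        raise ValueError("need >=2 networks")
    ids = [n.network_id for n in networks]
    edge_sets = [n.edge_set() for n in networks]
    k = len(networks)
    sim = np.zeros((k, k))
    for i in range(k):
        sim[i, i] = 1.0 if edge_sets[i] else 0.0
        for j in range(i + 1, k):
            sim[i, j] = sim[j, i] = simpson_index(edge_sets[i], edge_sets[j])
    sim_df = pd.DataFrame(sim, index=ids, columns=ids)
    pv_df = None
    if n_permutations > 0:
        if universe is None:
            raise ValueError("permutation test requires a candidate-pair universe")
        uni = list(universe)
        rng = np.random.default_rng(seed)
        pv = np.full((k, k), np.nan)
        sizes = [min(len(s), len(uni)) for s in edge_sets]
        for i in range(k):
            pv[i, i] = 1.0 / (1.0 + n_permutations)
            for j in range(i + 1, k):
                obs = sim[i, j]
                count = 0
                for _ in range(n_permutations):
                    ea = rng.choice(len(uni), size=sizes[i], replace=False)
                    eb = rng.choice(len(uni), size=sizes[j], replace=False)
                    if simpson_index(ea, eb) >= obs:
                        count += 1
                pv[i, j] = pv[j, i] = (1 + count) / (1 + n_permutations)
        pv_df = pd.DataFrame(pv, index=ids, columns=ids)
    return SimilarityMatrix(sim=sim_df, pvalues=pv_df)


def edge_profile_counts(networks: Sequence[CeRNANetwork]) -> pd.DataFrame:
    """Occurrence count of every unique edge across the given networks."""
    counter: Counter[Edge] = Counter()
    for net in networks:
        counter.update(net.edge_set())
    df = pd.DataFrame(
        [(a, b, c) for (a, b), c in counter.items()],
        columns=["gene_a", "gene_b", "count"],
    )
    return df.sort_values(
        ["count", "gene_a", "gene_b"], ascending=[False, True, True], ignore_index=True
    )


def edge_count_summary(counts: pd.DataFrame, n_networks: int) -> dict[str, float]:
    """Distribution summary of edge occurrence counts."""
    total = len(counts)
    if total == 0:
        return {"n_edges": 0, "frac_in_1": 0.0, "frac_gt_10": 0.0, "frac_in_all": 0.0}
    c = counts["count"]
    return {
        "n_edges": total,
        "frac_in_1": float((c == 1).mean()),
        "frac_gt_10": float((c > 10).mean()),
        "frac_in_all": float((c == n_networks).mean()),
    }


def extract_core_network(
    networks: Sequence[CeRNANetwork],
    min_profiles: int = 16,
) -> CeRNANetwork:
    """Edges recurring in at least ``min_profiles`` networks.

    The default encodes the "observed in more than 15 networks" rule.
    Edge attributes are inherited from the occurrence with smallest p.
    """
    if min_profiles > len(networks):
        raise ValueError(
            f"min_profiles={min_profiles} exceeds the {len(networks)} networks supplied"
        )
    counts = edge_profile_counts(networks)
    keep = {
        (row.gene_a, row.gene_b)
        for row in counts.itertuples(index=False)
        if row.count >= min_profiles
    }
    core = CeRNANetwork(network_id="core", level="global")
    best_p: dict[Edge, float] = {}
    for net in networks:
        for u, v, d in net.graph.edges(data=True):
            e = canonical_pair(u, v)
            if e in keep and d.get("p", np.inf) < best_p.get(e, np.inf):
                best_p[e] = d.get("p", np.inf)
                core.graph.add_edge(*e, **d)
    return core


def identify_hubs(network: CeRNANetwork, top_frac: float = 0.10) -> set[str]:
    """Nodes in the top ``top_frac`` of the degree distribution.

    The threshold is the (1 - top_frac) quantile of the degree sequence
    (method "higher"); all nodes tied at the threshold are included, so the
    hub set is deterministic.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must lie in (0, 1]")
    degs = network.degrees()
    if degs.size == 0:
        return set()
    thresh = np.quantile(degs, 1 - top_frac, method="higher")
    return {n for n, d in network.graph.degree if d >= thresh}


@dataclass(frozen=True)
class HubRecord:
    """Classification of one hub gene across disease networks."""

    gene: str
    hub_networks: frozenset[str]
    category: str  # common | differential | specific
    max_neighbor_simpson: float


def classify_hubs(
    networks: Sequence[CeRNANetwork],
    top_frac: float = 0.10,
    simpson_threshold: float = 0.8,
) -> list[HubRecord]:
    """Three-way hub taxonomy over a set of (disease) networks.

    A gene that is a hub in exactly one network is *specific*.  Otherwise
    the Simpson index of its neighbor sets is computed for every pair of
    networks in which it is a hub: *common* if any pairwise index exceeds
    ``simpson_threshold``, else *differential*.
    """
    by_id = {n.network_id: n for n in networks}
    hub_networks: dict[str, set[str]] = {}
    for net in networks:
        for gene in identify_hubs(net, top_frac=top_frac):
            hub_networks.setdefault(gene, set()).add(net.network_id)
    records = []
    for gene in sorted(hub_networks):
        nets = sorted(hub_networks[gene])
        if len(nets) == 1:
            records.append(
                HubRecord(gene, frozenset(nets), "specific", float("nan"))
            )
            continue
        neighbor_sets = [set(by_id[nid].graph[gene]) for nid in nets]
        best = max(
            simpson_index(neighbor_sets[i], neighbor_sets[j])
            for i in range(len(nets))
            for j in range(i + 1, len(nets))
        )
        category = "common" if best > simpson_threshold else "differential"
        records.append(HubRecord(gene, frozenset(nets), category, best))
    return records


def hub_category_counts(records: Sequence[HubRecord]) -> dict[str, int]:
    counts = Counter(r.category for r in records)
    return {c: counts.get(c, 0) for c in ("common", "differential", "specific")}


def hubs_frame(records: Sequence[HubRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "category": r.category,
                "n_hub_networks": len(r.hub_networks),
                "hub_networks": ",".join(sorted(r.hub_networks)),
                "max_neighbor_simpson": r.max_neighbor_simpson,
            }
            for r in records
        ]
    )
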