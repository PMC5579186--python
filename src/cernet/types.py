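"""Core domain containers shared by every stage of the pipeline.

The pipeline reasons about four kinds of objects: a bipartite miRNA→gene
interaction table (the universe for the shared-miRNA hypergeometric test),
gene-by-sample expression profiles, pathway gene-set collections, and
undirected ceRNA networks whose edges carry both hypergeometric and
co-expression statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

#: edge attributes every ceRNA network edge carries (TSV column order)
EDGE_ATTRS = ("r", "p", "q", "n_shared")


@dataclass(frozen=True)
class InteractionTable:
    """Deduplicated set of (miRNA, gene) target interactions.

    ``m`` is the miRNA-universe size used by the hypergeometric test.  By
    default it equals the number of distinct miRNAs observed in the table;
    it may be overridden (e.g. to the full count of annotated miRNAs in the
    genome) when the table is known to be a subset.
    """

    pairs: frozenset[tuple[str, str]]
    m: int = 0

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("no interactions")
        for mirna, gene in self.pairs:
            if not mirna or not gene:
                raise ValueError("empty miRNA or gene id in interaction table")
        n_mirnas = len({mi for mi, _ in self.pairs})
        if self.m == 0:
            object.__setattr__(self, "m", n_mirnas)
        elif self.m < n_mirnas:
            raise ValueError(
                f"miRNA universe m={self.m} smaller than the {n_mirnas} "
                "distinct miRNAs present"
            )

    @cached_property
    def targets_of(self) -> dict[str, frozenset[str]]:
        """Map gene id → set of miRNAs targeting it."""
        out: dict[str, set[str]] = {}
        for mirna, gene in self.pairs:
            out.setdefault(gene, set()).add(mirna)
        return {g: frozenset(s) for g, s in out.items()}

    @cached_property
    def mirnas(self) -> frozenset[str]:
        return frozenset(mi for mi, _ in self.pairs)

    @cached_property
    def genes(self) -> frozenset[str]:
        return frozenset(g for _, g in self.pairs)


@dataclass
class ExpressionProfile:
    """A genes × samples expression matrix with study metadata.

    Values are expected on a log2-like scale after ingestion; gene ids are
    unique (duplicate probes collapsed at read time) and the matrix is
    finite.  At least 3 samples are required so Pearson correlation is
    defined with positive degrees of freedom.
    """

    profile_id: str
    values: pd.DataFrame  # index: gene ids, columns: sample ids
    disease: str = ""
    platform: str = ""

    def __post_init__(self) -> None:
        if self.values.shape[1] < 3:
            raise ValueError(
                f"profile {self.profile_id!r}: need >=3 samples, "
                f"got {self.values.shape[1]}"
            )
        if self.values.index.has_duplicates:
            raise ValueError(f"profile {self.profile_id!r}: duplicate gene ids")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or not np.isfinite(arr).all():
            raise ValueError(f"profile {self.profile_id!r}: non-finite values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named pathway gene sets (GMT semantics)."""

    sets: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set {name!r}")

    @cached_property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def sets_of(self, gene: str) -> frozenset[str]:
        """Pathway names annotating ``gene`` (possibly empty)."""
        return frozenset(n for n, g in self.sets.items() if gene in g)

    def __len__(self) -> int:
        return len(self.sets)


def canonical_pair(gene_a: str, gene_b: str) -> tuple[str, str]:
    """Order an undirected gene pair lexicographically; reject self-loops."""
    if gene_a == gene_b:
        raise ValueError(f"self-loop pair {gene_a!r}")
    return (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)


@dataclass
class CeRNANetwork:
    """Undirected ceRNA network at profile, disease or global level.

    Backed by a :class:`networkx.Graph`; every edge carries the attributes
    in :data:`EDGE_ATTRS` — Pearson ``r``, its p-value ``p``, the BH FDR
    ``q`` computed over the pairs tested in the source profile, and the
    number of shared miRNAs ``n_shared``.
    """

    network_id: str
    graph: nx.Graph = field(default_factory=nx.Graph)
    level: str = "profile"  # profile | disease | global

    def __post_init__(self) -> None:
        if self.level not in ("profile", "disease", "global"):
            raise ValueError(f"unknown network level {self.level!r}")
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops[:3]}")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_set(self) -> frozenset[tuple[str, str]]:
        """Canonically ordered undirected edge set."""
        return frozenset(canonical_pair(a, b) for a, b in self.graph.edges)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> np.ndarray:
        return np.array([d for _, d in self.graph.degree], dtype=int)

    def add_edge(self, gene_a: str, gene_b: str, **attrs: float) -> None:
        a, b = canonical_pair(gene_a, gene_b)
        self.graph.add_edge(a, b, **attrs)

    def edges_frame(self) -> pd.DataFrame:
        """Edge list as a DataFrame with canonical gene order."""
        rows = []
        for u, v, d in self.graph.edges(data=True):
            a, b = canonical_pair(u, v)
            rows.append({"gene_a": a, "gene_b": b, **{k: d.get(k) for k in EDGE_ATTRS}})
        cols = ["gene_a", "gene_b", *EDGE_ATTRS]
        return pd.DataFrame(rows, columns=cols).sort_values(
            ["gene_a", "gene_b"], ignore_index=True
        )


def network_from_edges(
    network_id: str,
    edges: Iterable[tuple[str, str, Mapping[str, float]]],
    level: str = "profile",
) -> CeRNANetwork:
    net = CeRNANetwork(network_id=network_id, level=level)
    for a, b, attrs in edges:
        net.add_edge(a, b, **attrs)
    return net
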