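"""Readers and writers for the pipeline's external formats.

All inputs are plain text: TSV for interactions, expression matrices,
transcript features and network edge lists; GMT for pathway gene sets;
YAML for run configuration.  Every other module consumes only the typed
containers produced here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .types import (
    EDGE_ATTRS,
    CeRNANetwork,
    ExpressionProfile,
    GeneSetCollection,
    InteractionTable,
)

logger = logging.getLogger("cernet")

PathLike = Union[str, Path]


def read_interactions(
    path: PathLike,
    *,
    has_header: bool = False,
    mirna_col: int = 0,
    gene_col: int = 1,
    m_override: int = 0,
) -> InteractionTable:
    """Read a miRNA→gene interaction TSV into an :class:`InteractionTable`.

    Duplicate rows are dropped (and counted in the log); the miRNA universe
    size ``m`` defaults to the number of distinct miRNAs unless
    ``m_override`` is given.
    """
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    n_dup = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if has_header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) <= max(mirna_col, gene_col):
                raise ValueError(
                    f"{path}:{lineno}: expected >= "
                    f"{max(mirna_col, gene_col) + 1} columns, got {len(fields)}"
                )
            pair = (fields[mirna_col].strip(), fields[gene_col].strip())
            if not pair[0] or not pair[1]:
                raise ValueError(f"{path}:{lineno}: empty miRNA or gene id")
            if pair in pairs:
                n_dup += 1
            pairs.add(pair)
    if not pairs:
        raise ValueError(f"{path}: no interactions")
    if n_dup:
        logger.info("%s: dropped %d duplicate interaction rows", path, n_dup)
    return InteractionTable(pairs=frozenset(pairs), m=m_override)


def write_interactions(table: InteractionTable, path: PathLike) -> None:
    with Path(path).open("w") as fh:
        for mirna, gene in sorted(table.pairs):
            fh.write(f"{mirna}\t{gene}\n")


def read_expression(
    path: PathLike,
    *,
    profile_id: str,
    disease: str = "",
    platform: str = "",
    log2_transform: bool = False,
    collapse: str = "mean",
) -> ExpressionProfile:
    """Read a genes × samples TSV (first column = gene id).

    Duplicate gene rows are collapsed (default: mean).  When
    ``log2_transform`` is set the values are mapped to ``log2(x + 1)``,
    intended for profiles delivered on a raw intensity/count scale.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need >=3 sample columns, got {df.shape[1]}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric expression column(s) {non_numeric}")
    if df.index.has_duplicates:
        if collapse != "mean":
            raise ValueError(f"unknown collapse method {collapse!r}")
        n_before = len(df)
        df = df.groupby(level=0, sort=False).mean()
        logger.info(
            "%s: collapsed %d duplicate gene rows by mean", path, n_before - len(df)
        )
    if log2_transform:
        df = np.log2(df + 1.0)
    df.index = df.index.astype(str)
    return ExpressionProfile(
        profile_id=profile_id, values=df, disease=disease, platform=platform
    )


def write_expression(profile: ExpressionProfile, path: PathLike) -> None:
    profile.values.to_csv(path, sep="\t", index_label="gene")


def read_gene_sets(path: PathLike) -> GeneSetCollection:
    """Read GMT: one set per line, fields name, description, genes..."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 fields, got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
            sets[name] = genes
    if not sets:
        raise ValueError(f"{path}: no gene sets")
    return GeneSetCollection(sets=sets)


def write_gene_sets(collection: GeneSetCollection, path: PathLike) -> None:
    with Path(path).open("w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


_NET_COLUMNS = ("gene_a", "gene_b", *EDGE_ATTRS)


def write_network(network: CeRNANetwork, path: PathLike) -> None:
    """Write an edge-list TSV: gene_a, gene_b, r, p, q, n_shared.

    Floats are rendered with 6 significant digits; a leading comment line
    preserves the network id and level for round-tripping.
    """
    with Path(path).open("w") as fh:
        fh.write(f"# network_id={network.network_id}\tlevel={network.level}\n")
        fh.write("\t".join(_NET_COLUMNS) + "\n")
        df = network.edges_frame()
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.gene_a}\t{row.gene_b}\t{row.r:.6g}\t{row.p:.6g}\t"
                f"{row.q:.6g}\t{int(row.n_shared)}\n"
            )


def read_network(path: PathLike) -> CeRNANetwork:
    path = Path(path)
    network_id, level = path.stem, "profile"
    net = None
    with path.open() as fh:
        lines = fh.readlines()
    start = 0
    if lines and lines[0].startswith("#"):
        meta = dict(
            kv.split("=", 1) for kv in lines[0][1:].strip().split("\t") if "=" in kv
        )
        network_id = meta.get("network_id", network_id)
        level = meta.get("level", level)
        start = 1
    if start < len(lines) and lines[start].startswith("gene_a"):
        start += 1
    net = CeRNANetwork(network_id=network_id, level=level)
    for lineno, line in enumerate(lines[start:], start=start + 1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != len(_NET_COLUMNS):
            raise ValueError(
                f"{path}:{lineno}: expected {len(_NET_COLUMNS)} columns, "
                f"got {len(fields)}"
            )
        a, b = fields[0], fields[1]
        if a == b:
            raise ValueError(f"{path}:{lineno}: self-loop edge {a!r}")
        net.add_edge(
            a,
            b,
            r=float(fields[2]),
            p=float(fields[3]),
            q=float(fields[4]),
            n_shared=int(fields[5]),
        )
    return net


def read_transcript_features(path: PathLike) -> pd.DataFrame:
    """Read per-gene transcript features.

    Columns: gene, transcript_length, exon_count, conservation_score.
    Lengths and exon counts must be positive.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    required = {"transcript_length", "exon_count", "conservation_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing feature column(s) {sorted(missing)}")
    if (df["transcript_length"] <= 0).any() or (df["exon_count"] < 1).any():
        raise ValueError(f"{path}: transcript lengths and exon counts must be positive")
    df.index = df.index.astype(str)
    return df


def write_transcript_features(features: pd.DataFrame, path: PathLike) -> None:
    features.to_csv(path, sep="\t", index_label="gene")


def read_run_config(path: PathLike) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run config must be a YAML mapping")
    return cfg


def configure_logging(logfile: PathLike | None = None, level: int = logging.INFO) -> None:
    """Log to stderr, and optionally also to ``logfile``."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
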