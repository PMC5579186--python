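"""Synthetic study generator with planted ceRNA structure.

Emulates, at desk scale, the ingredients of a multi-disease ceRNA study:

* a bipartite miRNA→gene target table in which designated gene pairs (and
  one gene clique) are guaranteed a large block of shared miRNAs, while all
  remaining target sets are drawn uniformly at random;
* one expression matrix per profile in which each planted pair (and the
  clique) loads on a shared latent factor, ``x = sqrt(rho) z + sqrt(1-rho) e``,
  so the population correlation equals ``rho`` exactly; all other genes are
  independent noise;
* a Dicer-proxy gene with bimodal expression across samples — the planted
  correlation is attenuated to ``rho * (1 - dicer_effect)`` in high-Dicer
  samples, mimicking miRNA-abundance-dependent ceRNA activity;
* pathway gene sets that cover a configurable fraction of the planted
  genes, and per-gene transcript features (length, exon count, conservation)
  shifted upward for pathway-planted genes.

Every generator is deterministic given ``cfg.seed``; each stage draws from
its own child RNG stream so adding a stage never perturbs earlier output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .types import ExpressionProfile, GeneSetCollection, InteractionTable

_DISEASES = ("CAD", "HCM", "DCM", "ICM", "HF", "MI", "PAH", "CHD")
_PLATFORMS = ("GPL96", "GPL570", "GPL6244")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated study design: 21 profiles over 8 diseases,
    a 386-miRNA universe with ~30 targets per gene (so random gene pairs
    share ~2.3 miRNAs on average and the >=3-shared filter is non-trivial),
    planted pairs correlated at rho = 0.8 over 100 samples, and a Dicer
    effect halving the correlation in high-Dicer samples.
    """

    seed: int = 0
    n_mirnas: int = 386
    n_genes: int = 2000
    n_samples: int = 100
    n_profiles: int = 21
    n_diseases: int = 8
    targets_per_gene: int = 30
    n_planted_pairs: int = 200
    planted_correlation: float = 0.8
    noise_sd: float = 1.0
    dicer_effect: float = 0.5
    n_pathways: int = 16
    pathway_size: int = 62
    planted_shared_mirnas: int = 18
    clique_size: int = 12
    pathway_planted_fraction: float = 1.0
    dicer_gene_id: str = "DICER1"

    def __post_init__(self) -> None:
        if self.targets_per_gene > self.n_mirnas:
            raise ValueError("targets_per_gene exceeds n_mirnas: infeasible")
        if not (3 <= self.planted_shared_mirnas <= self.targets_per_gene):
            raise ValueError("planted_shared_mirnas must be in [3, targets_per_gene]")
        if not (0 < self.planted_correlation < 1):
            raise ValueError("planted_correlation must lie in (0, 1)")
        if not (0 <= self.dicer_effect * self.planted_correlation < 1):
            raise ValueError("dicer_effect attenuates rho outside (0, 1)")
        if 2 * self.n_planted_pairs + self.clique_size + 1 > self.n_genes:
            raise ValueError("too many planted genes for n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_diseases > self.n_profiles:
            raise ValueError("need at least one profile per disease")
        if not (0 <= self.pathway_planted_fraction <= 1):
            raise ValueError("pathway_planted_fraction must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated study."""

    planted_pairs: frozenset[tuple[str, str]]
    clique_genes: frozenset[str]
    dicer_gene_id: str
    # pair -> profile ids in which the pair is co-expressed (here: all)
    activity: Mapping[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    pathway_of: Mapping[str, str] = field(default_factory=dict)
    disease_of_profile: Mapping[str, str] = field(default_factory=dict)


@dataclass
class SyntheticStudy:
    interactions: InteractionTable
    profiles: list[ExpressionProfile]
    pathways: GeneSetCollection
    features: pd.DataFrame
    truth: SyntheticTruth


def _rng(cfg: SyntheticConfig, stage: int) -> np.random.Generator:
    # independent child stream per stage
    return np.random.default_rng([stage, cfg.seed])


def gene_ids(cfg: SyntheticConfig) -> list[str]:
    width = len(str(cfg.n_genes))
    return [f"G{i:0{width}d}" for i in range(cfg.n_genes)]


def profile_ids(cfg: SyntheticConfig) -> list[str]:
    return [f"SIM{i + 1:02d}" for i in range(cfg.n_profiles)]


def planted_gene_pairs(cfg: SyntheticConfig) -> list[tuple[str, str]]:
    g = gene_ids(cfg)
    return [(g[2 * i], g[2 * i + 1]) for i in range(cfg.n_planted_pairs)]


def generate_interactions(
    cfg: SyntheticConfig,
) -> tuple[InteractionTable, SyntheticTruth]:
    """Generate the miRNA→gene table and the study ground truth.

    Planted pairs (and the clique) receive a dedicated block of
    ``planted_shared_mirnas`` shared miRNAs, guaranteeing they pass the
    >=3-shared filter; all remaining target slots are uniform draws.
    """
    rng = _rng(cfg, 1)
    genes = gene_ids(cfg)
    mirnas = [f"miR-{i + 1}" for i in range(cfg.n_mirnas)]
    pairs: set[tuple[str, str]] = set()

    n_extra = cfg.targets_per_gene - cfg.planted_shared_mirnas
    planted = planted_gene_pairs(cfg)
    clique = genes[2 * cfg.n_planted_pairs : 2 * cfg.n_planted_pairs + cfg.clique_size]
    special: dict[str, np.ndarray] = {}  # gene -> shared block indices
    for a, b in planted:
        block = rng.choice(cfg.n_mirnas, size=cfg.planted_shared_mirnas, replace=False)
        special[a] = block
        special[b] = block
    if clique:
        block = rng.choice(cfg.n_mirnas, size=cfg.planted_shared_mirnas, replace=False)
        for g in clique:
            special[g] = block

    for g in genes:
        if g in special:
            block = special[g]
            rest = np.setdiff1d(np.arange(cfg.n_mirnas), block)
            extra = rng.choice(rest, size=n_extra, replace=False)
            idx = np.concatenate([block, extra])
        else:
            idx = rng.choice(cfg.n_mirnas, size=cfg.targets_per_gene, replace=False)
        for j in idx:
            pairs.add((mirnas[j], g))

    table = InteractionTable(pairs=frozenset(pairs), m=cfg.n_mirnas)
    pids = profile_ids(cfg)
    disease_of = {
        pid: _DISEASES[i % cfg.n_diseases] for i, pid in enumerate(pids)
    }
    truth = SyntheticTruth(
        planted_pairs=frozenset(planted),
        clique_genes=frozenset(clique),
        dicer_gene_id=cfg.dicer_gene_id,
        activity={pair: frozenset(pids) for pair in planted},
        disease_of_profile=disease_of,
    )
    return table, truth


def generate_expression(
    cfg: SyntheticConfig, truth: SyntheticTruth, profile_index: int
) -> ExpressionProfile:
    """Generate one genes × samples profile with planted co-expression.

    Planted pairs load on a shared standard-normal factor z with weight
    sqrt(rho_eff), where rho_eff = rho in low-Dicer samples and
    rho * (1 - dicer_effect) in high-Dicer samples.  Clique genes all share
    one factor.  Everything else is independent Gaussian noise.  Values are
    shifted by per-gene baselines to resemble log2 intensities.
    """
    if not 0 <= profile_index < cfg.n_profiles:
        raise ValueError(f"profile_index {profile_index} out of range")
    rng = _rng(cfg, 1000 + profile_index)
    genes = gene_ids(cfg)
    n_g, n_s = cfg.n_genes, cfg.n_samples
    rho = cfg.planted_correlation

    # Dicer grouping: half the samples low, half high, in random order
    high = np.zeros(n_s, dtype=bool)
    high[rng.permutation(n_s)[: n_s // 2]] = True
    rho_eff = np.where(high, rho * (1.0 - cfg.dicer_effect), rho)

    X = rng.normal(0.0, 1.0, size=(n_g, n_s))
    pairs = sorted(truth.planted_pairs)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for a, b in pairs:
        z = rng.normal(0.0, 1.0, size=n_s)
        w = np.sqrt(rho_eff)
        v = np.sqrt(1.0 - rho_eff)
        X[gene_pos[a]] = w * z + v * rng.normal(0.0, 1.0, size=n_s)
        X[gene_pos[b]] = w * z + v * rng.normal(0.0, 1.0, size=n_s)
    if truth.clique_genes:
        z = rng.normal(0.0, 1.0, size=n_s)
        for g in sorted(truth.clique_genes):
            X[gene_pos[g]] = np.sqrt(rho_eff) * z + np.sqrt(1.0 - rho_eff) * rng.normal(
                0.0, 1.0, size=n_s
            )

    baseline = rng.normal(7.0, 1.0, size=(n_g, 1))
    values = baseline + cfg.noise_sd * X

    dicer = np.where(high, rng.normal(9.0, 0.3, n_s), rng.normal(5.0, 0.3, n_s))
    pid = profile_ids(cfg)[profile_index]
    samples = [f"{pid}_S{j + 1:03d}" for j in range(n_s)]
    df = pd.DataFrame(values, index=genes, columns=samples)
    df.loc[truth.dicer_gene_id] = dicer
    return ExpressionProfile(
        profile_id=pid,
        values=df,
        disease=truth.disease_of_profile.get(pid, _DISEASES[profile_index % cfg.n_diseases]),
        platform=_PLATFORMS[profile_index % len(_PLATFORMS)],
    )


def generate_pathways(
    cfg: SyntheticConfig, truth: SyntheticTruth
) -> GeneSetCollection:
    """Draw pathway gene sets overlapping the planted network.

    A ``pathway_planted_fraction`` share of the planted genes is dealt
    round-robin into the pathways (clique genes all land in the first
    pathway so they stay mutually within-pathway); remaining slots are
    filled with random background genes.
    """
    rng = _rng(cfg, 2)
    genes = gene_ids(cfg)
    planted_genes = sorted({g for pair in truth.planted_pairs for g in pair})
    n_take = int(round(cfg.pathway_planted_fraction * len(planted_genes)))
    taken = planted_genes[:n_take]

    members: list[set[str]] = [set() for _ in range(cfg.n_pathways)]
    for g in sorted(truth.clique_genes):
        members[0].add(g)
    for i, g in enumerate(taken):
        members[i % cfg.n_pathways].add(g)

    background = [g for g in genes if g not in set(planted_genes) | truth.clique_genes]
    pathway_of: dict[str, str] = {}
    sets: dict[str, frozenset[str]] = {}
    for k in range(cfg.n_pathways):
        name = f"PW{k + 1:02d}"
        need = cfg.pathway_size - len(members[k])
        if need > 0:
            fill = rng.choice(len(background), size=need, replace=False)
            members[k] |= {background[j] for j in fill}
        sets[name] = frozenset(members[k])
        for g in members[k]:
            pathway_of.setdefault(g, name)
    truth.pathway_of = pathway_of
    return GeneSetCollection(sets=sets)


def generate_transcript_features(
    cfg: SyntheticConfig, truth: SyntheticTruth, pathways: GeneSetCollection
) -> pd.DataFrame:
    """Per-gene transcript length, exon count and conservation score.

    Pathway-annotated planted genes ("pathway-associated ceRNAs") receive
    longer transcripts, more exons and higher conservation, providing a
    recoverable signal for the transcript-feature comparison.
    """
    rng = _rng(cfg, 3)
    genes = gene_ids(cfg)
    planted = {g for pair in truth.planted_pairs for g in pair} | truth.clique_genes
    assoc = np.array([g in planted and g in pathways.all_genes for g in genes])
    meanlog = np.where(assoc, 8.0, 7.5)
    length = np.exp(rng.normal(meanlog, 0.6)).round().astype(int) + 1
    exons = rng.poisson(np.where(assoc, 12.0, 8.0)) + 1
    cons = np.where(assoc, rng.beta(5.0, 2.0, len(genes)), rng.beta(2.0, 5.0, len(genes)))
    return pd.DataFrame(
        {
            "transcript_length": length,
            "exon_count": exons,
            "conservation_score": cons,
        },
        index=pd.Index(genes, name="gene"),
    )


def generate_study(cfg: SyntheticConfig) -> SyntheticStudy:
    """Generate the full study: interactions, profiles, pathways, features."""
    interactions, truth = generate_interactions(cfg)
    profiles = [
        generate_expression(cfg, truth, i) for i in range(cfg.n_profiles)
    ]
    pathways = generate_pathways(cfg, truth)
    features = generate_transcript_features(cfg, truth, pathways)
    return SyntheticStudy(
        interactions=interactions,
        profiles=profiles,
        pathways=pathways,
        features=features,
        truth=truth,
    )


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A scaled-down configuration for quick runs and unit tests."""
    base = dict(
        seed=seed,
        n_mirnas=120,
        n_genes=300,
        n_samples=60,
        n_profiles=6,
        n_diseases=3,
        targets_per_gene=15,
        n_planted_pairs=40,
        planted_shared_mirnas=12,
        clique_size=8,
        n_pathways=6,
        pathway_size=30,
    )
    base.update(overrides)
    return SyntheticConfig(**base)
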