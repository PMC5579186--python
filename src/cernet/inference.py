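"""Candidate ceRNA pair discovery and per-profile network construction.

Two competing endogenous RNAs are inferred in two stages:

1. *Shared-miRNA stage* (expression-independent).  For every unordered gene
   pair sharing at least ``min_shared`` miRNAs, the significance of the
   overlap ``r`` between the two target sets (sizes ``t`` and ``n``) inside a
   universe of ``m`` miRNAs is scored by the hypergeometric upper tail

       p = P(X >= r),  X ~ Hypergeometric(m, t, n),

   equivalently ``1 - sum_{i<r} C(t,i) C(m-t, n-i) / C(m,n)``.  P-values are
   Holm-adjusted once across the whole candidate universe and pairs with
   adjusted p below ``alpha_holm`` are flagged as candidates.

2. *Co-expression stage* (per profile).  Candidates are kept as network
   edges when their sample Pearson correlation is positive with two-sided
   p < ``alpha_p``; Benjamini–Hochberg q-values over all pairs tested in the
   profile are stored on each edge.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CeRNANetwork, ExpressionProfile, InteractionTable, canonical_pair

logger = logging.getLogger("cernet")

#: columns of the candidate-pair table
PAIR_COLUMNS = (
    "gene_a",
    "gene_b",
    "t",
    "n",
    "n_shared",
    "m",
    "p_hyper",
    "p_holm",
    "candidate",
)


def hypergeom_pvalue(m: int, t: int, n: int, r: int) -> float:
    """Upper-tail probability P(X >= r) of the shared-target overlap.

    ``m``: miRNA universe size; ``t``, ``n``: target-set sizes of the two
    genes; ``r``: observed overlap.  Evaluated through the hypergeometric
    survival function, which is numerically stable for large ``m``.
    """
    if not (0 <= r <= min(t, n)):
        raise ValueError(f"need 0 <= r <= min(t, n); got r={r}, t={t}, n={n}")
    if t > m or n > m:
        raise ValueError(f"target counts t={t}, n={n} exceed universe m={m}")
    if r == 0:
        return 1.0
    return float(stats.hypergeom.sf(r - 1, m, t, n))


def _check_probs(pvalues: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return p


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, in the original input order."""
    p = _check_probs(pvalues)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the original input order."""
    p = _check_probs(pvalues)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def candidate_pairs(
    interactions: InteractionTable,
    min_shared: int = 3,
    alpha_holm: float = 0.01,
) -> pd.DataFrame:
    """Score every gene pair sharing at least ``min_shared`` miRNAs.

    Returns a DataFrame with :data:`PAIR_COLUMNS`; the ``candidate`` flag
    marks pairs whose Holm-adjusted hypergeometric p-value is below
    ``alpha_holm``.  The Holm correction is applied once over the whole
    universe of pairs passing the ``min_shared`` filter.
    """
    genes = sorted(interactions.targets_of)
    mirnas = sorted(interactions.mirnas)
    mirna_idx = {mi: j for j, mi in enumerate(mirnas)}
    # binary gene × miRNA incidence; shared counts via one matmul
    A = np.zeros((len(genes), len(mirnas)), dtype=np.int32)
    for i, g in enumerate(genes):
        for mi in interactions.targets_of[g]:
            A[i, mirna_idx[mi]] = 1
    shared = A @ A.T
    tcounts = A.sum(axis=1)
    ia, ib = np.triu_indices(len(genes), k=1)
    keep = shared[ia, ib] >= min_shared
    ia, ib = ia[keep], ib[keep]
    r = shared[ia, ib]
    t, n = tcounts[ia], tcounts[ib]
    m = interactions.m
    p_hyper = stats.hypergeom.sf(r - 1, m, t, n)
    p_holm = holm_adjust(p_hyper) if len(p_hyper) else np.array([])
    df = pd.DataFrame(
        {
            "gene_a": np.array(genes, dtype=object)[ia],
            "gene_b": np.array(genes, dtype=object)[ib],
            "t": t,
            "n": n,
            "n_shared": r,
            "m": m,
            "p_hyper": p_hyper,
            "p_holm": p_holm,
            "candidate": p_holm < alpha_holm if len(p_holm) else [],
        },
        columns=list(PAIR_COLUMNS),
    )
    logger.info(
        "candidate_pairs: %d pairs share >=%d miRNAs, %d pass Holm < %g",
        len(df),
        min_shared,
        int(df["candidate"].sum()),
        alpha_holm,
    )
    return df


def pearson_edge_stats(
    profile: ExpressionProfile, gene_a: str, gene_b: str
) -> tuple[float, float] | None:
    """Sample Pearson r and two-sided p for one gene pair in one profile.

    Returns ``None`` (and logs) when a gene is absent or has zero variance;
    the p-value comes from the t distribution with ``n_samples - 2`` degrees
    of freedom.
    """
    for g in (gene_a, gene_b):
        if g not in profile.values.index:
            logger.debug("profile %s: gene %s absent, pair skipped", profile.profile_id, g)
            return None
    x = profile.values.loc[gene_a].to_numpy(dtype=float)
    y = profile.values.loc[gene_b].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        logger.debug(
            "profile %s: zero-variance gene in pair (%s, %s), skipped",
            profile.profile_id,
            gene_a,
            gene_b,
        )
        return None
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def pearson_stats_table(
    profile: ExpressionProfile, pairs: pd.DataFrame
) -> pd.DataFrame:
    """Vectorized Pearson r/p/q for many pairs in one profile.

    Pairs with a missing or zero-variance gene are dropped (logged).  The
    BH q-value is computed over all pairs actually tested here.
    """
    values = profile.values
    present = pairs["gene_a"].isin(values.index) & pairs["gene_b"].isin(values.index)
    if (~present).any():
        logger.info(
            "profile %s: %d pairs skipped (gene absent)",
            profile.profile_id,
            int((~present).sum()),
        )
    sub = pairs.loc[present, ["gene_a", "gene_b", "n_shared"]].copy()
    if sub.empty:
        return sub.assign(r=[], p=[], q=[])
    X = values.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    nonzero = sd[:, 0] > 0
    Z = np.zeros_like(X)
    np.divide(X - mu, sd, out=Z, where=sd > 0)
    gene_pos = {g: i for i, g in enumerate(values.index)}
    ia = sub["gene_a"].map(gene_pos).to_numpy()
    ib = sub["gene_b"].map(gene_pos).to_numpy()
    var_ok = nonzero[ia] & nonzero[ib]
    if (~var_ok).any():
        logger.info(
            "profile %s: %d pairs skipped (zero variance)",
            profile.profile_id,
            int((~var_ok).sum()),
        )
        sub = sub.loc[var_ok]
        ia, ib = ia[var_ok], ib[var_ok]
    n_s = profile.n_samples
    r = (Z[ia] * Z[ib]).sum(axis=1) / n_s
    r = np.clip(r, -1.0, 1.0)
    df_t = n_s - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(df_t / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(tstat), df_t))
    sub = sub.assign(r=r, p=p)
    sub["q"] = bh_fdr(sub["p"].to_numpy()) if len(sub) else []
    return sub.reset_index(drop=True)


def build_profile_network(
    profile: ExpressionProfile,
    candidates: pd.DataFrame,
    r_min: float = 0.0,
    alpha_p: float = 0.01,
    filter_on: str = "p",
) -> CeRNANetwork:
    """Construct the ceRNA network of one expression profile.

    Edges are candidate pairs with Pearson ``r > r_min`` and ``p < alpha_p``
    (``filter_on="q"`` filters on the BH q-value instead, reproducing the
    adjusted-p reading of the selection rule).  BH q-values over all tested
    pairs are stored on every retained edge regardless of the filter used.
    """
    if filter_on not in ("p", "q"):
        raise ValueError(f"filter_on must be 'p' or 'q', got {filter_on!r}")
    if "candidate" in candidates.columns:
        tested = candidates.loc[candidates["candidate"].astype(bool)]
    else:
        tested = candidates
    stats_df = pearson_stats_table(profile, tested)
    net = CeRNANetwork(network_id=profile.profile_id, level="profile")
    if stats_df.empty:
        return net
    crit = stats_df["p"] if filter_on == "p" else stats_df["q"]
    kept = stats_df.loc[(stats_df["r"] > r_min) & (crit < alpha_p)]
    for row in kept.itertuples(index=False):
        net.add_edge(
            row.gene_a,
            row.gene_b,
            r=float(row.r),
            p=float(row.p),
            q=float(row.q),
            n_shared=int(row.n_shared),
        )
    logger.info(
        "profile %s: %d / %d candidate pairs retained as ceRNA edges",
        profile.profile_id,
        net.n_edges,
        len(stats_df),
    )
    return net


def infer_all_profiles(
    profiles: Iterable[ExpressionProfile],
    candidates: pd.DataFrame,
    r_min: float = 0.0,
    alpha_p: float = 0.01,
    filter_on: str = "p",
) -> list[CeRNANetwork]:
    """Build one ceRNA network per expression profile."""
    return [
        build_profile_network(p, candidates, r_min=r_min, alpha_p=alpha_p, filter_on=filter_on)
        for p in profiles
    ]
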