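"""Topological characterization of a ceRNA network.

Covers the recurring descriptive analyses of a profile network: scale-free
degree-distribution fitting, the relationship between connectivity (node
degree, pair degree, shared-miRNA count) and co-expression strength,
modularity communities, Dicer-stratified co-expression, and cross-network
degree-distribution comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .inference import pearson_stats_table
from .types import CeRNANetwork, ExpressionProfile


@dataclass(frozen=True)
class PowerLawFit:
    """Discrete power-law fit of a degree sequence."""

    alpha: float
    xmin: int
    ks_distance: float
    n_tail: int


def fit_power_law(degrees, min_tail: int = 50) -> PowerLawFit:
    """Fit a discrete power law P(d) ∝ d^-alpha to a degree sequence.

    The exponent is the exact discrete maximum-likelihood estimate obtained
    by maximizing the Hurwitz-zeta likelihood over the tail d >= xmin; xmin
    is chosen to minimize the Kolmogorov–Smirnov distance between empirical
    and fitted CCDFs.  ``min_tail`` caps how far the xmin scan may erode the
    tail sample.
    """
    d = np.asarray(degrees, dtype=int)
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("cannot fit: empty degree sequence")
    uniq = np.unique(d)
    if uniq.size < 2:
        raise ValueError("cannot fit: degenerate (constant) degree sequence")
    if uniq.size < 10:
        raise ValueError(
            f"cannot fit: need >=10 distinct positive degrees, got {uniq.size}"
        )
    best: PowerLawFit | None = None
    for xmin in uniq:
        tail = d[d >= xmin]
        if tail.size < max(min_tail, 2) or np.unique(tail).size < 2:
            break
        logsum = float(np.sum(np.log(tail)))
        n = tail.size
        res = minimize_scalar(
            lambda a: n * np.log(zeta(a, xmin)) + a * logsum,
            bounds=(1.01, 8.0),
            method="bounded",
        )
        alpha = float(res.x)
        xs = np.arange(xmin, tail.max() + 1)
        fitted_ccdf = zeta(alpha, xs) / zeta(alpha, xmin)
        tail_sorted = np.sort(tail)
        # empirical P(D >= x) via searchsorted
        emp_ccdf = 1.0 - np.searchsorted(tail_sorted, xs, side="left") / n
        ks = float(np.max(np.abs(emp_ccdf - fitted_ccdf)))
        if best is None or ks < best.ks_distance:
            best = PowerLawFit(alpha=alpha, xmin=int(xmin), ks_distance=ks, n_tail=n)
    if best is None:
        raise ValueError("cannot fit: tail shorter than min_tail at every xmin")
    return best


def sample_power_law(
    alpha: float, size: int, xmin: int = 1, rng: np.random.Generator | None = None,
    xmax: int = 10**6,
) -> np.ndarray:
    """Draw integers from a discrete power law via inverse-CDF on x^-alpha."""
    if rng is None:
        rng = np.random.default_rng()
    x = np.arange(xmin, xmax + 1)
    pmf = x.astype(float) ** (-float(alpha))
    pmf /= pmf.sum()
    return x[np.searchsorted(np.cumsum(pmf), rng.random(size))]


def degree_vs_coexpression(network: CeRNANetwork, n_bins: int = 10) -> pd.DataFrame:
    """Mean incident-edge correlation per node-degree decile bin.

    Returns one row per bin with the mean Pearson r over edges incident to
    nodes in that bin, plus a Spearman trend statistic across bins stored
    in the frame's ``attrs`` (``rho``, ``pvalue``, ``degenerate``).
    """
    if network.n_edges == 0:
        raise ValueError("empty network")
    deg = dict(network.graph.degree)
    rows = []
    for node, d in deg.items():
        rs = [network.graph[node][nb]["r"] for nb in network.graph[node]]
        rows.append((node, d, float(np.mean(rs))))
    df = pd.DataFrame(rows, columns=["gene", "degree", "mean_r"])
    q_eff = min(n_bins, len(df))
    df["bin"] = pd.qcut(df["degree"].rank(method="first"), q_eff, labels=False)
    out = (
        df.groupby("bin")
        .agg(mean_degree=("degree", "mean"), mean_r=("mean_r", "mean"), n=("gene", "size"))
        .reset_index()
    )
    if out["mean_r"].nunique() < 2 or len(out) < 2:
        out.attrs.update(rho=0.0, pvalue=1.0, degenerate=True)
    else:
        res = stats.spearmanr(out["bin"], out["mean_r"])
        out.attrs.update(
            rho=float(res.statistic), pvalue=float(res.pvalue), degenerate=False
        )
    return out


def shared_mirna_vs_correlation(
    network: CeRNANetwork, min_bin_size: int = 5
) -> pd.DataFrame:
    """Mean edge correlation per shared-miRNA count, with a trend statistic."""
    if network.n_edges == 0:
        raise ValueError("empty network")
    rows = [
        (d["n_shared"], d["r"]) for _, _, d in network.graph.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["n_shared", "r"])
    out = (
        df.groupby("n_shared")
        .agg(mean_r=("r", "mean"), n=("r", "size"))
        .reset_index()
    )
    out["small_bin"] = out["n"] < min_bin_size
    if out["mean_r"].nunique() < 2 or len(out) < 2:
        out.attrs.update(rho=0.0, pvalue=1.0, degenerate=True)
    else:
        res = stats.spearmanr(out["n_shared"], out["mean_r"])
        out.attrs.update(
            rho=float(res.statistic), pvalue=float(res.pvalue), degenerate=False
        )
    return out


@dataclass(frozen=True)
class GroupComparison:
    """One-sided Mann–Whitney comparison of two correlation groups."""

    n_high: int
    n_low: int
    mean_high: float
    mean_low: float
    u_statistic: float
    pvalue: float
    applicable: bool = True


def pairdegree_vs_coexpression(
    network: CeRNANetwork,
    top_frac: float = 0.10,
    low_degrees: frozenset[int] = frozenset({1, 2}),
) -> GroupComparison:
    """Compare co-expression of high- vs low-pair-degree edges.

    Pair degree of an edge = sum of its endpoint degrees.  High group: the
    top ``top_frac`` of edges by pair degree; low group: edges whose both
    endpoint degrees fall in ``low_degrees``.  One-sided Mann–Whitney U
    tests whether high-pair-degree edges are more strongly co-expressed.
    """
    deg = dict(network.graph.degree)
    recs = []
    for u, v, d in network.graph.edges(data=True):
        recs.append((deg[u] + deg[v], deg[u], deg[v], d["r"]))
    if not recs:
        return GroupComparison(0, 0, np.nan, np.nan, np.nan, np.nan, applicable=False)
    df = pd.DataFrame(recs, columns=["pair_degree", "da", "db", "r"])
    cutoff = df["pair_degree"].quantile(1 - top_frac, interpolation="higher")
    high = df.loc[df["pair_degree"] >= cutoff, "r"]
    low = df.loc[df["da"].isin(low_degrees) & df["db"].isin(low_degrees), "r"]
    if high.empty or low.empty:
        return GroupComparison(
            len(high), len(low), float(high.mean()) if len(high) else np.nan,
            float(low.mean()) if len(low) else np.nan, np.nan, np.nan, applicable=False,
        )
    if high.nunique() == 1 and low.nunique() == 1 and high.iloc[0] == low.iloc[0]:
        return GroupComparison(
            len(high), len(low), float(high.mean()), float(low.mean()), np.nan, 0.5
        )
    res = stats.mannwhitneyu(high, low, alternative="greater")
    return GroupComparison(
        n_high=len(high),
        n_low=len(low),
        mean_high=float(high.mean()),
        mean_low=float(low.mean()),
        u_statistic=float(res.statistic),
        pvalue=float(res.pvalue),
    )


@dataclass(frozen=True)
class Community:
    """A modularity community of one network."""

    members: frozenset[str]
    method: str
    network_id: str

    @property
    def size(self) -> int:
        return len(self.members)


def detect_communities(
    network: CeRNANetwork,
    min_size: int = 4,
    max_size: int = 299,
    seed: int = 0,
) -> list[Community]:
    """Multi-level (Louvain) modularity communities, size-filtered.

    Only communities with ``min_size <= size <= max_size`` (defaults encode
    the "more than 3 and less than 300" rule) are retained.  Deterministic
    for a fixed seed.
    """
    if network.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    parts = nx.community.louvain_communities(network.graph, seed=seed)
    out = [
        Community(members=frozenset(p), method="modularity", network_id=network.network_id)
        for p in parts
        if min_size <= len(p) <= max_size
    ]
    return sorted(out, key=lambda c: (-c.size, sorted(c.members)[0]))


def community_size_histogram(communities: list[Community]) -> pd.DataFrame:
    sizes = pd.Series([c.size for c in communities], dtype=int)
    return (
        sizes.value_counts().sort_index().rename_axis("size").reset_index(name="count")
    )


def dicer_stratified_coexpression(
    profile: ExpressionProfile,
    pairs: pd.DataFrame,
    dicer_gene_id: str,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Recompute pair correlations within Dicer-low / Dicer-high samples.

    Samples are split at the median Dicer expression (ties to the low
    group); ``pairs`` is a table with gene_a/gene_b (candidate pairs or
    retained edges).  Returns the two correlation distributions and the
    one-sided Mann–Whitney p-value for r_low > r_high.
    """
    if dicer_gene_id not in profile.values.index:
        raise ValueError(f"Dicer gene {dicer_gene_id!r} absent from profile")
    dicer = profile.values.loc[dicer_gene_id]
    med = float(dicer.median())
    low_cols = dicer.index[dicer <= med]
    high_cols = dicer.index[dicer > med]
    if len(low_cols) < 3 or len(high_cols) < 3:
        raise ValueError("Dicer split leaves a group with <3 samples")
    sub_low = ExpressionProfile(
        profile_id=f"{profile.profile_id}|dicer_low",
        values=profile.values[low_cols],
        disease=profile.disease,
        platform=profile.platform,
    )
    sub_high = ExpressionProfile(
        profile_id=f"{profile.profile_id}|dicer_high",
        values=profile.values[high_cols],
        disease=profile.disease,
        platform=profile.platform,
    )
    need = pairs[["gene_a", "gene_b"]].copy()
    need["n_shared"] = pairs["n_shared"] if "n_shared" in pairs else 0
    r_low = pearson_stats_table(sub_low, need)["r"].to_numpy()
    r_high = pearson_stats_table(sub_high, need)["r"].to_numpy()
    if len(r_low) == 0 or len(r_high) == 0:
        raise ValueError("no testable pairs in a Dicer group")
    if np.array_equal(r_low, r_high):
        return r_low, r_high, 0.5
    p = float(stats.mannwhitneyu(r_low, r_high, alternative="greater").pvalue)
    return r_low, r_high, p


def ks_compare_degrees(
    network_a: CeRNANetwork, network_b: CeRNANetwork
) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test on the two degree sequences."""
    da, db = network_a.degrees(), network_b.degrees()
    if da.size == 0 or db.size == 0:
        raise ValueError("both networks must be non-empty")
    res = stats.ks_2samp(da, db)
    return float(res.statistic), float(res.pvalue)
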