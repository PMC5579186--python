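# Methods

## Model and procedure

`cernet` infers miRNA-mediated mRNA–mRNA cross-talk (competing endogenous
RNA, ceRNA) networks in two stages and then analyses them comparatively.

**Stage 1 — shared-miRNA candidates (expression-independent).**
From a bipartite miRNA→gene target table, every unordered gene pair is
scored by the overlap of its target sets. Writing `m` for the miRNA
universe size, `t` and `n` for the two genes' target counts and `r` for the
shared count, the significance of the overlap is the hypergeometric upper
tail

    p = P(X >= r) = 1 − Σ_{i=0}^{r−1} C(t,i) C(m−t, n−i) / C(m,n).

Pairs sharing fewer than 3 miRNAs are removed before testing. P-values are
Holm-adjusted **once across the entire candidate universe** (the candidate
set is a property of the interaction table, not of any expression profile),
and pairs with adjusted p < 0.01 become candidates. The tail is evaluated
through the hypergeometric survival function, which is stable for large
`m`; exact rational summation is used as the oracle in tests, never in the
pipeline.

`m` defaults to the number of distinct miRNAs in the supplied table. When
the table is a subset of a larger annotation, `m` can be overridden at read
time; a larger `m` makes every overlap look more surprising, so this choice
is deliberately explicit.

**Stage 2 — positive co-expression per profile.**
Because a ceRNA pair competes for a shared miRNA pool, its expression
should be positively correlated. For each expression profile, candidates
are kept as edges when the sample Pearson correlation satisfies R > 0 and
two-sided p < 0.01 (t distribution, n−2 df). Benjamini–Hochberg q-values
over all pairs tested in the profile are stored on every edge; a
`filter_on="q"` switch reproduces the stricter adjusted-p reading of the
rule. Raw-p filtering is the default because the BH q-values it produces
can then be inspected against any FDR level post hoc (they stay below 0.2
in the synthetic studies). Pairs with a missing or zero-variance gene are
skipped and logged, not errors: real platforms routinely lack genes.

**Cross-profile analyses.** Profile networks are merged by disease label
(edge union; a duplicated edge keeps the attributes of its smallest-p
occurrence — the best-supported observation). Network similarity uses the
Simpson (overlap) index |A∩B| / min(|A|,|B|) over edge sets, which is
insensitive to the large edge-count differences between profiles; its
significance is estimated by resampling each network's edge count uniformly
from the candidate universe (the source publication style of analysis
reports similarity p-values without naming a test, so the permutation
scheme here is this package's documented choice). The conserved core keeps
edges recurring in ≥ 16 of 21 networks ("more than 15"). Hubs are the top
10 % of nodes by degree, with the threshold at the 90th percentile
(`method="higher"`) and all ties included, so hub sets are deterministic.
A hub in exactly one network is *specific*; otherwise its neighbor sets in
the networks where it is a hub are compared pairwise by Simpson index —
*common* if any pair exceeds 0.8, else *differential*.

**Pathway analyses.** The pathway subnetwork keeps edges whose both
endpoints are pathway-annotated. Common modules are the k-clique
percolation communities (k = 3 by default; the smallest k for which the
method is defined) of the common-hub pathway subnetwork: communities are
connected components of the graph whose vertices are k-cliques, adjacent
when sharing k−1 nodes; they may overlap. Each edge of a ceRNA pair is
classified CPWP when some pathway contains both genes, CPBP when both
genes are annotated but share no pathway, and unclassified when at most
one gene is annotated — so CPWP + CPBP exactly counts the
doubly-annotated edges. Gene-set enrichment is a one-sided hypergeometric
test with BH correction, with the interaction-table gene set as the
default universe.

**Degree-distribution fit.** The power-law exponent is the exact discrete
maximum-likelihood estimate: α̂ maximizes −N log ζ(α, xmin) − α Σ log d_i
(Hurwitz zeta), with xmin chosen to minimize the KS distance between the
empirical and fitted CCDFs. The popular closed form
1 + N/Σ ln(d_i/(xmin−0.5)) is a continuous approximation that is biased by
≈ 0.4 at xmin = 1 for α = 2.5; the exact MLE recovers α within ±0.02 at
N = 10,000, which is why the package fits the likelihood numerically
instead of using the closed form.

## Synthetic-study generator

The generator produces the inputs the analysis assumes, with known ground
truth. Defaults encode the emulated study design: 21 profiles over 8
disease labels, a 386-miRNA universe, 2,000 genes with 30 targets each
(random pairs then share t·n/m ≈ 2.3 miRNAs, so the ≥3-shared filter keeps
a non-trivial ~40 % of pairs), 200 planted ceRNA pairs plus one 12-gene
clique, correlation ρ = 0.8 over 100 samples, and a Dicer effect of 0.5.

* *Interactions*: each planted pair (and the clique jointly) receives a
  dedicated block of 18 shared miRNAs — deep enough in the hypergeometric
  tail to survive Holm correction over ~10⁶ tests — with remaining target
  slots drawn uniformly.
* *Expression*: a planted pair loads on a shared latent factor,
  x = √ρ_eff·z + √(1−ρ_eff)·ε, the simplest construction whose population
  correlation equals ρ_eff exactly. A Dicer-proxy gene is bimodal across
  samples; in high-Dicer samples ρ_eff = ρ·(1 − dicer_effect), emulating
  attenuated ceRNA cross-talk when miRNA abundance is high. The source
  observation is qualitative, so this generative mechanism is the module's
  own modeling choice.
* *Pathways*: planted genes are dealt round-robin into the 16 sets
  (clique genes jointly into the first, keeping them within-pathway);
  remaining slots are random background genes.
* *Features*: transcript length (lognormal), exon count (Poisson + 1) and
  conservation (Beta) are shifted upward for pathway-annotated planted
  genes.

Each stage draws from its own child RNG stream (`[stage, seed]` seed
sequence), so adding a stage never perturbs earlier outputs; all outputs
are bit-reproducible given the seed.

**What the generator does not emulate** — and hence what green tests do
not establish about real data: platform/batch effects, missing values,
count-based (RNA-seq) noise, probe-mapping ambiguity, correlated
background genes, hub-degree heterogeneity (planted networks are a union
of disjoint pairs plus one clique, so degree distributions are nearly
degenerate and the power-law analysis is validated on zeta-sampled degree
sequences instead), and any dependence of ceRNA activity on miRNA
*identity* rather than a single global Dicer proxy.

## Numerical and design choices

* Holm/BH implementations are delegated to `statsmodels.stats.multitest`
  behind the package's `holm_adjust` / `bh_fdr` surface; hand-computed
  vectors pin the behavior in tests.
* Pearson statistics are computed vectorized on standardized rows; r is
  clipped to [−1, 1] before the t transform; |r| = 1 maps to p = 0.
* "Pair degree" of an edge is the sum of its endpoint degrees (top 10 % of
  edges vs edges with both endpoint degrees in {1, 2}); distribution
  comparisons use one-sided Mann–Whitney U throughout, chosen because
  correlation distributions are bounded and skewed.
* The Dicer split is at the median with ties to the low group; groups must
  keep ≥ 3 samples.
* Modularity communities come from seeded multi-level (Louvain)
  optimization via networkx; only sizes in (3, 300) are retained.
  Degenerate cases: a constant degree sequence cannot be power-law fitted
  (error); a constant-r network reports a zero trend with a `degenerate`
  flag; an empty comparison group yields a not-applicable result rather
  than an error.
* Self-loops are rejected everywhere; undirected pairs are canonicalized
  lexicographically (gene_a < gene_b).

## Problem sizes

The bundled tests exercise a scaled-down study (300 genes, 120 miRNAs, 6
profiles, 60 samples) for unit-level checks and the full design (2,000
genes, 386 miRNAs, 21 profiles, 100 samples) for the recovery,
calibration and classification analyses; `scripts/acceptance.py` re-runs
the full design from scratch. Null calibration of the co-expression filter
uses ~18,000 independent candidate pairs; the Dicer null calibration uses
50 seeded replicates of the scaled-down study.

## Known limitations

* The hypergeometric model treats target sets as uniform random draws;
  real target sets are structured (expression- and sequence-biased), so
  candidate p-values on real data are anti-conservative.
* Disease-level merging keeps the best-supported duplicate edge; no
  meta-analytic combination of per-profile correlations is attempted.
* The permutation test for network similarity resamples edges uniformly,
  ignoring degree structure; it answers "more overlap than random edge
  sets of the same size", not "more than random graphs of the same degree
  sequence".
* Clique percolation is exponential in the worst case; it is intended for
  the sparse common-hub subnetwork, not for whole profile networks.
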