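# cernet

Inference and comparative analysis of miRNA-mediated mRNA–mRNA cross-talk
(competing endogenous RNA, ceRNA) networks across multiple disease
expression profiles.

Transcripts that share miRNA response elements compete for a common miRNA
pool, so the abundance of one indirectly de-represses the other. `cernet`
turns that mechanism into a testable pipeline for systems-biology studies
that have (1) a miRNA→target interaction table, (2) several gene
expression profiles with disease labels, and (3) pathway gene sets. It is
aimed at computational biologists studying shared and disease-specific
regulatory structure across related conditions (the bundled synthetic
design emulates a multi-cohort cardiovascular-disease study).

## Method

A gene pair is a **candidate ceRNA pair** when its target sets overlap more
than expected by chance: with `m` miRNAs in the universe, `t` and `n`
targeting each gene and `r` shared, the pair is scored by the
hypergeometric upper tail

    p = 1 − Σ_{i=0}^{r−1} C(t,i) C(m−t, n−i) / C(m,n),

pairs sharing < 3 miRNAs are discarded, and Holm-adjusted p < 0.01 over the
whole candidate universe is required. A candidate becomes a **ceRNA edge**
of a profile network when its expression is positively correlated there
(Pearson R > 0, p < 0.01; BH q-values stored on every edge). Downstream,
the package characterizes network topology (discrete-MLE power-law fits,
degree/co-expression trends, Louvain communities, Dicer-stratified
co-expression), compares networks by the Simpson overlap index, extracts
the conserved core (edges in > 15 of 21 networks), classifies hubs (top
10 % by degree) into common / differential / specific by neighbor-set
conservation (Simpson > 0.8), finds pathway-anchored modules by k-clique
percolation among common hubs, and classifies pairs as within-pathway
(CPWP) or between-pathway (CPBP) cross-talk. See `docs/methods.md` for
assumptions, defaults and limitations.

A synthetic-study generator (`cernet.simulate`) plants ceRNA pairs with
known correlation, a Dicer-proxy effect, pathway membership and transcript
features, so the whole pipeline runs and is validated with no downloads.

## Worked example

Run the full pipeline on a small simulated study (6 profiles, 3 diseases,
300 genes):

```sh
cat > run.yaml <<'YAML'
seed: 5
simulate:
  n_mirnas: 120
  n_genes: 300
  n_samples: 60
  n_profiles: 6
  n_diseases: 3
  targets_per_gene: 15
  n_planted_pairs: 40
  planted_shared_mirnas: 12
  clique_size: 8
  n_pathways: 6
  pathway_size: 30
core_min: 6
dicer_gene: DICER1
YAML
cernet run --config run.yaml --out demo/
```

The summary it prints includes (abridged):

```json
{
  "n_pairs_min_shared": 12893,
  "n_candidate_pairs": 68,
  "profile_edge_counts": {"SIM01": 68, "SIM02": 68, "...": "..."},
  "core_edges": 68,
  "hub_counts": {"common": 88, "differential": 0, "specific": 0},
  "n_common_modules": 1,
  "crosstalk_counts": {"CPWP": 28, "CPBP": 40, "unclassified": 0},
  "topology": {
    "dicer_mean_r_low": 0.799,
    "dicer_mean_r_high": 0.361,
    "dicer_p": 7.3e-24
  }
}
```

Reading: 12,893 gene pairs share ≥ 3 miRNAs, of which 68 survive the Holm
filter — exactly the 40 planted pairs plus the 28 edges of the planted
8-gene clique. Every profile recovers all 68, so the conserved core equals
the planted network and all 88 participating genes are common hubs. The
clique genes sit in one pathway (28 CPWP edges); planted pairs straddle
pathways (40 CPBP edges). Planted co-expression is strong in Dicer-low
samples (mean r ≈ 0.80) and attenuated in Dicer-high samples (≈ 0.36), as
simulated. `demo/` contains every intermediate as TSV (networks,
similarity matrix, hub table, modules, cross-talk classes) plus
`summary.json`.

The same steps are available as library calls
(`cernet.candidate_pairs`, `cernet.build_profile_network`,
`cernet.classify_hubs`, …) and as the subcommands
`cernet simulate|infer|topology|compare|hubs|pathways`.

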