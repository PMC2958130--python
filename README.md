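# evoccur

Expression-variation occurrence analysis for paired two-condition expression
data (e.g. stimulated vs. unstimulated two-channel microarrays), across a
small cohort of donors.

The pipeline:

1. **EV scoring** (`ev_core`) — per donor, both intensity channels are
   variance-stabilized with a maximum-likelihood Box-Cox transform; on that
   scale the paired data are decomposed into mean intensity `A` and
   difference `M`, and GCV-tuned cubic smoothing splines through windowed
   robust location/scale estimates define an intensity-dependent dispersion
   band.  A gene's EV is its standardized distance from the band center,
   mapped one-to-one to a one-sided p-value (EV 1.28 ↔ p 0.10,
   EV 2.32 ↔ p 0.01).  Replicate probes are collapsed by median with a
   homogeneity summary.
2. **Occurrence selection** (`occurrence`) — a gene's occurrence is the
   number of donors in which it exceeds the EV threshold in the *same*
   direction.  Per-donor significance combines as a product bound
   (`p^k`) and a binomial tail; selections at each stringency level `k/n`
   are nested.
3. **Network structuring** (`netstruct`) — selected ("focus") genes are
   overlaid on an interaction graph and grouped into ≤35-gene networks by a
   deterministic greedy seed-and-grow procedure, scored by the
   hypergeometric upper tail (reported as −log10 p), with per-level
   structuring metrics (eligible / common / main-network / specific gene
   counts), meta-network components, cross-level sharing matrices, and
   Fisher-exact gene-set scores.
4. **Threshold optimization** (`optimizer`) — evaluates every occurrence
   level and recommends one via two rules: the structuring peak (maximal
   percentage of genes common to ≥2 networks) and best-score continuity
   across consecutive levels.
5. **Variability decomposition** (`variability`) — pairwise inter-donor
   selection overlap, a technical/biological split of the implied
   variability, and geometric-attrition projections of expected gene counts
   at stricter occurrence levels.
6. **Synthetic data** (`synthdata`) — seeded generators for heteroscedastic
   paired-intensity cohorts with per-donor response heterogeneity,
   module-structured interaction graphs, and enriched/random gene sets, so
   every stage is testable offline.

## CLI

All stages are exposed through one executable:

```sh
# generate a synthetic cohort + interaction graph + gene sets + truth labels
evoccur simulate --out-dir sim --n-genes 2000 --n-donors 6 --seed 7

# per-gene, per-donor EV scores (one TSV per donor in; ev_table.tsv out)
evoccur ev sim/donor*.tsv --out-dir ev

# occurrence counting and selection at one level
evoccur select --ev-table ev/ev_table.tsv --out-dir sel --k-min 4

# networks + structuring metrics for one level
evoccur networks --ev-table ev/ev_table.tsv --edges sim/edges.tsv \
    --out-dir nets --k-min 4

# full stringency grid + recommended occurrence threshold
evoccur optimize --ev-table ev/ev_table.tsv --edges sim/edges.tsv \
    --gmt sim/sets.gmt --out-dir opt

# inter-donor overlap and variability decomposition
evoccur variability --ev-table ev/ev_table.tsv --out-dir var
```

Common flags: `--config` (YAML mirroring `RunConfig`), `--seed`,
`--out-dir`.  Expression tables are TSV with columns
`gene_id, ref, test[, flag]` (`#` comments allowed; duplicate gene ids are
replicate probes); edge lists are TSV `gene_a, gene_b[, interaction]`; gene
sets use standard GMT.

## Notes

- The EV↔p mapping is the one-sided standard-normal tail; displayed
  thresholds truncate to two decimals while internal math keeps full
  precision.  Because the mapping is one-sided, null calibration is stated
  and tested per regulation direction (each direction's call rate at
  `p ≤ α` is `α`).
- No per-gene multiple-testing correction is applied; error control comes
  from occurrence combination across donors.
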