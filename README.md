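# paneldx

Biomarker panel discovery and small-sample validation for bulk expression
cohorts: differential-expression screening, preranked gene-set enrichment,
weighted co-expression modules, network hub ranking, sparse (L1) panel
selection, and two validation procedures built for tiny imbalanced cohorts —
nested cross-validation with Firth-penalized logistic regression and a safe
stratified 0.632+ bootstrap of a PCA + ridge classifier with a matched
permutation null.

A first-class synthetic-data module generates fixture studies with known
truth (planted differentially expressed genes, latent-factor co-expression
modules, probe multiplicity), plus hub-boosted interaction graphs and gene
set collections, so the whole pipeline is testable offline.

## Layout

| module               | what it does |
|----------------------|--------------|
| `paneldx.io`         | expression/phenotype/GMT/edge-list I/O, quantile normalization, probe→gene collapse, variance filter |
| `paneldx.dex`        | log2FC, moderated/ordinary/Welch t, exact & tie-corrected Wilcoxon rank-sum, BH-FDR, screening gate, summary tables |
| `paneldx.enrich`     | preranked KS-like enrichment (ES/NES, random-set permutation null) and hypergeometric over-representation |
| `paneldx.coexpr`     | soft-threshold scan (scale-free R² criterion), unsigned adjacency, TOM, static-cut module detection, eigengenes, merging, module–trait correlation |
| `paneldx.netrank`    | 11 centralities (Degree, MNC, DMNC, MCC, EPC, BottleNeck, EcCentricity, Closeness, Radiality, Betweenness, Stress) and ≥m-method consensus hubs |
| `paneldx.select`     | L1-penalized logistic path with stratified CV (λ_min/λ_1se), per-gene ROC/AUC, AUC + adjusted-p diagnostic gate |
| `paneldx.validate`   | Firth fit, nested CV, safe stratified 0.632+ bootstrap, permutation null, empirical p, Cohen's d |
| `paneldx.simulate`   | synthetic studies/graphs/gene sets with ground truth |
| `paneldx.pipeline` / `paneldx.cli` | orchestration, manifests, `paneldx` CLI |

## CLI

```sh
# synthetic fixture with planted truth
paneldx simulate --n-genes 2000 --n-de-genes 5 --effect 3 --seed 1 --out-dir fix/

# differential expression
paneldx dex --expression fix/expression.tsv --phenotype fix/phenotype.tsv \
    --group-a Case --group-b Control --out dex.tsv

# co-expression modules (power scanned automatically)
paneldx modules --expression fix/expression.tsv --phenotype fix/phenotype.tsv \
    --out-dir modules/

# hub ranking on an edge list
paneldx netrank --edges edges.tsv --top-k 10 --min-methods 3 --out-dir hubs/

# sparse panel selection
paneldx select --expression fix/expression.tsv --phenotype fix/phenotype.tsv \
    --group-a Case --group-b Control --rule 1se --out-dir panel/

# validation of a fixed panel
paneldx validate boot632 --expression fix/expression.tsv \
    --phenotype fix/phenotype.tsv --group-pos Case --group-neg Control \
    --panel g01995,g01996,g01997,g01998 -B 200 -P 200 --out boot.json

# everything in one pass
paneldx run-all --expression fix/expression.tsv --phenotype fix/phenotype.tsv \
    --group-pos Case --group-neg Control --out-dir run/
```

## Conventions

- Expression matrices are features × samples, log2 scale, throughout;
  transposition to samples × features happens only inside the validators.
- Two-sided exact rank-sum p-values are the doubled smaller tail, capped at 1.
- The DEG screen uses raw p with strict inequalities; the per-gene
  diagnostic gate uses BH-adjusted Wilcoxon p.
- All randomness flows from a single seed; simulation child streams are
  derived via `SeedSequence(seed, spawn_key=(component,))`.
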