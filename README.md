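# enrichdag

Disease-gene prediction from network-neighborhood functional enrichment.

Given a protein–protein interaction network (STRING-style edge list), GO
and KEGG annotation catalogs, and a list of known disease genes — the
motivating application is retinoblastoma (RB) gene screening — `enrichdag`
encodes every gene *g* by how over-represented each term *t* is among its
direct network neighbors:

    s(g, t) = −log10 P(X ≥ k),   X ~ Hypergeometric(N, K, n)

where, within an annotated background of size *N* containing *K* genes
annotated with *t*, the gene's *n* neighbors include *k* annotated ones.
On top of this encoding the pipeline runs:

1. **negative sampling & splitting** — negatives drawn at ratio 1:50 to the
   positives and split into 10 disjoint blocks, each paired with all
   positives (10 datasets, 660 rows each at the published geometry);
2. **Cramér's V filter** — features discretized to three states
   (mean ± t·sd) and dropped when V = √(χ²/(n·min(r−1, c−1))) < 0.1;
3. **mRMR ranking** — greedy minimum-redundancy maximum-relevance (MID:
   maximize I(f;c) − mean I(f;s) over selected s), alongside the pure
   relevance (MaxRel) sort;
4. **Dagging classification** — k = 10 disjoint random subsets, one linear
   SVM each, majority vote (ties → negative);
5. **incremental feature selection** — stratified 10-fold cross-validation
   (pooled confusion matrix) on the top-1, top-2, … ranked prefixes;
   the smallest prefix maximizing MCC is each dataset's optimal feature
   set, and the cross-dataset union is the final result, with Sn, Sp, Acc
   and MCC reported per dataset.

A seeded synthetic generator (network + annotations + shallow ontology with
a *planted* neighborhood signal) makes every stage runnable and testable
offline; no external database snapshot is required or bundled.

## Worked example

A complete run on a small synthetic corpus (300 genes, 70 terms, 20
positives, 10 planted signal terms at p1 = 0.9 against a p0 = 0.05
background):

```sh
$ cat demo.yaml
n_genes: 300
n_go_terms: 60
n_kegg_terms: 10
n_positives: 20
n_signal_terms: 10
p0: 0.05
p1: 0.9
mean_degree: 6
positive_module_extra_degree: 8

$ enrichdag simulate --workdir demo --config demo.yaml --seed 11
[simulate] seed=11 genes=300 terms=70 positives=20
$ enrichdag encode --workdir demo --negative-ratio 8 --n-datasets 4 --seed 2
[encode] seed=2 background=286 rows=180 features=70 datasets=4 rows_per_dataset=60
$ enrichdag filter --workdir demo
[filter] dataset=1 rows=60 kept=57/70
...
$ enrichdag rank --workdir demo --top-m 20
[rank] dataset=1 features=57 ranked=20
...
$ enrichdag ifs --workdir demo --d-max 10 --folds 5 --k 5 --seed 0
[ifs] dataset=1 seed=1 rows=60 optimal_d=3 MCC=1.0000
[ifs] dataset=2 seed=2 rows=60 optimal_d=2 MCC=1.0000
[ifs] dataset=3 seed=3 rows=60 optimal_d=2 MCC=1.0000
[ifs] dataset=4 seed=4 rows=60 optimal_d=2 MCC=1.0000
[ifs] union=4 features (BP=1, CC=2, MF=1)
$ enrichdag report --workdir demo
[report] categories=12 selected=4 enriched_terms_adj<0.05=0

$ cat demo/summary.csv
dataset,optimal_d,Sn,Sp,Acc,MCC
1,3,1.0000,1.0000,1.0000,1.0000
2,2,1.0000,1.0000,1.0000,1.0000
3,2,1.0000,1.0000,1.0000,1.0000
4,2,1.0000,1.0000,1.0000,1.0000
mean,,1.0000,1.0000,1.0000,1.0000
sd,,0.0000,0.0000,0.0000,0.0000
```

Reading the output: every dataset reaches MCC 1.0 using only 2–3 top-ranked
features — the planted signal is strong, so the incremental selection stops
at a very small optimal set, and the cross-dataset union (4 features,
tallied by GO namespace) contains the few discriminators actually needed.
Each stage writes its artifacts (feature matrix, surviving-feature lists,
MaxRel/mRMR tables, per-dataset IFS curves as CSV + PNG, the optimal union,
a category report, a positive-set enrichment table) into the working
directory, and `manifest.json` records every stage's arguments, seeds and
input digests for bit-identical re-runs.

The same workflow is available as a library:

```python
from enrichdag import SyntheticConfig, generate, run_pipeline, PipelineConfig

data = generate(SyntheticConfig(seed=17))
res = run_pipeline(data.network, data.catalog, data.positives,
                   data.negatives_universe.ids,
                   PipelineConfig(negative_ratio=10, n_datasets=5,
                                  top_m=50, d_max=30, seed=1))
print(res.summary["MCC"])   # (mean, sd) over the 5 datasets -> (1.0, 0.0)
print(len(res.union.union), res.union.namespace_counts)
```

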