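# phenonet

A toolkit for building and analysing literature-mined microbial phenotype
networks. It covers every computational stage around externally trained
NER/RE models: corpus preparation, span-metric evaluation, strain-name
normalization, network construction and scale-free analysis, triad-based
trophic interaction inference, gradient-boosted gene–phenotype association,
reference benchmarking, and a synthetic-data module that makes the whole
pipeline testable offline.

## Modules

| Module | Purpose |
| --- | --- |
| `phenonet.corpus` | Sentence/span/relation data model, corpus filtering rules, reference tokenizer, BIO encoding/decoding, stratified splits, strain-swap augmentation |
| `phenonet.evaluation` | Token-score aggregation to spans (max rule, ≥0.5 threshold), cross-entropy loss, strict/partial NER metrics (one-to-one span matching), binary RE metrics |
| `phenonet.normalize` | Two-stage Levenshtein strain matching (abbreviation-aware local fit, then full normalized distance) against a canonical catalog; term-variant clustering |
| `phenonet.network` | Typed directed multigraph from relation records; discrete power-law MLE with KS-minimizing cutoff and log-normal comparison; components, betweenness, Jaccard pairs, Leiden modularity; GraphML/TSV export |
| `phenonet.trophic` | Environment subnetworks, the four compound-mediated triad motifs (competition, direct inhibition, cross-feeding, resistance), interaction weights `w = n⁺ − n⁻` |
| `phenonet.genepheno` | Pfam copy-count feature matrices from InterProScan tables, phenotype cluster definition/filters, gradient-boosted classifiers with early stopping and gain ranking, pooled Fisher/BH GO enrichment |
| `phenonet.benchmark` | Strain-level comparison of predictions against a curated reference TSV, accuracy vs conflicting phenotypes |
| `phenonet.simulate` | Seeded generators for corpora, power-law relation networks, planted triads, planted-feature genomes, and perturbed strain catalogs — each with exact ground truth |
| `phenonet.cli` | `phenonet` command with composable pipeline stages |

All character offsets are 0-based and half-open. Inputs/outputs are plain
text: JSONL for sentences, annotations and relation records; TSV for
catalogs, edge lists and reports; GraphML for graphs.

## CLI

```sh
phenonet --seed 1 simulate --out sim/             # synthetic inputs + ground truth
phenonet prep-corpus --sentences sim/sentences.jsonl --out prep/
phenonet build-network --records sim/relations.jsonl --out net/
phenonet --seed 1 analyze-network --edges net/edges.tsv --out report.json --direction out
phenonet infer-trophic --edges net/edges.tsv --environment t0000002 --out trophic.tsv
phenonet normalize --terms sim/terms.txt --catalog sim/catalog.tsv --out norm.tsv
phenonet eval-ner --pred pred.jsonl --gold gold.jsonl --out metrics.tsv
phenonet benchmark --predictions pred.jsonl --reference bacdive.tsv --out bench.tsv
```

Each stage appends a `manifest.json` entry recording input hashes, the seed
and record counts; stages are deterministic given (inputs, config, seed).

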