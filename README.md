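# grnx

Inference of **direct transcriptional repression** in neural-progenitor
gene-regulatory networks, by integrating TF binding (ChIP-seq peaks) with
perturbation/time-course RNA-seq.

In the ventral neural tube, Sonic hedgehog signalling patterns progenitors
into discrete domains (dorsal, pMN, p3, floor plate), each defined by
transcription factors such as Nkx2.2, Olig2 and Nkx6.1. A striking feature
of this system is *selection by exclusion*: broadly acting activators
(SoxB, Gli) switch on the programs of several domains at once, and
domain-restricted repressors eliminate every program but one. Testing that
model genome-wide requires answering, gene by gene: *is this gene
down-regulated when a repressor is forced on, and does the repressor
actually bind near it?* `grnx` implements that analysis as a reusable,
tested pipeline — and ships a synthetic-data generator that plants a known
"broad activation + dense cross-repression" network, so every stage of the
pipeline can be scored against ground truth without any sequencing data.

It is aimed at computational biologists working on developmental GRNs who
want the downstream statistics (not read alignment or peak calling, which
are out of scope) in one place, with explicit, configurable thresholds.

## What it computes

- **Differential expression** (`grnx.diffexpr`): pairwise negative-binomial
  contrasts on gene-level counts. Counts are modelled as
  `K ~ NB(mu * s_j, phi)` with variance `mu + phi mu²`; `s_j` is the
  median-of-ratios size factor, `phi` a moderated method-of-moments
  dispersion, and the test a Wald statistic on the difference of log
  normalized means referred to a t distribution. P-values are
  Benjamini–Hochberg adjusted; a gene is *up*/*down* when
  `padj < alpha` and `|log2FC| >= lfc_min`. Exposed as
  `PairwiseNB(matrix, condA, condB, time_h).fit() -> DETable`.
- **Domain signatures** (`grnx.signatures`): gene sets defined by
  conjunctions of directional DE calls across contrasts (e.g. *dorsal* =
  up in dorsal-vs-pMN ∧ dorsal-vs-p3 ∧ dorsal-vs-FP at 36 h), with an
  optional peak-expression-time filter, plus early/intermediate/late
  temporal classification of induction profiles.
- **Peak–gene association** (`grnx.binding`): each peak summit is linked to
  the nearest TSS within 100 kb (promoter/distal split at ±1 kb); binding
  enrichment in a gene set versus a background is the 2×2 chi-squared test
  (no continuity correction, Fisher's exact reported for sparse tables).
- **CRE co-occupancy** (`grnx.binding`): peaks trimmed to summit ± 150 bp
  and merged across TFs into cis-regulatory elements; sharing fractions
  between TF pairs, CREs-per-gene counts, and activator/repressor overlap.
- **Direct-target calls** (`grnx.targets`): a signature gene is a *direct*
  repression target of an induced TF if it is both significantly
  down-regulated on induction and bound by that TF; repressed-but-unbound
  genes are *indirect*. Fold-repression strength distributions and
  Pearson correlations of transcriptomes over signature genes complete the
  picture.
- **Synthetic benchmark** (`grnx.synthetic`): generates counts, peaks,
  annotation and a serialized `SyntheticTruth` from a planted network
  (4 domain conditions × 4 time points, TF inductions, NB counts, decoy
  peaks and a decoy TF), fully determined by a config and one seed.

## Worked example

Simulate a dataset, run one induction contrast, then the whole pipeline:

```sh
grnx simulate --out demo --seed 1
grnx de --counts demo/counts.tsv --meta demo/metadata.tsv \
        --cond-a pMN --cond-b "pMN+Nkx2.2" --time 36 --out demo/de.tsv
```

```
Pairwise NB differential expression: pMN+Nkx2.2 vs pMN at 36 h
  genes tested          1647
  genes excluded (low)  153
  up   (padj<0.05, log2fc>=+1)  200
  down (padj<0.05, log2fc<=-1)  201
```

The 201 down-regulated genes are the planted pMN program (200 genes, all
carrying Nkx2.2 repressor edges) collapsing under forced Nkx2.2; the 200
up-regulated genes are the p3 program de-repressed as Nkx2.2 replaces the
resident pMN repressors.

```sh
grnx run --out demo_run --seed 1     # full pipeline + report.json
```

Key numbers from `demo_run/report.json` (seed 1):

```json
"signature_jaccard": {"dorsal": 1.0, "pMN": 1.0, "p3": 1.0, "FP": 1.0},
"targets": {"pMN+Nkx2.2": {
    "fraction_repressed": 1.0,
    "fraction_repressed_bound": 0.69,
    "background_bound_fraction": 0.048,
    "recovery": {"precision": 0.978, "recall": 1.0, "f1": 0.989},
    "correlation": {"pMN+Nkx2.2~p3": 0.981, "pMN+Nkx2.2~pMN": -0.641}}},
"cooccupancy": {"fraction_genes_ge3_cres": 0.590,
    "sharing": {"Olig2|Nkx2.2": 0.174, "Nkx6.1|Nkx2.2": 0.056, ...}}
```

Read: the derived domain signatures coincide exactly with the planted
domain gene sets; every pMN-signature gene is repressed by Nkx2.2
induction and 69% of the repressed genes carry Nkx2.2 binding (versus
4.8% of non-changing background genes); direct/indirect calls recover the
planted direct edges at F1 = 0.99; the induced transcriptome correlates
with p3 (r = 0.98), not with its base condition (r = −0.64); 59% of genes
have three or more distinct CREs; and the measured CRE sharing fractions
match the planted co-placements.

The library surface mirrors the CLI: see `grnx.pipeline.run_pipeline`,
and `docs/methods.md` for the model and every default.

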