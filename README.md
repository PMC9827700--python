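# togcn

Comparative, time-ordered gene co-expression network analysis for
dual-condition developmental transcriptomes — built around the fruit-acidity
study design in peach: two high-acid varieties (LG, MY), two low-acid
varieties (XC, XH) and one wild variety (ST), sampled at five developmental
stages (34–117 days after full bloom) in three biological replicates.

## What it does

Given a replicate-level FPKM matrix, a list of acid-pathway target genes and
a list of transcription factors (TFs), the pipeline:

1. **Averages** replicates per (variety, stage), then averages each
   condition's member varieties into one time series per gene, where the
   conditions C1 (high-acid) / C2 (low-acid) are either fixed by the user or
   inferred from total organic acid (malate + citrate + quinate) at maturity.
2. **Correlates** every target–TF pair under each condition (Pearson
   product-moment correlation, PCC, on the 5-stage series) and derives
   significance cutoffs from the empirical PCC distribution: the positive
   cutoff is the largest bin edge that still carries ≥ α upper-tail mass
   (α = 0.05), so values beyond it are rarer than α. The published
   reference cutoffs (+0.75 / −0.60, not-co-expressed band −0.5 ≤ PCC < 0.5)
   are available as `CutoffSet.paper_defaults()`.
3. **Classifies** each pair jointly across conditions into
   `C1{+,0,−}C2{+,0,−}`; the eight exported relation sets (`C1+C2+`,
   `C1+C20`, `C1+C2−`, `C10C2+`, `C1−C2+`, `C1−C2−`, `C1−C20`, `C10C2−`)
   exclude the double-null `C10C20`. PCCs falling between the band and a
   cutoff are unclassified and dropped with a count.
4. **Time-orders** the positive co-expression network by breadth-first
   search from a seed gene (level 1 = seed, level k = k−1 hops away). The
   seed is the first-expressed acid-pathway gene: the candidate whose
   condition profile peaks at the earliest stage.
5. **Ranks hub candidates** in a chosen relation network by degree
   (Rank / Name / Count / Annotation table, default top 20).

A synthetic 3D-transcriptome generator (`togcn.synth3d`) emulates the study
design end to end — 75 samples, planted co-expression waves, condition-
specific and anti-correlated gene pairs, acid phenotype trajectories — with
full ground truth, so recovery of every stage is testable without any
sequencing data.

## Worked example

```python
from togcn import *
from togcn.pipeline import time_order_positive_network

cfg = SimConfig(noise_sigma=0.1, rng_seed=7)
matrix, acids, gene_sets, truth = simulate_dataset(cfg)

cmap = assign_conditions(acids, exclude={"ST"})       # high/low split from total acid
res = run_pipeline(matrix, gene_sets, cmap, cutoffs="estimate")
ton = time_order_positive_network(res, candidates=set(gene_sets.acid_genes))
```

This prints (via the calls shown in `scripts/acceptance.py` and the CLI):

```
condition split: {'LG': 'C1', 'MY': 'C1', 'XC': 'C2', 'XH': 'C2'}
cutoffs: C1 (+0.85, -0.80)  C2 (+0.84, -0.81)
relation counts: {'C1+C2+': 514, 'C1+C20': 910, 'C1+C2-': 27, 'C10C2+': 1002,
                  'C1-C2+': 18, 'C1-C2-': 361, 'C1-C20': 860, 'C10C2-': 827,
                  'C10C20': 14790}
seed gene: ['ACID0001']  distinct levels (planted waves): 8
C1+C20 recovery vs planted truth: precision=1.000 recall=1.000
```

Reading the output: the acid-phenotype split recovers the high/low design;
the empirical cutoffs land near the published ±0.75/−0.60 regime; the
high-acid-specific set `C1+C20` — the focal set for acidity candidate genes
— contains the planted condition-specific pairs with perfect precision and
recall at this noise level; and BFS from the automatically selected seed
gene (the earliest-peaking acid gene, planted in wave 1) redistributes the
planted wave genes into exactly 8 time levels, one per planted wave.

The same workflow is available from the shell:

```bash
togcn simulate --outdir data --seed 5
togcn conditions --acids data/acids.csv --exclude ST --out cmap.yaml
togcn cutoff  --matrix data/expression_fpkm.tsv --targets data/acid_genes.txt \
              --tfs data/tf_genes.txt --condition-map cmap.yaml --out cutoffs.yaml
togcn build   --matrix data/expression_fpkm.tsv --targets data/acid_genes.txt \
              --tfs data/tf_genes.txt --condition-map cmap.yaml \
              --cutoffs cutoffs.yaml --types C1+C20 --outdir rel
togcn order   --matrix data/expression_fpkm.tsv --targets data/acid_genes.txt \
              --tfs data/tf_genes.txt --condition-map cmap.yaml --out levels.tsv
togcn hubs    --graph rel/network.graphml --k 20 --out hubs.tsv
```

Relation sets are written in the five-column CSV dialect
(`acid_gene,type,tf_gene,pcc_c1,pcc_c2`), networks as edge-list TSV and
GraphML, hub tables as Rank/Name/Count/Annotation TSV.

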