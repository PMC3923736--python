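# rddkit

Clone-level **RNA–DNA difference (RDD)** analysis for Sanger-sequenced
cDNA/gDNA clone sets, built around the study design used for insect
chemosensory protein (CSP) genes: for each gene, 10–20 plasmid clones of the
coding amplicon are sequenced per tissue per individual from both cDNA and
genomic DNA; any site where a transcript clone differs from the invariant
genomic consensus is an RDD — a candidate RNA-editing event.

`rddkit` implements the whole computational side of such a screen:

1. **Reference handling** — gene models (GFF3 + FASTA), exon splicing,
   reading-frame-aware translation, average protein mass.
2. **Alignment** — global pairwise alignment of each clone to the spliced
   coding reference under affine gap scoring (Gotoh three-state DP;
   default match +2, mismatch −2, gap open −6, gap extend −1), with
   deterministic traceback and left-normalised gap placement, plus a
   majority-vote gDNA consensus whose discordant sites (possible allelic
   variation) are masked from calling.
3. **RDD calling & nomenclature** — per-column event calling, merging of
   contiguous deletion runs, and the RNA-level naming dialect used in clone
   variant tables: `r.68c>a` (substitution), `r.187a<` (deletion),
   `r.115_116at<` (two-base deletion), `r.181-192ga<` (range deletion),
   `r.317a>` (insertion) — with a parser that inverts it.
4. **Effect prediction** — each clone's events are applied to the amplicon
   and re-translated; outcomes are classified into silent, missense,
   stop-gain (`pmutLys96*`), early/late-stop frameshift
   (`fsPro90*e` / `fsHis87*l`) and in-frame motif deletion
   (`deleAsp45-Pro48`), with residue counts and masses in kDa.
5. **Statistics & clustering** — gene × tissue count matrices with totals,
   the 12-class substitution spectrum, 3′-adenosine context bias (binomial
   test against the reference's background A frequency),
   synonymous/non-synonymous splits, RDD rates per clone and per kb per
   clone, and complete-linkage Euclidean clustering of tissues with Newick
   export.
6. **Synthetic data** — a seeded simulator that plants RDDs with a
   configurable tissue-specific Poisson load (pheromone gland elevated), an
   A>G-dominated substitution spectrum and rare indels, writing a
   ground-truth manifest so every stage is testable end to end.

## Worked example

```python
import numpy as np
import rddkit as rk

# simulate a small study: 2 genes, 5 tissues, 5 cDNA clones per tissue
cfg = rk.SimConfig(seed=7, n_genes=2, clones_per_tissue=5, gdna_clones=5)
res = rk.run_pipeline(rk.PipelineConfig(simulate=cfg))

print(res.matrix.with_totals())
print("recovered:", {e.key() for e in res.events} == res.manifest.keys())
print("A>G fraction:", round(res.spectrum.fraction_a_to_g, 3))
```

prints

```
tissue  antennae  head  legs  pheromone_gland  wings  Total
gene
gene01         3     5     4                9      3     24
gene02         1     0     5               10      1     17
Total          4     5     9               19      4     41
recovered: True
A>G fraction: 0.395
```

i.e. 41 planted events, all recovered exactly by alignment + calling
(precision = recall = 1), with the pheromone gland carrying the highest
per-tissue load (19 of 41) thanks to its 3× rate multiplier, and A>G the
most common substitution class, as configured.

The same pipeline runs from the shell:

```bash
rddkit simulate --seed 7 -o data/
rddkit run-all -d data/ -o report/     # table1/table2/spectrum/sites/newick/json
```

## Layout

```
src/rddkit/
  seq_core.py        gene models, splicing, translation, protein mass, I/O
  alignment.py       Gotoh global alignment, left-normalisation, consensus
  rdd_caller.py      event calling, deletion merging, nomenclature, sites
  effects.py         variant reconstruction and effect categories
  stats_cluster.py   spectrum, context bias, matrices, rates, clustering
  synthetic_data.py  seeded simulator + engineered worked examples
  pipeline.py        end-to-end orchestration and report emission
  cli.py             rddkit simulate|call|effects|stats|cluster|run-all
docs/methods.md      model, conventions and limitations
```
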