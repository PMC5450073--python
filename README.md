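# supermatrixqc

Phylogenomic supermatrix construction and quality control for amino-acid
data, built the way transcriptome-based phylogenomic studies assemble
their matrices: per-locus orthogroup alignments plus gene trees go in,
filtered concatenated matrices with partition tables and audit trails come
out — together with the two hypothesis tests such studies use to probe a
contested clade, the SOWH parametric bootstrap and Bayesian posterior
model odds.

It is aimed at researchers who want the matrix-construction and
locus-screening machinery of a phylogenomic pipeline as a tested,
scriptable library rather than a chain of external tools, and at anyone
who wants to study the statistical behaviour of these filters on data
with known ground truth.

## What it does

* **Paralog pruning** (`supermatrixqc.prune`). Gene-tree-based reduction
  of each orthogroup to ≤ 1 putatively orthologous sequence per taxon:
  internal edges with support < 0.7 are collapsed into polytomies; the
  maximally inclusive subtree is kept, where a taxon may contribute
  several sequences only if they form a clade or share one polytomy
  (in-paralogs); within an in-paralog set only the longest sequence
  survives. Exact duplicate contigs are deleted first.
* **Occupancy filtering.** `min_taxa = ⌈fraction × n_taxa⌉`; for 40 taxa
  the 25/50/75/100 % thresholds demand 10/20/30/40 taxa.
* **Locus diagnostics** (`supermatrixqc.diagnostics`). Branch-length
  heterogeneity per gene tree — mean patristic distance (PD), tip-to-root
  standard deviation, and the dispersion of per-taxon long-branch (LB)
  scores, `LB_i = 100·(meanPD_i / meanPD − 1)` — and compositional
  heterogeneity per alignment — a Pearson χ² homogeneity test of residue
  counts and relative composition frequency variability,
  `RCFV = Σ_i Σ_j |f_ij − μ_j| / n_taxa`. Elimination is two-staged: any
  locus at or above `median + 1.5·IQR` on a branch-length index goes
  first; χ² p < 0.05 or an IQR-flagged RCFV (quantiles recomputed on the
  survivors) goes second.
* **Supermatrix assembly** (`supermatrixqc.supermatrix`). Per-locus
  removal of columns with > 50 % gaps, concatenation with gap fill,
  RAxML-style partition files, and the usual matrix characteristics:
  locus/character counts, parsimony-informative characters, and per-taxon
  percent missing (gaps and `X` both count as missing).
* **Likelihood engine** (`supermatrixqc.likelihood`). Felsenstein pruning
  under Poisson/JTT/WAG/LG with discrete-gamma rates, ML pairwise
  distances, neighbor-joining starts, branch-length optimisation, NNI
  hill-climbing with optional monophyly constraints, per-locus model
  selection, and sequence simulation along a tree.
* **Topology tests** (`supermatrixqc.topotests`). The SOWH test — the
  statistic is δ = lnL(unconstrained ML) − lnL(constrained ML), referred
  to a null distribution simulated on the constrained ML tree, with a
  Clopper–Pearson 95 % interval tracked per replicate — and posterior
  model odds, the ratio of post-burn-in tree counts supporting one
  topological hypothesis versus its alternative (infinite when the
  alternative never occurs).
* **Synthetic data** (`supermatrixqc.synthetic`). Seeded generator of
  Yule species trees, duplication/loss gene trees, long-branch taxa,
  compositionally biased loci, truncated contigs and Beta-distributed
  occupancy, with a full truth manifest so every pipeline stage can be
  scored against known answers.

## Worked example

```python
from supermatrixqc import PipelineConfig, SyntheticConfig, run_pipeline

cfg = PipelineConfig(
    synthetic=SyntheticConfig(
        n_taxa=12, n_loci=80, locus_length_range=(80, 160),
        duplication_rate=0.3, loss_rate=0.3,
        long_branch_taxa={"t01": 5.0}, biased_taxa={"t04": 0.5, "t05": 0.5},
        model="Poisson", seed=42),
    occupancy_fractions=(0.25, 0.5, 0.75),
    out_dir="smqc_out", seed=42)
manifest = run_pipeline(cfg)
```

With this seed, 73 of 80 simulated loci survive duplication/loss and
occupancy masking, and 72 remain usable after paralog pruning. The
per-matrix section of the manifest reads:

| matrix | min_taxa | after occupancy | after diagnostics | # loci | # characters | parsimony-informative | % missing |
|--------|---------:|----------------:|------------------:|-------:|-------------:|----------------------:|----------:|
| occ25  |  3 | 69 | 64 | 64 | 7474 | 3924 | 47.39 |
| occ50  |  6 | 47 | 44 | 44 | 5059 | 3447 | 38.72 |
| occ75  |  9 | 10 |  9 |  9 | 1112 |  978 | 21.07 |

Raising the occupancy threshold trades loci (and characters) for
completeness — the same trade-off real transcriptome matrices show.
`smqc_out/` additionally holds the matrices (FASTA + relaxed PHYLIP),
partition files, the pruning report and per-matrix diagnostics tables.

The same stages are available as a CLI
(`supermatrixqc simulate|prune|occupancy|diagnose|trim|concat|summarize|sowh|odds|run-all`),
e.g.:

```sh
supermatrixqc simulate --seed 42 --out data/
supermatrixqc sowh data/matrix.fasta --constraint t03,t04,t05 --model LG --n-sim 100 --seed 1
```

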