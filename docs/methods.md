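# Methods

This note documents the models and procedures implemented in
`supermatrixqc`, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
decisions that matter for reproducing its outputs.

## Paralog pruning

Each orthogroup arrives as an aligned amino-acid FASTA (possibly several
sequences per taxon; the taxon is the sequence-ID prefix before the first
`|`, with a configurable delimiter) plus a gene tree whose internal node
labels are support values in [0, 1]. Pruning proceeds in four steps:

1. **Deduplication** — records identical in (taxon, residues) collapse to
   the first-encountered sequence ID.
2. **Support collapsing** — internal edges with support strictly below
   the threshold (default 0.7) are contracted into polytomies. Supports
   exactly at the threshold, and edges without a parseable support, are
   kept.
3. **Maximally inclusive subtree** — every directed edge of the unrooted
   tree defines a candidate subtree, and the whole tree is a candidate
   too. A candidate is valid when each taxon contributes at most one
   sequence, except taxa whose sequences within the candidate form a
   clade or attach to a single polytomy node (in-paralogs), which may
   contribute all of theirs. Among valid candidates the winner has the
   most leaves; ties break by more distinct taxa, then greater total
   non-gap residue count, then the lexicographically smallest leaf-label
   set. The field's tooling leaves both the "largest" measure and
   tie-breaking unspecified; a fully deterministic rule is required for a
   testable implementation, and leaves-then-taxa-then-length is the
   natural preference order for downstream matrix occupancy. The
   implementation is validated against an independently written
   exhaustive enumeration on random multi-copy trees.
4. **In-paralog resolution** — within each retained in-paralog set only
   the sequence with the most non-gap residues survives (ties to the
   smaller sequence ID). All-gap columns are then dropped; no realignment
   is attempted (callers realign externally if desired).

A pruned locus with fewer than two distinct taxa is flagged unusable.

## Occupancy filtering

`min_taxa = ⌈fraction × n_total_taxa⌉`, computed with a 1e-9 guard
against binary-float artefacts. This ceiling rule reproduces all the
standard printed thresholds (e.g. 10/20/30/40 of 40 taxa; 10/19/28 of 37;
30 of 39 at 75 %).

## Locus diagnostics and elimination

Branch-length indices per gene tree: mean pairwise patristic distance;
the sample standard deviation of root-to-tip distances (midpoint-rooting
unrooted inputs; a bifurcating root is treated as fixed); and the
dispersion of per-taxon LB scores. `LB_i = 100·(meanPD_i/meanPD − 1)`
averages to exactly zero over taxa — an algebraic identity the tests
assert — so the per-locus scalar is its sample standard deviation (an
upper-quartile mean is a plausible alternative; the SD is the default
because it uses all taxa and is scale-invariant). Loci with fewer than
three leaves carry no branch-length signal and get NaN indices, which the
outlier rule ignores.

Compositional indices per alignment, excluding gaps and `X` and without
any prior column filtering: a Pearson χ² homogeneity test on the
taxon × residue count table (no continuity correction; residues absent
from the whole locus are dropped from the table and the degrees of
freedom; taxa with zero countable residues are dropped with a warning)
and RCFV, the mean over taxa of summed absolute deviations of per-taxon
residue frequencies from the across-taxon mean.

Elimination is two-staged, and stage order matters: stage 1 removes loci
flagged `value ≥ median + 1.5·IQR` on *any* branch-length index; stage 2
recomputes the RCFV quantiles **on the stage-1 survivors** and removes
loci with χ² p < 0.05 or a flagged RCFV. Quantiles use linear
interpolation (numpy's default, type 7); the cutoff is inclusive (≥).
When an index's IQR is zero the index is uninformative and its flagging
is skipped (the raw `iqr_flags` primitive would flag everything in that
degenerate case, which is documented behaviour).

A caveat the tests make explicit: the χ² homogeneity test assumes
independent counts. On shallow trees shared ancestry makes taxon
compositions more similar than multinomial sampling allows, so the test
is conservative there; its rejection rate matches the nominal α only in
the independence regime (deep/saturated divergence). The calibration
test therefore simulates saturated star trees, where per-taxon counts are
i.i.d. multinomial.

## Likelihood engine

Reversible 20-state models are built as `Q_ij = S_ij π_j` from published
exchangeabilities (Poisson, JTT, WAG, LG) and normalised to one expected
substitution per unit branch length. `P(t)` comes from the symmetrised
eigendecomposition, entries clamped to [0, 1]; the Poisson case uses the
20-state closed form. Rate variation uses K = 4 equal-probability
discrete-gamma categories represented by category means, renormalised to
mean 1.

Likelihoods use Felsenstein pruning on site patterns (identical columns
share computation), with per-node rescaling against underflow; gaps and
`X` are fully ambiguous. Branch lengths are optimised one edge at a time
by bounded Brent (bounds [1e-9, 50], default `xatol` 1e-6) in a preorder
sweep that maintains exact "outside" partial vectors, so each single-edge
optimisation acts on the true likelihood surface and per-sweep lnL is
non-decreasing; sweeps repeat until the gain drops below `tol`
(default 1e-4; non-convergence within `max_sweeps` returns best-so-far
with a warning). Tree search starts from neighbor joining (scikit-bio) on
ML pairwise distances and hill-climbs with NNI: moves are screened by
optimising only the central edge against cached partials, the best
improving move is applied, and all branch lengths are re-optimised. With
a monophyly constraint, the start tree grafts the constrained taxa as a
clade (NJ within the group, NJ of the rest around a mean-distance
placeholder) and constraint-breaking NNI moves are rejected. NNI rather
than SPR, and no rapid bootstrapping: the engine targets desk-scale
matrices (≲ 10 taxa, ≲ 10⁴ sites), not production tree search.

Model selection scores each candidate by lnL on a shared NJ topology with
branch lengths re-fitted per model; ties break by candidate order. Note
that even a constant alignment does not tie the default candidates, since
their equilibrium frequencies differ.

Simulation draws root states from π, one gamma category per site, and
evolves states by `P(t)` edge by edge — deterministic given the seed.

## Topology tests

**SOWH.** δ = lnL(unconstrained) − lnL(constrained), floored at zero
(negative values are optimiser noise and are logged). If the
unconstrained ML tree already satisfies the constraint, δ = 0 without a
second search. `n_sim` replicates of the observed length are simulated on
the constrained ML tree with its fitted branch lengths and the named
model's equilibrium frequencies; each replicate repeats both searches.
`p = #{δ_sim ≥ δ_obs}/n_sim` (a `(k+1)/(n+1)` pseudocount variant is
available), with an exact Clopper–Pearson 95 % binomial interval recorded
after every replicate; adaptive stopping is deliberately absent so runs
are exactly reproducible. With zero exceedances in 100 replicates the
interval's upper bound is 0.0362167. Because δ piles up at zero under the
null, the k/n rule is conservative at small sample sizes — the
calibration test accepts any rejection count inside the exact binomial
95 % region around α.

**Posterior model odds.** Given a post-burn-in multi-Newick sample and
two decidable predicates (monophyly of a taxon set or its negation), the
odds are `n₁/n₂`; trees resolving neither count separately, `n₂ = 0`
with `n₁ > 0` gives +∞, and both zero is an error. Monophyly on unrooted
trees is a bipartition test: some edge must split exactly the focal taxa
from the rest.

## Synthetic data generator

The generator emulates the statistical structure this kind of pipeline
confronts, with all randomness flowing from one seed through named
substreams:

* **Species tree** — Yule (pure birth), scaled to unit height; the
  simplest ultrametric generator, sufficient because downstream stages
  only consume the induced gene trees.
* **Gene trees** — independent Poisson duplication and loss along species
  branches; copies evolve independently after duplication. Leaves are
  labelled `taxon|cN`; leaves reachable from the root without crossing a
  duplicated lineage are recorded as the locus's true ortholog set (at
  most one per taxon, mutually orthologous).
* **Rate and composition confounders** — pendant edges of configured
  long-branch taxa are scaled (default one taxon, ×5, echoing the single
  conspicuously long-branched terminal real datasets often carry);
  emitted gene trees carry these scaled lengths so diagnostics see the
  same trees that generated the sequences. In a configurable fraction of
  loci (default 0.3), designated taxa evolve their pendant edge toward
  `(1−b)π + b·target` (default target: uniform over A/I/L/M/V,
  hydrophobic enrichment; default b = 0.5 on two taxa).
* **Contig truncation** — with probability 0.1 a sequence loses a random
  prefix or suffix (≤ 30 %) to gaps, giving the length variation the
  longest-in-paralog rule and the gappy-column trimmer act on.
* **Occupancy** — each (locus, taxon) is retained with probability drawn
  from Beta(α, β), default α = 2, β = 1: mean retention 2/3 with support
  spanning the 25–100 % occupancy range, matching the wide per-taxon
  missingness (roughly 20–80 %) that transcriptome matrices exhibit.
* **Gene-tree noise** — each internal edge is NNI-perturbed with
  probability 0.1 and given a Uniform(0,1) support; untouched edges get
  support 1.0. The pipeline consumes supports rather than estimating
  them, so supports are generated, not inferred.
* Defaults elsewhere: 20 taxa, 100 loci of 120–300 columns, duplication
  and loss rates 0.2 per unit branch length, LG model.

What the generator does **not** emulate: alignment error and realignment,
indel processes beyond terminal truncation, assembly artefacts,
nucleotide/codon-level effects, site-heterogeneous (CAT-like)
composition, or rate variation along internal branches. Tests passing on
these data therefore validate the algorithms and their statistical
behaviour under the stated model — not robustness to misalignment or
model violation in real transcriptomes.

## Problem sizes in the test suite

The suite exercises every stage at sizes a single core handles in
minutes: pruning-oracle equivalence on 200 random trees of ≤ 8 leaves;
LB identities on 1000 random trees; χ² calibration on 1000 simulated
loci; model-selection recovery on 50 replicates of 8 taxa × 2000 sites;
SOWH calibration as 50 tests of 100 replicates each on 6 taxa × 120
sites, and power on 15 runs at 600 sites. These are scaled-down analogues
of the regimes the methods are used in; the statistical acceptance bands
(exact binomial regions, ≥ 90–95 % recovery) are chosen from the
experiment sizes, not tuned to outcomes.

## Known limitations

* The likelihood engine is deliberately small: no SPR, no CAT-GTR or
  other site-heterogeneous mixtures, no bootstrapping, single-threaded.
* `estimate_distances` caps saturated pairs at a configurable maximum
  (default 10), which distorts NJ starts for extremely divergent pairs;
  the subsequent NNI search is the corrective.
* The SOWH implementation refits branch lengths but takes equilibrium
  frequencies from the named model rather than the data (configurable in
  principle via a custom `SubstitutionModel`), and does not implement
  adaptive replicate addition.
* Two-taxon loci bypass branch-length diagnostics entirely.
* Gene-tree supports in synthetic data are stylised (1.0 or Uniform), so
  support-threshold behaviour between 0.7 and 1.0 is only exercised by
  the perturbed-edge population.
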