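# Methods

This note documents the models and procedures implemented in `pctrace`, the
assumptions behind them, the parameters that matter, and what the synthetic
benchmark does and does not establish.

## Chain pairing and clonotype definition

Each droplet barcode may yield several immunoglobulin contigs. A cell enters
the analysis only if it resolves to exactly one heavy (IGH) and one light
(IGK/IGL) chain:

* Among several light chains, the **productively rearranged** one defines
  clonal identity; among several productive lights the highest-UMI chain is
  taken, with ties broken lexicographically by V call so results are
  deterministic. Barcodes whose light chains are all nonproductive are
  excluded: such a cell has no defined clonal identity under this rule.
* Barcodes with more than one heavy chain are excluded by default
  (`heavy_policy="drop"`), treating them as likely doublets; a `max_umi`
  policy is available.
* All exclusions are counted and reported, so input contigs are conserved:
  every barcode is either paired or excluded with a reason.

A **clone** is an equivalence class under exact string equality of
`(heavy V, heavy D, heavy J, heavy CDR3 aa, light V, light J)`. Light-chain
CDR3 identity is *not* required (a strict mode adds it behind a flag), and no
Hamming/length-normalized junction clustering is performed: the identity rule
is deliberately exact. V-call granularity is configurable — allele level
(`IGHV1-72*01`, the default) or gene level (`IGHV1-72`). Clone ids are stable
integers ordered by descending clone size, then lexicographic key order.

Consequences worth knowing: exact identity cannot merge clones that differ by
sequencing error in the CDR3 (the generator does not model such errors), and
an empty D call is a literal key field, never a wildcard.

## Antigen-specificity inference

Specificity is assigned at the level of heavy V genes, exploiting the fact
that anti-NP responses are dominated by a characteristic IGHV set:

1. Build per-sample IGHV **rank lists**: per-cell counts of the resolved heavy
   V call, sorted by descending count with lexicographic tie-break, truncated
   to top-N (reference N=25; tracked samples N=50).
2. `np_genes = reference ∩ sample_a ∩ sample_b` (membership in the truncated
   lists), `klh_genes = (sample_a ∩ sample_b) − reference`. The sets are
   disjoint by construction.
3. Cells are labelled NP / KLH / unassigned by membership of their heavy V
   call alone.

"Prevalent" is operationalized as top-N membership; no additional frequency
floor is applied. The truncation depths are parameters, not fitted values.

## Somatic hypermutation and affinity maturation

Mutation counts are **nucleotide substitutions** between an observed V segment
and its germline over an equal-length, gap-padded alignment. Positions where
either sequence has a gap (`-`, `.`) or an ambiguous base (`N`) are excluded
from numerator and denominator; the frequency is `n_mutations /
aligned_length`. The operation is symmetric in its arguments. Alignments are
consumed pre-computed (AIRR `sequence_alignment` / `germline_alignment`); the
package performs no alignment itself.

The high-affinity substitution is specified as `(v_gene, position, from_aa,
to_aa)` — default `(IGHV1-72*01, 33, W, L)`, the classic W33L of the NP
response. The position is a plain 1-based index into the provided germline
amino-acid sequence; Kabat/IMGT renumbering, if needed for a real reference,
must be done upstream. A germline residue other than `from_aa` at that
position raises an error rather than silently returning False. Only the
designated `to_aa` counts: W→F at the same position is negative.

Group comparisons use the two-sided Wilcoxon rank-sum test (via
`scipy.stats.mannwhitneyu`): exact when the combined sample is ≤ 20 without
ties, normal approximation with continuity correction otherwise. The tests
validate it against exhaustive enumeration of all rank assignments for every
group-size combination up to 6.

## Genomic-state label transfer

The reference clustering is consumed as input (barcode → state labels plus a
marker-gene list); the package performs no de-novo clustering. Per-state
**centroids** are means of `log2(1 + normalized count)` over marker genes,
with each state requiring ≥ 2 cells. A query cell receives the state of the
centroid with the highest Pearson correlation over the marker panel, or
`unassigned` when the best r falls below `min_correlation` (default **0.7**) —
the guard against low-quality cells — or when the cell's marker vector has
zero variance. Centroid ties break by state name.

Normalization scales each cell to a common library size before the log
transform. The default target is the per-dataset median library (common
single-cell practice); a fixed `norm_target` may be supplied, which makes
centroids exactly invariant to uniform library scaling and is the right
choice when references must be portable across datasets of very different
depth.

## Gene-signature score

For a gene set, each signature gene is matched to `background_size_per_gene`
(default 50) genes drawn (seeded) from its expression bin, where all genes are
binned into `n_background_bins` (default 25) quantile bins of dataset-wide
mean log-normalized expression. The score is mean signature expression minus
mean background expression, per cell. Matching the background by expression
controls for library quality/complexity. The score is meaningful only in
contrasts (between cells or groups); absolute values depend on the binning and
are never interpreted.

## Sorted-subset frequency decomposition

A sorted subset that is a mixture of a target population and a contaminating
population with known state fractions `f_pure` is corrected as

```
corrected_i = max(f_mixed_i − α · f_pure_i, 0) / Σ_j max(f_mixed_j − α · f_pure_j, 0)
```

`α = 1` (default) is the literal subtraction of the contaminant's cluster
proportions, clipped at zero; `α < 1` models partial contamination. On exact
mixtures `f_mixed = (1−a)·f_target + a·f_pure` the target is recovered exactly
(to machine precision) for any `a < 1`, which the tests verify on random
triples. An all-zero corrected vector (pure contaminant) is an error, not a
silent zero vector.

## Differential expression

Fold is the ratio of group means on the **linear** normalized scale (absolute
fold = max(fold, 1/fold)); the test statistic is a moderated two-sample t on
`log2(1 + normalized)` values. Per-gene pooled variances `s²_g` are shrunk
toward a common prior variance `s₀²`:

```
s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d),   t_g = (m̄₁ − m̄₂) / (s̃_g·√(1/n₁+1/n₂))
```

with `d = n₁+n₂−2` and t degrees of freedom `d₀ + d`. The prior `(d₀, s₀²)`
is estimated by the method of moments: under the hierarchical model
`s² ~ s₀²·F(d, d₀)`, the squared coefficient of variation of `s²` across genes
identifies `d₀` through the F-distribution moments (solved by bisection; a CV²
at or below the `d₀ → ∞` limit yields complete shrinkage, and a CV² heavier
than any admissible `d₀ > 4` floors the prior at d₀ ≈ 4). `shrink=False`
reduces the statistic to the ordinary pooled t, which the tests verify against
`scipy.stats.ttest_ind` exactly — the dual route that pins the implementation.

A gene is differentially expressed iff absolute fold > **1.2** and
Benjamini–Hochberg adjusted p < **0.05**. Both thresholds are parameters of
`DEGConfig`.

The chi-square test of state frequencies is the Pearson statistic on the 2×k
contingency table (`df = k−1`, no continuity correction); states with zero
total count are dropped with a warning, reducing df. Note the test assumes
independent cells — with strong clonal structure (cells of a clone share a
state) counts are overdispersed and the statistic is descriptive.

## Clonal tracing

The clone partition is joined with per-barcode state and compartment labels
into a `(clone, compartment, state, n_cells)` table; unlabeled cells are
excluded with a count. A clone **spans** when present in ≥ `min_nodes`
distinct (compartment, state) nodes (default 2). The span-frequency matrix
entry (i, j) counts clones with ≥ 1 cell in spleen state i and ≥ 1 cell in BM
state j; a clone touching several states contributes to every touched pair
(all-pairs convention — no dominant-state collapsing by default, though a
cell-counting mode exists). Rows are normalized by splenic state by default,
matching the per-precursor-state reading: "of the clones leaving this splenic
state, where in the BM do they land". Rows with zero mass are reported as
empty, never NaN-filled. The chord-adjacency export writes one row per
spanning clone and unordered node pair with weight 1, so the weight sum equals
the total number of spanning incidences.

## The synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated. Defaults (all `SimConfig` fields):

* **Nine genomic states** mirroring a CD138-enriched splenic compartment: MZ
  B, two B-cell clusters, LZ/DZ GC B cells, PC progenitor, and PC clusters
  marked by *Tigit*, *Slpi*, *Lag3* (proportions 0.06/0.10/0.08/0.16/0.14/
  0.16/0.14/0.09/0.07).
* **IGHV usage** led by an IGHV1-72\*01 analogue (weight 30) and
  IGHV1-53\*01 (12), a KLH tier (IGHV9-3, 5-17, 1-82, 14-3) and a sporadic
  tail; clone specificity (NP/KLH/other) is determined by the clone's heavy V
  gene. The antigen-sorted reference sample restricts usage to the NP genes —
  the in-silico version of tetramer sorting.
* **Clone sizes** from a shuffled power-law weight sequence (exponent 1.0),
  multiplied by 3 for PC-state clones (differentiating PCs expand after fate
  specification), with every clone guaranteed ≥ 1 cell.
* **SHM**: substitution count ~ Poisson(rate × timepoint index), rate 3.0 per
  V segment per timepoint unit, indices 21 d.p.i. → 1, 35 d.p.i. → 2.
  Substitution positions are uniform over the V segment, excluding the
  affinity codon; each substituted position changes to a different base, so
  the emitted Hamming distance equals the drawn count exactly and is recorded
  in the truth table. Lineages flagged with probability
  `affinity_mutation_prob = 0.4` have the affinity codon rewritten to encode
  leucine (adding up to 3 further substitutions, also reflected in the truth).
* **Compartments**: only PC-state clones seed the bone marrow; the per-cell
  seeding probability is the BM fraction (0.2) scaled by a per-state gradient
  (*Tigit* 3×, *Slpi* 2×, *Lag3* 1×, capped at 0.95), encoding the
  precursor-activity ordering. Each PC clone draws **one** BM destination
  state — its splenic state with probability 3/(3+2) = 0.6, else uniform among
  the other PC states — so "BM progeny predominantly retain the precursor
  state" is a clone-level property, as the tracing figures read it. Progenitor
  clones never leave the spleen; B/GC clones spread into at most one secondary
  splenic state (per-cell probability 0.2).
* **Expression**: gamma-Poisson (NB, dispersion 0.1) counts over a lognormal
  baseline profile; each state's 20 marker genes are elevated
  `marker_fold = 8`-fold; library sizes ~ Gamma with mean 2000 UMIs. The
  baseline profile has its own fixed seed (`expression_profile_seed`): it is a
  property of the transcriptome shared by all samples of a study, while
  per-cell noise follows the sample seed — without this, cross-sample label
  transfer and DEG contrasts would compare unrelated transcriptomes.
* A second, nonproductive decoy light chain is emitted with probability 0.1
  to exercise the productive-light-chain rule.

The DEG benchmark (`simulate_deg_groups`) draws two groups from one NB model
and plants 2-fold changes **balanced** across the groups (half up in each) and
only into genes with baseline mean in [5, 50] counts: one-sided planting
distorts per-cell total-count normalization (a compositional artifact), and a
fold change on an unexpressed gene is not a meaningful benchmark.

### What the generator does not emulate

No transcriptome manifolds (trajectories, RNA velocity), no doublets or
ambient RNA, no sequencing errors in contigs, no SHM hotspot targeting
(available behind a parameter but off), no shared CDR3 convergence between
clones, no batch effects. Passing tests therefore establish that the
*computational logic* recovers planted structure exactly or within sampling
error — not that the pipeline is robust to the full noise spectrum of real
droplet data.

## Problem sizes and tolerances

The validation suite uses: 2000 cells / 150 clones for clone calling (ARI
must be exactly 1.0 on noiseless data); 1000 independent single-cell lineages
for the SHM Poisson mean and the W→L fraction (each within 3 standard errors
of its target; the Poisson-mean check uses the unflagged lineages, whose
Hamming distance is the pure Poisson draw); 4500 cells (500 per state) for
label transfer (accuracy ≥ 0.95 at fold 8, monotone over folds {2, 4, 8},
pure-noise cells 100% unassigned); 20 seeds × (2 × 100 cells × 2000 genes)
for DEG calibration (null DEG fraction ≤ 0.05, ≥ 15/20 planted genes
recovered, realized FDR ≤ 0.10 on average); and 20 seeds × 8000 cells / 600
clones for tracing. The tracing size is chosen so the smallest splenic PC
state (PC-*Lag3*, 7% of clones) contributes ~20+ BM-seeded clones per seed:
the diagonal-dominance check is a multinomial-mode comparison and needs that
many clones for the mode to be reliable; at this size it held in 60/60
independent seed batches during development.

## Known limitations

* Exact-identity clonotyping is brittle to sequencing error in real data;
  junction-similarity clustering is deliberately out of scope.
* The moderated-t prior assumes exchangeable gene variances; a mean-variance
  trend (as in counts) makes the shrinkage slightly anticonservative for
  high-variance genes. The fold filter absorbs most of this in practice, as
  the calibration tests show.
* The signature score's background draw is seeded but binning-dependent;
  scores are comparable only within one dataset and bin configuration.
* The chi-square state-frequency test ignores clonal overdispersion (see
  above).
* Specificity inference is heavy-V-gene-level only; it cannot separate NP and
  KLH clones that use the same IGHV gene.
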