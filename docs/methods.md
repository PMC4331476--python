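# Methods

## Model and assumptions

The pipeline assumes a case/control microarray study in which disease
signal appears as (i) fold-change shifts of individual mRNAs and
miRNAs, (ii) coordinated shifts of pathway gene sets, and (iii) inverse
miRNA–mRNA coupling: an overexpressed miRNA represses its targets, so
truly up-regulated pathways should surface both in the up-mRNA
enrichment (P₁) and in the enrichment of targets of *down* miRNAs (P₄),
and symmetrically for down-regulated pathways (P₂ ∩ P₃). Pathway
membership is treated as a fixed annotation; enrichment and crosstalk
are sampling-without-replacement (hypergeometric) nulls over a finite
gene background.

## Statistical components

**SAM screen.** The moderated statistic is
d_i = (x̄₁ − x̄₂) / (s_i + s₀) with s_i the pooled standard error and s₀
a fudge factor that stabilizes low-variance features. Default
s₀ = median(s_i); a percentile scan minimizing the coefficient of
variation of the d-spread across s-bins is selectable
(`s0_rule="percentile_min_cv"`). FDR: group labels are permuted
(default 1,000 draws; all distinct assignments when fewer exist), and
the q-value at threshold t = |d_i| is the median permutation count of
|d*| ≥ t divided by the observed count, capped at 1 and forced monotone
non-increasing in |d|. This is deliberately simple (no π₀ estimate), so
q-values are mildly conservative. Screening keeps q < 0.05 AND
fold change > 2, both strict; "FC > 2" is interpreted symmetrically as
max(case/control, control/case) > 2, i.e. |Δlog2| > 1.

**miRNA screen.** The smaller miRNA designs are screened on fold change
alone after per-array background subtraction (2nd-percentile constant,
floored at ε = 10⁻³ intensity units) quantile normalization and log2.
No significance column is produced in this mode (q is NaN): the
fold-change-only rule is the documented contract, and an optional
q-value would suggest evidence the design does not support.

**Hypergeometric tails.** Two conventions are exposed because the
cumulative crosstalk formula is sometimes printed with its sum running
through k = x, which equals P(X > x) rather than the conventional
P(X ≥ x). `at_least` (P(X ≥ x), the one-sided Fisher tail) is the
default everywhere; `as_printed` (P(X > x)) is one argument away. The
two satisfy at_least(x) = as_printed(x−1), which the tests verify on an
exhaustive rational-arithmetic grid up to N = 30.

**Background N.** "All genes in the genome" is not observable from the
inputs, so the default background is the union of all genes annotated
in the loaded collection (`background_size: auto`), overridable with an
integer (the universe is then padded with unannotated placeholders so
only N changes). Annotation sets smaller than 2 genes in the background
are skipped.

**GO adjustment.** Benjamini–Hochberg step-up within each namespace
(BP/MF/CC separately), because term counts are conventionally reported
per namespace; selection is strict (adjusted p < 0.05).

**Crosstalk clustering.** Complete-linkage agglomeration on Euclidean
distances between rows of the −log₁₀ P matrix (p floored at 10⁻³⁰⁰;
scipy's deterministic lowest-index merge ordering). The default flat
cut is placed in the middle of the largest gap between successive merge
heights: block structure produces many low merges and few high ones,
and the gap cut separates them without a hand-tuned height. Both an
explicit height and a target cluster count remain available. With an
all-zero matrix a single cluster is returned with a warning.

**LAP mining.** Signature genes default to key-gene candidates (DE
pathway nodes that are consensus targets of an inversely DE miRNA);
`targets` and `de` modes relax this. Pairwise shortest-path distances
are computed on the symmetrized graph; signature pairs meeting the
distance constraint form an auxiliary graph whose maximal cliques
(Bron–Kerbosch, via networkx) are the LAPs. The strict convention
"distance < k" is the default (k = 4 ⇒ d ≤ 3); the inclusive "≤ k"
convention used by some subpathway tools is `strict=False`. The
k-constraint applies to signature genes only; linker genes on at least
one shortest path between signature pairs are added for context. LAPs
of two signature genes are legitimate (`min_signature=2`).

**miRNA clusters.** Single-linkage chaining of same-chromosome loci
with consecutive end-to-start gaps ≤ 10 kb (inclusive), so a cluster
may span more than 10 kb overall; overlapping loci always co-cluster
and strand is ignored. The gap is measured end-to-start rather than
start-to-start — configurable only through the interval coordinates
themselves, since end-to-start is the natural reading of "distance
between two genes".

## The synthetic study

Defaults are the study conditions, scaled to desk size: 20 cases vs 10
controls; 2,000 genes with 100 planted up and 100 down (|Δlog2| = 1.5,
Gaussian noise σ = 0.5 in log2 scale); 200 miRNA probes with 21 up /
25 down planted and ~3% empty background-level probes; 10 prediction
tools at sensitivity 0.8 and false-positive rate 0.005 per pair; 20
pathways of 30 genes of which 2 up and 4 down are planted dysregulated;
k = 4 and 10 kb as in the analysis defaults.

Design choices worth knowing:

* **Crosstalk blocks.** The planted up pathways form one block and the
  down pathways another. Each block carries `n_shared = 5` mediator
  genes present in *every* block member, so every within-block pair
  overlaps in exactly 5 genes and cross-block pairs in none. Five was
  chosen so the overlap is significant (P ≈ 10⁻²–10⁻³) under the
  auto background of ≈ 600 genes; one or two shared genes are *not*
  significant at that background size, mirroring the real situation
  where only substantial sharing survives a genome-wide null.
* **Key genes.** Each planted pathway carries its block's 5 mediators
  plus 2 pathway-specific key genes, all DE with the pathway's
  direction and all targeted by the pathway's regulator miRNAs
  (12 up-regulating miRNAs wired to down pathways, 2 down to up
  pathways); 6 further DE-but-untargeted genes per pathway strengthen
  the mRNA enrichment without entering the key-gene set.
* **Graphs.** Each planted pathway graph contains a clique over all but
  one of its key genes (the planted LAP) and places the remaining key
  gene exactly k edges away through a linker chain, with all other
  nodes attached on the clique side so no shortcut arises. Background
  pathways get random connected graphs.
* **Array artefacts.** mRNA arrays receive a monotone intensity bias
  (amplitude ±0.2, tanh-shaped) for the lowess step to remove; miRNA
  arrays receive a multiplicative array scale and an additive
  background (20–40 intensity units) for the preprocessing chain to
  undo. Empty probes anchor the 2nd-percentile background estimate.
* **Randomness.** One seed fans out through named per-simulation
  generators (CRC-keyed seed sequences), so adding a sub-simulation
  never perturbs another's stream; equal seeds give bitwise-identical
  bundles.

What the generator does **not** emulate: probe-level summarization,
batch or dye effects, correlated noise between genes, annotation
incompleteness, and the heavy redundancy of real prediction databases.
Passing tests therefore demonstrate the correctness and calibration of
the statistical machinery under its stated assumptions, not performance
on any particular clinical dataset.

## Problem sizes and determinism

The default bundle (2,000 × 30 mRNA matrix, 1,000 permutations, 20
pathways) runs the full pipeline in well under a minute on one CPU;
the test suite uses 200-permutation SAM runs for its calibration and
power checks (2,000 features, 10 vs 10). All stochastic steps are
seeded; permutation FDR, the generator and the pipeline are
deterministic given their seeds.

## Known limitations

* Permutation q-values are granular at small permutation counts and
  conservative without a π₀ estimate.
* With very small groups (e.g. 3 vs 3) the distinct-permutation space
  is tiny (C(6,3) = 20); the FDR floor is then 1/20-ish and the screen
  effectively degrades toward fold-change ranking.
* The miRNA FC-only screen has no error control by design; its false
  calls are harmless downstream only because un-targeted miRNAs cannot
  contribute to the pathway quadrants.
* Per-miRNA pathway attribution re-runs enrichment on each single
  miRNA's target set; with block-level mediators a miRNA regulating one
  pathway of a block is usually attributed to the whole block — a
  faithful consequence of shared membership, not a bug.
* Quantile normalization slightly compresses large planted miRNA fold
  changes; recovery at |Δlog2| = 1.5 is ~80–90% rather than complete.
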