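# Methods

This note documents the models, conventions and numerical choices behind
`cnmod`, and what the synthetic validation does and does not establish.

## Copy-number calling model

Input profiles are assumed already corrected for tumour ploidy and
normal-cell contamination (e.g. by an allele-specific segmentation tool);
the per-sample ploidy and aberrant cell fraction accompany the segments, and
the aberrant cell fraction is carried as metadata only.  Calls are made
relative to each tumour's own ploidy, not to 2n — essential in a cohort
whose mean ploidy is near-triploid.

* **Call threshold δ = 0.9 copies, strict inequality.** A segment is gained
  iff `cn − ploidy > 0.9` and lost iff `ploidy − cn > 0.9`.  The strict
  reading makes the boundary case neutral; boundary ties are rare relative
  to the ambiguity cost of an inclusive rule.  Note that with binary floats
  a nominally exact boundary like `3.7 − 2.8` may land on either side; the
  threshold is a continuous parameter, not a place to encode semantics.
* **Minimum 10 consecutive markers** per called segment; fewer markers make
  a call unreliable regardless of amplitude.
* **Masking**: segments whose overlap with the union of telomere/centromere/
  segmental-duplication masks exceeds 50% of the segment length are removed
  (strict >, union not per-mask maximum).  Masking is idempotent.
* **Gene projection by midpoint.** A gene inherits the copy number and call
  of the segment containing its midpoint; a gene with no covering segment is
  treated as unaltered at ploidy.  The midpoint rule is our convention for
  breakpoint-spanning genes — unambiguous and order-independent; how genes
  overlapping two aberrant segments should be resolved is otherwise
  underdetermined.
* **Recurrence** is evaluated per gene (not per marker or per segment), at
  an inclusive ≥ 20% of samples.
* A LogR export threshold of ±0.12 is kept as a constant
  (`segments.LOGR_EXPORT_THRESHOLD`) for preparing input to an external
  region-significance tool; it plays no role internally.

## Region significance

The built-in scorer is a deliberately simple permutation surrogate for
dedicated tools (whose all-lesions output `read_gistic_lesions` consumes as
the fidelity path).  Per gene and direction the score is the summed
amplitude `Σ_s max(0, ±(cn − ploidy))`.  The null cyclically rotates each
sample's gene-order amplitude vector by an independent uniform offset —
preserving within-sample spatial autocorrelation, the property a proper
background model must respect — and the empirical p is the fraction of null
scores ≥ observed (non-strict, so a flat cohort yields p = 1 everywhere
rather than spuriously small p).  BH-FDR per direction; maximal runs of
genome-adjacent genes with q < 0.25 form regions (region score = peak gene
score, region q = the run minimum).  Internal coordinates are 0-based
half-open everywhere; SEG input is treated as 1-based inclusive and
converted on read, BED is read natively, GISTIC peak coordinates are
converted from 1-based inclusive.

## Copy-number/expression association

Only genes inside significant regions are tested.  The test statistic is
the sample Pearson r; the null permutes the expression matrix's sample
labels as whole columns, one shared permutation per iteration across all
genes, which preserves the inter-gene correlation structure of the null.
The p-value follows the one-sided counting formula
`p = #(r_perm > r_obs)/N` with N = 1,000 by default: both
gains-with-higher-expression and losses-with-lower-expression produce
positive r, so the positive tail is the direction of interest.  Ties
(`r_perm = r_obs`) do not count, and p = 0 is reported as printed by the
formula; an add-one smoothing `(1+count)/(1+N)` is available behind a flag,
default off.  Genes with zero variance in either vector are flagged
degenerate and excluded from testing and from the BH correction.  Selection
threshold: BH-FDR q < 0.1.

## Network assembly

Drivers (selected genes) are mapped onto the reference interactome; genes
absent from it are dropped with a logged count.  Direct edges are
interactome edges with both ends altered; linker candidates are non-altered
nodes adjacent to ≥ 2 altered genes (a driver pair may be bridged by several
linkers).  Each candidate's enrichment is hypergeometric: population
N = |interactome| − 1 (the candidate cannot be its own neighbour — our
convention), successes = altered genes present in the interactome, draws =
the candidate's global degree, upper tail at the observed altered-neighbour
count, BH-FDR across candidates at q < 0.05 (FDR rather than a family-wise
correction, consistent with the other stages).  The network is the induced
subgraph on connected drivers plus accepted linkers, reduced to its largest
connected component; fragments are reported as dropped, not silently
discarded.  A driver altered in both directions across samples is labelled
with its more frequent direction, ties resolving to gain.  The
connectedness null redraws equally many interactome genes uniformly and
re-runs the identical induction/testing/assembly (same linker FDR — the
null must mirror the observed procedure), with
`p = #(size_random > size_obs)/N` separately for nodes and edges.

## Module detection and the modularity null

Girvan–Newman edge-betweenness decomposition, with the partition taken at
the dendrogram cut maximizing Newman modularity
`Q = Σ_c [e_c/m − (d_c/2m)²]`; among equally good cuts the coarsest wins.
The dendrogram is computed by igraph's C implementation of the algorithm;
nodes and edges are handed over in lexicographically sorted order, making
the result deterministic for a given graph.  `modularity()` itself is an
independent re-implementation of the formula used to score the returned
partition (and, in the tests, to enumerate all dendrogram cuts).

The null model randomizes the network by double edge swaps — rewiring edge
pairs (a,b),(c,d) to (a,d),(c,b) unless a self-loop or duplicate would
result — which preserves the exact degree multiset.  Each of the (default
1,000) null networks applies 10 attempted swaps per edge (a standard burn-in
for degree-preserving randomization) and is re-decomposed with the same
algorithm.  Reported: the scaled modularity score
`(Q_obs − mean Q_null)/sd Q_null` and the empirical
`p = #(Q_null ≥ Q_obs)/N`.  Hubs: global hubs are all nodes with degree at
or above the k-th largest, k = ⌊0.05·n⌋ (ties therefore can push the table
beyond k rows); per-module hubs maximize within-module degree with
lexicographic tie-breaks.  Singleton and very small modules are permitted.

## Annotation and survival

Module enrichment is a hypergeometric upper-tail test per module × term,
BH-adjusted across all tests, against a background defaulting to all
interactome genes (enrichment is judged against what the interactome could
produce).  No particular annotation database is bundled; any GMT collection
works, which keeps results decoupled from database versions.

Survival uses Kaplan–Meier estimates and the two-group log-rank test (via
lifelines).  The per-gene screen compares copy-number-lost against neutral
samples; gained samples are excluded rather than pooled, since pooling would
dilute the neutral reference with a differently altered group.  Groups
smaller than 3 are skipped (the log-rank statistic is degenerate below
that).  The ploidy comparison splits at ploidy > 3 (strict; a tumour at
exactly 3n is "low").  The statistic is the standard log-rank chi-square
with 1 df; where a source labels this comparison simply "Chi-square", we
implement the log-rank variant and note the naming looseness.

## Synthetic cohort: what it emulates

`SyntheticConfig` defaults encode the emulated study conditions: 41
samples, per-sample ploidy ~ Normal(2.8, 0.3) truncated at 1.5 (matching
the reported near-triploid spread without modelling the segmentation tool),
a recorded mean normal-cell fraction of 31%, and five planted 12-gene
modules.  Design choices:

* **Planted modules are genomic blocks.** Each module is a
  clique-with-dropout (within-module edge probability 0.8) on a
  Barabási–Albert background (attachment 2 — heavy-tailed degrees), and its
  genes occupy one contiguous block, so one recurrent event hits the whole
  module.  This constructs, controllably, the premise that heterogeneous
  alterations converge on shared modules.  Modules alternate gain/loss; the
  first loss module's genes carry the survival hazard.
* **Events**: carried per sample with probability 0.5 (alteration
  penetrance), amplitude drawn uniformly in [1.0, 2.0] copies — always
  beyond the 0.9 threshold.  Marker counts are uniform in [10, 200]; two
  5-marker high-amplitude decoy segments per sample deliberately sit below
  the marker threshold so the rule is exercised from both sides.  Segment
  length and marker-density distributions are conventions, not facts about
  any particular dataset.
* **Expression**: causal (planted) genes follow
  `expr = 1.0·cn + Normal(0, 1.1)`; with the copy-number variance the
  planted events induce, this places the dosage correlation near r ≈ 0.6 at
  n = 41 — a moderate, realistic effect.  All other genes are a fixed
  baseline plus unit noise, independent of copy number.
* **Survival**: exponential times at a 60-month baseline median; samples
  with a loss call in any risk gene have their hazard multiplied by 5.
  Censoring is an independent exponential whose rate sets the expected
  censored fraction to 20% under the baseline hazard; a censor rate of 1 is
  special-cased to censor everything.
* Every generator is a pure function of the config seed through named
  substreams; same seed, bit-identical output.

What passing the synthetic suite does **not** show: robustness to
segmentation artefacts, probe-level expression noise and batch effects,
allele-specific events, subclonal fractions, interactome ascertainment bias
(literature-biased degree), or overlapping biological modules.  Real-data
behaviour additionally depends on the upstream segmentation and
normalization, both out of scope here.

## Problem sizes and replicate counts

Defaults mirror the emulated analysis (1,000 permutations for association,
connectedness and the modularity null).  The bundled fixture configs and
analysis scripts use desk-scale replicate counts (100–200 draws for the
resampling nulls; 50 edge-swap networks at the 5,000-gene fixture scale,
where one Girvan–Newman decomposition of the ~300-node network costs a few
seconds), chosen as the package's own convention for interactive work; the
statistical acceptance tests run the edge-swap null at the full 1,000
networks on the 600-gene cohort.  `cnmod run --perms F` scales all null
counts uniformly.

## Numerical conventions and degenerate inputs

* BH-FDR is the standard step-up adjustment (via statsmodels), capped at 1,
  mapped back to input order; validated against the direct formula in tests.
* Hypergeometric tails come from scipy; exact-enumeration oracles cover all
  small instances in tests.
* Empty networks, one-sided ploidy splits, zero-event survival tables,
  degree-0 linker candidates, and graphs with no legal edge swap raise
  errors naming the condition rather than returning silent defaults.
* All tabular writers emit floats at %.10g so identical results are
  byte-identical on disk; the pipeline manifest records the config hash,
  seed and per-stage row counts.
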